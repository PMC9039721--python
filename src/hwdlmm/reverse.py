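"""Reverse (retrospective) regression: genotype regressed on phenotype.

The forward LMM uses a kinship-based covariance for the *phenotype*,
which is what makes its heritability nuisance parameter absorb — and be
biased by — HWD at causal SNPs.  The retrospective alternative swaps
the roles: the tested SNP's genotypes are the response,

    g = alpha 1 + beta y + gamma z + eps,   Var(eps) = Sigma_g,

and ``Sigma_g`` models the *genotype* covariance directly: kinship plus
HWD at the tested locus, with per-family 2x2 blocks

    [[v_hat, c_hat], [c_hat, v_hat]],
    v_hat = 2 (p_hat (1 - p_hat) + delta_hat),

where ``v_hat`` is the HWD-adjusted genotype variance and ``c_hat`` the
within-pair genotype covariance estimated by moments (absorbing both
kinship and HWD at the tested SNP).  Since the score statistic is
invariant to the overall scale of ``Sigma_g``, only the ratio
``c_hat / v_hat`` matters.

When the reverse covariance blocks are numerically equal (up to scale)
to the forward model's phenotype covariance blocks, the two score
statistics coincide exactly; the gain is that ``Sigma_g`` is estimable
from genotype moments at the tested SNP, keeping the test size correct
even when HWD at causal SNPs distorts the phenotype covariance.

Genotypes are treated as continuous in the linear model; the score-test
construction requires only correct first and second moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hwd import sample_hwd_stats
from .lmm import AssocTestResult, _pair_design, _projected_score, chisq1_pvalue

__all__ = ["GenotypeCovModel", "estimate_genotype_covariance", "reverse_score_test"]

_R_CAP = 1.0 - 1e-8  # genotype correlation kept away from +-1 so blocks stay PD


@dataclass(frozen=True)
class GenotypeCovModel:
    """Per-family 2x2 genotype covariance blocks ``[[v, c], [c, v]]``."""

    p_hat: float
    delta_hat: float
    v_hat: float
    c_hat: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.v_hat < 0:
            raise ValueError("genotype variance must be non-negative")
        if abs(self.c_hat) > self.v_hat + 1e-12:
            raise ValueError("|c_hat| must not exceed v_hat (block must be PSD)")

    @property
    def pair_correlation(self) -> float:
        """Within-pair genotype correlation implied by the blocks.

        Clipped into ``(-1, 1)`` so the block stays positive definite
        at boundary HWD (the clip is inactive in non-degenerate cases).
        """
        if self.v_hat <= 0.0:
            raise ValueError("degenerate genotype covariance (monomorphic SNP)")
        return float(np.clip(self.c_hat / self.v_hat, -_R_CAP, _R_CAP))

    def block(self) -> np.ndarray:
        if self.v_hat <= 0.0:
            raise ValueError("degenerate genotype covariance (monomorphic SNP)")
        r = self.pair_correlation
        return self.v_hat * np.array([[1.0, r], [r, 1.0]])


def estimate_genotype_covariance(g: np.ndarray) -> GenotypeCovModel:
    """Moment estimate of the sib-pair genotype covariance at one SNP.

    ``p_hat`` and ``delta_hat`` come from the pooled genotype vector
    (both sibs), giving the HWD-adjusted variance
    ``v_hat = 2(p_hat(1-p_hat) + delta_hat)``; ``c_hat`` is the
    divisor-n within-pair sample covariance about the pooled mean,
    clipped into ``[-v_hat, v_hat]`` so every block is PSD.
    """
    g = np.asarray(g, dtype=float)
    if g.ndim != 2 or g.shape[1] != 2:
        raise ValueError("g must have shape (n_pairs, 2)")
    n = g.shape[0]
    if n < 10:
        raise ValueError("at least 10 pairs are required for stable moment estimates")
    p_hat, delta_hat, v_hat = sample_hwd_stats(g.ravel())
    if v_hat == 0.0:
        raise ValueError("monomorphic tested SNP: genotype covariance model is degenerate")
    mu = g.mean()
    c_hat = float(((g[:, 0] - mu) * (g[:, 1] - mu)).mean())
    c_hat = float(np.clip(c_hat, -v_hat, v_hat))
    return GenotypeCovModel(
        p_hat=p_hat, delta_hat=delta_hat, v_hat=v_hat, c_hat=c_hat, n_pairs=n
    )


def _whiten_blocks(a: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Whiten (n, 2, ...) data by the Cholesky factor of one 2x2 block."""
    try:
        L = np.linalg.cholesky(block)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular genotype covariance block after regularization") from err
    w = np.linalg.solve(L, np.moveaxis(np.asarray(a, dtype=float), 1, 0).reshape(2, -1))
    return w.reshape((2,) + a.shape[:1] + a.shape[2:]).reshape(2 * a.shape[0], *a.shape[2:])


def reverse_score_test(
    g: np.ndarray,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    cov_model: Optional[GenotypeCovModel] = None,
) -> AssocTestResult:
    """Score test of no association from the retrospective genotype model.

    Tests ``beta = 0`` in ``g = alpha 1 + beta y + gamma z + eps`` with
    ``Var(eps)`` given by the genotype covariance blocks (estimated from
    the tested SNP itself when ``cov_model`` is omitted).  The statistic
    is the same GLS projector construction as the forward LMM score test
    with the roles of ``g`` and ``y`` swapped, referred to chi-square
    with 1 df.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape != g.shape or g.ndim != 2 or g.shape[1] != 2:
        raise ValueError("g and y must both have shape (n_pairs, 2)")
    if cov_model is None:
        cov_model = estimate_genotype_covariance(g)
    block = cov_model.block()
    X = _pair_design(g.shape[0], covariates)
    stat = _projected_score(
        _whiten_blocks(g, block), _whiten_blocks(y, block), _whiten_blocks(X, block)
    )
    return AssocTestResult(
        statistic=stat, p_value=chisq1_pvalue(stat), method="reverse", nuisance=cov_model
    )


def reverse_score_many(y: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Vectorized reverse-regression score statistics across replicates.

    For each replicate the genotype covariance model is estimated from
    that replicate's tested-SNP genotypes; since the statistic depends
    on the blocks only through ``c_hat / v_hat``, the computation reuses
    the correlation-parameterized pair quadratic forms.
    """
    from .lmm import lmm_score_many

    g = np.asarray(g, dtype=float)
    gm = g.mean(axis=(1, 2))
    p_hat = gm / 2.0
    freq2 = (g == 2).mean(axis=(1, 2))
    delta_hat = freq2 - p_hat**2
    v_hat = 2.0 * (p_hat * (1.0 - p_hat) + delta_hat)
    gc = g - gm[:, None, None]
    c_hat = (gc[:, :, 0] * gc[:, :, 1]).mean(axis=1)
    c_hat = np.clip(c_hat, -v_hat, v_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip(c_hat / v_hat, -_R_CAP, _R_CAP)
    return lmm_score_many(y, g, r)
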