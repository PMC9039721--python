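"""Algebra of Hardy-Weinberg disequilibrium at a biallelic locus.

For a biallelic SNP with alleles ``A`` (frequency ``p``) and ``a``
(frequency ``1 - p``), Hardy-Weinberg equilibrium (HWE) states that the
three genotype frequencies are the binomial proportions
``(1-p)^2, 2p(1-p), p^2``.  Departure from HWE (Hardy-Weinberg
disequilibrium, HWD) is measured here by the classical coefficient

    delta = P(AA) - p^2,

so that the genotype frequencies become::

    P(aa) = (1-p)^2 + delta
    P(Aa) = 2p(1-p) - 2*delta
    P(AA) = p^2     + delta

Equivalently ``delta = p(1-p) F`` where ``F`` is the inbreeding
coefficient, the correlation between the two alleles carried by one
individual.  ``delta`` is the canonical parameter throughout the
package; ``F`` is a derived view.

The module also provides the sample-moment identity
``var_hat(G) = 2(p_hat(1-p_hat) + delta_hat)`` that makes ordinary
(independent-sample) association score tests self-adjusting for HWD,
the one-degree-of-freedom Pearson chi-square HWE test, and the
closed-form expected bias of the sib-pair LMM heritability estimate
when causal SNPs are in HWD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "HWDSpec",
    "GenotypeFreqs",
    "CausalLocus",
    "HWETestResult",
    "delta_bounds",
    "genotype_freqs",
    "delta_from_freqs",
    "inbreeding_from_delta",
    "delta_from_inbreeding",
    "genotype_variance",
    "sample_hwd_stats",
    "hwe_chisq_test",
    "heritability_bias",
]

#: slack used when validating delta against its admissible interval,
#: so that analytically exact boundary values survive float round-off
_BOUND_TOL = 1e-12


def delta_bounds(p: float) -> tuple[float, float]:
    """Admissible range of the HWD coefficient at allele frequency ``p``.

    Non-negativity of the three genotype frequencies forces
    ``delta in [max(-p^2, -(1-p)^2), p(1-p)]`` (a closed interval; the
    endpoints give degenerate but valid distributions).

    Parameters
    ----------
    p : allele frequency of ``A``, strictly inside (0, 1).

    Returns
    -------
    (delta_min, delta_max)
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency p must be in (0, 1), got {p!r}")
    q = 1.0 - p
    return max(-p * p, -q * q), p * q


@dataclass(frozen=True)
class HWDSpec:
    """A locus described by allele frequency ``p`` and HWD coefficient ``delta``.

    ``p`` may be 0 or 1 (monomorphic locus) only with ``delta == 0``.
    """

    p: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0 or not np.isfinite(self.p):
            raise ValueError(f"allele frequency p must be in [0, 1], got {self.p!r}")
        if self.p in (0.0, 1.0):
            if self.delta != 0.0:
                raise ValueError("monomorphic locus (p in {0, 1}) requires delta = 0")
            return
        lo, hi = delta_bounds(self.p)
        if self.delta < lo - _BOUND_TOL:
            which = "P(AA)" if -self.p**2 > -((1 - self.p) ** 2) else "P(aa)"
            raise ValueError(
                f"delta={self.delta} below admissible minimum {lo} at p={self.p}: "
                f"{which} would be negative"
            )
        if self.delta > hi + _BOUND_TOL:
            raise ValueError(
                f"delta={self.delta} above admissible maximum {hi} at p={self.p}: "
                "P(Aa) would be negative"
            )

    @property
    def f(self) -> float:
        """Inbreeding coefficient ``F = delta / (p(1-p))`` (0 for monomorphic loci)."""
        return inbreeding_from_delta(self)


@dataclass(frozen=True)
class GenotypeFreqs:
    """Population genotype frequencies ``(P(aa), P(Aa), P(AA))``."""

    p_aa: float
    p_Aa: float
    p_AA: float

    def __post_init__(self) -> None:
        freqs = (self.p_aa, self.p_Aa, self.p_AA)
        for name, f in zip(("p_aa", "p_Aa", "p_AA"), freqs):
            if not -1e-12 <= f <= 1.0 + 1e-12:
                raise ValueError(f"{name}={f} is not a probability")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies must sum to 1, got {sum(freqs)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_aa, self.p_Aa, self.p_AA])


def genotype_freqs(spec: HWDSpec) -> GenotypeFreqs:
    """Genotype frequencies ``((1-p)^2 + d, 2p(1-p) - 2d, p^2 + d)``."""
    p, d = spec.p, spec.delta
    q = 1.0 - p
    return GenotypeFreqs(
        p_aa=max(q * q + d, 0.0),
        p_Aa=max(2.0 * p * q - 2.0 * d, 0.0),
        p_AA=max(p * p + d, 0.0),
    )


def delta_from_freqs(freqs: GenotypeFreqs) -> HWDSpec:
    """Invert :func:`genotype_freqs`: ``p = P(AA) + P(Aa)/2``, ``delta = P(AA) - p^2``."""
    p = freqs.p_AA + 0.5 * freqs.p_Aa
    return HWDSpec(p=p, delta=freqs.p_AA - p * p)


def inbreeding_from_delta(spec: HWDSpec) -> float:
    """Inbreeding coefficient ``F = delta / (p(1-p))``.

    For a monomorphic locus the allele correlation is undefined; 0 is
    returned by convention (delta is necessarily 0 there).
    """
    pq = spec.p * (1.0 - spec.p)
    if pq == 0.0:
        return 0.0
    return spec.delta / pq


def delta_from_inbreeding(p: float, f: float) -> HWDSpec:
    """Locus spec from allele frequency and inbreeding coefficient: ``delta = p(1-p)F``."""
    return HWDSpec(p=p, delta=p * (1.0 - p) * f)


def genotype_variance(spec: HWDSpec) -> float:
    """Population variance of the genotype ``G in {0, 1, 2}``: ``2(p(1-p) + delta)``."""
    return 2.0 * (spec.p * (1.0 - spec.p) + spec.delta)


def _validate_genotypes(g: Iterable[float]) -> np.ndarray:
    arr = np.asarray(g)
    if arr.size == 0:
        raise ValueError("empty genotype vector")
    if not np.isin(arr, (0, 1, 2)).all():
        bad = arr[~np.isin(arr, (0, 1, 2))]
        raise ValueError(f"genotype codes must be in {{0, 1, 2}}; found {bad[:5]!r}")
    return arr.astype(float)


def sample_hwd_stats(g: Iterable[float]) -> tuple[float, float, float]:
    """Sample allele frequency, HWD coefficient, and genotype variance.

    Returns ``(p_hat, delta_hat, var_hat)`` where ``p_hat = mean(g)/2``,
    ``delta_hat = freq(g == 2) - p_hat^2`` and ``var_hat`` is the
    divisor-``n`` sample variance.  These satisfy the exact identity

        var_hat = 2 * (p_hat * (1 - p_hat) + delta_hat)

    which is why the ordinary (independent-sample) score statistic
    inherently adjusts for HWD.
    """
    arr = _validate_genotypes(g).ravel()
    p_hat = arr.mean() / 2.0
    delta_hat = np.mean(arr == 2) - p_hat * p_hat
    var_hat = arr.var()
    return float(p_hat), float(delta_hat), float(var_hat)


@dataclass(frozen=True)
class HWETestResult:
    """Pearson chi-square HWE goodness-of-fit test (1 df)."""

    chi2: float
    p_value: float
    df: int = 1
    monomorphic: bool = False


def hwe_chisq_test(counts: Sequence[int]) -> HWETestResult:
    """Pearson chi-square test of HWE from genotype counts ``(n_aa, n_Aa, n_AA)``.

    Expected counts are ``n * genotype_freqs(p_hat, 0)``; no continuity
    correction.  When ``p_hat not in {0, 1}`` the statistic equals
    ``n * delta_hat^2 / (p_hat^2 (1 - p_hat)^2)``.  A monomorphic sample
    is flagged and given statistic 0, p-value 1.
    """
    n_aa, n_Aa, n_AA = counts
    if min(n_aa, n_Aa, n_AA) < 0 or any(c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts!r}")
    n = n_aa + n_Aa + n_AA
    if n < 1:
        raise ValueError("at least one observation is required")
    p_hat = (2 * n_AA + n_Aa) / (2 * n)
    if p_hat in (0.0, 1.0):
        return HWETestResult(chi2=0.0, p_value=1.0, monomorphic=True)
    expected = n * genotype_freqs(HWDSpec(p=p_hat)).as_array()
    observed = np.array([n_aa, n_Aa, n_AA], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HWETestResult(chi2=chi2, p_value=float(stats.chi2.sf(chi2, df=1)))


@dataclass(frozen=True)
class CausalLocus:
    """One causal SNP: per-allele effect ``beta`` on the phenotype scale and its locus law."""

    beta: float
    p: float
    delta: float = 0.0

    @property
    def spec(self) -> HWDSpec:
        return HWDSpec(p=self.p, delta=self.delta)

    def __post_init__(self) -> None:
        self.spec  # noqa: B018 - validates (p, delta)


def heritability_bias(h2: float, arch: Sequence[CausalLocus]) -> float:
    """Expected bias of the sib-pair LMM heritability estimate under HWD.

    With causal SNPs ``k = 1..S`` of effect ``beta_k``, allele frequency
    ``p_k`` and HWD coefficient ``delta_k``, the estimate based on twice
    the sib phenotype correlation has expected bias

        E[h2_hat] - h2 = h2 * sum(beta_k^2 delta_k) / sum(beta_k^2 p_k (1-p_k)),

    reducing to ``h2 * delta / (p (1-p))`` for a single causal SNP.
    The bias is positive when the effect-weighted HWD is positive
    (heterozygote deficit at causal loci) and negative otherwise.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"true heritability must be in (0, 1], got {h2!r}")
    loci = list(arch)
    if not loci:
        raise ValueError("the causal architecture must contain at least one locus")
    betas2 = np.array([loc.beta**2 for loc in loci])
    pq = np.array([loc.p * (1.0 - loc.p) for loc in loci])
    deltas = np.array([loc.delta for loc in loci])
    denom = float(betas2 @ pq)
    if denom == 0.0:
        raise ValueError(
            "heritability bias undefined: all effects are zero or all loci monomorphic"
        )
    return h2 * float(betas2 @ deltas) / denom
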