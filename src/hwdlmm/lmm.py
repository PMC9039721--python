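"""Sib-pair linear mixed model: heritability estimation and association score tests.

The null model for phenotypes ``y`` of paired relatives is

    y = X alpha + eps,   eps ~ N(0, sigma_y^2 Sigma_y),
    Sigma_y = h2 * Sigma_Phi + (1 - h2) * I,

where ``Sigma_Phi`` is the kinship matrix with entries ``2 phi`` off the
diagonal within a family (``phi = 1/4`` for full siblings) and 1 on the
diagonal.  For a pair, the intra-pair phenotype correlation is
``r = 2 phi h2``, so ``h2`` is identified as ``corr(Y1, Y2)/(2 phi)``
and may legitimately exceed 1 (or be negative) without truncation; the
search domain is the full positive-definite range ``|2 phi h2| < 1``.

Estimation profiles the Gaussian likelihood: for each ``h2`` the mean
coefficients and ``sigma_y^2`` have closed GLS forms after a per-family
whitening transform, leaving a 1-D maximization over ``h2``.  Both
maximum likelihood (``ml``) and residual maximum likelihood (``reml``,
the default) are available; REML removes most of the O(1/n) downward
bias the ML intraclass-correlation estimate carries in small samples.

Association score tests refer the squared GLS partial correlation
statistic ``T = N * (g' P y)^2 / ((g' P g)(y' P y))`` (with ``P`` the
null-covariance projector removing the fixed effects) to chi-square
with 1 df.  At identity kinship this reduces exactly to the classical
independent-sample score statistic, which is robust to HWD because its
denominator contains the HWD-adjusted genotype variance
``2(p_hat(1-p_hat) + delta_hat)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KinshipMatrix",
    "LMMFit",
    "AssocTestResult",
    "fit_null_lmm",
    "fit_h2_pairs",
    "lmm_score_test",
    "lmm_score_many",
    "indep_score_test",
    "chisq1_pvalue",
]

_EPS = 1e-6  # distance kept from the positive-definiteness boundary |r| = 1


@dataclass(frozen=True)
class KinshipMatrix:
    """Block-diagonal kinship for ``n_pairs`` families of two members.

    Within a family the matrix ``Sigma_Phi`` has unit diagonal and
    off-diagonal ``2 phi``; ``phi`` may be a scalar (constant
    relatedness, e.g. 1/4 for full sibs) or a per-family array.
    """

    n_pairs: int
    phi: Union[float, np.ndarray] = 0.25

    def pair_correlations(self, h2: float) -> np.ndarray:
        """Intra-pair model correlation ``r_i = 2 phi_i h2`` for each family."""
        return np.broadcast_to(2.0 * np.asarray(self.phi) * h2, (self.n_pairs,)).astype(float)

    @property
    def phi_max(self) -> float:
        return float(np.max(np.abs(self.phi)))

    def h2_bounds(self) -> tuple[float, float]:
        """Open interval of ``h2`` keeping every family block positive definite."""
        if self.phi_max == 0.0:
            return (-np.inf, np.inf)
        hb = (1.0 - _EPS) / (2.0 * self.phi_max)
        return (-hb, hb)

    @classmethod
    def sib_pairs(cls, n_pairs: int) -> "KinshipMatrix":
        return cls(n_pairs=n_pairs, phi=0.25)

    def to_dense(self, h2: float = 1.0) -> np.ndarray:
        """Dense ``Sigma = h2 Sigma_Phi + (1-h2) I`` (family-major individual order)."""
        r = self.pair_correlations(h2)
        out = np.zeros((2 * self.n_pairs, 2 * self.n_pairs))
        for i, ri in enumerate(r):
            out[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = [[1.0, ri], [ri, 1.0]]
        return out


@dataclass(frozen=True)
class LMMFit:
    """Null-model fit: untruncated heritability estimate and variance scale."""

    h2_hat: float
    sigma_y2_hat: float
    loglik: float
    converged: bool
    mode: str  # "fixed" | "estimated"
    method: str  # "ml" | "reml"
    n_pairs: int
    boundary: bool = False


@dataclass(frozen=True)
class AssocTestResult:
    """Score test result referred to chi-square with 1 df."""

    statistic: float
    p_value: float
    method: str  # "indep" | "lmm_fixed_h2" | "lmm_estimated_h2" | "reverse"
    df: int = 1
    nuisance: Optional[object] = None


def chisq1_pvalue(statistic: float) -> float:
    """Upper-tail probability of chi-square with one degree of freedom."""
    if statistic < 0:
        raise ValueError(f"score statistic must be non-negative, got {statistic!r}")
    return float(stats.chi2.sf(statistic, df=1))


def _pair_design(n_pairs: int, covariates: Optional[np.ndarray]) -> np.ndarray:
    """Stack intercept and optional per-individual covariates into (n, 2, q)."""
    X = np.ones((n_pairs, 2, 1))
    if covariates is not None:
        z = np.asarray(covariates, dtype=float)
        if z.shape[:2] != (n_pairs, 2):
            raise ValueError(f"covariates must have shape ({n_pairs}, 2[, q])")
        if z.ndim == 2:
            z = z[:, :, None]
        X = np.concatenate([X, z], axis=2)
    return X


def _whiten(a: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Per-family decorrelation of (n, 2, ...) data given pair correlations r.

    Maps each pair ``(a1, a2)`` to ``((a1+a2)/sqrt(2(1+r)), (a1-a2)/sqrt(2(1-r)))``
    so that the transformed errors are i.i.d. with variance sigma^2.
    """
    r = r.reshape((-1,) + (1,) * (a.ndim - 2))
    u = (a[:, 0] + a[:, 1]) / np.sqrt(2.0 * (1.0 + r))
    v = (a[:, 0] - a[:, 1]) / np.sqrt(2.0 * (1.0 - r))
    return np.concatenate([u, v], axis=0)


def _profile_pieces(
    y: np.ndarray, X: np.ndarray, r: np.ndarray
) -> tuple[float, float, float, int]:
    """GLS at fixed pair correlations: (rss, logdet_R, logdet_XtRiX, q)."""
    yw = _whiten(y, r)
    Xw = _whiten(X, r)
    coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < Xw.shape[1]:
        raise ValueError("covariate design is rank deficient")
    resid = yw - Xw @ coef
    rss = float(resid @ resid)
    logdet_r = float(np.log1p(-r * r).sum())
    sign, logdet_x = np.linalg.slogdet(Xw.T @ Xw)
    if sign <= 0:
        raise ValueError("X' Sigma^-1 X not positive definite")
    return rss, logdet_r, float(logdet_x), Xw.shape[1]


def _neg_loglik(h2: float, y, X, kinship: KinshipMatrix, method: str) -> float:
    r = kinship.pair_correlations(h2)
    rss, logdet_r, logdet_x, q = _profile_pieces(y, X, r)
    n_obs = 2 * kinship.n_pairs
    if method == "ml":
        sigma2 = rss / n_obs
        ll = -0.5 * (n_obs * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_r)
    else:  # reml
        dof = n_obs - q
        sigma2 = rss / dof
        ll = -0.5 * (dof * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_r + logdet_x)
    return -ll


def fit_null_lmm(
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    kinship: Optional[KinshipMatrix] = None,
    mode: str = "estimated",
    h2: Optional[float] = None,
    method: str = "reml",
) -> LMMFit:
    """Fit the null (no tested SNP) linear mixed model for paired data.

    Parameters
    ----------
    y : (n_pairs, 2) phenotype array, one column per family member.
    covariates : optional (n_pairs, 2) or (n_pairs, 2, q) fixed-effect
        covariates; an intercept is always included.
    kinship : defaults to full-sib pairs (phi = 1/4).
    mode : "estimated" profiles the likelihood over ``h2``; "fixed"
        plugs in the supplied ``h2``.
    h2 : the fixed heritability (required when ``mode == "fixed"``).
    method : "reml" (default) or "ml".

    The heritability estimate is reported untruncated: values above 1
    (or below 0) are legitimate outcomes of the profile maximization.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must have shape (n_pairs, 2)")
    n_pairs = y.shape[0]
    if kinship is None:
        kinship = KinshipMatrix.sib_pairs(n_pairs)
    if kinship.n_pairs != n_pairs:
        raise ValueError("kinship size does not match data")
    if method not in ("ml", "reml"):
        raise ValueError(f"unknown method {method!r}")
    X = _pair_design(n_pairs, covariates)
    n_obs = 2 * n_pairs

    if mode == "fixed":
        if h2 is None:
            raise ValueError("mode='fixed' requires an h2 value")
        nll = _neg_loglik(h2, y, X, kinship, method)
        r = kinship.pair_correlations(h2)
        rss, _, _, q = _profile_pieces(y, X, r)
        sigma2 = rss / (n_obs if method == "ml" else n_obs - q)
        return LMMFit(
            h2_hat=float(h2),
            sigma_y2_hat=float(sigma2),
            loglik=-nll,
            converged=True,
            mode="fixed",
            method=method,
            n_pairs=n_pairs,
        )
    if mode != "estimated":
        raise ValueError(f"unknown mode {mode!r}")

    lo, hi = kinship.h2_bounds()
    if not np.isfinite(lo):
        # phi == 0: correlation structure is the identity for every h2
        h2_hat = 0.0
        nll = _neg_loglik(0.0, y, X, kinship, method)
        res_x, converged = 0.0, True
    else:
        res = optimize.minimize_scalar(
            _neg_loglik,
            args=(y, X, kinship, method),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        res_x, nll, converged = float(res.x), float(res.fun), bool(res.success)
        h2_hat = res_x
    r = kinship.pair_correlations(h2_hat)
    rss, _, _, q = _profile_pieces(y, X, r)
    sigma2 = rss / (n_obs if method == "ml" else n_obs - q)
    boundary = np.isfinite(lo) and min(h2_hat - lo, hi - h2_hat) < 1e-4 * (hi - lo)
    return LMMFit(
        h2_hat=h2_hat,
        sigma_y2_hat=float(sigma2),
        loglik=-float(nll),
        converged=converged and not boundary,
        mode="estimated",
        method=method,
        n_pairs=n_pairs,
        boundary=bool(boundary),
    )


# ---------------------------------------------------------------------------
# Vectorized intercept-only fits (the replicate-level engine of the
# simulation experiments).  For constant phi and no covariates, the GLS
# intercept is the pooled mean whatever the correlation, so the profile
# reduces to one scalar pair (S, C) per dataset:
#   S = sum of squared centered phenotypes, C = sum of within-pair
#   cross-products.  The ML profile maximum is the closed form
#   r_hat = 2C/S; the REML profile is maximized by a vectorized
#   golden-section search.
# ---------------------------------------------------------------------------


def _reml_crit(r: np.ndarray, S: np.ndarray, C: np.ndarray, n_pairs: int) -> np.ndarray:
    """-2 x profiled REML log-likelihood (up to constants), vectorized over r."""
    n_obs = 2 * n_pairs
    rss = (S - 2.0 * r * C) / (1.0 - r * r)
    return (
        (n_obs - 1) * np.log(rss)
        + n_pairs * np.log1p(-r * r)
        - np.log1p(r)  # from log det(1' R^-1 1) = log(2 n / (1 + r))
    )


def _golden_min(f, lo: float, hi: float, shape, iters: int = 96):
    """Elementwise golden-section minimizer of a vectorized unimodal function."""
    inv_phi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(shape, lo)
    b = np.full(shape, hi)
    for _ in range(iters):
        c = b - inv_phi * (b - a)
        d = a + inv_phi * (b - a)
        take_left = f(c) < f(d)
        b = np.where(take_left, d, b)
        a = np.where(take_left, a, c)
    return 0.5 * (a + b)


def fit_h2_pairs(
    y: np.ndarray, method: str = "reml", phi: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Profile heritability estimates for stacked replicates of sib pairs.

    Parameters
    ----------
    y : array of shape (n_replicates, n_pairs, 2) — or (n_pairs, 2) for
        a single dataset — with intercept-only fixed effects.
    method : "reml" (default) or "ml".
    phi : constant kinship coefficient (1/4 for full sibs).

    Returns
    -------
    (h2_hat, sigma_y2_hat) arrays of length ``n_replicates``.  Estimates
    are untruncated within the positive-definite range ``|2 phi h2| < 1``.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 2
    if single:
        y = y[None]
    n_pairs = y.shape[1]
    n_obs = 2 * n_pairs
    mu = y.mean(axis=(1, 2), keepdims=True)
    e = y - mu
    S = (e**2).sum(axis=(1, 2))
    C = (e[:, :, 0] * e[:, :, 1]).sum(axis=1)
    r_cap = 1.0 - _EPS
    if method == "ml":
        r_hat = np.clip(2.0 * C / S, -r_cap, r_cap)
        sigma2 = (S - 2.0 * r_hat * C) / (n_obs * (1.0 - r_hat**2))
    elif method == "reml":
        r_hat = _golden_min(
            lambda r: _reml_crit(r, S, C, n_pairs), -r_cap, r_cap, S.shape
        )
        sigma2 = (S - 2.0 * r_hat * C) / ((n_obs - 1) * (1.0 - r_hat**2))
    else:
        raise ValueError(f"unknown method {method!r}")
    h2_hat = r_hat / (2.0 * phi)
    if single:
        return h2_hat[0], sigma2[0]
    return h2_hat, sigma2


def _pair_quad(a: np.ndarray, b: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Quadratic form a' R^-1 b summed over pairs, vectorized over replicates.

    ``a``, ``b``: (R, n, 2); ``r``: broadcastable to (R, 1).
    """
    num = (a * b).sum(axis=2) - r * (a[:, :, 0] * b[:, :, 1] + a[:, :, 1] * b[:, :, 0])
    return (num / (1.0 - r * r)).sum(axis=1)


def lmm_score_many(y: np.ndarray, g: np.ndarray, r) -> np.ndarray:
    """Vectorized intercept-only GLS score statistics across replicates.

    ``y``, ``g``: (n_replicates, n_pairs, 2); ``r``: scalar or
    per-replicate intra-pair model correlation (``2 phi h2``).  Returns
    the chi-square(1) statistics ``N (g'Py)^2 / ((g'Pg)(y'Py))``.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    r = np.broadcast_to(np.asarray(r, dtype=float), (y.shape[0],)).reshape(-1, 1)
    n_obs = 2 * y.shape[1]
    yc = y - y.mean(axis=(1, 2), keepdims=True)
    gc = g - g.mean(axis=(1, 2), keepdims=True)
    sgy = _pair_quad(gc, yc, r)
    sgg = _pair_quad(gc, gc, r)
    syy = _pair_quad(yc, yc, r)
    with np.errstate(divide="ignore", invalid="ignore"):
        return n_obs * sgy**2 / (sgg * syy)


def _projected_score(yw: np.ndarray, gw: np.ndarray, Xw: np.ndarray) -> float:
    """N x squared partial correlation of whitened g and y given whitened X."""
    Q, _ = np.linalg.qr(Xw)
    ry = yw - Q @ (Q.T @ yw)
    rg = gw - Q @ (Q.T @ gw)
    den = float(rg @ rg) * float(ry @ ry)
    if den <= 0.0:
        raise ValueError("undefined score test: genotype or phenotype in covariate span")
    return len(yw) * float(rg @ ry) ** 2 / den


def lmm_score_test(
    y: np.ndarray,
    g: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    kinship: Optional[KinshipMatrix] = None,
    mode: str = "estimated",
    h2: Optional[float] = None,
    method: str = "reml",
) -> AssocTestResult:
    """GLS score test of no association between the tested SNP and the trait.

    The null covariance ``Sigma_y(h2)`` is either profiled from the data
    (``mode="estimated"``) or fixed at a supplied heritability
    (``mode="fixed"``).  With ``P`` the projector removing fixed effects
    under ``Sigma_y^{-1}``, the statistic ``N (g'Py)^2 / ((g'Pg)(y'Py))``
    is referred to chi-square with 1 df.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape or y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y and g must both have shape (n_pairs, 2)")
    n_pairs = y.shape[0]
    if kinship is None:
        kinship = KinshipMatrix.sib_pairs(n_pairs)
    fit = fit_null_lmm(y, covariates, kinship, mode=mode, h2=h2, method=method)
    r = kinship.pair_correlations(fit.h2_hat)
    X = _pair_design(n_pairs, covariates)
    stat = _projected_score(_whiten(y, r), _whiten(g, r), _whiten(X, r))
    tag = "lmm_fixed_h2" if mode == "fixed" else "lmm_estimated_h2"
    return AssocTestResult(
        statistic=stat, p_value=chisq1_pvalue(stat), method=tag, nuisance=fit
    )


def indep_score_test(
    y: np.ndarray, g: np.ndarray, z: Optional[np.ndarray] = None
) -> AssocTestResult:
    """Classical independent-sample score statistic T_indep.

    Evaluates, exactly in its classical centered form,

        T = n * (g'y~ - g'z~ y'z~ / z'z~)^2
            / [(g'g~ - (g'z~)^2/z'z~)(y'y~ - (y'z~)^2/z'z~)]

    (tildes denoting centering), i.e. ``n`` times the squared partial
    correlation of genotype and phenotype given the covariate; the
    statistic lies in ``[0, n]``.  Its denominator contains
    ``var_hat(G) = 2(p_hat(1-p_hat) + delta_hat)``, the HWD-adjusted
    genotype variance, which is what makes the independent-sample test
    robust to HWD.
    """
    y = np.asarray(y, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    n = y.size
    if g.size != n:
        raise ValueError("y and g must have equal length")
    if n < 4:
        raise ValueError("at least 4 observations are required")
    yc = y - y.mean()
    gc = g - g.mean()
    if z is None:
        sgy, sgg, syy = gc @ yc, gc @ gc, yc @ yc
    else:
        zc = np.asarray(z, dtype=float).ravel() - np.mean(z)
        szz = zc @ zc
        if szz <= 0.0:
            raise ValueError("covariate is constant")
        sgy = gc @ yc - (gc @ zc) * (yc @ zc) / szz
        sgg = gc @ gc - (gc @ zc) ** 2 / szz
        syy = yc @ yc - (yc @ zc) ** 2 / szz
    if sgg <= 0.0 or syy <= 0.0:
        raise ValueError("undefined score test: zero residual variance of g or y")
    stat = n * float(sgy) ** 2 / (float(sgg) * float(syy))
    return AssocTestResult(statistic=stat, p_value=chisq1_pvalue(stat), method="indep")
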