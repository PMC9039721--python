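"""Synthetic sib-pair genotype/phenotype generator under Hardy-Weinberg disequilibrium.

The central object is the exact 9-state joint distribution of the two
siblings' genotypes ``(G1, G2)`` at one biallelic locus with allele
frequency ``p`` and HWD coefficient ``delta``.  It is built by exact
enumeration of a conditional-draw identity-by-descent (IBD) scheme:

1. Sib 1's ordered allele pair is drawn from the HWD pair law
   ``P(1,1) = p^2 + d``, ``P(0,0) = (1-p)^2 + d``,
   ``P(1,0) = P(0,1) = p(1-p) - d``.
2. An IBD state ``K in {0, 1, 2}`` is drawn with the full-sib
   probabilities ``(1/4, 1/2, 1/4)``.
3. ``K = 2``: sib 2 copies both alleles.  ``K = 1``: sib 2 shares the
   first allele and draws the second from the pair-law conditional
   given the shared allele.  ``K = 0``: sib 2 draws a fresh pair.

The scheme is valid over the whole admissible delta range (including
negative delta), reduces to the classical outbred full-sib table at
``delta = 0``, and yields

    Cov(G1, G2) = p(1-p)(1+F)(2+F)/2,   Corr(G1, G2) = (2+F)/4,

with ``F = delta/(p(1-p))`` — so twice the sib phenotype correlation of
a trait driven by this locus recovers the closed-form heritability
inflation ``h2 (p(1-p)+delta)/(p(1-p))`` exactly at ``h2 = 0.5``.

Phenotypes follow the single-causal-SNP model ``Y = beta*G + eps`` with
i.i.d. normal environmental noise calibrated so that the trait
heritability under the HWE variance convention equals a target ``h2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .hwd import HWDSpec, GenotypeFreqs, genotype_freqs, genotype_variance

__all__ = [
    "SibPairJointDist",
    "JointMoments",
    "PhenoModel",
    "Scenario",
    "SibPairData",
    "build_joint_dist",
    "joint_dist_moments",
    "sample_sibpairs",
    "simulate_phenotypes",
    "generate_dataset",
]

RandomState = Union[int, np.random.Generator, np.random.SeedSequence, None]


def _as_rng(seed: RandomState) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SibPairJointDist:
    """Exact 3x3 joint law of a sib pair's genotype counts at one locus.

    ``probs[i, j] = P(G1 = i, G2 = j)`` — non-negative, summing to one,
    symmetric under sib exchange, with both marginals equal to the
    locus's HWD genotype frequencies.
    """

    probs: np.ndarray
    spec: HWDSpec

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (3, 3):
            raise ValueError("probs must be a 3x3 table")
        if probs.min() < -1e-12 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be a probability table summing to 1")
        object.__setattr__(self, "probs", probs)


def build_joint_dist(spec: HWDSpec) -> SibPairJointDist:
    """Enumerate the sib-pair joint genotype distribution exactly (no sampling)."""
    p, d = spec.p, spec.delta
    probs = np.zeros((3, 3))
    if p in (0.0, 1.0):
        g = 2 if p == 1.0 else 0
        probs[g, g] = 1.0
        return SibPairJointDist(probs=probs, spec=spec)

    q = 1.0 - p
    # ordered allele pair law for one individual (allele coded 1 for A)
    pair_law = {(1, 1): p * p + d, (0, 0): q * q + d, (1, 0): p * q - d, (0, 1): p * q - d}
    # P(second allele = 1 | first allele), from the pair law
    cond1 = {1: (p * p + d) / p, 0: (p * q - d) / q}
    ibd = {0: 0.25, 1: 0.5, 2: 0.25}

    for (a, b), p_ab in pair_law.items():
        if p_ab <= 0.0:
            continue
        g1 = a + b
        for k, p_k in ibd.items():
            if k == 2:
                probs[g1, g1] += p_ab * p_k
            elif k == 1:
                # sib 2 shares allele a; its second allele follows the
                # conditional pair law given the shared allele
                for b2 in (0, 1):
                    p_b2 = cond1[a] if b2 == 1 else 1.0 - cond1[a]
                    probs[g1, a + b2] += p_ab * p_k * p_b2
            else:
                for (a2, b2), p_fresh in pair_law.items():
                    probs[g1, a2 + b2] += p_ab * p_k * p_fresh
    np.clip(probs, 0.0, None, out=probs)
    return SibPairJointDist(probs=probs, spec=spec)


@dataclass(frozen=True)
class JointMoments:
    """Moments of a sib-pair joint genotype distribution."""

    marginal: GenotypeFreqs
    mean: float
    var: float
    cov: float
    corr: float


def joint_dist_moments(dist: SibPairJointDist) -> JointMoments:
    """Exact marginal frequencies and first/second moments of ``(G1, G2)``."""
    g = np.arange(3.0)
    marg = dist.probs.sum(axis=1)
    mean = float(marg @ g)
    var = float(marg @ g**2 - mean**2)
    cov = float(g @ dist.probs @ g - mean * mean)
    corr = cov / var if var > 0 else float("nan")
    return JointMoments(
        marginal=GenotypeFreqs(*np.clip(marg, 0.0, 1.0)),
        mean=mean,
        var=var,
        cov=cov,
        corr=corr,
    )


def sample_sibpairs(
    dist: SibPairJointDist, n_pairs: int, seed: RandomState = None
) -> np.ndarray:
    """Draw ``n_pairs`` i.i.d. sib pairs from the 9-state table.

    Returns an ``(n_pairs, 2)`` integer array of genotype counts.
    Reproducible under a fixed seed.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = _as_rng(seed)
    cdf = np.cumsum(dist.probs.ravel())
    cdf[-1] = 1.0
    idx = np.searchsorted(cdf, rng.random(n_pairs), side="right")
    return np.stack([idx // 3, idx % 3], axis=1).astype(np.int64)


@dataclass(frozen=True)
class PhenoModel:
    """Single-causal-SNP additive phenotype model ``Y = beta*G + eps``.

    ``sigma_e2`` is the environmental noise variance.  When left unset
    it is calibrated from the target heritability under the HWE variance
    convention ``h2 = beta^2 * 2p(1-p) / (beta^2 * 2p(1-p) + sigma_e2)``:

        sigma_e2 = beta^2 * 2p(1-p) * (1 - h2) / h2

    Note the convention uses the HWE genotype variance ``2p(1-p)``, not
    the HWD-inflated ``2(p(1-p)+delta)``; this is what makes the induced
    sib correlation reproduce the closed-form heritability bias.
    """

    beta: float
    h2: float
    causal_spec: HWDSpec
    sigma_e2: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"target heritability must be in (0, 1), got {self.h2!r}")
        if self.sigma_e2 is None:
            pq = self.causal_spec.p * (1.0 - self.causal_spec.p)
            derived = self.beta**2 * 2.0 * pq * (1.0 - self.h2) / self.h2
            if derived <= 0.0:
                raise ValueError(
                    "derived sigma_e2 is not positive (beta = 0 or monomorphic locus); "
                    "pass sigma_e2 explicitly"
                )
            object.__setattr__(self, "sigma_e2", derived)
        elif self.sigma_e2 <= 0.0:
            raise ValueError("sigma_e2 must be positive")


def simulate_phenotypes(
    g_causal: np.ndarray, model: PhenoModel, seed: RandomState = None
) -> np.ndarray:
    """Phenotypes ``y_ij = beta * g_ij + eps_ij`` with i.i.d. N(0, sigma_e2) noise.

    No shared-environment term: all within-pair phenotype correlation
    comes from the causal genotypes.
    """
    g = np.asarray(g_causal, dtype=float)
    rng = _as_rng(seed)
    return model.beta * g + rng.normal(0.0, np.sqrt(model.sigma_e2), size=g.shape)


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: sample size, both locus laws, and the trait model.

    Defaults mirror the reference sib-pair design: 65 pairs, both loci
    at MAF 0.2, heritability 0.5, unit allele effect, tested SNP null.
    """

    n_pairs: int = 65
    p_causal: float = 0.2
    delta_causal: float = 0.0
    p_tested: float = 0.2
    delta_tested: float = 0.0
    h2: float = 0.5
    beta: float = 1.0

    @property
    def causal_spec(self) -> HWDSpec:
        return HWDSpec(p=self.p_causal, delta=self.delta_causal)

    @property
    def tested_spec(self) -> HWDSpec:
        return HWDSpec(p=self.p_tested, delta=self.delta_tested)

    @property
    def pheno_model(self) -> PhenoModel:
        return PhenoModel(beta=self.beta, h2=self.h2, causal_spec=self.causal_spec)


@dataclass(frozen=True)
class SibPairData:
    """Genotypes, phenotypes and optional covariate for ``n_pairs`` sib pairs.

    All member arrays have shape ``(n_pairs, 2)`` (one column per sib).
    """

    g_causal: np.ndarray
    g_tested: np.ndarray
    y: np.ndarray
    z: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shape = np.asarray(self.y).shape
        if len(shape) != 2 or shape[1] != 2:
            raise ValueError("arrays must have shape (n_pairs, 2)")
        for name in ("g_causal", "g_tested"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != phenotype shape {shape}")
            if not np.isin(arr, (0, 1, 2)).all():
                raise ValueError(f"{name} contains codes outside {{0, 1, 2}}")
        if self.z is not None and np.asarray(self.z).shape != shape:
            raise ValueError("covariate shape mismatch")

    @property
    def n_pairs(self) -> int:
        return np.asarray(self.y).shape[0]


def generate_dataset(scenario: Scenario, seed: RandomState = None) -> SibPairData:
    """Simulate one dataset under a scenario.

    The causal and tested SNPs are drawn independently of each other (no
    linkage disequilibrium), each from its own sib-pair joint law; the
    phenotype depends on the causal SNP only (the tested SNP is null).
    """
    rng = _as_rng(seed)
    g_causal = sample_sibpairs(build_joint_dist(scenario.causal_spec), scenario.n_pairs, rng)
    g_tested = sample_sibpairs(build_joint_dist(scenario.tested_spec), scenario.n_pairs, rng)
    y = simulate_phenotypes(g_causal, scenario.pheno_model, rng)
    return SibPairData(g_causal=g_causal, g_tested=g_tested, y=y)


def expected_h2_estimate(h2: float, spec: HWDSpec) -> float:
    """Population value of twice the sib phenotype correlation, ``h2 (pq+delta)/pq``.

    This is the quantity the LMM heritability estimate converges to for
    a single causal SNP; it equals ``h2 + bias`` with the closed-form
    bias ``h2*delta/(p(1-p))``.  Exact at ``h2 = 0.5`` under the noise
    calibration of :class:`PhenoModel`.
    """
    pq = spec.p * (1.0 - spec.p)
    if pq == 0.0:
        raise ValueError("monomorphic causal locus")
    return h2 * (pq + spec.delta) / pq
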