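"""Seeded simulation pipelines: heritability-bias grid, type-I-error grid, tail probability.

Each pipeline simulates fresh genotypes *and* phenotypes per replicate
(genotype resampling contributes real variance to the heritability
estimate and must not be frozen), runs the vectorized replicate engine,
and returns a tidy long-format :class:`pandas.DataFrame` carrying the
per-condition aggregates together with the closed-form predictions and
Monte Carlo standard errors.

Reproducibility: one root seed per experiment; each grid point gets a
child stream spawned from :class:`numpy.random.SeedSequence`, so the
output is bit-identical for identical ``(config, seed)`` and
independent across grid points.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .hwd import HWDSpec, CausalLocus, heritability_bias
from .lmm import fit_h2_pairs, lmm_score_many
from .reverse import reverse_score_many
from .sibpairs import PhenoModel, build_joint_dist

log = logging.getLogger(__name__)

_CHUNK = 20_000  # replicates per simulation block (bounds peak memory)

DELTA_GRID_DEFAULT = tuple(np.round(np.arange(-0.04, 0.1601, 0.02), 4))


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment's full condition set.

    ``h2_mode`` is ``"estimated"`` or ``"fixed:<value>"`` (e.g.
    ``"fixed:0.5"``); ``estimator`` selects the likelihood flavor of
    the heritability profile; ``method`` selects the association test
    for the type-I grid (``"lmm"`` or ``"reverse"``).
    """

    n_pairs: int = 65
    n_replicates: int = 10_000
    p_causal: float = 0.2
    p_tested: float = 0.2
    delta_causal_grid: Sequence[float] = field(default_factory=lambda: DELTA_GRID_DEFAULT)
    delta_tested: float = 0.0
    h2: float = 0.5
    beta: float = 1.0
    nominal_level: float = 0.05
    h2_mode: str = "estimated"
    estimator: str = "reml"
    method: str = "lmm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 100:
            raise ValueError("n_replicates must be >= 100")
        if not 0.0 < self.nominal_level < 1.0:
            raise ValueError("nominal_level must be in (0, 1)")
        for d in self.delta_causal_grid:
            HWDSpec(p=self.p_causal, delta=float(d))
        HWDSpec(p=self.p_tested, delta=self.delta_tested)
        if self.h2_mode != "estimated" and not self.h2_mode.startswith("fixed:"):
            raise ValueError("h2_mode must be 'estimated' or 'fixed:<value>'")
        if self.estimator not in ("ml", "reml"):
            raise ValueError("estimator must be 'ml' or 'reml'")
        if self.method not in ("lmm", "reverse"):
            raise ValueError("method must be 'lmm' or 'reverse'")

    @property
    def fixed_h2(self) -> Optional[float]:
        if self.h2_mode.startswith("fixed:"):
            return float(self.h2_mode.split(":", 1)[1])
        return None

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, (tuple, list)) else v for k, v in asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def metadata(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash(),
            "hwdlmm_version": __version__,
            "numpy_version": np.__version__,
        }


def _sample_genotype_chunk(dist, n_reps: int, n_pairs: int, rng) -> np.ndarray:
    cdf = np.cumsum(dist.probs.ravel())
    cdf[-1] = 1.0
    idx = np.searchsorted(cdf, rng.random((n_reps, n_pairs)), side="right")
    return np.stack([idx // 3, idx % 3], axis=2).astype(np.int64)


def _replicate_chunks(config: ExperimentConfig, delta_causal: float, rng, tested: bool):
    """Yield (y, g_tested) chunks of fresh replicates under one grid condition."""
    causal = build_joint_dist(HWDSpec(p=config.p_causal, delta=float(delta_causal)))
    model = PhenoModel(
        beta=config.beta, h2=config.h2, causal_spec=causal.spec
    )
    tested_dist = (
        build_joint_dist(HWDSpec(p=config.p_tested, delta=config.delta_tested))
        if tested
        else None
    )
    left = config.n_replicates
    while left > 0:
        m = min(_CHUNK, left)
        g_causal = _sample_genotype_chunk(causal, m, config.n_pairs, rng)
        y = model.beta * g_causal + rng.normal(
            0.0, np.sqrt(model.sigma_e2), size=g_causal.shape
        )
        g_tested = (
            _sample_genotype_chunk(tested_dist, m, config.n_pairs, rng) if tested else None
        )
        yield y, g_tested
        left -= m


def run_bias_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Distribution of the estimated heritability across the delta_causal grid.

    For each grid value the null LMM is fitted (heritability profiled,
    no truncation) to every replicate; the table reports mean, median,
    sd and quartiles of the estimates next to the closed-form predicted
    value ``h2 (pq + delta)/pq``.  Non-finite fits (none expected for
    non-degenerate data) are excluded and counted.
    """
    children = np.random.SeedSequence(config.seed).spawn(len(config.delta_causal_grid))
    rows = []
    for delta, child in zip(config.delta_causal_grid, children):
        t0 = time.perf_counter()
        rng = np.random.default_rng(child)
        estimates = []
        for y, _ in _replicate_chunks(config, delta, rng, tested=False):
            h2_hat, _ = fit_h2_pairs(y, method=config.estimator)
            estimates.append(h2_hat)
        h2_hat = np.concatenate(estimates)
        ok = np.isfinite(h2_hat)
        h = h2_hat[ok]
        predicted = config.h2 + heritability_bias(
            config.h2, [CausalLocus(beta=config.beta, p=config.p_causal, delta=float(delta))]
        )
        rows.append(
            {
                "experiment": "bias_grid",
                "delta_causal": float(delta),
                "n_pairs": config.n_pairs,
                "n_replicates": config.n_replicates,
                "estimator": config.estimator,
                "mean_h2": h.mean(),
                "median_h2": np.median(h),
                "sd_h2": h.std(ddof=1),
                "q25_h2": np.quantile(h, 0.25),
                "q75_h2": np.quantile(h, 0.75),
                "frac_above_1": (h > 1.0).mean(),
                "predicted_h2": predicted,
                "mc_se_mean": h.std(ddof=1) / np.sqrt(ok.sum()),
                "n_excluded": int((~ok).sum()),
                "seed": config.seed,
            }
        )
        log.info(
            "bias_grid delta_causal=%+.3f: mean h2=%.4f (predicted %.4f) [%.2fs]",
            delta,
            rows[-1]["mean_h2"],
            predicted,
            time.perf_counter() - t0,
        )
    return pd.DataFrame(rows)


def run_type1_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Empirical size of the association test on a null tested SNP.

    The tested SNP is simulated independently of the causal SNP with its
    own HWD coefficient; for each grid value the table reports the
    rejection rate at ``nominal_level``, its Monte Carlo standard error
    ``sqrt(r(1-r)/R)``, and the inflation threshold
    ``nominal + 3 sqrt(nominal(1-nominal)/R)``.
    """
    children = np.random.SeedSequence(config.seed).spawn(len(config.delta_causal_grid))
    se_nominal = np.sqrt(config.nominal_level * (1 - config.nominal_level) / config.n_replicates)
    threshold = config.nominal_level + 3 * se_nominal
    crit = stats.chi2.isf(config.nominal_level, df=1)
    rows = []
    for delta, child in zip(config.delta_causal_grid, children):
        t0 = time.perf_counter()
        rng = np.random.default_rng(child)
        stats_chunks = []
        for y, g_tested in _replicate_chunks(config, delta, rng, tested=True):
            if config.method == "reverse":
                t = reverse_score_many(y, g_tested)
            elif config.fixed_h2 is not None:
                t = lmm_score_many(y, g_tested, 0.5 * config.fixed_h2)
            else:
                h2_hat, _ = fit_h2_pairs(y, method=config.estimator)
                t = lmm_score_many(y, g_tested, 0.5 * h2_hat)
            stats_chunks.append(t)
        t_all = np.concatenate(stats_chunks)
        ok = np.isfinite(t_all)
        rate = float((t_all[ok] > crit).mean())
        rows.append(
            {
                "experiment": "type1_grid",
                "delta_causal": float(delta),
                "delta_tested": config.delta_tested,
                "h2_mode": config.h2_mode,
                "method": config.method,
                "estimator": config.estimator,
                "n_pairs": config.n_pairs,
                "n_replicates": config.n_replicates,
                "nominal_level": config.nominal_level,
                "rejection_rate": rate,
                "mc_se": np.sqrt(rate * (1 - rate) / ok.sum()),
                "inflation_threshold": threshold,
                "inflated": rate > threshold,
                "n_excluded": int((~ok).sum()),
                "seed": config.seed,
            }
        )
        log.info(
            "type1_grid delta_causal=%+.3f (%s, %s): size=%.4f [%.2fs]",
            delta,
            config.h2_mode,
            config.method,
            rate,
            time.perf_counter() - t0,
        )
    return pd.DataFrame(rows)


def run_tail_prob(config: ExperimentConfig, threshold: float) -> pd.DataFrame:
    """Fraction of heritability estimates strictly above ``threshold``.

    One row per ``delta_causal`` grid value, with an exact binomial 95%
    confidence interval for the exceedance fraction.
    """
    children = np.random.SeedSequence(config.seed).spawn(len(config.delta_causal_grid))
    rows = []
    for delta, child in zip(config.delta_causal_grid, children):
        rng = np.random.default_rng(child)
        count, total = 0, 0
        for y, _ in _replicate_chunks(config, delta, rng, tested=False):
            h2_hat, _ = fit_h2_pairs(y, method=config.estimator)
            ok = np.isfinite(h2_hat)
            count += int((h2_hat[ok] > threshold).sum())
            total += int(ok.sum())
        ci = stats.binomtest(count, total).proportion_ci(confidence_level=0.95)
        rows.append(
            {
                "experiment": "tail_prob",
                "delta_causal": float(delta),
                "threshold": threshold,
                "estimator": config.estimator,
                "n_pairs": config.n_pairs,
                "n_replicates": config.n_replicates,
                "fraction": count / total,
                "ci_low": ci.low,
                "ci_high": ci.high,
                "n_excluded": config.n_replicates - total,
                "seed": config.seed,
            }
        )
        log.info(
            "tail_prob delta_causal=%+.3f: P(h2_hat > %.3g) = %.5f",
            delta,
            threshold,
            rows[-1]["fraction"],
        )
    return pd.DataFrame(rows)
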