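# Methods

## The problem setting

Association studies of related individuals model the phenotype
covariance as a kinship-weighted mixture, with the weight h²
interpreted as trait heritability. Because the kinship matrix enters
the *phenotype* model, the amount of Hardy–Weinberg disequilibrium
(HWD) at *causal* loci leaks into the heritability nuisance parameter:
sib phenotype correlation is driven by sib genotype covariance, and HWD
changes that covariance. This package provides the algebra, an exact
simulator, and the estimation/testing machinery to measure the effect.

All quantities are dimensionless. The canonical locus parameter is the
HWD coefficient δ = P(AA) − p² (admissible range
[max(−p², −(1−p)²), p(1−p)], closed: boundary values that zero out a
genotype class are legal); the inbreeding coefficient F = δ/(p(1−p)) is
a derived view. δ was chosen as canonical because simulation grids and
quality-control practice are stated in δ.

## Sib-pair joint genotype law

`build_joint_dist` enumerates, exactly, a conditional-draw
identity-by-descent (IBD) scheme:

1. sib 1's ordered allele pair from the HWD pair law
   P(1,1) = p²+δ, P(0,0) = (1−p)²+δ, P(1,0) = P(0,1) = p(1−p)−δ;
2. IBD state K ∈ {0,1,2} with probabilities (1/4, 1/2, 1/4);
3. K=2: sib 2 copies both alleles; K=1: the shared allele is copied and
   the other drawn from the pair-law conditional given the shared
   allele; K=0: a fresh pair-law draw.

Properties (all tested): the 3×3 table is symmetric with marginals
equal to the HWD genotype frequencies; at δ = 0 it equals the classical
outbred full-sib table obtained by enumerating parental mating types;
and over the entire admissible range (including δ < 0)

    Cov(G1, G2) = p(1−p)(1+F)(2+F)/2,  Corr(G1, G2) = (2+F)/4.

This construction is a reconstruction: the derivation of the
HWD-aware sib genotype correlation circulating in the literature is
not available in full detail. We therefore validate the scheme against
every closed-form moment above rather than against a published recipe,
and do not claim it is the unique scheme with these margins.

## Phenotype model and heritability convention

One causal SNP: y_ij = β g_ij + ε_ij with ε i.i.d. N(0, σ²_e), no
shared-environment term (the proof-of-principle design attributes all
sib resemblance to the causal SNP). The noise is calibrated under the
**HWE variance convention**

    σ²_e = β² · 2p(1−p) · (1−h²)/h²,

i.e. the h² definition uses the HWE genotype variance 2p(1−p), not the
HWD-inflated 2(p(1−p)+δ). Only under this convention does twice the
population sib phenotype correlation equal the closed-form

    E[ĥ²] ≈ h² (p(1−p)+δ)/(p(1−p)),

exactly so at h² = 0.5 (the identity is algebraic at 0.5 and
approximate elsewhere; the package's reference design uses 0.5
throughout). The multi-SNP generalization of the bias,
h²·Σβ²ₖδₖ/Σβ²ₖpₖ(1−pₖ), is available analytically
(`heritability_bias`) but only the single-SNP case is simulated.

## Heritability estimation

For sib pairs the model covariance per family is σ²_y [[1, r],[r, 1]]
with r = 2φh² (φ = 1/4), so positive definiteness bounds the
*estimable* range at |h²| < 2 − ε (ε = 1e−6). Estimates are reported
untruncated — values above 1 are meaningful evidence of HWD-induced
inflation, and truncating them would hide exactly the phenomenon under
study.

Fitting profiles the Gaussian likelihood: per-family whitening by
(sum, difference)/sqrt scaling makes the GLS mean and σ²_y closed-form
at each h², leaving a 1-D problem. Two flavors:

* **REML (default).** Chosen because the ML intraclass-correlation
  estimate carries the classic O(1/n) downward bias — about −0.02 in ĥ²
  at 65 pairs — while REML's replicate mean under HWE is ≈0.49 at the
  reference design, matching how mainstream variance-components
  software estimates heritability. The REML profile criterion is
  maximized by bounded Brent search (tolerance 1e−8); the vectorized
  replicate engine uses an elementwise golden-section search (96
  iterations, equivalent accuracy), and the two routes are tested to
  agree to 1e−6.
* **ML.** For intercept-only designs with constant φ the profile
  stationarity condition has the exact solution r̂ = 2C/S (C = sum of
  within-pair cross-products of centered phenotypes, S = total sum of
  squares), used directly; Brent search handles covariate designs.
  Tested against dense-matrix grid search and against an independent
  direct (μ, σ², ρ) maximization.

Small-sample caveat: at 65 pairs even REML retains a residual bias of
order 0.005–0.01 in ĥ², visible when Monte Carlo error is pushed below
it. The closed-form prediction is therefore validated to 3 MC standard
errors at 500 pairs, and at the 65-pair reference design against the
reported values' ±0.02 tolerances.

## Association score tests

All tests reduce to the same symmetric statistic

    T = N (g'Py)² / ((g'Pg)(y'Py)),   P = W⁻¹ − W⁻¹X(X'W⁻¹X)⁻¹X'W⁻¹,

referred to χ²₁, where W is the null covariance structure and X the
fixed effects (intercept, optional covariate). T is N times the
squared GLS partial correlation, is invariant to the overall scale of
W and to affine transforms of y and the covariates, and lies in [0, N].
Choices embedded here: the forward LMM version plugs in the null-fitted
covariance with the ML variance divisor (making T exactly symmetric in
g and y — which is what makes the forward and reverse tests coincide
under matched covariances); a Wald or likelihood-ratio construction
would differ at O(1/N).

* `indep_score_test` evaluates the independent-sample statistic in its
  classical centered form; its denominator contains the HWD-adjusted
  genotype variance 2(p̂(1−p̂)+δ̂) — the algebraic reason independent
  samples are immune to HWD.
* `lmm_score_test` uses W = Σ_y(ĥ²) (mode `estimated`) or Σ_y(h²)
  (mode `fixed`). With kinship φ = 0 both reduce exactly to
  `indep_score_test`.
* `reverse_score_test` swaps the roles of g and y and uses per-family
  genotype covariance blocks [[v̂, ĉ],[ĉ, v̂]] with
  v̂ = 2(p̂(1−p̂)+δ̂) from the pooled genotypes and ĉ the divisor-n
  within-pair cross-moment about the pooled mean (ĉ absorbs kinship
  and HWD jointly; the exact decomposition used in the original
  retrospective proposal is not publicly documented, so this moment model is a
  pragmatic, testable stand-in). Degenerate blocks are guarded by
  clipping the implied correlation ĉ/v̂ into (−1+1e−8, 1−1e−8) — a
  guard that is exactly inactive away from boundary HWD — rather than
  by an unconditional diagonal ridge, which would perturb every
  statistic at the 1e−10 level.

## Simulation pipelines and reproducibility

`run_bias_grid`, `run_type1_grid` and `run_tail_prob` simulate fresh
genotypes *and* phenotypes each replicate (freezing genotypes would
understate the estimator's variance), vectorized over replicates in
20,000-replicate blocks. Defaults mirror the reference design: 65
pairs, both loci at MAF 0.2, h² = 0.5, β = 1, nominal level 0.05,
δ_causal grid −0.04 to 0.16 in steps of 0.02 (the grid endpoints are
the admissible bounds at p = 0.2; the step is a package choice to make
the inflation trend testable at modest cost). Monte Carlo standard
errors and the inflation threshold nominal + 3·SE accompany every rate.
Rejection is strict (p < nominal). One root seed per experiment; grid
points get independent `SeedSequence`-spawned child streams, so outputs
are bit-identical for identical (config, seed) and the default problem
sizes (10,000 replicates; 100,000 for the tail probability) run in
seconds.

## What the generator does and does not emulate

It emulates: exact sib-pair genotype dependence under arbitrary
admissible HWD at two unlinked loci, a single additive causal SNP,
Gaussian noise, and a null tested SNP. It does **not** emulate: multiple
or linked causal loci (no LD, no HWD×LD interplay), dominance, shared
environment, ascertainment or selection mechanisms that generate HWD in
real cohorts, genotyping error, or general pedigrees beyond sib pairs
(the API accepts block kinship with arbitrary φ, but only pairs are
validated). Passing tests therefore demonstrate the *mechanism* —
HWD-induced bias and test-size distortion in an idealized sib design —
not the magnitude of either effect in any real cohort.

## Known limitations

* One reference quantity does not reproduce: the reported 4.24% tail
  probability P(ĥ² > 0.82) under HWE with h² = 0.5 and 65 pairs. This
  implementation obtains 7.6% (ML), 8.5% (REML), 8.9% (Pearson
  correlation) over 100,000 replicates. The discrepancy appears
  structural rather than a flavor choice: under the stated design the
  sib phenotype correlation is exactly 0.25 and
  P(ĥ² > 0.82) = P(ρ̂ > 0.41); reaching 4.24% would require
  sd(ρ̂) ≈ 0.099, below the Fisher-information bound (≈0.113) for any
  approximately unbiased estimator of an intraclass correlation from 65
  pairs — it would correspond to roughly 95 pairs. The estimator behind
  the reported figure is not publicly documented and could not be
  consulted. The acceptance script reports the honestly computed value.
* The forward and reverse variance structures assume no shared-environment
  component; adding one is straightforward in the simulator but the
  estimators would then be misspecified by design.
* The closed-form bias line is exact (as an expectation of 2·corr) only
  at h² = 0.5; elsewhere it is a first-order description.
* Whether the original type-I-error evaluation used a score, Wald, or
  LRT construction is not documented; the score test is implemented as
  primary. The observed sizes (nominal with estimated h², inflated above
  the 0.056 threshold at δ_causal = 0.16 with fixed h²) are robust to
  this choice at the reported tolerances.
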