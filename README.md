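# hwdlmm

Linear mixed-effect models (LMMs) are the standard tool for genetic
association studies with related individuals. `hwdlmm` is a simulation
and analysis toolkit that quantifies a subtle failure mode of that
standard: **the LMM is sensitive to Hardy–Weinberg disequilibrium (HWD)
at causal SNPs**. It is aimed at statistical geneticists who want to
reproduce, probe, or extend that result with exact, seeded sib-pair
simulations.

## The model

For a biallelic SNP with allele frequency *p*, HWD is measured by
δ = P(AA) − p², giving genotype frequencies

    P(aa) = (1−p)² + δ,   P(Aa) = 2p(1−p) − 2δ,   P(AA) = p² + δ,

with δ = p(1−p)F for inbreeding coefficient *F*. The sib-pair LMM for a
trait *y* is

    y = Xα + ε,   ε ~ N(0, σ²_y Σ_y),   Σ_y = h² Σ_Φ + (1−h²) I,

where Σ_Φ is the kinship matrix (off-diagonal 2φ = 1/2 for full sibs)
and the weight h² is interpreted as the trait heritability, identified
through the intra-pair phenotype correlation: ĥ² = corr(Y₁, Y₂)/2φ.

The package's core results, all computable from its API:

* **Exact sib-pair joint genotype law under HWD.** An
  identity-by-descent construction gives the 9-state joint distribution
  of (G₁, G₂) with Cov(G₁,G₂) = p(1−p)(1+F)(2+F)/2 — valid over the
  whole admissible δ range, reducing to the classical outbred table at
  δ = 0.
* **Closed-form heritability bias.** With causal SNPs k = 1..S,
  E[ĥ²] − h² = h² · Σβ²ₖδₖ / Σβ²ₖpₖ(1−pₖ); a single causal SNP with
  p = 0.2, δ = 0.1 and h² = 0.5 gives bias 0.5·0.1/0.16 = 0.3125, so
  the estimate centers near 0.81 instead of 0.5.
* **Type-I error of the score test.** With h² estimated as a nuisance
  parameter the test size is correct even under HWD; with the *true*
  h² plugged in, the size inflates for δ_causal > 0 and deflates for
  δ_causal < 0.
* **Reverse (retrospective) regression.** Regressing genotype on
  phenotype with a genotype covariance Σ_g modelling kinship *plus*
  HWD at the tested SNP restores correct test size, and coincides
  exactly with the forward score test when the covariances match.

## Worked example

`python examples/heritability_bias_grid.py` simulates replicated
sib-pair studies (65 pairs, causal SNP at MAF 0.2, true h² = 0.5),
profiles the REML heritability per replicate without truncation, and
prints:

```
 delta_causal  mean_h2  median_h2  sd_h2  predicted_h2  frac_above_1
        -0.04   0.3716     0.3777 0.2356        0.3750        0.0025
         0.00   0.4909     0.4958 0.2445        0.5000        0.0115
         0.06   0.6761     0.6919 0.2357        0.6875        0.0780
         0.10   0.8034     0.8214 0.2393        0.8125        0.2150
         0.16   0.9828     1.0037 0.2272        1.0000        0.5085
```

The replicate means track the closed-form line h²(p(1−p)+δ)/(p(1−p)):
the true heritability is 0.5 everywhere, yet at δ = 0.10 the estimate
centers near 0.80, and at the boundary δ = 0.16 half the estimates
exceed 1. `examples/type1_error.py` prints the companion test-size
table (estimated-h² LMM and reverse regression stay at the nominal
0.05; fixed-h² inflates with δ_causal), `examples/hwd_basics.py` and
`examples/joint_distribution.py` show the underlying algebra, and
`examples/dataset_workflow.py` walks the single-dataset
simulate/write/fit/test path.

The same pipelines are available from the shell:

```sh
hwdsib bias-grid  --n-reps 2000 --seed 1 --out bias.tsv
hwdsib type1-grid --n-reps 2000 --delta-tested 0.06 --h2-mode fixed:0.5 --out t1.tsv
hwdsib simulate --n-pairs 65 --delta-causal 0.1 --seed 3 --out pairs.tsv
hwdsib fit pairs.tsv
```

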