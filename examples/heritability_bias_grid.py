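"""Heritability-estimate bias across a grid of causal-SNP HWD coefficients.

Simulates replicated sib-pair studies (65 pairs, causal SNP at MAF 0.2,
true heritability 0.5), profiles the LMM heritability per replicate
without truncation, and compares the replicate mean to the closed-form
prediction h2*(pq + delta)/pq.  2,000 replicates per grid point keep
this example fast; the full design uses 10,000.
"""

from hwdlmm import ExperimentConfig, run_bias_grid

cfg = ExperimentConfig(
    delta_causal_grid=(-0.04, 0.0, 0.06, 0.10, 0.16),
    n_replicates=2_000,
    seed=1,
)
table = run_bias_grid(cfg)
cols = ["delta_causal", "mean_h2", "median_h2", "sd_h2", "predicted_h2", "frac_above_1"]
print(table[cols].round(4).to_string(index=False))
print(
    "\nTrue heritability is 0.5 throughout: the estimate is deflated for"
    " delta<0 and inflated for delta>0, tracking the predicted line;"
    " at delta=0.16 a fifth-plus of estimates exceed 1."
)
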