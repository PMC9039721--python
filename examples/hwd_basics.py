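"""HWD algebra: genotype frequencies, admissible bounds, and the heritability bias.

Builds a locus at allele frequency 0.2 with HWD coefficient 0.1 and
prints the quantities the rest of the package is built on.
"""

from hwdlmm import (
    CausalLocus,
    HWDSpec,
    delta_bounds,
    genotype_freqs,
    genotype_variance,
    heritability_bias,
    hwe_chisq_test,
    inbreeding_from_delta,
)

spec = HWDSpec(p=0.2, delta=0.1)
f = genotype_freqs(spec)

print(f"locus: p = {spec.p}, delta = {spec.delta}")
print(f"genotype frequencies (aa, Aa, AA): ({f.p_aa:.2f}, {f.p_Aa:.2f}, {f.p_AA:.2f})")
print(f"inbreeding coefficient F = delta/(pq): {inbreeding_from_delta(spec):.4f}")
print(f"genotype variance 2(pq + delta):      {genotype_variance(spec):.4f}")
lo, hi = delta_bounds(0.2)
print(f"admissible delta range at p=0.2:      [{lo:.2f}, {hi:.2f}]")

# A sample of 100 individuals drawn exactly at those frequencies is
# strongly rejected by the 1-df Pearson HWE test:
res = hwe_chisq_test((74, 12, 14))
print(f"HWE chi-square for counts (74, 12, 14): {res.chi2:.4f} (p = {res.p_value:.3g})")

# If this locus is the single causal SNP of a trait with true
# heritability 0.5, the sib-pair LMM heritability estimate is inflated:
bias = heritability_bias(0.5, [CausalLocus(beta=1.0, p=0.2, delta=0.1)])
print(f"expected heritability bias at h2=0.5:   {bias:.4f} (estimate centers near 0.81)")
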