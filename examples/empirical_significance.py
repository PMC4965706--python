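"""Empirical null, tail p-values, and the r² cutoff for a corrected alpha.

On an effect-free cohort, samples a null distribution of single-SNP r²,
converts an observed value to an empirical tail probability, and asks which
r² cutoff corresponds to a Bonferroni-style corrected alpha.
"""

from ldgwas import (
    SimConfig,
    bin_r2,
    empirical_p,
    r2_cutoff_for_alpha,
    sample_null,
    simulate_matrix,
)

cohort = simulate_matrix(
    SimConfig(n_cases=191, n_controls=279, n_unknown=32, n_snps=400, seed=31)
)
null = sample_null(cohort.matrix, cohort.pheno, 50_000, mode="single", seed=31)

p_at_cutoff = empirical_p(0.025, null)
print(f"empirical p of r2 = 0.025: {p_at_cutoff:.6g}")
# fraction of null draws at or above 0.025 — how surprising that reporting
# threshold is under no association with this cohort's size.

for alpha in (0.05, 0.01, 0.001):
    cut = r2_cutoff_for_alpha(alpha, null)
    flag = "" if cut.attainable else " (unattainable at this null size)"
    print(f"alpha = {alpha}: r2 cutoff = {cut.value:.6g}{flag}")
# the cutoff is the smallest observed null r2 whose tail probability drops
# to alpha; a corrected alpha maps to a stricter r2 threshold.

hist = bin_r2(list(null.samples), 0.005)
print("\nnull r2 histogram (non-empty bins):")
print(hist[hist["count"] > 0].head(6).to_string(index=False))
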