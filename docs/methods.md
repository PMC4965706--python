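# Methods

## Model and observation unit

The package measures association as linkage disequilibrium between genomic
events and a binary phenotype treated as a locus (C₁ = case, C₂ = control).
The observation unit is the **haplotype**: each phenotyped diploid sample
contributes two observations, each carrying the sample's status. All
probabilities are maximum-likelihood frequencies over included
observations; there are no pseudocounts. Unknown-status samples and missing
allele calls never enter any count, so adding or dropping them leaves every
statistic unchanged.

For one SNP, D = p(A₁∧C₁) − p(A₁)p(C₁) is normalized to the Pearson
correlation r = D / √(p(A₁)p(A₂)p(C₁)p(C₂)) of the allele and case
indicator vectors; r² is the score. For a SNP pair, the eight combinations
(i, j, k) ∈ {1,2}³ give D_ijk = p(A_i∧B_j∧C_k) − p(A_iB_j)p(C_k), each
normalized by d_ijk = √(p(A_iB_j)(1−p(A_iB_j))p(C₁)p(C₂)), and
r = max_ijk D_ijk/d_ijk. p(A_iB_j) is a cis-haplotype frequency: both
alleles must lie on the same haplotype, so the statistic literally measures
cis co-occurrence. An individual-level (dosage) mode is deliberately not
provided; the haplotype observation model is the method.

One consequence worth knowing: even a fully penetrant cis interaction does
not drive the pair r² to 1, because a case individual's second, non-cis
haplotype is still a case observation lacking the combination. The
attainable maximum depends on allele frequencies (≈ 0.4 at MAF 0.3–0.4 in
the deterministic limit). r² = 1 requires the combination indicator to
match status on every haplotype.

## Numerical choices

Both statistics are computed from integer contingency counts:
r = (c₁₁c₂₂ − c₁₂c₂₁)/√(row₁·row₂·col₁·col₂) for the single statistic, and
for each pair combination r = (n_joint·n − t·m_k)/√(t(n−t)m₁m₂), where t is
the combination's haplotype count and m₁, m₂ the class counts. These are
algebraically identical to the frequency forms but make the exact
invariances hold to the last bit: allele relabeling and phenotype
relabeling negate r (single) or permute the eight combinations (pair), and
swapping the two SNPs permutes combinations, all on identical integers.

Degenerate cases return r = r² = 0 with a `degenerate` flag instead of NaN
or an exception — a genome-wide scan must not abort on monomorphic sites or
single-class strata. Pair combinations with d_ijk = 0 are **excluded** from
the maximization rather than zero-filled: a 0/0 combination carries no
evidence, and zero-filling could mask a valid negative-only signal. Exact
ties among the eight ratios are broken by lexicographic (i, j, k) order,
first wins.

## Phasing

Unphased genotypes are loaded reference-allele-first (deterministic) and
flagged. For a pair, a sample heterozygous at both SNPs with either site
unphased has an unknown cis arrangement; by default its haplotypes are
included under the loaded order and reported per pair as
`n_phase_ambiguous`, and `strict_phase=True` excludes them. Both behaviors
are exposed because the right choice depends on how the cohort was phased;
the ambiguous count makes the default auditable. No statistical phasing or
imputation is attempted.

## Partitioned scanning

The pair scan is anchors × all: a restricted anchor set (typically SNPs in
a supplied disease-gene list) against every other SNP, since an all-vs-all
scan scales quadratically. The anchor range [start, end) of k partitions
can run anywhere; results stream (memory stays O(L)), and
`merge_partitions` validates the cover (overlaps and gaps are errors) and
sorts canonically by (anchor chrom, pos, partner chrom, pos), making the
merged output byte-identical to a monolithic scan. Reported default
thresholds — r² ≥ 0.025 single, r² ≥ 0.04 pair — are conventional cutoffs
exposed as flags; nothing in the method depends on them.

## Empirical significance

`sample_null` draws SNPs (or SNP pairs) uniformly with replacement and
records their observed r² — the premise being that the overwhelming
majority of sites are null — or, with `permute=True`, recomputes each draw
under a fresh label permutation for a strictly effect-free null. The
default matches the "draw from the observed distribution" construction; the
permutation mode is the statistically cleaner alternative; both are exposed.
`empirical_p` is the fraction of null draws at or above the observed value
(a (k+1)/(n+1) variant guards against p = 0), and `r2_cutoff_for_alpha`
returns the smallest null value whose tail probability reaches alpha.
Resolution is limited not only by the number of draws but by the number of
distinct underlying statistics: with few SNPs the largest observed value is
drawn many times, and alphas below its tie fraction are flagged
unattainable rather than extrapolated.

## Synthetic cohorts

The simulator emulates the shape of a whole-genome case/control cohort with
unknowns (the bundled defaults mirror a 191-case / 279-control / 332-unknown
study) at desk scale. Per SNP an alternate-allele frequency is drawn
uniformly from `maf_range` (default 0.05–0.45); haplotypes are i.i.d.
Bernoulli per sample per SNP — deliberate linkage equilibrium, so every
background pair is a true null and the statistic's behavior is isolated.
Disease liability is logistic:
logit P(case) = baseline + Σ β_s·(allele dosage) + Σ β_p·1[carries ≥ 1 cis
A₁B₁ haplotype], with baseline −1 by default (≈ 27 % penetrance with no
effects, a realistic case fraction). Exact class quotas are met by
seed-deterministic rejection sampling in fixed batches, with a budget of
2000 draws per requested sample before the configuration is rejected as
unattainable. Outputs (phased VCF 4.2, phenotype TSV, truth JSON) are
byte-identical for a fixed config.

What the simulator does **not** model: linkage disequilibrium between
background SNPs, population structure, relatedness, genotyping or phasing
error, and rare-variant site-frequency spectra. Tests passing on these
cohorts therefore demonstrate the statistics' correctness and calibration
under the stated observation model, not robustness to confounding in real
cohorts — in real data, LD between a null SNP and a causal one produces
correlated signals by design, exactly as in ordinary GWAS.

## Test problem sizes

The validation suite uses sizes chosen to make each property measurable on
a single CPU in seconds to minutes: oracle equivalence on 1000+ random
instances of ≤ 50 haplotypes; partition invariance on 12 anchors × 200
SNPs; type-I calibration on twenty 470-sample, 1000-SNP effect-free
cohorts, pooling 20 000 SNP-level decisions against binomial 99 % bounds;
and planted-pair recovery (β = 2.0, MAF 0.3, 500 + 500 samples, 500
background SNPs, anchors × all with 12 anchors) over 20 replicates, where
the planted pair's expected r² (≈ 0.05–0.06) sits far above the null
maximum (≈ 0.01) at that sample size.

## Known limitations

- No asymptotic p-values for r²; significance is empirical only, so its
  resolution is bounded by the null sample.
- Strictly biallelic: multi-allelic sites are skipped (or collapsed to
  ref/alt if biallelic filtering is disabled), never split into pseudo-SNPs.
- No extension beyond pairs, and no LD pruning of the input panel.
- The gene-pair summary groups un-annotated SNPs into 1-Mb positional
  pseudo-genes (`chrom:bucket`), which is a reporting convenience, not a
  biological claim.
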