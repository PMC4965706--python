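# ldgwas

Linkage-disequilibrium GWAS statistics that treat the phenotype as a locus:
single-SNP scans of the correlation between each variant's alleles and
case/control status, and pairwise (epistasis) scans of the correlation
between a SNP pair's cis allele combinations and the phenotype.

## Who this is for

Statistical geneticists analyzing phased case/control cohorts (e.g.
whole-genome studies of Alzheimer's disease) who want an LD-style r²
association score instead of regression p-values, and in particular a
tractable way to screen for **epistatic SNP pairs**: pairs of variants whose
joint haplotype state signals disease even when neither variant shows a
marginal effect. Standard single-marker GWAS assumes additivity and cannot
see such pairs.

## The statistic

Linkage disequilibrium between two events A₁ and B₁ is

```
D = p(A₁ ∧ B₁) − p(A₁)·p(B₁)
r = D / sqrt(p(A₁) p(A₂) p(B₁) p(B₂))
```

Here the second "locus" is the phenotype C with outcomes C₁ = case,
C₂ = control. Observations are **haplotypes**: each phenotyped individual
contributes two, carrying its status. The single-SNP score is r² between
the alternate-allele indicator and the case indicator; r² = 1 means allele
and status always co-occur.

For a SNP pair (A, B) there are eight allele/status combinations
(i, j, k) ∈ {1, 2}³:

```
D_ijk = p(A_i ∧ B_j ∧ C_k) − p(A_i B_j)·p(C_k)
d_ijk = sqrt( p(A_i B_j)·(1 − p(A_i B_j))·p(C₁)·p(C₂) )
r     = max_ijk ( D_ijk / d_ijk ),   r² = r²
```

with p(A_i B_j) a *cis*-haplotype frequency (both alleles on the same
haplotype). The maximization targets the single allele combination most
associated with disease. A single-SNP scan over S samples and L SNPs runs
in O(‖S‖·‖L‖); the pair scan is O(‖S‖·‖L‖²/k) across k partitions that can
run on separate machines and merge to a byte-identical result.

Significance is empirical: a null distribution of r² is sampled (from the
observed, overwhelmingly null statistics, or from label permutations), an
observed r² maps to the fraction of null draws at or above it, and a
multiplicity-corrected alpha maps back to an r² cutoff.

## Worked example

`examples/worked_example.py` runs the packaged 8-haplotype toy (2 cases,
2 controls, 2 SNPs):

```
SNP A vs phenotype: D = 0.125, r = 0.5, r2 = 0.25
pair (A,B) vs phenotype: best combo (i,j,k) = (1, 1, 1), r2 = 0.33333
```

The A₁ allele co-occurs with case status 12.5 percentage points more often
than independence predicts and explains a quarter of the status variance
over haplotype observations. The best pair combination — alternate alleles
at both SNPs in cis, in cases — explains a third: the pairwise signal
exceeds either marginal one. The other examples simulate cohorts with
planted effects, run the partitioned pair scan, and walk the
null/p-value/cutoff machinery:

```
python examples/worked_example.py
python examples/single_scan_simulated.py
python examples/epistasis_scan_partitioned.py
python examples/empirical_significance.py
```

## Command line

```
ldgwas single  --vcf cohort.vcf --pheno status.tsv --min-r2 0.025 --out-prefix run
ldgwas pairs   --vcf cohort.vcf --pheno status.tsv --anchors ad_genes.bed \
               --start 0 --end 100 --k-total 4 --min-r2 0.04 --out-prefix part1
ldgwas merge   --parts part1 part2 part3 part4 --out-prefix merged
ldgwas null    --vcf cohort.vcf --pheno status.tsv --mode pair --n-samples 4000000 --seed 1
ldgwas cutoff  --null-prefix ldgwas --alpha 1e-4
ldgwas summarize --pairs merged.pairs.tsv --out-prefix merged
ldgwas simulate --n-cases 191 --n-controls 279 --n-unknown 332 --n-snps 1000 \
                --planted-pair 0:1:2.0 --seed 1 --out-prefix sim
ldgwas fixture --out-prefix toy
```

Inputs: VCF 4.x with GT fields (phased preferred), a `sample_id<TAB>status`
TSV (`1`/`case`, `0`/`control`, `NA`/`unknown`/`-9`), and optional BED files
of gene regions and anchor genes. Outputs are TSV tables with headers;
default thresholds (0.025 single, 0.04 pair) are ordinary flags, not baked
in.

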