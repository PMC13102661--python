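# miredit

Mutation/editing (M/E) analysis of miRNAs from **single-cell small-RNA
sequencing**: per-cell editing-site calling against pre-miRNA hairpins,
cohort editing-level matrices, cell-type pattern analyses, and correlation
of 3' nucleotide additions with terminal nucleotidyltransferase (TENT)
expression. A fully seeded synthetic-cohort generator makes every stage
testable without any downloads.

## Who this is for

Groups studying post-transcriptional miRNA modification — A-to-I editing by
ADAR (read as A→G), C-to-U editing by APOBEC (read as C→T), and
non-templated 3' adenylation/uridylation by the TENT family — in single-cell
or bulk small-RNA profiles, and anyone who needs a transparent, tested
re-implementation of the classic pileup-and-binomial site-calling recipe.

## The method

For each cell, reads are kept when every base among the first 25 nt has
Phred quality ≥ 30, collapsed to unique sequences (> 18 nt), and aligned to
pre-miRNA hairpins. Each alignment decomposes a read into a templated
**body** (≤ 1 internal mismatch) and a **non-templated 3' tail** (≤ 3 nt).
Multi-locus reads are down-weighted by iterative expression-proportional
reallocation (cross-mapping correction). Weighted pileups yield, per
position and alternative nucleotide, an editing level

```
level = weighted alt count / weighted coverage
```

and a candidate site is **significant** when

1. level ≥ 5 %,
2. raw read support ≥ 10,
3. the Benjamini–Hochberg-adjusted p-value of P(X ≥ k), X ~ Binomial(n, e),
   is < 0.05, with e = 10^(−30/10) = 0.001 from the quality threshold.

Significant sites are classified into nine types — A-to-I, C-to-U, 3'-A,
3'-U, 3'-Other, 5'-editing, Other, SNP, Pseudo — and named
`<precursor>_<pos>_<REF>_<alt>` (reference upper case, variant lower case,
RNA alphabet), e.g. `hsa-mir-376a-1_49_A_g`.

Cohort analyses on the sites × cells level matrix: prevalence filtering
(sites significant in ≥ 5 % of cells, `ceil(0.05 · n)`), PCA and
hierarchical biclustering, cell-type-specific sites (Pearson r > 0.3 and
P < 0.05 against 0/1 type-indicator vectors), within-type variance tiers
(std ≤ 0.2 low, ≤ 0.3 medium, > 0.3 high), Mann–Whitney differential
editing against a reference type (BH-corrected), and an enzyme ×
added-nucleotide mediation grid from Pearson correlations between enzyme
expression and 3'-site levels.

## Worked example

Simulate the default synthetic study (5 cell types × 20 cells, 20 hairpins,
~30 planted sites covering all nine classes), call sites, and analyze:

```bash
miredit simulate --seed 7 --out cohort
miredit call --fastq-dir cohort/fastq --fasta cohort/precursors.fa \
    --gff3 cohort/precursors.gff3 --annotations cohort/cell_annotation.tsv \
    --snp-vcf cohort/snp_catalog.vcf --out called
miredit analyze specific --matrix called/editing_matrix.tsv \
    --types called/cell_types.tsv --out specific.tsv
miredit analyze pca --matrix called/editing_matrix.tsv \
    --types called/cell_types.tsv --out pca_scores.tsv
miredit analyze differential --matrix called/editing_matrix.tsv \
    --types called/cell_types.tsv --reference-type nESC --out diff.tsv
miredit enzymes --expression cohort/enzyme_expression.tsv \
    --matrix called/editing_matrix.tsv --site-types called/site_types.tsv \
    --out enzyme_corr.tsv --grid-out mediation.tsv
```

prints

```
wrote synthetic cohort (100 cells) to cohort
28 sites x 100 cells
15 specific (site, type) pairs
variance explained: 0.204, 0.198, 0.197
24 significant (site, type) pairs
```

28 sites pass the 5 %-prevalence filter (the ~26 planted sites plus the
planted cross-mapping Pseudo pair); the 15 specific pairs are exactly the
planted type-exclusive sites (three per cell type), e.g.
`sim-mir-7_13_A_g` is Leuk-specific with r = 0.997. The first three
principal components carry the between-type structure that k-means recovers
with adjusted Rand index 1.0. The mediation grid starts

```
        Adenine  Uracil  Cytosine  Guanine
TENT2   Y        N       N         N
TENT4A  N        N       Y         N
```

showing the planted TENT2→3'-adenylation and TENT4A→3'-cytosine couplings
(r ≈ 0.8 over 100 cells); because pairs are reported at per-pair P < 0.05
without correction, occasional spurious Y cells appear, as expected at that
threshold (a BH option exists behind a flag).

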