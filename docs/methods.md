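# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic experiments can show. It documents the package's own design;
every number quoted here is computed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Site-calling model

**Quality filter.** A read qualifies when every base among its first
`min(25, length)` bases has Phred ≥ 30 (Phred+33). Reads shorter than 25 nt
are constrained over their whole length — the conservative reading of a
"first 25 nt" rule. Qualified reads are kept whole; there is no quality
trimming, and inputs are assumed adapter-trimmed. Unique sequences longer
than 18 nt (≥ 19) carry integer multiplicities through the rest of the
pipeline.

**Alignment.** Reads are aligned to the precursor set only, not the genome:
at desk scale the hairpins are the only mapping targets, and what matters
downstream is the candidate decomposition — a templated body with at most
one internal mismatch plus a non-templated 3' tail of at most three bases
(`max_tail=3` covers mono-/di-/tri-nucleotide additions; configurable).
Rules, in order, at each start offset:

* the longest valid body wins, so templated explanations beat tail
  explanations;
* a body may not end in a mismatch when a tail follows — a mismatch
  adjacent to the tail belongs to the tail (otherwise a two-base addition
  would be split into "internal edit + one-base tail");
* a tail's first base must mismatch the templated continuation or overhang
  the precursor 3' end;
* reads overhanging the 3' end keep their overhang in the tail, but
  positions past the precursor's last base are never callable (a site name
  requires a templated reference nucleotide).

`align_sample` uses an 8-mer seed index (pigeonhole: a body of ≥ 16 nt with
≤ 1 mismatch contains an exact 8-mer in its first 16 bases); `align_read`
is the exhaustive per-precursor form, and a brute-force enumeration oracle
in the tests checks their agreement on random inputs.

**Cross-mapping correction.** Multi-locus reads are reallocated
iteratively: initialize uniformly, set locus expression to the weighted
read-count sum, re-split each read's weight in proportion to its loci's
expressions, stop when no weight moves by more than `tol = 1e-6` (cap 100
sweeps). Single-locus reads keep weight 1; a read whose loci all reach zero
expression reverts to uniform weights with a logged warning. This is a
simplified, expression-proportional stand-in for published cross-mapping
correction methods — it is not claimed to be equivalent to any of them.

**Statistical test.** Editing level uses cross-mapping-weighted counts; the
support rule uses raw integer counts (conservative reading of "at least 10
reads"). The null is per-base sequencing error at a fixed rate
`e = 10^(-Q/10)` with Q = 30, the only error model derivable from the
stated quality threshold; p = P(X ≥ k) under Binomial(n, e) via a
numerically stable survival function, BH-adjusted across all candidate
sites within a sample. Per-base-quality error models and strand-bias
filters are out of scope.

**Classification.** Decision order: (1) SNP, when the site's genomic
projection (strand-aware, alleles complemented on minus-strand loci)
matches a user-supplied catalog record and the site reaches a 100 % level
in at least one cohort sample; (2) Pseudo, when the mean cross-mapping
weight of the supporting reads is below 0.5 (an artifact-level threshold —
the concept of a site explained by reads from another locus is inherited,
the cutoff is ours); (3) position relative to the mature arm: the arm is
attributed from the supporting reads' body overlap (majority vote), with a
fallback to the nearest arm whose 3' end precedes the site. Past the arm's
3' end → 3'-A / 3'-U / 3'-Other keyed by the added nucleotide; before its
5' start → 5'-editing; inside the arm, A→G is A-to-I, C→T is C-to-U,
anything else Other. Read-based arm attribution is what makes sites inside
the 3p arm body classify as central rather than as 3' additions of the 5p
arm, and 5'-extensions of the 3p arm as 5'-editing. Precursors without
mature annotation are treated as all-body with a warning. Only
single-nucleotide substitutions and single-position tail additions are
considered.

## Cohort analyses

* **Prevalence filter:** a site enters the matrix when significant in at
  least `ceil(0.05 · n_cells)` cells (23 of 448 at the study scale the
  arithmetic mirrors). Matrix entries: the cell's level; 0 when the
  position is covered but the variant unobserved; NA at zero coverage.
* **NA policy:** NA is imputed to 0 for PCA, clustering and correlations —
  undetected editing at zero depth is closest to "no observed editing" —
  and written out as NA in TSVs so users can re-impute.
* **PCA:** column-mean-centered, unscaled SVD (scaling to unit variance is
  deliberately off; levels share a [0,1] scale). Signs are fixed by making
  each loading vector's largest-magnitude entry positive.
* **Clustering:** Euclidean distance, complete linkage, rows and columns
  independently; deterministic leaf order; Newick export.
* **Specificity:** Pearson r between a site's levels and each type's 0/1
  indicator, two-sided p from t = r·sqrt((n−2)/(1−r²)) with n−2 df;
  specific iff r > 0.3 and p < 0.05. Spearman available behind a flag.
  Vectors that are numerically constant (sum of squared deviations
  ≤ 1e−20) give undefined r and are never specific.
* **Variance tiers:** population (n-denominator) standard deviation within
  each type; zero / low (≤ 0.2) / medium (≤ 0.3) / high (> 0.3), boundary
  values falling into the lower tier; the reported low-variance class is
  zero ∪ low. The n vs n−1 denominator distinction is immaterial at cohort
  sizes but fixed for determinism.
* **Differential editing:** two-sided Mann–Whitney per site against the
  reference type; exact null when the pooled size is ≤ 16 with no ties,
  otherwise the normal approximation with tie and continuity corrections;
  BH within each type-vs-reference comparison; significance on the
  adjusted p by default (raw behind a flag, since the wording of such
  pipelines is often ambiguous on this point).
* **Enzyme correlation:** Pearson r with the same t-based p over cells
  shared between the expression and editing matrices (≥ 3 required),
  restricted to 3' sites; positively significant iff r > 0 and p < 0.05,
  per pair, uncorrected — matching how such mediation evidence is usually
  reported; a BH option exists behind a flag and logs a caveat. The
  mediation grid marks an (enzyme, added-nucleotide) cell Y when at least
  one positively significant pair supports it. Note the per-pair test is
  anticonservative when site vectors are strongly type-structured and
  expression is heavy-tailed (lognormal): spurious Y cells at a few
  percent per pair are expected and visible in the worked example.

## Synthetic cohort generator

The generator emulates the study conditions end to end and writes full
ground truth. Defaults (the shipped scenario): 5 cell types named after the
cohort it emulates (GBM, HEK293FT, Leuk, nESC, pESC) × 20 cells; 20
hairpins of 70–90 nt with 22-nt 5p/3p arms on a toy genome (a quarter of
loci on the minus strand, exercising the coordinate arithmetic); ~26
planted sites: three exclusive sites per type (two 3' additions and one
central A-to-I, in-type mean 0.8, std 0.05 — mirroring the observation that
type-specific sites are mostly 3'-U/3'-A), three shared variance-tier sites
(mean 0.5; std 0.05 / 0.25 / 0.35), shared central A-to-I, C-to-U, Other
and 5'-editing sites (means 0.3–0.45), three enzyme-coupled 3' sites
(TENT2→A, TUT7→U, TENT4A→C), one SNP-like site at level 1.0 with a matching
VCF record, and a cross-mapping decoy pair planting a Pseudo site.

Mechanics: per cell and precursor, coverage is negative binomial (mean 150,
size 5; Poisson configurable) split evenly between arms — the
overdispersion reproduces the large spread of valid reads across real
cells. Per-cell true levels are Beta draws matched by moments to the type's
mean and std (degenerate means are constants; the generator rejects
configs with std² ≥ μ(1−μ)). Edits apply independently per read (Bernoulli
at the cell's level), matching the binomial model the caller assumes. A 3'
event's position is covered with probability 0.5 per arm read (templated
extension vs added base), so the measured level is unbiased for the planted
level; 5' events mirror this. Sequencing errors are uniform at e = 0.001
with at most one substitution per affected read (multi-error reads are
negligible at this rate). Quality strings are Q40 everywhere; a configured
fraction (default 2 %) of *extra* junk reads carry one low-quality base in
the first 25 nt so the Q30 filter has something to remove without
disturbing the planted coverage. Enzyme expression is log-normal
(log-mean 2.0, log-sd 0.6); coupled sites take
`level = clip(0.4 + 0.18·z + N(0, 0.08))` of the z-scored expression
(r ≈ 0.9). The decoy precursor shares the target's 5p arm up to one
substitution and draws coverage at 5× the mean with proportionally scaled
NB size (a constitutively high-expression locus); its reads call an
apparent site on the target whose supporting reads carry mean weight ≈ 1/6.
Coverage noise can still flip the dominance in a rare cell, so Pseudo
classification is asserted as a ≥ 90 % property, not per-cell.

Everything is bit-reproducible from the seed (independent child streams for
reference, expression and cells).

**What the generator does not model:** realistic quality-score error
profiles, ligation bias, adapter read-through, 5'-isomiR heterogeneity
beyond single-base extensions, UMIs, or the real cohort's composition
(448 cells across labs). Passing tests therefore show the pipeline is
correct under its own statistical assumptions — Bernoulli edits, uniform
errors, hairpin-only mapping — not that it reproduces any real cohort's
site list.

## Problem sizes and tolerances in the checks

The shipped experiments use: the default 100-cell cohort for recovery,
classification, PCA/k-means (ARI ≥ 0.8) and the mediation grid; 20
independent null runs of 100 cells × 50 precursors at coverage 100 for
type-I control (zero significant calls expected in ≥ 95 % of runs); 10
seeds of 75-cell matrices for specificity (all planted exclusive sites
recovered; ≤ 5 % false flags on uniform sites); 10 seeds of 100-cell
matrices for variance tiers (≥ 90 % correct); 50 seeds at n = 19 cells for
enzyme power at true ρ = 0.5 (majority detected; the null rate stays within
0.05 + 2·sqrt(0.05·0.95/N)). "Criterion-satisfying in expectation" for
recovery means the planted level and support clear the 5 % and 10-read
thresholds by three binomial standard deviations — at the thresholds
themselves, recovery is 50 % by construction, so a margin is part of the
property's definition. Level recovery is asserted within
3·sqrt(λ(1−λ)/n) for ≥ 99 % of called planted events. Exact-oracle
agreement: BH vs an independent step-up on 1,000 random vectors (n ≤ 20),
Mann–Whitney vs full enumeration for all group sizes with n+m ≤ 10,
binomial survival p vs a big-rational sum for n ≤ 50 (relative error
~1e−15). The two-locus cross-mapping fixture (shared count 10, unique
support 9 vs 1) has the hand-solvable fixed point w = (9 + 10w)/20 = 0.9
and converges within 1e−6.

## Known limitations

* The cross-mapping reallocation is a documented simplification; weights
  depend only on precursor-level expression, not on alignment quality.
* The binomial null ignores per-base quality variation; with recalibrated
  qualities the fixed-e model is conservative at high-quality positions.
* The Pseudo threshold (mean weight < 0.5) and the arm-attribution
  majority vote are package-level decisions; alternative conventions would
  shift a small number of classifications between neighboring categories.
* Editing levels at multi-site arms are planted independently per site;
  haplotype-like co-editing along one read is not modeled.
* The SNP rule requires a user-supplied catalog (VCF subset); no databases
  are bundled or downloaded.
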