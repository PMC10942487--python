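# Methods

This note documents the models, conventions and numerical choices behind
`betatype`, and what the synthetic validation does and does not show.

## Synthetic data model

**Counts.** Cells are drawn per sample with fixed cell-type proportions; β
cells split into latent subtypes A (reporter⁺) and B. Gene baseline rates
are lognormal(0, 1); per-cell library sizes lognormal(log 2000, 0.3);
counts are gamma-Poisson (negative binomial, dispersion 0.1) — the
standard overdispersed model for droplet scRNA-seq, which never states
its own count model in closed form. Cell-type markers (5 per type) are
elevated 20-fold in their own type, the magnitude of canonical islet
markers such as *Ins1*/*Gcg*. Mitochondrial-tagged genes are rescaled to
contribute 5% of each library. The lineage reporter is bimodal: expected
normalized expression 10 in subtype A and 0.002 in B, so the arcsinh
histogram is cleanly two-modal around the 0.9 gate.

**Planted differential expression.** Subtype effects are parameterized on
the arcsinh scale: a gene with expected normalized mean μ gets the
multiplicative rate change f = sinh(asinh μ + δ)/μ, whose plug-in arcsinh
difference is exactly δ (Jensen shrinkage at low expression is accepted
and covered by the recovery margins). Effects alternate up/down and are
planted on genes with moderate expression (expected normalized mean in
[0.25, 20]), where a 0.2 arcsinh shift is estimable at all.

**Methylomes.** CpG positions have exponential spacing (mean 100 bp) on
two 2-Mb chromosomes (~40k CpGs); background methylation 0.75; 40 shared
hypomethylated windows at level 0.1 and 30 differential windows of 8
consecutive CpGs shifted ±0.4 in group A (up-shifts clip at 1.0 with a
logged warning, mirroring the bounded nature of methylation levels).
Coverage is Poisson(30); methylated reads are binomial at the local
level. Windows are placed on disjoint CpG runs with buffer gaps, so truth
windows never overlap.

**Annotations.** Non-overlapping gene models (25 per chromosome, one per
length-slot), random strand, TSS = start (+) or end − 1 (−), 3′UTR = the
terminal 10% of the body. All coordinates are 0-based half-open
everywhere in the package.

**What the generator does not emulate:** ambient RNA, doublets, batch
effects, transcript-length bias, strand-resolved CpGs, beta-binomial
methylation dispersion. Passing tests therefore demonstrate correctness
of the procedures and their calibration under idealized sampling noise,
not robustness to those artifacts.

## Transformation and gating

Normalization scales each cell to the median library size;
arcsinh is applied elementwise (log-like, defined at zero); z-scoring is
per gene with the convention that constant genes get z = 0 rather than
NaN. Zero-library cells are dropped with a warning rather than divided
by zero. The reporter cutoff (default 0.9) is applied on the arcsinh
stage, before z-scoring: z-scoring recenters every gene at zero, which
would make a fixed absolute cutoff meaningless across datasets. A
`scale="zscore"` option exists for matrices gated on the standardized
scale. The gate uses strict `>`; boundary cells are negative
("positivity being 0.9" read as exceedance).

## Pseudobulk paired DE

Arcsinh values are averaged per gene per (sample, reporter group);
samples missing a group are excluded and logged; fewer than two usable
samples is an error. The low-expression floor (0.002, roughly one read
per cell after transformation) removes a gene if **any** sample/group
falls below it — the strictest reading, which keeps every retained
gene's pairs complete; the boundary is inclusive. The paired t-test is
two-sided across samples; the pass rule is p < 0.05 **and** |mean
difference| ≥ 0.05 on the arcsinh scale (≈5% multiplicative change).
Zero-variance conventions: all-zero differences give p = 1, constant
nonzero differences give p = 0 (the t statistic's limits); differences
constant up to floating-point noise are treated the same. No
multiple-testing correction is applied to the pass rule (the stated
criterion is a raw p), but a BH-adjusted q column is emitted for users.

## HMR and DMR calling

The original analyses delegate segmentation to an external methylation
toolkit whose model is not restated; this package substitutes a
deterministic, auditable procedure and keeps the explicit gates. HMRs:
a centered moving average over 3 CpGs, maximal runs below τ = 0.5 with
inter-CpG gaps ≤ 1 kb and ≥ 4 CpGs. DMRs: per-CpG two-sided Fisher exact
test on (methylated, unmethylated) × (group A, B); CpGs with p < 0.05
and consistent difference sign merge when ≤ 500 bp apart; a region is
kept iff span ≥ 50 bp and ≥ 2 significant CpGs. The span convention is
(last CpG − first CpG + 2), covering the terminal dinucleotide.
Zero-coverage CpGs are skipped. `mean_diff` is the mean per-CpG level
difference over the region and `fold` the higher group mean over the
lower; the gates are asserted on every output. The merge gap (500 bp)
and sign-consistency splitting are this package's choices, both
configurable. Under the per-CpG α, a null genome emits isolated small
regions at the rate the α and merging imply; the permutation-baseline
test bounds this against per-CpG group-label shuffles. Region clustering
is k-means (k = 6, 10 restarts, fixed seed) on per-condition mean
levels, flagging clusters whose centroid max/min ratio exceeds 1.8.

## Regulatory domains and DMR location

Basal domains are strand-aware TSS windows (5 kb upstream / 1 kb
downstream — the GREAT defaults, since only "default protocol" is
stated); extension proceeds per side to the nearest other basal edge,
capped at 1 Mb beyond the basal edge and truncated at chromosome ends;
overlapping basal domains degenerate the extension to the basal window
(logged). Assignment is half-open interval overlap — a 1-bp touch does
not count. DMR-to-gene distance is midpoint-to-TSS (the source defines
none). The regulatory window for location classification runs from 2 kb
5′ of the TSS through the 3′UTR end, strand-aware. The curated-domain
layer of GREAT is omitted: no curated set exists for toy genomes.

## Enrichment statistics

Hypergeometric overlap p is the upper tail P(X ≥ k) (enrichment;
depletion via `tail="lower"`); expected overlap |A||B|/|U| and fold =
observed/expected. Fisher tests are two-sided by the point-probability
rule. The gene universe must be supplied explicitly (the defaults used
in the original enrichment claims are not recoverable); the pipeline
uses genes surviving the low-expression filter.

## Signature scoring and the Gini test

Genes are placed in 25 equal-frequency mean-expression bins; each
signature gene draws ~100 controls from its own bin without replacement
(total pool ≈ 2000 — "reference sample size" read as the control pool;
the per-cell score is mean(signature) − mean(controls), with the control
average weighted by the signature's bin occupancy so depleted bins do
not bias the score. Pop1 is score > 0.2, strict inequality. The
clusteredness statistic is the Gini index (normalized mean absolute
difference, computed by the sorted closed form) of per-cell signature
means, with a permutation null of bin-matched random gene sets and the
add-one p-value (1 + #{null ≥ obs})/(1 + n_perm); the external toolkit
the original analysis used does not document its statistic, so this
definition is this package's own, stated here precisely. Subpopulation
DE is two-sided Wilcoxon rank-sum (exact for groups ≤ 10 cells,
tie-corrected normal approximation otherwise) with BH adjustment at
q < 0.05 and a signed-z rank score for pre-ranked enrichment.
Score-group comparisons run Kruskal–Wallis first and only run pairwise
Mann–Whitney U when the omnibus p < 0.05 (two groups degenerate to a
single MWU). Population fractions are compared per donor with an
equal-variance two-sample t-test; constant-but-shifted fractions report
p = 0 by convention.

## Pre-ranked enrichment

The classic weighted running sum: +|score|^p/Σ_hits|score|^p at hits,
−1/(N−k) at misses, ES = the extremum of largest magnitude. Computed as
a ratio of cumulative sums so the boundary cases (top-k / bottom-k sets
at p = 0) evaluate to exactly ±1. The null permutes gene sets (not
phenotypes — the input is already a ranked list); NES divides ES by the
mean |null ES| of the same sign; p uses the add-one rule over same-sign
permutations, reported as a bound with a warning if no permutation
shares the sign. Default weight p = 1.

## Study sizes used for validation

Chosen once as the synthetic study conditions: DEG calibration and
recovery use 4 samples of 500–1000 β cells (≈250–500 cells per reporter
group per sample), 1000 genes, 100 planted effects of 0.2; methylome
validation uses two 2-Mb chromosomes at 30× coverage with 30 planted
windows of δ = 0.4; the signature arm uses 2000 cells with a 30%
subpopulation carrying a +0.5 arcsinh 20-gene module — a minority Pop1,
matching the "visually notable subpopulation" reading of the human arm;
with an even 50/50 split the bin-matched controls absorb half the
planted shift and a fixed 0.2 threshold cannot separate the
populations, regardless of scorer.

## Known limitations

- The DMR caller is a per-CpG Fisher + merging substitute, not a
  beta-binomial or HMM segmenter; its absolute region counts are not
  comparable to toolkit-specific callers, only its gated behavior is.
- The Gini statistic and its null are this package's definition of
  "clustered expression"; other toolkits normalize differently.
- Enrichment p-values depend strongly on the chosen universe, which must
  be supplied by the user.
- The simulator's idealized noise means calibration results (e.g. the
  5% type-I error) translate to real data only to the extent the paired
  pseudobulk design absorbs cell-level artifacts.
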