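# betatype

Lineage-resolved β-cell subtype analysis in Python: reporter-gated cell
classification, pseudobulk paired differential expression, whole-genome
bisulfite DMR calling with regulatory-domain gene association, exact
set-overlap enrichment, and gene-signature subpopulation scoring — plus a
seeded synthetic-data generator so the entire pipeline is testable end to
end without any sequencing data.

## The scientific problem

Pancreatic islets contain β-cell subtypes of different insulin-secretion
capacity that descend from distinct embryonic progenitor pools. When the
descendants of one pool carry a heritable fluorescent lineage reporter
(e.g. tdTomato/eYFP), single-cell RNA-seq and whole-genome bisulfite
sequencing of the sorted subtypes can ask three questions:

1. **Which genes differ between the subtypes?** Cells are normalized to
   the median library size, arcsinh-transformed, and gated on the reporter
   transcript (positive iff arcsinh expression > 0.9). Per sample, the two
   reporter groups are averaged into pseudobulk profiles; genes below an
   arcsinh floor of 0.002 in any sample are removed; the remaining genes
   are tested with a paired t-test across samples, a gene being called
   differentially expressed when p < 0.05 and the mean paired difference
   is at least 0.05 (≈5% on the log-like scale).
2. **Which regulatory regions differ in DNA methylation?** Per shared CpG
   a Fisher exact test compares methylated/unmethylated read counts
   between groups; significant CpGs of consistent sign are merged into
   differentially methylated regions (DMRs), gated at span ≥ 50 bp and
   ≥ 2 significant CpGs (p < 0.05). Hypomethylated regions (HMRs) are
   segmented by smoothing + thresholding and clustered (k-means, k = 6)
   by their methylation changes, flagging clusters whose centroid changes
   more than 1.8-fold. DMRs are tied to putative target genes through
   GREAT-style basal-plus-extension regulatory domains (5 kb/1 kb basal,
   extension capped at 1 Mb) and classified as regulatory when they fall
   between 2 kb upstream of the TSS and the 3′UTR. DEG/DMR overlaps are
   scored with upper-tail hypergeometric and two-sided Fisher exact tests.
3. **Do equivalent subpopulations exist in other (e.g. human) datasets?**
   A 20-gene signature is scored per cell as the mean signature expression
   minus the mean of expression-bin-matched control genes (control pool of
   2000 genes); cells scoring above 0.2 are Pop1, the rest Pop2. A Gini
   index of per-cell signature means with a bin-matched permutation null
   tests whether the signature is expressed in a clustered rather than
   uniform manner; Wilcoxon rank-sum DE and pre-ranked running-sum
   gene-set enrichment (GSEA) characterize the populations, and
   per-donor Pop1 fractions are compared between conditions with an
   equal-variance t-test.

Since the analysis is validated on synthetic data, the package ships a
first-class generator (`betatype.simulate`) that draws negative-binomial
count matrices with a bimodal lineage reporter, planted subtype DEGs and
cell-type markers, two-group CpG methylomes with planted HMR/DMR windows,
and toy gene annotations — all with recorded ground truth.

## Worked example

```python
from betatype import prep, pseudobulk
from betatype.simulate import SimConfig, simulate_counts

cfg = SimConfig(seed=1, cell_type_proportions={"beta": 1.0},
                n_cells_per_sample=1000)
adata, truth = simulate_counts(cfg)
adata = prep.normalize_transform(adata)
labels = prep.reporter_gate(adata, cfg.reporter_gene, cutoff=0.9)
pb = pseudobulk.filter_low_expression(
    pseudobulk.pseudobulk_means(adata, labels), min_level=0.002)
deg = pseudobulk.paired_deg(pb, alpha=0.05, min_diff=0.05)
```

Running `python examples/02_pseudobulk_deg.py` (the script behind the
snippet) prints:

```
999 genes tested after the low-expression filter
105 DEGs called; sensitivity 0.99, false-discovery proportion 0.06
```

meaning 99% of the 100 planted subtype effects (0.2 on the arcsinh scale)
are recovered and 6% of the calls are noise — the expected behavior of a
raw-p 0.05 criterion combined with the 0.05 minimum-difference gate at
this study size. The other `examples/` scripts walk the methylome, the
regulatory-domain assignment, the signature/Gini workflow and pre-ranked
GSEA the same way.

## Command line

A thin CLI wraps the library for shell use:

```bash
betatype simulate --out data --seed 1
betatype dmr --a data/group_a.meth --b data/group_b.meth --out dmrs.bed
betatype link --dmrs dmrs.bed --genes data/genes.tsv --out links.tsv
betatype run-all --simulate --seed 7 --out results/
```

`run-all` writes every stage table plus a manifest with parameter and
file hashes; identical seeds give byte-identical outputs.

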