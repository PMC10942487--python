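"""End-to-end orchestration on simulated inputs: simulate -> QC/transform
-> reporter gate -> pseudobulk DEG -> HMR/DMR calling and clustering ->
regulatory-domain gene assignment -> cross-modality enrichment ->
signature scoring -> pre-ranked enrichment.

Every stage writes a TSV under the output directory and the run ends with
a manifest (parameters, seed, SHA-256 of every output) so identical seeds
give byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dmrlink, enrich, gsea, io, methylome, prep, pseudobulk, signature
from .config import PipelineParams
from .simulate import SimConfig, simulate_annotation, simulate_counts, simulate_methylome

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    params: PipelineParams,
    outdir: str | Path,
    sim_config: SimConfig | None = None,
) -> dict:
    """Run the simulated pipeline and return the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params.validate()
    sim = sim_config or SimConfig(seed=params.seed)

    # --- simulate ---------------------------------------------------------
    adata, truth = simulate_counts(sim)
    meth_a, meth_b, meth_truth = simulate_methylome(sim)
    genes = simulate_annotation(sim)
    io.write_counts(adata, outdir / "counts")
    io.write_methylome(meth_a, outdir / "group_a.meth")
    io.write_methylome(meth_b, outdir / "group_b.meth")
    io.write_annotation(genes, outdir / "genes.tsv")
    truth_rows = [
        {"kind": "deg", "id": g, "direction": d, "effect": e}
        for g, d, e in sorted(truth.deg_genes)
    ] + [
        {"kind": "dmr", "id": f"{c}:{s}-{e}", "direction": sign, "effect": sim.dmr_delta}
        for c, s, e, sign in meth_truth.dmr_regions
    ]
    pd.DataFrame(truth_rows, columns=["kind", "id", "direction", "effect"]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )

    # --- prep + reporter gate --------------------------------------------
    adata = prep.qc_filter(adata, min_counts=params.min_counts, max_mito=params.max_mito)
    adata = prep.normalize_transform(adata, zscore=True)
    reporter = prep.reporter_gate(
        adata, sim.reporter_gene, cutoff=params.reporter_cutoff
    )
    markers = {
        t: [g for g in adata.var_names if g.startswith(f"mk-{t}-")]
        for t in sorted(sim.cell_type_proportions)
    }
    cell_types = prep.label_celltypes(adata, markers)
    obs = adata.obs.copy()
    obs["reporter"] = reporter
    obs["cell_type"] = cell_types
    obs.to_csv(outdir / "cell_labels.tsv", sep="\t")
    fractions = prep.subtype_fraction(
        reporter[cell_types == "beta"],
        by=adata.obs.loc[cell_types == "beta", "sample_id"],
    )
    fractions.to_csv(outdir / "reporter_fractions.tsv", sep="\t")

    # --- pseudobulk DEG (beta cells only) --------------------------------
    beta = adata[(cell_types == "beta").to_numpy()].copy()
    beta_reporter = reporter[(cell_types == "beta").to_numpy()]
    pb = pseudobulk.pseudobulk_means(beta, beta_reporter)
    pb = pseudobulk.filter_low_expression(pb, min_level=params.low_expr_min)
    deg = pseudobulk.paired_deg(
        pb, alpha=params.deg_alpha, min_diff=params.deg_min_diff
    )
    deg.to_csv(outdir / "deg.tsv", sep="\t")

    # --- methylome --------------------------------------------------------
    hmrs = methylome.call_hmrs(
        meth_a,
        tau=params.hmr_tau,
        min_cpgs=params.hmr_min_cpgs,
        max_gap=params.hmr_max_gap,
    )
    dmrs = methylome.call_dmrs(
        meth_a,
        meth_b,
        cpg_alpha=params.cpg_alpha,
        min_span=params.dmr_min_span,
        min_cpgs=params.dmr_min_cpgs,
        max_gap=params.dmr_max_gap,
    )
    io.write_regions_bed(hmrs, outdir / "hmrs.bed")
    io.write_regions_bed(dmrs, outdir / "dmrs.bed")
    if len(hmrs) >= params.hmr_k:
        levels = hmrs[["mean_level_a"]].copy()
        # second condition: the same regions in the other group's methylome
        levels["mean_level_b"] = _region_means(meth_b, hmrs)
        labels, clusters = methylome.cluster_regions(
            levels,
            k=params.hmr_k,
            fold_flag=params.fold_flag,
            seed=params.seed,
        )
        clusters.to_csv(outdir / "hmr_clusters.tsv", sep="\t")

    # --- regulatory domains + assignment ---------------------------------
    domains = dmrlink.build_regulatory_domains(
        genes,
        basal_up=params.great_basal_up,
        basal_down=params.great_basal_down,
        max_ext=params.great_max_ext,
        chrom_sizes={f"chr{i + 1}": sim.chrom_length for i in range(sim.n_chroms)},
    )
    assignments = dmrlink.assign_dmrs(dmrs, domains)
    assignments = dmrlink.location_summary(
        assignments, genes, upstream=params.enhancer_upstream
    )
    assignments.to_csv(outdir / "dmr_gene_links.tsv", sep="\t", index=False)

    # --- cross-modality enrichment ---------------------------------------
    # map simulated transcriptome genes onto annotation genes by rank so
    # the toy genome and the toy transcriptome share one namespace
    assigned = assignments.dropna(subset=["gene_id"])
    enrichment = {}
    deg_genes = set(deg.index[deg["pass"]])
    universe = set(deg.index)
    gene_map = _annotation_to_expression_map(genes, list(deg.index))
    dmr_assoc = {
        gene_map[g] for g in assigned["gene_id"] if g in gene_map
    } & universe
    if deg_genes and dmr_assoc:
        res = enrich.deg_dmr_association(deg_genes, dmr_assoc, universe)
        enrichment["deg_dmr_fisher"] = res.as_dict()
    with open(outdir / "enrichment.json", "w") as fh:
        json.dump(enrichment, fh, indent=2, sort_keys=True)

    # --- signature scoring on beta cells ---------------------------------
    up_degs = [g for g in deg.index[deg["pass"] & (deg["direction"] == "up")]]
    sig_genes = up_degs[:20]
    score_rows = {}
    if len(sig_genes) >= 5:
        scores = signature.module_score(
            beta,
            sig_genes,
            n_bins=params.n_bins,
            ctrl_pool=params.ctrl_pool,
            seed=params.seed,
        )
        pops = signature.classify_population(scores, threshold=params.pop_threshold)
        gini = signature.gini_signature_test(
            beta, sig_genes, n_perm=params.n_perm, seed=params.seed,
            n_bins=params.n_bins,
        )
        score_df = pd.DataFrame(
            {
                "score": scores,
                "population": pops,
                "donor_id": beta.obs["sample_id"],
            }
        )
        score_df.to_csv(outdir / "signature_scores.tsv", sep="\t")
        score_rows = {"gini": gini["gini"], "gini_p": gini["p"]}

        de = signature.subpop_de(beta, pops)
        de.to_csv(outdir / "subpop_de.tsv", sep="\t")
        ranked = gsea.RankedList(list(de.index), de["rank_score"].to_numpy())
        g = gsea.gsea_permutation(
            ranked, sig_genes, n_perm=min(params.n_perm, 500), seed=params.seed
        )
        score_rows.update({"gsea_es": g["es"], "gsea_p": g["p"]})
    with open(outdir / "signature_summary.json", "w") as fh:
        json.dump(score_rows, fh, indent=2, sort_keys=True)

    # --- manifest ---------------------------------------------------------
    outputs = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "params": params.as_dict(),
        "sim_seed": sim.seed,
        "n_cells": int(adata.n_obs),
        "n_genes": int(adata.n_vars),
        "n_degs": int(deg["pass"].sum()),
        "n_hmrs": int(len(hmrs)),
        "n_dmrs": int(len(dmrs)),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _region_means(meth: pd.DataFrame, regions: pd.DataFrame) -> list[float]:
    """Mean methylation level of each region in a CpG table."""
    out = []
    for r in regions.itertuples():
        sub = meth[
            (meth["chrom"] == r.chrom)
            & (meth["pos"] >= r.start)
            & (meth["pos"] < r.end)
            & (meth["total_reads"] > 0)
        ]
        out.append(
            float((sub["meth_reads"] / sub["total_reads"]).mean())
            if len(sub)
            else float("nan")
        )
    return out


def _annotation_to_expression_map(
    genes: pd.DataFrame, expr_genes: list[str]
) -> dict[str, str]:
    """Pair annotation gene ids with expression gene ids positionally.

    The simulator draws the transcriptome and the toy genome independently;
    this deterministic pairing gives the cross-modality stages a shared
    gene namespace.
    """
    ann = list(genes["gene_id"])
    return {a: e for a, e in zip(ann, expr_genes)}
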