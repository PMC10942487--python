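"""File-format readers and writers: MTX + TSV count bundles, MethPipe-style
CpG tables, annotation TSV, BED6+ region sets, GMT gene sets."""

from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "write_counts",
    "read_counts",
    "write_methylome",
    "read_methylome",
    "write_annotation",
    "read_annotation",
    "write_regions_bed",
    "read_regions_bed",
    "write_gmt",
    "read_gmt",
]

_METH_COLS = ["chrom", "pos", "strand", "context", "meth_level", "total_reads"]


def write_counts(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write a count bundle: matrix.mtx (genes x cells), features.tsv,
    barcodes.tsv, cell_metadata.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    sio.mmwrite(outdir / "matrix.mtx", X.T.astype(np.int64))
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    meta = adata.obs.copy()
    if "mito" in adata.var.columns:
        adata.var.to_csv(outdir / "gene_metadata.tsv", sep="\t")
    meta.to_csv(outdir / "cell_metadata.tsv", sep="\t")


def read_counts(indir: str | Path) -> ad.AnnData:
    """Read a count bundle written by :func:`write_counts`."""
    indir = Path(indir)
    try:
        X = sio.mmread(indir / "matrix.mtx")
    except Exception as exc:  # mmread errors are unhelpful about location
        raise ValueError(f"malformed MTX file {indir / 'matrix.mtx'}: {exc}")
    genes = pd.read_csv(
        indir / "features.tsv", sep="\t", header=None
    )[0].astype(str)
    cells = pd.read_csv(
        indir / "barcodes.tsv", sep="\t", header=None
    )[0].astype(str)
    X = sparse.csr_matrix(X).T  # back to cells x genes
    if X.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {X.shape} does not match "
            f"{len(cells)} barcodes x {len(genes)} features"
        )
    adata = ad.AnnData(
        X=np.asarray(X.todense()),
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame(index=genes),
    )
    meta_path = indir / "cell_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        adata.obs = meta.loc[cells]
    gene_meta_path = indir / "gene_metadata.tsv"
    if gene_meta_path.exists():
        adata.var = pd.read_csv(gene_meta_path, sep="\t", index_col=0).loc[genes]
    return adata


def write_methylome(table: pd.DataFrame, path: str | Path) -> None:
    """Write a MethPipe-style six-column CpG TSV (chrom, pos, strand,
    context, meth_level, total_reads) plus a companion ``meth_reads``
    column."""
    out = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "pos": table["pos"],
            "strand": table["strand"],
            "context": table["context"],
            "meth_level": table["meth_reads"]
            / np.maximum(table["total_reads"], 1),
            "total_reads": table["total_reads"],
            "meth_reads": table["meth_reads"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def read_methylome(path: str | Path) -> pd.DataFrame:
    """Read a MethPipe-style CpG TSV; accepts the 6-column dialect (level
    is converted back to read counts by rounding) or the 7-column dialect
    with explicit meth_reads."""
    try:
        df = pd.read_csv(path, sep="\t", header=None)
    except Exception as exc:
        raise ValueError(f"malformed methylome TSV {path}: {exc}")
    if df.shape[1] == 6:
        df.columns = _METH_COLS
        df["meth_reads"] = np.rint(
            df["meth_level"] * df["total_reads"]
        ).astype(np.int64)
    elif df.shape[1] == 7:
        df.columns = _METH_COLS + ["meth_reads"]
    else:
        raise ValueError(
            f"{path}: expected 6 or 7 columns, found {df.shape[1]}"
        )
    bad = df.index[df["meth_reads"] > df["total_reads"]]
    if len(bad):
        raise ValueError(
            f"{path}: meth_reads > total_reads at line {bad[0] + 1}"
        )
    return df[
        ["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]
    ].sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "strand", "utr3_start"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write a RegionSet as BED6+ (name, score = int(1000|mean_diff|),
    strand '.', then n_cpg, per-group means, mean_diff, fold, p_min)."""
    rows = []
    for i, r in enumerate(regions.itertuples()):
        mean_diff = getattr(r, "mean_diff", float("nan"))
        score = int(round(1000 * abs(mean_diff))) if np.isfinite(mean_diff) else 0
        rows.append(
            [
                r.chrom,
                int(r.start),
                int(r.end),
                f"{getattr(r, 'kind', 'region')}_{i}",
                score,
                ".",
                int(getattr(r, "n_cpg", 0)),
                getattr(r, "mean_level_a", float("nan")),
                getattr(r, "mean_level_b", float("nan")),
                mean_diff,
                getattr(r, "fold", float("nan")),
                getattr(r, "p_min", float("nan")),
            ]
        )
    pd.DataFrame(rows).to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6g"
    )


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None)
    except Exception as exc:
        raise ValueError(f"malformed BED file {path}: {exc}")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    names = [
        "chrom", "start", "end", "name", "score", "strand",
        "n_cpg", "mean_level_a", "mean_level_b", "mean_diff", "fold", "p_min",
    ]
    df.columns = names[: df.shape[1]]
    return df


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {ln}: GMT rows need name, description "
                    "and at least one gene"
                )
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
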