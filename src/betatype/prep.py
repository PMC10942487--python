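"""Quality filtering, normalization/transformation, reporter gating and
marker-based cell-type labeling of count matrices.

The transformation recipe is: scale each cell to the median library size,
apply the inverse hyperbolic sine (a log-like transform defined at zero),
and optionally z-score each gene.  The lineage-reporter gate (default
cutoff 0.9) is applied on the arcsinh scale, before z-scoring, because
z-scoring recenters every gene at zero and would make a fixed cutoff
unstable across datasets.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "qc_filter",
    "normalize_transform",
    "reporter_gate",
    "label_celltypes",
    "subtype_fraction",
]


class EmptyResultError(ValueError):
    """Raised when a filter removes every cell."""


def _counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X)


def qc_filter(
    adata: ad.AnnData, min_counts: int = 0, max_mito: float = 1.0
) -> ad.AnnData:
    """Keep cells with total counts >= ``min_counts`` and mitochondrial
    fraction <= ``max_mito``; the gene axis and cell order are preserved."""
    X = _counts(adata)
    totals = X.sum(axis=1)
    if max_mito < 1.0:
        if "mito" not in adata.var.columns:
            raise ValueError("max_mito < 1 requires a 'mito' gene flag")
        mito_mask = adata.var["mito"].to_numpy(dtype=bool)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(
                totals > 0, X[:, mito_mask].sum(axis=1) / totals, 1.0
            )
    else:
        mito_frac = np.zeros(adata.n_obs)
    keep = (totals >= min_counts) & (mito_frac <= max_mito)
    if not keep.any():
        raise EmptyResultError(
            f"all {adata.n_obs} cells removed "
            f"(low counts: {int((totals < min_counts).sum())}, "
            f"high mito: {int((mito_frac > max_mito).sum())})"
        )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("qc_filter removed %d of %d cells", n_drop, adata.n_obs)
    return adata[keep].copy()


def normalize_transform(adata: ad.AnnData, zscore: bool = False) -> ad.AnnData:
    """Median-library normalization, arcsinh transform, optional z-score.

    Returns a copy with the transformed values in ``.X``, the arcsinh-stage
    values kept in ``layers['arcsinh']``, raw counts in ``layers['counts']``
    and the final stage recorded in ``uns['stage']``.  Cells with zero
    library size are dropped with a warning.  Constant genes get z-score 0.
    """
    X = _counts(adata).astype(float)
    libs = X.sum(axis=1)
    nonzero = libs > 0
    if not nonzero.any():
        raise ValueError("no cell has nonzero counts")
    if not nonzero.all():
        logger.warning(
            "dropping %d zero-library cells", int((~nonzero).sum())
        )
        adata = adata[nonzero].copy()
        X = X[nonzero]
        libs = libs[nonzero]
    med = float(np.median(libs))
    arc = np.arcsinh(X * (med / libs)[:, None])

    out = adata.copy()
    out.layers["counts"] = X.astype(np.int64)
    out.layers["arcsinh"] = arc
    if zscore:
        mu = arc.mean(axis=0)
        sd = arc.std(axis=0, ddof=0)
        z = np.where(sd > 0, (arc - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        out.X = z
        out.uns["stage"] = "zscore"
    else:
        out.X = arc.copy()
        out.uns["stage"] = "arcsinh"
    out.uns["median_library_size"] = med
    return out


def reporter_gate(
    adata: ad.AnnData,
    reporter_gene: str,
    cutoff: float = 0.9,
    scale: str = "arcsinh",
) -> pd.Series:
    """Label each cell reporter positive/negative by thresholding the
    reporter transcript at ``cutoff`` (strict ``>``; boundary is negative).

    ``scale`` selects the layer the cutoff applies to (``arcsinh`` by
    default; ``zscore`` requires a z-scored matrix in ``.X``).
    """
    if reporter_gene not in adata.var_names:
        raise KeyError(f"reporter gene {reporter_gene!r} not in matrix")
    j = adata.var_names.get_loc(reporter_gene)
    if scale == "arcsinh":
        if "arcsinh" not in adata.layers:
            raise ValueError("matrix has no arcsinh layer; run normalize_transform")
        values = np.asarray(adata.layers["arcsinh"])[:, j]
    elif scale == "zscore":
        if adata.uns.get("stage") != "zscore":
            raise ValueError("scale='zscore' requires a z-scored matrix")
        values = _counts(adata)[:, j]
    else:
        raise ValueError(f"unknown gate scale {scale!r}")
    labels = np.where(values > cutoff, "positive", "negative")
    return pd.Series(labels, index=adata.obs_names, name="reporter")


def label_celltypes(
    adata: ad.AnnData, markers: dict[str, list[str]]
) -> pd.Series:
    """Assign each cell the type whose z-scored marker mean is highest.

    Ties break to the lexicographically first type name.  Marker z-scores
    are computed from the arcsinh layer so the call does not depend on
    whether the matrix was z-scored globally.
    """
    if not markers:
        raise ValueError("marker map is empty")
    arc = np.asarray(adata.layers.get("arcsinh", adata.X))
    mu = arc.mean(axis=0)
    sd = arc.std(axis=0, ddof=0)
    z = np.where(sd > 0, (arc - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    types = sorted(markers)
    scores = np.empty((adata.n_obs, len(types)))
    for k, t in enumerate(types):
        genes = markers[t]
        if not genes:
            raise ValueError(f"marker set for {t!r} is empty")
        missing = [g for g in genes if g not in adata.var_names]
        if missing:
            raise KeyError(f"markers absent from matrix: {missing}")
        idx = [adata.var_names.get_loc(g) for g in genes]
        scores[:, k] = z[:, idx].mean(axis=1)
    # argmax returns the first (lexicographically smallest) type on ties
    best = np.argmax(scores, axis=1)
    return pd.Series(
        [types[k] for k in best], index=adata.obs_names, name="cell_type"
    )


def subtype_fraction(
    labels: pd.Series, by: pd.Series | None = None
) -> pd.DataFrame:
    """Per-group fraction of positive cells and positive/negative ratio.

    Groups with zero negative cells report the ratio as ``inf``.
    """
    if labels.empty:
        raise ValueError("labels are empty")
    df = pd.DataFrame({"label": labels})
    df["group"] = "all" if by is None else pd.Series(by).reindex(labels.index)
    if df["group"].isna().any():
        raise KeyError("grouping key missing for some cells")
    rows = []
    for g, sub in df.groupby("group", sort=True):
        pos = int((sub["label"] == "positive").sum())
        neg = int((sub["label"] == "negative").sum())
        rows.append(
            {
                "group": g,
                "n_positive": pos,
                "n_negative": neg,
                "fraction_positive": pos / (pos + neg),
                "ratio": pos / neg if neg else float("inf"),
            }
        )
    return pd.DataFrame(rows).set_index("group")
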