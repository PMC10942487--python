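"""Pseudobulk paired differential expression between reporter-positive and
reporter-negative cells.

Per sample, arcsinh-transformed expression is averaged separately within
the two reporter groups; genes whose pseudobulk mean drops below a floor
(default 0.002, roughly one read per cell) in any sample/group are removed;
the remaining genes are tested with a two-sided paired t-test across
samples, and a gene is called differentially expressed when p < alpha and
the mean paired difference is at least ``min_diff`` (default 0.05 on the
arcsinh scale, ~5% multiplicative change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PseudobulkTable",
    "pseudobulk_means",
    "filter_low_expression",
    "paired_deg",
]


class InsufficientReplicationError(ValueError):
    """Fewer than two samples carry both reporter groups."""


@dataclass
class PseudobulkTable:
    """Gene x (sample, group) means of transformed expression."""

    #: DataFrame indexed by gene; columns MultiIndex (sample, group)
    means: pd.DataFrame
    #: cells behind each column, indexed like ``means.columns``
    n_cells: pd.Series

    @property
    def samples(self) -> list[str]:
        return sorted({s for s, _ in self.means.columns})


def pseudobulk_means(
    adata: ad.AnnData,
    groups: pd.Series,
    sample_key: str = "sample_id",
    layer: str = "arcsinh",
) -> PseudobulkTable:
    """Average transformed expression per gene per (sample, reporter group).

    Samples missing either group are excluded with a log line; fewer than
    two usable samples is an error (the paired test would be undefined).
    """
    if layer not in adata.layers:
        raise ValueError(f"matrix has no {layer!r} layer")
    X = np.asarray(adata.layers[layer])
    groups = pd.Series(groups).reindex(adata.obs_names)
    samples = adata.obs[sample_key].astype(str)

    cols: dict[tuple[str, str], np.ndarray] = {}
    counts: dict[tuple[str, str], int] = {}
    for s in sorted(samples.unique()):
        in_s = (samples == s).to_numpy()
        per_group = {}
        for g in ("positive", "negative"):
            mask = in_s & (groups == g).to_numpy()
            if mask.sum() > 0:
                per_group[g] = mask
        if len(per_group) < 2:
            logger.info("sample %s lacks a reporter group; excluded", s)
            continue
        for g, mask in per_group.items():
            cols[(s, g)] = X[mask].mean(axis=0)
            counts[(s, g)] = int(mask.sum())

    usable = {s for s, _ in cols}
    if len(usable) < 2:
        raise InsufficientReplicationError(
            f"only {len(usable)} sample(s) have both reporter groups"
        )
    means = pd.DataFrame(cols, index=adata.var_names)
    means.columns = pd.MultiIndex.from_tuples(
        means.columns, names=["sample", "group"]
    )
    n_cells = pd.Series(counts)
    n_cells.index = pd.MultiIndex.from_tuples(
        n_cells.index, names=["sample", "group"]
    )
    return PseudobulkTable(means=means, n_cells=n_cells)


def filter_low_expression(
    pb: PseudobulkTable, min_level: float = 0.002
) -> PseudobulkTable:
    """Drop genes whose mean falls below ``min_level`` in any sample/group.

    The boundary is inclusive: a gene at exactly ``min_level`` everywhere
    is retained.  Failing in a single sample removes the gene (strictest
    reading), keeping every retained gene's pseudobulk pairs complete.
    """
    if pb.means.empty:
        raise ValueError("pseudobulk table is empty")
    keep = (pb.means >= min_level).all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "low-expression filter removed %d of %d genes (< %g)",
            n_drop,
            len(keep),
            min_level,
        )
    if not keep.any():
        logger.warning("low-expression filter removed every gene")
    return PseudobulkTable(means=pb.means.loc[keep], n_cells=pb.n_cells)


def paired_deg(
    pb: PseudobulkTable, alpha: float = 0.05, min_diff: float = 0.05
) -> pd.DataFrame:
    """Two-sided paired t-test of positive vs negative pseudobulk means.

    Returns a per-gene table with the per-sample differences, mean
    difference, t, p, BH-adjusted q, direction and the pass flag
    (p < alpha and |mean difference| >= min_diff).

    Zero-variance conventions: differences all exactly zero give p = 1
    (no evidence); constant nonzero differences give p = 0 (the t statistic
    diverges).
    """
    samples = pb.samples
    if len(samples) < 2:
        raise InsufficientReplicationError("paired test needs >= 2 samples")
    pos = pb.means.loc[:, [(s, "positive") for s in samples]].to_numpy()
    neg = pb.means.loc[:, [(s, "negative") for s in samples]].to_numpy()
    d = pos - neg  # genes x samples
    n = d.shape[1]
    mean_d = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)

    t = np.zeros(len(mean_d))
    p = np.ones(len(mean_d))
    # differences constant up to floating-point noise count as zero-variance
    nonzero_sd = sd > 1e-12 * np.maximum(1.0, np.abs(mean_d))
    t[nonzero_sd] = mean_d[nonzero_sd] / (sd[nonzero_sd] / np.sqrt(n))
    p[nonzero_sd] = 2.0 * stats.t.sf(np.abs(t[nonzero_sd]), df=n - 1)
    # constant nonzero differences: the statistic diverges
    const_nonzero = (~nonzero_sd) & (mean_d != 0)
    t[const_nonzero] = np.sign(mean_d[const_nonzero]) * np.inf
    p[const_nonzero] = 0.0

    q = multipletests(p, method="fdr_bh")[1]
    passed = (p < alpha) & (np.abs(mean_d) >= min_diff)
    out = pd.DataFrame(
        {
            "mean_diff": mean_d,
            "t": t,
            "p": p,
            "q": q,
            "direction": np.where(mean_d >= 0, "up", "down"),
            "pass": passed,
        },
        index=pb.means.index,
    )
    for k, s in enumerate(samples):
        out[f"diff_{s}"] = d[:, k]
    return out
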