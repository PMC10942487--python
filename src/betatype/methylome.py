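"""CpG-level methylation summaries, hypomethylated-region segmentation,
differential-methylation region calling and region clustering.

Segmentation is deliberately simple and auditable: HMRs are maximal runs
of CpGs whose smoothed methylation falls below a threshold; DMRs merge
per-CpG Fisher-exact-significant sites of consistent sign and are gated at
a minimum span of 50 bp and at least 2 significant CpGs (p < 0.05).  The
span convention is last CpG position - first CpG position + 2, covering
the terminal dinucleotide.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = ["call_hmrs", "call_dmrs", "cluster_regions"]

REGION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_cpg",
    "n_sig_cpg",
    "mean_level_a",
    "mean_level_b",
    "mean_diff",
    "fold",
    "p_min",
    "kind",
    "sign",
]


def _empty_regions() -> pd.DataFrame:
    return pd.DataFrame(columns=REGION_COLUMNS)


def _check_sorted(m: pd.DataFrame) -> None:
    for _, sub in m.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError("methylome table must be sorted by (chrom, pos)")


def call_hmrs(
    m: pd.DataFrame,
    tau: float = 0.5,
    min_cpgs: int = 4,
    max_gap: int = 1000,
    smooth_w: int = 3,
) -> pd.DataFrame:
    """Segment hypomethylated regions from a single-group CpG table.

    A centered moving average over ``smooth_w`` CpGs is thresholded at
    ``tau``; maximal runs of sub-threshold CpGs with inter-CpG gaps at most
    ``max_gap`` and at least ``min_cpgs`` CpGs become regions.
    """
    if m.empty:
        logger.warning("empty methylome table: no HMRs")
        return _empty_regions()
    _check_sorted(m)
    regions = []
    for chrom, sub in m.groupby("chrom", sort=True):
        sub = sub[sub["total_reads"] > 0]
        if len(sub) < min_cpgs:
            continue
        pos = sub["pos"].to_numpy()
        level = (sub["meth_reads"] / sub["total_reads"]).to_numpy(float)
        kernel = np.ones(smooth_w) / smooth_w
        pad = smooth_w // 2
        padded = np.concatenate(
            [np.repeat(level[0], pad), level, np.repeat(level[-1], pad)]
        )
        smoothed = np.convolve(padded, kernel, mode="valid")
        low = smoothed < tau
        # break runs at gaps larger than max_gap
        run_start = None
        for i in range(len(pos) + 1):
            open_run = run_start is not None
            breaks = (
                i == len(pos)
                or not low[i]
                or (open_run and pos[i] - pos[i - 1] > max_gap)
            )
            if open_run and breaks:
                if i - run_start >= min_cpgs:
                    idx = slice(run_start, i)
                    regions.append(
                        {
                            "chrom": chrom,
                            "start": int(pos[run_start]),
                            "end": int(pos[i - 1]) + 2,
                            "n_cpg": i - run_start,
                            "n_sig_cpg": 0,
                            "mean_level_a": float(level[idx].mean()),
                            "mean_level_b": float("nan"),
                            "mean_diff": float("nan"),
                            "fold": float("nan"),
                            "p_min": float("nan"),
                            "kind": "HMR",
                            "sign": ".",
                        }
                    )
                run_start = None
            if i < len(pos) and low[i] and run_start is None:
                run_start = i
    return pd.DataFrame(regions, columns=REGION_COLUMNS)


@lru_cache(maxsize=1 << 20)
def _fisher_p(a_meth: int, a_un: int, b_meth: int, b_un: int) -> float:
    return float(
        stats.fisher_exact([[a_meth, a_un], [b_meth, b_un]])[1]
    )


def call_dmrs(
    a: pd.DataFrame,
    b: pd.DataFrame,
    cpg_alpha: float = 0.05,
    min_span: int = 50,
    min_cpgs: int = 2,
    max_gap: int = 500,
) -> pd.DataFrame:
    """Call differentially methylated regions between two CpG tables.

    Per shared CpG a two-sided Fisher exact test compares (methylated,
    unmethylated) reads between groups; significant CpGs of consistent
    difference sign within ``max_gap`` are merged, and a merged region is
    kept iff its span is at least ``min_span`` bp and it holds at least
    ``min_cpgs`` significant CpGs.  ``mean_diff`` is mean(level A - level B)
    over all covered CpGs in the region; ``fold`` is the higher group mean
    over the lower.
    """
    if len(a) != len(b) or not (
        (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
        and (a["pos"].to_numpy() == b["pos"].to_numpy()).all()
    ):
        off = "length mismatch"
        if len(a) == len(b):
            bad = np.flatnonzero(
                (a["chrom"].to_numpy() != b["chrom"].to_numpy())
                | (a["pos"].to_numpy() != b["pos"].to_numpy())
            )
            off = f"first offending row {bad[0]}: {a.iloc[bad[0]][['chrom', 'pos']].tolist()}"
        raise ValueError(f"methylome coordinate frames differ ({off})")
    _check_sorted(a)

    covered = (a["total_reads"].to_numpy() > 0) & (b["total_reads"].to_numpy() > 0)
    a = a.loc[covered].reset_index(drop=True)
    b = b.loc[covered].reset_index(drop=True)

    am = a["meth_reads"].to_numpy(np.int64)
    at = a["total_reads"].to_numpy(np.int64)
    bm = b["meth_reads"].to_numpy(np.int64)
    bt = b["total_reads"].to_numpy(np.int64)
    level_a = am / at
    level_b = bm / bt
    diff = level_a - level_b

    p = np.array(
        [
            _fisher_p(int(am[i]), int(at[i] - am[i]), int(bm[i]), int(bt[i] - bm[i]))
            for i in range(len(a))
        ]
    )
    sig = p < cpg_alpha

    regions = []
    chroms = a["chrom"].to_numpy()
    pos = a["pos"].to_numpy()
    sig_idx = np.flatnonzero(sig)
    if len(sig_idx) == 0:
        return _empty_regions()
    # group significant CpGs: same chromosome, gap <= max_gap, same sign
    blocks: list[list[int]] = [[int(sig_idx[0])]]
    for i in sig_idx[1:]:
        prev = blocks[-1][-1]
        same = (
            chroms[i] == chroms[prev]
            and pos[i] - pos[prev] <= max_gap
            and np.sign(diff[i]) == np.sign(diff[prev])
        )
        if same:
            blocks[-1].append(int(i))
        else:
            blocks.append([int(i)])

    for block in blocks:
        if len(block) < min_cpgs:
            continue
        start = int(pos[block[0]])
        end = int(pos[block[-1]]) + 2
        if end - start < min_span:
            continue
        chrom = chroms[block[0]]
        # all covered CpGs inside the merged span
        inside = (chroms == chrom) & (pos >= start) & (pos < end)
        mean_a = float(level_a[inside].mean())
        mean_b = float(level_b[inside].mean())
        lo, hi = sorted([mean_a, mean_b])
        regions.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_cpg": int(inside.sum()),
                "n_sig_cpg": len(block),
                "mean_level_a": mean_a,
                "mean_level_b": mean_b,
                "mean_diff": mean_a - mean_b,
                "fold": hi / lo if lo > 0 else float("inf"),
                "p_min": float(p[block].min()),
                "kind": "DMR",
                "sign": "+" if mean_a - mean_b > 0 else "-",
            }
        )
    out = pd.DataFrame(regions, columns=REGION_COLUMNS)
    # the gates are a contract: assert them on every output
    if len(out):
        assert (out["end"] - out["start"] >= min_span).all()
        assert (out["n_sig_cpg"] >= min_cpgs).all()
    return out


def cluster_regions(
    levels: pd.DataFrame,
    k: int = 6,
    fold_flag: float = 1.8,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster regions by their per-condition mean methylation levels.

    ``levels`` is a region x condition matrix.  K-means with 10 restarts
    partitions the rows into ``k`` clusters; a cluster is flagged when the
    ratio of its centroid's highest to lowest condition mean exceeds
    ``fold_flag`` (default 1.8).  Returns (labels, cluster summary).
    """
    if k > len(levels):
        raise ValueError(f"k={k} exceeds number of regions ({len(levels)})")
    if not np.isfinite(levels.to_numpy(float)).all():
        raise ValueError("levels must be finite")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = pd.Series(
        km.fit_predict(levels.to_numpy(float)),
        index=levels.index,
        name="cluster",
    )
    rows = []
    for c in range(k):
        centroid = km.cluster_centers_[c]
        lo, hi = centroid.min(), centroid.max()
        fold = hi / lo if lo > 0 else float("inf")
        rows.append(
            {
                "cluster": c,
                "n_regions": int((labels == c).sum()),
                **{
                    f"centroid_{col}": float(v)
                    for col, v in zip(levels.columns, centroid)
                },
                "fold": float(fold),
                "flagged": bool(fold > fold_flag),
            }
        )
    return labels, pd.DataFrame(rows).set_index("cluster")
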