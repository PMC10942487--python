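"""Gene-signature subpopulation workflow for beta-cell matrices.

A per-cell module score is the mean transformed expression of a signature
gene set minus the mean of expression-bin-matched control genes (control
pool ~2000 genes by default).  Cells scoring above 0.2 are labeled Pop1,
the rest Pop2.  Whether signature expression is clustered across cells
(rather than spread evenly) is tested with the Gini index of per-cell
signature means against a permutation null of bin-matched random gene
sets.  Downstream comparisons use Wilcoxon rank-sum DE between
subpopulations, Kruskal-Wallis with post hoc Mann-Whitney U across score
groups, and an equal-variance t-test on per-donor Pop1 fractions.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "module_score",
    "classify_population",
    "gini_index",
    "gini_signature_test",
    "subpop_de",
    "grouped_score_test",
    "compare_population_fractions",
]


class BinExhaustedError(ValueError):
    """An expression bin required for control matching has no candidates."""


def _matrix(adata: ad.AnnData, layer: str | None) -> np.ndarray:
    if layer is not None:
        if layer not in adata.layers:
            raise ValueError(f"matrix has no {layer!r} layer")
        return np.asarray(adata.layers[layer], dtype=float)
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def _bins(gene_means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency expression bins (rank-based, ties keep one bin)."""
    order = np.argsort(gene_means, kind="stable")
    bins = np.empty(len(gene_means), dtype=int)
    bins[order] = np.arange(len(gene_means)) * n_bins // len(gene_means)
    return bins


def _matched_controls(
    bins: np.ndarray,
    set_idx: np.ndarray,
    ctrl_pool: int,
    rng: np.random.Generator,
) -> list[tuple[float, np.ndarray]]:
    """Sample control genes bin-matched to the signature, w/o replacement.

    Returns (weight, gene indices) per occupied bin, where the weight is
    the signature's share of genes in that bin, so the control average
    mirrors the signature's bin distribution even when a bin's candidate
    pool is smaller than requested.
    """
    per_gene = max(1, round(ctrl_pool / len(set_idx)))
    in_set = np.zeros(len(bins), dtype=bool)
    in_set[set_idx] = True
    chosen: list[tuple[float, np.ndarray]] = []
    n_set = len(set_idx)
    for b, count in zip(*np.unique(bins[set_idx], return_counts=True)):
        pool = np.flatnonzero((bins == b) & ~in_set)
        if len(pool) == 0:
            raise BinExhaustedError(
                f"expression bin {b} has no non-signature genes; "
                "try fewer bins"
            )
        take = min(len(pool), count * per_gene)
        chosen.append(
            (count / n_set, rng.choice(pool, size=take, replace=False))
        )
    return chosen


def module_score(
    adata: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 25,
    ctrl_pool: int = 2000,
    seed: int = 0,
    layer: str | None = "arcsinh",
) -> pd.Series:
    """Per-cell signature score: mean set expression minus mean
    bin-matched control expression."""
    missing = [g for g in gene_set if g not in adata.var_names]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing}")
    X = _matrix(adata, layer)
    set_idx = np.array([adata.var_names.get_loc(g) for g in gene_set])
    if len(set_idx) == adata.n_vars:
        raise ValueError("signature covers every gene; no controls available")
    bins = _bins(X.mean(axis=0), n_bins)
    rng = np.random.default_rng(seed)
    ctrl = _matched_controls(bins, set_idx, ctrl_pool, rng)
    ctrl_mean = sum(w * X[:, idx].mean(axis=1) for w, idx in ctrl)
    scores = X[:, set_idx].mean(axis=1) - ctrl_mean
    return pd.Series(scores, index=adata.obs_names, name="score")


def classify_population(
    scores: pd.Series, threshold: float = 0.2
) -> pd.Series:
    """Pop1 iff score strictly exceeds the threshold, else Pop2."""
    if not np.isfinite(scores.to_numpy(float)).all():
        raise ValueError("scores must be finite")
    return pd.Series(
        np.where(scores > threshold, "Pop1", "Pop2"),
        index=scores.index,
        name="population",
    )


def gini_index(x) -> float:
    """Gini coefficient of a non-negative vector.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)); 0 for constant vectors,
    approaching 1 when all mass sits on one element.  Scale-invariant.
    """
    x = np.sort(np.asarray(x, dtype=float))
    if x.size == 0 or (x < 0).any():
        raise ValueError("gini_index needs a non-empty non-negative vector")
    total = x.sum()
    if total == 0:
        raise ValueError("gini_index undefined for an all-zero vector")
    n = x.size
    # equivalent closed form of the mean-absolute-difference definition
    return float((2.0 * np.arange(1, n + 1) @ x) / (n * total) - (n + 1) / n)


def gini_signature_test(
    adata: ad.AnnData,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    n_bins: int = 25,
    layer: str | None = "arcsinh",
) -> dict:
    """Permutation test for clustered signature expression across cells.

    The statistic is the Gini index of per-cell mean signature expression;
    the null draws ``n_perm`` bin-matched random gene sets of equal size.
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    missing = [g for g in gene_set if g not in adata.var_names]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing}")
    X = _matrix(adata, layer)
    X = np.clip(X, 0.0, None)  # Gini needs non-negative input
    set_idx = np.array([adata.var_names.get_loc(g) for g in gene_set])
    bins = _bins(X.mean(axis=0), n_bins)
    observed = gini_index(X[:, set_idx].mean(axis=1))

    rng = np.random.default_rng(seed)
    in_set = np.zeros(adata.n_vars, dtype=bool)
    in_set[set_idx] = True
    bin_ids, bin_counts = np.unique(bins[set_idx], return_counts=True)
    pools = {b: np.flatnonzero(bins == b) for b in bin_ids}
    hits = 0
    for _ in range(n_perm):
        draw = np.concatenate(
            [
                rng.choice(pools[b], size=min(c, len(pools[b])), replace=False)
                for b, c in zip(bin_ids, bin_counts)
            ]
        )
        null = gini_index(X[:, draw].mean(axis=1))
        if null >= observed:
            hits += 1
    return {
        "gini": observed,
        "p": (1 + hits) / (1 + n_perm),
        "n_perm": n_perm,
    }


def subpop_de(
    adata: ad.AnnData,
    labels: pd.Series,
    layer: str | None = "arcsinh",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test of Pop1 vs Pop2.

    Exact p for groups of up to 10 cells, normal approximation with tie
    correction otherwise; BH-adjusted q; ``rank_score`` is the signed z
    (positive = higher in Pop1), suitable for pre-ranked enrichment.
    """
    labels = pd.Series(labels).reindex(adata.obs_names)
    a_mask = (labels == "Pop1").to_numpy()
    b_mask = (labels == "Pop2").to_numpy()
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("both populations need at least 2 cells")
    X = _matrix(adata, layer)
    A, B = X[a_mask], X[b_mask]
    method = "exact" if max(A.shape[0], B.shape[0]) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(A, B, axis=0, method=method)
    p = np.asarray(res.pvalue, dtype=float)
    q = multipletests(p, method="fdr_bh")[1]
    diff = A.mean(axis=0) - B.mean(axis=0)
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    out = pd.DataFrame(
        {
            "mean_diff": diff,
            "u": np.asarray(res.statistic, dtype=float),
            "p": p,
            "q": q,
            "rank_score": np.sign(diff) * z,
            "significant": q < q_threshold,
        },
        index=adata.var_names,
    )
    return out


def grouped_score_test(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis across score groups, gated post hoc Mann-Whitney U.

    Pairwise tests run only when the Kruskal-Wallis p is below 0.05; with
    exactly two groups the comparison degenerates to a single
    Mann-Whitney U (reported as both the omnibus and the pairwise p).
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    values = [np.asarray(groups[n], dtype=float) for n in names]
    if any(len(v) < 2 for v in values):
        raise ValueError("each group needs at least 2 observations")
    if len(names) == 2:
        p = float(stats.mannwhitneyu(values[0], values[1]).pvalue)
        return {
            "omnibus": "mannwhitneyu",
            "p": p,
            "pairwise": {(names[0], names[1]): p},
        }
    if all((v == values[0][0]).all() for v in values):
        kw_p = 1.0  # identical constant groups: no evidence
    else:
        kw_p = float(stats.kruskal(*values).pvalue)
    pairwise: dict[tuple[str, str], float | None] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise[(names[i], names[j])] = (
                float(stats.mannwhitneyu(values[i], values[j]).pvalue)
                if kw_p < 0.05
                else None
            )
    return {"omnibus": "kruskal", "p": kw_p, "pairwise": pairwise}


def compare_population_fractions(
    labels: pd.Series, donors: pd.Series, conditions: pd.Series
) -> dict:
    """Equal-variance t-test of per-donor Pop1 fractions between two
    conditions.

    Zero-variance convention: if both conditions have constant fractions,
    p = 1 when the means agree and p = 0 otherwise.
    """
    df = pd.DataFrame(
        {"label": labels, "donor": donors, "condition": conditions}
    )
    frac = (
        df.assign(pop1=lambda d: d["label"] == "Pop1")
        .groupby(["condition", "donor"], observed=True)["pop1"]
        .mean()
    )
    conds = sorted(frac.index.get_level_values(0).unique())
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conds}")
    a = frac.loc[conds[0]].to_numpy(float)
    b = frac.loc[conds[1]].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each condition needs >= 2 donors")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return {
        "conditions": conds,
        "fractions": {conds[0]: a.tolist(), conds[1]: b.tolist()},
        "mean_fraction": {conds[0]: float(a.mean()), conds[1]: float(b.mean())},
        "p": p,
    }
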