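"""Exact set-overlap statistics: hypergeometric retention enrichment,
Fisher 2x2 association tests, and the DEG/DMR cross-modality contingency
helpers.

The hypergeometric p is the upper tail P(X >= overlap) for X ~
Hypergeometric(|universe|, |A|, |B|), matching enrichment claims; fold is
observed/expected overlap with expected = |A||B|/|U|.  The two-sided
Fisher p follows the point-probability rule (sum over all margin-fixed
tables whose probability does not exceed the observed table's).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "hypergeom_overlap",
    "fisher_2x2",
    "deg_dmr_association",
    "direction_contingency",
]


@dataclass
class EnrichmentResult:
    overlap: int
    size_a: int
    size_b: int
    universe: int
    expected: float
    fold: float
    p: float
    test: str
    table: list[list[int]] | None = None
    odds_ratio: float | None = None

    def as_dict(self) -> dict:
        return {
            "overlap": self.overlap,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "universe": self.universe,
            "expected": self.expected,
            "fold": self.fold,
            "p": self.p,
            "test": self.test,
        }


def hypergeom_overlap(
    set_a: set, set_b: set, universe: set, tail: str = "upper"
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets.

    ``tail='lower'`` tests depletion (P(X <= overlap)) instead.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    stray = (set_a | set_b) - universe
    if stray:
        raise ValueError(
            f"sets must be subsets of the universe; offenders: {sorted(stray)[:10]}"
        )
    M, n, N = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = n * N / M if M else float("nan")
    fold = k / expected if expected > 0 else float("nan")
    rv = stats.hypergeom(M, n, N)
    if tail == "upper":
        p = float(rv.sf(k - 1))  # P(X >= k)
    elif tail == "lower":
        p = float(rv.cdf(k))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return EnrichmentResult(
        overlap=k,
        size_a=n,
        size_b=N,
        universe=M,
        expected=expected,
        fold=fold,
        p=min(p, 1.0),
        test=f"hypergeometric_{tail}",
    )


def fisher_2x2(table) -> EnrichmentResult:
    """Two-sided Fisher exact test of a 2x2 contingency table."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table cells must be non-negative")
    if t.sum() == 0:
        raise ValueError("table has no observations")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    total = int(t.sum())
    k = int(t[0, 0])
    n, N = int(t[0].sum()), int(t[:, 0].sum())
    expected = n * N / total if total else float("nan")
    return EnrichmentResult(
        overlap=k,
        size_a=n,
        size_b=N,
        universe=total,
        expected=expected,
        fold=k / expected if expected > 0 else float("nan"),
        p=float(p),
        test="fisher_two_sided",
        table=t.tolist(),
        odds_ratio=float(odds) if np.isfinite(odds) else float("inf"),
    )


def deg_dmr_association(
    degs: set, dmr_genes: set, expressed_universe: set
) -> EnrichmentResult:
    """Fisher test of DEG status against DMR association over the
    expressed-gene universe."""
    degs, dmr_genes, universe = set(degs), set(dmr_genes), set(expressed_universe)
    stray = (degs | dmr_genes) - universe
    if stray:
        raise ValueError(
            f"sets must be subsets of the universe; offenders: {sorted(stray)[:10]}"
        )
    a = len(degs & dmr_genes)
    b = len(degs - dmr_genes)
    c = len(dmr_genes - degs)
    d = len(universe) - a - b - c
    return fisher_2x2([[a, b], [c, d]])


def direction_contingency(
    deg_table: pd.DataFrame, dmr_class: dict[str, set]
) -> EnrichmentResult:
    """Fisher test of DEG direction (up/down) against DMR methylation
    class (lower/higher).

    ``dmr_class`` maps class name ("lower", "higher") to gene sets; every
    classified gene must be a DEG (a row of ``deg_table`` with pass=True).
    Genes present in both classes are counted in both columns.
    """
    degs = deg_table[deg_table["pass"]]
    if degs.empty:
        raise ValueError("no passing DEGs to classify")
    lower = set(dmr_class.get("lower", set()))
    higher = set(dmr_class.get("higher", set()))
    stray = (lower | higher) - set(degs.index)
    if stray:
        raise ValueError(
            f"classified genes must be DEGs; offenders: {sorted(stray)[:10]}"
        )
    up = set(degs.index[degs["direction"] == "up"])
    down = set(degs.index[degs["direction"] == "down"])
    table = [
        [len(up & lower), len(up & higher)],
        [len(down & lower), len(down & higher)],
    ]
    return fisher_2x2(table)
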