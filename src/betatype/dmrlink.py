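"""Associate DMRs with putative target genes via GREAT-style regulatory
domains ("basal plus extension") and classify DMR position relative to
gene structure.

Each gene gets a strand-aware basal domain around its TSS (default 5 kb
upstream / 1 kb downstream) extended on each side toward the nearest
neighboring basal domain, capped at 1 Mb.  A DMR is assigned to every gene
whose extended domain it overlaps (half-open interval intersection; a
1-bp touch at the boundary is not overlap).  A DMR assigned to a gene is
"regulatory" when it overlaps the window from 2 kb upstream of the TSS to
the end of the 3'UTR, and "distal" otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "build_regulatory_domains",
    "assign_dmrs",
    "classify_location",
    "location_summary",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with strand-aware TSS and 3'UTR."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    utr3_start: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def utr3_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.utr3_start, self.end)
        utr_len = max(1, (self.end - self.start) // 10)
        return (self.start, self.start + utr_len)


def _models(genes: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(
            str(r.gene_id),
            str(r.chrom),
            int(r.start),
            int(r.end),
            str(r.strand),
            int(r.utr3_start),
        )
        for r in genes.itertuples()
    ]


def _basal(g: GeneModel, basal_up: int, basal_down: int) -> tuple[int, int]:
    # strand-aware basal window, 0-based half-open, mirror-symmetric
    if g.strand == "+":
        return (g.tss - basal_up, g.tss + basal_down)
    return (g.end - basal_down, g.end + basal_up)


def build_regulatory_domains(
    genes: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Compute basal-plus-extension regulatory domains for each gene.

    Returns a DataFrame (gene_id, chrom, basal_start, basal_end,
    ext_start, ext_end, tss, strand).  Extension on each side stops at the
    nearest other basal domain edge, never exceeds ``max_ext`` beyond the
    basal edge, and never retracts inside the basal domain.  Chromosome
    ends truncate when ``chrom_sizes`` is given; coordinates are floored
    at zero regardless.
    """
    models = _models(genes)
    rows = []
    by_chrom: dict[str, list[tuple[GeneModel, tuple[int, int]]]] = {}
    for g in models:
        by_chrom.setdefault(g.chrom, []).append(
            (g, _basal(g, basal_up, basal_down))
        )
    for chrom, items in by_chrom.items():
        items.sort(key=lambda it: it[1])
        basals = [b for _, b in items]
        for i, (g, (bs, be)) in enumerate(items):
            # nearest basal edge of any other gene on each side
            left_limit = bs - max_ext
            for j in range(i - 1, -1, -1):
                ob = basals[j][1]  # other basal end
                if basals[j][0] >= bs and basals[j][1] <= be:
                    continue
                if ob <= bs:
                    left_limit = max(left_limit, ob)
                    break
                else:  # overlapping basal: extension degenerates
                    left_limit = bs
                    logger.info(
                        "%s: overlapping basal domain on the left", g.gene_id
                    )
                    break
            right_limit = be + max_ext
            for j in range(i + 1, len(items)):
                os_ = basals[j][0]
                if os_ >= be:
                    right_limit = min(right_limit, os_)
                    break
                else:
                    right_limit = be
                    logger.info(
                        "%s: overlapping basal domain on the right", g.gene_id
                    )
                    break
            ext_start = max(0, min(left_limit, bs))
            ext_end = max(right_limit, be)
            if chrom_sizes and chrom in chrom_sizes:
                ext_end = min(ext_end, chrom_sizes[chrom])
                ext_start = min(ext_start, ext_end)
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": chrom,
                    "basal_start": max(0, bs),
                    "basal_end": be,
                    "ext_start": ext_start,
                    "ext_end": max(ext_end, ext_start + 1),
                    "tss": g.tss,
                    "strand": g.strand,
                }
            )
    return pd.DataFrame(rows)


def assign_dmrs(dmrs: pd.DataFrame, domains: pd.DataFrame) -> pd.DataFrame:
    """Assign each DMR to every gene whose extended domain overlaps it.

    ``dmrs`` needs (chrom, start, end); rows are identified by position in
    the frame (``dmr_<i>`` ids).  Returns a long table (dmr_id, chrom,
    start, end, gene_id, distance) where distance is the signed bp from
    the DMR midpoint to the TSS (positive when the midpoint is 3' of the
    TSS in genome coordinates).  Unassigned DMRs appear once with
    gene_id = NaN.
    """
    trees: dict[str, IntervalTree] = {}
    meta = {}
    for r in domains.itertuples():
        trees.setdefault(r.chrom, IntervalTree()).addi(
            int(r.ext_start), int(r.ext_end), r.gene_id
        )
        meta[r.gene_id] = (int(r.tss), str(r.strand))
    rows = []
    for i, r in enumerate(dmrs.itertuples()):
        dmr_id = f"dmr_{i}"
        hits = (
            sorted(trees[r.chrom].overlap(int(r.start), int(r.end)),
                   key=lambda iv: iv.data)
            if r.chrom in trees
            else []
        )
        mid = (int(r.start) + int(r.end)) // 2
        if not hits:
            rows.append(
                {
                    "dmr_id": dmr_id,
                    "chrom": r.chrom,
                    "start": int(r.start),
                    "end": int(r.end),
                    "gene_id": np.nan,
                    "distance": np.nan,
                }
            )
            continue
        for iv in hits:
            tss, _ = meta[iv.data]
            rows.append(
                {
                    "dmr_id": dmr_id,
                    "chrom": r.chrom,
                    "start": int(r.start),
                    "end": int(r.end),
                    "gene_id": iv.data,
                    "distance": mid - tss,
                }
            )
    return pd.DataFrame(rows)


def classify_location(
    dmr_start: int, dmr_end: int, gene: GeneModel, upstream: int = 2000
) -> str:
    """Classify an assigned DMR as ``regulatory`` or ``distal``.

    Regulatory means overlapping the strand-aware window from ``upstream``
    bp 5' of the TSS through the end of the 3'UTR; everything else
    assigned to the gene is distal.
    """
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.utr3_interval[1]
    else:
        lo, hi = gene.utr3_interval[0], gene.end + upstream
    return "regulatory" if (dmr_start < hi and dmr_end > lo) else "distal"


def location_summary(
    assignments: pd.DataFrame, genes: pd.DataFrame, upstream: int = 2000
) -> pd.DataFrame:
    """Per-assignment location categories plus category fractions.

    Adds a ``category`` column to the assignment table and returns it; the
    summary fractions (share of assigned DMR-gene pairs that fall in the
    regulatory window, and share of DMRs within 100 kb of their gene's
    TSS) are attached in ``.attrs['fractions']``.
    """
    by_id = {m.gene_id: m for m in _models(genes)}
    cats = []
    for r in assignments.itertuples():
        if pd.isna(r.gene_id):
            cats.append("unassigned")
        else:
            cats.append(
                classify_location(r.start, r.end, by_id[r.gene_id], upstream)
            )
    out = assignments.copy()
    out["category"] = cats
    assigned = out.dropna(subset=["gene_id"])
    fractions = {
        "regulatory": float((assigned["category"] == "regulatory").mean())
        if len(assigned)
        else float("nan"),
        "within_100kb": float(
            (assigned["distance"].abs() <= 100_000).mean()
        )
        if len(assigned)
        else float("nan"),
    }
    out.attrs["fractions"] = fractions
    return out
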