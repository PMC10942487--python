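"""Seeded synthetic data: islet-like scRNA-seq counts, two-group CpG
methylomes, and toy gene annotations with recorded ground truth.

The count model is a gamma-Poisson (negative binomial) with lognormal
per-cell library sizes and lognormal per-gene baseline rates.  A beta-cell
population is split into two latent subtypes; subtype A expresses a lineage
reporter transcript at high rate (subtype B at a near-zero rate), and a set
of planted differentially expressed genes is shifted between subtypes by a
multiplicative rate change calibrated so the plug-in arcsinh-mean
difference equals the requested effect size.

The methylome model places CpGs with exponential spacing on a mostly
methylated background, carves hypomethylated windows shared by both groups
(TSS-proximal HMR analogues), and shifts planted differentially methylated
windows in group A only.  Coverage is Poisson; methylated read counts are
binomial at the local methylation level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_methylome",
    "simulate_annotation",
]

#: genes reserved per cell type as elevated markers
_N_MARKERS = 5
#: fold change of a marker gene in its own cell type; canonical islet
#: markers (e.g. Ins1/Gcg) are strongly enriched in their own type
_MARKER_FOLD = 20.0
#: reporter mean normalized expression in subtype A / subtype B
_REPORTER_MU_A = 10.0
_REPORTER_MU_B = 0.002


def _default_proportions() -> dict[str, float]:
    return {
        "beta": 0.5,
        "alpha": 0.2,
        "delta": 0.1,
        "endothelial": 0.1,
        "neuron": 0.1,
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate a small multi-sample islet experiment: four samples
    (mouse pools), ~500 cells each across five cell types, 1000 genes with
    100 planted subtype DEGs at arcsinh effect 0.2, and a two-chromosome
    methylome with 30 planted DMRs of delta 0.4 at 30x coverage.
    """

    # scRNA-seq
    n_samples: int = 4
    n_cells_per_sample: int = 500
    cell_type_proportions: dict[str, float] = field(
        default_factory=_default_proportions
    )
    beta_subtype_fraction: float = 0.5
    n_genes: int = 1000
    n_deg: int = 100
    deg_effect: float = 0.2
    reporter_gene: str = "tdTomato"
    libsize_log_mean: float = math.log(2000.0)
    libsize_log_sd: float = 0.3
    nb_dispersion: float = 0.1
    mito_fraction_mean: float = 0.05
    # methylome
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    cpg_spacing_mean: float = 100.0
    background_meth: float = 0.75
    hmr_level: float = 0.1
    n_hmr: int = 40
    n_dmr: int = 30
    dmr_delta: float = 0.4
    dmr_n_cpg: int = 8
    coverage_mean: float = 30.0
    # annotation
    genes_per_chrom: int = 25
    seed: int = 0

    def validate(self) -> None:
        props = self.cell_type_proportions
        if not props:
            raise ValueError("cell_type_proportions must be non-empty")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("cell_type_proportions must sum to 1")
        for name, frac in [
            ("beta_subtype_fraction", self.beta_subtype_fraction),
            ("mito_fraction_mean", self.mito_fraction_mean),
            ("background_meth", self.background_meth),
            ("hmr_level", self.hmr_level),
            ("dmr_delta", self.dmr_delta),
            *[(f"proportion[{k}]", v) for k, v in props.items()],
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.n_cells_per_sample <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells_per_sample and n_genes must be positive")
        if self.n_deg > self.n_genes:
            raise ValueError("n_deg cannot exceed n_genes")
        if self.n_samples < 1 or self.n_chroms < 1:
            raise ValueError("n_samples and n_chroms must be positive")


@dataclass
class SimTruth:
    """Planted ground truth recorded alongside each simulated dataset."""

    #: (gene, direction in {up, down} for subtype A vs B, arcsinh effect)
    deg_genes: set[tuple[str, str, float]] = field(default_factory=set)
    #: (chrom, start, end, sign in {+1, -1} of group A minus group B)
    dmr_regions: list[tuple[str, int, int, int]] = field(default_factory=list)
    #: (chrom, start, end) hypomethylated windows shared by both groups
    hmr_regions: list[tuple[str, int, int]] = field(default_factory=list)
    #: cell id -> (cell type, beta subtype or "", reporter-positive flag)
    cell_labels: dict[str, tuple[str, str, bool]] = field(default_factory=dict)

    @property
    def deg_gene_ids(self) -> set[str]:
        return {g for g, _, _ in self.deg_genes}


def _gene_names(config: SimConfig):
    """Lay out the gene axis: mito genes, per-type markers, reporter, rest."""
    n = config.n_genes
    n_mito = max(3, n // 100)
    types = sorted(config.cell_type_proportions)
    names: list[str] = []
    mito = np.zeros(n, dtype=bool)
    marker_of = np.full(n, "", dtype=object)
    i = 0
    for j in range(n_mito):
        names.append(f"mt-g{j:04d}")
        mito[i] = True
        i += 1
    for t in types:
        for j in range(_N_MARKERS):
            names.append(f"mk-{t}-{j}")
            marker_of[i] = t
            i += 1
    names.append(config.reporter_gene)
    reporter_idx = i
    i += 1
    while i < n:
        names.append(f"g{i:04d}")
        i += 1
    if len(names) > n:
        raise ValueError(
            "n_genes too small to hold mito, marker and reporter genes"
        )
    return names, mito, marker_of, reporter_idx


def simulate_counts(config: SimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Draw a gene x cell count matrix and its ground truth.

    Returns an :class:`anndata.AnnData` (cells x genes) with integer counts
    in ``.X``, per-cell metadata (``sample_id``, ``sex``, truth labels) in
    ``.obs`` and per-gene flags (``mito``, ``marker_type``) in ``.var``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    names, mito, marker_of, reporter_idx = _gene_names(config)
    n_genes = config.n_genes
    types = sorted(config.cell_type_proportions)
    props = np.array([config.cell_type_proportions[t] for t in types])

    n_cells = config.n_samples * config.n_cells_per_sample
    sample_id = np.repeat(
        [f"s{k + 1}" for k in range(config.n_samples)],
        config.n_cells_per_sample,
    )
    sex = np.repeat(
        ["F" if k % 2 else "M" for k in range(config.n_samples)],
        config.n_cells_per_sample,
    )
    cell_type = rng.choice(types, size=n_cells, p=props)
    is_beta = cell_type == "beta"
    subtype = np.where(
        is_beta & (rng.random(n_cells) < config.beta_subtype_fraction), "A", ""
    )
    subtype[is_beta & (subtype == "")] = "B"

    # baseline relative rates; mito genes rescaled to hit the target fraction
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base[reporter_idx] = 0.0
    if config.mito_fraction_mean > 0 and mito.any():
        non_mito_sum = base[~mito].sum()
        target = (
            config.mito_fraction_mean / (1 - config.mito_fraction_mean)
        ) * non_mito_sum
        base[mito] *= target / base[mito].sum()

    lib_median = math.exp(config.libsize_log_mean)
    rel = base / base.sum()
    mu_norm = rel * lib_median  # expected normalized count per gene

    # plant DEGs among moderately expressed ordinary genes
    truth = SimTruth()
    ordinary = np.flatnonzero(
        (~mito) & (marker_of == "") & (np.arange(n_genes) != reporter_idx)
    )
    deg_mult = np.ones(n_genes)
    if config.n_deg > 0 and config.deg_effect != 0.0:
        candidates = ordinary[
            (mu_norm[ordinary] >= 0.25) & (mu_norm[ordinary] <= 20.0)
        ]
        if len(candidates) < config.n_deg:
            candidates = ordinary
        deg_idx = rng.choice(candidates, size=config.n_deg, replace=False)
        for k, gi in enumerate(deg_idx):
            sign = 1.0 if k % 2 == 0 else -1.0
            mu = mu_norm[gi]
            # multiplicative change with plug-in arcsinh difference == effect
            f = math.sinh(math.asinh(mu) + sign * config.deg_effect) / mu
            deg_mult[gi] = f
            truth.deg_genes.add(
                (names[gi], "up" if sign > 0 else "down", config.deg_effect)
            )

    # per-cell expected rates
    rates = np.tile(base, (n_cells, 1))
    type_idx = {t: np.flatnonzero(marker_of == t) for t in types}
    for t in types:
        rows = cell_type == t
        rates[np.ix_(rows, type_idx[t])] *= _MARKER_FOLD
    rows_a = subtype == "A"
    rates[rows_a] *= deg_mult
    # reporter: bimodal between beta subtypes, near-zero elsewhere
    rep_rel_a = _REPORTER_MU_A / lib_median
    rep_rel_b = _REPORTER_MU_B / lib_median
    rates[:, reporter_idx] = np.where(rows_a, rep_rel_a, rep_rel_b) * base.sum()

    rates /= rates.sum(axis=1, keepdims=True)
    libsize = rng.lognormal(
        config.libsize_log_mean, config.libsize_log_sd, size=n_cells
    )
    mu = rates * libsize[:, None]

    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    cells = [f"c{j:05d}" for j in range(n_cells)]
    for j, c in enumerate(cells):
        truth.cell_labels[c] = (
            str(cell_type[j]),
            str(subtype[j]),
            bool(subtype[j] == "A"),
        )

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {
                "sample_id": sample_id,
                "sex": sex,
                "true_cell_type": cell_type,
                "true_subtype": subtype,
                "true_reporter_positive": subtype == "A",
            },
            index=cells,
        ),
        var=pd.DataFrame(
            {"mito": mito, "marker_type": marker_of.astype(str)}, index=names
        ),
    )
    return adata, truth


def _place_windows(
    n_cpg_total: int,
    n_windows: int,
    window_cpgs: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Pick disjoint runs of consecutive CpG indices, one per window."""
    if n_windows == 0:
        return []
    gap = 3 * window_cpgs  # buffer keeps windows well separated
    need = n_windows * (window_cpgs + gap)
    if need > n_cpg_total:
        raise ValueError("genome too small for the requested windows")
    free = n_cpg_total - need
    offsets = np.sort(rng.choice(free + 1, size=n_windows, replace=True))
    starts = offsets + np.arange(n_windows) * (window_cpgs + gap) + gap // 2
    return [np.arange(s, s + window_cpgs) for s in starts]


def simulate_methylome(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw CpG methylation tables for two groups on a shared frame.

    Returns ``(table_a, table_b, truth)`` where each table has columns
    (chrom, pos, strand, context, meth_reads, total_reads) sorted by
    (chrom, pos).  Group A carries the planted DMR shifts.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x6D657468])
    )

    chroms, positions = [], []
    for c in range(config.n_chroms):
        name = f"chr{c + 1}"
        gaps = rng.exponential(config.cpg_spacing_mean, size=max(
            8, int(1.2 * config.chrom_length / config.cpg_spacing_mean)
        ))
        pos = np.unique((10 + np.cumsum(gaps)).astype(np.int64))
        pos = pos[pos < config.chrom_length - 2]
        chroms.append(np.full(len(pos), name, dtype=object))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    n = len(pos)

    level_a = np.full(n, config.background_meth)
    level_b = np.full(n, config.background_meth)
    truth = SimTruth()

    # choose window slots, then split between HMRs and DMRs
    slots = _place_windows(n, config.n_hmr + config.n_dmr, config.dmr_n_cpg, rng)
    rng.shuffle(slots)
    hmr_slots = slots[: config.n_hmr]
    dmr_slots = slots[config.n_hmr : config.n_hmr + config.n_dmr]

    for idx in hmr_slots:
        # windows must stay within one chromosome
        if chrom[idx[0]] != chrom[idx[-1]]:
            continue
        level_a[idx] = config.hmr_level
        level_b[idx] = config.hmr_level
        truth.hmr_regions.append(
            (str(chrom[idx[0]]), int(pos[idx[0]]), int(pos[idx[-1]]) + 2)
        )

    clipped = 0
    for k, idx in enumerate(dmr_slots):
        if chrom[idx[0]] != chrom[idx[-1]]:
            continue
        sign = 1 if k % 2 == 0 else -1
        shifted = level_a[idx] + sign * config.dmr_delta
        if ((shifted < 0) | (shifted > 1)).any():
            clipped += 1
        level_a[idx] = np.clip(shifted, 0.0, 1.0)
        if config.dmr_delta > 0:
            truth.dmr_regions.append(
                (str(chrom[idx[0]]), int(pos[idx[0]]), int(pos[idx[-1]]) + 2, sign)
            )
    if clipped:
        logger.warning(
            "dmr_delta clipped to [0, 1] in %d planted windows", clipped
        )

    def draw(levels: np.ndarray) -> pd.DataFrame:
        total = rng.poisson(config.coverage_mean, size=n)
        meth = rng.binomial(total, levels)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "strand": "+",
                "context": "CpG",
                "meth_reads": meth,
                "total_reads": total,
            }
        )

    return draw(level_a), draw(level_b), truth


def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Place non-overlapping gene models on the toy genome.

    Returns a DataFrame (gene_id, chrom, start, end, strand, utr3_start)
    with 0-based half-open coordinates.  The TSS is ``start`` on the plus
    strand and ``end - 1`` on the minus strand; the 3'UTR is the terminal
    10% of the gene body.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x616E6E6F])
    )
    n_per = config.genes_per_chrom
    records = []
    gi = 0
    for c in range(config.n_chroms):
        name = f"chr{c + 1}"
        slot = config.chrom_length // n_per
        if slot < 2000:
            raise ValueError("chrom_length too small for genes_per_chrom")
        for j in range(n_per):
            lo = j * slot
            length = int(rng.integers(1000, max(1001, slot // 2)))
            start = int(rng.integers(lo, lo + slot - length))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            utr_len = max(1, length // 10)
            utr3_start = end - utr_len if strand == "+" else start
            records.append(
                (f"gene{gi:04d}", name, start, end, strand, utr3_start)
            )
            gi += 1
    return pd.DataFrame(
        records,
        columns=["gene_id", "chrom", "start", "end", "strand", "utr3_start"],
    )


def plant_signature(
    adata: ad.AnnData,
    n_genes: int = 20,
    effect: float = 0.5,
    seed: int = 0,
) -> list[str]:
    """Shift a random signature of ordinary genes by ``effect`` on the
    arcsinh scale in subtype-A cells, in place; returns the gene list.

    Emulates a subpopulation marked by coordinated over-expression of a
    gene module (the human beta-cell arm of the study, where Pop1 is the
    smaller population carrying the signature).
    """
    if "arcsinh" not in adata.layers:
        raise ValueError("run normalize_transform before planting a signature")
    rng = np.random.default_rng(seed)
    ordinary = [g for g in adata.var_names if g.startswith("g")]
    genes = [str(g) for g in rng.choice(ordinary, size=n_genes, replace=False)]
    idx = [adata.var_names.get_loc(g) for g in genes]
    in_a = (adata.obs["true_subtype"] == "A").to_numpy()
    arc = np.asarray(adata.layers["arcsinh"])
    arc[np.ix_(in_a, idx)] += effect
    adata.layers["arcsinh"] = arc
    return genes


def null_config(config: SimConfig | None = None, **overrides) -> SimConfig:
    """A copy of ``config`` with no planted effects (DEGs or DMRs)."""
    base = config or SimConfig()
    return replace(base, n_deg=0, deg_effect=0.0, n_dmr=0, **overrides)
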