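"""Pipeline parameters and YAML configuration.

Every threshold the analysis depends on lives here with its default:
reporter positivity cutoff 0.9 (arcsinh scale); pseudobulk low-expression
floor 0.002; paired-test alpha 0.05 with minimum arcsinh difference 0.05;
DMR gates 50 bp span / 2 significant CpGs at per-CpG alpha 0.05;
regulatory-domain extension cap 1 Mb; enhancer window 2 kb upstream of the
TSS through the 3'UTR; signature control pool 2000 genes with Pop1
threshold 0.2; HMR clustering into 6 clusters flagged above a 1.8-fold
centroid change.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineParams", "load_config", "save_config"]


@dataclass
class PipelineParams:
    # reporter gating / pseudobulk DE
    reporter_cutoff: float = 0.9
    low_expr_min: float = 0.002
    deg_alpha: float = 0.05
    deg_min_diff: float = 0.05
    # methylome
    cpg_alpha: float = 0.05
    dmr_min_span: int = 50
    dmr_min_cpgs: int = 2
    dmr_max_gap: int = 500
    hmr_tau: float = 0.5
    hmr_min_cpgs: int = 4
    hmr_max_gap: int = 1000
    hmr_k: int = 6
    fold_flag: float = 1.8
    # regulatory domains
    great_basal_up: int = 5000
    great_basal_down: int = 1000
    great_max_ext: int = 1_000_000
    enhancer_upstream: int = 2000
    # signature scoring
    ctrl_pool: int = 2000
    pop_threshold: float = 0.2
    n_bins: int = 25
    n_perm: int = 1000
    # misc
    min_counts: int = 200
    max_mito: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        positive = [
            "reporter_cutoff", "low_expr_min", "deg_alpha", "deg_min_diff",
            "cpg_alpha", "dmr_min_span", "dmr_min_cpgs", "dmr_max_gap",
            "hmr_tau", "hmr_min_cpgs", "hmr_max_gap", "hmr_k", "fold_flag",
            "great_basal_up", "great_basal_down", "great_max_ext",
            "enhancer_upstream", "ctrl_pool", "pop_threshold", "n_bins",
            "n_perm",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("deg_alpha", "cpg_alpha", "max_mito"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> PipelineParams:
    """Load parameters from YAML; missing keys use defaults, unknown keys
    are rejected by name."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in fields(PipelineParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params = PipelineParams(**data)
    params.validate()
    return params


def save_config(params: PipelineParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.as_dict(), fh, sort_keys=True)
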