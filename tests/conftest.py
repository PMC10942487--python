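import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from betatype import prep
from betatype.simulate import SimConfig, simulate_counts, simulate_methylome

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def islet_sim():
    """Default multi-cell-type islet simulation (counts + truth)."""
    cfg = SimConfig(seed=11)
    adata, truth = simulate_counts(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def beta_sim():
    """Pure beta-cell simulation with planted DEGs, transformed."""
    cfg = SimConfig(
        seed=12, cell_type_proportions={"beta": 1.0}, n_cells_per_sample=400
    )
    adata, truth = simulate_counts(cfg)
    adata = prep.normalize_transform(adata, zscore=True)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def meth_sim():
    """Two-group methylome with planted DMRs."""
    cfg = SimConfig(seed=13)
    a, b, truth = simulate_methylome(cfg)
    return cfg, a, b, truth


@pytest.fixture()
def tiny_counts():
    """Hand-sized count matrix for closed-form checks."""
    import anndata as ad

    X = np.array(
        [
            [10, 0, 40, 50],  # lib 100
            [40, 10, 150, 200],  # lib 400
            [20, 5, 75, 100],  # lib 200
        ]
    )
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(
            {"sample_id": ["s1", "s1", "s2"]}, index=["c1", "c2", "c3"]
        ),
        var=pd.DataFrame(
            {"mito": [False, True, False, False]},
            index=["gA", "mt-1", "gB", "gC"],
        ),
    )
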