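"""QC filtering, the median-library/arcsinh/z-score transform, reporter
gating and marker labeling."""

import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from betatype import prep
from betatype.prep import EmptyResultError


class TestQcFilter:
    def test_identity_when_thresholds_trivial(self, tiny_counts):
        out = prep.qc_filter(tiny_counts, min_counts=0, max_mito=1.0)
        assert list(out.obs_names) == list(tiny_counts.obs_names)
        np.testing.assert_array_equal(out.X, tiny_counts.X)

    def test_pure_mito_cell_removed(self):
        a = ad.AnnData(
            X=np.array([[0, 50], [30, 5]]),
            obs=pd.DataFrame(index=["bad", "good"]),
            var=pd.DataFrame({"mito": [False, True]}, index=["g", "mt"]),
        )
        out = prep.qc_filter(a, min_counts=0, max_mito=0.2)
        assert list(out.obs_names) == ["good"]

    def test_planted_low_count_cells_removed_exactly(self, islet_sim):
        _, adata, _ = islet_sim
        X = np.asarray(adata.X).copy()
        rng = np.random.default_rng(0)
        victims = rng.choice(adata.n_obs, 10, replace=False)
        X[victims] = 0
        X[victims, 0] = 1  # keep nonzero so the cell still exists
        mod = ad.AnnData(X=X, obs=adata.obs.copy(), var=adata.var.copy())
        out = prep.qc_filter(mod, min_counts=100, max_mito=1.0)
        removed = set(adata.obs_names[victims])
        assert set(adata.obs_names) - set(out.obs_names) == removed

    def test_all_removed_raises_with_counts(self, tiny_counts):
        with pytest.raises(EmptyResultError, match="low counts"):
            prep.qc_filter(tiny_counts, min_counts=10_000)


class TestNormalizeTransform:
    def test_zero_count_maps_to_zero(self, tiny_counts):
        out = prep.normalize_transform(tiny_counts)
        assert out.layers["arcsinh"][0, 1] == 0.0

    def test_single_cell_single_gene_closed_form(self):
        a = ad.AnnData(X=np.array([[4]]), obs=pd.DataFrame(index=["c"]),
                       var=pd.DataFrame(index=["g"]))
        out = prep.normalize_transform(a)
        assert out.X[0, 0] == pytest.approx(math.log(4 + math.sqrt(17)), abs=1e-12)

    def test_median_ratio_scale_factors(self):
        # libraries 100 and 400, median 250 -> factors 2.5 and 0.625;
        # with a third cell at 200 the median is 200 -> 2.0 and 0.5
        a = ad.AnnData(X=np.array([[100.0], [400.0], [200.0]]).astype(int),
                       obs=pd.DataFrame(index=list("abc")),
                       var=pd.DataFrame(index=["g"]))
        out = prep.normalize_transform(a)
        normed = np.sinh(out.layers["arcsinh"][:, 0])
        np.testing.assert_allclose(normed, [200.0, 200.0, 200.0], rtol=1e-12)

    def test_normalized_library_equals_median_exactly(self, tiny_counts):
        out = prep.normalize_transform(tiny_counts)
        libs = np.sinh(out.layers["arcsinh"]).sum(axis=1)
        med = float(np.median(np.asarray(tiny_counts.X).sum(axis=1)))
        np.testing.assert_allclose(libs, med, rtol=1e-9)

    def test_zscore_stage_moments(self, beta_sim):
        _, adata, _ = beta_sim
        z = np.asarray(adata.X)
        arc = np.asarray(adata.layers["arcsinh"])
        varying = arc.std(axis=0) > 0
        assert np.abs(z[:, varying].mean(axis=0)).max() < 1e-8
        np.testing.assert_allclose(z[:, varying].std(axis=0), 1.0, atol=1e-6)
        constant = ~varying
        if constant.any():
            assert (z[:, constant] == 0).all()

    def test_monotone_per_gene(self, tiny_counts):
        out = prep.normalize_transform(tiny_counts)
        X = np.asarray(tiny_counts.X, dtype=float)
        arc = out.layers["arcsinh"]
        for i in range(X.shape[0]):
            order = np.argsort(X[i])
            assert (np.diff(arc[i][order]) >= 0).all()

    def test_permutation_invariance(self, tiny_counts):
        out = prep.normalize_transform(tiny_counts, zscore=True)
        perm = [2, 0, 1]
        shuffled = tiny_counts[perm].copy()
        out_p = prep.normalize_transform(shuffled, zscore=True)
        np.testing.assert_allclose(
            np.asarray(out.X)[perm], np.asarray(out_p.X), atol=1e-12
        )

    def test_zero_library_cell_dropped(self):
        a = ad.AnnData(X=np.array([[0, 0], [3, 1]]),
                       obs=pd.DataFrame(index=["dead", "live"]),
                       var=pd.DataFrame(index=["g1", "g2"]))
        out = prep.normalize_transform(a)
        assert list(out.obs_names) == ["live"]


class TestReporterGate:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.5, "positive"), (0.0, "negative"), (0.9, "negative")],
    )
    def test_cutoff_convention(self, value, expected):
        a = ad.AnnData(X=np.array([[1.0]]), obs=pd.DataFrame(index=["c"]),
                       var=pd.DataFrame(index=["tdTomato"]))
        a.layers["arcsinh"] = np.array([[value]])
        labels = prep.reporter_gate(a, "tdTomato", cutoff=0.9)
        assert labels["c"] == expected

    def test_missing_reporter_raises(self, tiny_counts):
        t = prep.normalize_transform(tiny_counts)
        with pytest.raises(KeyError):
            prep.reporter_gate(t, "nope")

    def test_recovers_truth_labels(self, beta_sim):
        cfg, adata, _ = beta_sim
        labels = prep.reporter_gate(adata, cfg.reporter_gene)
        truth = adata.obs["true_reporter_positive"]
        acc = ((labels == "positive") == truth).mean()
        assert acc >= 0.98


class TestLabelCelltypes:
    def test_single_type_labels_everything(self, beta_sim):
        _, adata, _ = beta_sim
        markers = {"beta": [g for g in adata.var_names if g.startswith("mk-beta")]}
        assert (prep.label_celltypes(adata, markers) == "beta").all()

    def test_tie_breaks_lexicographically(self):
        a = ad.AnnData(X=np.ones((3, 2)), obs=pd.DataFrame(index=list("abc")),
                       var=pd.DataFrame(index=["g1", "g2"]))
        a.layers["arcsinh"] = np.array([[1.0, 1.0], [2.0, 2.0], [0.0, 0.0]])
        labels = prep.label_celltypes(a, {"zeta": ["g1"], "alpha": ["g2"]})
        assert (labels == "alpha").all()

    def test_accuracy_on_planted_markers(self, islet_sim):
        cfg, adata, _ = islet_sim
        t = prep.normalize_transform(adata)
        markers = {
            ty: [g for g in t.var_names if g.startswith(f"mk-{ty}-")]
            for ty in sorted(cfg.cell_type_proportions)
        }
        labels = prep.label_celltypes(t, markers)
        assert (labels == t.obs["true_cell_type"]).mean() >= 0.95

    def test_empty_marker_map_rejected(self, beta_sim):
        _, adata, _ = beta_sim
        with pytest.raises(ValueError):
            prep.label_celltypes(adata, {})


class TestSubtypeFraction:
    def test_fraction_and_ratio_arithmetic(self):
        labels = pd.Series(
            ["positive"] * 3 + ["negative"], index=list("abcd")
        )
        out = prep.subtype_fraction(labels)
        assert out.loc["all", "fraction_positive"] == 0.75
        assert out.loc["all", "ratio"] == 3.0

    def test_all_positive_ratio_sentinel(self):
        labels = pd.Series(["positive", "positive"], index=["a", "b"])
        assert prep.subtype_fraction(labels).loc["all", "ratio"] == np.inf

    def test_recovers_simulated_fraction(self):
        from betatype.simulate import SimConfig, simulate_counts

        cfg = SimConfig(
            seed=5,
            cell_type_proportions={"beta": 1.0},
            n_cells_per_sample=250,
            beta_subtype_fraction=0.6,
        )
        adata, _ = simulate_counts(cfg)
        t = prep.normalize_transform(adata)
        labels = prep.reporter_gate(t, cfg.reporter_gene)
        out = prep.subtype_fraction(labels)
        assert abs(out.loc["all", "fraction_positive"] - 0.6) <= 0.05
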