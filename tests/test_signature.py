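"""Module scoring, Pop1/Pop2 classification, the Gini clusteredness test,
subpopulation DE and population-fraction comparisons."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from betatype import prep, signature
from betatype.simulate import SimConfig, plant_signature, simulate_counts


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(
        seed=31,
        cell_type_proportions={"beta": 1.0},
        n_cells_per_sample=500,
        beta_subtype_fraction=0.3,
    )
    adata, _ = simulate_counts(cfg)
    adata = prep.normalize_transform(adata)
    genes = plant_signature(adata, n_genes=20, effect=0.5, seed=31)
    return adata, genes


def _flat(n_cells=30, n_genes=40, value=1.0):
    X = np.full((n_cells, n_genes), value)
    a = ad.AnnData(
        X=X.copy(),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(n_genes)]),
    )
    a.layers["arcsinh"] = X
    return a


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        a = _flat()
        s = signature.module_score(a, ["g0", "g1"], n_bins=2, seed=0)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_full_gene_list_rejected(self):
        a = _flat(n_genes=10)
        with pytest.raises(ValueError, match="no controls"):
            signature.module_score(a, [f"g{i}" for i in range(10)], seed=0)

    def test_planted_subpopulation_scores_higher(self, planted):
        adata, genes = planted
        in_a = (adata.obs["true_subtype"] == "A").to_numpy()
        for seed in range(3):
            s = signature.module_score(adata, genes, seed=seed)
            assert s[in_a].mean() > s[~in_a].mean()

    def test_deterministic_under_seed(self, planted):
        adata, genes = planted
        s1 = signature.module_score(adata, genes, seed=5)
        s2 = signature.module_score(adata, genes, seed=5)
        pd.testing.assert_series_equal(s1, s2)

    def test_cell_shuffle_permutes_scores(self, planted):
        adata, genes = planted
        s = signature.module_score(adata, genes, seed=2)
        perm = np.random.default_rng(3).permutation(adata.n_obs)
        s_p = signature.module_score(adata[perm].copy(), genes, seed=2)
        np.testing.assert_allclose(s.to_numpy()[perm], s_p.to_numpy(), atol=1e-12)


class TestClassifyPopulation:
    @pytest.mark.parametrize(
        "score,expected", [(0.5, "Pop1"), (0.1, "Pop2"), (0.2, "Pop2")]
    )
    def test_threshold_convention(self, score, expected):
        out = signature.classify_population(pd.Series([score], index=["c"]))
        assert out["c"] == expected

    def test_accuracy_on_planted_signature(self, planted):
        adata, genes = planted
        s = signature.module_score(adata, genes, seed=0)
        pops = signature.classify_population(s)
        in_a = (adata.obs["true_subtype"] == "A").to_numpy()
        assert (((pops == "Pop1").to_numpy()) == in_a).mean() >= 0.9


class TestGiniIndex:
    def test_constant_vector_zero(self):
        assert signature.gini_index([3.0] * 7) == pytest.approx(0.0, abs=1e-12)

    def test_concentrated_vector(self):
        assert signature.gini_index([0, 0, 0, 1]) == pytest.approx(0.75, abs=1e-12)

    def test_matches_double_sum_definition(self):
        rng = np.random.default_rng(4)
        x = rng.random(50)
        n = len(x)
        oracle = np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())
        assert signature.gini_index(x) == pytest.approx(oracle, abs=1e-12)

    @given(
        x=st.lists(st.floats(0.001, 100.0), min_size=2, max_size=30),
        c=st.floats(0.01, 50.0),
    )
    def test_scale_invariance(self, x, c):
        x = np.asarray(x)
        assert signature.gini_index(c * x) == pytest.approx(
            signature.gini_index(x), abs=1e-9
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            signature.gini_index([0.0, 0.0])


class TestGiniSignatureTest:
    def test_clustered_signature_significant(self, planted):
        adata, genes = planted
        res = signature.gini_signature_test(adata, genes, n_perm=200, seed=0)
        assert res["p"] <= 0.05

    def test_uniform_signature_not_significant(self):
        rng = np.random.default_rng(8)
        X = np.arcsinh(rng.poisson(3.0, size=(400, 300)).astype(float))
        a = ad.AnnData(
            X=X.copy(),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(400)]),
            var=pd.DataFrame(index=[f"g{i}" for i in range(300)]),
        )
        a.layers["arcsinh"] = X
        res = signature.gini_signature_test(
            a, [f"g{i}" for i in range(20)], n_perm=99, seed=0
        )
        assert res["p"] > 0.05

    def test_zero_permutations_rejected(self, planted):
        adata, genes = planted
        with pytest.raises(ValueError):
            signature.gini_signature_test(adata, genes, n_perm=0)


class TestSubpopDe:
    def test_exact_small_sample_p(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        a = ad.AnnData(
            X=X.copy(),
            obs=pd.DataFrame(index=list("abcd")),
            var=pd.DataFrame(index=["g"]),
        )
        a.layers["arcsinh"] = X
        labels = pd.Series(["Pop1", "Pop1", "Pop2", "Pop2"], index=list("abcd"))
        out = signature.subpop_de(a, labels)
        assert out.iloc[0]["p"] == pytest.approx(1 / 3, abs=1e-12)

    def test_all_tied_p_one(self):
        a = _flat(n_cells=20, n_genes=3)
        labels = pd.Series(
            ["Pop1"] * 10 + ["Pop2"] * 10, index=a.obs_names
        )
        out = signature.subpop_de(a, labels)
        assert (out["p"] == 1.0).all()

    def test_planted_genes_recovered_with_sign(self, planted):
        adata, genes = planted
        s = signature.module_score(adata, genes, seed=0)
        pops = signature.classify_population(s)
        out = signature.subpop_de(adata, pops)
        hits = out.loc[genes]
        assert (hits["significant"]).mean() >= 0.9
        assert (hits["rank_score"] > 0).all()

    def test_tiny_population_rejected(self):
        a = _flat(n_cells=5, n_genes=3)
        labels = pd.Series(["Pop1"] + ["Pop2"] * 4, index=a.obs_names)
        with pytest.raises(ValueError):
            signature.subpop_de(a, labels)


class TestGroupedScoreTest:
    def test_identical_groups_gate_closed(self):
        g = {k: np.ones(5) for k in "abc"}
        res = signature.grouped_score_test(g)
        assert res["p"] == 1.0
        assert all(v is None for v in res["pairwise"].values())

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(0)
        g = {
            "a": rng.normal(0, 1, 40),
            "b": rng.normal(0, 1, 40),
            "c": rng.normal(3, 1, 40),
        }
        res = signature.grouped_score_test(g)
        assert res["p"] < 0.05
        assert res["pairwise"][("a", "c")] < 0.05
        assert res["pairwise"][("a", "b")] > 0.05

    def test_two_groups_degenerates_to_mwu(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        res = signature.grouped_score_test({"a": a, "b": b})
        assert res["omnibus"] == "mannwhitneyu"
        assert res["p"] == pytest.approx(stats.mannwhitneyu(a, b).pvalue)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            signature.grouped_score_test({"a": np.ones(5)})


class TestComparePopulationFractions:
    def _inputs(self, fracs_by_donor):
        rows = []
        for donor, (cond, frac) in fracs_by_donor.items():
            n = 100
            n1 = int(round(frac * n))
            for i in range(n):
                rows.append((f"{donor}_{i}", "Pop1" if i < n1 else "Pop2", donor, cond))
        df = pd.DataFrame(rows, columns=["cell", "label", "donor", "cond"])
        df = df.set_index("cell")
        return df["label"], df["donor"], df["cond"]

    def test_identical_fractions_p_one(self):
        labels, donors, conds = self._inputs(
            {"d1": ("ctl", 0.4), "d2": ("ctl", 0.4),
             "d3": ("t2d", 0.4), "d4": ("t2d", 0.4)}
        )
        assert signature.compare_population_fractions(labels, donors, conds)["p"] == 1.0

    def test_constant_shifted_fractions_convention(self):
        labels, donors, conds = self._inputs(
            {"d1": ("ctl", 0.5), "d2": ("ctl", 0.5),
             "d3": ("t2d", 0.2), "d4": ("t2d", 0.2)}
        )
        assert signature.compare_population_fractions(labels, donors, conds)["p"] == 0.0

    def test_planted_decline_detected(self):
        rng = np.random.default_rng(2)
        design = {}
        for i in range(6):
            design[f"c{i}"] = ("ctl", 0.45 + rng.normal(0, 0.03))
        for i in range(6):
            design[f"t{i}"] = ("t2d", 0.25 + rng.normal(0, 0.03))
        labels, donors, conds = self._inputs(design)
        res = signature.compare_population_fractions(labels, donors, conds)
        assert res["p"] < 0.05
        assert res["mean_fraction"]["t2d"] < res["mean_fraction"]["ctl"]

    def test_single_donor_condition_rejected(self):
        labels, donors, conds = self._inputs(
            {"d1": ("ctl", 0.4), "d3": ("t2d", 0.4), "d4": ("t2d", 0.4)}
        )
        with pytest.raises(ValueError):
            signature.compare_population_fractions(labels, donors, conds)
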