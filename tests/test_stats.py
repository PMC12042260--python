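"""Group tests, ECDF summaries, autoscaling, PCA, SOM, feature assembly."""

import numpy as np
import pandas as pd
import pytest

import nrtraj as nt
from nrtraj.errors import AssemblyError
from nrtraj.stats import FeatureTable


def _table(data, labels=None):
    df = pd.DataFrame(data)
    lab = pd.DataFrame(labels if labels is not None
                       else [{"receptor": "synthetic", "ligand": f"L{i}",
                              "start_conformation": "AGO", "activity_class": "agonist"}
                             for i in range(len(df))], index=df.index)
    return FeatureTable(data=df, labels=lab)


class TestKruskalDunn:
    def test_identical_groups(self):
        res = nt.kruskal_dunn([[1, 2, 3], [1, 2, 3]])
        assert res.h_statistic == 0.0
        assert res.p_value == 1.0

    def test_complete_separation_flagged(self):
        res = nt.kruskal_dunn([list(range(1, 51)), list(range(101, 151))])
        assert res.p_value < 0.05
        row = res.pairwise.iloc[0]
        assert row["p_adjusted"] < 0.05
        assert abs(row["cliffs_delta"]) == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            nt.kruskal_dunn([[1, 2, 3]])

    def test_h_matches_rank_sum_oracle(self):
        """Tie-free case: H from the textbook rank-sum formula."""
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=8), rng.normal(size=12), rng.normal(1.0, 1.0, 10)]
        pooled = np.concatenate(groups)
        from scipy.stats import rankdata
        ranks = rankdata(pooled)
        n = len(pooled)
        bounds = np.cumsum([0] + [len(g) for g in groups])
        h_oracle = (12 / (n * (n + 1))
                    * sum(len(g) * ranks[bounds[i]:bounds[i + 1]].mean() ** 2
                          for i, g in enumerate(groups))) - 3 * (n + 1)
        res = nt.kruskal_dunn(groups)
        assert res.h_statistic == pytest.approx(h_oracle, abs=1e-9)

    def test_adjusted_p_monotone_in_raw_p(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(loc=m, size=15) for m in (0.0, 0.3, 1.5, 2.0)]
        pw = nt.kruskal_dunn(groups).pairwise.sort_values("p_raw")
        adj = pw["p_adjusted"].to_numpy()
        assert np.all(np.diff(adj) >= -1e-12)
        assert (pw["p_adjusted"] >= pw["p_raw"] - 1e-12).all()


class TestEcdf:
    def test_median_of_1_to_100(self):
        s = nt.ecdf_summary(np.arange(1, 101))
        assert s.median == pytest.approx(50.5)

    def test_ecdf_at_max_is_one(self):
        s = nt.ecdf_summary([3.0, 1.0, 2.0])
        assert s.ecdf(3.0) == pytest.approx(1.0)

    def test_ecdf_at_planted_quantile(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=4000)
        s = nt.ecdf_summary(values)
        q30 = np.quantile(values, 0.3)
        se = np.sqrt(0.3 * 0.7 / len(values))
        assert abs(s.ecdf(q30) - 0.3) < 3 * se + 1 / len(values)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nt.ecdf_summary([])


class TestAutoscale:
    def test_columns_standardised(self):
        t = nt.autoscale(_table({"a": [1.0, 2.0, 3.0], "b": [10.0, 30.0, 20.0]}))
        assert np.allclose(t.data.mean(), 0.0, atol=1e-12)
        assert np.allclose(t.data.std(ddof=1), 1.0)

    def test_constant_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            t = nt.autoscale(_table({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]}))
        assert list(t.data.columns) == ["a"]

    def test_idempotent(self):
        t1 = nt.autoscale(_table({"a": [1.0, 2.0, 4.0], "b": [0.0, 5.0, 1.0]}))
        t2 = nt.autoscale(t1)
        assert np.allclose(t1.data.to_numpy(), t2.data.to_numpy(), atol=1e-12)


class TestPca:
    def test_single_axis_variance(self):
        t = _table({"x": [0.0, 1.0, 2.0, 3.0], "y": [5.0, 5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            res = nt.pca(nt.autoscale(t), 1)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(21)
        data = pd.DataFrame(rng.normal(size=(20, 8)),
                            columns=[f"d{i}" for i in range(8)])
        table = nt.autoscale(_table(data))
        res = nt.pca(table, 5)
        cov = np.cov(table.data.to_numpy(), rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        oracle = eig / eig.sum()
        assert np.allclose(res.explained_fraction, oracle[:5], atol=1e-8)

    def test_isotropic_two_dimensional(self):
        rng = np.random.default_rng(22)
        data = pd.DataFrame(rng.normal(size=(10000, 2)), columns=["x", "y"])
        res = nt.pca(nt.autoscale(_table(data)), 2)
        assert np.allclose(res.explained_fraction, 0.5, atol=0.02)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(23)
        data = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        table = nt.autoscale(_table(data))
        res = nt.pca(table, 4)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, table.data.to_numpy(), atol=1e-8)

    def test_loadings_orthonormal_and_fractions_sorted(self):
        rng = np.random.default_rng(24)
        data = pd.DataFrame(rng.normal(size=(15, 6)) * [1, 2, 3, 1, 5, 1],
                            columns=list("abcdef"))
        res = nt.pca(nt.autoscale(_table(data)), 4)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-9)
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)
        assert res.explained_fraction.sum() <= 1 + 1e-9

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(25)
        data = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        r1 = nt.pca(nt.autoscale(_table(data)), 2)
        r2 = nt.pca(nt.autoscale(_table(data)), 2)
        assert np.array_equal(r1.loadings.to_numpy(), r2.loadings.to_numpy())
        for k in range(2):
            col = r1.loadings.to_numpy()[:, k]
            assert col[np.argmax(np.abs(col))] > 0


class TestSom:
    def test_same_seed_identical(self):
        rng = np.random.default_rng(30)
        data = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        table = nt.autoscale(_table(data))
        r1 = nt.som_fit(table, epochs=20, seed=5)
        r2 = nt.som_fit(table, epochs=20, seed=5)
        assert np.array_equal(r1.assignments, r2.assignments)
        assert np.allclose(r1.weights, r2.weights)

    def test_repeated_row_collapses_to_one_neuron(self):
        data = pd.DataFrame(np.tile([[1.0, -1.0, 0.5]], (8, 1)), columns=list("abc"))
        table = FeatureTable(data=data, labels=pd.DataFrame(index=data.index))
        res = nt.som_fit(table, epochs=40, seed=2)
        assert len({tuple(a) for a in res.assignments}) == 1
        assert res.quantization_error < 0.05

    def test_planted_clusters_map_far_apart(self):
        rng = np.random.default_rng(31)
        a = rng.normal(0.0, 1.0, size=(10, 3))
        b = rng.normal(10.0, 1.0, size=(10, 3))
        data = pd.DataFrame(np.vstack([a, b]), columns=list("xyz"))
        res = nt.som_fit(nt.autoscale(_table(data)), epochs=40, seed=7)
        dists = [res.bmu_distance(i, 10 + j) for i in range(10) for j in range(10)]
        assert min(dists) >= 3

    def test_quantization_error_converges_in_fine_tuning(self):
        """After the ordering phase (radius shrunk), QE decreases monotonically."""
        rng = np.random.default_rng(32)
        data = pd.DataFrame(rng.normal(size=(30, 5)))
        data.columns = [f"c{i}" for i in range(5)]
        res = nt.som_fit(nt.autoscale(_table(data)), epochs=30, seed=1)
        tail = res.qe_history[15:]
        assert np.all(np.diff(tail) <= 1e-9)
        assert res.quantization_error <= tail[0]


class TestAssembleFeatures:
    def test_two_systems_full_registry(self):
        desc = {"s1": {"a": 1.0, "b": 2.0}, "s2": {"a": 3.0, "b": 4.0}}
        table = nt.assemble_features(desc)
        assert table.data.shape == (2, 2)
        assert list(table.data.columns) == ["a", "b"]

    def test_missing_descriptor_named(self):
        desc = {"s1": {"a": 1.0, "b": 2.0}, "s2": {"a": 3.0}}
        with pytest.raises(AssemblyError, match="s2"):
            nt.assemble_features(desc)

    def test_column_order_deterministic(self):
        desc = {"s1": {"z": 1.0, "a": 2.0, "m": 0.0}}
        t1 = nt.assemble_features(desc)
        t2 = nt.assemble_features({"s1": {"m": 0.0, "a": 2.0, "z": 1.0}})
        assert list(t1.data.columns) == list(t2.data.columns)
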