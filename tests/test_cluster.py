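import numpy as np
import pandas as pd
import pytest

from matchload import cluster as cl
from matchload.features import FEATURE_ORDER


@pytest.fixture(scope="module")
def small_model(small_table):
    return cl.fit_intensity_model(small_table, seed=17, n_init=5)


class TestExcludeLowDistance:
    def test_below_threshold_dropped(self, small_table):
        df = small_table.copy()
        df.loc[df.index[0], "excluded"] = False
        df.loc[df.index[0], "distance_m"] = 150.0
        train, dropped = cl.exclude_low_distance(df)
        assert df.index[0] not in train.index

    def test_boundary_retained(self, small_table):
        df = small_table.head(50).copy()
        df["excluded"] = False
        df["distance_m"] = 200.0
        train, dropped = cl.exclude_low_distance(df)
        assert len(train) == 50 and dropped.empty

    def test_halftime_adjacent_minutes_excluded(self, small_table):
        # every minute whose prior window touches halftime is out of training
        train, _ = cl.exclude_low_distance(small_table)
        assert not train.minute.between(45, 64).any()

    def test_empty_training_is_error(self, small_table):
        df = small_table.copy()
        df["excluded"] = True
        with pytest.raises(cl.ClusteringError):
            cl.exclude_low_distance(df)


class TestMinMax:
    def test_midpoint(self):
        df = pd.DataFrame({c: [2.0, 6.0] for c in FEATURE_ORDER})
        bounds = cl.fit_minmax(df)
        row = pd.DataFrame({c: [4.0] for c in FEATURE_ORDER})
        assert np.allclose(cl.transform_minmax(row, bounds), 0.5)

    def test_train_max_maps_to_one(self):
        df = pd.DataFrame({c: [2.0, 6.0] for c in FEATURE_ORDER})
        Z = cl.transform_minmax(df, cl.fit_minmax(df))
        assert np.allclose(Z[1], 1.0)

    def test_unseen_value_not_clipped(self):
        df = pd.DataFrame({c: [2.0, 6.0] for c in FEATURE_ORDER})
        bounds = cl.fit_minmax(df)
        row = pd.DataFrame({c: [8.0] for c in FEATURE_ORDER})
        assert np.allclose(cl.transform_minmax(row, bounds), 1.5)

    def test_constant_feature_maps_to_zero_with_warning(self):
        df = pd.DataFrame({c: [2.0, 6.0] for c in FEATURE_ORDER})
        df["walk_energy_jkg"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            bounds = cl.fit_minmax(df)
        Z = cl.transform_minmax(df, bounds)
        col = FEATURE_ORDER.index("walk_energy_jkg")
        assert np.allclose(Z[:, col], 0.0)


class TestPca:
    def test_full_variance_keeps_all_components(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(200, 25))
        pca = cl.fit_pca(Z, variance_target=1.0)
        assert pca.n_components_ == 25

    def test_low_rank_data_needs_few_components(self):
        # oracle: brute-force eigendecomposition of the constructed covariance
        rng = np.random.default_rng(1)
        signal = rng.normal(size=(500, 3)) @ rng.normal(size=(3, 25))
        Z = signal + 1e-4 * rng.normal(size=(500, 25))
        C = np.cov(Z.T)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        n_oracle = int(np.searchsorted(np.cumsum(evals) / evals.sum(), 0.92) + 1)
        pca = cl.fit_pca(Z, variance_target=0.92)
        assert pca.n_components_ == n_oracle <= 4

    def test_projected_training_data_centered(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(300, 25))
        pca = cl.fit_pca(Z, variance_target=0.92)
        P = pca.transform(Z)
        assert np.allclose(P.mean(axis=0), 0.0, atol=1e-9)

    def test_reconstruction_error_decreases_with_components(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(200, 10)) @ rng.normal(size=(10, 25))
        errors = []
        for n in (1, 3, 5, 8):
            pca = cl.fit_pca(Z, n_components=n)
            P = pca.transform(Z)
            back = P @ pca.components_ + pca.mean_
            errors.append(float(((Z - back) ** 2).sum()))
        assert errors == sorted(errors, reverse=True)

    def test_bad_target_rejected(self):
        with pytest.raises(cl.ClusteringError):
            cl.fit_pca(np.zeros((10, 25)), variance_target=1.5)


class TestChooseK:
    def test_worked_curve(self):
        # oracle: brute-force perpendicular chord distances give k=3
        assert cl.choose_k({2: 100.0, 3: 30.0, 4: 25.0, 5: 22.0, 6: 20.0}) == 3

    def test_linear_curve_ties_to_smallest(self):
        wcss = {k: 100.0 - 5.0 * k for k in range(2, 10)}
        assert cl.choose_k(wcss) == 2

    def test_too_few_points_rejected(self):
        with pytest.raises(cl.ClusteringError):
            cl.choose_k({2: 10.0, 3: 5.0})


class TestKmeans:
    def test_k1_equals_total_centered_ss(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(100, 3))
        _, _, wcss = cl.fit_kmeans(P, 1, seed=0)
        assert wcss == pytest.approx(((P - P.mean(axis=0)) ** 2).sum())

    def test_two_separated_clouds(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 0.1, size=(200, 2))
        b = rng.normal(5.0, 0.1, size=(200, 2))
        P = np.vstack([a, b])
        centroids, _, _ = cl.fit_kmeans(P, 2, seed=0)
        means = sorted([a.mean(axis=0), b.mean(axis=0)], key=lambda m: m[0])
        got = sorted(centroids, key=lambda m: m[0])
        assert np.allclose(got, means, atol=0.05)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        P = rng.normal(size=(150, 4))
        c1, l1, w1 = cl.fit_kmeans(P, 3, seed=11)
        c2, l2, w2 = cl.fit_kmeans(P, 3, seed=11)
        assert np.array_equal(c1, c2) and np.array_equal(l1, l2) and w1 == w2

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(cl.ClusteringError):
            cl.fit_kmeans(np.zeros((2, 2)), 3)

    def test_wcss_nonincreasing_in_k(self, small_table):
        train, _ = cl.exclude_low_distance(small_table)
        Z = cl.transform_minmax(train, cl.fit_minmax(train))
        P = cl.fit_pca(Z).transform(Z)
        wcss = [cl.fit_kmeans(P, k, seed=3, n_init=10)[2] for k in range(2, 8)]
        assert all(a >= b - 1e-6 for a, b in zip(wcss, wcss[1:]))


class TestLabelClusters:
    def _frame(self, event_counts, energies):
        df = pd.DataFrame({c: np.zeros(len(event_counts)) for c in FEATURE_ORDER})
        df["event_count"] = event_counts
        df["general_energy_jkg"] = energies
        return df

    def test_table_semantics(self):
        # means mirror the cluster profile: no-event cluster -> low; of the
        # rest, the one with greater prior energy -> high
        df = self._frame([0, 0, 1.8, 1.8, 2.0, 2.0], [2900, 2900, 1300, 1300, 2800, 2800])
        ids = np.array([0, 0, 1, 1, 2, 2])
        assert cl.label_clusters(df, ids, 3) == {0: "low", 1: "middle", 2: "high"}

    def test_permutation_invariance(self):
        df = self._frame([2.0, 2.0, 0, 0, 1.8, 1.8], [2800, 2800, 2900, 2900, 1300, 1300])
        ids = np.array([0, 0, 1, 1, 2, 2])
        assert cl.label_clusters(df, ids, 3) == {1: "low", 2: "middle", 0: "high"}

    def test_tie_breaks_by_index_with_warning(self):
        df = self._frame([0, 1.0, 1.0, 2.0], [100, 500, 500, 500])
        ids = np.array([0, 1, 1, 2])
        df.loc[3, "event_count"] = 1.0  # clusters 1 and 2 tied on both criteria
        df.loc[3, "general_energy_jkg"] = 500
        with pytest.warns(UserWarning, match="tie"):
            labels = cl.label_clusters(df, ids, 3)
        assert labels == {0: "low", 1: "middle", 2: "high"}

    def test_non_three_k_warns_ordinal(self):
        df = self._frame([0, 1, 2, 3], [1, 2, 3, 4])
        ids = np.array([0, 1, 2, 3])
        with pytest.warns(UserWarning, match="ordinal"):
            labels = cl.label_clusters(df, ids, 4)
        assert labels == {0: "zone_0", 1: "zone_1", 2: "zone_2", 3: "zone_3"}


class TestAssignAndModel:
    def test_training_rows_get_training_labels(self, small_model, small_table):
        out = cl.assign(small_model, small_table)
        train, _ = cl.exclude_low_distance(small_table)
        Z = small_model.scale(train[FEATURE_ORDER].to_numpy(float))
        P = small_model.project(Z)
        d2 = ((P[:, None, :] - small_model.kmeans_centroids[None]) ** 2).sum(axis=2)
        expect = [small_model.label_map[int(c)] for c in d2.argmin(axis=1)]
        assert out.loc[train.index, "label"].tolist() == expect

    def test_halftime_unclassified(self, small_model, small_table):
        out = cl.assign(small_model, small_table)
        merged = out.join(small_table[["excluded"]])
        assert (merged.loc[merged.excluded, "label"] == cl.UNCLASSIFIED).all()

    def test_schema_mismatch_rejected(self, small_model, small_table):
        with pytest.raises(cl.ClusteringError, match="event_count"):
            cl.assign(small_model, small_table.drop(columns=["event_count"]))

    def test_model_json_round_trip(self, small_model, tmp_path):
        p = tmp_path / "model.json"
        small_model.to_json(p)
        back = cl.IntensityModel.from_json(p)
        assert back.label_map == small_model.label_map
        assert np.allclose(back.kmeans_centroids, small_model.kmeans_centroids)
        assert np.allclose(back.pca_components, small_model.pca_components)
        assert back.training_meta == small_model.training_meta

    def test_end_to_end_determinism(self, small_table, tmp_path):
        m1 = cl.fit_intensity_model(small_table, seed=17, n_init=5)
        m2 = cl.fit_intensity_model(small_table, seed=17, n_init=5)
        m1.to_json(tmp_path / "a.json")
        m2.to_json(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_explained_variance_bounded(self, small_model):
        assert small_model.explained_variance_ratio.sum() <= 1.0 + 1e-9
        assert small_model.n_components == len(small_model.explained_variance_ratio)

    def test_label_map_bijective_when_k3(self, small_model):
        if small_model.k == 3:
            assert sorted(small_model.label_map.values()) == ["high", "low", "middle"]
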