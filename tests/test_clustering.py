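"""PCA reduction, gap-statistic model selection, MI nomination, assignment."""

import numpy as np
import pandas as pd
import pytest

import liqrad as lq
from liqrad.containers import FeatureMatrix
from liqrad import phenotyping as P
from liqrad._kmeans import kmeans_fit
from tests.conftest import make_mixture


class TestFitPca:
    def test_rank_two_data_needs_two_components(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        X = rng.normal(size=(200, 2)) @ basis
        pca = lq.fit_pca(X, 0.99)
        assert pca.n_components == 2
        assert np.cumsum(pca.explained_variance_ratio)[-1] > 0.999

    def test_isotropic_gaussian_keeps_all_dims(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10000, 5))
        pca = lq.fit_pca(X, 0.99)
        assert pca.n_components == 5
        assert np.allclose(pca.explained_variance_ratio, 0.2, atol=0.02)

    def test_threshold_one_keeps_everything_and_bad_threshold_raises(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        assert lq.fit_pca(X, 1.0).n_components == 4
        with pytest.raises(ValueError):
            lq.fit_pca(X, 0.0)

    def test_components_orthonormal(self):
        rng = np.random.default_rng(3)
        pca = lq.fit_pca(rng.normal(size=(100, 6)), 0.99)
        gram = pca.components @ pca.components.T
        np.testing.assert_allclose(gram, np.eye(pca.n_components), atol=1e-10)


class TestKmeansCore:
    def test_matches_sklearn_on_separable_data(self):
        """Independent cross-check of the compiled Lloyd core."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(m, 0.3, size=(60, 4)) for m in (0.0, 5.0, 10.0)])
        ours = kmeans_fit(X, 3, rng=0)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert ours.inertia == pytest.approx(ref.inertia_, rel=1e-6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 3))
        a = kmeans_fit(X, 4, rng=7)
        b = kmeans_fit(X, 4, rng=7)
        assert np.array_equal(a.centroids, b.centroids)


class TestComputeGap:
    def test_null_data_gap_near_zero(self):
        """Gap on draws from its own reference distribution centers on 0."""
        rng = np.random.default_rng(6)
        gaps = []
        for rep in range(20):
            X = rng.uniform(0, 1, size=(120, 3))
            gap, s = lq.compute_gap(X, 3, B=10, rng=rep)
            gaps.append(gap)
        assert abs(np.mean(gaps)) < 3 * np.std(gaps) / np.sqrt(len(gaps)) + 0.05

    def test_duplicating_points_shifts_gap_by_constant(self):
        """log W_k - log n is duplication-invariant, so Gap moves by an
        additive constant that does not reorder k."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 2))
        X2 = np.vstack([X, X])
        deltas = []
        for k in (2, 3, 4):
            g1, _ = lq.compute_gap(X, k, B=30, rng=0)
            g2, _ = lq.compute_gap(X2, k, B=30, rng=0)
            deltas.append(g2 - g1)
        assert np.std(deltas) < 0.25  # constant up to Monte-Carlo noise

    def test_k_near_n_drives_w_to_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 2))
        w2 = min(kmeans_fit(X, 2, rng=r).inertia for r in range(5))
        w11 = min(kmeans_fit(X, 11, rng=r).inertia for r in range(5))
        # only the closest pair shares a centroid: W collapses toward 0
        assert w11 < 0.05 * w2

    def test_k_out_of_range_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            lq.compute_gap(X, 5, B=2, rng=0)


class TestSelectK:
    def test_two_point_masses_give_k2(self):
        X = np.vstack([np.zeros((40, 2)), np.full((40, 2), 10.0)])
        X += np.random.default_rng(9).normal(0, 1e-3, X.shape)
        res = lq.select_k(X, (2, 6), B=10, seed=0)
        assert res.selected_k == 2

    def test_three_separated_gaussians(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            X = np.vstack(
                [rng.normal(m, 1.0, size=(100, 3)) for m in (0.0, 10.0, 20.0)]
            )
            if lq.select_k(X, (2, 8), B=10, seed=rep).selected_k == 3:
                hits += 1
        assert hits >= 19

    def test_structureless_data_selects_small_k(self):
        small = 0
        for rep in range(20):
            X = np.random.default_rng(200 + rep).uniform(size=(150, 4))
            if lq.select_k(X, (2, 8), B=10, seed=rep).selected_k <= 4:
                small += 1
        assert small >= 18

    def test_range_truncated_for_tiny_n(self):
        X = np.random.default_rng(10).normal(size=(8, 2))
        res = lq.select_k(X, (2, 50), B=3, seed=0)
        assert max(res.ks) <= 7


class TestNominateK:
    def test_deterministic_data_unanimous(self):
        morpho, _ = make_mixture(k_true=3, seed=5)
        std, _ = P.standardize_features(morpho)
        Z = lq.fit_pca(std.values()).transform(std.values())
        nom = lq.nominate_k(Z, iterations=8, k_range=(2, 8), B=10, seed=0)
        assert nom.nominated_k == 3
        assert nom.histogram == {3: 8}

    def test_single_iteration_equals_select_k(self):
        X = np.random.default_rng(11).uniform(size=(100, 3))
        nom = lq.nominate_k(X, iterations=1, k_range=(2, 5), B=5, seed=42)
        assert nom.nominated_k == lq.select_k(X, (2, 5), B=5, seed=42).selected_k
        assert nom.iterations == 1


class TestFitFinalModel:
    def test_single_candidate_returned_and_deterministic(self):
        X = np.random.default_rng(12).normal(size=(80, 3))
        m1 = lq.fit_final_model(X, 3, n_candidates=1, seed=3)
        m2 = lq.fit_final_model(X, 3, n_candidates=1, seed=3)
        assert np.array_equal(m1.centroids, m2.centroids)

    def test_best_candidate_reaches_global_optimum_on_separable_data(self):
        """Highest gap score == lowest within-cluster SS; on well-separated
        data that optimum is found independently by many-restart sklearn."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(13)
        X = np.vstack([rng.normal(m, 1.0, size=(50, 4)) for m in (0, 8, 16, 24)])
        model = lq.fit_final_model(X, 4, n_candidates=20, seed=5)
        d = ((X[:, None] - model.centroids[None]) ** 2).sum(-1).min(1).sum()
        ref = KMeans(n_clusters=4, n_init=50, random_state=0).fit(X).inertia_
        assert d == pytest.approx(ref, rel=1e-6)

    def test_model_json_roundtrip(self, tmp_path):
        X = np.random.default_rng(14).normal(size=(60, 3))
        model = lq.fit_final_model(X, 2, n_candidates=3, seed=1)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = lq.ClusterModel.from_json(path)
        assert back.k == model.k
        np.testing.assert_allclose(back.centroids, model.centroids)
        assert back.approach == model.approach


class TestPairwiseMi:
    def test_identical_vectors_give_log_bins(self):
        x = np.random.default_rng(15).normal(size=1000)
        assert lq.pairwise_mi(x, x, n_bins=10) == pytest.approx(np.log(10), abs=1e-9)

    def test_independent_uniforms_near_zero(self):
        rng = np.random.default_rng(16)
        mi = lq.pairwise_mi(rng.uniform(size=10000), rng.uniform(size=10000))
        assert 0 <= mi <= 0.05

    def test_symmetry_and_constant_convention(self):
        rng = np.random.default_rng(17)
        x, y = rng.normal(size=500), rng.normal(size=500)
        assert lq.pairwise_mi(x, y) == pytest.approx(lq.pairwise_mi(y, x), abs=1e-12)
        assert lq.pairwise_mi(x, np.ones(500)) == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            lq.pairwise_mi(np.arange(10.0), np.arange(10.0), n_bins=10)


class TestNominateFeatures:
    def test_independent_feature_beats_redundant_pair(self):
        """Category {A, B = A + tiny noise, C independent} nominates C."""
        wins = 0
        for rep in range(50):
            rng = np.random.default_rng(300 + rep)
            a = rng.normal(size=400)
            b = a + rng.normal(0, 0.05, size=400)
            c = rng.normal(size=400)
            data = pd.DataFrame({"a": a, "b": b, "c": c})
            m = FeatureMatrix(
                data=data,
                categories={"a": "cat", "b": "cat", "c": "cat"},
                patient_ids=pd.Series(["p"] * 400, index=data.index),
            )
            names, _ = lq.nominate_features(m)
            wins += names == ["c"]
        assert wins >= 45

    def test_singleton_categories_identity_and_count(self):
        rng = np.random.default_rng(18)
        names = [f"f{i}" for i in range(11)]
        data = pd.DataFrame(rng.normal(size=(100, 11)), columns=names)
        m = FeatureMatrix(
            data=data,
            categories={n: f"cat{i}" for i, n in enumerate(names)},
            patient_ids=pd.Series(["p"] * 100, index=data.index),
        )
        nominated, table = lq.nominate_features(m)
        assert sorted(nominated) == sorted(names)
        assert len(nominated) == 11


class TestAssignClusters:
    def test_training_set_reproduces_training_labels(self):
        morpho, _ = make_mixture(k_true=3, seed=6)
        std, params = P.standardize_features(morpho)
        pca = lq.fit_pca(std.values())
        Z = pca.transform(std.values())
        model = lq.fit_final_model(
            Z, 3, n_candidates=5, seed=2, standardization=params, pca=pca
        )
        train_labels = lq.assign_clusters(model, morpho)
        d = ((Z[:, None] - model.centroids[None]) ** 2).sum(-1)
        assert np.array_equal(train_labels.to_numpy(), d.argmin(1))

    def test_point_at_centroid_gets_that_cluster(self):
        model = lq.ClusterModel(
            approach="pca_kmeans", k=2,
            centroids=np.array([[0.0, 0.0], [5.0, 5.0]]), gap_score=0.0,
        )
        data = pd.DataFrame([[5.0, 5.0]], columns=["x", "y"])
        m = FeatureMatrix(data=data, categories={"x": "c", "y": "c"},
                          patient_ids=pd.Series(["p"], index=data.index))
        assert lq.assign_clusters(model, m).iloc[0] == 1

    def test_heldout_assignment_recovers_truth(self):
        spec = lq.ClusterSpec(k_true=3, n_features=20, separation=10.0, seed=2007)
        cohort_tr = lq.generate_cohort(
            lq.CohortConfig(n_patients=6, zero_inflation=0.0, seed=1007)
        ).assign(rarecyte_count=100)
        cohort_te = lq.generate_cohort(
            lq.CohortConfig(n_patients=6, zero_inflation=0.0, seed=1008)
        ).assign(rarecyte_count=100)
        # identical mixture (same spec seed draws the same means), new cells
        train_m, _ = lq.generate_ctc_features(cohort_tr, spec)
        test_m, test_truth = lq.generate_ctc_features(cohort_te, spec)
        keep = [c for c in train_m.data.columns if not c.startswith("mfi_")]
        train = train_m.select_features(keep)
        test = test_m.select_features(keep)
        std, params = P.standardize_features(train)
        pca = lq.fit_pca(std.values())
        model = lq.fit_final_model(
            pca.transform(std.values()), 3, n_candidates=10, seed=3,
            standardization=params, pca=pca,
        )
        labels = lq.assign_clusters(model, test)
        # same generative mixture => labels must agree with truth up to renaming
        tab = pd.crosstab(labels, test_truth)
        assert tab.max(axis=0).sum() / len(labels) >= 0.95

    def test_feature_order_permutation_invariance(self):
        morpho, _ = make_mixture(k_true=2, seed=8)
        std, params = P.standardize_features(morpho)
        pca = lq.fit_pca(std.values())
        model = lq.fit_final_model(
            pca.transform(std.values()), 2, n_candidates=3, seed=4,
            standardization=params, pca=pca,
        )
        shuffled = morpho.select_features(list(reversed(morpho.feature_names)))
        a = lq.assign_clusters(model, morpho)
        b = lq.assign_clusters(model, shuffled)
        assert np.array_equal(a.to_numpy(), b.to_numpy())


class TestAlternativeEstimatorsAndRules:
    def test_knn_mi_estimator_agrees_qualitatively(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=600)
        dep = lq.pairwise_mi(x, x + rng.normal(0, 0.2, 600), estimator="knn")
        indep = lq.pairwise_mi(x, rng.normal(size=600), estimator="knn")
        assert dep > 1.0 > indep
        with pytest.raises(ValueError):
            lq.pairwise_mi(x, x, estimator="magic")

    def test_argmax_rule_computes_full_profile(self):
        X = np.vstack([np.zeros((40, 2)), np.full((40, 2), 10.0)])
        X += np.random.default_rng(20).normal(0, 1e-3, X.shape)
        res = lq.select_k(X, (2, 6), B=5, seed=0, rule="argmax")
        assert res.ks == [2, 3, 4, 5, 6]
        assert res.selected_k == 2  # gap is maximal at the true k
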