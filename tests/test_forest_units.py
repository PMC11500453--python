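import numpy as np
import pytest
from scipy.stats import kruskal
from sklearn.datasets import make_blobs
from sklearn.metrics import roc_auc_score

from microhdf.forest_units import (
    bray_curtis,
    build_balanced_sets,
    cluster_majority,
    erts_proba,
    fit_erts,
    fit_rf_cus,
    kruskal_pvalues,
    lda_effect_scores,
    rank_features,
    rf_cus_proba,
    sequential_forward_select,
)

from conftest import fast_forest


def _bray_curtis_formula(a, b):
    """Independent hand evaluation of BC = 1 - 2*sum(min)/(sum(a)+sum(b))."""
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * np.minimum(a, b).sum() / denom


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        X = np.array([[0.2, 0.8], [0.2, 0.8]])
        D = bray_curtis(X)
        np.testing.assert_allclose(D, 0.0, atol=1e-12)

    def test_disjoint_supports_one(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert bray_curtis(X)[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        X = np.array([[0.2, 0.8], [0.8, 0.2]])
        assert bray_curtis(X)[0, 1] == pytest.approx(0.6)

    def test_matches_formula_on_random_profiles(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(12, 7)) * (rng.random((12, 7)) > 0.3)
        D = bray_curtis(X)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
        assert D.min() >= 0 and D.max() <= 1
        for i in range(12):
            for j in range(12):
                assert D[i, j] == pytest.approx(
                    _bray_curtis_formula(X[i], X[j]), abs=1e-12
                )

    def test_all_zero_pair_warns_and_is_zero(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            D = bray_curtis(X)
        assert D[0, 1] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[-1.0, 2.0]]))


class TestClusterMajority:
    def test_three_blobs_recovered(self):
        X, blob = make_blobs(
            n_samples=30, centers=3, cluster_std=0.3, random_state=4
        )
        X = np.abs(X)  # Bray–Curtis needs non-negative data
        cfg = fast_forest()
        assignment = cluster_majority(bray_curtis(X), cfg, X=X)
        assert assignment.n_clusters >= 2
        # clustering agrees with the generating blobs up to relabeling:
        # samples of one blob never straddle >1 cluster for >10% of points
        from scipy.stats import mode

        mismatch = 0
        for b in np.unique(blob):
            labels_in_blob = assignment.labels[blob == b]
            majority = mode(labels_in_blob, keepdims=False).mode
            mismatch += np.sum(labels_in_blob != majority)
        assert mismatch <= 3

    def test_single_sample_single_cluster(self):
        cfg = fast_forest()
        a = cluster_majority(np.zeros((1, 1)), cfg, X=np.ones((1, 2)))
        assert a.n_clusters == 1 and a.method == "single"

    def test_nonconvergence_triggers_kmeans_fallback(self):
        X = np.abs(np.random.default_rng(0).normal(size=(20, 4)))
        cfg = fast_forest(ap_max_iter=1)
        a = cluster_majority(bray_curtis(X), cfg, X=X)
        assert a.method == "kmeans_fallback"


class TestBuildBalancedSets:
    def _data(self, n_maj=85, n_min=25, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, size=(n_maj + n_min, 10))
        y = np.array([0] * n_maj + [1] * n_min)
        return X, y

    def test_exact_balance_85_25(self):
        X, y = self._data()
        cfg = fast_forest(n_subsets=10)
        rng = np.random.default_rng(1)
        clusters = cluster_majority(bray_curtis(X[y == 0]), cfg, X=X[y == 0], rng=rng)
        sets = build_balanced_sets(X, y, clusters, cfg, rng)
        assert len(sets) == 10
        for s in sets:
            assert len(s.majority_idx) == 34  # round(0.4 * 85)
            assert len(s.minority_idx) == 34
            assert np.all(y[s.majority_idx] == 0)
            assert np.all(y[s.minority_idx] == 1)
            assert len(np.unique(s.majority_idx)) == 34  # without replacement

    def test_full_ratio_is_permutation(self):
        X, y = self._data(n_maj=20, n_min=20)
        cfg = fast_forest(undersampling_ratio=1.0, n_subsets=3)
        rng = np.random.default_rng(2)
        clusters = cluster_majority(bray_curtis(X[y == 0]), cfg, X=X[y == 0], rng=rng)
        sets = build_balanced_sets(X, y, clusters, cfg, rng)
        for s in sets:
            assert sorted(s.majority_idx) == list(range(20))

    def test_every_cluster_represented(self):
        X, y = self._data()
        cfg = fast_forest(n_subsets=5)
        rng = np.random.default_rng(3)
        clusters = cluster_majority(bray_curtis(X[y == 0]), cfg, X=X[y == 0], rng=rng)
        m = round(0.4 * 85)
        if m >= clusters.n_clusters:
            maj = np.nonzero(y == 0)[0]
            pos = {int(s): i for i, s in enumerate(maj)}
            for s in build_balanced_sets(X, y, clusters, cfg, rng):
                picked_clusters = {
                    clusters.labels[pos[int(i)]] for i in s.majority_idx
                }
                assert picked_clusters == set(np.unique(clusters.labels))

    def test_zero_subset_errors(self):
        X, y = self._data(n_maj=1, n_min=1)
        cfg = fast_forest(undersampling_ratio=0.1)
        rng = np.random.default_rng(0)
        clusters = cluster_majority(np.zeros((1, 1)), cfg, X=X[:1], rng=rng)
        with pytest.raises(ValueError, match="too small"):
            build_balanced_sets(X, y, clusters, cfg, rng)


class TestRFCUS:
    def test_separable_training_auc(self, separable_data):
        X, y = separable_data
        unit = fit_rf_cus(X, y, fast_forest())
        p = rf_cus_proba(unit, X)
        assert roc_auc_score(y, p[:, 1]) == 1.0

    def test_proba_rows_sum_to_one(self, separable_data):
        X, y = separable_data
        unit = fit_rf_cus(X, y, fast_forest())
        p = rf_cus_proba(unit, X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).uniform(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_rf_cus(X, np.zeros(10, dtype=int), fast_forest())


class TestLDAEffectScores:
    def test_kruskal_matches_scipy(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(30, 8))
        X[:, 2] = np.round(X[:, 2], 1)  # introduce ties
        y = np.array([0] * 15 + [1] * 15)
        mine = kruskal_pvalues(X, y)
        for j in range(8):
            ref = kruskal(X[y == 0, j], X[y == 1, j]).pvalue
            assert mine[j] == pytest.approx(ref, rel=1e-9)

    def test_identical_feature_scores_zero(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.1, 1, size=(40, 3))
        X[:, 1] = 0.5  # constant
        y = np.array([0] * 20 + [1] * 20)
        X[y == 1, 0] *= 10
        scores = lda_effect_scores(X, y)
        assert scores[1] == 0.0

    def test_shifted_feature_ranks_first(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0.1, 1, size=(100, 20))
        y = np.array([0] * 50 + [1] * 50)
        X[y == 1, 7] *= 10
        scores = lda_effect_scores(X, y)
        assert rank_features(scores)[0] == 7

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.1, 1, size=(30, 5))
        y = np.array([0] * 15 + [1] * 15)
        X[y == 1, 2] *= 5
        perm = rng.permutation(30)
        np.testing.assert_allclose(
            lda_effect_scores(X, y), lda_effect_scores(X[perm], y[perm]), atol=1e-12
        )


class TestSequentialForwardSelect:
    def test_recovers_informative_features(self):
        """5 planted taxa (mixed up/down fold-changes) among 95 noise taxa."""
        hits = 0
        n_seeds = 6
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = np.array([0] * 50 + [1] * 50)
            X = rng.lognormal(0, 1, size=(100, 100))
            informative = [0, 1, 2, 3, 4]
            for f, e in zip(informative, (3, 1 / 3, 4, 1 / 4, 5)):
                X[y == 1, f] *= e
            X = X / X.sum(axis=1, keepdims=True)
            cfg = fast_forest(seed=seed, sfs_max_candidates=25, sfs_trees=40, sfs_folds=3)
            ranked = rank_features(lda_effect_scores(X, y))
            selected = sequential_forward_select(ranked, X, y, cfg)
            hits += len(set(selected) & set(informative)) >= 4
        assert hits >= n_seeds - 1  # near-unanimous recovery of >= 4 of 5

    def test_single_feature_returned(self):
        X = np.random.default_rng(0).uniform(size=(20, 1))
        y = np.array([0] * 10 + [1] * 10)
        assert sequential_forward_select([0], X, y, fast_forest()) == [0]

    def test_pure_noise_keeps_mostly_seed_feature(self):
        sizes = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.uniform(size=(40, 30))
            y = np.array([0] * 20 + [1] * 20)
            cfg = fast_forest(seed=seed)
            ranked = rank_features(lda_effect_scores(X, y))
            sizes.append(len(sequential_forward_select(ranked, X, y, cfg)))
        assert np.mean(sizes) <= 3  # improvement threshold rarely met on noise


class TestERTs:
    def test_proba_rows_sum_to_one(self, separable_data):
        X, y = separable_data
        unit = fit_erts(X, y, [0, 1], fast_forest())
        p = erts_proba(unit, X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_separable_selected_auc(self, separable_data):
        X, y = separable_data
        unit = fit_erts(X, y, [0], fast_forest())
        p = erts_proba(unit, X)
        assert roc_auc_score(y, p[:, 1]) == 1.0

    def test_out_of_range_selected(self, separable_data):
        X, y = separable_data
        with pytest.raises(IndexError):
            fit_erts(X, y, [99], fast_forest())

    def test_empty_selected(self, separable_data):
        X, y = separable_data
        with pytest.raises(ValueError):
            fit_erts(X, y, [], fast_forest())


class TestImbalanceBenefit:
    def test_rf_cus_minority_recall_vs_plain_rf(self):
        """Class rebalancing should lift minority-class recall (directional)."""
        from sklearn.ensemble import RandomForestClassifier

        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            y = np.array([0] * 80 + [1] * 20)  # IR = 4
            X = rng.lognormal(0, 1, size=(100, 30))
            X[y == 1, :5] *= 2.5  # moderate signal
            X = X / X.sum(axis=1, keepdims=True)
            test = rng.lognormal(0, 1, size=(60, 30))
            y_test = np.array([0] * 40 + [1] * 20)
            test[y_test == 1, :5] *= 2.5
            test = test / test.sum(axis=1, keepdims=True)
            unit = fit_rf_cus(X, y, fast_forest(seed=seed, n_subsets=5))
            rec_cus = np.mean(rf_cus_proba(unit, test)[y_test == 1, 1] > 0.5)
            rf = RandomForestClassifier(n_estimators=100, random_state=seed).fit(X, y)
            rec_rf = np.mean(rf.predict_proba(test)[y_test == 1, 1] > 0.5)
            wins += rec_cus >= rec_rf
        assert wins >= 4
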