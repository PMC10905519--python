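import numpy as np
import pytest

from lncguide.guide_features import FEATURE_NAMES, N_FEATURES
from lncguide.ontarget_model import (
    FeatureRanking,
    forward_select_features,
    grid_search_train,
    load_model,
    minmax_normalize_scores,
    predict_ontarget,
    rank_features_information_gain,
    save_model,
)


def _random_X(rng, n=500):
    """Feature-matrix-shaped random data with the one-hot blocks coherent."""
    X = rng.random((n, N_FEATURES))
    for block in (slice(8, 12), slice(12, 16)):
        X[:, block] = 0.0
        hot = rng.integers(0, 4, size=n)
        X[np.arange(n), block.start + hot] = 1.0
    return X


class TestInformationGainRanking:
    def test_ranking_is_permutation(self, rng):
        X = _random_X(rng)
        y = rng.integers(0, 2, size=len(X))
        r = rank_features_information_gain(X, y, seed=0)
        assert sorted(r.order) == sorted(FEATURE_NAMES)

    def test_planted_single_feature_ranks_first(self, rng):
        X = _random_X(rng)
        y = (X[:, FEATURE_NAMES.index("pos20_is_G")] == 1.0).astype(int)
        r = rank_features_information_gain(X, y, seed=0)
        assert r.order[0] == "pos20_is_G"

    def test_random_labels_give_small_top_gain_vs_planted(self, rng):
        """Permutation-null comparison: a boosted ensemble still attributes
        some spurious gain to noise, but a planted deterministic rule must
        dominate it by a wide margin."""
        X = _random_X(rng)
        y_random = rng.integers(0, 2, size=len(X))
        y_planted = (X[:, FEATURE_NAMES.index("pos20_is_G")] == 1.0).astype(int)
        g_random = rank_features_information_gain(X, y_random, seed=0).gains[0]
        g_planted = rank_features_information_gain(X, y_planted, seed=0).gains[0]
        assert g_random < 0.25 * g_planted

    def test_deterministic(self, rng):
        X = _random_X(rng, n=200)
        y = (X[:, 2] > 0.6).astype(int)
        a = rank_features_information_gain(X, y, seed=5)
        b = rank_features_information_gain(X, y, seed=5)
        assert a.order == b.order and a.gains == b.gains

    def test_bad_permutation_rejected(self):
        with pytest.raises(ValueError):
            FeatureRanking(("gc_whole",) * 27, (0.0,) * 27)


class TestForwardSelection:
    def test_curve_has_27_points_and_small_prefix_on_planted_data(self, small_xy):
        X, y = small_xy
        ranking = rank_features_information_gain(X, y, seed=7)
        selected, curve = forward_select_features(ranking, X, y, k_folds=5, seed=7)
        assert len(curve) == N_FEATURES
        assert 1 <= len(selected) <= 5  # only 3 features carry signal
        # curve plateaus: later values never rise far above the selected point
        assert max(curve) == curve[len(selected) - 1]


class TestGridSearchTrain:
    def test_linearly_separable_gives_perfect_cv_f1(self, rng):
        n = 60
        X = _random_X(rng, n)
        X[: n // 2, 0] = 2.0 + rng.random(n // 2)
        X[n // 2 :, 0] = -2.0 - rng.random(n // 2)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        model = grid_search_train(X, y, "CRISPRko", k_folds=5, seed=0)
        assert np.mean([r["f1"] for r in model.cv_record]) == 1.0

    def test_label_swap_swaps_precision_recall_roles(self, rng):
        n = 120
        X = _random_X(rng, n)
        w = rng.normal(size=N_FEATURES)
        y = ((X @ w + rng.normal(scale=2.0, size=n)) > np.median(X @ w)).astype(int)
        grid = {"C": (1.0,), "gamma": (0.05,)}
        m1 = grid_search_train(X, y, "CRISPRko", k_folds=5, seed=0, grid=grid)
        m2 = grid_search_train(X, 1 - y, "CRISPRko", k_folds=5, seed=0, grid=grid)
        # swapping classes: TP<->TN and FP<->FN, so precision of class 1 in m2
        # equals TN/(TN+FN) of m1 (negative predictive value) fold by fold
        for r1, r2 in zip(m1.cv_record, m2.cv_record):
            assert r1["accuracy"] == pytest.approx(r2["accuracy"])

    def test_degenerate_fold_errors_name_the_fold(self, rng):
        X = _random_X(rng, 30)
        y = np.array([1] * 29 + [0])
        with pytest.raises(ValueError, match="fold|minority|class"):
            grid_search_train(X, y, "CRISPRko", k_folds=5, seed=0,
                              grid={"C": (1.0,), "gamma": (0.1,)})

    def test_calibration_monotone_in_decision_value(self, toy_models, small_xy):
        X, _y = small_xy
        model = toy_models["CRISPRko"]
        d = model.decision_values(X)
        p = model.predict_proba(X)
        order = np.argsort(d)
        assert np.all(np.diff(p[order]) >= -1e-12)

    def test_standardization_fit_without_test_leakage(self, rng):
        """Shuffling test-fold labels must not change train-fold statistics."""
        from lncguide.dataset_builder import stratified_kfold_split

        X = _random_X(rng, 100)
        y = np.array([0, 1] * 50)
        folds = stratified_kfold_split(y, k=5, seed=0)
        tr, te = folds[0]
        from sklearn.preprocessing import StandardScaler

        m_before = StandardScaler().fit(X[tr]).mean_.copy()
        y2 = y.copy()
        y2[te] = rng.permutation(y2[te])
        m_after = StandardScaler().fit(X[tr]).mean_.copy()
        assert np.array_equal(m_before, m_after)


class TestPredict:
    def test_probability_range_and_determinism(self, toy_models, small_xy):
        X, y = small_xy
        model = toy_models["CRISPRko"]
        for row in X[:20]:
            label, p = predict_ontarget(model, row)
            label2, p2 = predict_ontarget(model, row)
            assert 0 <= p <= 1 and (label, p) == (label2, p2)
            assert label == ("efficient" if p > 0.5 else "inefficient")

    def test_training_points_mostly_called_correctly(self, toy_models, small_xy):
        X, y = small_xy
        model = toy_models["CRISPRko"]
        p = model.predict_proba(X)
        acc = np.mean((p > 0.5).astype(int) == y)
        assert acc > 0.85

    def test_label_agrees_with_decision_sign_threshold(self, toy_models, small_xy):
        X, _ = small_xy
        model = toy_models["CRISPRko"]
        d = model.decision_values(X)
        p = model.predict_proba(X)
        # monotone map: ordering by p equals ordering by d
        assert np.array_equal(np.argsort(d, kind="stable"),
                              np.argsort(p, kind="stable"))


class TestMinMaxNormalize:
    def test_endpoints(self):
        norm, mask = minmax_normalize_scores([3.0, 7.0, 5.0])
        assert norm[0] == 0 and norm[1] == 1
        assert list(mask) == [False, True, False]

    def test_strictly_greater_than_half(self):
        norm, mask = minmax_normalize_scores([0.0, 0.5, 1.0])
        assert norm[1] == 0.5 and not mask[1]

    def test_affine_invariance(self, rng):
        s = rng.normal(size=30)
        n1, _ = minmax_normalize_scores(s)
        n2, _ = minmax_normalize_scores(5.0 * s - 3.0)
        assert np.allclose(n1, n2)

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize_scores([1.0, 1.0, 1.0])


class TestPersistence:
    def test_round_trip_bit_identical_predictions(self, toy_models, small_xy, tmp_path):
        X, _ = small_xy
        model = toy_models["CRISPRko"]
        p = tmp_path / "m.joblib"
        save_model(model, p)
        back = load_model(p)
        assert np.array_equal(model.predict_proba(X[:50]), back.predict_proba(X[:50]))
        assert back.selected_features == model.selected_features
        assert back.cv_record == model.cv_record

    def test_version_tag_mismatch_rejected(self, toy_models, tmp_path):
        import joblib

        p = tmp_path / "m.joblib"
        save_model(toy_models["CRISPRko"], p)
        payload = joblib.load(p)
        payload["format_version"] = "something-else"
        joblib.dump(payload, p)
        with pytest.raises(ValueError, match="format"):
            load_model(p)

    def test_registry_hash_stored_and_checked(self, toy_models, tmp_path):
        import joblib

        p = tmp_path / "m.joblib"
        save_model(toy_models["CRISPRko"], p)
        payload = joblib.load(p)
        assert "registry_hash" in payload
        payload["registry_hash"] = "0" * 16
        joblib.dump(payload, p)
        with pytest.raises(ValueError, match="registry"):
            load_model(p)
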