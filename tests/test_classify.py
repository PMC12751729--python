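"""Tests of the boosted-stump classifier, oversampling, selection and CV."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scdeeg.boost import StumpBoost
from scdeeg.classify import (
    FeatureTable,
    borderline_smote,
    build_feature_table,
    classification_metrics,
    cv_evaluate,
    eeg_feature_names,
    permutation_pvalue,
    sfs_select,
    shap_summary,
)


def separable_table(n_pos=24, n_neg=82, n_noise=8, gap=3.0, seed=0):
    """One strongly separating feature plus pure-noise features."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [0] * n_neg)
    X = rng.standard_normal((n, n_noise + 1))
    X[:, 0] += gap * y
    names = ["signal"] + [f"noise{i}" for i in range(n_noise)]
    return FeatureTable([f"s{i}" for i in range(n)], names, X, y)


def noise_table(n_pos=24, n_neg=82, n_feat=10, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [0] * n_neg)
    return FeatureTable(
        [f"s{i}" for i in range(n)],
        [f"f{i}" for i in range(n_feat)],
        rng.standard_normal((n, n_feat)),
        y,
    )


class TestStumpBoost:
    def test_separable_data_fit_perfectly(self):
        t = separable_table(gap=6.0)
        clf = StumpBoost().fit(t.X, t.y)
        assert np.array_equal(clf.predict(t.X), t.y)

    def test_single_stump_threshold_placement(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        clf = StumpBoost().fit(X, y)
        assert np.array_equal(clf.predict(X), y)
        # perfect stump cuts between 1 and 2
        assert clf.thresholds_[0] == pytest.approx(1.5)

    def test_inverted_polarity_learned(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1, 1, 0, 0])  # positive class on the LOW side
        clf = StumpBoost().fit(X, y)
        assert np.array_equal(clf.predict(X), y)

    def test_degenerate_constant_features(self):
        X = np.ones((8, 3))
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1])
        clf = StumpBoost().fit(X, y)
        # majority vote: all predictions are the majority class
        assert np.all(clf.predict(X) == 0)

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            StumpBoost().fit(np.zeros((4, 1)), np.array([0, 1, 2, 1]))

    def test_feature_count_mismatch_rejected(self):
        t = separable_table()
        clf = StumpBoost().fit(t.X, t.y)
        with pytest.raises(ValueError, match="features"):
            clf.predict(t.X[:, :3])

    def test_agrees_with_sklearn_adaboost(self):
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 6))
        y = (X[:, 0] + 0.6 * X[:, 1] + 0.4 * rng.standard_normal(120) > 0).astype(int)
        ours = StumpBoost().fit(X, y)
        ref = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=50,
            learning_rate=1.0,
            random_state=0,
        ).fit(X, y)
        # identical model family; tie-breaking in the stump search may differ,
        # so require high (not perfect) agreement on fresh data
        Xnew = rng.standard_normal((500, 6))
        agree = np.mean(ours.predict(Xnew) == ref.predict(Xnew))
        assert agree > 0.9

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_property_margin_bounded(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((30, 3))
        y = (rng.random(30) > 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        clf = StumpBoost().fit(X, y)
        m = clf.decision_function(X)
        assert np.all(np.abs(m) <= 1.0 + 1e-12)


class TestMetrics:
    def test_hand_computed_example(self):
        """tp=3, fn=1, tn=7, fp=1: acc 10/12, sens 0.75, spec 0.875."""
        m = classification_metrics(tp=3, fp=1, tn=7, fn=1)
        assert m["accuracy"] == pytest.approx(10 / 12)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(0.875)
        assert m["f1"] == pytest.approx(6 / 8)
        mcc = (3 * 7 - 1 * 1) / np.sqrt(4 * 4 * 8 * 8)
        assert m["mcc"] == pytest.approx(mcc)

    def test_matches_sklearn(self):
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            matthews_corrcoef,
            recall_score,
        )

        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0])
        tp = int(np.sum((y_pred == 1) & (y_true == 1)))
        fp = int(np.sum((y_pred == 1) & (y_true == 0)))
        tn = int(np.sum((y_pred == 0) & (y_true == 0)))
        fn = int(np.sum((y_pred == 0) & (y_true == 1)))
        m = classification_metrics(tp, fp, tn, fn)
        assert m["accuracy"] == pytest.approx(accuracy_score(y_true, y_pred))
        assert m["sensitivity"] == pytest.approx(recall_score(y_true, y_pred))
        assert m["mcc"] == pytest.approx(matthews_corrcoef(y_true, y_pred))
        assert m["f1"] == pytest.approx(f1_score(y_true, y_pred))

    def test_empty_marginals(self):
        m = classification_metrics(tp=0, fp=0, tn=5, fn=0)
        assert np.isnan(m["sensitivity"])
        assert m["mcc"] == 0.0
        with pytest.raises(ValueError):
            classification_metrics(0, 0, 0, 0)


class TestBorderlineSmote:
    def test_balances_classes(self):
        t = separable_table(gap=1.0, seed=2)
        Xs, ys = borderline_smote(t.X, t.y, seed=0)
        counts = np.bincount(ys)
        assert counts[0] == counts[1] == 82

    def test_originals_preserved_as_prefix(self):
        t = separable_table(gap=1.0, seed=2)
        Xs, ys = borderline_smote(t.X, t.y, seed=0)
        np.testing.assert_array_equal(Xs[: t.X.shape[0]], t.X)
        np.testing.assert_array_equal(ys[: t.y.size], t.y)

    def test_synthetic_points_within_minority_hull(self):
        """Convex combinations of minority points stay in their bounding box."""
        t = separable_table(gap=1.0, seed=3)
        Xs, ys = borderline_smote(t.X, t.y, seed=1)
        Xmin = t.X[t.y == 1]
        syn = Xs[t.X.shape[0]:]
        lo, hi = Xmin.min(axis=0), Xmin.max(axis=0)
        assert np.all(syn >= lo - 1e-9) and np.all(syn <= hi + 1e-9)

    def test_deterministic_given_seed(self):
        t = separable_table(gap=1.0, seed=2)
        a, _ = borderline_smote(t.X, t.y, seed=5)
        b, _ = borderline_smote(t.X, t.y, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_balanced_input_is_noop(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([0, 1] * 10)
        Xs, ys = borderline_smote(X, y)
        np.testing.assert_array_equal(Xs, X)

    def test_tiny_minority_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([1] * 4 + [0] * 16)
        with pytest.raises(ValueError, match="at least"):
            borderline_smote(X, y, k_neighbors=5)

    def test_empty_danger_set_warns_and_noop(self, rng):
        # minority cluster far from the majority: all points are "safe"
        X = np.vstack([rng.standard_normal((10, 2)) + 100.0,
                       rng.standard_normal((30, 2))])
        y = np.array([1] * 10 + [0] * 30)
        with pytest.warns(UserWarning, match="danger"):
            Xs, ys = borderline_smote(X, y, seed=0)
        assert Xs.shape == X.shape


class TestSFS:
    def test_planted_signal_feature_selected_first(self):
        t = separable_table(gap=4.0, seed=1)
        feats = sfs_select(t, max_features=3, seed=0)
        assert feats[0] == "signal"

    def test_prescreen_reduces_candidates_but_keeps_signal(self):
        t = separable_table(gap=4.0, n_noise=30, seed=1)
        feats = sfs_select(t, max_features=2, seed=0, prescreen=5)
        assert "signal" in feats

    def test_max_features_respected(self):
        t = separable_table(seed=2)
        feats = sfs_select(t, max_features=2, seed=0)
        assert 1 <= len(feats) <= 2

    def test_invalid_max_features(self):
        with pytest.raises(ValueError):
            sfs_select(separable_table(), max_features=0)


class TestCVEvaluate:
    def test_separable_data_high_accuracy(self):
        t = separable_table(gap=5.0, seed=4)
        res = cv_evaluate(t, features=["signal"], seed=0)
        assert res.pooled_metrics["accuracy"] >= 0.95

    def test_smote_applied_to_training_folds_only(self):
        """Total test predictions equal the cohort size: no synthetic
        samples leak into evaluation."""
        t = separable_table(seed=5)
        res = cv_evaluate(t, seed=0)
        total = sum(sum(c.values()) for c in res.fold_confusions)
        assert total == len(t.subjects)

    def test_deterministic_given_seed(self):
        t = separable_table(seed=6)
        a = cv_evaluate(t, seed=3)
        b = cv_evaluate(t, seed=3)
        assert a.fold_confusions == b.fold_confusions
        assert a.pooled_metrics == b.pooled_metrics

    def test_noise_data_near_chance_mcc(self):
        t = noise_table(seed=7)
        res = cv_evaluate(t, seed=0)
        assert abs(res.pooled_metrics["mcc"]) < 0.35

    def test_nested_selection_runs_per_fold(self):
        t = separable_table(gap=5.0, n_noise=5, seed=15)
        res = cv_evaluate(
            t, seed=0,
            nested_sfs=dict(max_features=2, patience=1, n_folds=5),
        )
        # the strong planted signal is found inside every training fold
        assert res.pooled_metrics["accuracy"] >= 0.9
        total = sum(sum(c.values()) for c in res.fold_confusions)
        assert total == len(t.subjects)

    def test_nested_selection_excludes_fixed_features(self):
        t = separable_table()
        with pytest.raises(ValueError, match="mutually exclusive"):
            cv_evaluate(t, features=["signal"], nested_sfs=dict(max_features=1))

    def test_global_scaling_mode(self):
        t = separable_table(seed=8)
        res = cv_evaluate(t, seed=0, scale="global")
        assert res.pooled_metrics["accuracy"] > 0.8
        with pytest.raises(ValueError):
            cv_evaluate(t, seed=0, scale="bogus")


class TestPermutation:
    def test_pvalue_floor_and_range(self):
        t = separable_table(gap=5.0, seed=9)
        p = permutation_pvalue(t, features=["signal"], B=4, seed=0)
        # smallest achievable p with B=4 is 1/5
        assert p["accuracy"] == pytest.approx(0.2)
        assert all(0 < v <= 1 for v in p.values())

    def test_noise_data_large_pvalue(self):
        t = noise_table(n_feat=3, seed=10)
        p = permutation_pvalue(t, B=19, seed=0)
        assert p["accuracy"] > 0.05


class TestShap:
    def test_additivity_to_machine_precision(self):
        t = separable_table(seed=11)
        clf = StumpBoost().fit(t.X, t.y)
        summ = shap_summary(clf, t.X, t.feature_names)
        recon = summ.base_value + summ.values.sum(axis=1)
        np.testing.assert_allclose(recon, clf.decision_function(t.X), atol=1e-12)

    def test_signal_feature_dominates_attribution(self):
        t = separable_table(gap=5.0, seed=12)
        clf = StumpBoost().fit(t.X, t.y)
        summ = shap_summary(clf, t.X, t.feature_names)
        assert summ.top_k[0] == "signal"

    def test_missingness_axiom_unused_feature_gets_zero(self):
        t = separable_table(gap=6.0, seed=13)
        clf = StumpBoost().fit(t.X, t.y)
        summ = shap_summary(clf, t.X, t.feature_names)
        used = set(clf.features_)
        for j in range(len(t.feature_names)):
            if j not in used:
                np.testing.assert_array_equal(summ.values[:, j], 0.0)

    def test_symmetric_background_centering(self):
        """With the sample itself as the only background row, phi sums to 0."""
        t = separable_table(seed=14)
        clf = StumpBoost().fit(t.X, t.y)
        x = t.X[:1]
        summ = shap_summary(clf, x, t.feature_names, background=x)
        np.testing.assert_allclose(summ.values, 0.0, atol=1e-15)
        assert summ.base_value == pytest.approx(
            float(clf.decision_function(x)[0])
        )


class TestFeatureTable:
    def test_eeg_feature_names_count(self):
        names = eeg_feature_names()
        assert len(names) == 306
        assert names[-1] == "age"
        assert len(set(names)) == 306

    def test_build_eeg_table(self):
        names = eeg_feature_names(include_age=False)
        subj = [f"s{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        power_cols = [n for n in names if "_power_" in n]
        net_cols = [n for n in names if "_power_" not in n]
        spectral = pd.DataFrame(
            rng.random((6, len(power_cols))), index=subj, columns=power_cols
        )
        network = pd.DataFrame(
            rng.random((6, len(net_cols))), index=subj, columns=net_cols
        )
        meta = pd.DataFrame(
            {"group": ["A_plus"] * 3 + ["A_minus"] * 3, "age": 70.0}, index=subj
        )
        t = build_feature_table(spectral, network, meta, mode="eeg")
        assert t.X.shape == (6, 306)
        assert t.y.tolist() == [1, 1, 1, 0, 0, 0]
        np.testing.assert_array_equal(t.X[:, -1], 70.0)

    def test_missing_subject_rejected(self):
        names = eeg_feature_names(include_age=False)
        subj = ["a", "b", "c", "d"]
        power_cols = [n for n in names if "_power_" in n]
        net_cols = [n for n in names if "_power_" not in n]
        spectral = pd.DataFrame(0.0, index=subj[:3], columns=power_cols)
        network = pd.DataFrame(0.0, index=subj[:3], columns=net_cols)
        meta = pd.DataFrame(
            {"group": ["A_plus", "A_plus", "A_minus", "A_minus"], "age": 70.0},
            index=subj,
        )
        with pytest.raises(KeyError, match="missing"):
            build_feature_table(spectral, network, meta, mode="eeg")

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            FeatureTable(["a", "b"], ["f"], np.array([[1.0], [np.nan]]),
                         np.array([0, 1]))

    def test_subset_preserves_order(self):
        t = separable_table()
        sub = t.subset(["noise1", "signal"])
        assert sub.feature_names == ["noise1", "signal"]
        np.testing.assert_array_equal(sub.X[:, 1], t.X[:, 0])
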