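"""Splitting, model fits, metrics and correlation matrices on small inputs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnshape.models import (
    MultiOutcomeForest,
    backward_eliminate,
    fit_predict_gbm,
    fit_predict_logistic,
    fit_predict_rf,
    r_squared,
    repeat_evaluate,
    roc_auc,
    spearman_matrix,
    split_half,
)


def brute_force_auc(scores, labels):
    """Pairwise oracle: P(score+ > score-) + 0.5 P(score+ = score-)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def separable_table(n=40, seed=0):
    """Two well-separated feature clusters with matching binary label."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 3)) + 10 * y[:, None]
    df = pd.DataFrame(X, columns=["f1", "f2", "f3"])
    df["label"] = y
    return df


class TestSplitHalf:
    def test_partition_contract(self):
        items = list(range(96))
        train, test = split_half(items, seed=1)
        assert len(train) == len(test) == 48
        assert sorted(train + test) == items

    def test_same_seed_same_split(self):
        items = list(range(41))
        assert split_half(items, seed=9) == split_half(items, seed=9)
        t1, _ = split_half(items, seed=9)
        t2, _ = split_half(items, seed=10)
        assert t1 != t2

    def test_stratification_keeps_both_classes_in_both_halves(self):
        df = pd.DataFrame({"x": range(20), "y": [0] * 15 + [1] * 5})
        for seed in range(10):
            train, test = split_half(df, stratify=df["y"], seed=seed)
            assert train["y"].nunique() == 2
            assert test["y"].nunique() == 2
            assert abs(len(train) - len(test)) <= 1

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_half([1, 2, 3], seed=0)
        with pytest.raises(ValueError):
            split_half(list(range(10)), stratify=[0] * 9 + [1], seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_ties_hand_computed(self):
        # pairs: (0.8 vs 0.8)=0.5, (0.8 vs 0.4)=1, (0.2 vs 0.8)=0, (0.2 vs 0.4)=0
        assert roc_auc([0.8, 0.2, 0.8, 0.4], [1, 1, 0, 0]) == pytest.approx(0.375)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # ties likely
            assert roc_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_label_flip_mirrors_auc(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        labels = np.r_[0, 1, rng.integers(0, 2, size=n - 2)]
        scores = rng.normal(size=n)
        assert roc_auc(scores, labels) == pytest.approx(1 - roc_auc(scores, 1 - labels), abs=1e-12)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, size=5000)
        scores = rng.normal(size=5000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)


class TestRSquared:
    def test_perfect_and_mean_predictions(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0
        assert r_squared([1, 2, 3], [2, 2, 2]) == 0.0

    def test_hand_arithmetic(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_constant_actual_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2, 2, 2], [1, 2, 3])


class TestForest:
    def test_constant_outcome_predicted_as_constant(self):
        df = separable_table()
        df["const"] = 3.0
        pred = fit_predict_rf(df.iloc[:20], df.iloc[20:], ["const"], features=["f1", "f2", "f3"], n_estimators=10, seed=0)
        assert (pred["const"] == 3.0).all()

    def test_separable_clusters_reach_perfect_auc(self):
        df = separable_table(seed=1)
        train, test = split_half(df, stratify=df["label"], seed=0)
        pred = fit_predict_rf(train, test, ["label"], features=["f1", "f2", "f3"], n_estimators=50, seed=0)
        assert roc_auc(pred["label"], test["label"]) == 1.0

    def test_deterministic_given_seed(self):
        df = separable_table(seed=2)
        kw = dict(features=["f1", "f2", "f3"], n_estimators=25, seed=7)
        p1 = fit_predict_rf(df.iloc[:20], df.iloc[20:], ["label"], **kw)
        p2 = fit_predict_rf(df.iloc[:20], df.iloc[20:], ["label"], **kw)
        pd.testing.assert_frame_equal(p1, p2)

    def test_estimator_api(self):
        df = separable_table()
        est = MultiOutcomeForest(n_estimators=10, random_state=0)
        assert est.get_params()["n_estimators"] == 10
        est.fit(df[["f1", "f2", "f3"]], df[["label"]])
        assert est.outcome_names_ == ["label"]
        assert est.predict(df[["f1", "f2", "f3"]]).shape == (len(df), 1)


class TestGBM:
    def test_separable_clusters_reach_perfect_auc(self):
        df = separable_table(seed=3)
        train, test = split_half(df, stratify=df["label"], seed=0)
        scores = fit_predict_gbm(train, test, "label", features=["f1", "f2", "f3"], n_estimators=100, seed=0)
        assert roc_auc(scores, test["label"]) == 1.0

    def test_permuted_labels_give_null_auc(self):
        """With labels independent of features, mean test AUC sits near 0.5."""
        rng = np.random.default_rng(77)
        aucs = []
        for _ in range(200):
            X = rng.normal(size=(40, 4))
            df = pd.DataFrame(X, columns=list("abcd"))
            df["label"] = rng.permutation([0] * 20 + [1] * 20)
            train, test = split_half(df, stratify=df["label"], seed=int(rng.integers(2**31)))
            scores = fit_predict_gbm(train, test, "label", features=list("abcd"), n_estimators=30, seed=0)
            aucs.append(roc_auc(scores, test["label"]))
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestLogistic:
    def test_feature_equal_to_label_separates(self):
        df = separable_table(seed=4)
        df["exact"] = df["label"].astype(float)
        train, test = split_half(df, stratify=df["label"], seed=0)
        with pytest.warns(UserWarning):  # complete separation -> ridge fallback
            scores = fit_predict_logistic(train, test, "label", terms=["exact"])
        assert roc_auc(scores, test["label"]) == 1.0

    def test_intercept_only_scores_are_constant(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"one": np.ones(30), "label": rng.integers(0, 2, 30)})
        scores = fit_predict_logistic(df.iloc[:20], df.iloc[20:], "label", terms=["one"])
        assert scores.nunique() == 1
        assert roc_auc(scores, [0, 1] * 5) == 0.5  # tie convention

    def test_coefficient_recovery_from_simulated_data(self):
        rng = np.random.default_rng(31)
        n = 2000
        X = rng.normal(size=(n, 3))
        beta = np.array([1.0, -0.5, 0.8])
        eta = 0.3 + X @ beta
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["label"] = y
        _, params = fit_predict_logistic(df, df, "label", terms=["a", "b", "c"], return_params=True)
        assert np.allclose(params[1:], beta, rtol=0.2)

    def test_product_terms(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        df["label"] = (df["a"] * df["b"] > 0).astype(int)
        scores = fit_predict_logistic(df, df, "label", terms=["a*b"])
        assert roc_auc(scores, df["label"]) > 0.9


class TestRepeatEvaluate:
    def test_single_repeat_collapses_range(self):
        df = separable_table(seed=9)
        res = repeat_evaluate(df, "rf", ["label"], n_repeats=1, seed=0, features=["f1", "f2", "f3"], stratify_col="label", n_estimators=20)
        s = res.summaries["label"]
        assert s.min == s.mean == s.max
        assert s.metric == "auc"

    def test_reproducible_and_seed_sensitive(self):
        df = separable_table(n=24, seed=10)
        df["noise"] = np.random.default_rng(0).normal(size=len(df))
        kw = dict(features=["f1", "f2", "f3"], stratify_col="label", n_estimators=15)
        r1 = repeat_evaluate(df, "rf", ["label"], n_repeats=3, seed=5, **kw)
        r2 = repeat_evaluate(df, "rf", ["label"], n_repeats=3, seed=5, **kw)
        assert r1.to_json_dict() == r2.to_json_dict()

    def test_invariants_of_summary(self, table_A):
        res = repeat_evaluate(
            table_A, "rf", ["mean_dose_gy", "mix_index"], n_repeats=3, seed=2, n_estimators=50
        )
        for s in res.summaries.values():
            assert s.min <= s.mean <= s.max
            if s.metric == "auc":
                assert 0 <= s.min and s.max <= 1
            else:
                assert s.max <= 1

    def test_continuous_outcome_rejected_for_gbm(self, table_A):
        with pytest.raises(ValueError):
            repeat_evaluate(table_A, "gbm", ["mean_dose_gy"], n_repeats=1, seed=0)


class TestSpearman:
    def test_monotone_transform_and_sign(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        df["up"] = 2 * df["x"] + 1
        df["down"] = -df["x"]
        rho, _ = spearman_matrix(df)
        assert rho.loc["x", "up"] == pytest.approx(1.0)
        assert rho.loc["x", "down"] == pytest.approx(-1.0)

    def test_rank_formula_hand_value(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [1, 3, 2, 5, 4]})
        rho, pval = spearman_matrix(df.astype(float))
        assert rho.loc["x", "y"] == pytest.approx(0.8)
        assert np.allclose(rho.values, rho.values.T)
        assert (np.diag(rho) == 1).all()

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [7.0, 7, 7, 7]})
        rho, pval = spearman_matrix(df)
        assert np.isnan(rho.loc["x", "c"]) and np.isnan(pval.loc["x", "c"])
        assert rho.loc["x", "x"] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"x": [1.0, 2]}))


def test_backward_elimination_drops_pure_noise():
    rng = np.random.default_rng(13)
    n = 120
    signal = rng.normal(size=n)
    df = pd.DataFrame({"signal": signal, "noise1": rng.normal(size=n), "noise2": rng.normal(size=n)})
    df["label"] = (signal + 0.3 * rng.normal(size=n) > 0).astype(int)
    kept = backward_eliminate(df, "label", model="lr", features=["signal", "noise1", "noise2"], seed=0)
    assert "signal" in kept
    assert len(kept) < 3
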