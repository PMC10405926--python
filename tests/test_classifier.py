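"""Random-forest marker discovery: selection rule, ROC/AUC, CV discipline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metamarker import (
    AbundanceMatrix,
    CVConfig,
    CVCurve,
    DataError,
    make_binary_labels,
    roc_auc,
    run_marker_discovery,
    select_features,
)
from metamarker.classifier import (
    cv_feature_importance,
    default_k_schedule,
    out_of_fold_scores,
    sequential_feature_curve,
)

from oracles import oracle_auc, oracle_select_features

FAST = CVConfig(n_folds=3, n_repeats=1, tree_grid=(50,), mtry_grid=("sqrt",), seed=0)


def cohort_groups():
    return ["healthy"] * 80 + ["copd_mild"] * 31 + ["copd_severe"] * 49


class TestBinaryLabels:
    def test_one_vs_rest_counts(self):
        y = make_binary_labels(cohort_groups(), "healthy")
        assert y.sum() == 80 and (~y).sum() == 80
        y = make_binary_labels(cohort_groups(), "copd_mild")
        assert y.sum() == 31 and (~y).sum() == 129

    def test_pooled_positive(self):
        y = make_binary_labels(cohort_groups(), ["copd_mild", "copd_severe"])
        assert y.sum() == 80

    def test_two_group_identity(self):
        y = make_binary_labels(["a", "b", "a"], "a")
        assert y.tolist() == [True, False, True]

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            make_binary_labels(["a", "a"], "a")
        with pytest.raises(DataError):
            make_binary_labels(["a", "b"], "z")


class TestSelectFeatures:
    def test_hand_example_interior_minimum(self):
        curve = CVCurve(np.array([1, 2, 3]), np.array([0.30, 0.20, 0.22]), np.array([0.05, 0.02, 0.03]))
        res = select_features(curve)
        assert res["cutoff"] == pytest.approx(0.22)
        assert res["candidate_ks"] == (2,)
        assert res["chosen_k"] == 2

    def test_hand_example_zero_sd_fallback(self):
        curve = CVCurve(np.array([1, 2, 3]), np.array([0.25, 0.20, 0.19]), np.array([0.05, 0.02, 0.00]))
        res = select_features(curve)
        assert res["cutoff"] == pytest.approx(0.19)
        assert res["candidate_ks"] == ()
        assert res["chosen_k"] == 3

    def test_large_sd_at_minimum_can_choose_one(self):
        curve = CVCurve(np.array([1, 2, 3]), np.array([0.30, 0.25, 0.10]), np.array([0.0, 0.0, 0.25]))
        res = select_features(curve)
        assert res["chosen_k"] == 1

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_independent_oracle(self, data):
        n = data.draw(st.integers(min_value=1, max_value=30))
        ks = sorted(data.draw(st.sets(st.integers(1, 500), min_size=n, max_size=n)))
        means = data.draw(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)
        )
        sds = data.draw(
            st.lists(st.floats(0, 0.3, allow_nan=False), min_size=n, max_size=n)
        )
        curve = CVCurve(np.array(ks), np.array(means), np.array(sds))
        res = select_features(curve, [f"f{i}" for i in range(max(ks))])
        cutoff, candidates, chosen = oracle_select_features(ks, means, sds)
        assert res["cutoff"] == pytest.approx(cutoff)
        assert list(res["candidate_ks"]) == candidates
        assert res["chosen_k"] == chosen
        assert len(res["chosen_features"]) == chosen


class TestRocAuc:
    def test_perfect_ranking(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert res.auc == 1.0

    def test_hand_example_five_sixths(self):
        res = roc_auc([0.9, 0.8, 0.7, 0.6, 0.85], [True, True, False, False, False])
        assert res.auc == pytest.approx(5 / 6, abs=1e-12)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            res = roc_auc(scores, labels)
            assert res.auc == pytest.approx(oracle_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        scores = rng.random(50)
        labels = rng.random(50) < 0.4
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.random(1000)
        labels = np.repeat([True, False], 500)
        res = roc_auc(scores, labels)
        assert 0.45 <= res.auc <= 0.55
        assert res.ci_low < res.auc < res.ci_high

    def test_delong_ci_covers_and_orders(self):
        rng = np.random.default_rng(6)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 60)])
        labels = np.repeat([True, False], [40, 60])
        res = roc_auc(scores, labels)
        assert 0 <= res.ci_low <= res.auc <= res.ci_high <= 1

    def test_one_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.2], [True, True])


def _signal_matrix(n=60, p=30, seed=0):
    """One strongly separating feature among noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([True, False], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 7] += 3.0 * y
    data = pd.DataFrame(X - X.min() + 0.01, columns=[f"f{i:02d}" for i in range(p)],
                        index=[f"s{i}" for i in range(n)])
    return AbundanceMatrix(data, feature_kind="taxon", value_kind="count"), y


class TestCvFeatureImportance:
    def test_separating_feature_ranked_first(self):
        m, y = _signal_matrix()
        ranked, importances, params = cv_feature_importance(m, y, FAST)
        assert ranked[0] == "f07"
        assert importances.iloc[0] == importances.max()

    def test_constant_features_zero_importance(self):
        m, y = _signal_matrix()
        data = m.data.copy()
        data["f00"] = 1.0
        m2 = AbundanceMatrix(data, feature_kind="taxon", value_kind="count")
        _, importances, _ = cv_feature_importance(m2, y, FAST)
        assert importances["f00"] == 0.0

    def test_deterministic_given_seed(self):
        m, y = _signal_matrix()
        a = cv_feature_importance(m, y, FAST)
        b = cv_feature_importance(m, y, FAST)
        assert a[0] == b[0]
        pd.testing.assert_series_equal(a[1], b[1])


class TestSequentialCurve:
    def test_schedule_dense_then_geometric(self):
        ks = default_k_schedule(100)
        assert ks[:30] == tuple(range(1, 31))
        assert ks[-1] == 100
        assert all(b > a for a, b in zip(ks, ks[1:]))

    def test_curve_length_and_single_perfect_feature(self):
        m, y = _signal_matrix(seed=1)
        curve = sequential_feature_curve(m, y, ["f07", "f00", "f01"], FAST)
        assert len(curve.k) == 3
        assert curve.mean_error[0] <= 0.15  # near-perfect separation at k=1

    def test_oversized_k_truncated(self):
        m, y = _signal_matrix()
        curve = sequential_feature_curve(m, y, ["f07", "f00"], FAST, schedule=[1, 2, 50])
        assert list(curve.k) == [1, 2]


class TestOutOfFoldDiscipline:
    def test_every_sample_scored_exactly_once_per_repeat(self):
        m, y = _signal_matrix()
        scores = out_of_fold_scores(m, y, ["f07", "f00"], FAST, {"n_trees": 50, "mtry": "sqrt"})
        assert list(scores.index) == m.sample_ids
        assert scores.between(0, 1).all()

    def test_null_data_auc_near_half(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.random((60, 20)), index=[f"s{i}" for i in range(60)],
                            columns=[f"f{i}" for i in range(20)])
        m = AbundanceMatrix(data, feature_kind="taxon", value_kind="count")
        y = np.repeat([True, False], 30)
        scores = out_of_fold_scores(m, y, m.feature_ids, FAST, {"n_trees": 50, "mtry": "sqrt"})
        assert 0.3 <= roc_auc(scores.to_numpy(), y).auc <= 0.7


class TestRunMarkerDiscovery:
    def test_recovers_planted_markers(self, small_cohort):
        from metamarker.profiles import arcsin_sqrt_transform, relative_abundance

        counts, groups, truth = small_cohort
        t = arcsin_sqrt_transform(relative_abundance(counts))
        sel, roc = run_marker_discovery(t, groups, "copd_severe", FAST)
        assert roc.auc >= 0.8
        planted = set(truth.informative_features)
        assert len(set(sel.chosen_features) & planted) / sel.chosen_k >= 0.5

    def test_rerun_identical(self, small_cohort):
        from metamarker.profiles import arcsin_sqrt_transform, relative_abundance

        counts, groups, _ = small_cohort
        t = arcsin_sqrt_transform(relative_abundance(counts))
        sel1, roc1 = run_marker_discovery(t, groups, "healthy", FAST)
        sel2, roc2 = run_marker_discovery(t, groups, "healthy", FAST)
        assert sel1.chosen_features == sel2.chosen_features
        assert roc1.auc == roc2.auc
        np.testing.assert_array_equal(sel1.curve.mean_error, sel2.curve.mean_error)
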