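"""Stratified splitting, tuning, boosted-tree fitting, and importance ranking."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from recurmine.classifier import (
    SBCEMonthClassifier,
    SplitPlan,
    feature_importance,
    fit,
    predict_months,
    split_cohort,
    tune,
)
from recurmine.features import FeatureMatrix, build_feature_matrix
from recurmine.preprocess import (
    assign_valid_windows,
    build_month_panel,
    deduplicate_daily,
)
from recurmine.simulate import SimConfig, simulate_cohort

from conftest import make_record


def synthetic_matrix(X: pd.DataFrame, y, months_per_patient: int = 1) -> FeatureMatrix:
    n = len(X)
    pids = [f"P{i // months_per_patient}" for i in range(n)]
    months = [6 + i % months_per_patient for i in range(n)]
    return FeatureMatrix(
        X=X,
        y=np.asarray(y),
        index=pd.DataFrame({"patient_id": pids, "month_index": months}),
        feature_names=list(X.columns),
        group_ids=[],
    )


def plan_for(fm: FeatureMatrix, n_folds: int = 5) -> SplitPlan:
    pids = sorted(fm.index["patient_id"].unique())
    return SplitPlan(
        train_ids=pids,
        test_ids=[],
        fold_of={p: i % n_folds + 1 for i, p in enumerate(pids)},
        seed=0,
        n_folds=n_folds,
    )


class TestSplitCohort:
    def records(self, n_neg, n_pos):
        recs = [make_record(f"N{i}") for i in range(n_neg)]
        recs += [
            make_record(f"S{i}", sbce_day=300, followup_end_day=1000)
            for i in range(n_pos)
        ]
        return recs

    def test_per_stratum_80_20(self):
        plan = split_cohort(self.records(100, 20), seed=1)
        train = set(plan.train_ids)
        assert sum(p.startswith("N") for p in train) == 80
        assert sum(p.startswith("S") for p in train) == 16
        assert len(plan.test_ids) == 24

    def test_study_scale_split_sizes(self):
        plan = split_cohort(self.records(2698, 394), seed=1)
        test_neg = sum(p.startswith("N") for p in plan.test_ids)
        test_pos = sum(p.startswith("S") for p in plan.test_ids)
        assert test_neg == 2698 - round(0.8 * 2698) == 540
        assert test_pos == 394 - round(0.8 * 394) == 79

    def test_deterministic_and_seed_sensitive(self):
        recs = self.records(40, 10)
        a, b = split_cohort(recs, seed=3), split_cohort(recs, seed=3)
        c = split_cohort(recs, seed=4)
        assert (a.train_ids, a.fold_of) == (b.train_ids, b.fold_of)
        assert a.train_ids != c.train_ids

    def test_partition_and_fold_coverage(self):
        plan = split_cohort(self.records(40, 10), seed=2)
        assert not set(plan.train_ids) & set(plan.test_ids)
        assert set(plan.fold_of) == set(plan.train_ids)
        for k in range(1, 6):
            fold = [p for p, f in plan.fold_of.items() if f == k]
            assert any(p.startswith("S") for p in fold)  # stratified folds

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            split_cohort(self.records(40, 3), seed=0)


class TestTune:
    def test_grid_of_one_returns_it(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        y = (X["a"] > 0).astype(int)
        fm = synthetic_matrix(X, y)
        params, table = tune(fm, plan_for(fm), [{"max_depth": 2, "learning_rate": 0.3}])
        assert params["max_depth"] == 2 and len(table) == 1

    def test_interaction_problem_prefers_deeper_trees(self):
        # y = XOR(a, b): depth-1 stumps cannot express it, depth-3 trees can
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 600)
        b = rng.integers(0, 2, 600)
        X = pd.DataFrame({"a": a.astype(float), "b": b.astype(float)})
        y = a ^ b
        fm = synthetic_matrix(X, y)
        grid = [
            {"max_depth": 1, "learning_rate": 0.3},
            {"max_depth": 3, "learning_rate": 0.3},
        ]
        params, table = tune(fm, plan_for(fm), grid)
        assert params["max_depth"] == 3
        aucs = dict(zip(table["max_depth"], table["mean_oof_auc"]))
        assert aucs[3] > aucs[1] + 0.2

    def test_no_signal_features_give_chance_auc(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": np.zeros(400), "b": np.zeros(400)})
        y = rng.integers(0, 2, 400)
        fm = synthetic_matrix(X, y)
        params, table = tune(fm, plan_for(fm), [{"max_depth": 2, "learning_rate": 0.3}])
        assert 0.4 <= table["mean_oof_auc"].iloc[0] <= 0.6

    def test_empty_grid_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0] * 10})
        fm = synthetic_matrix(X, [0, 1] * 10)
        with pytest.raises(ValueError, match="grid"):
            tune(fm, plan_for(fm), [])


class TestFitPredict:
    def test_single_class_labels_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError, match="single class"):
            SBCEMonthClassifier().fit(X, np.zeros(10))

    def test_refit_reproducible_and_order_invariant(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        y = (X["a"] + 0.5 * rng.normal(size=300) > 0).astype(int)
        fm = synthetic_matrix(X, y)
        p1 = predict_months(fit(fm, seed=5), fm)
        p2 = predict_months(fit(fm, seed=5), fm)
        np.testing.assert_array_equal(p1, p2)
        perm = rng.permutation(300)
        shuffled = FeatureMatrix(
            X=X.iloc[perm].reset_index(drop=True),
            y=np.asarray(y)[perm],
            index=fm.index.iloc[perm].reset_index(drop=True),
            feature_names=fm.feature_names,
            group_ids=[],
        )
        p3 = predict_months(fit(fm, seed=5), shuffled)
        np.testing.assert_allclose(p3, p1[perm], rtol=1e-6)

    def test_probabilities_in_unit_interval_and_empty_ok(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=100)})
        fm = synthetic_matrix(X, (X["a"] > 0).astype(int))
        bundle = fit(fm, seed=0)
        probs = predict_months(bundle, fm)
        assert ((probs >= 0) & (probs <= 1)).all()
        empty = synthetic_matrix(X.iloc[:0], np.empty(0, dtype=int))
        assert predict_months(bundle, empty).size == 0

    def test_feature_name_mismatch_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0] * 20})
        fm = synthetic_matrix(X, [0, 1] * 20)
        bundle = fit(fm, seed=0)
        other = synthetic_matrix(X.rename(columns={"a": "zz"}), [0, 1] * 20)
        with pytest.raises(ValueError, match="feature names"):
            predict_months(bundle, other)

    def test_strong_signal_cohort_separates_training_months(self):
        cohort = simulate_cohort(SimConfig(n_patients=150, seed=9))
        claims = deduplicate_daily(cohort.claims)
        windows = assign_valid_windows(cohort.records, "relative")
        panel = build_month_panel(
            claims, cohort.records, windows, cohort.groupmap, "relative"
        )
        fm = build_feature_matrix(panel)
        bundle = fit(fm, seed=0)
        auc = roc_auc_score(fm.y, predict_months(bundle, fm))
        assert auc > 0.95

    def test_permuted_labels_give_chance_out_of_sample_auc(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(2000, 6)), columns=list("abcdef"))
        y = rng.permutation((np.arange(2000) < 400).astype(int))
        train = synthetic_matrix(X.iloc[:1200], y[:1200])
        bundle = fit(train, seed=0)
        probs = bundle.model.predict_proba(X.iloc[1200:])[:, 1]
        assert 0.45 <= roc_auc_score(y[1200:], probs) <= 0.55


class TestFeatureImportance:
    def test_planted_signal_feature_ranks_first(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(500, 5)), columns=list("abcde"))
        # noisy single-feature signal: boosting must keep splitting on it
        y = (X["c"] + 0.8 * rng.normal(size=500) > 0).astype(int)
        bundle = fit(synthetic_matrix(X, y), seed=0)
        top = feature_importance(bundle, top_k=1)
        assert top[0][0] == "c"

    def test_top_k_clamped_and_sorted(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = (X["a"] + X["b"] > 0).astype(int)
        bundle = fit(synthetic_matrix(X, y), seed=0)
        ranked = feature_importance(bundle, top_k=99)
        assert len(ranked) == 3
        values = [v for _, v in ranked]
        assert values == sorted(values, reverse=True)
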