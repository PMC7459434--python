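"""Cohort splitting, gradient-boosted month classification, and tuning.

Splitting and cross-validation folds are assigned at the *patient* level,
stratified by event status, even though classification happens at the
person-month level: all months of a patient stay on one side of the split and
inside one fold, so no patient leaks information across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

from .cohort import RegistryRecord
from .features import FeatureMatrix

#: default hyperparameter grid; tree depth and learning rate are the
#: flexibility parameters that matter most for boosted trees on this problem
DEFAULT_PARAM_GRID: list[dict] = [
    {"max_depth": d, "learning_rate": lr} for d in (3, 6) for lr in (0.1, 0.3)
]

DEFAULT_PARAMS: dict = {"max_depth": 3, "learning_rate": 0.1, "n_estimators": 300}


@dataclass
class SplitPlan:
    """Patient-level 80:20 split plus 5 cross-validation folds over train.

    Both the split and the folds are computed separately within the event and
    non-event strata, so each side preserves the cohort's event fraction.
    """

    train_ids: list[str]
    test_ids: list[str]
    fold_of: dict[str, int]
    seed: int
    n_folds: int = 5


def split_cohort(
    records: Sequence[RegistryRecord],
    fraction: float = 0.8,
    n_folds: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Stratified patient-level split; per-stratum train size = round(fraction*n)."""
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    fold_of: dict[str, int] = {}
    for flag in (False, True):
        ids = sorted(r.patient_id for r in records if r.sbce == flag)
        if len(ids) < n_folds:
            raise ValueError(
                f"stratum sbce={flag} has {len(ids)} patients; need >= {n_folds} "
                "to form folds"
            )
        perm = [ids[i] for i in rng.permutation(len(ids))]
        n_train = int(round(fraction * len(ids)))
        stratum_train, stratum_test = perm[:n_train], perm[n_train:]
        if len(stratum_train) < n_folds:
            raise ValueError(f"stratum sbce={flag}: training side smaller than folds")
        train_ids.extend(stratum_train)
        test_ids.extend(stratum_test)
        for i, pid in enumerate(stratum_train):
            fold_of[pid] = i % n_folds + 1
    return SplitPlan(sorted(train_ids), sorted(test_ids), fold_of, seed, n_folds)


class SBCEMonthClassifier(ClassifierMixin, BaseEstimator):
    """Gradient-boosted tree classifier over person-month rows.

    A thin, deterministic wrapper around XGBoost binary classification with
    frequency-based feature importance (how often each feature is used as a
    split across the ensemble's trees).
    """

    def __init__(
        self,
        max_depth: int = 3,
        learning_rate: float = 0.1,
        n_estimators: int = 300,
        min_child_weight: float = 1.0,
        subsample: float = 1.0,
        scale_pos_weight: float | None = None,
        random_state: int = 0,
    ):
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.min_child_weight = min_child_weight
        self.subsample = subsample
        self.scale_pos_weight = scale_pos_weight
        self.random_state = random_state

    def _booster_params(self) -> dict:
        params = dict(
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            min_child_weight=self.min_child_weight,
            subsample=self.subsample,
            random_state=self.random_state,
            tree_method="hist",
            n_jobs=1,
            eval_metric="logloss",
        )
        if self.scale_pos_weight is not None:
            params["scale_pos_weight"] = self.scale_pos_weight
        return params

    def fit(self, X, y, eval_set=None, early_stopping_rounds: int | None = None):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.feature_names_ = (
            list(X.columns) if isinstance(X, pd.DataFrame) else
            [f"f{i}" for i in range(np.asarray(X).shape[1])]
        )
        params = self._booster_params()
        if early_stopping_rounds is not None:
            params["early_stopping_rounds"] = early_stopping_rounds
            params["eval_metric"] = "auc"
        self.model_ = XGBClassifier(**params)
        if eval_set is not None:
            self.model_.fit(X, y, eval_set=eval_set, verbose=False)
        else:
            self.model_.fit(X, y)
        self.classes_ = np.unique(y)
        self.n_features_in_ = len(self.feature_names_)
        return self

    def _check_features(self, X) -> None:
        if isinstance(X, pd.DataFrame) and list(X.columns) != self.feature_names_:
            raise ValueError("feature names do not match the fitted model")

    def predict_proba(self, X) -> np.ndarray:
        self._check_features(X)
        if len(X) == 0:
            return np.empty((0, 2))
        return self.model_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        if len(X) == 0:
            return np.empty(0, dtype=int)
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def feature_importance(self, top_k: int = 20) -> list[tuple[str, float]]:
        """Features ranked by split frequency across trees, descending;
        ties broken by feature-name order.  Unused features score 0."""
        booster = self.model_.get_booster()
        raw = booster.get_score(importance_type="weight")
        scores = {name: float(raw.get(name, 0.0)) for name in self.feature_names_}
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[: min(top_k, len(ranked))]


@dataclass
class ModelBundle:
    """A fitted ensemble plus everything needed to reproduce and apply it."""

    model: SBCEMonthClassifier
    params: dict
    feature_names: list[str]
    seed: int
    fold_scores: dict = field(default_factory=dict)


def _fold_row_masks(fm: FeatureMatrix, plan: SplitPlan) -> dict[int, np.ndarray]:
    fold = fm.index["patient_id"].map(plan.fold_of)
    return {k: (fold == k).to_numpy() for k in range(1, plan.n_folds + 1)}


def tune(
    train_fm: FeatureMatrix,
    plan: SplitPlan,
    param_grid: Sequence[Mapping] | None = None,
    seed: int = 0,
    max_rounds: int = 400,
    early_stopping_rounds: int = 25,
) -> tuple[dict, pd.DataFrame]:
    """Grid search maximising mean out-of-fold month-level AUC.

    The number of boosting rounds is chosen by early stopping against each
    held-out fold; the winner's rounds are averaged into ``n_estimators``.
    Returns (best params incl. n_estimators, per-setting results table).
    """
    if param_grid is None:
        param_grid = DEFAULT_PARAM_GRID
    param_grid = list(param_grid)
    if not param_grid:
        raise ValueError("empty hyperparameter grid")
    masks = _fold_row_masks(train_fm, plan)
    results = []
    for i, setting in enumerate(param_grid):
        aucs, best_iters = [], []
        for k, mask in masks.items():
            X_tr, y_tr = train_fm.X[~mask], train_fm.y[~mask]
            X_va, y_va = train_fm.X[mask], train_fm.y[mask]
            clf = SBCEMonthClassifier(
                **setting, n_estimators=max_rounds, random_state=seed
            )
            clf.fit(
                X_tr,
                y_tr,
                eval_set=[(X_va, y_va)],
                early_stopping_rounds=early_stopping_rounds,
            )
            p = clf.predict_proba(X_va)[:, 1]
            aucs.append(roc_auc_score(y_va, p))
            best_iters.append(int(clf.model_.best_iteration) + 1)
        results.append(
            {
                "grid_index": i,
                **setting,
                "mean_oof_auc": float(np.mean(aucs)),
                "n_estimators": int(round(np.mean(best_iters))),
                "fold_aucs": aucs,
            }
        )
    table = pd.DataFrame(results)
    best = max(results, key=lambda r: (r["mean_oof_auc"], -r["grid_index"]))
    best_params = {k: v for k, v in best.items()
                   if k not in ("grid_index", "mean_oof_auc", "fold_aucs")}
    return best_params, table


def fit(train_fm: FeatureMatrix, params: Mapping | None = None, seed: int = 0) -> ModelBundle:
    """Fit the final ensemble on all training person-months."""
    params = dict(DEFAULT_PARAMS if params is None else params)
    model = SBCEMonthClassifier(**params, random_state=seed)
    model.fit(train_fm.X, train_fm.y)
    return ModelBundle(
        model=model,
        params=params,
        feature_names=list(train_fm.feature_names),
        seed=seed,
    )


def predict_months(bundle: ModelBundle, fm: FeatureMatrix) -> np.ndarray:
    """Per-row probability of being post-event, aligned with ``fm.index``."""
    if list(fm.feature_names) != bundle.feature_names:
        raise ValueError("feature names do not match the fitted bundle")
    if len(fm) == 0:
        return np.empty(0)
    return bundle.model.predict_proba(fm.X)[:, 1]


def feature_importance(bundle: ModelBundle, top_k: int = 20) -> list[tuple[str, float]]:
    return bundle.model.feature_importance(top_k)
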