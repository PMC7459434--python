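"""Month-level ROC/AUC, person-level diagnostics, timing errors, and KM curves.

Timing differences are signed as predicted minus observed month, so a
negative value means the predicted event precedes the observed one.
Undefined diagnostic ratios (zero denominators) are reported as ``None``,
never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn import metrics as _skm

from .cohort import RegistryRecord
from .preprocess import DAYS_PER_MONTH


@dataclass
class MonthRoc:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def month_roc(probs: Sequence[float], labels: Sequence[int]) -> MonthRoc:
    """ROC over all distinct probability cutpoints; AUC by the trapezoid rule
    (equal to the Mann-Whitney concordance with ties counted one half)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("month_roc requires both classes present")
    fpr, tpr, thresholds = _skm.roc_curve(labels, probs)
    auc = float(_skm.auc(fpr, tpr))
    return MonthRoc(fpr, tpr, thresholds, auc)


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Diagnostic rates from a person-level confusion matrix."""
    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def person_metrics(
    predictions: pd.DataFrame, truth: Mapping[str, bool]
) -> dict:
    """One threshold table row from person predictions at a single threshold.

    ``predictions`` needs columns patient_id and predicted_sbce and must cover
    exactly the patients in ``truth``.
    """
    pids = list(predictions["patient_id"])
    if set(pids) != set(truth) or len(pids) != len(set(pids)):
        raise ValueError("predictions and truth must cover identical patients")
    pred = dict(zip(predictions["patient_id"], predictions["predicted_sbce"]))
    tp = sum(1 for p in truth if truth[p] and pred[p])
    fn = sum(1 for p in truth if truth[p] and not pred[p])
    fp = sum(1 for p in truth if not truth[p] and pred[p])
    tn = sum(1 for p in truth if not truth[p] and not pred[p])
    return metrics_from_counts(tp, fp, tn, fn)


def threshold_table(sweep: pd.DataFrame, truth: Mapping[str, bool]) -> pd.DataFrame:
    """Per-threshold person-level metrics across the whole sweep."""
    rows = []
    for t, sub in sweep.groupby("threshold", sort=True):
        row = person_metrics(sub, truth)
        row["threshold"] = float(t)
        rows.append(row)
    cols = ["threshold", "sensitivity", "specificity", "ppv", "npv",
            "tp", "fp", "tn", "fn"]
    return pd.DataFrame(rows)[cols]


def timing_errors(
    sweep: pd.DataFrame,
    truth_months: Mapping[str, int],
    threshold: float,
) -> dict:
    """Timing-difference summaries over correctly predicted event patients.

    diff = predicted_month - observed_month per true positive.  With zero
    true positives the summaries are absent (None), n_correct = 0.
    """
    sub = sweep[np.isclose(sweep["threshold"], threshold)]
    diffs = []
    for row in sub.itertuples(index=False):
        if row.patient_id in truth_months and row.predicted_sbce:
            diffs.append(int(row.predicted_month) - int(truth_months[row.patient_id]))
    if not diffs:
        return {
            "threshold": threshold,
            "n_correct": 0,
            "mean_diff": None,
            "median_diff": None,
            "min_diff": None,
            "max_diff": None,
        }
    arr = np.asarray(diffs, dtype=float)
    return {
        "threshold": threshold,
        "n_correct": len(diffs),
        "mean_diff": float(arr.mean()),
        "median_diff": float(np.median(arr)),
        "min_diff": float(arr.min()),
        "max_diff": float(arr.max()),
    }


def timing_table(sweep: pd.DataFrame, truth_months: Mapping[str, int]) -> pd.DataFrame:
    rows = [
        timing_errors(sweep, truth_months, float(t))
        for t in sorted(sweep["threshold"].unique())
    ]
    return pd.DataFrame(rows)


@dataclass
class KmPair:
    """Observed vs predicted time-to-event product-limit curves."""

    observed: KaplanMeierFitter
    predicted: KaplanMeierFitter
    threshold: float


def km_pair(
    observed_months: Mapping[str, int],
    followup_end_months: Mapping[str, int],
    sweep: pd.DataFrame,
    threshold: float,
) -> KmPair:
    """KM curves for event patients: observed event times (all events) vs
    predicted event times, censoring non-predicted patients at last follow-up."""
    if not observed_months:
        raise ValueError("empty event subset")
    pids = sorted(observed_months)
    obs_kmf = KaplanMeierFitter(label="observed")
    obs_kmf.fit(
        durations=[observed_months[p] for p in pids],
        event_observed=[1] * len(pids),
    )
    sub = sweep[np.isclose(sweep["threshold"], threshold)]
    pred = {
        row.patient_id: (row.predicted_sbce, row.predicted_month)
        for row in sub.itertuples(index=False)
    }
    durations, events = [], []
    for p in pids:
        positive, month = pred.get(p, (False, None))
        if positive:
            durations.append(int(month))
            events.append(1)
        else:
            durations.append(int(followup_end_months[p]))
            events.append(0)
    pred_kmf = KaplanMeierFitter(label="predicted")
    pred_kmf.fit(durations=durations, event_observed=events)
    return KmPair(obs_kmf, pred_kmf, threshold)


def cohort_km(records: Sequence[RegistryRecord]) -> KaplanMeierFitter:
    """Net probability of a first second breast event from diagnosis, in months.

    Event patients contribute their event time; all others are censored at
    the end of follow-up.  Times use average-length months from day offsets,
    so no jitter is required.
    """
    durations, events = [], []
    for r in records:
        if r.sbce:
            durations.append(r.sbce_day / DAYS_PER_MONTH)
            events.append(1)
        else:
            durations.append(r.followup_end_day / DAYS_PER_MONTH)
            events.append(0)
    kmf = KaplanMeierFitter(label="sbce")
    kmf.fit(durations=durations, event_observed=events)
    return kmf


def cumulative_incidence_at(kmf: KaplanMeierFitter, t: float) -> float:
    """1 - S(t) from a fitted product-limit curve."""
    return float(1.0 - kmf.predict(t))


@dataclass
class EvaluationReport:
    """Everything the evaluation stage computes, JSON-serialisable via to_dict."""

    month_auc: float
    threshold_table: pd.DataFrame
    timing_table: pd.DataFrame
    km: KmPair | None = None
    roc: MonthRoc | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {
            "month_auc": self.month_auc,
            "threshold_table": [
                {k: clean(v) for k, v in row.items()}
                for row in self.threshold_table.to_dict(orient="records")
            ],
            "timing_table": [
                {k: clean(v) for k, v in row.items()}
                for row in self.timing_table.to_dict(orient="records")
            ],
            **self.extras,
        }


def round_like_report(value: float | None, ndigits: int = 3) -> float | None:
    """Display rounding used in emitted tables; internal values stay unrounded."""
    return None if value is None else round(value, ndigits)
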