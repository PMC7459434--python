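"""Person-month feature matrix and post-event labels.

Each in-window person-month becomes one row.  The label is 1 for the event
month and every later month, 0 before.  Features per code group g:

* ``count_g``   — claims of group g in the month;
* ``since_g``   — months since the last *prior* in-window occurrence (-1 if none);
* ``until_g``   — months until the next *later* in-window occurrence (-1 if none);
* ``frac_g``    — fraction of prior in-window months containing g (0 in the
  window's first month).

Prior/later are strict: the current month never feeds since/until.  ``until``
deliberately looks forward — this is a retrospective surveillance method that
uses the entire claims record, not a prospective predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import ConfigurationError, RECEPTOR_LEVELS, STAGES
from .preprocess import MonthPanel


def label_for(sbce_month: int | None, month: int) -> int:
    """1 iff the month is the event month or later; patients without an event
    are 0 everywhere."""
    return int(sbce_month is not None and month >= sbce_month)


def label_months(panel: MonthPanel) -> pd.DataFrame:
    """Labels for every in-window person-month.

    Raises if an event month lies beyond a patient's window end: such a
    patient should have been censored or excluded upstream.
    """
    rows = []
    for pid, window in panel.windows.items():
        if window.sbce_month is not None and window.sbce_month > window.end_month:
            raise ConfigurationError(
                f"patient {pid}: sbce_month {window.sbce_month} beyond window end "
                f"{window.end_month}; censor upstream"
            )
        for m in window.months:
            rows.append((pid, m, label_for(window.sbce_month, m)))
    return pd.DataFrame(rows, columns=["patient_id", "month_index", "label"])


def _temporal_arrays(occ: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(since, until, frac) for a boolean occurrence matrix (n_groups, n_months)."""
    occ = np.asarray(occ, dtype=bool)
    n_groups, n_months = occ.shape
    idx = np.arange(n_months)

    def prior_last(o: np.ndarray) -> np.ndarray:
        last = np.where(o, idx[None, :], -1)
        np.maximum.accumulate(last, axis=1, out=last)
        return np.concatenate([np.full((o.shape[0], 1), -1), last[:, :-1]], axis=1)

    pl = prior_last(occ)
    since = np.where(pl >= 0, idx[None, :] - pl, -1)

    pl_rev = prior_last(occ[:, ::-1])
    until_rev = np.where(pl_rev >= 0, idx[None, :] - pl_rev, -1)
    until = until_rev[:, ::-1]

    cum = np.cumsum(occ, axis=1)
    prior_cum = np.concatenate([np.zeros((n_groups, 1), dtype=int), cum[:, :-1]], axis=1)
    denom = np.maximum(idx, 1)
    frac = prior_cum / denom[None, :]
    frac[:, 0] = 0.0
    return since, until, frac


def build_temporal_features(
    panel: MonthPanel, patient_id: str, group_id: str, month: int
) -> tuple[int, int, int, float]:
    """(count, since, until, frac) for one patient, group, and month."""
    window = panel.windows[patient_id]
    if not window.start_month <= month <= window.end_month:
        raise ValueError(
            f"month {month} outside window [{window.start_month}, {window.end_month}] "
            f"for patient {patient_id}"
        )
    months, counts = panel.patient_counts(patient_id)
    g = panel.group_ids.index(group_id)
    since, until, frac = _temporal_arrays(counts > 0)
    j = month - window.start_month
    return (
        int(counts[g, j]),
        int(since[g, j]),
        int(until[g, j]),
        float(frac[g, j]),
    )


@dataclass
class FeatureMatrix:
    """Rectangular person-month design matrix with labels and row identity."""

    X: pd.DataFrame
    y: np.ndarray
    index: pd.DataFrame  # columns: patient_id, month_index
    feature_names: list[str]
    group_ids: list[str]

    def __len__(self) -> int:
        return len(self.X)

    def rows_for(self, patient_ids) -> "FeatureMatrix":
        mask = self.index["patient_id"].isin(set(patient_ids)).to_numpy()
        return FeatureMatrix(
            X=self.X[mask].reset_index(drop=True),
            y=self.y[mask],
            index=self.index[mask].reset_index(drop=True),
            feature_names=self.feature_names,
            group_ids=self.group_ids,
        )


class TemporalFeaturizer(BaseEstimator, TransformerMixin):
    """Turn a MonthPanel into the person-month design matrix.

    Parameters
    ----------
    include_diagnosis_year : bool, default False
        Optionally expose the diagnosis calendar year as a numeric feature.

    Fitted attributes store the group ordering and the categorical levels of
    the registry covariates so train and score matrices align column-wise.
    """

    def __init__(self, include_diagnosis_year: bool = False):
        self.include_diagnosis_year = include_diagnosis_year

    def fit(self, panel: MonthPanel, y=None) -> "TemporalFeaturizer":
        self.group_ids_ = list(panel.group_ids)
        records = panel.records.values()
        self.levels_ = {
            "stage": list(STAGES),
            "grade": sorted({r.grade for r in records}),
            "er_status": list(RECEPTOR_LEVELS),
            "pr_status": list(RECEPTOR_LEVELS),
            "site": sorted({r.site for r in records}),
        }
        names = ["months_since_diagnosis", "age_in_month"]
        if self.include_diagnosis_year:
            names.append("diagnosis_year")
        for var, levels in self.levels_.items():
            names.extend(f"{var}_{lvl}" for lvl in levels)
        for g in self.group_ids_:
            names.extend((f"count_{g}", f"since_{g}", f"until_{g}", f"frac_{g}"))
        self.feature_names_ = names
        return self

    def transform(self, panel: MonthPanel) -> pd.DataFrame:
        if list(panel.group_ids) != self.group_ids_:
            raise ConfigurationError("panel group_ids differ from fitted group_ids")
        blocks: list[np.ndarray] = []
        meta_rows: list[tuple[str, int]] = []
        n_groups = len(self.group_ids_)
        gpos = {g: i for i, g in enumerate(self.group_ids_)}
        grouped = (
            {pid: sub for pid, sub in panel.counts.groupby("patient_id", sort=False)}
            if len(panel.counts)
            else {}
        )
        for pid, window in panel.windows.items():
            rec = panel.records[pid]
            months = np.arange(window.start_month, window.end_month + 1)
            counts = np.zeros((n_groups, len(months)), dtype=np.int64)
            sub = grouped.get(pid)
            if sub is not None:
                gi = sub["group_id"].map(gpos).to_numpy()
                mi = sub["month_index"].to_numpy() - window.start_month
                counts[gi, mi] = sub["count"].to_numpy()
            since, until, frac = _temporal_arrays(counts > 0)
            n = len(months)
            reg = []
            reg.append(months.astype(float))  # months since diagnosis
            reg.append(rec.age_at_diagnosis + months / 12.0)
            if self.include_diagnosis_year:
                reg.append(np.full(n, float(rec.diagnosis_year)))
            for var, levels in self.levels_.items():
                val = getattr(rec, var)
                for lvl in levels:
                    reg.append(np.full(n, 1.0 if val == lvl else 0.0))
            per_group = np.empty((4 * n_groups, n))
            per_group[0::4] = counts
            per_group[1::4] = since
            per_group[2::4] = until
            per_group[3::4] = frac
            blocks.append(np.vstack([np.vstack(reg), per_group]).T)
            meta_rows.extend((pid, int(m)) for m in months)
        if blocks:
            data = np.concatenate(blocks, axis=0)
        else:
            data = np.empty((0, len(self.feature_names_)))
        X = pd.DataFrame(data, columns=self.feature_names_)
        self._last_index_ = pd.DataFrame(meta_rows, columns=["patient_id", "month_index"])
        return X

    def build(self, panel: MonthPanel) -> FeatureMatrix:
        """Transform plus labels and row identity in one FeatureMatrix."""
        X = self.transform(panel)
        index = self._last_index_
        labels = label_months(panel)
        merged = index.merge(labels, on=["patient_id", "month_index"], how="left")
        y = merged["label"].to_numpy(dtype=int)
        return FeatureMatrix(
            X=X,
            y=y,
            index=index,
            feature_names=list(self.feature_names_),
            group_ids=list(self.group_ids_),
        )


def build_feature_matrix(
    panel: MonthPanel, include_diagnosis_year: bool = False
) -> FeatureMatrix:
    """One-shot fit + build on the same panel."""
    return TemporalFeaturizer(include_diagnosis_year).fit(panel).build(panel)
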