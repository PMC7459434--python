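"""Eligibility filters, valid-claims windows, deduplication, and monthly aggregation.

The analysis interval for each patient ("valid window") starts with the first
full calendar month beginning at least 6 months after the primary diagnosis
and ends at follow-up end, truncated 3 months before a non-breast second
primary and 1 month before any second breast event after the first.  Claims
are consolidated so any code occurs at most once per patient-day, rare
diagnosis codes are dropped, surviving codes are mapped to clinical groups,
and counts are summed per patient x calendar month x group.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CodeGroupMap,
    ConfigurationError,
    RegistryRecord,
    ValidWindow,
    claims_frame,
)

#: average Gregorian month length, used by the jitter-free "relative" bin mode
DAYS_PER_MONTH = 30.4375

#: analysis starts this many months after the primary diagnosis
ANALYSIS_START_OFFSET_MONTHS = 6

#: censoring offsets, in months, applied in month-index arithmetic
NONBREAST_PRIMARY_OFFSET = -3
SECOND_SBCE_OFFSET = -1

BIN_MODES = ("calendar", "relative")


def _check_bin_mode(bin_mode: str) -> None:
    if bin_mode not in BIN_MODES:
        raise ConfigurationError(f"bin_mode must be one of {BIN_MODES}, got {bin_mode!r}")


def _add_months(date: dt.date, k: int) -> dt.date:
    month0 = date.month - 1 + k
    year = date.year + month0 // 12
    month = month0 % 12 + 1
    # clamp the day so e.g. Aug 31 + 6 months lands on Feb 28/29
    last = (dt.date(year + month // 12, month % 12 + 1, 1) - dt.timedelta(days=1)).day
    return dt.date(year, month, min(date.day, last))


def month_of_day(record: RegistryRecord, day: int, bin_mode: str = "calendar") -> int:
    """Month index (0 = diagnosis month) containing ``day`` days after diagnosis."""
    _check_bin_mode(bin_mode)
    if bin_mode == "relative":
        return int(day // DAYS_PER_MONTH)
    d0 = record.diagnosis_date
    if d0 is None:
        raise ConfigurationError(
            f"patient {record.patient_id}: calendar binning requires a jittered "
            "diagnosis date (run jitter_diagnosis_dates first)"
        )
    d = d0 + dt.timedelta(days=int(day))
    return (d.year - d0.year) * 12 + (d.month - d0.month)


def analysis_start_month(record: RegistryRecord, bin_mode: str = "calendar") -> int:
    """First month index whose start is >= diagnosis date + 6 calendar months."""
    _check_bin_mode(bin_mode)
    if bin_mode == "relative":
        return ANALYSIS_START_OFFSET_MONTHS
    d0 = record.diagnosis_date
    if d0 is None:
        raise ConfigurationError(
            f"patient {record.patient_id}: calendar binning requires a jittered "
            "diagnosis date"
        )
    target = _add_months(d0, ANALYSIS_START_OFFSET_MONTHS)
    k = (target.year - d0.year) * 12 + (target.month - d0.month)
    return k if target.day == 1 else k + 1


def assign_valid_window(record: RegistryRecord, bin_mode: str = "calendar") -> ValidWindow:
    """Valid-claims window for one patient, with censoring for competing events.

    An empty window (``end_month < start_month``) flags the patient as
    ineligible; it is a logged outcome, not an error.
    """
    start = analysis_start_month(record, bin_mode)
    end = month_of_day(record, record.followup_end_day, bin_mode)
    if record.nonbreast_primary_day is not None:
        end = min(
            end,
            month_of_day(record, record.nonbreast_primary_day, bin_mode)
            + NONBREAST_PRIMARY_OFFSET,
        )
    if record.second_sbce_day is not None:
        end = min(
            end,
            month_of_day(record, record.second_sbce_day, bin_mode) + SECOND_SBCE_OFFSET,
        )
    sbce_month = (
        month_of_day(record, record.sbce_day, bin_mode)
        if record.sbce_day is not None
        else None
    )
    return ValidWindow(record.patient_id, start, end, sbce_month)


def assign_valid_windows(
    records: Sequence[RegistryRecord], bin_mode: str = "calendar"
) -> dict[str, ValidWindow]:
    return {r.patient_id: assign_valid_window(r, bin_mode) for r in records}


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str


def _as_frame(claims) -> pd.DataFrame:
    return claims if isinstance(claims, pd.DataFrame) else claims_frame(claims)


def _claim_months(
    claims: pd.DataFrame, records: Mapping[str, RegistryRecord], bin_mode: str
) -> pd.Series:
    """Month index of every claim, vectorised per bin mode."""
    if bin_mode == "relative":
        return (claims["day"] // DAYS_PER_MONTH).astype(int)
    d0 = {}
    for pid, rec in records.items():
        date = rec.diagnosis_date
        if date is None:
            raise ConfigurationError(
                f"patient {pid}: calendar binning requires a jittered diagnosis date"
            )
        d0[pid] = date
    base = pd.to_datetime(claims["patient_id"].map(d0))
    dates = base + pd.to_timedelta(claims["day"].astype(int), unit="D")
    return (dates.dt.year - base.dt.year) * 12 + (dates.dt.month - base.dt.month)


def filter_eligible(
    records: Sequence[RegistryRecord],
    windows: Mapping[str, ValidWindow],
    claims,
    bin_mode: str = "calendar",
) -> tuple[list[RegistryRecord], list[Exclusion]]:
    """Drop patients with no in-window claims, and event patients with no claims
    on or after their event day.  Every dropped patient gets a logged reason."""
    _check_bin_mode(bin_mode)
    claims = _as_frame(claims)
    rec_map = {r.patient_id: r for r in records}
    months = _claim_months(claims, rec_map, bin_mode) if len(claims) else pd.Series(dtype=int)
    kept: list[RegistryRecord] = []
    excluded: list[Exclusion] = []
    by_patient = dict(tuple(claims.assign(_month=months).groupby("patient_id", sort=False))) \
        if len(claims) else {}
    for rec in records:
        window = windows[rec.patient_id]
        if window.is_empty:
            excluded.append(Exclusion(rec.patient_id, "empty_window"))
            continue
        sub = by_patient.get(rec.patient_id)
        if sub is None:
            excluded.append(Exclusion(rec.patient_id, "no_claims_in_window"))
            continue
        in_window = sub[
            (sub["_month"] >= window.start_month) & (sub["_month"] <= window.end_month)
        ]
        if in_window.empty:
            excluded.append(Exclusion(rec.patient_id, "no_claims_in_window"))
            continue
        if rec.sbce and not (in_window["day"] >= rec.sbce_day).any():
            excluded.append(Exclusion(rec.patient_id, "no_post_event_claims"))
            continue
        kept.append(rec)
    return kept, excluded


def deduplicate_daily(claims) -> pd.DataFrame:
    """Keep at most one event per (patient, day, system, code); order-independent."""
    claims = _as_frame(claims)
    out = claims.drop_duplicates(subset=["patient_id", "day", "system", "code"])
    return out.sort_values(["patient_id", "day", "system", "code"], kind="mergesort") \
        .reset_index(drop=True)


def filter_rare_codes(
    claims, include_procedures: bool = False
) -> tuple[pd.DataFrame, list[str]]:
    """Drop diagnosis codes never seen on >= 2 distinct days for any one patient.

    The rule is evaluated per code across the whole cohort: a code survives if
    at least one patient has it on two separate days, and a surviving code
    keeps all of its events for all patients.  By default the rule applies to
    diagnosis codes only; ``include_procedures`` extends it to procedures.
    """
    claims = _as_frame(claims)
    if claims.empty:
        return claims.copy(), []
    target = (
        claims["code_class"].isin(("diagnosis", "procedure"))
        if include_procedures
        else claims["code_class"].eq("diagnosis")
    )
    subset = claims[target]
    per = subset.groupby(["code", "patient_id"])["day"].nunique()
    keep_codes = set(per[per >= 2].index.get_level_values("code"))
    all_codes = set(subset["code"])
    dropped = sorted(all_codes - keep_codes)
    mask = ~target | claims["code"].isin(keep_codes)
    return claims[mask].reset_index(drop=True), dropped


@dataclass
class MonthPanel:
    """Per patient x calendar-month x code-group count cube with valid windows."""

    records: dict[str, RegistryRecord]
    windows: dict[str, ValidWindow]
    counts: pd.DataFrame  # columns: patient_id, month_index, group_id, count
    group_ids: list[str]
    n_unmapped_claims: int = 0
    bin_mode: str = "calendar"

    @property
    def patient_ids(self) -> list[str]:
        return list(self.records)

    def patient_counts(self, patient_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(months, counts) for one patient: months = window range, counts is a
        dense (n_groups, n_months) array in ``group_ids`` order."""
        window = self.windows[patient_id]
        months = np.arange(window.start_month, window.end_month + 1)
        mat = np.zeros((len(self.group_ids), len(months)), dtype=np.int64)
        sub = self.counts[self.counts["patient_id"] == patient_id]
        if not sub.empty:
            gpos = {g: i for i, g in enumerate(self.group_ids)}
            gi = sub["group_id"].map(gpos).to_numpy()
            mi = sub["month_index"].to_numpy() - window.start_month
            mat[gi, mi] = sub["count"].to_numpy()
        return months, mat

    def total_count(self) -> int:
        return int(self.counts["count"].sum()) if len(self.counts) else 0


def build_month_panel(
    claims,
    records: Sequence[RegistryRecord],
    windows: Mapping[str, ValidWindow],
    groupmap: CodeGroupMap,
    bin_mode: str = "calendar",
) -> MonthPanel:
    """Map claims to groups and calendar months, keep in-window claims, sum counts.

    Codes absent from the group map are dropped with a logged count; claims
    outside each patient's valid window are discarded.
    """
    _check_bin_mode(bin_mode)
    if not groupmap.entries:
        raise ConfigurationError("empty code-group map")
    claims = _as_frame(claims)
    rec_map = {r.patient_id: r for r in records}
    claims = claims[claims["patient_id"].isin(rec_map)].reset_index(drop=True)

    code_to_group = {c: gid for c, (gid, _) in groupmap.entries.items()}
    group = claims["code"].map(code_to_group)
    n_unmapped = int(group.isna().sum())
    claims = claims.assign(group_id=group).dropna(subset=["group_id"])

    if claims.empty:
        counts = pd.DataFrame(columns=["patient_id", "month_index", "group_id", "count"])
    else:
        months = _claim_months(claims, rec_map, bin_mode)
        claims = claims.assign(month_index=months)
        start = claims["patient_id"].map({p: w.start_month for p, w in windows.items()})
        end = claims["patient_id"].map({p: w.end_month for p, w in windows.items()})
        claims = claims[(claims["month_index"] >= start) & (claims["month_index"] <= end)]
        counts = (
            claims.groupby(["patient_id", "month_index", "group_id"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
    return MonthPanel(
        records={r.patient_id: r for r in records},
        windows={r.patient_id: windows[r.patient_id] for r in records},
        counts=counts,
        group_ids=groupmap.group_ids,
        n_unmapped_claims=n_unmapped,
        bin_mode=bin_mode,
    )
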