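"""Domain types, validation, and CSV I/O for registry-linked claims cohorts.

The data model mirrors a deidentified registry/claims linkage: every temporal
quantity is stored as *days since the primary diagnosis* (day 0).  Calendar
placement exists only through a synthetic "jitter" — a randomly drawn month and
day of diagnosis within the recorded diagnosis year — which is used solely to
bin claims into calendar months.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STAGES = ("I", "II")
SYSTEMS = ("ICD9CM", "CPT", "HCPCS")
CODE_CLASSES = ("diagnosis", "procedure")
RECEPTOR_LEVELS = ("positive", "negative", "unknown")

#: coding system -> the code class it is allowed to carry
SYSTEM_CLASS = {"ICD9CM": "diagnosis", "CPT": "procedure", "HCPCS": "procedure"}

REGISTRY_COLUMNS = [
    "patient_id",
    "diagnosis_year",
    "age_at_diagnosis",
    "stage",
    "grade",
    "er_status",
    "pr_status",
    "site",
    "sbce",
    "sbce_day",
    "second_sbce_day",
    "nonbreast_primary_day",
    "followup_end_day",
    "jitter_month",
    "jitter_day",
]

CLAIMS_COLUMNS = ["patient_id", "day", "system", "code", "code_class"]
GROUPMAP_COLUMNS = ["code", "group_id", "code_class"]


class SchemaError(ValueError):
    """A required column is missing or a file is structurally unreadable."""


class ConfigurationError(ValueError):
    """An operation was invoked with an inconsistent or empty configuration."""


@dataclass(frozen=True)
class ValidationIssue:
    """One rejected input row, with enough context to find it again."""

    row: int
    patient_id: str
    message: str


@dataclass
class RegistryRecord:
    """One patient: baseline covariates plus gold-standard event/censoring days.

    ``sbce_day`` is the chart-abstracted day of the first second breast cancer
    event (recurrence or second breast primary); ``second_sbce_day`` is a
    subsequent breast event used only for censoring; ``nonbreast_primary_day``
    is a non-breast second primary, also a censoring event.
    """

    patient_id: str
    diagnosis_year: int
    age_at_diagnosis: float
    stage: str
    grade: str
    er_status: str
    pr_status: str
    site: str
    sbce: bool
    followup_end_day: int
    sbce_day: int | None = None
    second_sbce_day: int | None = None
    nonbreast_primary_day: int | None = None
    jitter_month: int | None = None
    jitter_day: int | None = None

    #: day index of the primary diagnosis; all claim days are relative to it
    diagnosis_day: int = field(default=0, init=False, repr=False)

    @property
    def diagnosis_date(self) -> dt.date | None:
        """Jittered calendar date of diagnosis, or None before jittering."""
        if self.jitter_month is None or self.jitter_day is None:
            return None
        return dt.date(self.diagnosis_year, self.jitter_month, self.jitter_day)

    def validate(self) -> list[str]:
        problems: list[str] = []
        if not self.patient_id:
            problems.append("patient_id is empty")
        if not 1800 <= self.diagnosis_year <= 2100:
            problems.append(f"implausible diagnosis_year {self.diagnosis_year}")
        if not 0 < self.age_at_diagnosis < 120:
            problems.append(f"implausible age_at_diagnosis {self.age_at_diagnosis}")
        if self.stage not in STAGES:
            problems.append(f"stage {self.stage!r} not in {STAGES}")
        for name, val in (("er_status", self.er_status), ("pr_status", self.pr_status)):
            if val not in RECEPTOR_LEVELS:
                problems.append(f"{name} {val!r} not in {RECEPTOR_LEVELS}")
        if self.sbce and self.sbce_day is None:
            problems.append("sbce is true but sbce_day is absent")
        if not self.sbce and self.sbce_day is not None:
            problems.append("sbce is false but sbce_day is present")
        if self.sbce_day is not None and self.sbce_day <= self.diagnosis_day:
            problems.append("sbce_day must follow the diagnosis day")
        if (
            self.second_sbce_day is not None
            and self.sbce_day is not None
            and self.second_sbce_day <= self.sbce_day
        ):
            problems.append("second_sbce_day must follow sbce_day")
        if self.followup_end_day < self.diagnosis_day:
            problems.append("followup_end_day precedes the diagnosis day")
        return problems


@dataclass(frozen=True)
class ClaimEvent:
    """One coded claim line on one day for one patient."""

    patient_id: str
    day: int
    system: str
    code: str
    code_class: str

    def validate(self) -> list[str]:
        problems: list[str] = []
        if self.day < 0:
            problems.append(f"day {self.day} is negative")
        if not self.code:
            problems.append("code is empty")
        if self.system not in SYSTEMS:
            problems.append(f"unsupported coding system {self.system!r}")
        elif SYSTEM_CLASS[self.system] != self.code_class:
            problems.append(
                f"system {self.system} carries {SYSTEM_CLASS[self.system]} codes, "
                f"not {self.code_class!r}"
            )
        return problems


@dataclass
class CodeGroupMap:
    """Mapping code -> (group_id, code_class).

    The production map in the source setting was a fine grouping with 77
    diagnostic and 156 procedure code groups; the map is user-supplied and any
    consistent grouping may be used.
    """

    entries: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for code, (gid, cls) in self.entries.items():
            if cls not in CODE_CLASSES:
                raise ConfigurationError(f"group {gid}: bad code_class {cls!r}")
        classes: dict[str, str] = {}
        for code, (gid, cls) in self.entries.items():
            if classes.setdefault(gid, cls) != cls:
                raise ConfigurationError(f"group {gid} mixes code classes")

    @property
    def group_ids(self) -> list[str]:
        return sorted({gid for gid, _ in self.entries.values()})

    @property
    def n_diagnosis_groups(self) -> int:
        return len({g for g, c in self.entries.values() if c == "diagnosis"})

    @property
    def n_procedure_groups(self) -> int:
        return len({g for g, c in self.entries.values() if c == "procedure"})

    def group_of(self, code: str) -> tuple[str, str] | None:
        return self.entries.get(code)


@dataclass
class ValidWindow:
    """Per-patient analysis interval, in month indices from the diagnosis month."""

    patient_id: str
    start_month: int
    end_month: int
    sbce_month: int | None = None

    @property
    def is_empty(self) -> bool:
        return self.end_month < self.start_month

    @property
    def months(self) -> range:
        return range(self.start_month, self.end_month + 1)


@dataclass
class ReadResult:
    """Parsed rows plus per-row rejections; parsed + rejected = input rows."""

    records: list
    issues: list[ValidationIssue]
    n_rows: int


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _require_columns(fieldnames: Sequence[str] | None, required: Iterable[str], path) -> None:
    present = set(fieldnames or [])
    for col in required:
        if col not in present:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _opt_int(value: str | None) -> int | None:
    if value is None or value == "":
        return None
    return int(value)


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "true", "t", "yes"):
        return True
    if v in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def read_registry(path: str | Path) -> ReadResult:
    """Read registry CSV; invalid rows are collected, never silently dropped."""
    required = [c for c in REGISTRY_COLUMNS if c not in ("jitter_month", "jitter_day")]
    records: list[RegistryRecord] = []
    issues: list[ValidationIssue] = []
    n_rows = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, required, path)
        for lineno, row in enumerate(reader, start=2):
            n_rows += 1
            pid = (row.get("patient_id") or "").strip()
            try:
                rec = RegistryRecord(
                    patient_id=pid,
                    diagnosis_year=int(row["diagnosis_year"]),
                    age_at_diagnosis=float(row["age_at_diagnosis"]),
                    stage=row["stage"].strip(),
                    grade=row["grade"].strip(),
                    er_status=row["er_status"].strip(),
                    pr_status=row["pr_status"].strip(),
                    site=row["site"].strip(),
                    sbce=_parse_bool(row["sbce"]),
                    followup_end_day=int(row["followup_end_day"]),
                    sbce_day=_opt_int(row.get("sbce_day")),
                    second_sbce_day=_opt_int(row.get("second_sbce_day")),
                    nonbreast_primary_day=_opt_int(row.get("nonbreast_primary_day")),
                    jitter_month=_opt_int(row.get("jitter_month")),
                    jitter_day=_opt_int(row.get("jitter_day")),
                )
            except (ValueError, KeyError) as exc:
                issues.append(ValidationIssue(lineno, pid, f"unparseable row: {exc}"))
                continue
            problems = rec.validate()
            if problems:
                for msg in problems:
                    issues.append(ValidationIssue(lineno, pid, msg))
                continue
            records.append(rec)
    return ReadResult(records, issues, n_rows)


def write_registry(records: Iterable[RegistryRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REGISTRY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.diagnosis_year,
                    repr(r.age_at_diagnosis),
                    r.stage,
                    r.grade,
                    r.er_status,
                    r.pr_status,
                    r.site,
                    int(r.sbce),
                    "" if r.sbce_day is None else r.sbce_day,
                    "" if r.second_sbce_day is None else r.second_sbce_day,
                    "" if r.nonbreast_primary_day is None else r.nonbreast_primary_day,
                    r.followup_end_day,
                    "" if r.jitter_month is None else r.jitter_month,
                    "" if r.jitter_day is None else r.jitter_day,
                ]
            )


def read_claims(path: str | Path) -> ReadResult:
    records: list[ClaimEvent] = []
    issues: list[ValidationIssue] = []
    n_rows = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, CLAIMS_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            n_rows += 1
            pid = (row.get("patient_id") or "").strip()
            try:
                ev = ClaimEvent(
                    patient_id=pid,
                    day=int(row["day"]),
                    system=row["system"].strip(),
                    code=row["code"].strip(),
                    code_class=row["code_class"].strip(),
                )
            except ValueError as exc:
                issues.append(ValidationIssue(lineno, pid, f"unparseable row: {exc}"))
                continue
            problems = ev.validate()
            if problems:
                for msg in problems:
                    issues.append(ValidationIssue(lineno, pid, msg))
                continue
            records.append(ev)
    return ReadResult(records, issues, n_rows)


def write_claims(events: Iterable[ClaimEvent] | pd.DataFrame, path: str | Path) -> None:
    frame = events if isinstance(events, pd.DataFrame) else claims_frame(events)
    frame.to_csv(path, index=False, columns=CLAIMS_COLUMNS)


def claims_frame(events: Iterable[ClaimEvent]) -> pd.DataFrame:
    """Tabular view of a claim list (the in-memory working representation)."""
    rows = [(e.patient_id, e.day, e.system, e.code, e.code_class) for e in events]
    return pd.DataFrame(rows, columns=CLAIMS_COLUMNS)


def claims_from_frame(frame: pd.DataFrame) -> list[ClaimEvent]:
    return [
        ClaimEvent(r.patient_id, int(r.day), r.system, r.code, r.code_class)
        for r in frame.itertuples(index=False)
    ]


def read_groupmap(path: str | Path) -> CodeGroupMap:
    entries: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, GROUPMAP_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            code = row["code"].strip()
            if code in entries:
                raise SchemaError(f"{path}:{lineno}: duplicate code {code!r}")
            entries[code] = (row["group_id"].strip(), row["code_class"].strip())
    return CodeGroupMap(entries)


def write_groupmap(groupmap: CodeGroupMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GROUPMAP_COLUMNS)
        for code in sorted(groupmap.entries):
            gid, cls = groupmap.entries[code]
            writer.writerow([code, gid, cls])


# ---------------------------------------------------------------------------
# Diagnosis-date jitter
# ---------------------------------------------------------------------------

def jitter_diagnosis_dates(
    records: Sequence[RegistryRecord], seed: int
) -> list[RegistryRecord]:
    """Assign each patient a uniform random day-of-year within the diagnosis year.

    The jittered date places the deidentified day-offset data on a calendar
    grid for calendar-month binning.  The fractional part of age at diagnosis
    is redrawn uniformly, since the true birthday offset is not recoverable
    from deidentified data.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: list[RegistryRecord] = []
    for rec in records:
        year = rec.diagnosis_year
        n_days = 366 if dt.date(year, 12, 31).timetuple().tm_yday == 366 else 365
        doy = int(rng.integers(1, n_days + 1))
        date = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
        frac = float(rng.random())
        out.append(
            replace(
                rec,
                jitter_month=date.month,
                jitter_day=date.day,
                age_at_diagnosis=float(int(rec.age_at_diagnosis)) + frac,
            )
        )
    return out
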