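"""Shared fixtures: tiny hand-built cohorts and reusable pipeline runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from recurmine.cohort import CodeGroupMap, RegistryRecord, ValidWindow
from recurmine.pipeline import RunConfig, run_all
from recurmine.preprocess import MonthPanel
from recurmine.simulate import SimConfig

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_record(
    pid: str = "P1",
    sbce_day: int | None = None,
    followup_end_day: int = 1500,
    **kwargs,
) -> RegistryRecord:
    defaults = dict(
        diagnosis_year=2000,
        age_at_diagnosis=60.0,
        stage="I",
        grade="2",
        er_status="positive",
        pr_status="positive",
        site="C504",
    )
    defaults.update(kwargs)
    return RegistryRecord(
        patient_id=pid,
        sbce=sbce_day is not None,
        sbce_day=sbce_day,
        followup_end_day=followup_end_day,
        **defaults,
    )


def make_panel(
    spec: dict[str, tuple[int, int, int | None]],
    counts: list[tuple[str, int, str, int]],
    group_ids: list[str],
    records: dict[str, RegistryRecord] | None = None,
) -> MonthPanel:
    """Build a MonthPanel directly.

    ``spec`` maps patient_id -> (start_month, end_month, sbce_month or None);
    ``counts`` is a list of (patient_id, month_index, group_id, count).
    """
    if records is None:
        records = {}
        for pid, (_, end, sbce_month) in spec.items():
            sbce_day = None if sbce_month is None else int(sbce_month * 30.4375) + 5
            records[pid] = make_record(
                pid, sbce_day=sbce_day, followup_end_day=int((end + 1) * 30.4375)
            )
    windows = {
        pid: ValidWindow(pid, start, end, sbce_month)
        for pid, (start, end, sbce_month) in spec.items()
    }
    frame = pd.DataFrame(counts, columns=["patient_id", "month_index", "group_id", "count"])
    return MonthPanel(
        records=records,
        windows=windows,
        counts=frame,
        group_ids=list(group_ids),
        bin_mode="relative",
    )


def random_panel(rng: np.random.Generator) -> MonthPanel:
    """A random small panel for oracle-equivalence checks."""
    n_patients = int(rng.integers(1, 9))
    n_groups = int(rng.integers(1, 6))
    group_ids = [f"G{i}" for i in range(n_groups)]
    spec = {}
    counts = []
    for p in range(n_patients):
        pid = f"P{p}"
        start = int(rng.integers(6, 10))
        length = int(rng.integers(1, 25))
        end = start + length - 1
        sbce_month = (
            int(rng.integers(start, end + 1)) if rng.random() < 0.5 else None
        )
        spec[pid] = (start, end, sbce_month)
        for m in range(start, end + 1):
            for g in group_ids:
                c = int(rng.poisson(0.4))
                if c:
                    counts.append((pid, m, g, c))
    return make_panel(spec, counts, group_ids)


@pytest.fixture(scope="session")
def signal_run():
    """Default-signal synthetic cohort pushed through the whole pipeline."""
    return run_all(RunConfig(seed=1, sim=SimConfig(n_patients=600)))


@pytest.fixture(scope="session")
def null_run():
    """No-signal cohort (unit multipliers, unit hazard ratios) end to end."""
    return run_all(RunConfig(seed=2, sim=SimConfig.null(n_patients=600)))


@pytest.fixture(scope="session")
def calibration_registry():
    """Large registry-only draw for simulator calibration checks."""
    from recurmine.simulate import simulate_registry

    return simulate_registry(SimConfig(n_patients=3000, seed=1))


@pytest.fixture()
def tiny_groupmap() -> CodeGroupMap:
    return CodeGroupMap(
        {
            "D01A": ("DG01", "diagnosis"),
            "D01B": ("DG01", "diagnosis"),
            "D02A": ("DG02", "diagnosis"),
            "P01A": ("PG01", "procedure"),
            "P02A": ("PG02", "procedure"),
        }
    )
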