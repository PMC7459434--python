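"""Synthetic registry + claims cohorts with the structure the method assumes.

The generator is discrete-time (monthly), matching the pipeline's resolution:

* a second-breast-event month is drawn from a geometrically decaying monthly
  hazard, multiplicatively modulated by stage II and negative hormone-receptor
  status, with the baseline root-found so the covariate-mixture cumulative
  incidence hits a configured target (default 0.25 by month 168);
* follow-up lengths are gamma-distributed, matched to observed claim-month
  summaries (non-event mean 31.5 / SD 19.2 months); event patients get extra
  post-event follow-up, which makes their records longer on average;
* each code group emits Poisson monthly counts; designated "signal" groups
  carry a diagnostic-workup bump shortly before the event month and an
  elevated, geometrically decaying intensity from the event month onward
  (imaging/biopsy before, treatment signature after);
* monthly counts are expanded to day-level coded claims so the preprocessing
  stack (deduplication, rare-code filtering, grouping, binning) is exercised
  end to end.

``SimConfig.null()`` removes every association between the event and the
data (unit intensity multipliers, unit hazard ratios), giving a cohort where
claims carry no event signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import (
    ClaimEvent,
    CodeGroupMap,
    ConfigurationError,
    RegistryRecord,
    CLAIMS_COLUMNS,
)
from .preprocess import DAYS_PER_MONTH, assign_valid_windows, _claim_months


class CalibrationError(ValueError):
    """The configured cumulative-incidence target cannot be reached."""


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the calibration summaries of the
    study cohort (event probability, follow-up moments, signal shape)."""

    n_patients: int = 600
    seed: int = 0

    # --- event model ---------------------------------------------------
    sbce_cumulative_target: float = 0.25
    horizon_months: int = 168
    hazard_decay: float = 0.94          # geometric decay of the monthly hazard
    first_event_month: int = 7          # no events before the analysis window
    hr_stage_ii: float = 2.0
    hr_er_negative: float = 1.6
    hr_pr_negative: float = 1.3

    # --- covariate mix --------------------------------------------------
    p_stage_ii: float = 0.30
    p_er_negative: float = 0.15
    p_er_unknown: float = 0.05
    p_pr_negative: float = 0.20
    p_pr_unknown: float = 0.08

    # --- follow-up model (claim-months inside the valid window) --------
    followup_mean: float = 31.5
    followup_sd: float = 19.2
    followup_min: int = 1
    followup_max: int = 149
    post_event_mean: float = 19.0
    post_event_sd: float = 12.0

    # --- code groups and claim intensities ------------------------------
    n_dx_groups: int = 8
    n_px_groups: int = 12
    codes_per_group: int = 2
    signal_dx_groups: int = 2
    signal_px_groups: int = 3
    baseline_rate_cycle: tuple = (0.6, 0.4, 0.25, 0.15)
    signal_rate: float = 0.12

    # --- event signature -------------------------------------------------
    pre_window: int = 2                 # workup bump, months before the event
    pre_multiplier: float = 3.0
    post_multiplier: float = 8.0
    post_decay: float = 0.9             # geometric decay of the post-event excess

    # --- competing / subsequent events ----------------------------------
    p_nonbreast_primary: float = 0.02
    p_second_sbce: float = 0.10

    diagnosis_year_range: tuple = (1993, 2006)

    @classmethod
    def null(cls, **kwargs) -> "SimConfig":
        """A no-signal cohort: event independent of claims and covariates."""
        return cls(
            pre_multiplier=1.0,
            post_multiplier=1.0,
            hr_stage_ii=1.0,
            hr_er_negative=1.0,
            hr_pr_negative=1.0,
            **kwargs,
        )


@dataclass
class SimulatedCohort:
    records: list[RegistryRecord]
    claims: pd.DataFrame
    groupmap: CodeGroupMap


# ---------------------------------------------------------------------------
# hazard calibration
# ---------------------------------------------------------------------------

def _covariate_combos(config: SimConfig) -> list[tuple[float, float]]:
    """(probability, hazard ratio) over the stage x ER x PR mixture."""
    stage = [(1 - config.p_stage_ii, 1.0), (config.p_stage_ii, config.hr_stage_ii)]
    er = [
        (1 - config.p_er_negative - config.p_er_unknown, 1.0),
        (config.p_er_negative, config.hr_er_negative),
        (config.p_er_unknown, 1.0),
    ]
    pr = [
        (1 - config.p_pr_negative - config.p_pr_unknown, 1.0),
        (config.p_pr_negative, config.hr_pr_negative),
        (config.p_pr_unknown, 1.0),
    ]
    combos = []
    for ps, hs in stage:
        for pe, he in er:
            for pp, hp in pr:
                combos.append((ps * pe * pp, hs * he * hp))
    return combos


def _cumulative_incidence(a: float, hr: float, config: SimConfig, horizon: int) -> float:
    m = np.arange(config.first_event_month, horizon + 1)
    h = np.minimum(a * config.hazard_decay ** m * hr, 0.95)
    return 1.0 - float(np.prod(1.0 - h))


def calibrate_baseline_hazard(config: SimConfig) -> float:
    """Root-find the baseline so the mixture cumulative incidence at the
    horizon equals the configured target."""
    combos = _covariate_combos(config)

    def f(a: float) -> float:
        mix = sum(
            p * _cumulative_incidence(a, hr, config, config.horizon_months)
            for p, hr in combos
        )
        return mix - config.sbce_cumulative_target

    lo, hi = 1e-10, 0.01
    while f(hi) < 0:
        hi *= 2
        if hi > 1e4:
            raise CalibrationError(
                f"cumulative incidence target {config.sbce_cumulative_target} "
                f"unreachable by month {config.horizon_months} "
                f"(decay {config.hazard_decay})"
            )
    return float(brentq(f, lo, hi, xtol=1e-12))


def _survival_curve(a: float, hr: float, config: SimConfig, max_month: int) -> np.ndarray:
    """S(m) for m = 0..max_month under the capped geometric-decay hazard."""
    h = np.zeros(max_month + 1)
    m = np.arange(config.first_event_month, max_month + 1)
    h[m] = np.minimum(a * config.hazard_decay ** m * hr, 0.95)
    return np.cumprod(1.0 - h)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def default_groupmap(config: SimConfig) -> CodeGroupMap:
    """Synthetic group map: DGxx diagnosis groups (ICD-9-CM style codes) and
    PGxx procedure groups (CPT/HCPCS style codes)."""
    entries: dict[str, tuple[str, str]] = {}
    letters = "ABCDEFGH"
    for g in range(config.n_dx_groups):
        gid = f"DG{g + 1:02d}"
        for c in range(config.codes_per_group):
            entries[f"D{g + 1:02d}{letters[c]}"] = (gid, "diagnosis")
    for g in range(config.n_px_groups):
        gid = f"PG{g + 1:02d}"
        for c in range(config.codes_per_group):
            entries[f"P{g + 1:02d}{letters[c]}"] = (gid, "procedure")
    return CodeGroupMap(entries)


def _group_layout(config: SimConfig):
    """Per-group (group_id, code_class, system, rate, is_signal) in a fixed order."""
    layout = []
    cycle = config.baseline_rate_cycle
    for g in range(config.n_dx_groups):
        signal = g < config.signal_dx_groups
        rate = config.signal_rate if signal else cycle[g % len(cycle)]
        layout.append((f"DG{g + 1:02d}", "diagnosis", "ICD9CM", rate, signal))
    for g in range(config.n_px_groups):
        signal = g < config.signal_px_groups
        rate = config.signal_rate if signal else cycle[g % len(cycle)]
        system = "CPT" if g % 2 == 0 else "HCPCS"
        layout.append((f"PG{g + 1:02d}", "procedure", system, rate, signal))
    return layout


def simulate_registry(config: SimConfig) -> list[RegistryRecord]:
    """Registry records only (covariates, event and censoring days); claims
    can be generated separately for the same seed via simulate_cohort."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    a = calibrate_baseline_hazard(config)
    max_month = 600
    curves: dict[float, np.ndarray] = {}
    w_shape, w_scale = _gamma_params(config.followup_mean, config.followup_sd)
    p_shape, p_scale = _gamma_params(config.post_event_mean, config.post_event_sd)

    records: list[RegistryRecord] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        stage = "II" if rng.random() < config.p_stage_ii else "I"
        u = rng.random()
        er = ("negative" if u < config.p_er_negative
              else "unknown" if u < config.p_er_negative + config.p_er_unknown
              else "positive")
        u = rng.random()
        pr = ("negative" if u < config.p_pr_negative
              else "unknown" if u < config.p_pr_negative + config.p_pr_unknown
              else "positive")
        grade = str(1 + rng.choice(3, p=[0.30, 0.45, 0.25]))
        site = ["C504", "C508", "C502"][rng.choice(3, p=[0.5, 0.3, 0.2])]
        age = float(int(np.clip(rng.normal(61.0, 11.0), 25, 95)))
        year = int(rng.integers(config.diagnosis_year_range[0],
                                config.diagnosis_year_range[1] + 1))

        hr = 1.0
        if stage == "II":
            hr *= config.hr_stage_ii
        if er == "negative":
            hr *= config.hr_er_negative
        if pr == "negative":
            hr *= config.hr_pr_negative
        if hr not in curves:
            curves[hr] = _survival_curve(a, hr, config, max_month)
        surv = curves[hr]
        u = rng.random()
        below = np.nonzero(1.0 - surv >= u)[0]
        latent_event = int(below[0]) if below.size else None

        window_months = int(np.clip(round(rng.gamma(w_shape, w_scale)),
                                    config.followup_min, config.followup_max))
        end_base = 5 + window_months  # window [6, end_base]

        sbce = latent_event is not None and latent_event <= end_base
        sbce_day = None
        second_sbce_day = None
        nonbreast_day = None
        end_month = end_base
        if sbce:
            T = latent_event
            post = int(np.clip(round(rng.gamma(p_shape, p_scale)), 1, 60))
            end_month = min(max(end_base, T + post), 5 + config.followup_max)
            sbce_day = int(T * DAYS_PER_MONTH + rng.integers(1, 28))
            if rng.random() < config.p_second_sbce:
                gap = int(rng.integers(2, 24))
                ss_month = T + gap
                second_sbce_day = int(ss_month * DAYS_PER_MONTH + rng.integers(1, 28))
        elif rng.random() < config.p_nonbreast_primary:
            nb_month = int(rng.integers(8, max(9, end_base + 4)))
            nonbreast_day = int(nb_month * DAYS_PER_MONTH + rng.integers(1, 28))

        followup_end_day = int((end_month + 1) * DAYS_PER_MONTH) - 1
        records.append(
            RegistryRecord(
                patient_id=pid,
                diagnosis_year=year,
                age_at_diagnosis=age,
                stage=stage,
                grade=grade,
                er_status=er,
                pr_status=pr,
                site=site,
                sbce=sbce,
                followup_end_day=followup_end_day,
                sbce_day=sbce_day,
                second_sbce_day=second_sbce_day,
                nonbreast_primary_day=nonbreast_day,
            )
        )
    return records


def _event_month(record: RegistryRecord) -> int | None:
    if record.sbce_day is None:
        return None
    return int(record.sbce_day // DAYS_PER_MONTH)


def simulate_claims(records: Sequence[RegistryRecord], config: SimConfig) -> pd.DataFrame:
    """Day-level coded claims for simulated registry records."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    layout = _group_layout(config)
    n_groups = len(layout)
    rates = np.array([r for _, _, _, r, _ in layout])
    signal = np.array([s for _, _, _, _, s in layout])
    letters = "ABCDEFGH"
    group_codes = [
        [f"{'D' if cls == 'diagnosis' else 'P'}{int(gid[2:]):02d}{letters[c]}"
         for c in range(config.codes_per_group)]
        for gid, cls, _, _, _ in layout
    ]
    systems = [sys for _, _, sys, _, _ in layout]
    classes = [cls for _, cls, _, _, _ in layout]

    frames: list[pd.DataFrame] = []
    for rec in records:
        end_month = int(rec.followup_end_day // DAYS_PER_MONTH)
        months = np.arange(1, end_month + 1)
        rate = np.tile(rates[:, None], (1, len(months))).astype(float)
        T = _event_month(rec)
        if T is not None:
            rel = months - T
            pre = (rel >= -config.pre_window) & (rel < 0)
            rate[np.ix_(signal, np.nonzero(pre)[0])] *= config.pre_multiplier
            post = rel >= 0
            if post.any():
                mult = 1.0 + (config.post_multiplier - 1.0) * (
                    config.post_decay ** rel[post]
                )
                rate[np.ix_(signal, np.nonzero(post)[0])] *= mult
        counts = rng.poisson(rate)
        gi, mi = np.nonzero(counts)
        if gi.size == 0:
            continue
        reps = counts[gi, mi]
        g_idx = np.repeat(gi, reps)
        month_idx = np.repeat(months[mi], reps)
        days = (month_idx * DAYS_PER_MONTH
                + rng.uniform(0, DAYS_PER_MONTH, size=g_idx.size)).astype(int)
        code_pick = rng.integers(0, config.codes_per_group, size=g_idx.size)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": rec.patient_id,
                    "day": days,
                    "system": [systems[g] for g in g_idx],
                    "code": [group_codes[g][c] for g, c in zip(g_idx, code_pick)],
                    "code_class": [classes[g] for g in g_idx],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CLAIMS_COLUMNS)
    claims = pd.concat(frames, ignore_index=True)
    return claims.sort_values(["patient_id", "day", "system", "code"],
                              kind="mergesort").reset_index(drop=True)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Full synthetic cohort: registry, day-level claims, and group map.
    Deterministic given ``config.seed``."""
    records = simulate_registry(config)
    claims = simulate_claims(records, config)
    return SimulatedCohort(records, claims, default_groupmap(config))


# ---------------------------------------------------------------------------
# cohort description
# ---------------------------------------------------------------------------

def _stats(values: np.ndarray) -> dict:
    if values.size == 0:
        return {"n": 0, "mean": None, "median": None, "sd": None,
                "min": None, "max": None}
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "min": float(values.min()),
        "max": float(values.max()),
    }


def describe_cohort(
    records: Sequence[RegistryRecord],
    claims: pd.DataFrame | None = None,
    bin_mode: str = "relative",
) -> dict:
    """Claim-month summaries per event stratum, event fraction, code counts —
    the summaries used to calibrate and sanity-check the generator."""
    if not records:
        return {"n_patients": 0, "sbce_fraction": None, "strata": {}}
    windows = assign_valid_windows(records, bin_mode)
    rec_map = {r.patient_id: r for r in records}
    claim_months: dict[str, int] = {}
    if claims is not None and len(claims):
        months = _claim_months(claims, rec_map, bin_mode)
        tagged = claims.assign(_month=months)
        for pid, sub in tagged.groupby("patient_id", sort=False):
            w = windows.get(pid)
            if w is None or w.is_empty:
                continue
            inside = sub[(sub["_month"] >= w.start_month) & (sub["_month"] <= w.end_month)]
            n = int(inside["_month"].nunique())
            if n:
                claim_months[pid] = n
    else:
        for pid, w in windows.items():
            if not w.is_empty:
                claim_months[pid] = w.end_month - w.start_month + 1

    described = [r for r in records if r.patient_id in claim_months]
    out: dict = {
        "n_patients": len(described),
        "sbce_fraction": (
            float(np.mean([r.sbce for r in described])) if described else None
        ),
        "strata": {},
    }
    for label, flag in (("non_sbce", False), ("sbce", True)):
        vals = np.array(
            [claim_months[r.patient_id] for r in described if r.sbce == flag],
            dtype=float,
        )
        out["strata"][label] = _stats(vals)
    if claims is not None and len(claims):
        out["unique_diagnosis_codes"] = int(
            claims.loc[claims["code_class"] == "diagnosis", "code"].nunique()
        )
        out["unique_procedure_codes"] = int(
            claims.loc[claims["code_class"] == "procedure", "code"].nunique()
        )
    return out
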