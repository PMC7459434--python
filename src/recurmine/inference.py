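"""Person-level calls from month-level probability series.

A patient is called positive at a probability threshold PT if *any* month's
predicted probability strictly exceeds PT.  Two timing rules are provided:

* ``first_exceed`` — earliest month whose probability exceeds PT;
* ``max_increase`` — month of the largest increase in predicted probability
  between adjacent months (earliest maximiser on ties).

``first_exceed`` is the default; outputs record which rule produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TIMING_METHODS = ("first_exceed", "max_increase")


def default_grid() -> list[float]:
    """Probability thresholds 0.10, 0.15, ..., 0.75."""
    return [round(0.10 + 0.05 * i, 2) for i in range(14)]


@dataclass
class ThresholdConfig:
    grid: list[float] = field(default_factory=default_grid)
    timing_method: str = "first_exceed"

    def __post_init__(self) -> None:
        if self.timing_method not in TIMING_METHODS:
            raise ValueError(f"timing_method must be one of {TIMING_METHODS}")
        if not self.grid:
            raise ValueError("threshold grid is empty")
        if any(not 0.0 < t < 1.0 for t in self.grid):
            raise ValueError("thresholds must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("thresholds must be strictly increasing")


@dataclass(frozen=True)
class PersonPrediction:
    patient_id: str
    threshold: float
    predicted_sbce: bool
    predicted_month: int | None
    timing_method: str


def classify_person(probs: Sequence[float], threshold: float) -> bool:
    """True iff any month-level probability strictly exceeds the threshold."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("empty probability series")
    return bool(probs.max() > threshold)


def predict_event_month(
    months: Sequence[int],
    probs: Sequence[float],
    threshold: float,
    method: str = "first_exceed",
) -> int:
    """Predicted event month for a patient already classified positive."""
    months = np.asarray(months, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if months.shape != probs.shape or months.size == 0:
        raise ValueError("months and probs must be equal-length, nonempty")
    if not classify_person(probs, threshold):
        raise ValueError("predict_event_month called for a negative classification")
    if method == "first_exceed":
        return int(months[np.argmax(probs > threshold)])
    if method == "max_increase":
        if probs.size == 1:
            return int(months[0])  # no adjacent pair; the single month stands
        deltas = np.diff(probs)
        return int(months[int(np.argmax(deltas)) + 1])
    raise ValueError(f"unknown timing method {method!r}")


def threshold_sweep(
    all_series: Mapping[str, tuple[Sequence[int], Sequence[float]]],
    config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Person-level predictions for every (patient, threshold) pair.

    ``all_series`` maps patient_id -> (months, probabilities) over the
    patient's valid window, months ascending.
    """
    config = config or ThresholdConfig()
    rows = []
    for pid in sorted(all_series):
        months, probs = all_series[pid]
        for t in config.grid:
            positive = classify_person(probs, t)
            month = (
                predict_event_month(months, probs, t, config.timing_method)
                if positive
                else None
            )
            rows.append((pid, t, positive, month, config.timing_method))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "threshold", "predicted_sbce", "predicted_month",
                 "timing_method"],
    )
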