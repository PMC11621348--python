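"""Personalized relative glucose tertiles.

Each patient's observed glucose range [g_min, g_max] is split into three
equal-width thirds: low on [g_min, b1), medium on [b1, b2), high on
[b2, g_max]. The partition is per-patient ("relative"), so two patients
whose profiles differ only by an affine shift receive identical level
sequences. The default computes one range per patient over the full
recording; a per-calendar-day mode recomputes the range daily for
sensitivity analysis. Equal-width division of the range is the construction
used here; quantile (equal-count) tertiles are deliberately not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import GlucoseSeries, ValidationError
from .window_features import impute_glucose

#: Minimum number of non-missing CGM samples needed to define a range.
MIN_SAMPLES = 12

LEVELS = ("low", "medium", "high")
MISSING = "missing"


@dataclass
class TertileBounds:
    """Equal-width tertile boundaries of one patient's glucose range.

    For mode "per_day", ``daily`` maps day index (int, floor(t/86400)) to
    (g_min, b1, b2, g_max) tuples and the top-level bounds hold the
    recording-wide fallback.
    """

    patient_id: str
    g_min: float
    b1: float
    b2: float
    g_max: float
    mode: str = "recording"
    daily: dict = field(default_factory=dict)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.g_min, self.b1, self.b2, self.g_max)


def _equal_width_bounds(values: np.ndarray) -> tuple[float, float, float, float]:
    g_min = float(np.min(values))
    g_max = float(np.max(values))
    if g_max <= g_min:
        raise ValidationError("degenerate glucose range")
    width = (g_max - g_min) / 3.0
    return g_min, g_min + width, g_min + 2 * width, g_max


def compute_tertile_bounds(
    glucose: GlucoseSeries, mode: str = "recording", impute: bool = True
) -> TertileBounds:
    """Equal-width thirds of the patient's observed glucose range.

    The range is taken from the (short-gap imputed) CGM samples, either over
    the whole recording or per calendar day.
    """
    if mode not in ("recording", "per_day"):
        raise ValidationError(f"unknown tertile mode {mode!r}")
    g = impute_glucose(glucose.glucose_mgdl) if impute else glucose.glucose_mgdl
    finite = np.isfinite(g)
    if finite.sum() < MIN_SAMPLES:
        raise ValidationError(
            f"patient {glucose.patient_id}: need >= {MIN_SAMPLES} glucose samples, "
            f"have {int(finite.sum())}"
        )
    g_min, b1, b2, g_max = _equal_width_bounds(g[finite])
    bounds = TertileBounds(glucose.patient_id, g_min, b1, b2, g_max, mode=mode)
    if mode == "per_day":
        days = np.floor(glucose.timestamps / 86400.0).astype(int)
        for day in np.unique(days):
            sel = (days == day) & finite
            if sel.sum() >= MIN_SAMPLES:
                try:
                    bounds.daily[int(day)] = _equal_width_bounds(g[sel])
                except ValidationError:
                    pass  # constant day falls back to recording-wide bounds
    return bounds


def assign_tertile(value: float, bounds: TertileBounds, time_s: float | None = None) -> str:
    """Map one glucose value to low/medium/high (or missing).

    Bins are left-closed with the observed maximum included in "high";
    values outside the observed range clamp to the nearest extreme level.
    """
    if value is None or not np.isfinite(value):
        return MISSING
    tup = bounds.as_tuple()
    if bounds.mode == "per_day" and time_s is not None:
        tup = bounds.daily.get(int(time_s // 86400), tup)
    _, b1, b2, _ = tup
    if value < b1:
        return "low"
    if value < b2:
        return "medium"
    return "high"


def annotate_table(table: pd.DataFrame, bounds_by_patient: dict[str, TertileBounds]) -> pd.DataFrame:
    """Append a ``tertile`` column to a feature table.

    Every window with non-missing glucose gets a level from its patient's
    personalized bounds; a patient absent from ``bounds_by_patient`` is an
    error.
    """
    missing = set(table["patient_id"].unique()) - set(bounds_by_patient)
    if missing:
        raise ValidationError(f"no tertile bounds for patients: {sorted(missing)}")
    table = table.copy()
    table["tertile"] = [
        assign_tertile(g, bounds_by_patient[pid], time_s=t)
        for pid, g, t in zip(
            table["patient_id"], table["glucose_mgdl"], table["window_start_s"]
        )
    ]
    return table


def tertile_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Window counts per patient and tertile level."""
    return (
        table.groupby(["patient_id", "tertile"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
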