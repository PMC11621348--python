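"""Core data model and file I/O for RR-interval streams, CGM glucose series,
and per-window feature tables.

Time convention: all timestamps are seconds since the patient's recording
start (a float). The wall-clock time of recording start, when known, lives in
``PatientRecord.metadata["start_clock_h"]`` (hours, 0-24) so circadian clock
features can be derived; it defaults to midnight.

File dialect: comma-separated UTF-8 with a mandatory header row; missing
glucose values are empty fields. Python's shortest-repr float formatting makes
write/read round trips bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("bradyglu")

#: CGM reporting grid in seconds (5-minute averages).
GLUCOSE_GRID_S = 300.0
#: Physiologically plausible CGM range in mg/dL.
GLUCOSE_RANGE_MGDL = (20.0, 600.0)
#: Default maximum recording span: 7 days.
MAX_RECORDING_S = 7 * 86400.0

# The 29 short-term HRV features, grouped as in standard HRV practice:
# 14 time-domain, 9 frequency-domain, 6 nonlinear.
TIME_DOMAIN_FEATURES = [
    "RR-sdnn", "RR-pnn50", "RR-pnn20", "RR-rmssd",
    "HR-mean", "HR-median", "HR-std", "HR-max", "HR-min", "HR-p2p",
    "HR-kurtosis", "HR-skewness", "HR-mad", "HR-zcr",
]
FREQUENCY_DOMAIN_FEATURES = [
    "RR-vlf-power", "RR-lf-power", "RR-hf-power", "RR-total-power",
    "RR-lf-norm", "RR-hf-norm", "RR-lf-peak", "RR-hf-peak", "RR-lfhf-ratio",
]
NONLINEAR_FEATURES = [
    "RR-sd1", "RR-sd2", "RR-s-area", "RR-sd-ratio",
    "RR-sample-ent", "RR-perm-ent",
]
HRV_FEATURES = TIME_DOMAIN_FEATURES + FREQUENCY_DOMAIN_FEATURES + NONLINEAR_FEATURES

#: Non-feature columns every feature table carries.
TABLE_META_COLUMNS = [
    "patient_id", "window_start_s", "glucose_mgdl", "c24_sin", "c24_cos",
    "contains_brady_event", "n_beats", "valid",
]
#: Full schema of a feature table (optional columns such as "tertile" and
#: "zone" may be appended by downstream stages).
FEATURE_TABLE_SCHEMA = TABLE_META_COLUMNS + HRV_FEATURES


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


@dataclass
class RRSeries:
    """Timestamped beat-to-beat intervals for one patient.

    ``beat_times`` holds seconds since recording start for every detected
    beat, strictly increasing; ``rr_ms`` holds the interval durations in
    milliseconds, one per beat after the first, so
    ``rr_ms[i] == (beat_times[i+1] - beat_times[i]) * 1000``.
    """

    patient_id: str
    beat_times: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.validate()

    @classmethod
    def from_beat_times(cls, patient_id: str, beat_times) -> "RRSeries":
        bt = np.asarray(beat_times, dtype=float)
        return cls(patient_id, bt, np.diff(bt) * 1000.0)

    def validate(self) -> None:
        bt, rr = self.beat_times, self.rr_ms
        if bt.size == 0:
            raise ValidationError("empty RR series")
        if rr.size != bt.size - 1:
            raise ValidationError(
                f"rr_ms has {rr.size} entries for {bt.size} beats; expected {bt.size - 1}"
            )
        diffs = np.diff(bt)
        bad = np.flatnonzero(diffs <= 0)
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"beat times not strictly increasing at row {i + 1} "
                f"(t={bt[i + 1]:.6g} after t={bt[i]:.6g})"
            )
        if np.any(rr <= 0):
            i = int(np.flatnonzero(rr <= 0)[0])
            raise ValidationError(f"non-positive rr_ms at interval {i}")
        mismatch = np.abs(diffs * 1000.0 - rr) > 1.0
        if np.any(mismatch):
            i = int(np.flatnonzero(mismatch)[0])
            raise ValidationError(
                f"rr_ms[{i}]={rr[i]:.3f} disagrees with beat-time gap "
                f"{diffs[i] * 1000:.3f} ms by more than 1 ms"
            )
        if self.duration_s > MAX_RECORDING_S:
            warnings.warn(
                f"recording of patient {self.patient_id} spans "
                f"{self.duration_s / 86400:.2f} days (> 7); analyses use the full span",
                stacklevel=2,
            )

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)


@dataclass
class GlucoseSeries:
    """Interstitial glucose for one patient on the 5-minute CGM grid.

    Gaps are represented as NaN in ``glucose_mgdl``; timestamps stay on the
    grid (congruent to a common 300-s offset) and strictly increasing.
    """

    patient_id: str
    timestamps: np.ndarray
    glucose_mgdl: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.glucose_mgdl = np.asarray(self.glucose_mgdl, dtype=float)
        self.validate()

    def validate(self) -> None:
        t, g = self.timestamps, self.glucose_mgdl
        if t.size == 0:
            raise ValidationError("empty glucose series")
        if g.size != t.size:
            raise ValidationError("timestamps and glucose values differ in length")
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"glucose timestamps not strictly increasing at row {i + 1}"
            )
        offset = t - np.round((t - t[0]) / GLUCOSE_GRID_S) * GLUCOSE_GRID_S - t[0]
        off_grid = np.flatnonzero(np.abs(offset) > 1.0)
        if off_grid.size:
            i = int(off_grid[0])
            raise ValidationError(
                f"glucose timestamp at row {i} (t={t[i]:.6g} s) is off the 300-s grid"
            )
        lo, hi = GLUCOSE_RANGE_MGDL
        finite = np.isfinite(g)
        out = finite & ((g < lo) | (g > hi))
        if np.any(out):
            rows = np.flatnonzero(out)[:10].tolist()
            raise ValidationError(
                f"glucose values outside [{lo:g}, {hi:g}] mg/dL at rows {rows}"
            )

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.glucose_mgdl)))


@dataclass
class PatientRecord:
    """One patient's time-aligned RR and glucose streams plus metadata.

    Both streams share the same recording-start time origin; the clock hour
    of that origin is ``metadata.get("start_clock_h", 0.0)``.
    """

    rr: RRSeries
    glucose: GlucoseSeries
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rr.patient_id != self.glucose.patient_id:
            raise ValidationError(
                f"patient_id mismatch: rr={self.rr.patient_id!r} "
                f"glucose={self.glucose.patient_id!r}"
            )

    @property
    def patient_id(self) -> str:
        return self.rr.patient_id

    @property
    def start_clock_h(self) -> float:
        return float(self.metadata.get("start_clock_h", 0.0))


@dataclass
class AnalysisConfig:
    """All fixed analysis parameters in one place.

    Defaults encode the study conventions: 45-bpm bradycardia threshold,
    runs of at least 5 slow beats, 5-minute non-overlapping windows, 5-minute
    episode merging, 100 bootstrap iterations for the Fisher and Wilcoxon
    resampling, 200-point class subsamples, and 50 iterations of 5-fold
    stratified cross-validation.
    """

    hr_threshold_bpm: float = 45.0
    min_run_beats: int = 5
    window_len_s: float = 300.0
    episode_merge_gap_s: float = 300.0
    risk_lead_s: float = 300.0
    normal_buffer_s: float = 300.0
    n_boot_fisher: int = 100
    n_boot_wilcoxon: int = 100
    wilcoxon_sample_n: int = 200
    cv_iterations: int = 50
    cv_folds: int = 5
    rng_seed: int = 0
    tertile_mode: str = "recording"
    sampen_r_factor: float = 0.2
    interp_hz: float = 4.0
    # Forecasting extras (conventional defaults, recorded for reproducibility)
    rf_n_estimators: int = 500
    zscore_features: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_run_beats", "n_boot_fisher", "n_boot_wilcoxon",
            "wilcoxon_sample_n", "cv_iterations", "cv_folds", "rf_n_estimators",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in (
            "hr_threshold_bpm", "window_len_s", "episode_merge_gap_s",
            "risk_lead_s", "normal_buffer_s", "sampen_r_factor", "interp_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if 86400 % self.window_len_s != 0:
            raise ValidationError("window_len_s must divide 86400")
        if self.tertile_mode not in ("recording", "per_day"):
            raise ValidationError(f"unknown tertile_mode {self.tertile_mode!r}")

    @property
    def rr_threshold_ms(self) -> float:
        """RR duration equivalent to the HR threshold: 45 bpm <=> 1333.3 ms."""
        return 60000.0 / self.hr_threshold_bpm

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Readers / writers


def _float_fmt(x: float) -> str:
    # shortest representation that parses back to the identical double
    return format(x, ".17g")


def read_rr(path, patient_id: str | None = None) -> RRSeries:
    """Read an RR stream from CSV with columns ``time_s`` and/or ``rr_ms``.

    Whichever of the two columns is absent is derived from the other; a
    file with only ``rr_ms`` gets beat times by cumulative summation from 0.
    """
    df = _read_csv(path)
    pid = patient_id or _infer_patient_id(df, path)
    has_t, has_rr = "time_s" in df.columns, "rr_ms" in df.columns
    if not has_t and not has_rr:
        raise ValidationError(f"{path}: need a time_s or rr_ms column")
    if has_t:
        bt = df["time_s"].to_numpy(dtype=float)
        if has_rr:
            rr = df["rr_ms"].to_numpy(dtype=float)[1:]  # first beat has no interval
        else:
            rr = np.diff(bt) * 1000.0
    else:
        # rr_ms only: each row is one interval; synthesize beat times from 0
        rr = df["rr_ms"].to_numpy(dtype=float)
        bt = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    return RRSeries(pid, bt, rr)


def write_rr(series: RRSeries, path) -> None:
    rr_col = np.concatenate([[np.nan], series.rr_ms])
    df = pd.DataFrame({
        "patient_id": series.patient_id,
        "time_s": series.beat_times,
        "rr_ms": rr_col,
    })
    df.to_csv(path, index=False, float_format=_float_fmt)


def read_glucose(path, patient_id: str | None = None) -> GlucoseSeries:
    """Read a CGM series from CSV with columns ``time_s`` and ``glucose_mgdl``.

    Empty fields and ``NA`` mark gaps, preserved as NaN.
    """
    df = _read_csv(path)
    pid = patient_id or _infer_patient_id(df, path)
    for col in ("time_s", "glucose_mgdl"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return GlucoseSeries(
        pid,
        df["time_s"].to_numpy(dtype=float),
        df["glucose_mgdl"].to_numpy(dtype=float),
    )


def write_glucose(series: GlucoseSeries, path) -> None:
    pd.DataFrame({
        "patient_id": series.patient_id,
        "time_s": series.timestamps,
        "glucose_mgdl": series.glucose_mgdl,
    }).to_csv(path, index=False, float_format=_float_fmt)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table to CSV after checking the 29-feature schema."""
    _check_schema(table)
    table.to_csv(path, index=False, float_format=_float_fmt)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_schema(df)
    for col in ("contains_brady_event", "valid"):
        df[col] = df[col].astype(bool)
    non_float = {"patient_id", "contains_brady_event", "valid", "n_beats"}
    for col in df.columns:
        if col not in non_float and col != "tertile" and col != "zone":
            df[col] = df[col].astype(float)
    return df


def _check_schema(table: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_TABLE_SCHEMA if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table missing columns: {missing}")


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    return df


def _infer_patient_id(df: pd.DataFrame, path) -> str:
    if "patient_id" in df.columns:
        return str(df["patient_id"].iloc[0])
    return Path(path).stem
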