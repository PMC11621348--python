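"""Non-overlapping 5-minute windowing and the 29 short-term HRV features.

Each recording is tiled into half-open 300-s bins [k*300, (k+1)*300). For
every valid window three feature families are computed from the cleaned RR
subsequence:

* 14 time-domain features (SDNN, pNN50/pNN20, RMSSD and ten statistics of
  the instantaneous heart-rate series 60000/RR);
* 9 frequency-domain features from a Welch density of the cubic-spline
  4-Hz-resampled tachogram, integrated over the VLF (0.0033-0.04 Hz),
  LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz) bands;
* 6 nonlinear features: Poincare SD1/SD2/ellipse area/ratio, sample entropy
  (m=2, r = 0.2 * SD) and permutation entropy (order 3, lag 1, normalized).

Conventions fixed here because short-term HRV literature varies: SDNN and
HR-std use the sample standard deviation (n-1); the Poincare descriptors use
population variances so that SD1 = RMSSD/sqrt(2) holds exactly for windows
whose successive differences have zero mean; kurtosis is excess kurtosis;
the zero-crossing rate counts sign changes of the mean-centered HR series.
The ellipse area pi*SD1*SD2 is reported in ms^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spst
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import pdist

from .episode_detection import BradycardiaEpisode, detect_bradycardia
from .signal_io import (
    FEATURE_TABLE_SCHEMA,
    GLUCOSE_GRID_S,
    HRV_FEATURES,
    AnalysisConfig,
    PatientRecord,
)

#: Spectral bands in Hz: very-low, low, and high frequency.
VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Artifact gate on single intervals: keep RR within [300, 3000] ms.
RR_ARTIFACT_BOUNDS_MS = (300.0, 3000.0)
#: A window is valid when retained beats span >= 50% of it...
MIN_COVERAGE_FRACTION = 0.5
#: ...and at least this many intervals survive cleaning.
MIN_INTERVALS = 10
#: CGM gaps up to this many 5-min slots are linearly interpolated.
MAX_IMPUTE_SLOTS = 3


@dataclass
class RawWindow:
    """One 300-s bin with its RR subsequence and aligned CGM sample."""

    patient_id: str
    start_s: float
    beat_times: np.ndarray
    rr_ms: np.ndarray
    glucose_mgdl: float
    contains_brady_event: bool
    # filled by clean_rr_window
    clean_times: np.ndarray | None = None
    clean_rr: np.ndarray | None = None
    valid: bool = False


def impute_glucose(glucose_mgdl: np.ndarray, max_slots: int = MAX_IMPUTE_SLOTS) -> np.ndarray:
    """Linearly interpolate CGM gaps of at most ``max_slots`` grid slots.

    Longer gaps, and gaps touching either end of the series, stay missing.
    """
    g = np.asarray(glucose_mgdl, dtype=float).copy()
    isnan = ~np.isfinite(g)
    if not isnan.any() or isnan.all():
        return g
    idx = np.arange(g.size)
    filled = np.interp(idx, idx[~isnan], g[~isnan])
    # identify gap runs and only accept short interior ones
    padded = np.concatenate([[False], isnan, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        if i1 - i0 <= max_slots and i0 > 0 and i1 < g.size:
            g[i0:i1] = filled[i0:i1]
    return g


def segment_windows(
    record: PatientRecord,
    episodes: list[BradycardiaEpisode] | None = None,
    config: AnalysisConfig | None = None,
) -> list[RawWindow]:
    """Tile [0, duration) into half-open 300-s windows.

    Each window carries the beats whose time falls inside the bin, the CGM
    sample of the matching grid slot (after short-gap imputation), and a flag
    marking overlap with any detected bradycardia episode.
    """
    config = config or AnalysisConfig()
    if episodes is None:
        episodes = detect_bradycardia(record.rr, config)
    w = config.window_len_s
    bt = record.rr.beat_times
    duration = bt[-1]
    n_win = int(math.ceil(duration / w)) if duration > 0 else 0

    g_imputed = impute_glucose(record.glucose.glucose_mgdl)
    g_t0 = record.glucose.timestamps[0]
    slot_of = {
        int(round((t - g_t0) / GLUCOSE_GRID_S)): v
        for t, v in zip(record.glucose.timestamps, g_imputed)
    }

    # beat index boundaries per window via searchsorted on the tiling
    bounds = np.searchsorted(bt, np.arange(n_win + 1) * w, side="left")
    ep_starts = np.array([e.start_s for e in episodes])
    ep_ends = np.array([e.end_s for e in episodes])

    windows = []
    for k in range(n_win):
        start = k * w
        i0, i1 = bounds[k], bounds[k + 1]
        times = bt[i0:i1]
        # intervals fully determined by beats inside the bin
        rr = record.rr.rr_ms[i0: max(i1 - 1, i0)]
        slot = int(round((start - g_t0) / GLUCOSE_GRID_S))
        glucose = float(slot_of.get(slot, np.nan))
        has_ep = bool(np.any((ep_starts < start + w) & (ep_ends > start))) if episodes else False
        windows.append(
            RawWindow(
                patient_id=record.patient_id,
                start_s=float(start),
                beat_times=times,
                rr_ms=rr,
                glucose_mgdl=glucose,
                contains_brady_event=has_ep,
            )
        )
    return windows


def clean_rr_window(window: RawWindow, config: AnalysisConfig | None = None) -> RawWindow:
    """Drop artifact intervals and decide window validity.

    Intervals outside [300, 3000] ms are removed (with the beat that ends
    them). The window is valid when retained intervals span at least half
    of the 300 s and at least 10 intervals remain.
    """
    config = config or AnalysisConfig()
    rr, times = window.rr_ms, window.beat_times
    if rr.size == 0:
        window.clean_times = np.empty(0)
        window.clean_rr = np.empty(0)
        window.valid = False
        return window
    lo, hi = RR_ARTIFACT_BOUNDS_MS
    keep = (rr >= lo) & (rr <= hi)
    clean_rr = rr[keep]
    # interval i runs from beat i to beat i+1; keep end-beat times of retained intervals
    clean_times = times[1:][keep] if times.size > 1 else np.empty(0)
    coverage = clean_rr.sum() / 1000.0 / config.window_len_s
    window.clean_rr = clean_rr
    window.clean_times = clean_times
    window.valid = bool(
        coverage >= MIN_COVERAGE_FRACTION and clean_rr.size >= MIN_INTERVALS
    )
    return window


# ---------------------------------------------------------------------------
# Feature families


def time_domain_features(rr_ms: np.ndarray) -> dict:
    """The 14 time-domain features of the short-term HRV battery."""
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < MIN_INTERVALS:
        return {k: np.nan for k in _TD_KEYS}
    d = np.diff(rr)
    hr = 60000.0 / rr
    dhr = np.diff(hr)
    centered = hr - hr.mean()
    sign_changes = int(np.sum(centered[:-1] * centered[1:] < 0))
    return {
        "RR-sdnn": float(np.std(rr, ddof=1)),
        "RR-pnn50": float(100.0 * np.mean(np.abs(d) > 50.0)) if d.size else np.nan,
        "RR-pnn20": float(100.0 * np.mean(np.abs(d) > 20.0)) if d.size else np.nan,
        "RR-rmssd": float(np.sqrt(np.mean(d**2))) if d.size else np.nan,
        "HR-mean": float(hr.mean()),
        "HR-median": float(np.median(hr)),
        "HR-std": float(np.std(hr, ddof=1)),
        "HR-max": float(hr.max()),
        "HR-min": float(hr.min()),
        "HR-p2p": float(hr.max() - hr.min()),
        "HR-kurtosis": float(spst.kurtosis(hr, fisher=True, bias=True)),
        "HR-skewness": float(spst.skew(hr, bias=True)),
        "HR-mad": float(np.median(np.abs(dhr))) if dhr.size else np.nan,
        "HR-zcr": float(sign_changes / (hr.size - 1)),
    }


_TD_KEYS = [
    "RR-sdnn", "RR-pnn50", "RR-pnn20", "RR-rmssd", "HR-mean", "HR-median",
    "HR-std", "HR-max", "HR-min", "HR-p2p", "HR-kurtosis", "HR-skewness",
    "HR-mad", "HR-zcr",
]
_FD_KEYS = [
    "RR-vlf-power", "RR-lf-power", "RR-hf-power", "RR-total-power",
    "RR-lf-norm", "RR-hf-norm", "RR-lf-peak", "RR-hf-peak", "RR-lfhf-ratio",
]
_NL_KEYS = [
    "RR-sd1", "RR-sd2", "RR-s-area", "RR-sd-ratio", "RR-sample-ent", "RR-perm-ent",
]


def frequency_domain_features(
    beat_times: np.ndarray,
    rr_ms: np.ndarray,
    window_start_s: float,
    config: AnalysisConfig | None = None,
) -> dict:
    """Spectral features of the tachogram resampled to a uniform 4-Hz grid.

    RR(t) is taken at each interval's ending beat, cubic-spline interpolated
    onto the 4-Hz grid spanning the window (edge-held outside the beat span),
    mean-removed, and fed to a single full-length Hann-tapered Welch segment.
    Band powers integrate the density with the trapezoid rule; peaks are the
    argmax frequency inside each band.
    """
    config = config or AnalysisConfig()
    out = {k: np.nan for k in _FD_KEYS}
    t = np.asarray(beat_times, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < MIN_INTERVALS or t.size != rr.size:
        return out
    fs = config.interp_hz
    n = int(round(config.window_len_s * fs))
    grid = window_start_s + np.arange(n) / fs
    grid_clipped = np.clip(grid, t[0], t[-1])  # edge-hold outside beat span
    # strictly increasing times required; cleaning preserves order
    spline = CubicSpline(t, rr)
    x = spline(grid_clipped)
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=n, noverlap=0, detrend="constant",
        scaling="density",
    )

    def band_power(lo, hi):
        m = (freqs >= lo) & (freqs <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))

    def band_peak(lo, hi):
        m = (freqs >= lo) & (freqs <= hi)
        if not m.any():
            return np.nan
        return float(freqs[m][np.argmax(psd[m])])

    vlf = band_power(*VLF_BAND)
    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    out.update({
        "RR-vlf-power": vlf,
        "RR-lf-power": lf,
        "RR-hf-power": hf,
        "RR-total-power": band_power(VLF_BAND[0], HF_BAND[1]),
        "RR-lf-peak": band_peak(*LF_BAND),
        "RR-hf-peak": band_peak(*HF_BAND),
    })
    if lf + hf > 0:
        out["RR-lf-norm"] = 100.0 * lf / (lf + hf)
        out["RR-hf-norm"] = 100.0 * hf / (lf + hf)
    if hf > 0:
        out["RR-lfhf-ratio"] = 100.0 * lf / hf
    return out


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with template length m, Chebyshev tolerance r.

    A counts pairs of (m+1)-templates within r, B pairs of m-templates,
    self-matches excluded. Returns NaN when no m-template pair matches.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if r is None:
        r = 0.2 * np.std(x)
    if n <= m + 1 or r <= 0:
        return np.nan

    def pair_count(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        return int(np.sum(pdist(emb, metric="chebyshev") <= r))

    b = pair_count(m)
    a = pair_count(m + 1)
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


def permutation_entropy(x: np.ndarray, order: int = 3, lag: int = 1) -> float:
    """Permutation entropy of ordinal patterns, normalized to [0, 1] by
    log(order!). Ties resolve by order of appearance (stable argsort)."""
    x = np.asarray(x, dtype=float)
    n = x.size - (order - 1) * lag
    if n <= 0:
        return np.nan
    emb = np.column_stack([x[i * lag: i * lag + n] for i in range(order)])
    patterns = np.argsort(emb, axis=1, kind="stable")
    codes = patterns @ (order ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(math.factorial(order)))


def nonlinear_features(rr_ms: np.ndarray, config: AnalysisConfig | None = None) -> dict:
    """Poincare descriptors plus sample and permutation entropy."""
    config = config or AnalysisConfig()
    rr = np.asarray(rr_ms, dtype=float)
    out = {k: np.nan for k in _NL_KEYS}
    if rr.size < MIN_INTERVALS:
        return out
    d = np.diff(rr)
    var_d = float(np.var(d))          # population variance
    var_rr = float(np.var(rr))
    sd1 = math.sqrt(var_d / 2.0)
    sd2_sq = 2.0 * var_rr - var_d / 2.0
    sd2 = math.sqrt(max(sd2_sq, 0.0))
    out["RR-sd1"] = sd1
    out["RR-sd2"] = sd2
    out["RR-s-area"] = math.pi * sd1 * sd2
    if sd2 > 0:
        out["RR-sd-ratio"] = sd1 / sd2
    out["RR-sample-ent"] = sample_entropy(
        rr, m=2, r=config.sampen_r_factor * float(np.std(rr))
    )
    out["RR-perm-ent"] = permutation_entropy(rr, order=3, lag=1)
    return out


def clock_features(clock_hour: float) -> tuple[float, float]:
    """24-hour circadian encoding: (sin, cos) of the clock hour."""
    theta = 2.0 * math.pi * (clock_hour % 24.0) / 24.0
    return math.sin(theta), math.cos(theta)


# ---------------------------------------------------------------------------
# Table assembly


def window_features(window: RawWindow, config: AnalysisConfig | None = None) -> dict:
    """All 29 HRV features for one cleaned, valid window."""
    config = config or AnalysisConfig()
    feats = {}
    feats.update(time_domain_features(window.clean_rr))
    feats.update(
        frequency_domain_features(
            window.clean_times, window.clean_rr, window.start_s, config
        )
    )
    feats.update(nonlinear_features(window.clean_rr, config))
    return feats


def build_feature_table(
    records: list[PatientRecord],
    episodes_by_patient: dict[str, list[BradycardiaEpisode]] | None = None,
    config: AnalysisConfig | None = None,
    compute_hrv: bool = True,
) -> pd.DataFrame:
    """One row per 5-minute window across all patients.

    Invalid windows keep their metadata but carry missing feature values.
    ``compute_hrv=False`` fills the 29 feature columns with NaN, for
    analyses that only need window metadata (glucose, flags, clock).
    """
    config = config or AnalysisConfig()
    rows = []
    for record in records:
        eps = None if episodes_by_patient is None else episodes_by_patient.get(
            record.patient_id, []
        )
        for window in segment_windows(record, eps, config):
            clean_rr_window(window, config)
            sin_c, cos_c = clock_features(
                record.start_clock_h + window.start_s / 3600.0
            )
            row = {
                "patient_id": record.patient_id,
                "window_start_s": window.start_s,
                "glucose_mgdl": window.glucose_mgdl,
                "c24_sin": sin_c,
                "c24_cos": cos_c,
                "contains_brady_event": window.contains_brady_event,
                "n_beats": int(window.clean_rr.size),
                "valid": window.valid,
            }
            if compute_hrv and window.valid:
                row.update(window_features(window, config))
            else:
                row.update({k: np.nan for k in HRV_FEATURES})
            rows.append(row)
    table = pd.DataFrame(rows, columns=FEATURE_TABLE_SCHEMA)
    if not rows:
        table = pd.DataFrame(columns=FEATURE_TABLE_SCHEMA)
    return table
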