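"""Synthetic multi-patient 7-day RR + CGM cohorts with known ground truth.

No public recordings of the kind this pipeline targets exist, so every
downstream stage is exercised on generated data whose structure mirrors the
clinical setting: circadian glucose profiles with patient-specific mean,
range and occasional hypoglycemic dips; RR streams with circadian heart-rate
modulation, LF (0.1 Hz) and HF (0.25 Hz) sinusoidal variability and beat
noise; and injected bradycardia runs whose hourly intensity can depend on
the patient's relative glucose tertile and on the clock hour. The injector
records every placed run (``SimTruth``) so detection, enrichment and
forecasting can be validated against the truth.

Episodes are injected by re-spacing beats in place — the span boundaries
keep their original times — so the RR and glucose streams stay aligned as
in synchronized monitoring. An optional pre-episode heart-rate drift
depresses HR across the two lead windows before each injected run (total
span duration preserved), giving the forecasting stage a recoverable signal.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .relative_glucose import TertileBounds, assign_tertile, compute_tertile_bounds
from .rng import derive_rng
from .signal_io import (
    GLUCOSE_GRID_S,
    GLUCOSE_RANGE_MGDL,
    AnalysisConfig,
    GlucoseSeries,
    PatientRecord,
    RRSeries,
)


@dataclass
class SimPatientParams:
    """Generative parameters for one simulated patient.

    Circadian terms follow the cosinor convention: value(t) = mesor +
    amplitude * cos(2*pi*(t_hours - acrophase)/24). Bradycardia injection
    intensity per hour is ``brady_base_rate`` times the tertile odds
    multiplier (low/high relative glucose at the moment of onset) times the
    time-of-day multiplier on clock hours ``brady_time_window_h``.
    """

    glucose_mesor: float = 165.0
    glucose_amplitude: float = 30.0
    glucose_acrophase_h: float = 18.0
    glucose_ar1_phi: float = 0.8
    glucose_noise_sd: float = 8.0
    hypo_dips_per_day: float = 0.5
    hypo_dip_depth_mgdl: float = 45.0
    hypo_dip_width_min: float = 30.0
    hr_mesor: float = 73.0
    hr_amplitude: float = 7.0
    hr_acrophase_h: float = 15.0
    rr_lf_mod_ms: float = 20.0
    rr_hf_mod_ms: float = 15.0
    rr_noise_sd_ms: float = 20.0
    brady_base_rate: float = 0.3
    brady_odds_low: float = 1.0
    brady_odds_high: float = 1.0
    brady_nocturnal_mult: float = 1.0
    brady_time_window_h: tuple = (0.0, 6.0)
    episode_len_beats: tuple = (5, 15)
    episode_hr_bpm: tuple = (36.0, 44.0)
    pre_episode_drift_bpm: float = 0.0

    def __post_init__(self) -> None:
        if self.brady_base_rate < 0 or self.brady_odds_low < 0 or self.brady_odds_high < 0:
            raise ValueError("bradycardia rates and odds must be >= 0")
        if self.episode_hr_bpm[1] >= 45.0:
            raise ValueError("episode HR range must stay below the 45-bpm threshold")
        if self.episode_len_beats[0] < 5:
            raise ValueError("episodes must have at least 5 beats to be detectable")


@dataclass
class InjectedEpisode:
    start_s: float
    end_s: float
    n_beats: int
    hr_bpm: float
    tertile_at_onset: str
    clock_hour: float


@dataclass
class SimTruth:
    """Ground truth of the injected bradycardia runs for one patient."""

    patient_id: str
    episodes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        starts = [e.start_s for e in self.episodes]
        if sorted(starts) != starts:
            raise ValueError("injected episodes must be sorted")
        for prev, nxt in zip(self.episodes, self.episodes[1:]):
            if nxt.start_s < prev.end_s:
                raise ValueError("injected episodes overlap")


# ---------------------------------------------------------------------------
# Glucose


def simulate_glucose(
    params: SimPatientParams, days: float, seed: int, patient_id: str = "sim"
) -> GlucoseSeries:
    """Circadian cosinor + AR(1) noise + optional hypoglycemic dips on the
    5-minute CGM grid, clipped to the physiological range."""
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = derive_rng(seed, "glucose")
    n = int(round(days * 86400 / GLUCOSE_GRID_S))
    t = np.arange(n) * GLUCOSE_GRID_S
    hours = t / 3600.0
    base = params.glucose_mesor + params.glucose_amplitude * np.cos(
        2.0 * math.pi * (hours - params.glucose_acrophase_h) / 24.0
    )
    noise = np.zeros(n)
    if params.glucose_noise_sd > 0:
        eps = rng.normal(0.0, params.glucose_noise_sd, size=n)
        phi = params.glucose_ar1_phi
        # stationary start, then AR(1) recursion
        noise[0] = eps[0] / math.sqrt(max(1.0 - phi**2, 1e-12))
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + eps[i]
    g = base + noise
    n_dips = rng.poisson(params.hypo_dips_per_day * days)
    for _ in range(n_dips):
        center = rng.uniform(0, days * 86400)
        width = params.hypo_dip_width_min * 60.0
        g -= params.hypo_dip_depth_mgdl * np.exp(-0.5 * ((t - center) / width) ** 2)
    lo, hi = GLUCOSE_RANGE_MGDL
    clipped = np.clip(g, lo, hi)
    if np.all((clipped == lo) | (clipped == hi)):
        raise ValueError("glucose parameters drive the whole series into clipping")
    return GlucoseSeries(patient_id, t, clipped)


# ---------------------------------------------------------------------------
# RR stream


def _circadian_hr(params: SimPatientParams, hours: np.ndarray) -> np.ndarray:
    return params.hr_mesor + params.hr_amplitude * np.cos(
        2.0 * math.pi * (hours - params.hr_acrophase_h) / 24.0
    )


def simulate_rr(
    params: SimPatientParams,
    glucose: GlucoseSeries,
    seed: int,
    patient_id: str | None = None,
) -> RRSeries:
    """Beat-by-beat RR stream covering the glucose span.

    The instantaneous interval is 60000/HR_circadian(t) plus sinusoidal LF
    (0.1 Hz) and HF (0.25 Hz) modulation and white Gaussian beat noise; each
    beat time advances by the previous interval.
    """
    pid = patient_id or glucose.patient_id
    duration = float(glucose.timestamps[-1] + GLUCOSE_GRID_S)
    max_hr = params.hr_mesor + params.hr_amplitude
    floor_rr = (
        60000.0 / max_hr
        - params.rr_lf_mod_ms
        - params.rr_hf_mod_ms
        - 6.0 * params.rr_noise_sd_ms
    )
    if floor_rr <= 200.0:
        raise ValueError(
            f"parameters can yield RR <= 200 ms (floor {floor_rr:.0f} ms); "
            "reduce HR mesor/amplitude, modulation depths or noise"
        )
    rng = derive_rng(seed, "rr")
    grid_dt = 10.0  # circadian HR varies over hours; 10-s lookup is exact enough
    tg_hours = np.arange(0.0, duration + 2 * grid_dt, grid_dt) / 3600.0
    rr_circ = 60000.0 / _circadian_hr(params, tg_hours)

    est = int(duration / (rr_circ.min() / 1000.0) * 1.05) + 64
    noise = rng.normal(0.0, params.rr_noise_sd_ms, size=est) if params.rr_noise_sd_ms > 0 else np.zeros(est)

    lf, hf = params.rr_lf_mod_ms, params.rr_hf_mod_ms
    w_lf = 2.0 * math.pi * 0.1
    w_hf = 2.0 * math.pi * 0.25
    sin = math.sin
    times = [0.0]
    t = 0.0
    i = 0
    while True:
        if i >= noise.size:
            noise = np.concatenate([noise, rng.normal(0.0, params.rr_noise_sd_ms, size=est)])
        rr = rr_circ[int(t / grid_dt)] + lf * sin(w_lf * t) + hf * sin(w_hf * t) + noise[i]
        t += rr / 1000.0
        if t >= duration:
            break
        times.append(t)
        i += 1
    return RRSeries.from_beat_times(pid, np.asarray(times))


# ---------------------------------------------------------------------------
# Episode injection


def _slot_multiplier(
    params: SimPatientParams, tertile: str, clock_hour: float
) -> float:
    mult = {"low": params.brady_odds_low, "high": params.brady_odds_high}.get(tertile, 1.0)
    lo, hi = params.brady_time_window_h
    in_window = lo <= (clock_hour % 24.0) < hi
    return mult * (params.brady_nocturnal_mult if in_window else 1.0)


def inject_bradycardia(
    rr: RRSeries,
    glucose: GlucoseSeries,
    params: SimPatientParams,
    tertile_bounds: TertileBounds,
    seed: int,
    config: AnalysisConfig | None = None,
    start_clock_h: float = 0.0,
) -> tuple[RRSeries, SimTruth]:
    """Insert slow-beat runs by re-spacing beats inside non-overlapping spans.

    Per 5-minute slot the expected number of onsets is base_rate/12 times the
    tertile and time-of-day multipliers evaluated at that slot. Each placed
    run replaces the beats spanning ``n_beats * 60000/hr`` ms with ``n_beats``
    equal slow intervals between the original span boundaries, so the total
    recording duration and the CGM alignment are untouched.
    """
    config = config or AnalysisConfig()
    rng = derive_rng(seed, "inject")
    mean_episode_s = (
        np.mean(params.episode_len_beats) * 60000.0 / np.mean(params.episode_hr_bpm) / 1000.0
    )
    max_mult = max(params.brady_odds_low, params.brady_odds_high, 1.0) * max(
        params.brady_nocturnal_mult, 1.0
    )
    if params.brady_base_rate * max_mult * mean_episode_s / 3600.0 > 0.5:
        raise ValueError("requested bradycardia rate would force overlapping runs")

    bt = rr.beat_times
    truth_eps: list[InjectedEpisode] = []
    occupied: list[tuple[int, int]] = []  # beat-index spans, kept sorted

    for slot_idx, (t0, g_val) in enumerate(zip(glucose.timestamps, glucose.glucose_mgdl)):
        tert = assign_tertile(float(g_val), tertile_bounds, time_s=float(t0))
        hour = (start_clock_h + t0 / 3600.0) % 24.0
        lam = params.brady_base_rate / 12.0 * _slot_multiplier(params, tert, hour)
        n_events = int(rng.poisson(lam)) if lam > 0 else 0
        for _ in range(n_events):
            onset = rng.uniform(t0, t0 + GLUCOSE_GRID_S)
            n_beats = int(rng.integers(params.episode_len_beats[0], params.episode_len_beats[1] + 1))
            hr = float(rng.uniform(*params.episode_hr_bpm))
            i = int(np.searchsorted(bt, onset))
            if i >= bt.size - 1:
                continue
            target_span = n_beats * 60000.0 / hr / 1000.0
            j = int(np.searchsorted(bt, bt[i] + target_span, side="left"))
            if j >= bt.size:
                continue
            if any(i <= e and s <= j for s, e in occupied):
                continue  # overlap with an already placed run: skip this draw
            occupied.append((i, j))
            occupied.sort()
            truth_eps.append(
                InjectedEpisode(
                    start_s=float(bt[i]),
                    end_s=float(bt[j]),
                    n_beats=n_beats,
                    hr_bpm=60000.0 * n_beats / ((bt[j] - bt[i]) * 1000.0),
                    tertile_at_onset=tert,
                    clock_hour=hour,
                )
            )

    truth_eps.sort(key=lambda e: e.start_s)
    new_bt = _respace_spans(bt, occupied, truth_eps)
    if params.pre_episode_drift_bpm > 0:
        new_bt = _apply_pre_episode_drift(new_bt, truth_eps, params, config)
    out = RRSeries.from_beat_times(rr.patient_id, new_bt)
    return out, SimTruth(rr.patient_id, truth_eps)


def _respace_spans(bt: np.ndarray, occupied: list, eps: list) -> np.ndarray:
    """Rebuild beat times with each occupied span re-spaced into equal slow
    intervals; span boundary beats keep their original times."""
    if not occupied:
        return bt.copy()
    by_start = {s: (e, ep) for (s, e), ep in zip(sorted(occupied), eps)}
    pieces = []
    pos = 0
    for s in sorted(by_start):
        e, ep = by_start[s]
        pieces.append(bt[pos:s])
        pieces.append(np.linspace(bt[s], bt[e], ep.n_beats + 1))
        pos = e + 1
    pieces.append(bt[pos:])
    return np.concatenate(pieces)


def _apply_pre_episode_drift(
    bt: np.ndarray, eps: list, params: SimPatientParams, config: AnalysisConfig
) -> np.ndarray:
    """Depress HR across the two lead windows before each injected run.

    The depression ramps up linearly during the earlier lead window and
    holds at the full drift through the final one, emulating a sustained
    pre-episode decline in HR mean, median and minimum rather than a steep
    within-window trend. The modified intervals are rescaled to preserve
    the whole span's total duration, so no later beat shifts; the
    compensating speed-up mostly cancels inside the earlier window, which
    the labeling buffer excludes from the normal class.
    """
    bt = bt.copy()
    lead = config.risk_lead_s
    span = 2.0 * lead
    floor_hr = config.hr_threshold_bpm + 2.0
    prev_end = 0.0
    for ep in eps:
        lo_t = max(ep.start_s - span, prev_end)
        prev_end = ep.end_s
        i0 = int(np.searchsorted(bt, lo_t, side="left"))
        i1 = int(np.searchsorted(bt, ep.start_s, side="left"))
        if i1 - i0 < 4:
            continue
        seg = bt[i0: i1 + 1]
        rr = np.diff(seg) * 1000.0
        mid = (seg[:-1] + seg[1:]) / 2.0
        # rise over the earlier lead window, plateau through the last one
        ramp = np.clip((mid - (ep.start_s - span)) / lead, 0.0, 1.0)
        # additive RR-domain shift keeps the beat-noise variance untouched
        base_hr = 60000.0 / float(np.median(rr))
        target_hr = max(base_hr - params.pre_episode_drift_bpm, floor_hr)
        delta_rr = 60000.0 / target_hr - 60000.0 / base_hr
        delta = delta_rr * ramp
        rising = ramp < 1.0
        if rising.any():
            # compensate the added time inside the earlier (buffered) window
            delta[rising] -= delta.sum() / rising.sum()
        rr_new = np.clip(rr + delta, 320.0, 60000.0 / floor_hr)
        rr_new *= rr.sum() / rr_new.sum()  # exact span preservation after clipping
        bt[i0 + 1: i1 + 1] = seg[0] + np.cumsum(rr_new) / 1000.0
    return bt


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class CohortConfig:
    """Between-patient parameter ranges and shared injection settings.

    Per-patient parameters are drawn uniformly from the given (lo, hi)
    ranges; injection settings are shared across the cohort so scenarios
    (null coupling, tertile enrichment, pre-episode drift) are expressed by
    overriding the relevant fields.
    """

    days: float = 7.0
    glucose_mesor_range: tuple = (130.0, 210.0)
    glucose_amplitude_range: tuple = (15.0, 40.0)
    glucose_acrophase_range: tuple = (16.0, 20.0)
    glucose_noise_sd_range: tuple = (5.0, 12.0)
    hr_mesor_range: tuple = (62.0, 84.0)
    hr_amplitude_range: tuple = (5.0, 10.0)
    hr_acrophase_range: tuple = (13.0, 17.0)
    rr_lf_mod_range: tuple = (10.0, 30.0)
    rr_hf_mod_range: tuple = (8.0, 20.0)
    rr_noise_sd_range: tuple = (10.0, 30.0)
    brady_base_rate: float = 0.3
    brady_odds_low: float = 1.0
    brady_odds_high: float = 1.0
    brady_nocturnal_mult: float = 1.0
    brady_time_window_h: tuple = (0.0, 6.0)
    pre_episode_drift_bpm: float = 0.0
    tertile_mode: str = "recording"


def draw_patient_params(config: CohortConfig, rng: np.random.Generator) -> SimPatientParams:
    u = rng.uniform
    return SimPatientParams(
        glucose_mesor=u(*config.glucose_mesor_range),
        glucose_amplitude=u(*config.glucose_amplitude_range),
        glucose_acrophase_h=u(*config.glucose_acrophase_range),
        glucose_noise_sd=u(*config.glucose_noise_sd_range),
        hr_mesor=u(*config.hr_mesor_range),
        hr_amplitude=u(*config.hr_amplitude_range),
        hr_acrophase_h=u(*config.hr_acrophase_range),
        rr_lf_mod_ms=u(*config.rr_lf_mod_range),
        rr_hf_mod_ms=u(*config.rr_hf_mod_range),
        rr_noise_sd_ms=u(*config.rr_noise_sd_range),
        brady_base_rate=config.brady_base_rate,
        brady_odds_low=config.brady_odds_low,
        brady_odds_high=config.brady_odds_high,
        brady_nocturnal_mult=config.brady_nocturnal_mult,
        brady_time_window_h=config.brady_time_window_h,
        pre_episode_drift_bpm=config.pre_episode_drift_bpm,
    )


def simulate_patient(
    params: SimPatientParams,
    days: float,
    seed: int,
    patient_id: str = "sim",
    tertile_mode: str = "recording",
) -> tuple[PatientRecord, SimTruth]:
    """Glucose, RR, tertile bounds and injected episodes for one patient."""
    glucose = simulate_glucose(params, days, seed, patient_id)
    rr = simulate_rr(params, glucose, seed)
    bounds = compute_tertile_bounds(glucose, mode=tertile_mode)
    rr, truth = inject_bradycardia(rr, glucose, params, bounds, seed)
    record = PatientRecord(rr, glucose, metadata={"start_clock_h": 0.0})
    return record, truth


def simulate_cohort(
    n_patients: int, config: CohortConfig | None = None, seed: int = 0
) -> list[tuple[PatientRecord, SimTruth]]:
    """A reproducible multi-patient cohort.

    Each patient gets an independent substream derived from (seed, index),
    so growing the cohort never perturbs existing patients.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    config = config or CohortConfig()
    cohort = []
    for i in range(n_patients):
        rng = derive_rng(seed, "cohort-params", i)
        params = draw_patient_params(config, rng)
        patient_seed = int(derive_rng(seed, "cohort-seed", i).integers(0, 2**31 - 1))
        cohort.append(
            simulate_patient(
                params,
                config.days,
                patient_seed,
                patient_id=f"P{i:03d}",
                tertile_mode=config.tertile_mode,
            )
        )
    return cohort
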