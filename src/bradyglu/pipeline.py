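"""End-to-end orchestration: detect -> features -> tertiles -> stats ->
forecast, with one config and one seed, producing a consolidated report.

The report is a plain JSON-serializable dict; ``RunManifest`` snapshots the
configuration, seed and SHA-256 digests of every file written, so a re-run
with the same inputs can be checked for byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc_stats, episode_detection, relative_glucose, risk_forecast
from .signal_io import AnalysisConfig, PatientRecord
from .window_features import build_feature_table

logger = logging.getLogger("bradyglu")


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list = field(default_factory=list)
    file_digests: dict = field(default_factory=dict)

    def add_file(self, path) -> None:
        p = Path(path)
        self.file_digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_full_analysis(
    records: list[PatientRecord],
    config: AnalysisConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[RunManifest, dict]:
    """Run every analysis stage on a cohort of patient records.

    Returns the manifest and the consolidated report. When the cohort has
    no bradycardia at all, the statistical and forecasting stages are
    skipped with a note rather than erroring.
    """
    config = config or AnalysisConfig()
    manifest = RunManifest(config=dataclasses.asdict(config), seed=seed)
    report: dict = {"n_patients": len(records)}

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        manifest.stages.append(name)
        return t0

    def done(name, t0):
        logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)

    # --- detection -------------------------------------------------------
    t0 = stage("detect")
    episodes_by_patient, groups_by_patient, summaries = {}, {}, {}
    for rec in records:
        eps = episode_detection.detect_bradycardia(rec.rr, config)
        groups = episode_detection.group_episodes(eps, config)
        episodes_by_patient[rec.patient_id] = eps
        groups_by_patient[rec.patient_id] = groups
        summaries[rec.patient_id] = episode_detection.episode_summary(
            groups, days=rec.rr.duration_s / 86400.0, start_clock_h=rec.start_clock_h
        )
    n_with_brady = sum(1 for s in summaries.values() if s["group_count"] > 0)
    report["episodes"] = {
        "per_patient": summaries,
        "patients_with_bradycardia": n_with_brady,
        "prevalence_pct": 100.0 * n_with_brady / len(records) if records else 0.0,
    }
    done("detect", t0)

    # --- features --------------------------------------------------------
    t0 = stage("features")
    table = build_feature_table(records, episodes_by_patient, config)
    done("features", t0)

    # --- tertiles --------------------------------------------------------
    t0 = stage("tertiles")
    bounds = {
        rec.patient_id: relative_glucose.compute_tertile_bounds(
            rec.glucose, mode=config.tertile_mode
        )
        for rec in records
    }
    table = relative_glucose.annotate_table(table, bounds)
    report["tertile_bounds"] = {
        pid: dict(zip(("g_min", "b1", "b2", "g_max"), b.as_tuple()))
        for pid, b in bounds.items()
    }
    done("tertiles", t0)

    if n_with_brady == 0:
        report["note"] = "no bradycardia episodes detected; stats and forecast skipped"
        return _finish(manifest, report, table, out_dir)

    # --- statistics ------------------------------------------------------
    t0 = stage("stats")
    report["tertile_shares"] = assoc_stats.tertile_event_shares(table)
    try:
        corr = assoc_stats.hourly_hr_glucose_correlation(table)
        report["hr_glucose_correlation"] = {"r": corr["r"], "p": corr["p"]}
    except ValueError as exc:
        report["hr_glucose_correlation"] = {"error": str(exc)}
    freqs = assoc_stats.per_patient_brady_freq_by_tertile(table)
    try:
        utests = assoc_stats.mannwhitney_tertile_comparison(freqs)
        report["mannwhitney"] = [dataclasses.asdict(r) for r in utests]
    except ValueError as exc:
        report["mannwhitney"] = {"error": str(exc)}
    fisher = assoc_stats.bootstrap_fisher_by_timeband(table, config, seed=seed)
    report["fisher_enrichment"] = {
        k: {"median": r.median, "ci95": r.interval(), "n_windows": r.n_windows,
            "reliable": r.reliable}
        for k, r in fisher.items()
    }
    try:
        wil = assoc_stats.wilcoxon_hrv_bootstrap(table, config, seed=seed)
        report["wilcoxon_hrv"] = {
            k: {"median": r.median, "ci95": r.interval()} for k, r in wil.items()
        }
    except ValueError as exc:
        report["wilcoxon_hrv"] = {"error": str(exc)}
    done("stats", t0)

    # --- forecasting -----------------------------------------------------
    t0 = stage("forecast")
    labeled = risk_forecast.label_windows(table, groups_by_patient, config)
    labeled = labeled[labeled["valid"]]
    if config.zscore_features:
        labeled = risk_forecast.zscore_per_patient(labeled, config=config)
    try:
        cv = risk_forecast.balanced_cv_evaluate(labeled, config, seed=seed)
        summary = cv.summary()
        report["forecast"] = {
            "n_risk": cv.n_risk,
            "n_normal": cv.n_normal,
            "metrics_mean": summary["mean"].to_dict(),
            "metrics_sd": summary["std"].to_dict(),
            "top_features": risk_forecast.feature_importance_summary(cv)
            .head(10)["median"]
            .to_dict(),
        }
    except ValueError as exc:
        report["forecast"] = {"error": str(exc)}
    done("forecast", t0)
    return _finish(manifest, report, table, out_dir)


def _finish(manifest, report, table, out_dir):
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report_path = out / "report.json"
        report_path.write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True))
        manifest.add_file(report_path)
        manifest_path = out / "manifest.json"
        manifest_path.write_text(
            json.dumps(_jsonify(dataclasses.asdict(manifest)), indent=2, sort_keys=True)
        )
    return manifest, report
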