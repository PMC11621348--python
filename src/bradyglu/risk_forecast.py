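"""Bradycardia risk-zone labeling and balanced bootstrap classification.

Windows are partitioned into three zones relative to the merged episode
groups: *excluded* (the window contains an episode, or sits near a group
without qualifying as risk), *risk* (the window immediately preceding a
group's start, within the 5-minute lead), and *normal* (windows clear of
every group by more than the buffer on both sides). Features are Z-scored
within each patient, pooled, and a Random-Forest classifier separates risk
from normal under repeated class-balanced undersampling with stratified
5-fold cross-validation (50 iterations by default). Reported metrics are
per-iteration fold means, summarized as mean +/- SD, plus pooled
precision-recall curves and impurity-based feature importances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    auc,
    f1_score,
    precision_recall_curve as _sk_pr_curve,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .episode_detection import EpisodeGroup
from .rng import derive_rng
from .signal_io import HRV_FEATURES, AnalysisConfig

logger = logging.getLogger("bradyglu")

ZONES = ("risk", "normal", "excluded")

#: Feature set fed to the classifier: 29 HRV features + glucose + clock.
CLASSIFIER_FEATURES = HRV_FEATURES + ["glucose_mgdl", "c24_sin", "c24_cos"]
#: Clock features enter unscaled: they are already bounded and comparable.
SCALE_EXEMPT = {"c24_sin", "c24_cos"}


@dataclass
class CVReport:
    """Metric and importance distributions across balanced CV iterations."""

    metrics: pd.DataFrame           # one row per iteration
    importances: pd.DataFrame       # one row per iteration, columns = features
    pr_curves: list = field(default_factory=list)  # (precision, recall) per iteration
    n_risk: int = 0
    n_normal: int = 0

    def summary(self) -> pd.DataFrame:
        return self.metrics.agg(["mean", "std"]).T


def label_windows(
    table: pd.DataFrame,
    groups_by_patient: dict[str, list[EpisodeGroup]],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Assign each window a zone: risk, normal, or excluded.

    A window is excluded when an episode group overlaps it; risk when its
    end falls within ``risk_lead_s`` before a group's start (and it is not
    excluded); normal when its distance to every group exceeds
    ``normal_buffer_s`` on both sides. Near-but-not-risk windows are
    excluded from both classes to avoid label leakage.
    """
    config = config or AnalysisConfig()
    w = config.window_len_s
    table = table.copy()
    zones = np.full(len(table), "normal", dtype=object)
    for pid, sub in table.groupby("patient_id"):
        groups = groups_by_patient.get(pid, [])
        starts = sub["window_start_s"].to_numpy()
        ends = starts + w
        zone = np.full(starts.size, "normal", dtype=object)
        if groups:
            g_start = np.array([g.start_s for g in groups])
            g_end = np.array([g.end_s for g in groups])
            overlaps = (starts[:, None] < g_end[None, :]) & (ends[:, None] > g_start[None, :])
            contains = overlaps.any(axis=1)
            lead_gap = g_start[None, :] - ends[:, None]
            is_risk = ((lead_gap >= 0) & (lead_gap < config.risk_lead_s)).any(axis=1) & ~contains
            # distance from window to each group (0 if overlapping)
            dist = np.maximum(
                np.maximum(g_start[None, :] - ends[:, None], starts[:, None] - g_end[None, :]),
                0.0,
            )
            near = (dist <= config.normal_buffer_s).any(axis=1)
            zone[near] = "excluded"
            zone[is_risk] = "risk"
            zone[contains] = "excluded"
        zones[table["patient_id"] == pid] = zone
    table["zone"] = zones
    return table


def zscore_per_patient(
    table: pd.DataFrame,
    features: list[str] | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Z-score each feature within each patient (zero-variance columns -> 0).

    Clock features are carried through unscaled; labels and metadata are
    untouched. Requires at least 2 windows per patient.
    """
    config = config or AnalysisConfig()
    features = [
        f for f in (features or CLASSIFIER_FEATURES) if f not in SCALE_EXEMPT
    ]
    table = table.copy()
    for pid, sub in table.groupby("patient_id"):
        if len(sub) < 2:
            raise ValueError(f"patient {pid}: need >= 2 windows to normalize")
        idx = sub.index
        block = sub[features].to_numpy(dtype=float)
        mean = np.nanmean(block, axis=0)
        sd = np.nanstd(block, axis=0, ddof=0)
        scaled = np.where(sd > 0, (block - mean) / np.where(sd > 0, sd, 1.0), 0.0)
        table.loc[idx, features] = scaled
    return table


def _design_matrix(table: pd.DataFrame, features: list[str]):
    labeled = table[table["zone"].isin(["risk", "normal"])]
    X = labeled[features].to_numpy(dtype=float)
    keep = np.all(np.isfinite(X), axis=1)
    labeled = labeled.loc[keep]
    return labeled[features].to_numpy(dtype=float), (
        labeled["zone"].to_numpy() == "risk"
    ).astype(int)


def balanced_cv_evaluate(
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    seed: int = 0,
    features: list[str] | None = None,
) -> CVReport:
    """Balanced bootstrap Random-Forest evaluation.

    Per iteration: undersample the normal class without replacement to the
    risk-class size, run stratified k-fold CV, record fold-mean accuracy,
    ROC-AUC, precision, recall and F1, the pooled out-of-fold PR curve, and
    the fold-mean impurity importances.
    """
    config = config or AnalysisConfig()
    features = features or CLASSIFIER_FEATURES
    X, y = _design_matrix(table, features)
    n_risk = int(y.sum())
    n_normal = int((y == 0).sum())
    if n_risk < 2 * config.cv_folds:
        raise ValueError(
            f"need >= {2 * config.cv_folds} risk windows for {config.cv_folds}-fold CV, "
            f"have {n_risk}"
        )
    if n_normal < n_risk:
        raise ValueError("normal class smaller than risk class; cannot undersample")

    risk_idx = np.flatnonzero(y == 1)
    normal_idx = np.flatnonzero(y == 0)
    metric_rows, importance_rows, pr_curves = [], [], []
    for it in range(config.cv_iterations):
        rng = derive_rng(seed, "cv", it)
        pick = rng.choice(normal_idx, size=n_risk, replace=False)
        sel = np.concatenate([risk_idx, pick])
        Xb, yb = X[sel], y[sel]
        skf = StratifiedKFold(
            n_splits=config.cv_folds,
            shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        fold_metrics = []
        fold_importance = []
        oof_scores = np.zeros(yb.size)
        for train, test in skf.split(Xb, yb):
            clf = RandomForestClassifier(
                n_estimators=config.rf_n_estimators,
                max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            clf.fit(Xb[train], yb[train])
            scores = clf.predict_proba(Xb[test])[:, 1]
            pred = (scores >= 0.5).astype(int)
            oof_scores[test] = scores
            fold_metrics.append({
                "accuracy": accuracy_score(yb[test], pred),
                "auc": roc_auc_score(yb[test], scores),
                "precision": precision_score(yb[test], pred, zero_division=0),
                "recall": recall_score(yb[test], pred, zero_division=0),
                "f1": f1_score(yb[test], pred, zero_division=0),
            })
            fold_importance.append(clf.feature_importances_)
        metric_rows.append(pd.DataFrame(fold_metrics).mean().to_dict())
        imp = np.mean(fold_importance, axis=0)
        importance_rows.append(imp / imp.sum() if imp.sum() > 0 else imp)
        prec, rec, _ = _sk_pr_curve(yb, oof_scores)
        pr_curves.append((prec, rec))
    return CVReport(
        metrics=pd.DataFrame(metric_rows),
        importances=pd.DataFrame(importance_rows, columns=features),
        pr_curves=pr_curves,
        n_risk=n_risk,
        n_normal=n_normal,
    )


def precision_recall_curve(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Precision-recall curve with step-integrated area for pooled scores."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to build a precision-recall curve")
    precision, recall, thresholds = _sk_pr_curve(labels, np.asarray(scores, dtype=float))
    area = float(auc(recall, precision))
    return {
        "precision": precision,
        "recall": recall,
        "thresholds": thresholds,
        "area": area,
    }


def feature_importance_summary(report: CVReport) -> pd.DataFrame:
    """Per-feature importance distribution across iterations, ranked by
    median (descending)."""
    imp = report.importances
    out = pd.DataFrame({
        "median": imp.median(),
        "q25": imp.quantile(0.25),
        "q75": imp.quantile(0.75),
        "mean": imp.mean(),
    })
    return out.sort_values("median", ascending=False)
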