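"""Statistical battery linking glucose tertiles, time of day, HRV and
bradycardia.

Four analyses operate on the annotated feature table:

* pairwise Mann-Whitney U tests of per-patient bradycardia frequencies
  between tertile levels;
* the hourly heart-rate / glucose correlation: mean HR and mean glucose per
  clock hour averaged across patients, Pearson r over the 24 hourly pairs;
* a time-banded bootstrap Fisher enrichment: for each 3-hour clock band and
  each extreme tertile, windows are resampled with replacement and a signed
  statistic -log10(p) * direction summarizes whether bradycardia windows are
  over- or under-represented in that tertile;
* a bootstrap Wilcoxon rank-sum screen of every HRV feature between windows
  with and without bradycardia, on repeated balanced subsamples (200 per
  class), signed by the difference of class means.

No multiple-testing correction is applied; stratum sizes are reported so
users can adjust externally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as spst

from .rng import derive_rng
from .signal_io import HRV_FEATURES, AnalysisConfig

logger = logging.getLogger("bradyglu")

#: The eight 3-hour clock bands, by starting hour.
TIME_BANDS = [(h, h + 3) for h in range(0, 24, 3)]
#: Strata with fewer windows than this are flagged unreliable.
MIN_BAND_WINDOWS = 20
#: Conventional absolute glucose cut-offs in mg/dL.
ABSOLUTE_CUTS_MGDL = (70.0, 180.0)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows brady / non-brady windows, columns
    in-tertile / not-in-tertile."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class PairwiseUTestResult:
    comparison: str
    u_statistic: float
    p_value: float
    n1: int
    n2: int


@dataclass
class SignedEnrichmentResult:
    """Bootstrap distribution of signed -log10(p) statistics for one stratum."""

    stratum: str
    sample: np.ndarray
    n_windows: int
    reliable: bool = True

    @property
    def median(self) -> float:
        return float(np.median(self.sample))

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        return (
            float(np.quantile(self.sample, alpha)),
            float(np.quantile(self.sample, 1.0 - alpha)),
        )


# ---------------------------------------------------------------------------
# Core statistics


@lru_cache(maxsize=200_000)
def _hypergeom_pmf(n: int, r1: int, c1: int) -> tuple[int, np.ndarray]:
    k_lo = max(0, c1 - (n - r1))
    k_hi = min(c1, r1)
    k = np.arange(k_lo, k_hi + 1)
    return k_lo, spst.hypergeom.pmf(k, n, r1, c1)


def fisher_two_sided_p(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of tables
    no more likely than the observed one, at fixed margins."""
    a = table.a
    k_lo, pmf = _hypergeom_pmf(table.total, table.a + table.b, table.a + table.c)
    p_obs = pmf[a - k_lo]
    # scipy-compatible relative tolerance when comparing likelihoods
    return float(min(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum(), 1.0))


def fisher_signed(table: ContingencyTable2x2) -> float:
    """Direction-signed Fisher statistic -log10(p) * sign(a - E[a]).

    p is the two-sided Fisher exact probability; the direction compares the
    observed brady-in-tertile count to its fixed-margin expectation
    E[a] = row1 * col1 / total. Returns 0 for p = 1 or degenerate margins.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, table.total
    if row1 == 0 or col1 == 0 or (c + d) == 0 or (b + d) == 0:
        logger.debug("zero-margin contingency table; signed statistic set to 0")
        return 0.0
    p = fisher_two_sided_p(table)
    expected_a = row1 * col1 / n
    direction = float(np.sign(a - expected_a))
    if p >= 1.0:
        return 0.0
    return float(-math.log10(p) * direction)


def mannwhitney_tertile_comparison(
    freqs_by_level: dict[str, "np.ndarray | list"],
    exact_max_n: int = 20,
) -> list[PairwiseUTestResult]:
    """Two-sided Mann-Whitney U tests for each tertile pair.

    Input maps level -> per-patient bradycardia frequencies. The exact null
    distribution is enumerated when the combined sample size is at most
    ``exact_max_n``; larger samples use the tie-corrected normal
    approximation.
    """
    pairs = [("low", "medium"), ("low", "high"), ("medium", "high")]
    out = []
    for lv1, lv2 in pairs:
        x = np.asarray(freqs_by_level.get(lv1, []), dtype=float)
        y = np.asarray(freqs_by_level.get(lv2, []), dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError(f"need >= 2 patients per group for {lv1} vs {lv2}")
        method = "exact" if (x.size + y.size) <= exact_max_n else "asymptotic"
        res = spst.mannwhitneyu(x, y, alternative="two-sided", method=method)
        out.append(
            PairwiseUTestResult(
                comparison=f"{lv1} vs {lv2}",
                u_statistic=float(res.statistic),
                p_value=float(res.pvalue),
                n1=int(x.size),
                n2=int(y.size),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Feature-table helpers


def clock_hour(table: pd.DataFrame) -> np.ndarray:
    """Recover each window's clock hour from its circadian encoding."""
    theta = np.arctan2(table["c24_sin"].to_numpy(), table["c24_cos"].to_numpy())
    return (theta * 24.0 / (2.0 * np.pi)) % 24.0


def _band_label(lo: int, hi: int) -> str:
    return f"{lo:02d}:00-{hi % 24:02d}:00"


def _brady_tertile_table(
    brady: np.ndarray, in_tertile: np.ndarray
) -> ContingencyTable2x2:
    return ContingencyTable2x2(
        a=int(np.sum(brady & in_tertile)),
        b=int(np.sum(brady & ~in_tertile)),
        c=int(np.sum(~brady & in_tertile)),
        d=int(np.sum(~brady & ~in_tertile)),
    )


# ---------------------------------------------------------------------------
# Bootstrap analyses


def bootstrap_fisher_by_timeband(
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> dict[str, SignedEnrichmentResult]:
    """Signed Fisher enrichment per (3-hour band, extreme tertile) stratum.

    Within each band, windows (with a tertile level) are resampled with
    replacement at original size; each replicate forms the 2x2 table
    brady/non-brady x in-tertile/not and yields one signed statistic. The
    bootstrap repeats ``n_boot_fisher`` times (default 100).
    """
    config = config or AnalysisConfig()
    usable = table[(table["tertile"].isin(["low", "medium", "high"]))].copy()
    hours = clock_hour(usable)
    brady_all = usable["contains_brady_event"].to_numpy(dtype=bool)
    tert_all = usable["tertile"].to_numpy()

    results: dict[str, SignedEnrichmentResult] = {}
    for lo, hi in TIME_BANDS:
        in_band = (hours >= lo) & (hours < hi)
        brady = brady_all[in_band]
        tert = tert_all[in_band]
        n = int(in_band.sum())
        for level in ("low", "high"):
            stratum = f"{_band_label(lo, hi)}|{level}"
            rng = derive_rng(seed, "fisher", lo, level)
            sample = np.zeros(config.n_boot_fisher)
            if n > 0:
                in_t = tert == level
                for it in range(config.n_boot_fisher):
                    idx = rng.integers(0, n, size=n)
                    try:
                        sample[it] = fisher_signed(
                            _brady_tertile_table(brady[idx], in_t[idx])
                        )
                    except ValueError:
                        sample[it] = 0.0
            results[stratum] = SignedEnrichmentResult(
                stratum=stratum,
                sample=sample,
                n_windows=n,
                reliable=n >= MIN_BAND_WINDOWS,
            )
    return results


def wilcoxon_hrv_bootstrap(
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    seed: int = 0,
    features: list[str] | None = None,
) -> dict[str, SignedEnrichmentResult]:
    """Signed rank-sum significance of each HRV feature for bradycardia.

    Per iteration, equal-size subsamples (default 200) are drawn without
    replacement from windows with and without bradycardia; a two-sided
    Wilcoxon rank-sum test per feature gives -log10(p), signed by
    sign(mean_brady - mean_non_brady).
    """
    config = config or AnalysisConfig()
    features = features or HRV_FEATURES
    valid = table[table["valid"]]
    brady = valid[valid["contains_brady_event"]]
    normal = valid[~valid["contains_brady_event"]]
    n_sample = config.wilcoxon_sample_n
    min_class = min(len(brady), len(normal))
    if min_class == 0:
        raise ValueError("both classes must be non-empty")
    if min_class < n_sample:
        logger.warning(
            "class size %d below requested subsample %d; reducing", min_class, n_sample
        )
        n_sample = min_class

    results = {}
    b_mat = brady[features].to_numpy(dtype=float)
    n_mat = normal[features].to_numpy(dtype=float)
    samples = {f: np.zeros(config.n_boot_wilcoxon) for f in features}
    for it in range(config.n_boot_wilcoxon):
        rng = derive_rng(seed, "wilcoxon", it)
        bi = rng.choice(len(b_mat), size=n_sample, replace=False)
        ni = rng.choice(len(n_mat), size=n_sample, replace=False)
        for j, feat in enumerate(features):
            xb = b_mat[bi, j]
            xn = n_mat[ni, j]
            xb = xb[np.isfinite(xb)]
            xn = xn[np.isfinite(xn)]
            if xb.size < 2 or xn.size < 2:
                continue
            stat = spst.ranksums(xb, xn)
            direction = float(np.sign(xb.mean() - xn.mean()))
            p = max(stat.pvalue, 1e-300)
            samples[feat][it] = 0.0 if p >= 1.0 else -math.log10(p) * direction
    for feat in features:
        results[feat] = SignedEnrichmentResult(
            stratum=feat, sample=samples[feat], n_windows=int(len(brady))
        )
    return results


# ---------------------------------------------------------------------------
# Descriptive analyses


def hourly_hr_glucose_correlation(table: pd.DataFrame) -> dict:
    """Pearson correlation of the 24-hour mean HR and glucose profiles.

    Profiles are built per patient per clock hour, then averaged across
    patients; the correlation runs over the hourly pairs. Per-hour 95%
    confidence intervals across patients are included for plotting.
    """
    valid = table[table["valid"]].copy()
    # epsilon guards against arctan2 round-trip landing just below an integer
    valid["hour"] = (np.floor(clock_hour(valid) + 1e-6) % 24).astype(int)
    per_patient = valid.groupby(["patient_id", "hour"], observed=True).agg(
        hr=("HR-mean", "mean"), glucose=("glucose_mgdl", "mean")
    )
    by_hour = per_patient.groupby("hour")
    prof = by_hour.agg(
        hr_mean=("hr", "mean"),
        hr_sem=("hr", "sem"),
        glucose_mean=("glucose", "mean"),
        glucose_sem=("glucose", "sem"),
        n=("hr", "count"),
    )
    prof = prof.dropna(subset=["hr_mean", "glucose_mean"])
    if len(prof) < 3:
        raise ValueError("need at least 3 hourly bins with data")
    r, p = spst.pearsonr(prof["hr_mean"], prof["glucose_mean"])
    z = 1.959963984540054
    prof = prof.assign(
        hr_ci_lo=prof["hr_mean"] - z * prof["hr_sem"],
        hr_ci_hi=prof["hr_mean"] + z * prof["hr_sem"],
        glucose_ci_lo=prof["glucose_mean"] - z * prof["glucose_sem"],
        glucose_ci_hi=prof["glucose_mean"] + z * prof["glucose_sem"],
    )
    return {"r": float(r), "p": float(p), "profile": prof.reset_index()}


def tertile_event_shares(table: pd.DataFrame) -> dict:
    """Percentage breakdowns of windows and bradycardia windows by tertile.

    Returns overall per-tertile shares of brady windows, per-3-hour-band
    shares of all windows and of brady windows, and the absolute-glucose
    breakdown (< 70, 70-180, > 180 mg/dL) of brady windows.
    """
    usable = table[table["tertile"].isin(["low", "medium", "high"])].copy()
    brady = usable[usable["contains_brady_event"]]

    def shares(sub: pd.DataFrame) -> dict:
        if len(sub) == 0:
            return {lv: float("nan") for lv in ("low", "medium", "high")}
        counts = sub["tertile"].value_counts()
        return {
            lv: 100.0 * counts.get(lv, 0) / len(sub) for lv in ("low", "medium", "high")
        }

    hours = clock_hour(usable)
    band_all, band_brady = {}, {}
    for lo, hi in TIME_BANDS:
        label = _band_label(lo, hi)
        m = (hours >= lo) & (hours < hi)
        band_all[label] = shares(usable[m])
        band_brady[label] = shares(usable[m & usable["contains_brady_event"].to_numpy()])

    g = brady["glucose_mgdl"].to_numpy(dtype=float)
    g = g[np.isfinite(g)]
    lo_cut, hi_cut = ABSOLUTE_CUTS_MGDL
    if g.size:
        absolute = {
            "below_70": 100.0 * float(np.mean(g < lo_cut)),
            "70_to_180": 100.0 * float(np.mean((g >= lo_cut) & (g <= hi_cut))),
            "above_180": 100.0 * float(np.mean(g > hi_cut)),
        }
    else:
        absolute = {k: float("nan") for k in ("below_70", "70_to_180", "above_180")}
    return {
        "overall_brady": shares(brady),
        "by_band_windows": band_all,
        "by_band_brady": band_brady,
        "absolute_brady": absolute,
        "n_brady_windows": int(len(brady)),
        "n_windows": int(len(usable)),
    }


def per_patient_brady_freq_by_tertile(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-patient bradycardia-window rates within each tertile level,
    the input for the pairwise Mann-Whitney comparison."""
    usable = table[table["tertile"].isin(["low", "medium", "high"])]
    out = {}
    for level in ("low", "medium", "high"):
        rates = []
        for _, sub in usable.groupby("patient_id"):
            in_level = sub[sub["tertile"] == level]
            if len(in_level):
                rates.append(float(in_level["contains_brady_event"].mean()) * 100.0)
        out[level] = np.asarray(rates)
    return out
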