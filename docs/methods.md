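# Methods

This note documents the models, conventions and numerical choices behind
`bradyglu`, in the order the pipeline runs them.

## Data model

Each patient contributes two time-aligned streams sharing one time origin
(seconds since recording start): a beat-by-beat RR series (ms) extracted from
Holter ECG, and interstitial glucose (mg/dL) reported as 5-minute averages on
a 300-s grid. The wall-clock hour of the recording start is metadata
(default midnight) and feeds the circadian features. Files are plain CSV;
floats are written with 17 significant digits and parsed with a
correctly-rounded parser so write-then-read is bit-exact.

Recordings nominally span 7 days; shorter recordings are accepted with a
warning and analyzed over their available span.

## Bradycardia detection

A bradycardia episode is a maximal run of at least 5 consecutive beats whose
instantaneous heart rate 60000/RR is strictly below 45 bpm (equivalently RR
strictly above 60000/45 = 1333.3 ms; a beat at exactly 45 bpm breaks the
run). Episodes whose end-to-start gap is strictly less than 5 minutes are
chained into groups; a gap of exactly 5 minutes separates groups. Detection
runs on the raw RR stream *before* window-level artifact cleaning: the
cleaning step removes very long intervals, which are exactly the beats that
constitute bradycardia.

Per-patient burden is summarized as group count, an hour-of-day histogram of
group onsets, and a frequency category (<10, 10–50, >50 groups).

## Windowing, cleaning and the 29 HRV features

Recordings are tiled into non-overlapping half-open 5-minute windows
[k·300, (k+1)·300). Within each window, intervals outside [300, 3000] ms are
dropped as artifacts; a window is valid when the retained intervals cover at
least 50% of the 300 s and at least 10 intervals remain. Invalid windows keep
their metadata but carry missing features. CGM gaps of at most 3 grid slots
(15 min) are linearly interpolated; longer gaps stay missing. Each window's
glucose is the sample of its matching grid slot (CGM values are already
5-minute averages, so no further aggregation is applied).

Time-domain (14): SDNN and HR-std use the sample standard deviation (n−1);
pNN50/pNN20 are percentages of successive differences exceeding 50/20 ms;
RMSSD is the root mean square of successive differences; the HR statistics
(mean, median, std, max, min, peak-to-peak, kurtosis, skewness) act on the
per-beat series 60000/RR. Kurtosis is excess kurtosis and skewness the
standardized third moment, both with biased (population) moments. HR-mad is
the median absolute successive HR change; HR-zcr counts sign changes of the
mean-centered HR series divided by (n−1), with exact zeros not counted as
crossings.

Frequency-domain (9): RR(t), taken at each interval's ending beat, is
cubic-spline interpolated onto a 4-Hz grid spanning the window (1200
samples; the spline is edge-held outside the beat span), mean-removed, and
fed to a single full-length Hann-tapered Welch segment. Band powers
integrate the density with the trapezoid rule over VLF (0.0033–0.04 Hz),
LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz); total power integrates
0.0033–0.40 Hz. Normalized powers are 100·LF/(LF+HF) and 100·HF/(LF+HF);
the LF/HF ratio is reported ×100; band peaks are the argmax frequency of
the density within the band. The VLF band is retained for completeness but
is low-reliability on 5-minute windows (its lower edge equals the spectral
resolution 1/300 Hz).

Nonlinear (6): Poincaré SD1 = √(Var₀(ΔRR)/2) and
SD2 = √(2·Var₀(RR) − Var₀(ΔRR)/2) use population variances, which makes
SD1 = RMSSD/√2 exact on windows whose successive differences have zero
mean; the ellipse area π·SD1·SD2 is reported in ms² (an area, despite
occasionally being printed with a length unit elsewhere). Sample entropy
uses embedding m = 2, Chebyshev tolerance r = 0.2·SD(window), self-matches
excluded, and is missing when no template pair matches. Permutation entropy
uses order 3, lag 1, ties broken by order of appearance, normalized by
log 3! to [0, 1].

Circadian clock features are sin and cos of 2π·h/24 for the window's start
clock hour.

## Personalized relative glucose tertiles

Each patient's observed (post-imputation) glucose range [g_min, g_max] is
split into three equal-width thirds: low [g_min, b1), medium [b1, b2), high
[b2, g_max], left-closed with the maximum in "high"; out-of-range values
clamp to the nearest extreme level. The default computes one range per
patient over the full recording; a per-calendar-day mode recomputes ranges
daily for sensitivity analysis (days with fewer than 12 samples or a
degenerate range fall back to the recording-wide bounds). A constant series
has no defined tertiles and is an error. Equal-width division of the range
(not equal-count quantiles) is the construction throughout.

## Statistical battery

*Pairwise Mann–Whitney U.* Per-patient bradycardia-window rates within each
tertile are compared pairwise (low–medium, low–high, medium–high) with
two-sided U tests: the exact null distribution when the combined sample is
at most 20, the tie-corrected normal approximation otherwise.

*Hourly HR–glucose correlation.* Mean HR (HR-mean of valid windows) and mean
glucose per clock hour are formed per patient, averaged across patients, and
the Pearson correlation is taken over the hourly pairs; per-hour 95%
confidence intervals across patients accompany the profile.

*Time-banded signed Fisher enrichment.* For each of the eight 3-hour clock
bands and each extreme tertile (low, high), windows with a tertile level in
that band are resampled with replacement at original size, 100 times. Each
replicate forms the 2×2 table (bradycardia / non-bradycardia windows ×
in-tertile / not), and yields s = −log₁₀(p) · sign(a − E[a]) where p is the
two-sided Fisher exact probability and E[a] = row₁·col₁/n the fixed-margin
expectation; s = 0 when p = 1 or a margin is zero. The two-sided p is
computed from the hypergeometric pmf by the minimum-likelihood rule (total
probability of tables no more likely than the observed, with scipy's 1+1e−7
likelihood tolerance), cached per margin configuration; it is verified in
the test suite against exact integer enumeration for every table with total
≤ 60. Strata with fewer than 20 windows are flagged unreliable. No
multiple-testing correction is applied; stratum sizes are reported so users
can adjust externally.

*Bootstrap Wilcoxon HRV screen.* 100 iterations; each draws 200 windows per
class (with / without bradycardia) without replacement — reduced with a
warning when a class is smaller — and runs a two-sided rank-sum test per
feature; the statistic is −log₁₀(p) signed by the difference of class means.

## Risk forecasting

Windows are partitioned relative to merged episode groups: *excluded* when
a group overlaps the window; *risk* when the window's end lies within one
5-minute lead before a group's start; *normal* when the window is clear of
every group by more than a 5-minute buffer on both sides. Near-but-not-risk
windows are dropped from both classes to prevent label leakage; the buffer
and the lead (in windows) are configurable.

Features (29 HRV + glucose + the two clock terms) are Z-scored per patient
(clock terms exempt, zero-variance columns set to 0), pooled, and rows with
any missing feature are dropped. Per iteration (50 by default), the normal
class is undersampled without replacement to the risk-class size and a
Random Forest (500 trees, unlimited depth, √p features per split, per-fold
seeds derived from the iteration stream) is evaluated under stratified
5-fold cross-validation. Reported metrics (accuracy, ROC-AUC, precision,
recall, F1 at the 0.5 threshold) are fold means, aggregated across
iterations as mean ± SD; the PR curve pools out-of-fold scores within an
iteration; impurity importances are fold-averaged and renormalized to sum
to 1 per iteration. Z-scoring is kept for procedural fidelity even though
tree ensembles are scale-invariant; a config flag disables it.

## Synthetic cohort generator

The generator emulates the structure of synchronized 7-day Holter + CGM
recordings in patients with large between-patient glucose differences:

* **Glucose**: cosinor (mesor + amplitude·cos with a patient acrophase,
  default evening ≈ 18 h) + AR(1) noise (φ = 0.8 per 5-min step) + optional
  Gaussian-shaped hypoglycemic dips (default 0.5/day, 45 mg/dL deep,
  30 min wide), clipped to [20, 600] mg/dL.
* **RR**: instantaneous interval 60000/HR_circadian(t) plus sinusoidal LF
  (0.1 Hz) and HF (0.25 Hz) modulation and white beat noise; each beat
  advances time by its own interval. Parameter sets whose floor interval
  could reach 200 ms are rejected.
* **Episodes**: per 5-minute slot, the expected number of onsets is
  (base rate/12) × a tertile odds multiplier (low/high relative glucose at
  the slot) × a time-of-day multiplier on configurable clock hours. Each
  placed run re-spaces the beats spanning n_beats·60000/HR ms into n_beats
  equal slow intervals between unchanged span boundaries, so total duration
  and CGM alignment are preserved and every injected run satisfies the
  detector predicate by construction. Ground truth records each run's
  interval, beat count, HR, tertile and clock hour.
* **Pre-episode drift** (optional): HR is lowered on a linear ramp across
  the two lead windows before each injected run, with the modified intervals
  rescaled to preserve the ramp span's total duration. The compensating
  speed-up falls in the earlier window (which the labeling buffer excludes
  from the normal class), so the final pre-episode window shows a genuine
  decline in HR mean, median and minimum — the forecastable signal.

Per-patient parameters are drawn uniformly from cohort ranges chosen to
mirror a dialysis-age diabetic cohort (glucose mesor 130–210 mg/dL,
amplitude 15–40 mg/dL; HR mesor 62–84 bpm, amplitude 5–10 bpm, afternoon
acrophase), giving between-patient mean-glucose spreads well above
30 mg/dL. Everything is a pure function of (config, seed): substreams are
derived with a counter-based SeedSequence scheme keyed by stage and patient
index, so growing a cohort never perturbs existing patients.

What the generator does **not** emulate: meal and insulin pharmacokinetics,
sensor calibration drift and dropout bursts, ectopy/artifact structure of
real Holter R-peak detection, non-sinusoidal HRV (respiratory sinus
arrhythmia coupling, transients), or the clinical covariates of a real
cohort. Passing the recovery suites therefore shows the *pipeline* is
correct and calibrated, not that real recordings will show these effects.

## Validation design and problem sizes

The calibration and recovery suites, and the acceptance script, run on
cohorts of 4 patients × 2 days (the same code path handles 7-day cohorts of
any size). Null calibration uses 20 cohorts with no glucose–bradycardia
coupling; enrichment recovery plants 3× odds in the low tertile concentrated
at 06:00–09:00 and requires a positive median signed statistic in that
stratum in ≥ 90% of 20 seeds; forecasting recovery plants a 15-bpm
pre-episode drift and requires mean CV AUC ≥ 0.8 with the HR level features
top-ranked, while the drift-free cohort must stay ≤ 0.65. The permuted-label
null check uses 5 CV iterations × 100 trees (the statistic it checks — AUC
of label-permuted data — does not depend on these sizes).

## Known limitations

* The artifact/imputation rules (RR gate [300, 3000] ms, 50% coverage,
  15-min CGM interpolation) are this package's conventions; other choices
  are defensible and small differences propagate into the spectral features.
* VLF power on 5-minute windows is noise-dominated.
* The Fisher bootstrap resamples windows within band strata; windows are
  treated as exchangeable units, ignoring within-patient autocorrelation.
* The forecaster's precision/recall are evaluated on class-balanced samples;
  deployment-grade alarm performance at the true prevalence would be lower,
  and no calibration or alarm logic is provided.
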