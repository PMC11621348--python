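"""Independent straight-from-definition oracle implementations.

These deliberately use naive enumeration, explicit loops and textbook
formulas so they share no code path with the package; tests compare the
optimized implementations against them.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_episodes(rr_ms, beat_times, threshold_bpm=45.0, min_run=5):
    """Enumerate every candidate run of slow intervals and keep maximal ones."""
    n = len(rr_ms)
    slow = [60000.0 / rr_ms[i] < threshold_bpm for i in range(n)]
    episodes = []
    i = 0
    while i < n:
        if slow[i]:
            j = i
            while j < n and slow[j]:
                j += 1
            if j - i >= min_run:
                episodes.append((beat_times[i], beat_times[j], j - i))
            i = j
        else:
            i += 1
    return episodes


def time_domain_oracle(rr):
    """Table of 14 time-domain features computed with explicit loops."""
    rr = [float(v) for v in rr]
    n = len(rr)
    mean_rr = sum(rr) / n
    sdnn = math.sqrt(sum((v - mean_rr) ** 2 for v in rr) / (n - 1))
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    pnn50 = 100.0 * sum(1 for d in diffs if abs(d) > 50) / len(diffs)
    pnn20 = 100.0 * sum(1 for d in diffs if abs(d) > 20) / len(diffs)
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    hr = [60000.0 / v for v in rr]
    mean_hr = sum(hr) / n
    srt = sorted(hr)
    median_hr = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2
    std_hr = math.sqrt(sum((v - mean_hr) ** 2 for v in hr) / (n - 1))
    m2 = sum((v - mean_hr) ** 2 for v in hr) / n
    m3 = sum((v - mean_hr) ** 3 for v in hr) / n
    m4 = sum((v - mean_hr) ** 4 for v in hr) / n
    skew = m3 / m2**1.5
    kurt = m4 / m2**2 - 3.0
    dhr = [abs(hr[i + 1] - hr[i]) for i in range(n - 1)]
    dsrt = sorted(dhr)
    k = len(dsrt)
    mad = dsrt[k // 2] if k % 2 else (dsrt[k // 2 - 1] + dsrt[k // 2]) / 2
    centered = [v - mean_hr for v in hr]
    zc = sum(1 for i in range(n - 1) if centered[i] * centered[i + 1] < 0)
    return {
        "RR-sdnn": sdnn, "RR-pnn50": pnn50, "RR-pnn20": pnn20, "RR-rmssd": rmssd,
        "HR-mean": mean_hr, "HR-median": median_hr, "HR-std": std_hr,
        "HR-max": max(hr), "HR-min": min(hr), "HR-p2p": max(hr) - min(hr),
        "HR-kurtosis": kurt, "HR-skewness": skew, "HR-mad": mad,
        "HR-zcr": zc / (n - 1),
    }


def poincare_oracle(rr):
    """SD1/SD2/area/ratio from hand-evaluated population-variance formulas."""
    rr = [float(v) for v in rr]
    n = len(rr)
    mean_rr = sum(rr) / n
    var_rr = sum((v - mean_rr) ** 2 for v in rr) / n
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    mean_d = sum(diffs) / len(diffs)
    var_d = sum((d - mean_d) ** 2 for d in diffs) / len(diffs)
    sd1 = math.sqrt(var_d / 2.0)
    sd2 = math.sqrt(max(2.0 * var_rr - var_d / 2.0, 0.0))
    return {
        "RR-sd1": sd1,
        "RR-sd2": sd2,
        "RR-s-area": math.pi * sd1 * sd2,
        "RR-sd-ratio": sd1 / sd2 if sd2 > 0 else float("nan"),
    }


def sample_entropy_oracle(x, m=2, r=None):
    """O(n^2) template counting with explicit pair loops."""
    x = [float(v) for v in x]
    n = len(x)
    if r is None:
        mean = sum(x) / n
        r = 0.2 * math.sqrt(sum((v - mean) ** 2 for v in x) / n)

    def count(mm):
        total = 0
        n_t = n - mm + 1
        for i in range(n_t):
            for j in range(i + 1, n_t):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def permutation_entropy_oracle(x, order=3, lag=1):
    """Ordinal-pattern histogram built with explicit tuple keys."""
    x = [float(v) for v in x]
    n = len(x) - (order - 1) * lag
    counts = {}
    for i in range(n):
        vec = [x[i + k * lag] for k in range(order)]
        pattern = tuple(sorted(range(order), key=lambda k: vec[k]))
        counts[pattern] = counts.get(pattern, 0) + 1
    probs = [c / n for c in counts.values()]
    h = -sum(p * math.log(p) for p in probs)
    return h / math.log(math.factorial(order))


def spectral_oracle(beat_times, rr_ms, window_start, window_len=300.0, fs=4.0):
    """Band powers via an explicit Hann-tapered DFT of the cubic-resampled
    tachogram (no scipy.signal)."""
    from scipy.interpolate import CubicSpline

    t = np.asarray(beat_times, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    n = int(round(window_len * fs))
    grid = window_start + np.arange(n) / fs
    x = CubicSpline(t, rr)(np.clip(grid, t[0], t[-1]))
    x = x - x.mean()
    w = np.array([0.5 - 0.5 * math.cos(2 * math.pi * k / n) for k in range(n)])
    xw = x * w
    # one-sided periodogram density, normalized by fs * sum(w^2)
    spec = np.abs(np.fft.rfft(xw)) ** 2 / (fs * (w**2).sum())
    spec[1:-1] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    def band(lo, hi):
        m = (freqs >= lo) & (freqs <= hi)
        f, p = freqs[m], spec[m]
        total = 0.0
        for i in range(len(f) - 1):
            total += 0.5 * (p[i] + p[i + 1]) * (f[i + 1] - f[i])
        return total

    def peak(lo, hi):
        m = (freqs >= lo) & (freqs <= hi)
        f, p = freqs[m], spec[m]
        return float(f[int(np.argmax(p))])

    vlf, lf, hf = band(0.0033, 0.04), band(0.04, 0.15), band(0.15, 0.40)
    out = {
        "RR-vlf-power": vlf, "RR-lf-power": lf, "RR-hf-power": hf,
        "RR-total-power": band(0.0033, 0.40),
        "RR-lf-peak": peak(0.04, 0.15), "RR-hf-peak": peak(0.15, 0.40),
        "RR-lf-norm": float("nan"), "RR-hf-norm": float("nan"),
        "RR-lfhf-ratio": float("nan"),
    }
    if lf + hf > 0:
        out["RR-lf-norm"] = 100.0 * lf / (lf + hf)
        out["RR-hf-norm"] = 100.0 * hf / (lf + hf)
    if hf > 0:
        out["RR-lfhf-ratio"] = 100.0 * lf / hf
    return out


def fisher_exact_oracle(a, b, c, d):
    """Two-sided Fisher exact p by hypergeometric enumeration with exact
    integer binomials (scipy-free)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    k_lo = max(0, c1 - r2)
    k_hi = min(c1, r1)
    p_obs = math.comb(r1, a) * math.comb(r2, c1 - a) / denom
    total = 0.0
    for k in range(k_lo, k_hi + 1):
        p_k = math.comb(r1, k) * math.comb(r2, c1 - k) / denom
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(total, 1.0)


def mannwhitney_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y

    def u_of(idx_x):
        ux = 0.0
        xs = [pooled[i] for i in idx_x]
        ys = [pooled[i] for i in range(n1 + n2) if i not in idx_x]
        for xv in xs:
            for yv in ys:
                if xv > yv:
                    ux += 1.0
                elif xv == yv:
                    ux += 0.5
        return ux

    u_obs = 0.0
    for xv in x:
        for yv in y:
            if xv > yv:
                u_obs += 1.0
            elif xv == yv:
                u_obs += 0.5
    dev_obs = abs(u_obs - n1 * n2 / 2.0)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(set(idx)) - n1 * n2 / 2.0) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total
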