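"""Bradycardia episode detection and grouping.

A bradycardia episode is a maximal run of more than 4 consecutive beats
whose instantaneous heart rate (60000 / RR in ms) is strictly below the
45-bpm threshold, i.e. RR strictly above 60000/45 = 1333.3 ms. Episodes
closer together than 5 minutes (end of the earlier to start of the later)
are merged into one group by single-linkage chaining.

Detection always runs on the raw RR stream, before any window-level
artifact cleaning: the cleaning rules drop very long intervals, which are
exactly the phenomenon under study here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import AnalysisConfig, RRSeries


@dataclass(frozen=True)
class BradycardiaEpisode:
    """A maximal run of consecutive slow beats.

    ``n_beats`` counts the slow intervals in the run; ``start_s``/``end_s``
    are the times of the first and last beat bounding those intervals.
    """

    start_s: float
    end_s: float
    n_beats: int
    min_hr_bpm: float


@dataclass
class EpisodeGroup:
    """A cluster of episodes separated pairwise by less than the merge gap."""

    start_s: float
    end_s: float
    episodes: list = field(default_factory=list)

    @property
    def episode_count(self) -> int:
        return len(self.episodes)


def detect_bradycardia(
    rr: RRSeries, config: AnalysisConfig | None = None
) -> list[BradycardiaEpisode]:
    """Find all maximal runs of >= ``min_run_beats`` consecutive slow beats.

    Strict inequality HR < threshold is used: a beat at exactly 45 bpm
    breaks a run. Returns episodes ordered by start time.
    """
    config = config or AnalysisConfig()
    rr_ms = rr.rr_ms
    if rr_ms.size == 0:
        return []
    hr = 60000.0 / rr_ms
    slow = hr < config.hr_threshold_bpm
    episodes: list[BradycardiaEpisode] = []
    for i0, i1 in _runs(slow):
        n = i1 - i0
        if n >= config.min_run_beats:
            episodes.append(
                BradycardiaEpisode(
                    start_s=float(rr.beat_times[i0]),
                    end_s=float(rr.beat_times[i1]),
                    n_beats=int(n),
                    min_hr_bpm=float(hr[i0:i1].min()),
                )
            )
    return episodes


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs in ``mask``."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return zip(edges[::2], edges[1::2])


def group_episodes(
    episodes: list[BradycardiaEpisode], config: AnalysisConfig | None = None
) -> list[EpisodeGroup]:
    """Merge episodes into groups by single-linkage chaining.

    Two consecutive episodes join the same group when the gap from the end
    of the earlier to the start of the later is strictly less than
    ``episode_merge_gap_s``; an exact 5-minute gap keeps them apart.
    """
    config = config or AnalysisConfig()
    if not episodes:
        return []
    starts = np.array([e.start_s for e in episodes])
    if np.any(np.diff(starts) < 0):
        raise ValueError("episodes must be sorted by start time")
    groups = [EpisodeGroup(episodes[0].start_s, episodes[0].end_s, [episodes[0]])]
    for ep in episodes[1:]:
        if ep.start_s - groups[-1].end_s < config.episode_merge_gap_s:
            g = groups[-1]
            g.episodes.append(ep)
            g.end_s = max(g.end_s, ep.end_s)
        else:
            groups.append(EpisodeGroup(ep.start_s, ep.end_s, [ep]))
    return groups


#: Frequency categories used to summarize per-patient burden.
FREQUENCY_BINS = ("<10", "10-50", ">50")


def episode_summary(
    groups: list[EpisodeGroup], days: float, start_clock_h: float = 0.0
) -> dict:
    """Per-patient burden summary: group count, hour-of-day histogram of
    group onsets, and the frequency category (<10, 10-50, >50 groups)."""
    hist = np.zeros(24, dtype=int)
    for g in groups:
        hour = int((start_clock_h + g.start_s / 3600.0) % 24)
        hist[hour] += 1
    n = len(groups)
    if n < 10:
        category = "<10"
    elif n <= 50:
        category = "10-50"
    else:
        category = ">50"
    return {
        "group_count": n,
        "episode_count": int(sum(g.episode_count for g in groups)),
        "per_day": n / days if days > 0 else float("nan"),
        "hourly_histogram": hist.tolist(),
        "category": category,
    }
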