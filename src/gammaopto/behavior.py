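"""Locomotor-speed and Y-maze alternation analyses.

Speed is the frame-to-frame Euclidean displacement scaled by the frame
rate, moving-average smoothed, and stratified into rest/run states; the
alternation index scores sliding windows of three consecutive arm entries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .session import ArmEntrySequence, BehaviorTrack
from .stats import TestReport, ks_normal, paired_compare


@dataclass
class SpeedSeries:
    t: np.ndarray  # s, one entry per frame transition
    speed: np.ndarray  # cm/s, smoothed
    state: np.ndarray  # "rest" | "run" per frame
    fps: float

    def state_at(self, time: float) -> str:
        i = int(np.clip(np.searchsorted(self.t, time), 0, self.t.size - 1))
        return str(self.state[i])


@dataclass
class TriggeredAverage:
    lags: np.ndarray
    mean: np.ndarray
    se: np.ndarray  # NaN when fewer than 2 triggers
    n: int

    @property
    def empty(self) -> bool:
        return self.n == 0


@dataclass
class AlternationResult:
    index: float | None  # percent; None when fewer than 3 entries
    n_entries: int
    n_alternations: int
    time_course: list | None = None  # (block start s, index or None)

    @property
    def defined(self) -> bool:
        return self.index is not None


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p: float
    normal: bool
    pairwise: list  # (group_a, group_b, p)


def compute_speed(
    track: BehaviorTrack,
    smooth_window: int = 5,
    rest_threshold: float = 1.0,
    rest_min_duration: float = 1.0,
) -> SpeedSeries:
    """Instantaneous locomotion speed with rest/run stratification.

    ``speed[i] = fps * |pos[i+1] - pos[i]|``, moving-average smoothed over
    ``smooth_window`` frames. Rest frames are sub-threshold runs sustained
    for at least ``rest_min_duration`` seconds.
    """
    if track.n_frames < 2:
        raise ValueError("at least two frames are required")
    dt = np.diff(track.t)
    if np.max(np.abs(dt - 1.0 / track.fps)) > 1e-3 / track.fps:
        raise ValueError("frame times are not uniform at 1/fps")
    raw = track.fps * np.hypot(np.diff(track.x), np.diff(track.y))
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        speed = np.convolve(raw, kernel, mode="same")
    else:
        speed = raw
    below = speed < rest_threshold
    min_frames = max(1, int(round(rest_min_duration * track.fps)))
    state = np.full(speed.size, "run", dtype="U4")
    i = 0
    for flag, grp in itertools.groupby(below):
        length = sum(1 for _ in grp)
        if flag and length >= min_frames:
            state[i : i + length] = "rest"
        i += length
    return SpeedSeries(t=track.t[:-1], speed=speed, state=state, fps=track.fps)


def laser_triggered_speed(
    speed: SpeedSeries,
    onsets,
    window: float = 10.0,
    state_filter: str | None = None,
    state_margin: float = 0.25,
) -> TriggeredAverage:
    """Speed segments aligned at stimulation onsets, averaged over triggers.

    Triggers are kept when the animal is in ``state_filter`` shortly before
    onset (``state_margin`` seconds earlier, so the centered speed smoothing
    cannot leak the evoked response into the state judgment; no filtering
    when None). Out-of-range parts of a segment are NaN-padded; a result
    with zero qualifying triggers is returned flagged empty.
    """
    onsets = np.asarray(onsets, dtype=float)
    fps = speed.fps
    half = int(round(window * fps))
    lags = np.arange(-half, half + 1) / fps
    segments = []
    for t0 in onsets:
        t_state = max(t0 - state_margin, float(speed.t[0]))
        if state_filter is not None and speed.state_at(t_state) != state_filter:
            continue
        i0 = int(round((t0 - speed.t[0]) * fps))
        seg = np.full(lags.size, np.nan)
        lo = max(0, i0 - half)
        hi = min(speed.speed.size, i0 + half + 1)
        if hi > lo:
            seg[lo - (i0 - half) : hi - (i0 - half)] = speed.speed[lo:hi]
        segments.append(seg)
    if not segments:
        warnings.warn("no qualifying triggers", RuntimeWarning, stacklevel=2)
        return TriggeredAverage(lags, np.full(lags.size, np.nan), np.full(lags.size, np.nan), 0)
    seg = np.array(segments)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(seg, axis=0)
        if seg.shape[0] >= 2:
            se = np.nanstd(seg, axis=0, ddof=1) / np.sqrt(np.sum(np.isfinite(seg), axis=0))
        else:
            se = np.full(lags.size, np.nan)
    return TriggeredAverage(lags, mean, se, n=seg.shape[0])


def alternation_index(entries: ArmEntrySequence, block: float | None = None) -> AlternationResult:
    """Spontaneous-alternation index.

    A sliding window of three consecutive entries counts as an alternation
    iff its three arms are distinct; the index is
    ``100 x alternations / (entries - 2)``. With ``block`` set, a per-block
    time course is added (disjoint blocks; windows assigned by the time of
    their third entry).
    """
    arms = entries.arms
    times = entries.times
    n = len(arms)
    if n < 3:
        warnings.warn("fewer than 3 entries; alternation index undefined", RuntimeWarning, stacklevel=2)
        return AlternationResult(None, n, 0)
    wins = [(times[i + 2], len({arms[i], arms[i + 1], arms[i + 2]}) == 3) for i in range(n - 2)]
    n_alt = sum(ok for _, ok in wins)
    index = 100.0 * n_alt / (n - 2)
    time_course = None
    if block is not None:
        time_course = []
        t_end = times[-1]
        b0 = 0.0
        while b0 <= t_end:
            in_block = [ok for t, ok in wins if b0 <= t < b0 + block]
            time_course.append(
                (b0, 100.0 * sum(in_block) / len(in_block) if in_block else None)
            )
            b0 += block
    return AlternationResult(index, n, n_alt, time_course)


def group_comparison(groups: dict, design: str = "independent") -> GroupComparison:
    """Multi-group comparison behind a KS normality gate.

    Two groups: t-test (or paired comparison) when both pass the gate, else
    Mann-Whitney U / Wilcoxon. More groups: one-way ANOVA with pairwise
    Tukey contrasts, else Kruskal-Wallis with pairwise Mann-Whitney U.
    """
    names = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in names]
    if len(values) < 2:
        raise ValueError("at least two groups are required")
    for name, v in zip(names, values):
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    normal = all(ks_normal(v) for v in values)

    if len(values) == 2:
        a, b = values
        if design == "paired":
            rep = paired_compare(a, b)
            return GroupComparison(rep.test_name, rep.statistic, rep.p, normal, [(names[0], names[1], rep.p)])
        if normal:
            res = sps.ttest_ind(a, b)
            name = "t"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            name = "mannwhitneyu"
        return GroupComparison(name, float(res.statistic), float(res.pvalue), normal, [(names[0], names[1], float(res.pvalue))])

    if normal:
        stat, p = sps.f_oneway(*values)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        data = np.concatenate(values)
        labels = np.concatenate([[nm] * v.size for nm, v in zip(names, values)])
        tk = pairwise_tukeyhsd(data, labels)
        pairwise = [
            (str(r[0]), str(r[1]), float(r[3]))
            for r in tk.summary().data[1:]
        ]
        return GroupComparison("anova", float(stat), float(p), True, pairwise)
    stat, p = sps.kruskal(*values)
    pairwise = []
    for i in range(len(values)):
        for j in range(i + 1, len(values)):
            res = sps.mannwhitneyu(values[i], values[j], alternative="two-sided")
            pairwise.append((names[i], names[j], float(res.pvalue)))
    return GroupComparison("kruskal", float(stat), float(p), False, pairwise)
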