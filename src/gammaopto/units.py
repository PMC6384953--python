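"""Photostimulation response of single units.

Peri-event time histograms, the sliding-sweeps permutation test (basal-rate
normalized event-aligned templates against inter-event-interval-shuffled
surrogates), paired ON/OFF classification, and photoinhibition latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .session import LaserProtocol, SpikeTrain, epoch_complement
from .stats import TestReport

LABELS = ("suppressed", "excited", "unaffected")


@dataclass
class SlidingSweepsParams:
    window: float = 15.0  # half window (s), lag 0 at light onset
    bin: float = 0.5
    n_shuffles: int = 100
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not self.window > self.bin > 0:
            raise ValueError("window > bin > 0 required")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be at least 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PETH:
    lags: np.ndarray  # bin centers (s)
    rate: np.ndarray  # Hz, averaged over valid trials
    n_valid: np.ndarray  # valid trial count per bin
    empty: bool = False


@dataclass
class SlidingSweepsResult:
    lags: np.ndarray
    template: np.ndarray  # per-bin rate / basal rate
    p: np.ndarray  # per-bin one-sided empirical p (more extreme tail)
    sig_high: np.ndarray
    sig_low: np.ndarray
    undefined: bool = False

    @property
    def significant(self) -> np.ndarray:
        return self.sig_high | self.sig_low


@dataclass
class UnitClassification:
    unit_id: str
    label: str
    modulation_pct: float | None
    latency: float | None
    p: float
    rate_on: float
    rate_off: float
    n_trials: int
    flagged: bool = False
    significant_bins: np.ndarray | None = None


def _bin_counts(spikes: np.ndarray, onsets: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Summed per-bin spike counts over all aligned windows."""
    counts = np.zeros(edges.size - 1)
    for t0 in onsets:
        idx = np.searchsorted(spikes, t0 + edges)
        counts += np.diff(idx)
    return counts


def peri_event_histogram(
    spikes: SpikeTrain, onsets, window: float = 15.0, bin: float = 0.5
) -> PETH:
    """Trial-averaged spike rate (Hz) versus lag around event onsets.

    Bins are half-open with lag 0 at onset. Windows truncated by the session
    edges contribute only to the bins they cover; each bin is normalized by
    its own valid trial count.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 1:
        raise ValueError("at least one onset is required")
    n_bins = int(round(2 * window / bin))
    edges = -window + bin * np.arange(n_bins + 1)
    lags = edges[:-1] + bin / 2
    dur = spikes.session_duration
    n_valid = np.zeros(n_bins)
    for t0 in onsets:
        n_valid += (t0 + edges[:-1] >= 0) & (t0 + edges[1:] <= dur)
    if spikes.n_spikes == 0:
        warnings.warn(f"unit {spikes.unit_id!r} has no spikes", RuntimeWarning, stacklevel=2)
        return PETH(lags, np.zeros(n_bins), n_valid, empty=True)
    counts = _bin_counts(spikes.timestamps, onsets, edges)
    rate = np.divide(counts, n_valid * bin, out=np.zeros(n_bins), where=n_valid > 0)
    return PETH(lags, rate, n_valid)


def _shuffle_intervals(times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomized exchange of the original inter-event intervals.

    The first element and the interval multiset are preserved exactly.
    """
    if times.size < 2:
        return times.copy()
    isi = np.diff(times)
    return times[0] + np.r_[0.0, np.cumsum(rng.permutation(isi))]


def sliding_sweeps(
    spikes: SpikeTrain,
    onsets,
    params: SlidingSweepsParams | None = None,
    rng: np.random.Generator | None = None,
) -> SlidingSweepsResult:
    """Event-aligned template normalized to the basal rate, with a
    permutation null from interval-shuffled spike trains and onset times.

    A bin is flagged significant when its observed value lies outside the
    surrogate distribution: the one-sided empirical p-value
    ``(1 + #{surrogates at least as extreme}) / (n_shuffles + 1)`` falls
    below ``alpha`` in either direction.
    """
    if params is None:
        params = SlidingSweepsParams()
    if rng is None:
        rng = np.random.default_rng(0)
    onsets = np.asarray(onsets, dtype=float)
    if spikes.session_duration < 2 * params.window:
        raise ValueError("session shorter than the sliding-sweeps window")
    n_bins = int(round(2 * params.window / params.bin))
    edges = -params.window + params.bin * np.arange(n_bins + 1)
    lags = edges[:-1] + params.bin / 2
    if spikes.n_spikes < 2:
        nan = np.full(n_bins, np.nan)
        return SlidingSweepsResult(lags, nan, nan, np.zeros(n_bins, bool), np.zeros(n_bins, bool), undefined=True)

    basal = spikes.basal_rate
    norm = onsets.size * params.bin * basal

    def template(ts: np.ndarray, ons: np.ndarray) -> np.ndarray:
        return _bin_counts(ts, ons, edges) / norm

    obs = template(spikes.timestamps, onsets)
    n_hi = np.zeros(n_bins)
    n_lo = np.zeros(n_bins)
    for _ in range(params.n_shuffles):
        surr = template(
            _shuffle_intervals(spikes.timestamps, rng), _shuffle_intervals(onsets, rng)
        )
        n_hi += surr >= obs
        n_lo += surr <= obs
    p_hi = (1.0 + n_hi) / (params.n_shuffles + 1.0)
    p_lo = (1.0 + n_lo) / (params.n_shuffles + 1.0)
    p = np.minimum(p_hi, p_lo)
    return SlidingSweepsResult(
        lags, obs, p, sig_high=p_hi < params.alpha, sig_low=p_lo < params.alpha
    )


def _epoch_rates(spikes: SpikeTrain, epochs) -> np.ndarray:
    ts = spikes.timestamps
    out = []
    for a, b in epochs:
        if b <= a:
            out.append(np.nan)
            continue
        c = np.searchsorted(ts, b) - np.searchsorted(ts, a)
        out.append(c / (b - a))
    return np.asarray(out)


def classify_unit(
    spikes: SpikeTrain,
    laser: LaserProtocol,
    alpha: float = 0.05,
    latency_bin: float = 0.010,
) -> UnitClassification:
    """Label a unit suppressed / excited / unaffected from paired trials.

    Per-trial rates in each laser-ON epoch are compared with the rate in the
    immediately preceding OFF window of equal nominal length (two-sided
    Wilcoxon signed-rank). ``modulation_pct`` is the percent rate decrease
    for suppressed units and the percent rate increase for excited units,
    relative to the OFF rate.
    """
    if laser.n_epochs == 0:
        raise ValueError("laser protocol has no epochs")
    if laser.n_epochs < 10:
        warnings.warn("fewer than 10 laser trials; classification may be unstable", RuntimeWarning, stacklevel=2)
    pre = float(np.mean([b - a for a, b in laser.epochs]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        off_epochs = epoch_complement(laser, pre)
    keep = [i for i, (a, b) in enumerate(off_epochs) if b > a]
    on_rates = _epoch_rates(spikes, [laser.epochs[i] for i in keep])
    off_rates = _epoch_rates(spikes, [off_epochs[i] for i in keep])
    n_trials = len(keep)

    on_time = sum(b - a for a, b in (laser.epochs[i] for i in keep))
    off_time = sum(b - a for a, b in (off_epochs[i] for i in keep))
    ts = spikes.timestamps
    on_count = sum(
        np.searchsorted(ts, b) - np.searchsorted(ts, a) for a, b in (laser.epochs[i] for i in keep)
    )
    off_count = sum(
        np.searchsorted(ts, b) - np.searchsorted(ts, a) for a, b in (off_epochs[i] for i in keep)
    )
    rate_on = on_count / on_time
    rate_off = off_count / off_time

    d = on_rates - off_rates
    if np.allclose(d, 0.0):
        return UnitClassification(
            spikes.unit_id, "unaffected", 0.0, None, 1.0, rate_on, rate_off, n_trials
        )
    res = sps.wilcoxon(on_rates, off_rates, alternative="two-sided")
    p = float(res.pvalue)

    if rate_off == 0:
        return UnitClassification(
            spikes.unit_id, "unaffected", None, None, p, rate_on, rate_off, n_trials, flagged=True
        )
    label = "unaffected"
    modulation: float | None = 0.0
    latency = None
    if p < alpha:
        if rate_on < rate_off:
            label = "suppressed"
            modulation = 100.0 * (rate_off - rate_on) / rate_off
            latency = _latency(spikes, laser.onsets, latency_bin)
        else:
            label = "excited"
            modulation = 100.0 * (rate_on - rate_off) / rate_off
    return UnitClassification(
        spikes.unit_id, label, modulation, latency, p, rate_on, rate_off, n_trials
    )


def _latency(
    spikes: SpikeTrain,
    onsets: np.ndarray,
    bin: float = 0.010,
    baseline: float = 5.0,
    post: float = 5.0,
    smooth_bins: int = 5,
    n_consecutive: int = 3,
) -> float | None:
    """First post-onset time at which the fine-binned, smoothed PETH stays
    below baseline mean - 2 SD for ``n_consecutive`` bins."""
    peth = peri_event_histogram(spikes, onsets, window=max(baseline, post), bin=bin)
    kernel = np.ones(smooth_bins) / smooth_bins
    sm = np.convolve(peth.rate, kernel, mode="same")
    base = sm[(peth.lags >= -baseline) & (peth.lags < 0)]
    thr = base.mean() - 2.0 * base.std()
    post_mask = (peth.lags >= 0) & (peth.lags < post)
    lags_post = peth.lags[post_mask]
    below = sm[post_mask] < thr
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= n_consecutive:
            return float(lags_post[i - n_consecutive + 1] - bin / 2)
    return None


def suppression_latency(
    classification: UnitClassification,
    spikes: SpikeTrain,
    onsets,
    bin: float = 0.010,
    **kwargs,
) -> float | None:
    """Photoinhibition latency of a suppressed unit (s); None if the PETH
    never crosses the baseline-derived threshold."""
    if classification.label != "suppressed":
        raise ValueError("latency is defined only for suppressed units")
    return _latency(spikes, np.asarray(onsets, dtype=float), bin=bin, **kwargs)


def population_summary(classifications) -> pd.DataFrame:
    """Counts and percentages of each response label."""
    if not classifications:
        raise ValueError("at least one classified unit is required")
    labels = [c.label for c in classifications]
    rows = []
    for lab in LABELS:
        n = labels.count(lab)
        rows.append({"label": lab, "n": n, "pct": 100.0 * n / len(labels)})
    return pd.DataFrame(rows)
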