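"""Spike-gamma coupling statistics.

Event-triggered correlograms with circular-shift shuffle nulls, pairwise
phase consistency (PPC) spectra from analytic-signal phases, per-event
firing-rate vs gamma-magnitude correlation, and single-unit vs multi-unit
multitaper coherence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy import stats as sps

from .session import LFPSignal, SpikeTrain, in_epochs
from .stats import bh_fdr


@dataclass
class CouplingParams:
    xcorr_window: float = 0.5  # half window (s) around event references
    xcorr_bin: float = 0.05
    n_event_shuffles: int = 500
    xcorr_alpha: float = 0.05
    min_basal_rate: float = 0.8  # Hz, unit filter for rate-vs-magnitude
    ppc_freq_grid: tuple = tuple(float(f) for f in range(10, 65, 5))
    ppc_halfwidth: float = 2.0  # Hz, band-pass half width per grid frequency
    min_spikes_ppc: int = 20

    def __post_init__(self) -> None:
        if self.n_event_shuffles < 1:
            raise ValueError("n_event_shuffles must be at least 1")
        if self.min_basal_rate < 0:
            raise ValueError("min_basal_rate must be non-negative")


@dataclass
class PPCSpectrum:
    freqs: np.ndarray
    ppc: np.ndarray  # NaN where fewer than min_spikes_ppc spikes
    n_spikes: int


@dataclass
class XcorrResult:
    lags: np.ndarray
    prob: np.ndarray  # normalized discharge probability per lag bin
    coupled: bool
    p: float
    empty: bool = False


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coh_on: np.ndarray
    coh_off: np.ndarray
    pvalues: np.ndarray
    fdr_mask: np.ndarray
    n_pairs: int


def ppc(phases) -> float:
    """Pairwise phase consistency: mean cosine of all pairwise phase
    differences, computed via the closed form
    ``(|sum exp(i theta)|^2 - N) / (N (N - 1))``.

    Unbiased under uniform phases (expectation 0) and invariant to phase
    rotation. Requires at least two phases.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("PPC requires at least two phases")
    resultant = np.abs(np.exp(1j * phases).sum()) ** 2
    return float((resultant - n) / (n * (n - 1)))


def spike_gamma_xcorr(
    spikes: SpikeTrain,
    event_times,
    params: CouplingParams | None = None,
    rng: np.random.Generator | None = None,
) -> XcorrResult:
    """Discharge probability of a unit around gamma-event reference times.

    The correlogram is the per-lag-bin spike count normalized by the total
    count inside the window. The null is built from circularly shifted event
    times (uniform offset modulo the session length, preserving event
    spacing and the spike train's autostructure); the unit is flagged
    "coupled" when the observed central-bin probability exceeds the
    surrogate distribution at ``xcorr_alpha``.
    """
    if params is None:
        params = CouplingParams()
    if rng is None:
        rng = np.random.default_rng(0)
    events = np.sort(np.asarray(event_times, dtype=float))
    if events.size == 0:
        raise ValueError("at least one gamma event is required")
    n_bins = int(round(2 * params.xcorr_window / params.xcorr_bin))
    edges = -params.xcorr_window + params.xcorr_bin * np.arange(n_bins + 1)
    lags = edges[:-1] + params.xcorr_bin / 2
    center = n_bins // 2
    ts = spikes.timestamps
    dur = spikes.session_duration

    if ts.size == 0:
        return XcorrResult(lags, np.zeros(n_bins), False, 1.0, empty=True)

    def central_stat(ev: np.ndarray):
        counts = np.zeros(n_bins)
        for t0 in ev:
            counts += np.diff(np.searchsorted(ts, t0 + edges))
        total = counts.sum()
        prob = counts / total if total > 0 else counts
        return prob, prob[center]

    prob, obs = central_stat(events)
    n_ge = 0
    for _ in range(params.n_event_shuffles):
        shift = rng.uniform(0.0, dur)
        _, stat = central_stat(np.sort((events + shift) % dur))
        n_ge += stat >= obs
    p = (1.0 + n_ge) / (params.n_event_shuffles + 1.0)
    return XcorrResult(lags, prob, coupled=p < params.xcorr_alpha, p=p)


def spike_phases(
    spike_times: np.ndarray, lfp: LFPSignal, freq: float, halfwidth: float = 2.0
) -> np.ndarray:
    """Instantaneous band-limited LFP phase at each spike time.

    Zero-phase Butterworth band-pass (freq +/- halfwidth) followed by the
    analytic-signal (Hilbert) phase, sampled at the nearest LFP sample.
    """
    lo = max(freq - halfwidth, 0.1)
    sos = signal.butter(2, [lo, freq + halfwidth], "bandpass", fs=lfp.fs, output="sos")
    xb = signal.sosfiltfilt(sos, lfp.samples)
    phase = np.angle(signal.hilbert(xb))
    idx = np.clip(np.round((np.asarray(spike_times) - lfp.t0) * lfp.fs).astype(int), 0, lfp.n_samples - 1)
    return phase[idx]


def ppc_spectrum(
    spikes: SpikeTrain,
    lfp: LFPSignal,
    params: CouplingParams | None = None,
    epochs=None,
) -> PPCSpectrum:
    """PPC versus frequency for the spikes falling inside ``epochs``
    (all spikes when ``epochs`` is None).

    Frequencies with fewer than ``min_spikes_ppc`` spikes are NaN.
    """
    if params is None:
        params = CouplingParams()
    ts = spikes.timestamps
    if epochs is not None:
        ts = ts[in_epochs(ts, epochs)]
    freqs = np.asarray(params.ppc_freq_grid, dtype=float)
    out = np.full(freqs.size, np.nan)
    if ts.size >= max(params.min_spikes_ppc, 2):
        for i, f in enumerate(freqs):
            out[i] = ppc(spike_phases(ts, lfp, f, params.ppc_halfwidth))
    else:
        warnings.warn(
            f"unit {spikes.unit_id!r}: {ts.size} spikes < min_spikes_ppc; PPC undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    return PPCSpectrum(freqs, out, int(ts.size))


def rate_vs_gamma_amplitude(units, events, params: CouplingParams | None = None):
    """Pearson correlation between per-event firing rate and event magnitude.

    Units qualify when their basal rate exceeds ``min_basal_rate`` AND lies
    within the population interquartile range. Per event, the rate is the
    pooled spike count of qualifying units inside ``[onset, end)`` divided
    by ``duration x n_units``; events where no qualifying unit fired are
    dropped. Returns ``(r, p, n_events)``.
    """
    if params is None:
        params = CouplingParams()
    if len(events) < 3:
        raise ValueError("at least 3 gamma events are required")
    basal = np.array([u.basal_rate for u in units])
    q1, q3 = np.percentile(basal, [25, 75])
    qualifying = [
        u for u, r in zip(units, basal) if r > params.min_basal_rate and q1 <= r <= q3
    ]
    if not qualifying:
        raise ValueError("no unit passes the basal-rate filters")
    rates = []
    mags = []
    for ev in events:
        dur = ev.end - ev.onset
        count = sum(
            int(np.searchsorted(u.timestamps, ev.end) - np.searchsorted(u.timestamps, ev.onset))
            for u in qualifying
        )
        if count == 0:
            continue
        rates.append(count / (dur * len(qualifying)))
        mags.append(ev.magnitude)
    if len(rates) < 3:
        raise ValueError("fewer than 3 events with active qualifying units")
    r, p = sps.pearsonr(rates, mags)
    return float(r), float(p), len(rates)


def _bin_train(ts: np.ndarray, a: float, b: float, fs: float) -> np.ndarray:
    n = int(round((b - a) * fs))
    edges = a + np.arange(n + 1) / fs
    return np.diff(np.searchsorted(ts, edges)).astype(float)


def _mt_spectra(x: np.ndarray, y: np.ndarray, tapers: np.ndarray):
    xk = np.fft.rfft(tapers * x, axis=1)
    yk = np.fft.rfft(tapers * y, axis=1)
    sxx = np.mean(np.abs(xk) ** 2, axis=0)
    syy = np.mean(np.abs(yk) ** 2, axis=0)
    sxy = np.mean(xk * np.conj(yk), axis=0)
    return sxx, syy, sxy


def su_mu_coherence(
    unit: SpikeTrain,
    other_units,
    epochs_on,
    epochs_off,
    tw: float = 3.0,
    bin_fs: float = 500.0,
) -> CoherenceResult:
    """Multitaper coherence between one unit and the summed others.

    Multi-unit activity is the summed spiking of all simultaneously recorded
    units except the reference. Both trains are binned at ``bin_fs``;
    coherence per epoch uses ``2 TW - 1`` DPSS tapers and is averaged within
    the ON and OFF conditions; a two-sided Wilcoxon signed-rank test is run
    per frequency across paired epochs, with a BH-FDR mask at q = 0.05.
    """
    if len(other_units) < 1:
        raise ValueError("su_mu_coherence requires at least two simultaneously recorded units")
    pairs = [
        (on, off)
        for on, off in zip(epochs_on, epochs_off)
        if on[1] > on[0] and off[1] > off[0]
    ]
    if not pairs:
        raise ValueError("no valid ON/OFF epoch pairs")
    epoch_len = pairs[0][0][1] - pairs[0][0][0]
    n = int(round(epoch_len * bin_fs))
    k = int(2 * tw - 1)
    tapers = signal.windows.dpss(n, tw, Kmax=k)
    tapers /= np.sqrt(np.sum(tapers**2, axis=1, keepdims=True))
    mu_ts = np.sort(np.concatenate([u.timestamps for u in other_units]))
    freqs = np.fft.rfftfreq(n, d=1.0 / bin_fs)

    def coh(a: float, b: float) -> np.ndarray:
        x = _bin_train(unit.timestamps, a, b, bin_fs)
        y = _bin_train(mu_ts, a, b, bin_fs)
        x -= x.mean()
        y -= y.mean()
        sxx, syy, sxy = _mt_spectra(x, y, tapers)
        denom = sxx * syy
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.abs(sxy) ** 2 / denom
        c[denom == 0] = np.nan
        return c

    coh_on = np.array([coh(a, b) for (a, b), _ in pairs])
    coh_off = np.array([coh(a, b) for _, (a, b) in pairs])
    pvals = np.ones(freqs.size)
    for i in range(freqs.size):
        a, b = coh_on[:, i], coh_off[:, i]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 5 and not np.allclose(a[ok], b[ok]):
            pvals[i] = sps.wilcoxon(a[ok], b[ok]).pvalue
    mask = bh_fdr(pvals, 0.05)
    return CoherenceResult(
        freqs,
        np.nanmean(coh_on, axis=0),
        np.nanmean(coh_off, axis=0),
        pvals,
        mask,
        n_pairs=len(pairs),
    )
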