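"""Envelope-threshold detection of transient gamma-band oscillations.

Pipeline (all filtering is zero-phase): downsample -> FIR band-pass ->
rectify -> 4th-order Butterworth low-pass (20 Hz) -> z-score over the whole
signal -> 2 SD threshold crossings, each extended outward to the 1 SD
boundaries -> merge events separated by less than a refractory gap ->
complex-Morlet characterization (mean frequency) -> minimum-duration filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .session import LFPSignal, epoch_durations, in_epochs


@dataclass
class GammaDetectionParams:
    target_fs: float = 500.0
    band: tuple = (20.0, 80.0)
    rolloff: float = 0.5
    envelope_lp: float = 20.0
    envelope_order: int = 4
    thresh_sd: float = 2.0
    bound_sd: float = 1.0
    refractory: float = 0.150
    min_duration: float = 0.150
    wavelet_cycles: int = 7
    freq_step: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not lo < hi:
            raise ValueError("band must satisfy lo < hi")
        if not self.thresh_sd > self.bound_sd > 0:
            raise ValueError("thresh_sd > bound_sd > 0 required")
        if self.refractory <= 0 or self.min_duration <= 0:
            raise ValueError("refractory and min_duration must be positive")

    @property
    def fir_numtaps(self) -> int:
        """Two-way least-squares FIR convention: order 3 x round(fs / lo)."""
        n = 3 * int(round(self.target_fs / self.band[0]))
        return n + 1 if n % 2 == 0 else n

    def wavelet_freqs(self) -> np.ndarray:
        lo, hi = self.band
        return np.arange(lo, hi + self.freq_step / 2, self.freq_step)


@dataclass
class GammaEvent:
    """One detected oscillatory episode.

    ``amplitude`` is the envelope z-score at the event peak; ``magnitude``
    is an alias for it (the quantity the detector thresholds).
    """

    onset: float
    end: float
    peak_time: float
    mean_frequency: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.onset < self.end:
            raise ValueError("onset must precede end")

    @property
    def duration(self) -> float:
        return self.end - self.onset

    @property
    def magnitude(self) -> float:
        return self.amplitude


def _downsample(x: np.ndarray, fs: float, target_fs: float) -> tuple:
    """Anti-aliased polyphase resampling to ``target_fs``."""
    if fs == target_fs:
        return x, fs
    frac = Fraction(target_fs / fs).limit_denominator(10000)
    y = signal.resample_poly(x, frac.numerator, frac.denominator)
    return y, fs * frac.numerator / frac.denominator


def bandpass_fir(x: np.ndarray, fs: float, band, numtaps: int) -> np.ndarray:
    """Zero-phase (forward-backward) FIR band-pass."""
    taps = signal.firwin(numtaps, band, pass_zero=False, fs=fs)
    return signal.filtfilt(taps, [1.0], x)


def gamma_envelope(x: np.ndarray, fs: float, params: GammaDetectionParams) -> tuple:
    """Band-passed signal and its z-scored smooth envelope."""
    xb = bandpass_fir(x, fs, params.band, params.fir_numtaps)
    sos = signal.butter(params.envelope_order, params.envelope_lp, "lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(xb))
    sd = env.std()
    if sd == 0:
        return xb, np.zeros_like(env)
    return xb, (env - env.mean()) / sd


def morlet_power(x: np.ndarray, fs: float, freqs: np.ndarray, n_cycles: int = 7) -> np.ndarray:
    """Complex-Morlet wavelet power, shape (n_freqs, n_samples).

    The wavelet at frequency f is a complex exponential under a Gaussian
    envelope with sigma_t = n_cycles / (2 pi f), L2-normalized.
    """
    out = np.empty((len(freqs), x.size))
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2.0 * np.pi * f)
        half = int(np.ceil(4 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        wav = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2 * sigma_t**2))
        wav /= np.sqrt(np.sum(np.abs(wav) ** 2))
        conv = signal.fftconvolve(x.astype(complex), wav, mode="same")
        out[i] = np.abs(conv) ** 2
    return out


def characterize_event(
    xb: np.ndarray,
    fs: float,
    onset: float,
    end: float,
    params: GammaDetectionParams,
    t0: float = 0.0,
):
    """Morlet characterization of one event on the band-passed signal.

    Returns ``(mean_frequency, ridge_amplitude, duration)`` where the mean
    frequency is the amplitude-weighted mean of the per-sample wavelet-power
    ridge over the event span. A zero-power span yields NaN frequency.
    """
    i0 = int(round((onset - t0) * fs))
    i1 = int(round((end - t0) * fs))
    if i0 < 0 or i1 > xb.size or i0 >= i1:
        raise ValueError("event lies outside the signal bounds")
    freqs = params.wavelet_freqs()
    # pad with surrounding signal so the wavelet support is covered
    sigma_max = params.wavelet_cycles / (2 * np.pi * freqs[0])
    pad = int(np.ceil(5 * sigma_max * fs))
    a, b = max(0, i0 - pad), min(xb.size, i1 + pad)
    power = morlet_power(xb[a:b], fs, freqs, params.wavelet_cycles)[:, i0 - a : i1 - a]
    ridge_idx = np.argmax(power, axis=0)
    ridge_amp = np.sqrt(power[ridge_idx, np.arange(power.shape[1])])
    total = ridge_amp.sum()
    duration = end - onset
    if total == 0:
        return float("nan"), 0.0, duration
    mean_freq = float(np.sum(freqs[ridge_idx] * ridge_amp) / total)
    return mean_freq, float(ridge_amp.mean()), duration


def detect_gamma_events(lfp: LFPSignal, params: GammaDetectionParams | None = None):
    """Run the full detector on one LFP channel.

    Returns a list of :class:`GammaEvent`, sorted by onset, non-overlapping,
    each satisfying ``amplitude >= thresh_sd`` and
    ``duration >= min_duration``.
    """
    if params is None:
        params = GammaDetectionParams()
    x, fs = _downsample(lfp.samples, lfp.fs, params.target_fs)
    if fs < 2 * params.band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz after downsampling is below Nyquist for band {params.band}"
        )
    min_len = 3 * params.fir_numtaps + 1
    if x.size < min_len:
        raise ValueError(f"signal too short: need at least {min_len} samples at {fs} Hz")
    if np.all(x == x[0]):
        return []

    xb, env_z = gamma_envelope(x, fs, params)
    if not np.any(env_z >= params.thresh_sd):
        return []

    above = env_z >= params.thresh_sd
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    stops = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]

    below = env_z <= params.bound_sd
    below_idx = np.nonzero(below)[0]

    intervals = []
    for s, e in zip(starts, stops):
        # extend to the first 1 SD crossing before / after the threshold run
        j = np.searchsorted(below_idx, s) - 1
        i0 = below_idx[j] if j >= 0 else 0
        k = np.searchsorted(below_idx, e)
        i1 = below_idx[k] if k < below_idx.size else env_z.size - 1
        intervals.append([i0, i1])

    # merge overlapping extensions and gaps shorter than the refractory window
    gap = int(round(params.refractory * fs))
    merged = [intervals[0]]
    for i0, i1 in intervals[1:]:
        if i0 - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], i1)
        else:
            merged.append([i0, i1])

    t0 = lfp.t0
    events = []
    for i0, i1 in merged:
        onset = t0 + i0 / fs
        end = t0 + i1 / fs
        if end - onset < params.min_duration:
            continue
        seg = env_z[i0 : i1 + 1]
        pk = i0 + int(np.argmax(seg))
        mean_freq, _, _ = characterize_event(xb, fs, onset, end, params, t0=t0)
        events.append(
            GammaEvent(
                onset=onset,
                end=end,
                peak_time=t0 + pk / fs,
                mean_frequency=mean_freq,
                amplitude=float(env_z[pk]),
            )
        )
    return events


def gamma_event_density(events, epochs_on, epochs_off):
    """Per-condition gamma-event densities (events/s) and per-trial pairs.

    Events are assigned to epochs by peak-time membership (half-open
    intervals). Returns ``(density_on, density_off, pairs)`` where ``pairs``
    is a list of ``(off_density, on_density)`` per trial, ready for paired
    testing; trials are matched positionally.
    """
    dur_on = epoch_durations(epochs_on)
    dur_off = epoch_durations(epochs_off)
    if dur_on.sum() <= 0 or dur_off.sum() <= 0:
        raise ValueError("total epoch time must be positive in both conditions")
    peaks = np.array([ev.peak_time for ev in events], dtype=float)
    n_on = int(in_epochs(peaks, epochs_on).sum()) if peaks.size else 0
    n_off = int(in_epochs(peaks, epochs_off).sum()) if peaks.size else 0
    density_on = n_on / dur_on.sum()
    density_off = n_off / dur_off.sum()
    pairs = []
    for (a_on, b_on), (a_off, b_off) in zip(epochs_on, epochs_off):
        if b_on <= a_on or b_off <= a_off:
            continue
        c_on = int(np.sum((peaks >= a_on) & (peaks < b_on))) if peaks.size else 0
        c_off = int(np.sum((peaks >= a_off) & (peaks < b_off))) if peaks.size else 0
        pairs.append((c_off / (b_off - a_off), c_on / (b_on - a_on)))
    return density_on, density_off, pairs
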