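"""Multitaper LFP spectra, 1/f normalization, and laser ON/OFF comparisons.

The estimator uses discrete prolate spheroidal (Slepian) tapers with a
time-bandwidth product TW, K = 2 TW - 1 tapers and half bandwidth
W = TW / epoch; defaults follow TW = 3 over 5-second epochs (K = 5,
W = 0.6 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy import stats as sps

from .session import LFPSignal, LaserProtocol, epoch_complement
from .stats import TestReport, bh_fdr, paired_compare


@dataclass
class SpectralParams:
    tw: float = 3.0
    epoch: float = 5.0
    target_fs: float = 500.0
    notch: float = 50.0
    notch_halfwidth: float = 2.0
    gamma_band: tuple = (20.0, 40.0)
    max_freq: float = 100.0

    def __post_init__(self) -> None:
        if self.tw <= 0 or self.epoch <= 0:
            raise ValueError("tw and epoch must be positive")
        # defining identities of the estimator
        assert self.k == int(2 * self.tw - 1)
        assert abs(self.w - self.tw / self.epoch) < 1e-12

    @property
    def k(self) -> int:
        """Taper count, 2 TW - 1."""
        return int(2 * self.tw - 1)

    @property
    def w(self) -> float:
        """Half bandwidth (Hz), TW / epoch."""
        return self.tw / self.epoch

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch * self.target_fs))


@dataclass
class RatioSpectrum:
    freqs: np.ndarray
    mean_ratio: np.ndarray  # mean over trials of PSD_on / PSD_off
    pvalues: np.ndarray
    fdr_mask: np.ndarray
    n_pairs: int


def _tapers(params: SpectralParams) -> np.ndarray:
    t = signal.windows.dpss(params.n_samples, params.tw, Kmax=params.k)
    return t / np.sqrt(np.sum(t**2, axis=1, keepdims=True))


def multitaper_psd(segment: np.ndarray, params: SpectralParams | None = None):
    """One-sided multitaper PSD of a single epoch-length segment.

    The segment must hold exactly ``epoch x target_fs`` samples; frequency
    resolution is ``1 / epoch``. Satisfies Parseval up to taper leakage:
    ``sum(psd) * df ~ var(segment)``.
    """
    if params is None:
        params = SpectralParams()
    segment = np.asarray(segment, dtype=float)
    if segment.size != params.n_samples:
        raise ValueError(
            f"segment must hold {params.n_samples} samples ({params.epoch} s at {params.target_fs} Hz), got {segment.size}"
        )
    tapers = _tapers(params)
    x = segment - segment.mean()
    spec = np.abs(np.fft.rfft(tapers * x, axis=1)) ** 2
    psd = spec.mean(axis=0) / params.target_fs
    psd[1:-1] *= 2.0  # one-sided, DC and Nyquist not doubled
    freqs = np.fft.rfftfreq(params.n_samples, d=1.0 / params.target_fs)
    return freqs, psd


def normalize_1overf(freqs: np.ndarray, psd: np.ndarray):
    """Multiply each power value by its frequency; the f = 0 bin is dropped."""
    keep = freqs > 0
    return freqs[keep], psd[keep] * freqs[keep]


def _downsample(lfp: LFPSignal, target_fs: float):
    if lfp.fs == target_fs:
        return lfp.samples, lfp.fs
    frac = Fraction(target_fs / lfp.fs).limit_denominator(10000)
    return signal.resample_poly(lfp.samples, frac.numerator, frac.denominator), target_fs


def _paired_epochs(laser: LaserProtocol, epoch: float):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        off = epoch_complement(laser, epoch)
    pairs = []
    for (a_on, b_on), (a_off, b_off) in zip(laser.epochs, off):
        if b_on - a_on >= epoch and b_off - a_off >= epoch:
            pairs.append(((a_on, a_on + epoch), (a_on - epoch, a_on)))
    return pairs


def _epoch_segment(x: np.ndarray, fs: float, a: float, n: int) -> np.ndarray | None:
    i0 = int(round(a * fs))
    if i0 < 0 or i0 + n > x.size:
        return None
    return x[i0 : i0 + n]


def psd_ratio_on_off(
    lfp: LFPSignal,
    laser: LaserProtocol,
    params: SpectralParams | None = None,
    q: float = 0.05,
) -> RatioSpectrum:
    """Mean ON/OFF PSD ratio with per-frequency paired Wilcoxon and BH-FDR.

    Each laser-ON epoch is paired with the immediately preceding OFF window
    of the same length; bins within ``notch_halfwidth`` of the notch
    frequency are excised from the output grid.
    """
    if params is None:
        params = SpectralParams()
    x, fs = _downsample(lfp, params.target_fs)
    pairs = _paired_epochs(laser, params.epoch)
    n = params.n_samples
    psd_on, psd_off = [], []
    for (a_on, _), (a_off, _) in pairs:
        seg_on = _epoch_segment(x, fs, a_on, n)
        seg_off = _epoch_segment(x, fs, a_off, n)
        if seg_on is None or seg_off is None:
            continue
        f, p_on = multitaper_psd(seg_on, params)
        _, p_off = multitaper_psd(seg_off, params)
        psd_on.append(p_on)
        psd_off.append(p_off)
    if len(psd_on) < 5:
        raise ValueError(f"need at least 5 matched ON/OFF epoch pairs, got {len(psd_on)}")
    psd_on = np.array(psd_on)
    psd_off = np.array(psd_off)

    keep = (f > 0) & (f <= params.max_freq) & (np.abs(f - params.notch) > params.notch_halfwidth)
    f = f[keep]
    psd_on = psd_on[:, keep]
    psd_off = psd_off[:, keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.nanmean(psd_on / psd_off, axis=0)
    pvals = np.ones(f.size)
    for i in range(f.size):
        if not np.allclose(psd_on[:, i], psd_off[:, i]):
            pvals[i] = sps.wilcoxon(psd_on[:, i], psd_off[:, i]).pvalue
    return RatioSpectrum(f, ratio, pvals, bh_fdr(pvals, q), n_pairs=len(psd_on))


def band_power(x: np.ndarray, fs: float, band: tuple, numtaps: int | None = None) -> float:
    """Variance of the band-passed signal (two-way zero-phase FIR)."""
    if numtaps is None:
        numtaps = 3 * int(round(fs / band[0]))
        numtaps += 1 - numtaps % 2
    taps = signal.firwin(numtaps, band, pass_zero=False, fs=fs)
    xb = signal.filtfilt(taps, [1.0], x)
    return float(np.var(xb))


def gamma_band_power(
    lfp: LFPSignal,
    laser: LaserProtocol,
    params: SpectralParams | None = None,
):
    """Per-epoch gamma-band power, ON vs OFF, with the gated paired test.

    The whole downsampled signal is FIR band-pass filtered over
    ``gamma_band``; per-epoch power is the variance of the filtered trace.
    Differences pass a KS normality gate choosing paired t-test vs Wilcoxon.
    Returns ``(power_on, power_off, TestReport)``.
    """
    if params is None:
        params = SpectralParams()
    x, fs = _downsample(lfp, params.target_fs)
    numtaps = 3 * int(round(fs / params.gamma_band[0]))
    numtaps += 1 - numtaps % 2
    taps = signal.firwin(numtaps, params.gamma_band, pass_zero=False, fs=fs)
    xb = signal.filtfilt(taps, [1.0], x)
    pairs = _paired_epochs(laser, params.epoch)
    n = params.n_samples
    p_on, p_off = [], []
    for (a_on, _), (a_off, _) in pairs:
        seg_on = _epoch_segment(xb, fs, a_on, n)
        seg_off = _epoch_segment(xb, fs, a_off, n)
        if seg_on is None or seg_off is None:
            continue
        p_on.append(float(np.var(seg_on)))
        p_off.append(float(np.var(seg_off)))
    if len(p_on) < 5:
        raise ValueError(f"need at least 5 matched ON/OFF epoch pairs, got {len(p_on)}")
    report = paired_compare(p_on, p_off)
    return np.array(p_on), np.array(p_off), report
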