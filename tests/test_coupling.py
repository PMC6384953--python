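import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammaopto.coupling import (
    CouplingParams,
    ppc,
    ppc_spectrum,
    rate_vs_gamma_amplitude,
    spike_gamma_xcorr,
    spike_phases,
    su_mu_coherence,
)
from gammaopto.gamma import GammaEvent
from gammaopto.session import LFPSignal, SpikeTrain, epoch_complement
from gammaopto.synth import continuous_pulse_protocol

from conftest import poisson_train


def ppc_brute_force(phases: np.ndarray) -> float:
    """Independent oracle: explicit average over all distinct pairs."""
    n = len(phases)
    total = 0.0
    for j in range(n):
        for k in range(j + 1, n):
            total += np.cos(phases[j] - phases[k])
    return 2.0 * total / (n * (n - 1))


class TestPPC:
    def test_identical_phases(self):
        assert ppc(np.full(7, 1.3)) == pytest.approx(1.0)

    def test_antipodal_pair(self):
        assert ppc([0.0, np.pi]) == pytest.approx(-1.0)

    def test_three_phase_example(self):
        # pairs: cos(pi/2)=0, cos(pi)=-1, cos(pi/2)=0 -> mean -1/3
        assert ppc([0.0, np.pi / 2, np.pi]) == pytest.approx(-1.0 / 3.0, abs=1e-12)

    def test_requires_two(self):
        with pytest.raises(ValueError):
            ppc([0.5])

    @given(st.integers(2, 60), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_closed_form_equals_brute_force(self, n, seed):
        phases = np.random.default_rng(seed).uniform(0, 2 * np.pi, n)
        assert ppc(phases) == pytest.approx(ppc_brute_force(phases), abs=1e-12)

    @given(st.floats(-10, 10), st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_rotation_invariance(self, shift, seed):
        phases = np.random.default_rng(seed).uniform(0, 2 * np.pi, 30)
        assert ppc(phases + shift) == pytest.approx(ppc(phases), abs=1e-9)

    def test_unbiased_under_uniform(self, rng):
        vals = [ppc(rng.uniform(0, 2 * np.pi, 40)) for _ in range(300)]
        # E[ppc]=0, var ~ 1/(N(N-1)) per sample; PLV resultant would be ~0.157
        assert abs(np.mean(vals)) < 3.0 / np.sqrt(40 * 39 * 300)

    def test_less_biased_than_plv(self, rng):
        plv = [np.abs(np.exp(1j * rng.uniform(0, 2 * np.pi, 40)).mean()) for _ in range(300)]
        assert np.mean(plv) > 0.1  # PLV positively biased where PPC is centered at 0


class TestXcorr:
    def test_perfect_locking(self, rng):
        events = np.sort(rng.uniform(10, 590, 60))
        spikes = SpikeTrain("u", np.sort(events), 600.0)
        res = spike_gamma_xcorr(spikes, events, rng=rng)
        center = len(res.prob) // 2
        assert res.prob[center] == res.prob.max()
        assert res.coupled and res.p < 0.05

    def test_type_one_error_scaled(self):
        events = np.sort(np.random.default_rng(9).uniform(10, 590, 60))
        params = CouplingParams(n_event_shuffles=200)
        flags = 0
        for k in range(30):
            r = np.random.default_rng(500 + k)
            spikes = poisson_train("u", 5.0, 600.0, r)
            flags += spike_gamma_xcorr(spikes, events, params, rng=r).coupled
        assert flags <= 5  # nominal 0.05 -> expect ~1.5 of 30

    def test_no_events_errors(self, rng):
        spikes = poisson_train("u", 5.0, 600.0, rng)
        with pytest.raises(ValueError):
            spike_gamma_xcorr(spikes, [])

    def test_empty_train_flagged(self, rng):
        spikes = SpikeTrain("u", [], 600.0)
        res = spike_gamma_xcorr(spikes, [100.0, 200.0], rng=rng)
        assert res.empty and not res.coupled
        assert np.all(res.prob == 0)


class TestPPCSpectrum:
    FS = 500.0

    def locked_setup(self):
        tt = np.arange(int(120 * self.FS)) / self.FS
        lfp = LFPSignal(np.cos(2 * np.pi * 30 * tt), fs=self.FS)
        peaks = np.arange(1.0, 119.0, 1.0 / 30.0)
        return lfp, SpikeTrain("p", peaks, 120.0)

    def test_locked_spikes(self):
        lfp, spikes = self.locked_setup()
        params = CouplingParams(ppc_freq_grid=(25.0, 30.0, 35.0))
        spec = ppc_spectrum(spikes, lfp, params)
        assert spec.ppc[list(spec.freqs).index(30.0)] >= 0.95

    def test_independent_spikes_near_zero(self, rng):
        n = int(120 * self.FS)
        from gammaopto.synth import pink_noise

        lfp = LFPSignal(pink_noise(n, 1.0, rng), fs=self.FS)
        spikes = poisson_train("u", 5.0, 120.0, rng)
        params = CouplingParams(ppc_freq_grid=(20.0, 30.0, 40.0))
        spec = ppc_spectrum(spikes, lfp, params)
        n_sp = spec.n_spikes
        assert np.all(np.abs(spec.ppc) < 6.0 / np.sqrt(n_sp * (n_sp - 1)))

    def test_subsampling_bias_free(self, rng):
        lfp, spikes = self.locked_setup()
        phases = spike_phases(spikes.timestamps, lfp, 30.0)
        full = ppc(phases)
        subs = [
            ppc(rng.choice(phases, phases.size // 2, replace=False)) for _ in range(100)
        ]
        assert abs(np.mean(subs) - full) < 0.02

    def test_too_few_spikes_flagged(self):
        lfp, _ = self.locked_setup()
        spikes = SpikeTrain("u", [1.0, 2.0], 120.0)
        with pytest.warns(RuntimeWarning, match="min_spikes"):
            spec = ppc_spectrum(spikes, lfp, CouplingParams(min_spikes_ppc=20))
        assert np.all(np.isnan(spec.ppc))

    def test_epoch_restriction(self, rng):
        lfp, spikes = self.locked_setup()
        spec = ppc_spectrum(spikes, lfp, CouplingParams(ppc_freq_grid=(30.0,)), epochs=[(0.0, 60.0)])
        assert spec.n_spikes < spikes.n_spikes
        assert spec.ppc[0] >= 0.95


def make_events(mags, start=10.0, spacing=2.0, dur=0.5):
    out = []
    for k, m in enumerate(mags):
        a = start + k * spacing
        out.append(GammaEvent(onset=a, end=a + dur, peak_time=a + dur / 2, mean_frequency=30.0, amplitude=float(m)))
    return out


class TestRateVsAmplitude:
    def _population(self, events, rates_per_event, duration, rng):
        """Two qualifying units share the per-event rate; two decoys fall
        outside the basal-rate filters."""
        units = []
        for uid in ("q1", "q2"):
            ts = [rng.uniform(0, duration, rng.poisson(10.0 * duration))]  # background
            for ev, lam in zip(events, rates_per_event):
                n = rng.poisson(lam * (ev.end - ev.onset))
                ts.append(rng.uniform(ev.onset, ev.end, n))
            units.append(SpikeTrain(uid, np.unique(np.concatenate(ts)), duration))
        units.append(poisson_train("slow", 0.3, duration, rng))
        units.append(poisson_train("fast", 100.0, duration, rng))
        return units

    def test_constant_rate_uncorrelated(self, rng):
        duration = 1100.0
        mags = rng.normal(4.0, 0.8, 500)
        events = make_events(mags)
        units = self._population(events, np.full(500, 50.0), duration, rng)
        r, p, n = rate_vs_gamma_amplitude(units, events)
        assert abs(r) < 0.1
        assert n >= 490

    def test_generative_correlation_recovered(self, rng):
        duration = 1100.0
        mags = rng.normal(4.0, 0.8, 500)
        z = (mags - mags.mean()) / mags.std()
        beta, sigma = 4.5, np.sqrt(18.0**2 - 4.5**2)
        lam = np.clip(50.0 + beta * z + rng.normal(0, sigma, 500), 1.0, None)
        events = make_events(mags)
        units = self._population(events, lam, duration, rng)
        r, p, n = rate_vs_gamma_amplitude(units, events)
        assert r == pytest.approx(0.25, abs=0.08)
        assert p < 0.05

    def test_two_events_errors(self, rng):
        events = make_events([3.0, 4.0])
        with pytest.raises(ValueError):
            rate_vs_gamma_amplitude([poisson_train("u", 5.0, 100.0, rng)], events)

    def test_iqr_filter_applied(self, rng):
        duration = 200.0
        events = make_events(rng.normal(4, 0.5, 20))
        units = [
            poisson_train("a", 0.2, duration, rng),  # below 0.8 Hz floor
            poisson_train("b", 5.0, duration, rng),
            poisson_train("c", 5.0, duration, rng),
            poisson_train("d", 80.0, duration, rng),  # above Q3
        ]
        r, p, n = rate_vs_gamma_amplitude(units, events)
        assert n <= 20  # only middle units count


class TestSuMuCoherence:
    def common_drive_pair(self, seed, dur=600.0, depth=0.9):
        r = np.random.default_rng(seed)
        dt = 0.001
        tg = np.arange(int(dur / dt)) * dt
        rate = 40.0 * (1 + depth * np.cos(2 * np.pi * 30 * tg)) * dt

        def mk(uid):
            hits = np.nonzero(r.random(tg.size) < rate)[0]
            return SpikeTrain(uid, (hits + r.uniform(0, 1, hits.size)) * dt, dur)

        return mk("a"), mk("b")

    def epochs(self, dur=600.0):
        laser = continuous_pulse_protocol(dur)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            off = [w for w in epoch_complement(laser, 5.0) if w[1] > w[0]]
        return laser.epochs, off

    def test_common_drive_peak(self):
        u1, u2 = self.common_drive_pair(0)
        on, off = self.epochs()
        res = su_mu_coherence(u1, [u2], on, off)
        i30 = np.argmin(np.abs(res.freqs - 30.0))
        interior = (res.freqs > 1) & (res.freqs < 249)
        assert res.coh_on[i30] > 3.0 * np.nanmedian(res.coh_on[interior])

    def test_independent_trains_null(self):
        clean = 0
        for seed in range(5):
            r = np.random.default_rng(700 + seed)
            u1 = poisson_train("a", 20.0, 600.0, r)
            u2 = poisson_train("b", 20.0, 600.0, r)
            on, off = self.epochs()
            res = su_mu_coherence(u1, [u2], on, off)
            clean += not res.fdr_mask.any()
        assert clean >= 4

    def test_single_unit_errors(self, rng):
        u = poisson_train("a", 10.0, 600.0, rng)
        on, off = self.epochs()
        with pytest.raises(ValueError):
            su_mu_coherence(u, [], on, off)

    def test_reference_exclusion_matters(self):
        u1, u2 = self.common_drive_pair(3)
        on, off = self.epochs()
        res_excl = su_mu_coherence(u1, [u2], on, off)
        res_incl = su_mu_coherence(u1, [u1, u2], on, off)
        assert not np.allclose(
            np.nan_to_num(res_excl.coh_on), np.nan_to_num(res_incl.coh_on)
        )
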