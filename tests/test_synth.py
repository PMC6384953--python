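import itertools

import numpy as np
import pytest

from gammaopto.behavior import alternation_index
from gammaopto.session import in_epochs
from gammaopto.synth import (
    SimConfig,
    continuous_pulse_protocol,
    ms_like_config,
    pink_noise,
    pulse_train_protocol,
    simulate_lfp,
    simulate_open_field,
    simulate_session,
    simulate_units,
    simulate_ymaze,
    train_onsets,
    vp_like_config,
)

ARMS = ("A", "B", "C")


def markov_alternation_expectation(p: float) -> float:
    """Brute-force oracle: stationary per-step alternation probability of the
    arm-choice chain, computed by enumerating (prev, cur) states.

    From any state the next arm is the third arm w.p. ``p`` (the window is an
    alternation) or the previous arm w.p. ``1 - p`` (not an alternation), so
    the expectation is 100 p for every state; the enumeration verifies it.
    """
    states = [s for s in itertools.permutations(ARMS, 2)]
    idx = {s: i for i, s in enumerate(states)}
    T = np.zeros((6, 6))
    alt = np.zeros(6)
    for (prev, cur), i in idx.items():
        third = next(a for a in ARMS if a not in (prev, cur))
        T[i, idx[(cur, third)]] += p
        T[i, idx[(cur, prev)]] += 1 - p
        alt[i] = p  # P(window ending in the next entry is an alternation)
    vals, vecs = np.linalg.eig(T.T)
    pi = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
    pi /= pi.sum()
    return 100.0 * float(pi @ alt)


class TestProtocols:
    def test_continuous_cycle(self):
        laser = continuous_pulse_protocol(100.0, on=5.0, off=15.0)
        assert laser.epochs == [(15.0, 20.0), (35.0, 40.0), (55.0, 60.0), (75.0, 80.0), (95.0, 100.0)]

    def test_pulse_train_structure(self):
        rng = np.random.default_rng(0)
        laser = pulse_train_protocol(600.0, rng, interval_range=(50.0, 60.0))
        assert laser.kind == "pulse_train"
        ons = train_onsets(laser)
        assert 2 <= len(ons) <= 10
        # each train holds 10 pulses of 1 s
        assert len(laser.epochs) == 10 * len(ons)


class TestLFP:
    def test_deterministic(self):
        cfg = SimConfig(duration=20, seed=42)
        l1, e1 = simulate_lfp(cfg)
        l2, e2 = simulate_lfp(cfg)
        assert np.array_equal(l1.samples, l2.samples)
        assert len(e1) == len(e2)

    def test_zero_rate_pure_noise(self):
        cfg = SimConfig(duration=20, gamma_rate_off=0.0, seed=1)
        lfp, events = simulate_lfp(cfg)
        assert events == []
        assert lfp.n_samples == 20 * 500

    def test_pink_noise_slope(self):
        x = pink_noise(2**16, 1.0, np.random.default_rng(0))
        f = np.fft.rfftfreq(x.size)
        p = np.abs(np.fft.rfft(x)) ** 2
        lo = p[(f > 0.001) & (f < 0.01)].mean()
        hi = p[(f > 0.1) & (f < 0.5)].mean()
        # 1/f: one decade+ apart in frequency -> order-of-magnitude power drop
        assert lo / hi > 10

    def test_on_off_rate_factor_in_truth(self):
        laser = continuous_pulse_protocol(600.0)
        cfg = SimConfig(duration=600, gamma_rate_off=0.4, gamma_rate_on_factor=0.5, seed=7)
        _, events = simulate_lfp(cfg, laser)
        onsets = np.array([ev.onset for ev in events])
        n_on = int(in_epochs(onsets, laser.epochs).sum())
        n_off = len(events) - n_on
        t_on = sum(b - a for a, b in laser.epochs)
        t_off = 600.0 - t_on
        lam_on, lam_off = 0.2 * t_on, 0.4 * t_off
        assert abs(n_on - lam_on) < 4 * np.sqrt(lam_on)
        assert abs(n_off - lam_off) < 4 * np.sqrt(lam_off)

    def test_overflow_guard(self):
        with pytest.raises(ValueError, match="overflow"):
            SimConfig(duration=1e7, fs=1e5)


class TestUnits:
    def test_full_suppression_zero_on_spikes(self):
        laser = continuous_pulse_protocol(200.0)
        cfg = SimConfig(duration=200, som_suppression=1.0, seed=3)
        units, truth = simulate_units(cfg, 200.0, [], laser)
        for u in units:
            if truth.labels[u.unit_id] == "suppressed":
                assert not in_epochs(u.timestamps, laser.epochs).any()

    def test_half_suppression_rate_ratio(self):
        laser = continuous_pulse_protocol(600.0)
        cfg = SimConfig(duration=600, som_suppression=0.5, base_rate=10.0, seed=4)
        units, truth = simulate_units(cfg, 600.0, [], laser)
        t_on = sum(b - a for a, b in laser.epochs)
        t_off = 600.0 - t_on
        for u in units:
            if truth.labels[u.unit_id] != "suppressed":
                continue
            on = in_epochs(u.timestamps, laser.epochs).sum()
            off = u.n_spikes - on
            ratio = (on / t_on) / (off / t_off)
            assert ratio == pytest.approx(0.5, abs=0.12)

    def test_unaffected_stationary(self):
        laser = continuous_pulse_protocol(600.0)
        cfg = SimConfig(duration=600, seed=5)
        units, truth = simulate_units(cfg, 600.0, [], laser)
        t_on = sum(b - a for a, b in laser.epochs)
        for u in units:
            if truth.labels[u.unit_id] == "unaffected":
                on = in_epochs(u.timestamps, laser.epochs).sum()
                rate_on = on / t_on
                rate_off = (u.n_spikes - on) / (600.0 - t_on)
                assert rate_on == pytest.approx(rate_off, rel=0.15)

    def test_kappa_zero_uniform_phases(self):
        """Rayleigh test non-significant for unlocked units (alpha = 0.01)."""
        nonsig = 0
        n_tests = 0
        for seed in range(12):
            cfg = vp_like_config(seed=seed, phase_kappa=0.0, event_rate_gain=1.0)
            laser = continuous_pulse_protocol(cfg.duration)
            _, events = simulate_lfp(cfg, laser)
            units, truth = simulate_units(cfg, cfg.duration, events, laser)
            u = next(u for u in units if truth.labels[u.unit_id] == "suppressed")
            phases = np.concatenate(
                [
                    ev.phase_at(u.timestamps[(u.timestamps >= ev.onset) & (u.timestamps < ev.end)])
                    for ev in events
                ]
            )
            n = phases.size
            if n < 30:
                continue
            rbar = np.abs(np.exp(1j * phases).mean())
            z = n * rbar**2
            p = np.exp(-z) * (1 + (2 * z - z**2) / (4 * n))
            n_tests += 1
            nonsig += p > 0.01
        assert n_tests >= 10
        assert nonsig >= n_tests - 1

    def test_kappa_locks_phases(self):
        cfg = vp_like_config(seed=0, phase_kappa=3.0, event_rate_gain=1.0)
        laser = continuous_pulse_protocol(cfg.duration)
        _, events = simulate_lfp(cfg, laser)
        units, truth = simulate_units(cfg, cfg.duration, events, laser)
        u = next(u for u in units if truth.labels[u.unit_id] == "suppressed")
        phases = np.concatenate(
            [
                ev.phase_at(u.timestamps[(u.timestamps >= ev.onset) & (u.timestamps < ev.end)])
                for ev in events
            ]
        )
        rbar = np.abs(np.exp(1j * phases).mean())
        assert rbar > 0.5  # kappa=3 von Mises has mean resultant ~0.8

    def test_determinism(self):
        laser = continuous_pulse_protocol(100.0)
        cfg = SimConfig(duration=100, seed=11)
        u1, _ = simulate_units(cfg, 100.0, [], laser)
        u2, _ = simulate_units(cfg, 100.0, [], laser)
        for a, b in zip(u1, u2):
            assert np.array_equal(a.timestamps, b.timestamps)


class TestYmaze:
    def test_perfect_alternation(self):
        cfg = SimConfig(duration=600, alternation_p=1.0, mean_inter_entry=2.0, seed=0)
        res = alternation_index(simulate_ymaze(cfg))
        assert res.index == 100.0

    def test_zero_alternation(self):
        cfg = SimConfig(duration=600, alternation_p=0.0, mean_inter_entry=2.0, seed=0)
        res = alternation_index(simulate_ymaze(cfg))
        assert res.index == 0.0

    def test_markov_oracle_recovery(self):
        p = 0.7
        expect = markov_alternation_expectation(p)
        assert expect == pytest.approx(70.0, abs=1e-9)  # enumeration sanity
        cfg = SimConfig(duration=1100, alternation_p=p, mean_inter_entry=1.0, seed=5)
        seq = simulate_ymaze(cfg)
        assert seq.n_entries >= 1000
        res = alternation_index(seq)
        assert res.index == pytest.approx(expect, abs=3.0)


class TestOpenField:
    def test_positions_inside_arena(self):
        cfg = SimConfig(duration=120, seed=2)
        laser = pulse_train_protocol(120.0, cfg.rng(9), interval_range=(30.0, 40.0))
        track = simulate_open_field(cfg, laser)
        assert track.x.min() >= 0 and track.x.max() <= 50
        assert track.y.min() >= 0 and track.y.max() <= 30
        assert track.n_frames == 120 * 30

    def test_requires_pulse_train(self):
        cfg = SimConfig(duration=60, seed=2)
        with pytest.raises(ValueError, match="pulse_train"):
            simulate_open_field(cfg, continuous_pulse_protocol(60.0))

    def test_determinism(self):
        cfg = SimConfig(duration=60, seed=8)
        laser = pulse_train_protocol(60.0, cfg.rng(9), interval_range=(20.0, 30.0))
        t1 = simulate_open_field(cfg, laser)
        t2 = simulate_open_field(cfg, laser)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.y, t2.y)


class TestFullSession:
    def test_session_validates_and_truth_consistent(self):
        cfg = vp_like_config(seed=1, duration=200.0)
        session, truth = simulate_session(cfg)
        assert session.duration == pytest.approx(200.0)
        t_on = sum(b - a for a, b in session.laser.epochs)
        t_off = session.duration - t_on
        for u in session.units:
            if truth.labels[u.unit_id] == "suppressed":
                on = in_epochs(u.timestamps, session.laser.epochs).sum()
                assert on / t_on < (u.n_spikes - on) / t_off

    def test_ms_config_has_no_laser_gamma_effect(self):
        cfg = ms_like_config(seed=1)
        assert cfg.gamma_rate_on_factor == 1.0 and cfg.phase_kappa == 0.0
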