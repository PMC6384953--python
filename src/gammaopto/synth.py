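"""Synthetic recording sessions with ground truth.

Generates sessions carrying the statistical structure the analysis stages
assume: a pink-noise LFP with additive amplitude-enveloped gamma bursts
whose rate (and optionally amplitude) changes during laser-ON epochs, units
that are laser-suppressed / laser-excited / unaffected, optional von-Mises
phase locking of suppressed units to the burst oscillation, and behavioral
traces (open-field track, Y-maze arm entries). Every generator is
deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .session import (
    ArmEntrySequence,
    BehaviorTrack,
    LFPSignal,
    LaserProtocol,
    RecordingSession,
    SpikeTrain,
    in_epochs,
)

ARMS = ("A", "B", "C")


@dataclass
class SimConfig:
    """Parameters of the session generator (times s, rates Hz, speeds cm/s)."""

    duration: float = 600.0
    fs: float = 500.0
    lfp_sd: float = 0.1  # background SD in mV
    noise_exponent: float = 1.0
    gamma_rate_off: float = 0.2  # burst onsets per second, laser off
    gamma_rate_on_factor: float = 1.0  # multiplies the rate during laser ON
    gamma_amp_on_factor: float = 1.0  # multiplies burst amplitude during ON
    gamma_freq_mean: float = 30.0
    gamma_freq_sd: float = 3.0
    gamma_dur_mean: float = 0.30
    gamma_dur_min: float = 0.20
    gamma_amp_sd_units: float = 5.0  # burst amplitude in units of background SD
    gamma_amp_jitter: float = 0.15  # relative lognormal amplitude jitter
    n_som_pos: int = 3
    n_excited: int = 3
    n_unaffected: int = 4
    som_suppression: float = 0.5  # fractional ON-epoch rate decrease of SOM+ units
    excited_gain: float = 1.5  # ON-epoch rate multiplier of excited units
    phase_kappa: float = 0.0  # von-Mises locking of SOM+ spikes inside bursts
    event_rate_gain: float = 1.0  # SOM+ rate multiplier inside gamma events
    base_rate: float = 8.0
    rate_amp_coef: float = 0.0  # per-event SOM+ gain slope vs burst amplitude z
    laser_on: float = 5.0
    laser_off: float = 15.0
    speed_step: float = 0.0  # laser-evoked speed increment at rest
    speed_step_duration: float = 5.0
    rest_speed: float = 0.3
    run_speed: float = 8.0
    fps: float = 30.0
    alternation_p: float = 0.7
    mean_inter_entry: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.gamma_rate_off, self.base_rate, self.phase_kappa) < 0:
            raise ValueError("rates and phase_kappa must be non-negative")
        if not 0 <= self.som_suppression <= 1:
            raise ValueError("som_suppression must lie in [0, 1]")
        if self.duration * self.fs > 5e8:
            raise ValueError("duration x fs too large (overflow guard)")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class TrueGammaEvent:
    onset: float
    duration: float
    frequency: float
    amplitude_sd: float
    during_laser: bool
    phase0: float = 0.0

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def peak_time(self) -> float:
        return self.onset + self.duration / 2.0

    def phase_at(self, t) -> np.ndarray:
        """Oscillation phase (rad) at time(s) t, 0 at the burst cosine peak."""
        return np.mod(2 * np.pi * self.frequency * (np.asarray(t) - self.onset) + self.phase0, 2 * np.pi)


@dataclass
class GroundTruth:
    labels: dict  # unit_id -> "suppressed" | "excited" | "unaffected"
    modulation: dict  # unit_id -> generative ON/OFF rate factor
    events: list  # list[TrueGammaEvent]
    event_gains: dict | None = None  # unit_id -> per-event rate gain array
    rate_amp_coef: float = 0.0


# ---------------------------------------------------------------------------
# laser protocols


def continuous_pulse_protocol(duration: float, on: float = 5.0, off: float = 15.0) -> LaserProtocol:
    """Cyclic protocol: ``off`` s dark then ``on`` s light, repeated."""
    period = on + off
    epochs = []
    t = off
    while t + on <= duration:
        epochs.append((t, t + on))
        t += period
    return LaserProtocol(epochs, kind="continuous_pulse")


def pulse_train_protocol(
    duration: float,
    rng: np.random.Generator,
    n_pulses: int = 10,
    pulse: float = 1.0,
    gap: float = 1.0,
    interval_range: tuple = (120.0, 180.0),
) -> LaserProtocol:
    """Trains of ``n_pulses`` 1 s pulses (0.5 Hz), delivered at random intervals."""
    epochs = []
    train_len = n_pulses * pulse + (n_pulses - 1) * gap
    t = float(rng.uniform(*interval_range))
    while t + train_len <= duration:
        for k in range(n_pulses):
            a = t + k * (pulse + gap)
            epochs.append((a, a + pulse))
        t += train_len + float(rng.uniform(*interval_range))
    return LaserProtocol(epochs, kind="pulse_train")


def train_onsets(laser: LaserProtocol, max_gap: float = 5.0) -> np.ndarray:
    """First-pulse onsets of each pulse train in a pulse_train protocol."""
    ons = laser.onsets
    if ons.size == 0:
        return ons
    starts = [ons[0]]
    for prev_off, onset in zip(laser.offsets[:-1], ons[1:]):
        if onset - prev_off > max_gap:
            starts.append(onset)
    return np.array(starts)


# ---------------------------------------------------------------------------
# LFP


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD noise with power spectral density proportional to 1/f^exponent."""
    freqs = np.fft.rfftfreq(n)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def _poisson_times(rate: float, a: float, b: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * (b - a))
    return np.sort(rng.uniform(a, b, size=n))


def simulate_lfp(config: SimConfig, laser: LaserProtocol | None = None):
    """Pink-noise LFP with embedded gamma bursts.

    Burst onsets follow a piecewise-homogeneous Poisson process with rate
    ``gamma_rate_off`` outside laser epochs and ``gamma_rate_off x
    gamma_rate_on_factor`` inside them. Returns ``(LFPSignal, truth)`` where
    truth is the list of :class:`TrueGammaEvent` actually embedded.
    """
    rng = config.rng(stream=1)
    n = int(round(config.duration * config.fs))
    x = pink_noise(n, config.noise_exponent, rng) * config.lfp_sd

    on_epochs = laser.epochs if laser is not None else []
    # piecewise segments with their burst-onset rate
    bounds = [0.0]
    for a, b in on_epochs:
        bounds += [a, b]
    bounds.append(config.duration)
    events: list[TrueGammaEvent] = []
    if config.gamma_rate_off > 0:
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b <= a:
                continue
            inside = in_epochs(np.array([(a + b) / 2]), on_epochs)[0]
            rate = config.gamma_rate_off * (config.gamma_rate_on_factor if inside else 1.0)
            for onset in _poisson_times(rate, a, b, rng):
                dur = max(
                    config.gamma_dur_min,
                    float(rng.normal(config.gamma_dur_mean, config.gamma_dur_mean / 4)),
                )
                if onset + dur > config.duration:
                    continue
                freq = float(
                    np.clip(
                        rng.normal(config.gamma_freq_mean, config.gamma_freq_sd),
                        config.gamma_freq_mean - 3 * config.gamma_freq_sd,
                        config.gamma_freq_mean + 3 * config.gamma_freq_sd,
                    )
                )
                amp = config.gamma_amp_sd_units * float(
                    np.exp(rng.normal(0.0, config.gamma_amp_jitter))
                )
                if inside:
                    amp *= config.gamma_amp_on_factor
                events.append(
                    TrueGammaEvent(
                        onset=float(onset),
                        duration=float(dur),
                        frequency=freq,
                        amplitude_sd=amp,
                        during_laser=bool(inside),
                        phase0=float(rng.uniform(0, 2 * np.pi)),
                    )
                )
    events.sort(key=lambda ev: ev.onset)

    for ev in events:
        i0 = int(round(ev.onset * config.fs))
        i1 = min(n, i0 + int(round(ev.duration * config.fs)))
        m = i1 - i0
        if m < 2:
            continue
        tt = np.arange(m) / config.fs
        envelope = np.hanning(m)
        x[i0:i1] += (
            ev.amplitude_sd
            * config.lfp_sd
            * envelope
            * np.cos(2 * np.pi * ev.frequency * tt + ev.phase0)
        )
    return LFPSignal(x, fs=config.fs, channel_id="ch0"), events


# ---------------------------------------------------------------------------
# spike trains


def _thin_spikes(rate: np.ndarray, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli-per-bin inhomogeneous point process (bin width ``dt`` s)."""
    p = np.clip(rate * dt, 0.0, 1.0)
    hits = np.nonzero(rng.random(p.size) < p)[0]
    return (hits + rng.uniform(0.0, 1.0, size=hits.size)) * dt


def simulate_units(
    config: SimConfig,
    duration: float,
    true_events,
    laser: LaserProtocol,
    dt: float = 0.001,
):
    """Inhomogeneous point-process spike trains for all unit classes.

    Suppressed ("SOM+") units fire at ``base_rate x (1 - som_suppression)``
    during laser-ON epochs and, when ``phase_kappa > 0``, are von-Mises
    phase-locked to the burst oscillation inside true gamma events (rate
    modulated by ``exp(kappa cos(phase)) / I0(kappa)``, which preserves the
    mean rate over whole cycles). Excited units fire at ``base_rate x
    excited_gain`` during ON epochs; unaffected units are stationary.
    """
    from scipy.special import i0 as bessel_i0

    rng = config.rng(stream=2)
    n_bins = int(round(duration / dt))
    t_grid = (np.arange(n_bins) + 0.5) * dt
    on_mask = in_epochs(t_grid, laser.epochs)

    labels: dict[str, str] = {}
    modulation: dict[str, float] = {}
    event_gains: dict[str, np.ndarray] = {}
    units: list[SpikeTrain] = []

    amps = np.array([ev.amplitude_sd for ev in true_events]) if true_events else np.zeros(0)
    if amps.size > 1 and amps.std() > 0:
        amp_z = (amps - amps.mean()) / amps.std()
    else:
        amp_z = np.zeros_like(amps)

    def add_unit(uid: str, label: str, on_factor: float, locked: bool) -> None:
        rate = np.full(n_bins, config.base_rate)
        rate[on_mask] *= on_factor
        gains = None
        if locked and true_events:
            gains = config.event_rate_gain * np.clip(1.0 + config.rate_amp_coef * amp_z, 0.1, None)
            kappa = config.phase_kappa
            norm = float(bessel_i0(kappa)) if kappa > 0 else 1.0
            for ev, g in zip(true_events, gains):
                i0_ = int(np.ceil(ev.onset / dt))
                i1_ = min(n_bins, int(np.floor(ev.end / dt)))
                if i1_ <= i0_:
                    continue
                mod = g
                if kappa > 0:
                    ph = ev.phase_at(t_grid[i0_:i1_])
                    mod = g * np.exp(kappa * np.cos(ph)) / norm
                rate[i0_:i1_] = rate[i0_:i1_] * mod
        ts = _thin_spikes(rate, dt, rng)
        ts = ts[(ts >= 0) & (ts < duration)]
        units.append(SpikeTrain(uid, ts, session_duration=duration))
        labels[uid] = label
        modulation[uid] = on_factor
        if gains is not None:
            event_gains[uid] = gains

    for k in range(config.n_som_pos):
        add_unit(f"som{k}", "suppressed", 1.0 - config.som_suppression, locked=True)
    for k in range(config.n_excited):
        add_unit(f"exc{k}", "excited", config.excited_gain, locked=False)
    for k in range(config.n_unaffected):
        add_unit(f"una{k}", "unaffected", 1.0, locked=False)

    truth = GroundTruth(
        labels=labels,
        modulation=modulation,
        events=list(true_events),
        event_gains=event_gains or None,
        rate_amp_coef=config.rate_amp_coef,
    )
    return units, truth


# ---------------------------------------------------------------------------
# behavior


def simulate_open_field(
    config: SimConfig,
    laser: LaserProtocol,
    arena: tuple = (50.0, 30.0),
):
    """Mean-reverting rest/run speed process integrated into a 2-D track.

    After each pulse-train onset at which the animal is resting, the target
    speed is raised by ``speed_step`` for ``speed_step_duration`` seconds.
    """
    if laser.kind != "pulse_train":
        raise ValueError("open-field simulation expects a pulse_train protocol")
    rng = config.rng(stream=3)
    fps = config.fps
    n = int(round(config.duration * fps))
    t = np.arange(n) / fps

    p_rest_to_run = 1.0 / (25.0 * fps)  # mean 25 s rest bouts
    p_run_to_rest = 1.0 / (12.0 * fps)  # mean 12 s run bouts
    onsets = train_onsets(laser)
    onset_frames = set(np.round(onsets * fps).astype(int))
    step_frames = int(round(config.speed_step_duration * fps))

    speed = np.empty(n)
    state = np.empty(n, dtype="U4")
    v = config.rest_speed
    running = False
    boost_left = 0
    for i in range(n):
        if i in onset_frames and not running:
            boost_left = step_frames
        if boost_left > 0:
            running = False  # step is applied at rest; hold quiescent baseline
        elif rng.random() < (p_run_to_rest if running else p_rest_to_run):
            running = not running
        target = config.run_speed if running else config.rest_speed
        if boost_left > 0:
            target = config.rest_speed + config.speed_step
            boost_left -= 1
        v += 0.25 * (target - v) + rng.normal(0.0, 0.15)
        v = max(v, 0.0)
        speed[i] = v
        state[i] = "run" if running else "rest"

    heading = rng.uniform(0, 2 * np.pi)
    x = np.empty(n)
    y = np.empty(n)
    px, py = arena[0] / 2, arena[1] / 2
    for i in range(n):
        heading += rng.normal(0.0, 0.3)
        px += speed[i] / fps * np.cos(heading)
        py += speed[i] / fps * np.sin(heading)
        # reflect at the arena walls
        if px < 0 or px > arena[0]:
            px = np.clip(px, 0, arena[0])
            heading = np.pi - heading
        if py < 0 or py > arena[1]:
            py = np.clip(py, 0, arena[1])
            heading = -heading
        x[i] = px
        y[i] = py
    return BehaviorTrack(t, x, y, fps=fps)


def simulate_ymaze(config: SimConfig, laser: LaserProtocol | None = None) -> ArmEntrySequence:
    """Markov arm-entry sequence.

    With probability ``alternation_p`` the next entry is the arm not visited
    in the last two entries, otherwise the animal returns to the previous
    arm. Inter-entry intervals are exponential with mean
    ``mean_inter_entry``.
    """
    if not 0 <= config.alternation_p <= 1:
        raise ValueError("alternation_p must lie in [0, 1]")
    rng = config.rng(stream=4)
    entries = []
    t = float(rng.exponential(config.mean_inter_entry))
    prev, cur = ARMS[0], ARMS[1]
    entries.append((t, prev))
    t += float(rng.exponential(config.mean_inter_entry))
    entries.append((t, cur))
    while True:
        t += float(rng.exponential(config.mean_inter_entry))
        if t >= config.duration:
            break
        third = next(a for a in ARMS if a not in (prev, cur))
        nxt = third if rng.random() < config.alternation_p else prev
        entries.append((t, nxt))
        prev, cur = cur, nxt
    return ArmEntrySequence(entries)


# ---------------------------------------------------------------------------
# full sessions


def vp_like_config(seed: int = 0, **overrides) -> SimConfig:
    """Session whose suppressed units are gamma-locked and whose gamma is
    laser-reduced (both rate and amplitude)."""
    kw = dict(
        phase_kappa=3.0,
        event_rate_gain=2.0,
        gamma_rate_on_factor=0.5,
        gamma_amp_on_factor=1.0,
        som_suppression=0.5,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def ms_like_config(seed: int = 0, **overrides) -> SimConfig:
    """Session with no gamma locking and no laser effect on gamma."""
    kw = dict(
        phase_kappa=0.0,
        gamma_rate_on_factor=1.0,
        gamma_amp_on_factor=1.0,
        som_suppression=0.5,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def simulate_session(
    config: SimConfig,
    region: str = "VP",
    with_behavior: bool = False,
    with_ymaze: bool = False,
):
    """Assemble a full validated :class:`RecordingSession` plus ground truth."""
    laser = continuous_pulse_protocol(config.duration, config.laser_on, config.laser_off)
    lfp, true_events = simulate_lfp(config, laser)
    units, truth = simulate_units(config, lfp.duration, true_events, laser)
    behavior = None
    ymaze = None
    if with_behavior:
        behavior = simulate_open_field(config, pulse_train_protocol(config.duration, config.rng(9)))
    if with_ymaze:
        ymaze = simulate_ymaze(config)
    session = RecordingSession(
        lfps=[lfp],
        units=units,
        laser=laser,
        behavior=behavior,
        ymaze=ymaze,
        region=region,
        genotype="NpHR+",
    )
    return session, truth
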