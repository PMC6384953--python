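import numpy as np
import pytest

from gammaopto.session import LFPSignal, LaserProtocol, RecordingSession, SpikeTrain
from gammaopto.synth import SimConfig, continuous_pulse_protocol, simulate_lfp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def laser_600():
    """Standard 10-min continuous protocol: 15 s off, 5 s on."""
    return continuous_pulse_protocol(600.0)


def make_pink_lfp(seed: int, duration: float = 30.0, fs: float = 500.0) -> LFPSignal:
    cfg = SimConfig(duration=duration, fs=fs, gamma_rate_off=0.0, seed=seed)
    lfp, events = simulate_lfp(cfg)
    assert not events
    return lfp


def inject_burst(
    lfp: LFPSignal,
    t_start: float,
    duration: float,
    freq: float,
    amp_sd: float,
    envelope: str = "rect",
) -> LFPSignal:
    """Add a burst of given amplitude (units of the signal SD) to a copy."""
    x = lfp.samples.copy()
    sd = x.std()
    i0 = int(round(t_start * lfp.fs))
    m = int(round(duration * lfp.fs))
    tt = np.arange(m) / lfp.fs
    env = np.hanning(m) if envelope == "hann" else np.ones(m)
    x[i0 : i0 + m] += amp_sd * sd * env * np.cos(2 * np.pi * freq * tt)
    return LFPSignal(x, fs=lfp.fs, t0=lfp.t0, channel_id=lfp.channel_id)


def poisson_train(
    unit_id: str, rate: float, duration: float, rng: np.random.Generator
) -> SpikeTrain:
    n = rng.poisson(rate * duration)
    ts = np.sort(rng.uniform(0.0, duration, size=n))
    ts = np.unique(ts)
    return SpikeTrain(unit_id, ts, session_duration=duration)


def tiny_session(seed: int = 0) -> RecordingSession:
    rng = np.random.default_rng(seed)
    lfp = make_pink_lfp(seed, duration=60.0)
    laser = continuous_pulse_protocol(60.0)
    units = [poisson_train(f"u{k}", 5.0, 60.0, rng) for k in range(2)]
    return RecordingSession(lfps=[lfp], units=units, laser=laser)
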