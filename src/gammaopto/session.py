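"""Recording-session data model and on-disk layout.

A session bundles continuous LFP channels, sorted spike trains, the laser
stimulation protocol and (optionally) behavioral traces on a shared time
base: seconds, zero at session start, with intervals half-open
``[onset, offset)``.

On-disk layout (one directory per session)::

    lfp.bin     flat little-endian float64, C-order (n_channels, n_samples)
    lfp.json    sidecar: fs, t0, n_channels, n_samples, channel_ids, units
    spikes.tsv  unit_id <TAB> t
    laser.tsv   onset <TAB> offset <TAB> kind
    track.tsv   t <TAB> x <TAB> y          (optional)
    ymaze.tsv   t <TAB> arm                (optional)
    meta.json   region, genotype, duration, unit ids, fps, power label

Tabular files are UTF-8 TSV with a header row; times are written as decimal
text with :data:`TIME_DECIMALS` digits, so write -> read -> write is
byte-stable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TIME_DECIMALS = 6
TIME_FMT = f"%.{TIME_DECIMALS}f"
_TIME_TOL = 10.0 ** (-TIME_DECIMALS) * 5

LASER_KINDS = ("continuous_pulse", "pulse_train")
ARM_LABELS = ("A", "B", "C")


class SessionValidationError(ValueError):
    """An invariant of a session component is violated."""


class SessionLoadError(IOError):
    """A session directory is missing a required file or is malformed."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise SessionValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise SessionValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class LFPSignal:
    """Continuous voltage trace (mV) with sampling rate ``fs`` (Hz).

    The time of sample ``i`` is ``t0 + i / fs``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples, "samples")
        if self.samples.size < 1:
            raise SessionValidationError("samples must hold at least one sample")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise SessionValidationError(f"fs must be a positive finite number, got {self.fs!r}")
        self.fs = float(self.fs)
        self.t0 = float(self.t0)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def __eq__(self, other) -> bool:
        if not isinstance(other, LFPSignal):
            return NotImplemented
        return (
            self.fs == other.fs
            and self.t0 == other.t0
            and self.channel_id == other.channel_id
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class SpikeTrain:
    """Spike timestamps (s) of one sorted unit, strictly increasing."""

    unit_id: str
    timestamps: np.ndarray
    session_duration: float

    def __post_init__(self) -> None:
        self.timestamps = _as_float_array(self.timestamps, f"timestamps[{self.unit_id}]")
        self.session_duration = float(self.session_duration)
        if self.session_duration <= 0:
            raise SessionValidationError("session_duration must be positive")
        if self.timestamps.size:
            if np.any(np.diff(self.timestamps) <= 0):
                raise SessionValidationError(
                    f"timestamps of unit {self.unit_id!r} must be strictly increasing"
                )
            if self.timestamps[0] < 0 or self.timestamps[-1] > self.session_duration:
                raise SessionValidationError(
                    f"timestamps of unit {self.unit_id!r} fall outside [0, session_duration]"
                )

    @property
    def n_spikes(self) -> int:
        return self.timestamps.size

    @property
    def basal_rate(self) -> float:
        """Mean firing rate over the whole session (Hz)."""
        return self.n_spikes / self.session_duration

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.unit_id == other.unit_id
            and self.session_duration == other.session_duration
            and np.array_equal(self.timestamps, other.timestamps)
        )


@dataclass
class LaserProtocol:
    """Ordered, non-overlapping stimulation epochs ``(onset, offset)`` in s."""

    epochs: list
    kind: str = "continuous_pulse"
    power_label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in LASER_KINDS:
            raise SessionValidationError(f"kind must be one of {LASER_KINDS}, got {self.kind!r}")
        eps = [(float(a), float(b)) for a, b in self.epochs]
        for a, b in eps:
            if not (np.isfinite(a) and np.isfinite(b) and b > a):
                raise SessionValidationError(f"epoch ({a}, {b}) must satisfy offset > onset")
        for (a0, b0), (a1, b1) in zip(eps, eps[1:]):
            if a1 < b0:
                raise SessionValidationError("epochs must be sorted and non-overlapping")
        self.epochs = eps

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([a for a, _ in self.epochs])

    @property
    def offsets(self) -> np.ndarray:
        return np.array([b for _, b in self.epochs])

    def __eq__(self, other) -> bool:
        if not isinstance(other, LaserProtocol):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.power_label == other.power_label
            and self.epochs == other.epochs
        )


@dataclass
class BehaviorTrack:
    """Video-tracked position (cm) sampled uniformly at ``fps`` frames/s."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        if not (self.t.size == self.x.size == self.y.size):
            raise SessionValidationError("t, x, y must have equal length")
        if self.t.size < 1:
            raise SessionValidationError("track must hold at least one frame")
        self.fps = float(self.fps)
        if self.fps <= 0:
            raise SessionValidationError("fps must be positive")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - 1.0 / self.fps)) > _TIME_TOL * 10:
                raise SessionValidationError("t must be uniformly spaced at 1/fps")

    @property
    def n_frames(self) -> int:
        return self.t.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, BehaviorTrack):
            return NotImplemented
        return (
            self.fps == other.fps
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )


@dataclass
class ArmEntrySequence:
    """Ordered Y-maze arm entries ``(time s, arm label)``; entries imply arm changes."""

    entries: list

    def __post_init__(self) -> None:
        ent = [(float(t), str(arm)) for t, arm in self.entries]
        for t, arm in ent:
            if arm not in ARM_LABELS:
                raise SessionValidationError(f"arm label {arm!r} not in {ARM_LABELS}")
        times = [t for t, _ in ent]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise SessionValidationError("entry times must be strictly increasing")
        if any(a0 == a1 for (_, a0), (_, a1) in zip(ent, ent[1:])):
            raise SessionValidationError("consecutive entries must differ (an entry is an arm change)")
        self.entries = ent

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def arms(self) -> list:
        return [a for _, a in self.entries]

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.entries])


@dataclass
class RecordingSession:
    """One recording session; all components share the session time base."""

    lfps: list
    units: list
    laser: LaserProtocol
    behavior: BehaviorTrack | None = None
    ymaze: ArmEntrySequence | None = None
    region: str = "VP"
    genotype: str = "NpHR+"

    def __post_init__(self) -> None:
        if not self.lfps:
            raise SessionValidationError("session requires at least one LFP channel")
        fs0 = self.lfps[0].fs
        n0 = self.lfps[0].n_samples
        for ch in self.lfps:
            if ch.fs != fs0 or ch.n_samples != n0:
                raise SessionValidationError("all LFP channels must share fs and length")
        dur = self.duration
        for u in self.units:
            if abs(u.session_duration - dur) > _TIME_TOL:
                raise SessionValidationError(
                    f"unit {u.unit_id!r} session_duration differs from LFP duration"
                )
        if self.laser.epochs and (
            self.laser.epochs[0][0] < 0 or self.laser.epochs[-1][1] > dur + _TIME_TOL
        ):
            raise SessionValidationError("laser epochs must lie within the session duration")

    @property
    def lfp(self) -> LFPSignal:
        """First (default analysis) LFP channel."""
        return self.lfps[0]

    @property
    def duration(self) -> float:
        return self.lfps[0].duration

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RecordingSession):
            return NotImplemented
        return (
            self.lfps == other.lfps
            and self.units == other.units
            and self.laser == other.laser
            and self.behavior == other.behavior
            and (
                (self.ymaze is None and other.ymaze is None)
                or (
                    self.ymaze is not None
                    and other.ymaze is not None
                    and self.ymaze.entries == other.ymaze.entries
                )
            )
            and self.region == other.region
            and self.genotype == other.genotype
        )


# ---------------------------------------------------------------------------
# epoch algebra


def epoch_complement(laser: LaserProtocol, pre_window: float):
    """Pre-onset OFF window for each ON epoch.

    For each ON epoch ``(onset, offset)`` returns the immediately preceding
    window ``(onset - pre_window, onset)``, clipped so that it does not
    overlap the previous ON epoch and does not start before the session
    (t = 0). Windows that clip to zero length are kept (``start == stop``)
    and a warning is issued; callers normally drop them.
    """
    if pre_window <= 0:
        raise ValueError("pre_window must be positive")
    out = []
    prev_off = 0.0
    for onset, offset in laser.epochs:
        start = max(onset - pre_window, prev_off, 0.0)
        if start >= onset:
            warnings.warn(
                f"pre-onset window of epoch ({onset}, {offset}) is empty after clipping",
                RuntimeWarning,
                stacklevel=2,
            )
            start = onset
        out.append((start, onset))
        prev_off = offset
    return out


def epoch_durations(epochs) -> np.ndarray:
    return np.array([b - a for a, b in epochs], dtype=float)


def in_epochs(times: np.ndarray, epochs) -> np.ndarray:
    """Boolean mask: is each time inside any half-open epoch ``[a, b)``."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.shape, dtype=bool)
    for a, b in epochs:
        mask |= (times >= a) & (times < b)
    return mask


# ---------------------------------------------------------------------------
# on-disk I/O


def _round_times(arr) -> np.ndarray:
    return np.round(np.asarray(arr, dtype=float), TIME_DECIMALS)


def write_session(session: RecordingSession, path) -> Path:
    """Write a session directory readable by :func:`read_session`.

    Timestamps in tabular files are rounded to :data:`TIME_DECIMALS`
    decimals; LFP samples are stored bit-exact as little-endian float64.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    stacked = np.stack([ch.samples for ch in session.lfps])
    (path / "lfp.bin").write_bytes(np.ascontiguousarray(stacked, dtype="<f8").tobytes())
    sidecar = {
        "fs": session.lfp.fs,
        "t0": session.lfp.t0,
        "n_channels": len(session.lfps),
        "n_samples": session.lfp.n_samples,
        "channel_ids": [ch.channel_id for ch in session.lfps],
        "units": "mV",
    }
    (path / "lfp.json").write_text(json.dumps(sidecar, indent=1) + "\n")

    rows = []
    for u in session.units:
        for t in _round_times(u.timestamps):
            rows.append((u.unit_id, t))
    spikes = pd.DataFrame(rows, columns=["unit_id", "t"])
    spikes.to_csv(path / "spikes.tsv", sep="\t", index=False, float_format=TIME_FMT)

    laser = pd.DataFrame(
        [(a, b, session.laser.kind) for a, b in session.laser.epochs],
        columns=["onset", "offset", "kind"],
    )
    laser.to_csv(path / "laser.tsv", sep="\t", index=False, float_format=TIME_FMT)

    if session.behavior is not None:
        trk = pd.DataFrame(
            {
                "t": _round_times(session.behavior.t),
                "x": _round_times(session.behavior.x),
                "y": _round_times(session.behavior.y),
            }
        )
        trk.to_csv(path / "track.tsv", sep="\t", index=False, float_format=TIME_FMT)
    if session.ymaze is not None:
        ym = pd.DataFrame(session.ymaze.entries, columns=["t", "arm"])
        ym.to_csv(path / "ymaze.tsv", sep="\t", index=False, float_format=TIME_FMT)

    meta = {
        "region": session.region,
        "genotype": session.genotype,
        "laser_kind": session.laser.kind,
        "laser_power_label": session.laser.power_label,
        "unit_ids": [u.unit_id for u in session.units],
        "fps": session.behavior.fps if session.behavior is not None else None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    return path


def _require(path: Path) -> Path:
    if not path.exists():
        raise SessionLoadError(f"missing session file: {path}")
    return path


def read_session(path) -> RecordingSession:
    """Load and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    if not path.is_dir():
        raise SessionLoadError(f"not a session directory: {path}")

    sidecar = json.loads(_require(path / "lfp.json").read_text())
    raw = np.frombuffer(_require(path / "lfp.bin").read_bytes(), dtype="<f8")
    n_ch, n_s = int(sidecar["n_channels"]), int(sidecar["n_samples"])
    if raw.size != n_ch * n_s:
        raise SessionLoadError(
            f"lfp.bin holds {raw.size} samples, sidecar promises {n_ch}x{n_s}"
        )
    data = raw.reshape(n_ch, n_s)
    lfps = [
        LFPSignal(data[i].copy(), fs=sidecar["fs"], t0=sidecar.get("t0", 0.0), channel_id=cid)
        for i, cid in enumerate(sidecar["channel_ids"])
    ]
    duration = lfps[0].duration

    meta = json.loads(_require(path / "meta.json").read_text())
    spikes = pd.read_csv(_require(path / "spikes.tsv"), sep="\t", dtype={"unit_id": str})
    units = []
    for uid in meta["unit_ids"]:
        ts = spikes.loc[spikes["unit_id"] == uid, "t"].to_numpy(dtype=float)
        units.append(SpikeTrain(uid, ts, session_duration=duration))

    laser_df = pd.read_csv(_require(path / "laser.tsv"), sep="\t")
    kind = meta.get("laser_kind", "continuous_pulse")
    if len(laser_df) and "kind" in laser_df:
        kind = str(laser_df["kind"].iloc[0])
    laser = LaserProtocol(
        list(zip(laser_df["onset"], laser_df["offset"])),
        kind=kind,
        power_label=meta.get("laser_power_label", ""),
    )

    behavior = None
    if (path / "track.tsv").exists():
        trk = pd.read_csv(path / "track.tsv", sep="\t")
        behavior = BehaviorTrack(
            trk["t"].to_numpy(float),
            trk["x"].to_numpy(float),
            trk["y"].to_numpy(float),
            fps=meta.get("fps") or 30.0,
        )
    ymaze = None
    if (path / "ymaze.tsv").exists():
        ym = pd.read_csv(path / "ymaze.tsv", sep="\t", dtype={"arm": str})
        ymaze = ArmEntrySequence(list(zip(ym["t"], ym["arm"])))

    return RecordingSession(
        lfps=lfps,
        units=units,
        laser=laser,
        behavior=behavior,
        ymaze=ymaze,
        region=meta.get("region", "VP"),
        genotype=meta.get("genotype", "NpHR+"),
    )
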