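"""Reading, writing and aligning gait time-series, event lists and manifests.

All files are UTF-8, comma-delimited CSV with a "." decimal separator.
Time-series files carry a ``time_s`` column followed by one column per
channel; event files carry ``time_s,side,event``; manifests are YAML
key-value documents.  Time is stored in seconds; the sampling rate is
metadata and is checked against the rate inferred from the time column
(1% tolerance, to tolerate clock jitter in real exports).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("emgknee")

__all__ = [
    "EmgRecording", "AngleSeries", "EventList", "DatasetManifest",
    "FormatError", "RateError", "AlignmentError",
    "read_timeseries", "write_timeseries", "read_events", "write_events",
    "align_streams",
]


class FormatError(ValueError):
    """Malformed time-series / event file."""


class RateError(ValueError):
    """Declared and inferred sampling rates disagree by more than 1%."""


class AlignmentError(ValueError):
    """Streams share no overlapping time support."""


@dataclass
class EmgRecording:
    """Multichannel surface-EMG stream (time x channel, arbitrary units)."""

    channels: list[str]
    rate_hz: float
    samples: np.ndarray  # (n_samples, n_channels)
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if len(self.channels) == 0:
            raise ValueError("recording needs at least one channel")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if len(self.channels) != self.samples.shape[1]:
            raise ValueError("channel count does not match sample matrix")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate_hz

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n_samples - 1) / self.rate_hz


@dataclass
class AngleSeries:
    """Knee flexion angle in degrees at a fixed sampling rate."""

    rate_hz: float
    values: np.ndarray
    convention: str = "flexion_positive"
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("angle values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate_hz

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n_samples - 1) / self.rate_hz


@dataclass
class EventList:
    """Ordered (time, side, label) gait events; labels include foot_contact."""

    events: list[tuple[float, str, str]]

    VOCABULARY = ("foot_contact", "foot_off")

    def __post_init__(self):
        for _, _, label in self.events:
            if label not in self.VOCABULARY:
                raise ValueError(f"unknown event label {label!r}")
        for side in {s for _, s, _ in self.events}:
            times = [t for t, s, _ in self.events if s == side]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"event times not strictly increasing for side {side!r}")

    def contacts(self, side: str) -> np.ndarray:
        return np.array([t for t, s, lab in self.events
                         if s == side and lab == "foot_contact"])


@dataclass
class DatasetManifest:
    """Paths, channels, rates and identifiers for one recorded trial."""

    emg_path: str
    angle_path: str
    events_path: str
    channels: list[str]
    emg_rate_hz: float
    angle_rate_hz: float
    subject: str = "S1"
    visit: str = "V1"
    trial: str = "T1"

    def save(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)
        return path

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        manifest = cls(**data)
        base = path.parent
        for key in ("emg_path", "angle_path", "events_path"):
            p = base / getattr(manifest, key)
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
        with open(base / manifest.emg_path, encoding="utf-8") as fh:
            header = fh.readline().strip().split(",")
        missing = set(manifest.channels) - set(header[1:])
        if missing:
            raise ValueError(f"manifest declares channels absent from the EMG "
                             f"file header: {sorted(missing)}")
        return manifest

    def resolve(self, key: str, base) -> Path:
        return Path(base) / getattr(self, key)


# -- time-series I/O --------------------------------------------------------

def _infer_rate(times: np.ndarray) -> float:
    steps = np.diff(times)
    if steps.size == 0:
        raise FormatError("cannot infer sampling rate from a single sample")
    if np.any(steps <= 0):
        raise FormatError("time column must be strictly increasing")
    return 1.0 / float(np.median(steps))


def read_timeseries(path, expected_rate: float | None = None, kind: str = "auto"):
    """Read a delimited time-series file into an EmgRecording or AngleSeries.

    The first header column must be ``time_s``.  The rate is inferred from
    the median time step; a declared ``expected_rate`` must agree within 1%.
    ``kind`` is "emg", "angle" or "auto" (single column named ``angle`` =>
    AngleSeries).
    """
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise FormatError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: no data columns")
    times = df["time_s"].to_numpy(dtype=float)
    if df.shape[0] < 2:
        raise FormatError(f"{path}: need at least two rows to infer a rate")
    rate = _infer_rate(times)
    if expected_rate is not None:
        if abs(rate - expected_rate) > 0.01 * expected_rate:
            raise RateError(
                f"{path}: declared rate {expected_rate} Hz vs inferred {rate:.6g} Hz")
        rate = float(expected_rate)
    channels = list(df.columns[1:])
    values = df[channels].to_numpy(dtype=float)
    if kind == "angle" or (kind == "auto" and channels == ["angle"]):
        return AngleSeries(rate_hz=rate, values=values[:, 0], t0=float(times[0]))
    return EmgRecording(channels=channels, rate_hz=rate, samples=values,
                        t0=float(times[0]))


def write_timeseries(recording, path) -> Path:
    """Write an EmgRecording or AngleSeries as time_s + channel columns.

    Values are printed with 12 significant digits so a read/write round trip
    preserves them to well below 1e-9 absolute error at gait magnitudes.
    """
    path = Path(path)
    if isinstance(recording, AngleSeries):
        channels, values = ["angle"], recording.values[:, None]
    else:
        channels, values = recording.channels, recording.samples
    if len(channels) == 0:
        raise ValueError("cannot write a recording with no channels")
    df = pd.DataFrame(values, columns=channels)
    df.insert(0, "time_s", recording.times)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_events(path) -> EventList:
    df = pd.read_csv(path)
    expected = ["time_s", "side", "event"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: event header must be {','.join(expected)}")
    return EventList([(float(t), str(s), str(e))
                      for t, s, e in df.itertuples(index=False)])


def write_events(events: EventList, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(events.events, columns=["time_s", "side", "event"])
    df.to_csv(path, index=False, float_format="%.12g")
    return path


# -- alignment --------------------------------------------------------------

def align_streams(emg: EmgRecording, angle: AngleSeries):
    """Trim both streams to their common time window (no resampling).

    Sampling rates are left untouched; cycle-level time normalization is the
    job of the gait module.  Returns (emg, angle) annotated with the common
    start/stop times.  Idempotent.
    """
    start = max(emg.t0, angle.t0)
    stop = min(emg.t_end, angle.t_end)
    if stop <= start:
        raise AlignmentError(
            f"no overlap: EMG [{emg.t0}, {emg.t_end}] vs angle [{angle.t0}, {angle.t_end}]")

    def window(t0, rate, n):
        i0 = int(np.ceil(round((start - t0) * rate, 9)))
        i1 = int(np.floor(round((stop - t0) * rate, 9)))
        return max(i0, 0), min(i1, n - 1)

    e0, e1 = window(emg.t0, emg.rate_hz, emg.n_samples)
    a0, a1 = window(angle.t0, angle.rate_hz, angle.n_samples)
    meta = dict(emg.meta)
    meta.update(common_start=start, common_stop=stop)
    emg_out = EmgRecording(channels=list(emg.channels), rate_hz=emg.rate_hz,
                           samples=emg.samples[e0:e1 + 1],
                           t0=emg.t0 + e0 / emg.rate_hz, meta=meta)
    angle_out = AngleSeries(rate_hz=angle.rate_hz, values=angle.values[a0:a1 + 1],
                            convention=angle.convention,
                            t0=angle.t0 + a0 / angle.rate_hz)
    return emg_out, angle_out
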