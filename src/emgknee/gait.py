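"""Gait-cycle segmentation, time normalization and dataset assembly.

A gait cycle spans one foot-ground contact to the next contact of the same
foot.  Each cycle's conditioned EMG envelopes and knee angle are linearly
interpolated onto L equally spaced points (default L=100) and the EMG is
tiled into non-overlapping 20-sample segments, ordered time-window-major /
channel-minor, so one cycle yields (L/20) x n_channels encoder inputs
(40 segments for 8 muscles, 30 for 6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AngleSeries, EmgRecording, EventList

logger = logging.getLogger("emgknee")

__all__ = [
    "GaitCycle", "SegmentSequence", "NormStats", "GaitCycleDataset",
    "split_cycles", "time_normalize", "segment", "make_dataset",
]

MIN_CYCLE_S = 0.2
MAX_CYCLE_S = 5.0


@dataclass
class GaitCycle:
    """One stride: EMG envelope matrix and knee angle on a shared time base."""

    start: float
    end: float
    channels: list[str]
    emg: np.ndarray          # (n_emg, n_channels)
    angle: np.ndarray        # (n_angle,)
    emg_times: np.ndarray
    angle_times: np.ndarray
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("cycle end must be after start")

    @property
    def L(self) -> int:
        if not self.normalized:
            raise ValueError("cycle is not time-normalized")
        return self.angle.size

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SegmentSequence:
    """Ordered fixed-width EMG segments forming one encoder input."""

    segments: np.ndarray     # (M, window), time-window-major / channel-minor
    channels: list[str]
    window: int

    def __post_init__(self):
        self.segments = np.asarray(self.segments, dtype=float)
        if self.segments.ndim != 2 or self.segments.shape[1] != self.window:
            raise ValueError("segments must be (M, window)")

    def __len__(self) -> int:
        return self.segments.shape[0]

    def reassemble(self) -> np.ndarray:
        """Invert segmentation back to the (L, n_channels) envelope matrix."""
        n_ch = len(self.channels)
        n_tw = len(self) // n_ch
        mat = self.segments.reshape(n_tw, n_ch, self.window)
        return np.concatenate([mat[i].T for i in range(n_tw)], axis=0)


@dataclass
class NormStats:
    """Train-set min/max bounds for EMG channels and knee angle."""

    ch_min: np.ndarray
    ch_max: np.ndarray
    angle_min: float
    angle_max: float

    def norm_emg(self, emg: np.ndarray) -> np.ndarray:
        span = np.where(self.ch_max > self.ch_min, self.ch_max - self.ch_min, 1.0)
        return (emg - self.ch_min) / span

    def norm_angle(self, angle: np.ndarray) -> np.ndarray:
        span = self.angle_max - self.angle_min
        return (angle - self.angle_min) / (span if span > 0 else 1.0)

    def denorm_angle(self, y: np.ndarray) -> np.ndarray:
        return self.angle_min + y * (self.angle_max - self.angle_min)


def split_cycles(emg: EmgRecording, angle: AngleSeries, events: EventList,
                 side: str = "right") -> list[GaitCycle]:
    """Cut aligned streams into per-stride cycles between foot contacts.

    Cycles shorter than 0.2 s or longer than 5 s are discarded with a
    logged warning; fewer than two contacts yields an empty list.
    """
    contacts = events.contacts(side)
    if contacts.size < 2:
        logger.warning("side %r has %d foot_contact events; no cycles", side,
                       contacts.size)
        return []
    cycles: list[GaitCycle] = []
    et, at = emg.times, angle.times
    for t0, t1 in zip(contacts[:-1], contacts[1:]):
        dur = t1 - t0
        if not (MIN_CYCLE_S <= dur <= MAX_CYCLE_S):
            logger.warning("discarding %.3f s cycle at t=%.3f s (outside "
                           "[%.1f, %.1f] s)", dur, t0, MIN_CYCLE_S, MAX_CYCLE_S)
            continue
        em = (et >= t0) & (et <= t1)
        am = (at >= t0) & (at <= t1)
        if em.sum() < 2 or am.sum() < 2:
            logger.warning("discarding cycle at t=%.3f s: too few samples", t0)
            continue
        cycles.append(GaitCycle(start=float(t0), end=float(t1),
                                channels=list(emg.channels),
                                emg=emg.samples[em], angle=angle.values[am],
                                emg_times=et[em], angle_times=at[am]))
    return cycles


def time_normalize(cycle: GaitCycle, L: int = 100) -> GaitCycle:
    """Linearly interpolate EMG channels and angle onto L points per cycle."""
    if cycle.duration <= 0:
        raise ValueError("degenerate zero-duration cycle")
    if cycle.emg.shape[0] < 2 or cycle.angle.size < 2:
        raise ValueError("need at least 2 samples per stream")
    grid_emg = np.linspace(cycle.emg_times[0], cycle.emg_times[-1], L)
    grid_ang = np.linspace(cycle.angle_times[0], cycle.angle_times[-1], L)
    emg = np.column_stack([np.interp(grid_emg, cycle.emg_times, cycle.emg[:, c])
                           for c in range(cycle.emg.shape[1])])
    angle = np.interp(grid_ang, cycle.angle_times, cycle.angle)
    return GaitCycle(start=cycle.start, end=cycle.end, channels=list(cycle.channels),
                     emg=emg, angle=angle, emg_times=grid_emg, angle_times=grid_ang,
                     normalized=True, meta=dict(cycle.meta))


def segment(cycle: GaitCycle, window: int = 20) -> SegmentSequence:
    """Tile a normalized cycle into ordered non-overlapping segments."""
    if not cycle.normalized:
        raise ValueError("segment() requires a time-normalized cycle")
    L = cycle.L
    if L % window != 0:
        raise ValueError(
            f"normalized length {L} is not divisible by window {window}; "
            f"use L={window * (L // window)} or {window * (L // window + 1)}")
    n_tw = L // window
    n_ch = len(cycle.channels)
    segs = np.empty((n_tw * n_ch, window))
    k = 0
    for tw in range(n_tw):          # time-window-major
        sl = slice(tw * window, (tw + 1) * window)
        for c in range(n_ch):        # channel-minor
            segs[k] = cycle.emg[sl, c]
            k += 1
    return SegmentSequence(segments=segs, channels=list(cycle.channels), window=window)


@dataclass
class GaitCycleDataset:
    """Normalized cycles with a train/test split and train-only statistics."""

    cycles: list[GaitCycle]
    split: list[str]                  # "train"/"test" per cycle
    stats: NormStats
    train_frac: float
    seed: int = 0

    @property
    def channels(self) -> list[str]:
        return self.cycles[0].channels

    @property
    def L(self) -> int:
        return self.cycles[0].L

    @property
    def train_cycles(self) -> list[GaitCycle]:
        return [c for c, s in zip(self.cycles, self.split) if s == "train"]

    @property
    def test_cycles(self) -> list[GaitCycle]:
        return [c for c, s in zip(self.cycles, self.split) if s == "test"]

    def drop_channel(self, channel: str) -> "GaitCycleDataset":
        """Dataset with `channel` removed and statistics recomputed."""
        if channel not in self.channels:
            raise ValueError(f"unknown channel {channel!r}")
        keep = [i for i, c in enumerate(self.channels) if c != channel]
        names = [self.channels[i] for i in keep]
        new_cycles = [GaitCycle(start=c.start, end=c.end, channels=list(names),
                                emg=c.emg[:, keep], angle=c.angle,
                                emg_times=c.emg_times, angle_times=c.angle_times,
                                normalized=c.normalized, meta=dict(c.meta))
                      for c in self.cycles]
        ds = GaitCycleDataset(cycles=new_cycles, split=list(self.split),
                              stats=_compute_stats([c for c, s in
                                                    zip(new_cycles, self.split)
                                                    if s == "train"]),
                              train_frac=self.train_frac, seed=self.seed)
        return ds


def _compute_stats(train_cycles: list[GaitCycle]) -> NormStats:
    emg = np.concatenate([c.emg for c in train_cycles], axis=0)
    ang = np.concatenate([c.angle for c in train_cycles])
    return NormStats(ch_min=emg.min(axis=0), ch_max=emg.max(axis=0),
                     angle_min=float(ang.min()), angle_max=float(ang.max()))


def make_dataset(cycles: list[GaitCycle], train_frac: float = 0.6,
                 seed: int = 0, shuffle: bool = False) -> GaitCycleDataset:
    """Chronological 60/40 split with train-only normalization statistics.

    The first floor(train_frac * n) cycles form the training set (avoids
    temporal leakage between adjacent strides); `shuffle=True` enables a
    seeded random split instead.
    """
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    if len(cycles) < 2:
        raise ValueError("need at least 2 cycles")
    if not all(c.normalized for c in cycles):
        raise ValueError("all cycles must be time-normalized first")
    n_train = int(np.floor(train_frac * len(cycles)))
    n_train = max(n_train, 1)
    order = np.arange(len(cycles))
    if shuffle:
        order = np.random.default_rng(seed).permutation(len(cycles))
    split = ["test"] * len(cycles)
    for i in order[:n_train]:
        split[i] = "train"
    train = [c for c, s in zip(cycles, split) if s == "train"]
    return GaitCycleDataset(cycles=list(cycles), split=split,
                            stats=_compute_stats(train),
                            train_frac=train_frac, seed=seed)


def dataset_arrays(cycles: list[GaitCycle], stats: NormStats,
                   window: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Normalized encoder/decoder arrays X (n, M, window) and Y (n, L)."""
    X, Y = [], []
    for c in cycles:
        seq = segment(GaitCycle(start=c.start, end=c.end, channels=c.channels,
                                emg=stats.norm_emg(c.emg), angle=c.angle,
                                emg_times=c.emg_times, angle_times=c.angle_times,
                                normalized=True, meta=dict(c.meta)), window)
        X.append(seq.segments)
        Y.append(stats.norm_angle(c.angle))
    return np.asarray(X), np.asarray(Y)
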