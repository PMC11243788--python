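"""Multi-stage surface-EMG conditioning chain.

Stage order per channel: Hampel outlier removal -> zero-phase band-pass
(50-190 Hz) -> full-wave rectification with a 50-sample moving average ->
consecutive peak and RMS envelope detectors -> zero-phase low-pass
smoothing.  Every stage preserves signal length; sliding windows are
truncated at the signal boundaries rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d

from .io import EmgRecording

__all__ = [
    "FilterConfig", "hampel_filter", "bandpass", "rectify", "envelope",
    "lowpass_smooth", "condition",
]

# consistency constant relating MAD to the Gaussian standard deviation
_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the conditioning chain.

    Windows are in samples at the recording's EMG rate; cutoffs in Hz.
    The band edges (50-190 Hz), the Hampel window (20 samples) and the
    rectification window (50 samples) are the published operating points;
    the low-pass cutoff (6 Hz, a typical linear-envelope choice) and the
    Butterworth orders are package defaults, all overridable.
    """

    hampel_window: int = 20
    hampel_nsigma: float = 3.0
    band_low: float = 50.0
    band_high: float = 190.0
    band_order: int = 4
    rectify_window: int = 50
    envelope_window: int = 50
    lowpass_cut: float = 6.0
    lowpass_order: int = 4

    def validate(self, rate_hz: float) -> None:
        if not (0 < self.band_low < self.band_high < rate_hz / 2):
            raise ValueError(
                f"band edges must satisfy 0 < {self.band_low} < {self.band_high} "
                f"< Nyquist ({rate_hz / 2})")
        if self.lowpass_cut >= rate_hz / 2:
            raise ValueError("low-pass cutoff must be below Nyquist")
        for name in ("hampel_window", "rectify_window", "envelope_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _window_bounds(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated centered-window bounds [lo, hi) for each sample index."""
    half_lo = (window - 1) // 2
    half_hi = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    return lo, hi


def hampel_filter(x, window: int = 20, nsigma: float = 3.0) -> np.ndarray:
    """Replace outliers by the local window median.

    Sample i is replaced when |x_i - median| exceeds nsigma * 1.4826 * MAD
    of its (truncated, centered) window of `window` samples.  Constant
    windows are never flagged (|x_i - median| = 0 is not an exceedance).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n == 0:
        raise ValueError("empty signal")
    if window < 1:
        raise ValueError("window must be >= 1")
    w = min(window, n)
    med = np.empty(n)
    mad = np.empty(n)
    if w >= 1 and n >= w:
        # interior: full windows, vectorized
        views = np.lib.stride_tricks.sliding_window_view(x, w)
        m = np.median(views, axis=1)
        d = np.median(np.abs(views - m[:, None]), axis=1)
        first_center = (w - 1) // 2
        med[first_center:first_center + views.shape[0]] = m
        mad[first_center:first_center + views.shape[0]] = d
        # truncated edges
        lo, hi = _window_bounds(n, w)
        edge = list(range(first_center)) + list(range(first_center + views.shape[0], n))
        for i in edge:
            seg = x[lo[i]:hi[i]]
            med[i] = np.median(seg)
            mad[i] = np.median(np.abs(seg - med[i]))
    out = x.copy()
    flag = np.abs(x - med) > nsigma * _MAD_SCALE * mad
    out[flag] = med[flag]
    return out


def bandpass(x, rate_hz: float, low: float = 50.0, high: float = 190.0,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, unit passband gain)."""
    x = np.asarray(x, dtype=float).ravel()
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= rate_hz / 2:
        raise ValueError("high cutoff must be below Nyquist")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated edge windows (length preserving)."""
    n = x.size
    w = min(window, n)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo, hi = _window_bounds(n, w)
    return (csum[hi] - csum[lo]) / (hi - lo)


def rectify(x, window: int = 50) -> np.ndarray:
    """Full-wave rectification followed by a centered `window`-sample mean."""
    x = np.asarray(x, dtype=float).ravel()
    if window < 1:
        raise ValueError("window must be >= 1")
    return _moving_average(np.abs(x), window)


def envelope(x, window: int = 50) -> np.ndarray:
    """Consecutive peak and RMS detectors over the same window length.

    Stage 1 is a sliding-window maximum (peak detector); stage 2 a
    sliding-window root-mean-square of the peak signal.  Input is expected
    nonnegative (rectified); output is nonnegative and length preserving.
    """
    x = np.asarray(x, dtype=float).ravel()
    if window < 1:
        raise ValueError("window must be >= 1")
    w = min(window, x.size)
    # mode="constant" with a -inf fill realizes truncated-window maxima
    peak = maximum_filter1d(x, size=w, mode="constant", cval=-np.inf)
    ms = _moving_average(peak ** 2, w)
    return np.sqrt(ms)


def lowpass_smooth(x, rate_hz: float, cut: float = 6.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass smoothing."""
    x = np.asarray(x, dtype=float).ravel()
    if cut >= rate_hz / 2:
        raise ValueError("cutoff must be below Nyquist")
    sos = sps.butter(order, cut, btype="lowpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x)


def condition(recording: EmgRecording, cfg: FilterConfig | None = None) -> EmgRecording:
    """Apply the full conditioning chain to every channel of a recording."""
    cfg = cfg or FilterConfig()
    cfg.validate(recording.rate_hz)
    out = np.empty_like(recording.samples)
    for c in range(recording.samples.shape[1]):
        x = recording.samples[:, c]
        x = hampel_filter(x, cfg.hampel_window, cfg.hampel_nsigma)
        x = bandpass(x, recording.rate_hz, cfg.band_low, cfg.band_high, cfg.band_order)
        x = rectify(x, cfg.rectify_window)
        x = envelope(x, cfg.envelope_window)
        x = lowpass_smooth(x, recording.rate_hz, cfg.lowpass_cut, cfg.lowpass_order)
        out[:, c] = x
    meta = dict(recording.meta)
    meta["conditioned"] = True
    return EmgRecording(channels=list(recording.channels), rate_hz=recording.rate_hz,
                        samples=out, t0=recording.t0, meta=meta)
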