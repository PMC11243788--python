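"""Evaluation metrics for knee-angle estimates.

RMSE, Pearson correlation (CC), a signal-to-noise ratio in dB, normalized
RMSE (RMSE over the measured range), and the average convergence rate of a
sequential-learning run (slope of the line joining the first and last
per-stride RMSE, in degrees per stride).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StrideMetrics", "rmse", "cc", "snr", "nrmse", "convergence_rate",
           "stride_metrics"]


@dataclass(frozen=True)
class StrideMetrics:
    rmse: float     # degrees
    cc: float       # dimensionless, in [-1, 1]
    snr: float      # dB
    nrmse: float    # fraction of the measured range


def _pair(measured, estimated) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float).ravel()
    e = np.asarray(estimated, dtype=float).ravel()
    if m.size != e.size:
        raise ValueError(f"length mismatch: {m.size} vs {e.size}")
    if m.size == 0:
        raise ValueError("empty sequences")
    return m, e


def rmse(measured, estimated) -> float:
    """Root-mean-square error sqrt(sum((est - meas)^2) / N)."""
    m, e = _pair(measured, estimated)
    return float(np.sqrt(np.mean((e - m) ** 2)))


def cc(measured, estimated) -> float:
    """Pearson correlation coefficient between measured and estimated."""
    m, e = _pair(measured, estimated)
    if m.size < 2:
        raise ValueError("need at least 2 samples for a correlation")
    dm, de = m - m.mean(), e - e.mean()
    denom = np.sqrt(np.mean(dm ** 2)) * np.sqrt(np.mean(de ** 2))
    if denom == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.mean(dm * de) / denom)


def snr(measured, estimated, mode: str = "literal") -> float:
    """Signal-to-noise ratio of the estimate in dB.

    mode="literal" (default): 10*log10(mean(measured^2) / mean(estimated^2)),
    the published form.  mode="error": the conventional
    10*log10(mean(measured^2) / mean((measured - estimated)^2)).
    """
    m, e = _pair(measured, estimated)
    num = np.mean(m ** 2)
    if mode == "literal":
        den = np.mean(e ** 2)
        if den == 0:
            raise ValueError("zero-power estimate")
    elif mode == "error":
        den = np.mean((m - e) ** 2)
        if den == 0:
            raise ValueError("zero error: SNR is infinite")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(10.0 * np.log10(num / den))


def nrmse(measured, estimated) -> float:
    """RMSE normalized by the range of the measured sequence."""
    m, e = _pair(measured, estimated)
    rng = float(m.max() - m.min())
    if rng == 0:
        raise ValueError("zero measured range")
    return rmse(m, e) / rng


def convergence_rate(per_stride_rmse) -> float:
    """Slope joining the first and last per-stride RMSE (deg/stride).

    Strides are unit-spaced points, so the slope is
    (rmse_last - rmse_first) / (n_strides - 1).
    """
    r = np.asarray(per_stride_rmse, dtype=float).ravel()
    if r.size < 2:
        raise ValueError("need at least 2 strides")
    return float((r[-1] - r[0]) / (r.size - 1))


def stride_metrics(measured, estimated, snr_mode: str = "literal") -> StrideMetrics:
    """All per-stride metrics at once."""
    return StrideMetrics(rmse=rmse(measured, estimated),
                         cc=cc(measured, estimated),
                         snr=snr(measured, estimated, mode=snr_mode),
                         nrmse=nrmse(measured, estimated))
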