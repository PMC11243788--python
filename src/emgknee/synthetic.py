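"""Physiologically structured synthetic gait sEMG + knee-angle generator.

Each trial is built stride by stride.  Muscle activation envelopes are sums
of periodic Gaussian bursts at standard gait timings (tibialis anterior at
contact and in swing; gastrocnemius/soleus in late stance; quadriceps at
loading and pre-swing; hamstrings in terminal swing).  The knee angle is a
fixed linear combination of the lagged envelopes, calibrated once per
preset (non-negative least squares) so that the deterministic part of the
combination reproduces a two-bump knee-flexion template (small stance
flexion wave, large swing flexion wave).  Electromyographic activity
therefore genuinely precedes and drives the motion, with a configurable
electromechanical lag (default 40 ms), and per-stride amplitude jitter on
the envelopes propagates to per-stride angle variation that an estimator
can (and must) learn from the EMG.

Raw EMG = envelope x band-limited (60-180 Hz) zero-mean unit-RMS carrier
plus an additive band-limited noise floor and sparse motion-artifact
spikes, so the 50-190 Hz conditioning chain is exercised meaningfully.
Ground-truth envelopes, coupling weights and noise powers are stored on
the trial for end-to-end validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.optimize import nnls

from .io import AngleSeries, EmgRecording, EventList

__all__ = [
    "GaitProfile", "MuscleTemplate", "SyntheticTrial", "Preset",
    "knee_angle_template", "synthesize_trial", "cp_degrade", "make_presets",
    "driver_muscles",
]

HV8_CHANNELS = ["TA", "MG", "SL", "PL", "HL", "RF", "VL", "MH"]
SHARED6_CHANNELS = ["TA", "MG", "SL", "VL", "RF", "MH"]


@dataclass(frozen=True)
class GaitProfile:
    """Stride timing, spatiotemporal statistics and knee-angle template."""

    step_len_mean: float          # m
    step_len_sd: float
    speed_mean: float             # m/s
    speed_sd: float
    baseline_deg: float           # knee flexion offset over the cycle
    stance_peak_deg: float        # absolute flexion at the stance wave peak
    swing_peak_deg: float         # absolute flexion at the swing wave peak
    stance_time: float = 0.15     # cycle fraction of the stance wave peak
    swing_time: float = 0.72
    stance_width: float = 0.07
    swing_width: float = 0.09

    @property
    def stride_s_mean(self) -> float:
        # stride = two steps
        return 2.0 * self.step_len_mean / self.speed_mean

    @property
    def stride_s_sd(self) -> float:
        rel = np.hypot(self.step_len_sd / self.step_len_mean,
                       self.speed_sd / self.speed_mean)
        return self.stride_s_mean * rel


@dataclass(frozen=True)
class MuscleTemplate:
    """Per-channel burst timings/gains and the EMG-to-angle coupling recipe."""

    channels: tuple[str, ...]
    bursts: dict  # channel -> list of (center cycle fraction, width, gain)
    noise_floor: float = 0.05       # additive carrier-band noise RMS (a.u.)
    amp_jitter_sd: float = 0.08     # per-stride multiplicative envelope jitter
    tonic_level: float = 0.02       # resting activation baseline
    carrier_band: tuple[float, float] = (60.0, 180.0)
    lag_s: float = 0.04             # electromechanical delay, seconds
    coupling_channels: tuple[str, ...] | None = None  # None = all channels

    def __post_init__(self):
        for ch, bs in self.bursts.items():
            for c, w, g in bs:
                if not (0 <= c < 1):
                    raise ValueError(f"burst center {c} of {ch} outside [0,1)")
                if g < 0:
                    raise ValueError("burst gains must be >= 0")


def _bump(phi: np.ndarray, center: float, width: float) -> np.ndarray:
    """Periodic Gaussian bump on the unit cycle (wrapped at both ends)."""
    phi = np.asarray(phi, dtype=float)
    out = np.zeros_like(phi)
    for k in (-1.0, 0.0, 1.0):
        out += np.exp(-0.5 * ((phi - center + k) / width) ** 2)
    return out


def knee_angle_template(profile: GaitProfile, L: int = 100) -> np.ndarray:
    """Two-bump knee-flexion trajectory over one normalized cycle (degrees)."""
    phi = np.arange(L) / L
    st_amp = profile.stance_peak_deg - profile.baseline_deg
    sw_amp = profile.swing_peak_deg - profile.baseline_deg
    return (profile.baseline_deg
            + st_amp * _bump(phi, profile.stance_time, profile.stance_width)
            + sw_amp * _bump(phi, profile.swing_time, profile.swing_width))


def _unit_envelope(muscles: MuscleTemplate, channel: str,
                   phi: np.ndarray) -> np.ndarray:
    env = np.full(phi.shape, muscles.tonic_level)
    for c, w, g in muscles.bursts[channel]:
        env += g * _bump(phi, c, w)
    return env


def calibrate_coupling(profile: GaitProfile,
                       muscles: MuscleTemplate) -> dict[str, float]:
    """Non-negative least-squares weights mapping lagged envelopes to angle.

    Fitted once on a dense cycle grid so that
    baseline + sum_c w_c * e_c(phi - lag) approximates the knee template.
    Channels outside `coupling_channels` get weight zero.
    """
    grid = np.linspace(0, 1, 400, endpoint=False)
    lag_frac = muscles.lag_s / profile.stride_s_mean
    target = knee_angle_template(profile, 400) - profile.baseline_deg
    allowed = muscles.coupling_channels or muscles.channels
    basis = np.column_stack([_unit_envelope(muscles, ch, grid - lag_frac)
                             for ch in allowed])
    # mild Tikhonov augmentation spreads weight over collinear channels
    lam = 0.05 * np.linalg.norm(basis, axis=0).mean()
    a_aug = np.vstack([basis, lam * np.eye(len(allowed))])
    b_aug = np.concatenate([target, np.zeros(len(allowed))])
    w, _ = nnls(a_aug, b_aug)
    weights = {ch: 0.0 for ch in muscles.channels}
    weights.update({ch: float(wi) for ch, wi in zip(allowed, w)})
    return weights


@dataclass
class SyntheticTrial:
    """A generated walking trial with full ground truth."""

    emg: EmgRecording
    angle: AngleSeries
    events: EventList
    envelopes: np.ndarray          # ground truth at the EMG rate (n, C)
    coupling: dict
    noise_power: float             # additive noise floor power (a.u.^2)
    amp_jitter: np.ndarray         # (n_strides, C) per-stride multipliers
    stride_durations: np.ndarray
    realized_speeds: np.ndarray
    seed: int
    preset: str = "custom"
    profile: GaitProfile | None = None
    muscles: MuscleTemplate | None = None

    @property
    def n_strides(self) -> int:
        return self.stride_durations.size

    @property
    def envelope_noise_ratio(self) -> float:
        """Mean envelope power over additive noise power."""
        return float(np.mean(self.envelopes ** 2) / self.noise_power)


def _bandlimited_noise(rng: np.random.Generator, n: int, rate: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS zero-mean noise confined to `band` (Hz)."""
    lo, hi = band
    hi = min(hi, 0.49 * rate)
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = sps.sosfilt(sos, x)
    rms = np.sqrt(np.mean(y ** 2))
    return y / (rms if rms > 0 else 1.0)


def synthesize_trial(profile: GaitProfile, muscles: MuscleTemplate,
                     n_strides: int = 60, rate_emg: float = 1000.0,
                     rate_angle: float = 100.0, seed: int = 0,
                     noise_scale: float = 1.0, preset: str = "custom",
                     side: str = "right") -> SyntheticTrial:
    """Generate one multichannel walking trial, fully determined by `seed`."""
    if n_strides < 1:
        raise ValueError("need at least one stride")
    if rate_emg <= 0 or rate_angle <= 0:
        raise ValueError("sampling rates must be positive")
    rng = np.random.default_rng(seed)
    channels = list(muscles.channels)
    n_ch = len(channels)

    # stride timing: duration from sampled step length and speed
    speeds = np.clip(rng.normal(profile.speed_mean, profile.speed_sd, n_strides),
                     0.05, None)
    steps = np.clip(rng.normal(profile.step_len_mean, profile.step_len_sd,
                               n_strides), 0.05, None)
    durations = np.clip(2.0 * steps / speeds, 0.3, 4.5)
    realized_speeds = 2.0 * steps / durations
    boundaries = np.concatenate(([0.0], np.cumsum(durations)))
    total = boundaries[-1]

    # per-stride, per-channel amplitude jitter
    jitter = np.clip(rng.normal(1.0, muscles.amp_jitter_sd, (n_strides, n_ch)),
                     0.1, None)

    coupling = calibrate_coupling(profile, muscles)

    def phase_of(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.clip(np.searchsorted(boundaries, times, side="right") - 1,
                      0, n_strides - 1)
        phi = (times - boundaries[idx]) / durations[idx]
        return np.clip(phi, 0.0, 1.0), idx

    # ---- EMG at rate_emg ---------------------------------------------------
    n_emg = int(np.floor(total * rate_emg)) + 1
    t_emg = np.arange(n_emg) / rate_emg
    phi_e, idx_e = phase_of(t_emg)
    envelopes = np.empty((n_emg, n_ch))
    raw = np.empty((n_emg, n_ch))
    floor = muscles.noise_floor * noise_scale
    for c, ch in enumerate(channels):
        env = _unit_envelope(muscles, ch, phi_e) * jitter[idx_e, c]
        carrier = _bandlimited_noise(rng, n_emg, rate_emg, muscles.carrier_band)
        noise = _bandlimited_noise(rng, n_emg, rate_emg, muscles.carrier_band)
        x = env * carrier + floor * noise
        # sparse motion-artifact spikes (exercises the Hampel stage)
        spikes = rng.random(n_emg) < 1e-4
        x[spikes] += rng.choice([-1.0, 1.0], spikes.sum()) * 8.0 * env.max()
        envelopes[:, c] = env
        raw[:, c] = x

    # ---- knee angle at rate_angle -----------------------------------------
    n_ang = int(np.floor(total * rate_angle)) + 1
    t_ang = np.arange(n_ang) / rate_angle
    phi_a, idx_a = phase_of(t_ang)
    lag_frac = muscles.lag_s / durations[idx_a]
    theta = np.full(n_ang, profile.baseline_deg)
    for c, ch in enumerate(channels):
        w = coupling[ch]
        if w > 0:
            theta += w * jitter[idx_a, c] * _unit_envelope(muscles, ch,
                                                           phi_a - lag_frac)
    # smooth measurement noise (~0.3 deg RMS)
    wn = rng.standard_normal(n_ang)
    sos = sps.butter(2, min(6.0, 0.45 * rate_angle), fs=rate_angle, output="sos")
    smooth = sps.sosfilt(sos, wn)
    smooth_rms = np.sqrt(np.mean(smooth ** 2))
    theta += 0.3 * smooth / (smooth_rms if smooth_rms > 0 else 1.0)

    events = EventList([(float(t), side, "foot_contact") for t in boundaries])
    emg = EmgRecording(channels=channels, rate_hz=rate_emg, samples=raw,
                       meta={"preset": preset, "seed": seed})
    angle = AngleSeries(rate_hz=rate_angle, values=theta)
    return SyntheticTrial(emg=emg, angle=angle, events=events,
                          envelopes=envelopes, coupling=coupling,
                          noise_power=float(floor ** 2) if floor > 0 else 1e-12,
                          amp_jitter=jitter, stride_durations=durations,
                          realized_speeds=realized_speeds, seed=seed,
                          preset=preset, profile=profile, muscles=muscles)


def cp_degrade(trial: SyntheticTrial, snr_scale: float = 0.25,
               variability_scale: float = 2.0, seed: int = 0) -> SyntheticTrial:
    """Degrade a trial: lower envelope-to-noise ratio, inflate amplitude
    variability.

    ``snr_scale`` divides the envelope-to-noise power ratio (0.25 -> four
    times more noise power); ``variability_scale`` inflates the per-stride
    amplitude jitter.  Ground-truth envelopes are kept consistent with the
    degraded raw EMG; the angle is untouched, so the degraded EMG is a
    genuinely weaker predictor of motion.  Identity when both factors are 1.
    """
    if snr_scale <= 0 or variability_scale <= 0:
        raise ValueError("scale factors must be positive")
    rng = np.random.default_rng(seed)
    muscles = trial.muscles
    raw = trial.emg.samples.copy()
    env = trial.envelopes.copy()
    n, n_ch = raw.shape

    # amplitude-variability inflation: extra per-stride multiplicative jitter
    extra_sd = muscles.amp_jitter_sd * max(variability_scale - 1.0, 0.0)
    if extra_sd > 0:
        extra = np.clip(rng.normal(1.0, extra_sd, (trial.n_strides, n_ch)),
                        0.1, None)
    else:
        extra = np.ones((trial.n_strides, n_ch))
    boundaries = np.concatenate(([0.0], np.cumsum(trial.stride_durations)))
    idx = np.clip(np.searchsorted(boundaries, trial.emg.times, side="right") - 1,
                  0, trial.n_strides - 1)
    raw *= extra[idx]
    env *= extra[idx]

    # noise-floor increase so envelope-to-noise power ratio scales by snr_scale
    new_power = trial.noise_power / snr_scale
    added = new_power - trial.noise_power
    if added > 0:
        for c in range(n_ch):
            raw[:, c] += np.sqrt(added) * _bandlimited_noise(
                rng, n, trial.emg.rate_hz, muscles.carrier_band)

    emg = EmgRecording(channels=list(trial.emg.channels),
                       rate_hz=trial.emg.rate_hz, samples=raw,
                       t0=trial.emg.t0, meta=dict(trial.emg.meta, degraded=True))
    return SyntheticTrial(emg=emg, angle=trial.angle, events=trial.events,
                          envelopes=env, coupling=dict(trial.coupling),
                          noise_power=float(new_power),
                          amp_jitter=trial.amp_jitter * extra,
                          stride_durations=trial.stride_durations,
                          realized_speeds=trial.realized_speeds,
                          seed=trial.seed, preset=trial.preset + "+degraded",
                          profile=trial.profile, muscles=muscles)


# -- presets ----------------------------------------------------------------

_HEALTHY_BURSTS = {
    "TA": [(0.05, 0.10, 0.2), (0.68, 0.13, 1.0)],
    "MG": [(0.40, 0.15, 1.0)],
    "SL": [(0.42, 0.17, 0.7)],
    "PL": [(0.45, 0.18, 0.5)],
    "HL": [(0.50, 0.18, 0.4)],
    "RF": [(0.12, 0.12, 0.9), (0.62, 0.12, 0.6)],
    "VL": [(0.12, 0.12, 1.0)],
    "MH": [(0.95, 0.12, 0.9), (0.05, 0.10, 0.4)],
}

# knee flexor/extensor drivers carrying the EMG-to-angle coupling
_DRIVER_CHANNELS = ("TA", "MG", "RF", "VL")


@dataclass(frozen=True)
class Preset:
    """A named generating condition (profile + muscle set + rates)."""

    name: str
    profile: GaitProfile
    muscles: MuscleTemplate
    rate_emg: float
    rate_angle: float = 100.0
    visit_profiles: dict | None = None   # CP: per-visit spatiotemporal rows

    def synthesize(self, n_strides: int = 60, seed: int = 0,
                   noise_scale: float = 1.0, visit: str | None = None
                   ) -> SyntheticTrial:
        profile = self.profile
        if visit is not None:
            if not self.visit_profiles or visit not in self.visit_profiles:
                raise ValueError(f"preset {self.name} has no visit {visit!r}")
            profile = self.visit_profiles[visit]
        return synthesize_trial(profile, self.muscles, n_strides=n_strides,
                                rate_emg=self.rate_emg,
                                rate_angle=self.rate_angle, seed=seed,
                                noise_scale=noise_scale, preset=self.name)


def make_presets() -> dict[str, Preset]:
    """The three study conditions: hv8, shared6 and cp6."""
    healthy_profile = GaitProfile(step_len_mean=0.52, step_len_sd=0.02,
                                  speed_mean=0.91, speed_sd=0.04,
                                  baseline_deg=5.0, stance_peak_deg=20.0,
                                  swing_peak_deg=60.0, stance_time=0.155,
                                  swing_time=0.715, stance_width=0.12,
                                  swing_width=0.13)
    hv8 = Preset(name="hv8", profile=healthy_profile,
                 muscles=MuscleTemplate(channels=tuple(HV8_CHANNELS),
                                        bursts=dict(_HEALTHY_BURSTS),
                                        coupling_channels=_DRIVER_CHANNELS),
                 rate_emg=1000.0)

    shared_bursts = {ch: _HEALTHY_BURSTS[ch] for ch in SHARED6_CHANNELS}
    shared6 = Preset(name="shared6", profile=healthy_profile,
                     muscles=MuscleTemplate(channels=tuple(SHARED6_CHANNELS),
                                            bursts=shared_bursts,
                                            coupling_channels=_DRIVER_CHANNELS),
                     rate_emg=1000.0)

    # crouch gait: elevated flexion baseline, damped swing wave, slow and
    # variable strides, noisier EMG; ST is mapped onto the MH slot
    def cp_profile(step, step_sd, speed, speed_sd):
        return GaitProfile(step_len_mean=step, step_len_sd=step_sd,
                           speed_mean=speed, speed_sd=speed_sd,
                           baseline_deg=30.0, stance_peak_deg=38.0,
                           swing_peak_deg=55.0, stance_time=0.135,
                           swing_time=0.70, stance_width=0.12,
                           swing_width=0.13)

    visits = {"V1": cp_profile(0.20, 0.04, 0.14, 0.03),
              "V2": cp_profile(0.19, 0.02, 0.37, 0.16),
              "V3": cp_profile(0.17, 0.04, 0.52, 0.06)}
    cp6 = Preset(name="cp6", profile=visits["V1"],
                 muscles=MuscleTemplate(channels=tuple(SHARED6_CHANNELS),
                                        bursts=shared_bursts,
                                        coupling_channels=_DRIVER_CHANNELS,
                                        noise_floor=0.25, amp_jitter_sd=0.20),
                 rate_emg=2000.0, visit_profiles=visits)
    return {"hv8": hv8, "shared6": shared6, "cp6": cp6}


def driver_muscles(channels=tuple(HV8_CHANNELS), driver: str = "RF",
                   jitter_sd: float = 0.15) -> MuscleTemplate:
    """Template whose knee-angle coupling uses only `driver`.

    The driver carries bursts aligned with both knee-flexion waves; the
    remaining channels keep their standard activity but are excluded from
    the coupling, so only the driver's envelope informs the angle.  Used
    for sensitivity-analysis ground truth.
    """
    if driver not in channels:
        raise ValueError(f"driver {driver!r} not in channels")
    bursts = {ch: list(_HEALTHY_BURSTS.get(ch, [(0.5, 0.1, 0.5)]))
              for ch in channels}
    bursts[driver] = [(0.12, 0.07, 0.6), (0.68, 0.09, 1.0)]
    return MuscleTemplate(channels=tuple(channels), bursts=bursts,
                          amp_jitter_sd=jitter_sd,
                          coupling_channels=(driver,))
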