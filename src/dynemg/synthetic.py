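"""Synthetic dynamic-contraction studies for end-to-end testing.

Generates complete studies — triangle-wave elbow kinematics, raw sEMG
and MVC trials — with a known, controllable ground truth.  The sEMG is
an amplitude-modulated band-limited Gaussian carrier: the modulation
m(θ, type) is the target envelope as a fraction of MVC,

    m = (b0 + b1·θ/120) · (1 − r·g(θ)·1[eccentric]),

with g(θ) ramping linearly from 0 at the attenuation onset to 1 over a
configurable angle span.  This emulates the empirical pattern the method
is designed to detect — activation rising with flexion angle, eccentric
activation attenuated only above ~30° — and is ground truth for
recovery tests, not a physiological motor-unit model.

Each movement trial is one flexion/extension repetition: a 0→120→0°
triangle at a nominal 25°/s with 200 ms cosine-blended turnarounds, so
one cycle lasts 9.6 s, the peak reaches exactly 120°, and kinematics
(200 Hz) and EMG (2000 Hz) are generated at their native rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core_io import ConfigError, TrialRecording


@dataclass
class GeneratorParams:
    """Study-design constants and ground-truth activation parameters."""

    n_subjects: int = 10
    n_cycles: int = 20
    angle_range: tuple[float, float] = (0.0, 120.0)
    angular_speed_deg_s: float = 25.0
    fs_emg: float = 2000.0
    fs_kin: float = 200.0
    mvc_amplitude_mv: float = 1.0
    baseline_activation: float = 0.03  # b0: fraction of MVC at full extension
    angle_gain: float = 0.25  # b1: added fraction of MVC at 120°
    eccentric_attenuation: float = 0.3  # r
    attenuation_onset_deg: float = 30.0
    attenuation_ramp_deg: float = 30.0
    subject_sd: float = 0.2  # relative SD of subject random effects on b0, b1, r
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    angle_noise_sd_deg: float = 0.5
    prosup_drift_deg: float = 0.5
    adjacent_drift_deg: float = 1.0
    turnaround_blend_s: float = 0.2
    mvc_duration_s: float = 5.0
    mvc_angle_deg: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_activation > 0:
            raise ConfigError("baseline_activation (b0) must be > 0")
        if self.baseline_activation + self.angle_gain >= 1.5:
            raise ConfigError("b0 + b1 must stay below 1.5")
        if not 0 <= self.eccentric_attenuation < 1:
            raise ConfigError("eccentric_attenuation (r) must lie in [0, 1)")
        for name in ("fs_emg", "fs_kin", "angular_speed_deg_s"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")

    @property
    def cycle_period_s(self) -> float:
        lo, hi = self.angle_range
        return 2.0 * (hi - lo) / self.angular_speed_deg_s


@dataclass
class SubjectEffects:
    b0: float
    b1: float
    r: float


@dataclass
class KinematicsTrial:
    """One repetition's kinematic channels plus noise-free EMG-rate truth."""

    t_kin: np.ndarray
    angle: np.ndarray  # noisy flexion/extension course at fs_kin
    prosup: np.ndarray
    shoulder: np.ndarray
    wrist: np.ndarray
    t_emg: np.ndarray
    angle_true_emg: np.ndarray  # noise-free angle at fs_emg
    velocity_true_emg: np.ndarray


@dataclass
class StudyData:
    trials: list[TrialRecording]
    ground_truth: dict[str, dict[str, float]]
    params: GeneratorParams


def _cycle_profile(params: GeneratorParams):
    """Closure evaluating the blended triangle angle and velocity at any time."""
    lo, hi = params.angle_range
    span = hi - lo
    period = params.cycle_period_s
    half = period / 2.0
    tb = params.turnaround_blend_s
    if not 0 < tb < half:
        raise ConfigError("turnaround_blend_s must be positive and shorter than a ramp")
    # linear-segment speed chosen so the blends join without a kink and the
    # apex touches the top of the range exactly
    s = span / (half - tb + 2.0 * tb / np.pi)
    k = s * tb / np.pi

    def angle_velocity(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tau = np.mod(t, period)
        m = np.minimum(tau, period - tau)  # mirror symmetry of the triangle
        sign = np.where(tau <= half, 1.0, -1.0)
        theta = np.empty_like(m)
        dtheta = np.empty_like(m)
        ease = m < tb / 2.0
        apex = m >= half - tb / 2.0
        lin = ~ease & ~apex
        theta[ease] = k * (1.0 - np.cos(np.pi * m[ease] / tb))
        dtheta[ease] = k * np.pi / tb * np.sin(np.pi * m[ease] / tb)
        theta[lin] = k + s * (m[lin] - tb / 2.0)
        dtheta[lin] = s
        theta[apex] = span - k * (1.0 - np.cos(np.pi * (m[apex] - half) / tb))
        dtheta[apex] = -k * np.pi / tb * np.sin(np.pi * (m[apex] - half) / tb)
        return lo + theta, sign * dtheta

    return angle_velocity


def generate_kinematics(params: GeneratorParams, rng: np.random.Generator) -> KinematicsTrial:
    """One repetition of noisy kinematics plus the noise-free EMG-rate course."""
    period = params.cycle_period_s
    n_kin = int(round(period * params.fs_kin))
    n_emg = int(round(period * params.fs_emg))
    t_kin = np.arange(n_kin) / params.fs_kin
    t_emg = np.arange(n_emg) / params.fs_emg
    angle_velocity = _cycle_profile(params)
    angle_true_kin, _ = angle_velocity(t_kin)
    angle_true_emg, velocity_true = angle_velocity(t_emg)
    angle = angle_true_kin + rng.normal(0.0, params.angle_noise_sd_deg, n_kin)

    def drifting(target_deg: float) -> np.ndarray:
        # deterministic half-sine excursion whose peak equals the target drift,
        # plus small sensor noise
        base = target_deg * np.sin(np.pi * t_kin / t_kin[-1])
        return base + rng.normal(0.0, 0.1, n_kin)

    return KinematicsTrial(
        t_kin=t_kin,
        angle=angle,
        prosup=drifting(params.prosup_drift_deg),
        shoulder=drifting(params.adjacent_drift_deg),
        wrist=drifting(params.adjacent_drift_deg),
        t_emg=t_emg,
        angle_true_emg=angle_true_emg,
        velocity_true_emg=velocity_true,
    )


def activation_surface(
    theta: np.ndarray | float,
    ctype: str | np.ndarray,
    effects: SubjectEffects,
    params: GeneratorParams,
) -> np.ndarray | float:
    """Target envelope fraction of MVC at angle ``theta``.

    ``ctype`` is "con"/"ecc" (or a boolean array marking eccentric
    samples).  g(θ) is 0 up to the attenuation onset, ramps linearly to 1
    over ``attenuation_ramp_deg`` and saturates at 1.
    """
    theta = np.asarray(theta, dtype=float)
    lo, hi = params.angle_range
    base = effects.b0 + effects.b1 * (theta - lo) / (hi - lo)
    if isinstance(ctype, str):
        is_ecc = np.asarray(ctype == "ecc")
    else:
        is_ecc = np.asarray(ctype, dtype=bool)
    ramp = params.attenuation_ramp_deg
    if ramp > 0:
        g = np.clip((theta - params.attenuation_onset_deg) / ramp, 0.0, 1.0)
    else:
        g = (theta > params.attenuation_onset_deg).astype(float)
    m = base * (1.0 - effects.r * g * is_ecc)
    return m if m.ndim else float(m)


def _carrier(n: int, params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Band-limited unit-variance Gaussian noise carrier."""
    lo, hi = params.carrier_band_hz
    nyq = params.fs_emg / 2.0
    sos = butter(4, [lo, min(hi, 0.99 * nyq)], btype="bandpass", fs=params.fs_emg, output="sos")
    c = sosfiltfilt(sos, rng.standard_normal(n))
    return c / np.std(c)


def generate_emg_trial(
    kin: KinematicsTrial,
    effects: SubjectEffects,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw sEMG (mV) for one repetition: modulated Gaussian carrier."""
    is_ecc = kin.velocity_true_emg < 0
    m = activation_surface(kin.angle_true_emg, is_ecc, effects, params)
    return m * params.mvc_amplitude_mv * _carrier(kin.t_emg.size, params, rng)


def _subject_effects(params: GeneratorParams, rng: np.random.Generator) -> SubjectEffects:
    b0 = params.baseline_activation * max(0.2, 1.0 + params.subject_sd * rng.normal())
    b1 = params.angle_gain * max(0.2, 1.0 + params.subject_sd * rng.normal())
    r = float(np.clip(params.eccentric_attenuation * (1.0 + params.subject_sd * rng.normal()), 0.0, 0.95))
    return SubjectEffects(b0=b0, b1=b1, r=r)


def generate_study(params: GeneratorParams) -> StudyData:
    """Full study: movement + 5 MVC trials per subject, deterministic in seed."""
    master = np.random.SeedSequence(params.seed)
    trials: list[TrialRecording] = []
    ground_truth: dict[str, dict[str, float]] = {}
    for s_idx, subject_ss in enumerate(master.spawn(params.n_subjects)):
        subject_id = f"S{s_idx + 1:02d}"
        eff_ss, mvc_ss, move_ss = subject_ss.spawn(3)
        effects = _subject_effects(params, np.random.default_rng(eff_ss))
        ground_truth[subject_id] = {"b0": effects.b0, "b1": effects.b1, "r": effects.r}

        for t_idx, trial_ss in enumerate(mvc_ss.spawn(5)):
            rng = np.random.default_rng(trial_ss)
            n_emg = int(round(params.mvc_duration_s * params.fs_emg))
            n_kin = int(round(params.mvc_duration_s * params.fs_kin))
            emg = params.mvc_amplitude_mv * _carrier(n_emg, params, rng)
            angle = np.full(n_kin, params.mvc_angle_deg) + rng.normal(0.0, 0.1, n_kin)
            const = lambda: rng.normal(0.0, 0.1, n_kin)  # noqa: E731
            trials.append(
                TrialRecording(
                    subject_id=subject_id,
                    trial_id=f"mvc{t_idx + 1}",
                    emg=emg,
                    fs_emg=params.fs_emg,
                    flexion_angle=angle,
                    fs_kin=params.fs_kin,
                    prosup_angle=const(),
                    shoulder_angle=const(),
                    wrist_angle=const(),
                    is_mvc=True,
                )
            )

        for t_idx, trial_ss in enumerate(move_ss.spawn(params.n_cycles)):
            rng = np.random.default_rng(trial_ss)
            kin = generate_kinematics(params, rng)
            emg = generate_emg_trial(kin, effects, params, rng)
            trials.append(
                TrialRecording(
                    subject_id=subject_id,
                    trial_id=f"rep{t_idx + 1:02d}",
                    emg=emg,
                    fs_emg=params.fs_emg,
                    flexion_angle=kin.angle,
                    fs_kin=params.fs_kin,
                    prosup_angle=kin.prosup,
                    shoulder_angle=kin.shoulder,
                    wrist_angle=kin.wrist,
                    is_mvc=False,
                )
            )
    return StudyData(trials=trials, ground_truth=ground_truth, params=params)
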