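"""Kinematic alignment, contraction-type classification, trial exclusion.

Kinematic channels recorded at a lower rate (motion capture at 200 Hz)
are linearly interpolated onto the EMG timebase.  Contraction type is
derived from the sign of the angular velocity of the flexion/extension
course: positive slope = joint flexes = concentric (for a flexor),
negative slope = eccentric.  A small velocity dead-band around zero
leaves samples near movement reversals unassigned rather than labelling
them arbitrarily.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import (
    LABEL_CONCENTRIC,
    LABEL_ECCENTRIC,
    LABEL_UNASSIGNED,
    InputError,
    StudyConfig,
    TrialRecording,
)
from .preprocess import moving_average_centered


def resample_to_emg(
    channel: np.ndarray, channel_times: np.ndarray, emg_times: np.ndarray
) -> np.ndarray:
    """Linearly interpolate a kinematic channel onto the EMG sample times.

    Endpoints are clamped to the nearest kinematic sample.  The channel
    must cover the EMG time span to within one kinematic sample period.
    """
    channel = np.asarray(channel, dtype=float)
    channel_times = np.asarray(channel_times, dtype=float)
    emg_times = np.asarray(emg_times, dtype=float)
    if channel.size == 0:
        raise InputError("cannot resample an empty kinematic channel")
    if channel.size != channel_times.size:
        raise InputError("channel and channel_times lengths differ")
    if channel.size > 1:
        period = (channel_times[-1] - channel_times[0]) / (channel.size - 1)
        if emg_times[0] < channel_times[0] - period or emg_times[-1] > channel_times[-1] + period:
            raise InputError(
                "kinematic channel does not cover the EMG time span "
                "to within one sample period"
            )
    return np.interp(emg_times, channel_times, channel)


def classify_contraction(angle: np.ndarray, fs: float, cfg: StudyConfig) -> np.ndarray:
    """Label each sample concentric (+1), eccentric (-1) or unassigned (0).

    Angular velocity is estimated by central differences on the angle
    course after 100 ms moving-average smoothing; the dead-band
    ``velocity_deadband_deg_s`` around zero maps to unassigned.
    """
    angle = np.asarray(angle, dtype=float)
    if angle.size < 3:
        raise InputError("need at least 3 angle samples to classify contraction type")
    window = int(round(cfg.ma_window_ms * fs / 1000.0))
    smoothed = moving_average_centered(angle, window)
    velocity = np.gradient(smoothed) * fs
    labels = np.zeros(angle.size, dtype=np.int8)
    labels[velocity > cfg.velocity_deadband_deg_s] = LABEL_CONCENTRIC
    labels[velocity < -cfg.velocity_deadband_deg_s] = LABEL_ECCENTRIC
    labels[np.abs(velocity) <= cfg.velocity_deadband_deg_s] = LABEL_UNASSIGNED
    return labels


@dataclass
class ExclusionReport:
    """Outcome of the posture-tolerance screening of one trial."""

    trial_id: str
    excluded: bool
    reason: str  # prosup_drift | shoulder_drift | wrist_drift | none
    max_deviation_deg: float


def apply_exclusion(trial: TrialRecording, cfg: StudyConfig) -> ExclusionReport:
    """Screen a trial against the posture tolerances.

    Deviation of a channel is the maximum absolute excursion from its
    value at the trial start.  A trial is excluded when the
    pronation/supination deviation strictly exceeds ±5° or an adjacent
    joint (shoulder, wrist) strictly exceeds ±10°; the first violated
    rule, in that order, is the reason.  Missing channels skip their rule
    with a warning.
    """

    def deviation(ch: np.ndarray) -> float | None:
        if ch.size == 0:
            return None
        return float(np.max(np.abs(ch - ch[0])))

    checks = (
        ("prosup_drift", deviation(trial.prosup_angle), cfg.prosup_tolerance_deg),
        ("shoulder_drift", deviation(trial.shoulder_angle), cfg.adjacent_tolerance_deg),
        ("wrist_drift", deviation(trial.wrist_angle), cfg.adjacent_tolerance_deg),
    )
    max_dev = 0.0
    for reason, dev, tol in checks:
        if dev is None:
            warnings.warn(
                f"trial {trial.trial_id!r}: channel for rule {reason!r} missing, rule skipped",
                stacklevel=2,
            )
            continue
        max_dev = max(max_dev, dev)
        if dev > tol:
            return ExclusionReport(trial.trial_id, True, reason, dev)
    return ExclusionReport(trial.trial_id, False, "none", max_dev)
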