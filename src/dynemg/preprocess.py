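"""Raw sEMG to normalized envelope.

The envelope is computed by band-pass filtering (4th-order Butterworth,
applied forward-backward so the envelope stays time-aligned with the
kinematic channels), full-wave rectification, and a centered 100 ms
moving average.  Normalization expresses the envelope in %MVC relative
to a reference derived from five maximum-voluntary-contraction trials:
the mean of the three trial values with the smallest standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core_io import InputError, StudyConfig, ValidationError


def moving_average_centered(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at edges.

    Output has the same length as the input, preserving time alignment.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    half = max(window // 2, 0)
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    cs = np.concatenate(([0.0], np.cumsum(x)))
    return (cs[idx + h + 1] - cs[idx - h]) / (2 * h + 1)


def _bandpass_sos(fs: float, cfg: StudyConfig):
    hi = cfg.bandpass_hi_hz
    nyq = fs / 2.0
    if hi >= nyq:
        hi = 0.99 * nyq
        warnings.warn(
            f"band-pass upper cutoff clipped to {hi:.1f} Hz (Nyquist {nyq:.1f} Hz)",
            stacklevel=3,
        )
    return butter(4, [cfg.bandpass_lo_hz, hi], btype="bandpass", fs=fs, output="sos")


def compute_envelope(emg: np.ndarray, fs: float, cfg: StudyConfig) -> np.ndarray:
    """Band-pass filter, rectify and smooth a raw sEMG sequence (mV in, mV out)."""
    emg = np.asarray(emg, dtype=float)
    window = int(round(cfg.ma_window_ms * fs / 1000.0))
    if emg.size < max(window, 2):
        raise InputError(
            f"sEMG sequence of {emg.size} samples is shorter than the "
            f"{window}-sample moving-average window"
        )
    filtered = sosfiltfilt(_bandpass_sos(fs, cfg), emg)
    return moving_average_centered(np.abs(filtered), window)


@dataclass
class MvcReference:
    """MVC normalization reference: mean of the 3 most consistent of 5 trials."""

    reference_value: float
    chosen_trial_ids: tuple[str, str, str]
    per_trial_values: dict[str, float]

    def __post_init__(self) -> None:
        if not self.reference_value > 0:
            raise ValidationError("MVC reference_value must be > 0")


def mvc_trial_value(envelope: np.ndarray) -> float:
    """Per-trial MVC amplitude: mean envelope over the central 50 % of the trial.

    The central window avoids contraction onset/offset transients.
    """
    envelope = np.asarray(envelope, dtype=float)
    n = envelope.size
    if n < 4:
        raise InputError("MVC envelope too short to extract a central window")
    return float(np.mean(envelope[n // 4 : n - n // 4]))


def mvc_reference(
    mvc_envelopes: list[np.ndarray], trial_ids: list[str] | None = None
) -> MvcReference:
    """Choose the MVC reference from exactly five MVC trial envelopes.

    All ten 3-subsets of the five per-trial values are enumerated; the
    subset whose values have the smallest standard deviation is chosen and
    the reference is the mean of those three values.  Ties go to the
    lexicographically first trial-id subset.
    """
    if len(mvc_envelopes) != 5:
        raise InputError(f"exactly 5 MVC trials are required, got {len(mvc_envelopes)}")
    if trial_ids is None:
        trial_ids = [f"mvc{i + 1}" for i in range(5)]
    if len(trial_ids) != 5:
        raise InputError("trial_ids must name the 5 MVC trials")
    order = sorted(range(5), key=lambda i: trial_ids[i])
    values = {trial_ids[i]: mvc_trial_value(mvc_envelopes[i]) for i in range(5)}
    for tid, v in values.items():
        if not v > 0:
            raise InputError(f"degenerate MVC trial {tid!r}: non-positive envelope value {v}")
    best_sd = np.inf
    best: tuple[int, int, int] | None = None
    for subset in combinations(order, 3):
        sd = float(np.std([values[trial_ids[i]] for i in subset], ddof=1))
        if sd < best_sd - 0.0:  # strict improvement keeps the first (lexicographic) tie
            best_sd = sd
            best = subset
    assert best is not None
    chosen = tuple(trial_ids[i] for i in best)
    ref = float(np.mean([values[t] for t in chosen]))
    return MvcReference(reference_value=ref, chosen_trial_ids=chosen, per_trial_values=values)


def normalize_envelope(envelope: np.ndarray, ref: MvcReference) -> np.ndarray:
    """Express an envelope in %MVC (values may exceed 100)."""
    if not ref.reference_value > 0:
        raise InputError("MVC reference must be positive")
    return 100.0 * np.asarray(envelope, dtype=float) / ref.reference_value
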