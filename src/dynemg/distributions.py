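"""Empirical frequency distributions of categorized envelope amplitudes.

For each combination of movement factors, the categorized %MVC
amplitudes form an empirical distribution.  A relative frequency
histogram (bins anchored at 0, default width 0.5 %MVC) locates the most
probable envelope value (the mode); interval probabilities are computed
directly on the raw samples so they are exact and independent of the
histogram binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import InputError, ValidationError


@dataclass
class FrequencyDistribution:
    """Binned relative and cumulative frequencies of one category."""

    bin_edges: np.ndarray
    rel_freq: np.ndarray
    cum_freq: np.ndarray
    n_samples: int
    mode_value: float  # center of the highest-frequency bin, %MVC

    def validate(self) -> None:
        if abs(self.rel_freq.sum() - 1.0) > 1e-9:
            raise ValidationError("rel_freq must sum to 1")
        if np.any(self.rel_freq < 0) or np.any(self.rel_freq > 1):
            raise ValidationError("each rel_freq must lie in [0, 1]")
        if np.any(np.diff(self.cum_freq) < -1e-12):
            raise ValidationError("cum_freq must be nondecreasing")
        if abs(self.cum_freq[-1] - 1.0) > 1e-9:
            raise ValidationError("cum_freq must end at 1")
        if not self.bin_edges[0] <= self.mode_value <= self.bin_edges[-1]:
            raise ValidationError("mode_value must lie within the binned range")


def relative_frequency(samples: np.ndarray, bin_width: float) -> FrequencyDistribution:
    """Histogram of amplitudes in uniform bins [k·w, (k+1)·w) anchored at 0.

    The mode is the center of the highest-count bin; ties break toward
    the lowest bin.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise InputError("cannot build a frequency distribution from zero samples")
    if not bin_width > 0:
        raise InputError(f"bin_width must be > 0, got {bin_width}")
    k0 = int(np.floor(samples.min() / bin_width))
    k1 = int(np.floor(samples.max() / bin_width))
    edges = bin_width * np.arange(k0, k1 + 2)
    counts, _ = np.histogram(samples, bins=edges)
    rel = counts / samples.size
    mode_idx = int(np.argmax(counts))  # argmax returns the first (lowest) maximum
    return FrequencyDistribution(
        bin_edges=edges,
        rel_freq=rel,
        cum_freq=np.cumsum(rel),
        n_samples=int(samples.size),
        mode_value=float(edges[mode_idx] + bin_width / 2.0),
    )


def prob_in_interval(samples: np.ndarray, interval: tuple[float, float]) -> float:
    """Probability of the envelope amplitude falling in a closed interval.

    Computed on the raw samples, not on histogram masses, so the result
    is exact: (# samples with a <= x <= b) / n.
    """
    samples = np.asarray(samples, dtype=float)
    a, b = interval
    if samples.size == 0:
        raise InputError("cannot compute an interval probability from zero samples")
    if a > b:
        raise InputError(f"interval must have a <= b, got [{a}, {b}]")
    return float(np.count_nonzero((samples >= a) & (samples <= b)) / samples.size)
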