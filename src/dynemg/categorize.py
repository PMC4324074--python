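"""Decision-tree categorization of normalized envelope samples.

Every retained sample is assigned to a combination of variable movement
factors.  Three analyzing scenarios are supported:

* A - contraction type only: keys (concentric, any), (eccentric, any);
* B - angle interval only: 12 fine 10° bins over 0-120°, contraction
  label ignored;
* C - the full combination: 2 contraction types × 12 angle bins.

Angle bins are half-open [lo, hi) with a closed top bin so that the bins
partition [0, 120] exactly.  Samples with an unassigned contraction
label (scenarios A, C) or an out-of-range angle (B, C) are counted as
excluded, never silently dropped.
"""

from __future__ import annotations

import numpy as np

from .core_io import (
    ANY,
    CONCENTRIC,
    ECCENTRIC,
    LABEL_CONCENTRIC,
    LABEL_ECCENTRIC,
    CategoryKey,
    CategoryTable,
    ConfigError,
    InputError,
    NormalizedEnvelope,
    StudyConfig,
)

SCENARIOS = ("A", "B", "C")


def angle_bin_edges(cfg: StudyConfig, width: float | None = None) -> np.ndarray:
    lo, hi = cfg.angle_range_deg
    w = cfg.angle_bin_width_deg if width is None else width
    n = int(round((hi - lo) / w))
    if abs(lo + n * w - hi) > 1e-9:
        raise ConfigError(f"bin width {w} does not tile the angle range {cfg.angle_range_deg}")
    return lo + w * np.arange(n + 1)


def assign_angle_bin(angle: float, edges: np.ndarray) -> tuple[float, float] | None:
    """Locate an angle in half-open bins [lo, hi); the top bin is closed."""
    edges = np.asarray(edges, dtype=float)
    if angle < edges[0] or angle > edges[-1]:
        return None
    idx = int(np.searchsorted(edges, angle, side="right")) - 1
    if idx == edges.size - 1:  # angle exactly at the top edge
        idx -= 1
    return (float(edges[idx]), float(edges[idx + 1]))


def _bin_index(angles: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bin lookup; returns (indices, in_range mask)."""
    in_range = (angles >= edges[0]) & (angles <= edges[-1])
    idx = np.searchsorted(edges, angles, side="right") - 1
    idx = np.clip(idx, 0, edges.size - 2)
    return idx, in_range


def categorize_scenario(
    env: NormalizedEnvelope, scenario: str, cfg: StudyConfig, subject_id: str = ""
) -> CategoryTable:
    """Run the decision tree of one analyzing scenario over one envelope."""
    if scenario not in SCENARIOS:
        raise InputError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    env.validate()
    values = env.values
    if values.size == 0:
        raise InputError("cannot categorize an empty envelope")
    labels = env.labels
    angles = env.angle_at_sample
    edges = angle_bin_edges(cfg)
    bins = [(float(edges[i]), float(edges[i + 1])) for i in range(edges.size - 1)]

    entries: dict[CategoryKey, np.ndarray] = {}
    if scenario == "A":
        con = labels == LABEL_CONCENTRIC
        ecc = labels == LABEL_ECCENTRIC
        entries[CategoryKey(CONCENTRIC, ANY)] = values[con]
        entries[CategoryKey(ECCENTRIC, ANY)] = values[ecc]
        excluded = values.size - int(con.sum()) - int(ecc.sum())
    elif scenario == "B":
        idx, in_range = _bin_index(angles, edges)
        for b, bin_ in enumerate(bins):
            entries[CategoryKey(ANY, bin_)] = values[in_range & (idx == b)]
        excluded = values.size - int(in_range.sum())
    else:  # C
        idx, in_range = _bin_index(angles, edges)
        retained_any = np.zeros(values.size, dtype=bool)
        for ctype, code in ((CONCENTRIC, LABEL_CONCENTRIC), (ECCENTRIC, LABEL_ECCENTRIC)):
            type_mask = labels == code
            for b, bin_ in enumerate(bins):
                mask = type_mask & in_range & (idx == b)
                entries[CategoryKey(ctype, bin_)] = values[mask]
                retained_any |= mask
        excluded = values.size - int(retained_any.sum())
    return CategoryTable(
        subject_id=subject_id,
        scenario=scenario,
        entries=entries,
        n_excluded_samples=excluded,
    )


def merge_angle_bins(table: CategoryTable, merged_width: float) -> CategoryTable:
    """Pool fine angle bins into wider ones (e.g. 12×10° into 4×30°)."""
    fine_bins = sorted(
        {k.angle_bin for k in table.entries if k.angle_bin != ANY}, key=lambda b: b[0]
    )
    if not fine_bins:
        return table
    fine_width = fine_bins[0][1] - fine_bins[0][0]
    ratio = merged_width / fine_width
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigError(
            f"merged width {merged_width}° is not an integer multiple of the "
            f"fine width {fine_width}°"
        )
    lo0 = fine_bins[0][0]

    def merged_bin(bin_: tuple[float, float]) -> tuple[float, float]:
        k = int(np.floor((bin_[0] - lo0) / merged_width + 1e-9))
        return (lo0 + k * merged_width, lo0 + (k + 1) * merged_width)

    pooled: dict[CategoryKey, list[np.ndarray]] = {}
    for key, samples in table.entries.items():
        new_key = (
            key
            if key.angle_bin == ANY
            else CategoryKey(key.contraction, merged_bin(key.angle_bin))
        )
        pooled.setdefault(new_key, []).append(samples)
    entries = {k: np.concatenate(v) if v else np.empty(0) for k, v in pooled.items()}
    return CategoryTable(
        subject_id=table.subject_id,
        scenario=table.scenario,
        entries=entries,
        n_excluded_samples=table.n_excluded_samples,
        n_excluded_trials=table.n_excluded_trials,
        exclusion_reasons=list(table.exclusion_reasons),
    )
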