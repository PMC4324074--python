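"""Shared domain types and plain-text readers/writers.

Trial files are one repetition per file, comma-separated with a header row.
EMG and kinematic channels may be sampled at different rates; each rate
group carries its own time column (``time_s`` for EMG, ``time_kin_s`` for
kinematics) and shorter groups are padded with empty cells at the tail.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

# contraction-type vocabulary shared across modules
CONCENTRIC = "concentric"
ECCENTRIC = "eccentric"
UNASSIGNED = "unassigned"
ANY = "any"

# integer per-sample label codes used in NormalizedEnvelope.labels
LABEL_CONCENTRIC = 1
LABEL_ECCENTRIC = -1
LABEL_UNASSIGNED = 0

LABEL_NAMES = {
    LABEL_CONCENTRIC: CONCENTRIC,
    LABEL_ECCENTRIC: ECCENTRIC,
    LABEL_UNASSIGNED: UNASSIGNED,
}


class FormatError(ValueError):
    """A trial file violates the CSV contract."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class ConfigError(ValueError):
    """An analysis configuration value is inconsistent."""


class InputError(ValueError):
    """An operation received data it cannot process."""


@dataclass
class StudyConfig:
    """Analysis constants of the study design.

    All defaults mirror the experimental protocol: 10-500 Hz band-pass,
    100 ms envelope smoothing, ±2.5 %MVC analyzing interval, ±5°
    pronation/supination tolerance, ±10° adjacent-joint tolerance, 12
    fine angle bins of 10° over 0-120° merged to four 30° bins for the
    statistical and probabilistic comparisons.
    """

    bandpass_lo_hz: float = 10.0
    bandpass_hi_hz: float = 500.0
    ma_window_ms: float = 100.0
    hist_bin_width_pct_mvc: float = 0.5
    interval_halfwidth_pct_mvc: float = 2.5
    velocity_deadband_deg_s: float = 2.5
    prosup_tolerance_deg: float = 5.0
    adjacent_tolerance_deg: float = 10.0
    angle_bin_width_deg: float = 10.0
    merged_bin_width_deg: float = 30.0
    angle_range_deg: tuple[float, float] = (0.0, 120.0)
    alpha: float = 0.05
    min_category_samples: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bandpass_lo_hz",
            "bandpass_hi_hz",
            "ma_window_ms",
            "hist_bin_width_pct_mvc",
            "interval_halfwidth_pct_mvc",
            "velocity_deadband_deg_s",
            "prosup_tolerance_deg",
            "adjacent_tolerance_deg",
            "angle_bin_width_deg",
            "merged_bin_width_deg",
        ):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        lo, hi = self.angle_range_deg
        if not lo < hi:
            raise ConfigError(f"angle_range_deg must have lo < hi, got {self.angle_range_deg}")
        if self.bandpass_lo_hz >= self.bandpass_hi_hz:
            raise ConfigError("bandpass_lo_hz must be below bandpass_hi_hz")
        ratio = self.merged_bin_width_deg / self.angle_bin_width_deg
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                "merged_bin_width_deg must be an integer multiple of angle_bin_width_deg"
            )
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class TrialRecording:
    """Synchronized raw sEMG and joint-angle channels for one repetition.

    ``emg`` is the raw bipolar signal in mV at ``fs_emg``; angle channels
    are in degrees at ``fs_kin`` (full extension = 0°, flexion positive).
    Optional channels may be empty arrays.
    """

    subject_id: str
    trial_id: str
    emg: np.ndarray
    fs_emg: float
    flexion_angle: np.ndarray
    fs_kin: float
    prosup_angle: np.ndarray = field(default_factory=lambda: np.empty(0))
    shoulder_angle: np.ndarray = field(default_factory=lambda: np.empty(0))
    wrist_angle: np.ndarray = field(default_factory=lambda: np.empty(0))
    is_mvc: bool = False

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.flexion_angle = np.asarray(self.flexion_angle, dtype=float)
        self.prosup_angle = np.asarray(self.prosup_angle, dtype=float)
        self.shoulder_angle = np.asarray(self.shoulder_angle, dtype=float)
        self.wrist_angle = np.asarray(self.wrist_angle, dtype=float)

    def validate(self, cfg: StudyConfig | None = None) -> None:
        if not self.fs_emg > 0:
            raise ValidationError("fs_emg must be > 0")
        if not self.fs_kin > 0:
            raise ValidationError("fs_kin must be > 0")
        if self.emg.size < 1:
            raise ValidationError("emg must contain at least one sample")
        if self.flexion_angle.size < 1:
            raise ValidationError("flexion_angle must contain at least one sample")
        if cfg is not None and self.fs_emg < 2 * cfg.bandpass_hi_hz:
            raise ValidationError(
                f"fs_emg={self.fs_emg} is below twice the band-pass upper "
                f"cutoff {cfg.bandpass_hi_hz} Hz"
            )
        span_emg = (self.emg.size - 1) / self.fs_emg
        span_kin = (self.flexion_angle.size - 1) / self.fs_kin
        tol = max(1.0 / self.fs_emg, 1.0 / self.fs_kin)
        if abs(span_emg - span_kin) > tol + 1e-12:
            raise ValidationError(
                f"emg and flexion_angle spans differ by more than one sample "
                f"period ({span_emg:.4f} s vs {span_kin:.4f} s)"
            )
        for name in ("prosup_angle", "shoulder_angle", "wrist_angle"):
            ch = getattr(self, name)
            if ch.size and abs((ch.size - 1) / self.fs_kin - span_kin) > tol + 1e-12:
                raise ValidationError(f"{name} does not cover the trial time span")

    def emg_times(self) -> np.ndarray:
        return np.arange(self.emg.size) / self.fs_emg

    def kin_times(self) -> np.ndarray:
        return np.arange(self.flexion_angle.size) / self.fs_kin


@dataclass
class NormalizedEnvelope:
    """Per-sample sEMG envelope in %MVC with aligned angle and labels."""

    values: np.ndarray
    times: np.ndarray
    angle_at_sample: np.ndarray
    labels: np.ndarray  # int8 codes, see LABEL_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.angle_at_sample = np.asarray(self.angle_at_sample, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def validate(self) -> None:
        n = self.values.size
        for name in ("times", "angle_at_sample", "labels"):
            if getattr(self, name).size != n:
                raise ValidationError(f"{name} length differs from values length")
        if n and self.values.min() < 0:
            raise ValidationError("values must be non-negative (rectified envelope)")


@dataclass(frozen=True)
class CategoryKey:
    """One combination of variable movement factors.

    ``contraction`` is "concentric", "eccentric" or "any"; ``angle_bin``
    is a half-open (lo, hi) interval in degrees, or "any".
    """

    contraction: str
    angle_bin: tuple[float, float] | str

    def __post_init__(self) -> None:
        if self.contraction not in (CONCENTRIC, ECCENTRIC, ANY):
            raise ValidationError(f"invalid contraction type {self.contraction!r}")
        if self.angle_bin != ANY:
            lo, hi = self.angle_bin
            if not lo < hi:
                raise ValidationError(f"angle_bin must have lo < hi, got {self.angle_bin}")

    def __str__(self) -> str:
        if self.angle_bin == ANY:
            return f"{self.contraction}|any"
        lo, hi = self.angle_bin
        return f"{self.contraction}|{lo:g}-{hi:g}"


@dataclass
class CategoryTable:
    """Categorized %MVC amplitudes of one subject under one scenario."""

    subject_id: str
    scenario: str
    entries: dict[CategoryKey, np.ndarray]
    n_excluded_samples: int = 0
    n_excluded_trials: int = 0
    exclusion_reasons: list[str] = field(default_factory=list)

    def total_samples(self) -> int:
        return sum(v.size for v in self.entries.values()) + self.n_excluded_samples

    @staticmethod
    def merge(tables: list["CategoryTable"]) -> "CategoryTable":
        """Pool categorized samples of several trials of one subject."""
        if not tables:
            raise InputError("cannot merge an empty list of category tables")
        first = tables[0]
        keys: list[CategoryKey] = []
        for t in tables:
            if t.subject_id != first.subject_id or t.scenario != first.scenario:
                raise InputError("can only merge tables of one subject and scenario")
            for k in t.entries:
                if k not in keys:
                    keys.append(k)
        entries = {
            k: np.concatenate([t.entries.get(k, np.empty(0)) for t in tables]) for k in keys
        }
        return CategoryTable(
            subject_id=first.subject_id,
            scenario=first.scenario,
            entries=entries,
            n_excluded_samples=sum(t.n_excluded_samples for t in tables),
            n_excluded_trials=sum(t.n_excluded_trials for t in tables),
            exclusion_reasons=sum((t.exclusion_reasons for t in tables), []),
        )


# ---------------------------------------------------------------------------
# trial file I/O

_REQUIRED = ("time_s", "emg_mV", "angle_deg")
_OPTIONAL_KIN = ("prosup_deg", "shoulder_deg", "wrist_deg")


def _parse_column(series: pd.Series, col: str, allow_padding: bool) -> np.ndarray:
    s = series.astype(str).str.strip()
    nonempty = (s != "").to_numpy()
    n = int(nonempty.sum())
    if n == 0:
        return np.empty(0)
    if not nonempty[:n].all():
        first_gap = int(np.argmin(nonempty)) + 1
        raise FormatError(f"column {col!r} has an empty cell at data row {first_gap}")
    if not allow_padding and n != s.size:
        raise FormatError(f"column {col!r} is shorter than the file ({n} of {s.size} rows)")
    vals = pd.to_numeric(s.iloc[:n], errors="coerce").to_numpy(dtype=float)
    # literal "nan"/"NA" coerce to NaN and are rejected like any other bad cell
    bad = np.flatnonzero(np.isnan(vals))
    if bad.size:
        i = int(bad[0])
        raise FormatError(
            f"non-numeric value {s.iloc[i]!r} in column {col!r} at data row {i + 1}"
        )
    return vals


def _rate_from_times(times: np.ndarray, col: str) -> float:
    if times.size < 2:
        raise FormatError(f"time column {col!r} needs at least two samples")
    span = times[-1] - times[0]
    if span <= 0:
        raise FormatError(f"time column {col!r} is not increasing")
    return (times.size - 1) / span


def read_trial(
    path: str | Path,
    column_spec: dict[str, str] | None = None,
    subject_id: str | None = None,
    trial_id: str | None = None,
    is_mvc: bool | None = None,
) -> TrialRecording:
    """Read a one-repetition CSV into a validated TrialRecording.

    Subject and trial identifiers default to the ``<subject>__<trial>.csv``
    filename convention; a trial id starting with ``mvc`` marks an MVC trial.
    """
    path = Path(path)
    spec = {name: name for name in _REQUIRED + _OPTIONAL_KIN + ("time_kin_s",)}
    if column_spec:
        spec.update(column_spec)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    for name in _REQUIRED:
        if spec[name] not in df.columns:
            raise FormatError(f"required column {spec[name]!r} missing from {path.name}")

    time_s = _parse_column(df[spec["time_s"]], spec["time_s"], allow_padding=True)
    emg = _parse_column(df[spec["emg_mV"]], spec["emg_mV"], allow_padding=True)
    if emg.size != time_s.size:
        raise FormatError("emg_mV and time_s must have the same length")
    fs_emg = _rate_from_times(time_s, spec["time_s"])

    two_rate = spec["time_kin_s"] in df.columns
    if two_rate:
        time_kin = _parse_column(df[spec["time_kin_s"]], spec["time_kin_s"], allow_padding=True)
        fs_kin = _rate_from_times(time_kin, spec["time_kin_s"])
    else:
        time_kin, fs_kin = time_s, fs_emg
    n_kin = time_kin.size

    def kin_column(name: str, required: bool) -> np.ndarray:
        col = spec[name]
        if col not in df.columns:
            if required:
                raise FormatError(f"required column {col!r} missing from {path.name}")
            warnings.warn(f"optional channel {col!r} missing from {path.name}", stacklevel=2)
            return np.empty(0)
        vals = _parse_column(df[col], col, allow_padding=True)
        if vals.size not in (0, n_kin):
            raise FormatError(f"column {col!r} length does not match its time column")
        return vals

    angle = kin_column("angle_deg", required=True)
    if angle.size != n_kin:
        raise FormatError("angle_deg length does not match its time column")

    stem = path.stem
    if subject_id is None or trial_id is None:
        parts = stem.split("__")
        subject_id = subject_id or (parts[0] if len(parts) > 1 else stem)
        trial_id = trial_id or (parts[1] if len(parts) > 1 else stem)
    if is_mvc is None:
        is_mvc = trial_id.lower().startswith("mvc")

    trial = TrialRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        emg=emg,
        fs_emg=fs_emg,
        flexion_angle=angle,
        fs_kin=fs_kin,
        prosup_angle=kin_column("prosup_deg", required=False),
        shoulder_angle=kin_column("shoulder_deg", required=False),
        wrist_angle=kin_column("wrist_deg", required=False),
        is_mvc=is_mvc,
    )
    trial.validate()
    return trial


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write a TrialRecording to the per-repetition CSV contract."""
    path = Path(path)
    n_emg = trial.emg.size
    n_kin = trial.flexion_angle.size
    n = max(n_emg, n_kin)

    def pad(x: np.ndarray) -> list[str]:
        out = [f"{v:.12g}" for v in x]
        out.extend([""] * (n - len(out)))
        return out

    cols: dict[str, list[str]] = {
        "time_s": pad(trial.emg_times()),
        "emg_mV": pad(trial.emg),
        "time_kin_s": pad(trial.kin_times()),
        "angle_deg": pad(trial.flexion_angle),
    }
    for name, ch in (
        ("prosup_deg", trial.prosup_angle),
        ("shoulder_deg", trial.shoulder_angle),
        ("wrist_deg", trial.wrist_angle),
    ):
        if ch.size:
            cols[name] = pad(ch)
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results I/O


def to_jsonable(obj):
    """Recursively convert results (dataclasses, numpy, tuples) to JSON types."""
    if isinstance(obj, CategoryKey):
        return str(obj)
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def write_results(results, path: str | Path) -> None:
    """Serialize a result record to deterministic, sorted-key JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(to_jsonable(results), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
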