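"""End-to-end orchestration: preprocess → exclude → classify → categorize
→ distributions → probabilistic + deterministic → report.

Both analysis arms consume the identical categorization pass: the
deterministic scenario tests and the probabilistic overlap statistic see
the same per-subject category tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .categorize import angle_bin_edges, categorize_scenario, merge_angle_bins
from .core_io import (
    ANY,
    CONCENTRIC,
    ECCENTRIC,
    CategoryKey,
    CategoryTable,
    NormalizedEnvelope,
    StudyConfig,
    TrialRecording,
    read_trial,
)
from .deterministic import (
    SubjectCategoryMeans,
    TestReport,
    scenario_a_test,
    scenario_b_test,
    scenario_c_test,
    subject_means,
)
from .kinematics import apply_exclusion, classify_contraction, resample_to_emg
from .preprocess import compute_envelope, mvc_reference, normalize_envelope
from .probabilistic import AggregateOverlap, OverlapResult, aggregate_across_subjects, overlap_probability

logger = logging.getLogger("dynemg")


@dataclass
class SubjectSummary:
    subject_id: str
    n_trials_retained: int
    n_trials_excluded: int
    mvc_reference_mv: float
    mvc_chosen_trials: tuple[str, ...]
    n_samples_categorized: dict[str, int]
    n_samples_excluded: dict[str, int]
    means: dict[str, SubjectCategoryMeans]
    overlaps: list[OverlapResult]


@dataclass
class StudyResult:
    """Structured outcome of one full study analysis."""

    config: StudyConfig
    constant_factors: dict[str, object]
    subjects_analyzed: list[str]
    subjects_skipped: dict[str, str]
    exclusions: list[dict[str, object]]
    per_subject: dict[str, SubjectSummary]
    aggregate: list[AggregateOverlap]
    tests: dict[str, TestReport | None]
    notes: list[str] = field(default_factory=list)


DEFAULT_CONSTANT_FACTORS = {
    "external_load_kg": 3.5,
    "nominal_speed_deg_s": 25.0,
    "forearm_posture": "neutral",
    "muscle": "brachioradialis",
}


def process_trial(
    trial: TrialRecording, ref, cfg: StudyConfig
) -> NormalizedEnvelope:
    """Raw trial → normalized envelope with aligned angle and labels."""
    env = normalize_envelope(compute_envelope(trial.emg, trial.fs_emg, cfg), ref)
    t_emg = trial.emg_times()
    angle = resample_to_emg(trial.flexion_angle, trial.kin_times(), t_emg)
    labels = classify_contraction(angle, trial.fs_emg, cfg)
    out = NormalizedEnvelope(values=env, times=t_emg, angle_at_sample=angle, labels=labels)
    out.validate()
    return out


def _merged_bins(cfg: StudyConfig) -> list[tuple[float, float]]:
    edges = angle_bin_edges(cfg, width=cfg.merged_bin_width_deg)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(edges.size - 1)]


def analyze_study(trials: list[TrialRecording], cfg: StudyConfig) -> StudyResult:
    """Analyze an in-memory collection of trials into a StudyResult."""
    by_subject: dict[str, list[TrialRecording]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)

    subjects_analyzed: list[str] = []
    subjects_skipped: dict[str, str] = {}
    exclusions: list[dict[str, object]] = []
    per_subject: dict[str, SubjectSummary] = {}
    all_overlaps: list[OverlapResult] = []
    notes: list[str] = []
    bins = _merged_bins(cfg)

    for subject_id in sorted(by_subject):
        subj_trials = by_subject[subject_id]
        mvc_trials = sorted((t for t in subj_trials if t.is_mvc), key=lambda t: t.trial_id)
        move_trials = sorted((t for t in subj_trials if not t.is_mvc), key=lambda t: t.trial_id)
        if len(mvc_trials) != 5:
            reason = f"{len(mvc_trials)} MVC trials (exactly 5 required)"
            logger.error("subject %s skipped: %s", subject_id, reason)
            subjects_skipped[subject_id] = reason
            continue
        ref = mvc_reference(
            [compute_envelope(t.emg, t.fs_emg, cfg) for t in mvc_trials],
            [t.trial_id for t in mvc_trials],
        )

        retained: list[TrialRecording] = []
        n_trial_excl = 0
        for t in move_trials:
            report = apply_exclusion(t, cfg)
            if report.excluded:
                n_trial_excl += 1
                logger.info(
                    "subject %s trial %s excluded: %s (%.2f deg)",
                    subject_id, t.trial_id, report.reason, report.max_deviation_deg,
                )
                exclusions.append(
                    {
                        "subject_id": subject_id,
                        "trial_id": t.trial_id,
                        "reason": report.reason,
                        "max_deviation_deg": report.max_deviation_deg,
                    }
                )
            else:
                retained.append(t)
        if not retained:
            subjects_skipped[subject_id] = "all movement trials excluded"
            logger.error("subject %s skipped: all movement trials excluded", subject_id)
            continue

        envelopes = [process_trial(t, ref, cfg) for t in retained]
        tables: dict[str, CategoryTable] = {}
        for scenario in ("A", "B", "C"):
            per_trial = [
                categorize_scenario(env, scenario, cfg, subject_id=subject_id)
                for env in envelopes
            ]
            table = CategoryTable.merge(per_trial)
            table.n_excluded_trials = n_trial_excl
            tables[scenario] = table
        merged_b = merge_angle_bins(tables["B"], cfg.merged_bin_width_deg)
        merged_c = merge_angle_bins(tables["C"], cfg.merged_bin_width_deg)

        overlaps: list[OverlapResult] = []
        for bin_ in bins:
            con = merged_c.entries.get(CategoryKey(CONCENTRIC, bin_), np.empty(0))
            ecc = merged_c.entries.get(CategoryKey(ECCENTRIC, bin_), np.empty(0))
            if con.size == 0 or ecc.size == 0:
                notes.append(
                    f"subject {subject_id}: no samples of one contraction type in "
                    f"bin {bin_[0]:g}-{bin_[1]:g} deg; overlap skipped"
                )
                continue
            overlaps.append(
                overlap_probability(con, ecc, cfg, subject_id=subject_id, angle_bin=bin_)
            )
        all_overlaps.extend(overlaps)

        per_subject[subject_id] = SubjectSummary(
            subject_id=subject_id,
            n_trials_retained=len(retained),
            n_trials_excluded=n_trial_excl,
            mvc_reference_mv=ref.reference_value,
            mvc_chosen_trials=ref.chosen_trial_ids,
            n_samples_categorized={
                s: tables[s].total_samples() - tables[s].n_excluded_samples
                for s in ("A", "B", "C")
            },
            n_samples_excluded={s: tables[s].n_excluded_samples for s in ("A", "B", "C")},
            means={
                "A": subject_means(tables["A"]),
                "B_merged": subject_means(merged_b),
                "C_merged": subject_means(merged_c),
            },
            overlaps=overlaps,
        )
        subjects_analyzed.append(subject_id)

    if not subjects_analyzed:
        raise RuntimeError("no subjects analyzable")

    tests: dict[str, TestReport | None] = {"A": None, "B": None, "C": None}
    # scenario A: paired concentric vs eccentric subject means
    con_means, ecc_means, complete = [], [], []
    for sid in subjects_analyzed:
        stats_a = per_subject[sid].means["A"].stats
        key_c, key_e = CategoryKey(CONCENTRIC, ANY), CategoryKey(ECCENTRIC, ANY)
        if key_c in stats_a and key_e in stats_a:
            con_means.append(stats_a[key_c].mean)
            ecc_means.append(stats_a[key_e].mean)
            complete.append(sid)
    if len(complete) >= 3:
        tests["A"] = scenario_a_test(np.array(con_means), np.array(ecc_means), cfg)
    else:
        notes.append("scenario A test skipped: fewer than 3 subjects with both types")

    # scenario B: subjects × merged-bin means
    bin_labels = [f"{lo:g}-{hi:g}" for lo, hi in bins]
    rows_b = []
    for sid in subjects_analyzed:
        stats_b = per_subject[sid].means["B_merged"].stats
        row = [
            stats_b[CategoryKey(ANY, b)].mean if CategoryKey(ANY, b) in stats_b else np.nan
            for b in bins
        ]
        rows_b.append(row)
    mat_b = np.array(rows_b)
    keep = ~np.isnan(mat_b).any(axis=1)
    if keep.sum() >= 3:
        tests["B"] = scenario_b_test(mat_b[keep], bin_labels, cfg)
    else:
        notes.append("scenario B test skipped: fewer than 3 complete subjects")

    # scenario C: contraction type × merged-bin means
    con_rows, ecc_rows = [], []
    for sid in subjects_analyzed:
        stats_c = per_subject[sid].means["C_merged"].stats
        con_rows.append(
            [
                stats_c[CategoryKey(CONCENTRIC, b)].mean
                if CategoryKey(CONCENTRIC, b) in stats_c
                else np.nan
                for b in bins
            ]
        )
        ecc_rows.append(
            [
                stats_c[CategoryKey(ECCENTRIC, b)].mean
                if CategoryKey(ECCENTRIC, b) in stats_c
                else np.nan
                for b in bins
            ]
        )
    mat_con, mat_ecc = np.array(con_rows), np.array(ecc_rows)
    keep = ~(np.isnan(mat_con).any(axis=1) | np.isnan(mat_ecc).any(axis=1))
    if keep.sum() >= 3:
        tests["C"] = scenario_c_test(mat_con[keep], mat_ecc[keep], bins, cfg)
    else:
        notes.append("scenario C test skipped: fewer than 3 complete subjects")

    return StudyResult(
        config=cfg,
        constant_factors=dict(DEFAULT_CONSTANT_FACTORS),
        subjects_analyzed=subjects_analyzed,
        subjects_skipped=subjects_skipped,
        exclusions=exclusions,
        per_subject=per_subject,
        aggregate=aggregate_across_subjects(all_overlaps) if all_overlaps else [],
        tests=tests,
        notes=notes,
    )


def run_study(input_dir: str | Path, cfg: StudyConfig) -> StudyResult:
    """Read every trial CSV under ``input_dir`` and analyze the study."""
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob("*.csv"))
    if not paths:
        raise RuntimeError(f"no trial CSV files found in {input_dir}")
    trials = [read_trial(p) for p in paths]
    return analyze_study(trials, cfg)
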