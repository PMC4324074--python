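"""Deterministic comparison arm: category means and within-subject tests.

The units of analysis are subject-level category means (n = subjects).
Scenario A compares concentric vs eccentric means with a paired t-test;
scenario B runs a one-way repeated-measures ANOVA over the four merged
angle intervals with Mauchly's sphericity test, a conditional
Greenhouse-Geisser correction and Bonferroni-adjusted post-hoc
comparisons of adjacent intervals; scenario C tests the contraction type
× angle interval interaction and the simple main effects of contraction
type at each interval.

The two-way within-subject interaction for a 2×k design is computed via
the standard reduction to a one-way repeated-measures ANOVA on the
per-subject concentric−eccentric difference scores, which also yields
the sphericity diagnostics of the interaction term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .core_io import CategoryKey, CategoryTable, InputError, StudyConfig


@dataclass
class CategoryStat:
    mean: float
    sd: float
    n: int
    degenerate: bool = False  # single-sample category: SD reported as 0


@dataclass
class SubjectCategoryMeans:
    subject_id: str
    scenario: str
    stats: dict[CategoryKey, CategoryStat]


@dataclass
class PairwiseComparison:
    label: str
    statistic: float
    df: float
    p_value: float
    p_adjusted: float
    significant: bool


@dataclass
class SimpleEffect:
    angle_bin: tuple[float, float]
    f_value: float
    df1: float
    df2: float
    p_value: float
    significant: bool


@dataclass
class TestReport:
    """Result of one scenario's statistical test with assumption checks."""

    scenario: str
    test_name: str
    statistic: float
    df1: float
    df2: float | None
    p_value: float
    correction: str = "none"  # none | greenhouse_geisser | bonferroni
    epsilon: float | None = None
    corrected_df1: float | None = None
    corrected_df2: float | None = None
    corrected_p: float | None = None
    mauchly_w: float | None = None
    mauchly_chi2: float | None = None
    mauchly_p: float | None = None
    shapiro_p: dict[str, float] = field(default_factory=dict)
    posthoc: list[PairwiseComparison] = field(default_factory=list)
    simple_effects: list[SimpleEffect] = field(default_factory=list)
    degenerate: bool = False
    notes: str = ""


def subject_means(table: CategoryTable) -> SubjectCategoryMeans:
    """Mean ± SD (n−1 denominator) and n per category of one subject."""
    stats_: dict[CategoryKey, CategoryStat] = {}
    for key, samples in table.entries.items():
        n = samples.size
        if n == 0:
            continue  # empty category omitted; caller sees it missing
        if n == 1:
            stats_[key] = CategoryStat(float(samples[0]), 0.0, 1, degenerate=True)
        else:
            stats_[key] = CategoryStat(
                float(np.mean(samples)), float(np.std(samples, ddof=1)), int(n)
            )
    return SubjectCategoryMeans(table.subject_id, table.scenario, stats_)


def _long_frame(matrix: np.ndarray, labels: list[str]) -> pd.DataFrame:
    n, k = matrix.shape
    return pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "cond": np.tile(np.asarray(labels, dtype=object), n),
            "y": matrix.ravel(),
        }
    )


def _one_way_rm(matrix: np.ndarray, labels: list[str], alpha: float):
    """One-way RM-ANOVA with Mauchly test and GG epsilon via pingouin."""
    df = _long_frame(matrix, labels)
    row = pg.rm_anova(
        data=df, dv="y", within="cond", subject="subject", correction=True
    ).iloc[0]
    k = matrix.shape[1]
    degenerate = "F" not in row.index or not np.isfinite(row["F"])
    aov = {
        "F": 0.0 if degenerate else float(row["F"]),
        "ddof1": float(row.get("ddof1", k - 1)),
        "ddof2": float(row.get("ddof2", (k - 1) * (matrix.shape[0] - 1))),
        "p_unc": 1.0 if degenerate else float(row["p_unc"]),
        "degenerate": degenerate,
    }
    # for 2-level factors pingouin returns a plain tuple (sphericity trivial)
    _, w, chi2, _, pval = pg.sphericity(data=df, dv="y", within="cond", subject="subject")
    mauchly = {"W": float(w), "chi2": float(chi2), "pval": float(pval)}
    with np.errstate(invalid="ignore", divide="ignore"):
        eps = float(
            pg.epsilon(data=df, dv="y", within="cond", subject="subject", correction="gg")
        )
    if not np.isfinite(eps):
        eps = 1.0
    p_gg = float(row["p_GG_corr"]) if "p_GG_corr" in row.index else aov["p_unc"]
    if not np.isfinite(p_gg):
        p_gg = aov["p_unc"]
    aov["p_GG_corr"] = p_gg
    violated = mauchly["pval"] < alpha
    return aov, mauchly, eps, violated


def scenario_a_test(
    con_means: np.ndarray, ecc_means: np.ndarray, cfg: StudyConfig
) -> TestReport:
    """Paired t-test of concentric vs eccentric subject means."""
    con = np.asarray(con_means, dtype=float)
    ecc = np.asarray(ecc_means, dtype=float)
    if con.size != ecc.size:
        raise InputError("concentric and eccentric means must be paired")
    n = con.size
    if n < 3:
        raise InputError(f"need at least 3 subjects for the paired t-test, got {n}")
    diff = con - ecc
    if np.std(diff, ddof=1) == 0:
        return TestReport(
            scenario="A",
            test_name="paired_t",
            statistic=0.0,
            df1=float(n - 1),
            df2=None,
            p_value=1.0,
            degenerate=True,
            notes="zero-variance differences; t undefined, reported as no difference",
        )
    t, p = stats.ttest_rel(con, ecc)
    sw = stats.shapiro(diff)
    return TestReport(
        scenario="A",
        test_name="paired_t",
        statistic=float(t),
        df1=float(n - 1),
        df2=None,
        p_value=float(p),
        shapiro_p={"differences": float(sw.pvalue)},
    )


def scenario_b_test(means_matrix: np.ndarray, bin_labels: list[str], cfg: StudyConfig) -> TestReport:
    """One-way RM-ANOVA over merged angle intervals with post-hoc contrasts."""
    m = np.asarray(means_matrix, dtype=float)
    if m.ndim != 2 or np.isnan(m).any():
        raise InputError("scenario B needs a complete subjects × angle-bins matrix")
    n, k = m.shape
    if n < 3:
        raise InputError(f"need at least 3 subjects, got {n}")
    aov, mauchly, eps, violated = _one_way_rm(m, bin_labels, cfg.alpha)
    shapiro = {
        lab: float(stats.shapiro(m[:, j]).pvalue) if np.std(m[:, j]) > 0 else 1.0
        for j, lab in enumerate(bin_labels)
    }
    posthoc = []
    n_comp = k - 1
    for j in range(n_comp):  # adjacent angle intervals
        t, p = stats.ttest_rel(m[:, j], m[:, j + 1])
        p_adj = min(1.0, float(p) * n_comp)
        posthoc.append(
            PairwiseComparison(
                label=f"{bin_labels[j]} vs {bin_labels[j + 1]}",
                statistic=float(t),
                df=float(n - 1),
                p_value=float(p),
                p_adjusted=p_adj,
                significant=p_adj < cfg.alpha,
            )
        )
    return TestReport(
        scenario="B",
        test_name="one_way_rm_anova",
        statistic=float(aov["F"]),
        df1=float(aov["ddof1"]),
        df2=float(aov["ddof2"]),
        p_value=float(aov["p_unc"]),
        degenerate=bool(aov["degenerate"]),
        correction="greenhouse_geisser" if violated else "none",
        epsilon=eps,
        corrected_df1=eps * float(aov["ddof1"]),
        corrected_df2=eps * float(aov["ddof2"]),
        corrected_p=float(aov["p_GG_corr"]),
        mauchly_w=mauchly["W"],
        mauchly_chi2=mauchly["chi2"],
        mauchly_p=mauchly["pval"],
        shapiro_p=shapiro,
        posthoc=posthoc,
    )


def scenario_c_test(
    con_matrix: np.ndarray,
    ecc_matrix: np.ndarray,
    bins: list[tuple[float, float]],
    cfg: StudyConfig,
) -> TestReport:
    """Contraction type × angle interval interaction and simple main effects.

    ``con_matrix`` and ``ecc_matrix`` are subjects × angle-bins tables of
    category means.  The interaction F with df (k−1, (k−1)(n−1)) equals
    the one-way RM-ANOVA F on the per-subject difference scores; the
    simple main effect of contraction type at each interval is the paired
    comparison F(1, n−1) = t².
    """
    con = np.asarray(con_matrix, dtype=float)
    ecc = np.asarray(ecc_matrix, dtype=float)
    if con.shape != ecc.shape or con.ndim != 2:
        raise InputError("scenario C needs matched subjects × angle-bins matrices")
    if np.isnan(con).any() or np.isnan(ecc).any():
        raise InputError("scenario C needs complete cells for every subject")
    n, k = con.shape
    if n < 3:
        raise InputError(f"need at least 3 subjects, got {n}")
    if k != len(bins):
        raise InputError("bin labels do not match the matrix width")
    diff = con - ecc
    labels = [f"{lo:g}-{hi:g}" for lo, hi in bins]
    aov, mauchly, eps, violated = _one_way_rm(diff, labels, cfg.alpha)

    simple = []
    for j, bin_ in enumerate(bins):
        d = diff[:, j]
        if np.std(d, ddof=1) == 0:
            f, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(con[:, j], ecc[:, j])
            f, p = float(t) ** 2, float(p)
        simple.append(
            SimpleEffect(
                angle_bin=bin_,
                f_value=f,
                df1=1.0,
                df2=float(n - 1),
                p_value=p,
                significant=p < cfg.alpha,
            )
        )
    return TestReport(
        scenario="C",
        test_name="two_way_rm_anova_interaction",
        statistic=float(aov["F"]),
        df1=float(aov["ddof1"]),
        df2=float(aov["ddof2"]),
        p_value=float(aov["p_unc"]),
        degenerate=bool(aov["degenerate"]),
        correction="greenhouse_geisser" if violated else "none",
        epsilon=eps,
        corrected_df1=eps * float(aov["ddof1"]),
        corrected_df2=eps * float(aov["ddof2"]),
        corrected_p=float(aov["p_GG_corr"]),
        mauchly_w=mauchly["W"],
        mauchly_chi2=mauchly["chi2"],
        mauchly_p=mauchly["pval"],
        simple_effects=simple,
        notes="interaction computed on concentric-eccentric difference scores",
    )
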