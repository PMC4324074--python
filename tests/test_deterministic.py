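import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from dynemg import (
    ANY,
    CONCENTRIC,
    CategoryKey,
    CategoryTable,
    StudyConfig,
    scenario_a_test,
    scenario_b_test,
    scenario_c_test,
    subject_means,
)
from dynemg.core_io import InputError

BINS4 = [(0.0, 30.0), (30.0, 60.0), (60.0, 90.0), (90.0, 120.0)]
LABELS4 = ["0-30", "30-60", "60-90", "90-120"]


def make_table(samples_by_key):
    return CategoryTable(
        subject_id="S01",
        scenario="A",
        entries={k: np.asarray(v, dtype=float) for k, v in samples_by_key.items()},
    )


class TestSubjectMeans:
    def test_mean_and_sd_closed_form(self):
        key = CategoryKey(CONCENTRIC, ANY)
        sm = subject_means(make_table({key: [10.0, 20.0]}))
        assert sm.stats[key].mean == pytest.approx(15.0)
        assert sm.stats[key].sd == pytest.approx(np.sqrt(50.0))
        assert sm.stats[key].n == 2

    def test_single_sample_flagged_degenerate(self):
        key = CategoryKey(CONCENTRIC, ANY)
        sm = subject_means(make_table({key: [7.0]}))
        assert sm.stats[key].mean == 7.0
        assert sm.stats[key].sd == 0.0
        assert sm.stats[key].degenerate

    def test_empty_category_omitted(self):
        key = CategoryKey(CONCENTRIC, ANY)
        sm = subject_means(make_table({key: []}))
        assert key not in sm.stats

    def test_constant_categories(self):
        keys = [CategoryKey(CONCENTRIC, b) for b in BINS4]
        sm = subject_means(make_table({k: [4.0, 4.0, 4.0] for k in keys}))
        assert all(sm.stats[k].mean == 4.0 and sm.stats[k].sd == 0.0 for k in keys)


class TestScenarioA:
    def test_closed_form_t_on_differences(self, cfg):
        ecc = np.array([10.0, 10.0, 10.0])
        con = ecc + np.array([1.0, 2.0, 3.0])
        report = scenario_a_test(con, ecc, cfg)
        assert report.statistic == pytest.approx(2 * np.sqrt(3))
        assert report.df1 == 2

    def test_identical_pairs_flagged(self, cfg):
        x = np.array([10.0, 12.0, 14.0, 16.0])
        report = scenario_a_test(x, x, cfg)
        assert report.degenerate and report.p_value == 1.0

    def test_constant_offset_flagged(self, cfg):
        ecc = np.array([10.0, 12.0, 14.0])
        report = scenario_a_test(ecc + 5.0, ecc, cfg)
        assert report.degenerate

    def test_too_few_subjects_rejected(self, cfg):
        with pytest.raises(InputError, match="3 subjects"):
            scenario_a_test(np.array([1.0, 2.0]), np.array([0.5, 1.0]), cfg)

    def test_shapiro_reported(self, cfg, rng):
        con = rng.normal(20, 3, 10)
        ecc = con - rng.normal(5, 1, 10)
        report = scenario_a_test(con, ecc, cfg)
        assert 0 <= report.shapiro_p["differences"] <= 1


class TestScenarioB:
    def test_identical_conditions_give_zero_f(self, cfg, rng):
        base = rng.normal(10, 2, 8)
        m = np.tile(base[:, None], (1, 4))
        report = scenario_b_test(m, LABELS4, cfg)
        assert report.statistic == pytest.approx(0.0, abs=1e-10)

    def test_two_condition_f_equals_t_squared(self, cfg, rng):
        m = rng.normal(10, 2, size=(10, 2)) + np.array([0.0, 1.0])
        report = scenario_b_test(m, ["a", "b"], cfg)
        t, _ = stats.ttest_rel(m[:, 0], m[:, 1])
        assert report.statistic == pytest.approx(t**2, abs=1e-8)

    def test_strong_monotone_effect_detected(self, cfg, rng):
        m = np.arange(4) * 5.0 + rng.normal(0, 0.5, size=(10, 4))
        report = scenario_b_test(m, LABELS4, cfg)
        p = report.corrected_p if report.correction == "greenhouse_geisser" else report.p_value
        assert p < cfg.alpha
        assert report.posthoc[0].significant  # 0-30 vs 30-60 increase

    def test_mauchly_and_epsilon_reported(self, cfg, rng):
        m = rng.normal(size=(12, 4))
        report = scenario_b_test(m, LABELS4, cfg)
        assert 0 <= report.mauchly_p <= 1
        assert 1 / 3 - 1e-12 <= report.epsilon <= 1 + 1e-12
        assert report.corrected_df1 <= report.df1

    def test_incomplete_matrix_rejected(self, cfg):
        m = np.full((5, 4), np.nan)
        with pytest.raises(InputError, match="complete"):
            scenario_b_test(m, LABELS4, cfg)


class TestScenarioC:
    def test_no_effect_gives_small_f(self, cfg, rng):
        base = rng.normal(10, 2, size=(10, 4))
        noise = rng.normal(0, 0.01, size=(10, 4))
        report = scenario_c_test(base + noise, base, BINS4, cfg)
        assert report.p_value > cfg.alpha
        assert not any(se.significant for se in report.simple_effects)

    def test_effect_only_above_30_detected(self, cfg, rng):
        """Type effect restricted to bins above 30° produces a significant
        interaction and simple effects exactly in those bins."""
        con = 10.0 + np.arange(4) * 5.0 + rng.normal(0, 0.5, size=(10, 4))
        ecc = con.copy()
        ecc[:, 1:] -= 4.0 + rng.normal(0, 0.3, size=(10, 3))
        report = scenario_c_test(con, ecc, BINS4, cfg)
        p = report.corrected_p if report.correction == "greenhouse_geisser" else report.p_value
        assert p < cfg.alpha
        flags = [se.significant for se in report.simple_effects]
        assert flags == [False, True, True, True]

    def test_interaction_matches_pingouin_two_way(self, cfg, rng):
        con = rng.normal(10, 2, size=(9, 4))
        ecc = rng.normal(9, 2, size=(9, 4))
        report = scenario_c_test(con, ecc, BINS4, cfg)
        rows = []
        for i in range(9):
            for t_idx, mat in ((0, con), (1, ecc)):
                for j in range(4):
                    rows.append((i, t_idx, j, mat[i, j]))
        df = pd.DataFrame(rows, columns=["subject", "ctype", "abin", "y"])
        aov = pg.rm_anova(data=df, dv="y", within=["ctype", "abin"], subject="subject")
        f_pg = float(aov.loc[aov["Source"] == "ctype * abin", "F"].iloc[0])
        assert report.statistic == pytest.approx(f_pg, rel=1e-8)
        assert report.df1 == 3 and report.df2 == 24

    def test_simple_effect_is_squared_paired_t(self, cfg, rng):
        con = rng.normal(10, 2, size=(10, 4))
        ecc = rng.normal(9, 2, size=(10, 4))
        report = scenario_c_test(con, ecc, BINS4, cfg)
        for j, se in enumerate(report.simple_effects):
            t, p = stats.ttest_rel(con[:, j], ecc[:, j])
            assert se.f_value == pytest.approx(t**2, abs=1e-8)
            assert se.p_value == pytest.approx(p, abs=1e-12)

    def test_mismatched_shapes_rejected(self, cfg, rng):
        with pytest.raises(InputError, match="matched"):
            scenario_c_test(rng.normal(size=(5, 4)), rng.normal(size=(5, 3)), BINS4, cfg)


class TestGreenhouseGeisser:
    def test_epsilon_is_one_for_two_levels(self, cfg, rng):
        m = rng.normal(size=(10, 2))
        report = scenario_b_test(m, ["a", "b"], cfg)
        assert report.epsilon == pytest.approx(1.0)

    def test_epsilon_bounds_for_four_levels(self, cfg, rng):
        for _ in range(10):
            # random covariance structure via random loadings
            loadings = rng.normal(size=(4, 4))
            m = rng.normal(size=(12, 4)) @ loadings
            report = scenario_b_test(m, LABELS4, cfg)
            assert 1 / 3 - 1e-9 <= report.epsilon <= 1 + 1e-9

    def test_epsilon_one_on_compound_symmetry(self, cfg, rng):
        subject = rng.normal(0, 3, size=(200, 1))
        m = subject + rng.normal(0, 1, size=(200, 4))
        report = scenario_b_test(m, LABELS4, cfg)
        assert report.epsilon > 0.9


class TestNullCalibration:
    def test_type_one_error_rates(self, cfg, rng):
        """Under pure Gaussian noise each scenario test rejects ~5% of the time."""
        n_rep = 500
        rej = {"A": 0, "B": 0, "C": 0}
        for _ in range(n_rep):
            con = rng.normal(10, 2, size=(10, 4))
            ecc = rng.normal(10, 2, size=(10, 4))
            ra = scenario_a_test(con.mean(axis=1), ecc.mean(axis=1), cfg)
            rej["A"] += ra.p_value < cfg.alpha
            rb = scenario_b_test(con, LABELS4, cfg)
            pb = rb.corrected_p if rb.correction == "greenhouse_geisser" else rb.p_value
            rej["B"] += pb < cfg.alpha
            rc = scenario_c_test(con, ecc, BINS4, cfg)
            pc = rc.corrected_p if rc.correction == "greenhouse_geisser" else rc.p_value
            rej["C"] += pc < cfg.alpha
        for scenario, count in rej.items():
            assert 0.03 <= count / n_rep <= 0.07, f"scenario {scenario}: {count / n_rep}"
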