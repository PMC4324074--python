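import dataclasses

import numpy as np
import pytest

from dynemg import (
    CONCENTRIC,
    ECCENTRIC,
    ANY,
    CategoryKey,
    GeneratorParams,
    StudyConfig,
    activation_surface,
    apply_exclusion,
    generate_kinematics,
    generate_study,
)
from dynemg.categorize import categorize_scenario, merge_angle_bins
from dynemg.core_io import LABEL_UNASSIGNED, CategoryTable
from dynemg.pipeline import process_trial
from dynemg.preprocess import compute_envelope, mvc_reference
from dynemg.synthetic import SubjectEffects


class TestKinematics:
    def test_cycle_duration_and_peak(self):
        params = GeneratorParams(angle_noise_sd_deg=0.0, prosup_drift_deg=0.0)
        kin = generate_kinematics(params, np.random.default_rng(0))
        assert kin.t_kin.size == 1920  # 9.6 s at 200 Hz
        assert kin.angle.max() == pytest.approx(120.0, abs=1e-9)
        assert kin.angle.min() >= -1e-9

    def test_nominal_ramp_speed(self):
        params = GeneratorParams(angle_noise_sd_deg=0.0)
        kin = generate_kinematics(params, np.random.default_rng(0))
        mid = (kin.angle_true_emg > 30) & (kin.angle_true_emg < 90)
        speeds = np.abs(kin.velocity_true_emg[mid])
        assert np.median(speeds) == pytest.approx(25.0, rel=0.05)

    def test_deterministic_given_seed(self):
        params = GeneratorParams(n_subjects=1, n_cycles=1)
        s1, s2 = generate_study(params), generate_study(params)
        assert s1.ground_truth == s2.ground_truth
        np.testing.assert_array_equal(s1.trials[-1].emg, s2.trials[-1].emg)
        np.testing.assert_array_equal(s1.trials[-1].flexion_angle, s2.trials[-1].flexion_angle)

    def test_prosup_drift_makes_trial_excludable(self, cfg):
        params = GeneratorParams(n_subjects=1, n_cycles=1, prosup_drift_deg=8.0)
        trial = [t for t in generate_study(params).trials if not t.is_mvc][0]
        report = apply_exclusion(trial, cfg)
        assert report.excluded and report.reason == "prosup_drift"


class TestActivationSurface:
    params = GeneratorParams()
    eff = SubjectEffects(b0=0.03, b1=0.25, r=0.3)

    def test_no_type_effect_at_full_extension(self):
        m_con = activation_surface(0.0, "con", self.eff, self.params)
        m_ecc = activation_surface(0.0, "ecc", self.eff, self.params)
        assert m_con == m_ecc == pytest.approx(0.03)

    def test_full_attenuation_at_peak_flexion(self):
        m_con = activation_surface(120.0, "con", self.eff, self.params)
        m_ecc = activation_surface(120.0, "ecc", self.eff, self.params)
        assert m_ecc == pytest.approx(0.7 * m_con)

    def test_null_case_identical_surfaces(self):
        eff0 = SubjectEffects(b0=0.03, b1=0.25, r=0.0)
        theta = np.linspace(0, 120, 50)
        np.testing.assert_allclose(
            activation_surface(theta, "con", eff0, self.params),
            activation_surface(theta, "ecc", eff0, self.params),
        )

    def test_ramp_spans_onset_window(self):
        m_mid = activation_surface(45.0, "ecc", self.eff, self.params)
        base = self.eff.b0 + self.eff.b1 * 45.0 / 120.0
        assert m_mid == pytest.approx(base * (1 - 0.3 * 0.5))


class TestEmgSynthesis:
    def test_mvc_normalizes_to_100(self, cfg):
        """An MVC trial normalized by the MVC reference sits near 100 %MVC."""
        study = generate_study(GeneratorParams(n_subjects=1, n_cycles=1, seed=11))
        mvc = [t for t in study.trials if t.is_mvc]
        envs = [compute_envelope(t.emg, t.fs_emg, cfg) for t in mvc]
        ref = mvc_reference(envs, [t.trial_id for t in mvc])
        central = envs[0][len(envs[0]) // 4 : -len(envs[0]) // 4]
        assert 100 * central.mean() / ref.reference_value == pytest.approx(100.0, rel=0.05)

    def test_mvc_amplitude_cancels_in_normalization(self, cfg):
        p1 = GeneratorParams(n_subjects=1, n_cycles=1, seed=5)
        p2 = dataclasses.replace(p1, mvc_amplitude_mv=2.0)
        s1, s2 = generate_study(p1), generate_study(p2)

        def normalized_trial(study):
            mvc = [t for t in study.trials if t.is_mvc]
            ref = mvc_reference(
                [compute_envelope(t.emg, t.fs_emg, cfg) for t in mvc],
                [t.trial_id for t in mvc],
            )
            move = [t for t in study.trials if not t.is_mvc][0]
            return 100 * compute_envelope(move.emg, move.fs_emg, cfg) / ref.reference_value

        np.testing.assert_allclose(normalized_trial(s1), normalized_trial(s2), rtol=1e-9)

    def test_unassigned_fraction_small_without_noise(self, cfg):
        params = GeneratorParams(n_subjects=1, n_cycles=1, angle_noise_sd_deg=0.0)
        study = generate_study(params)
        move = [t for t in study.trials if not t.is_mvc][0]
        mvc = [t for t in study.trials if t.is_mvc]
        ref = mvc_reference(
            [compute_envelope(t.emg, t.fs_emg, cfg) for t in mvc],
            [t.trial_id for t in mvc],
        )
        env = process_trial(move, ref, cfg)
        assert (env.labels == LABEL_UNASSIGNED).mean() < 0.05


@pytest.fixture(scope="module")
def single_subject_tables():
    params = GeneratorParams(n_subjects=1, n_cycles=20, subject_sd=0.0, seed=21)
    study = generate_study(params)
    cfg = StudyConfig()
    mvc = [t for t in study.trials if t.is_mvc]
    ref = mvc_reference(
        [compute_envelope(t.emg, t.fs_emg, cfg) for t in mvc],
        [t.trial_id for t in mvc],
    )
    moves = [t for t in study.trials if not t.is_mvc]
    tables = [
        categorize_scenario(process_trial(t, ref, cfg), "C", cfg, subject_id="S01")
        for t in moves
    ]
    merged = merge_angle_bins(CategoryTable.merge(tables), 30.0)
    return params, study.ground_truth["S01"], merged


class TestGroundTruthRecovery:
    def test_concentric_bin_means_recover_surface(self, single_subject_tables):
        params, truth, merged = single_subject_tables
        eff = SubjectEffects(**truth)
        mids = [15.0, 45.0, 75.0, 105.0]
        bins = [(0.0, 30.0), (30.0, 60.0), (60.0, 90.0), (90.0, 120.0)]
        means = []
        for mid, bin_ in zip(mids, bins):
            samples = merged.entries[CategoryKey(CONCENTRIC, bin_)]
            assert samples.size > 500
            expected = 100 * activation_surface(mid, "con", eff, params)
            assert samples.mean() == pytest.approx(expected, rel=0.10)
            means.append(samples.mean())
        assert means == sorted(means)  # monotone in angle

    def test_eccentric_attenuated_only_above_onset(self, single_subject_tables):
        params, truth, merged = single_subject_tables
        con_low = merged.entries[CategoryKey(CONCENTRIC, (0.0, 30.0))].mean()
        ecc_low = merged.entries[CategoryKey(ECCENTRIC, (0.0, 30.0))].mean()
        assert abs(con_low - ecc_low) < 1.0
        con_hi = merged.entries[CategoryKey(CONCENTRIC, (90.0, 120.0))].mean()
        ecc_hi = merged.entries[CategoryKey(ECCENTRIC, (90.0, 120.0))].mean()
        assert ecc_hi < 0.85 * con_hi


class TestNullFidelity:
    def test_no_type_effect_when_r_zero(self, cfg):
        params = GeneratorParams(n_subjects=3, n_cycles=8, eccentric_attenuation=0.0, seed=31)
        study = generate_study(params)
        diffs = []
        for sid in {t.subject_id for t in study.trials}:
            subj = [t for t in study.trials if t.subject_id == sid]
            mvc = [t for t in subj if t.is_mvc]
            ref = mvc_reference(
                [compute_envelope(t.emg, t.fs_emg, cfg) for t in mvc],
                [t.trial_id for t in mvc],
            )
            tables = [
                categorize_scenario(process_trial(t, ref, cfg), "A", cfg, subject_id=sid)
                for t in subj
                if not t.is_mvc
            ]
            table = CategoryTable.merge(tables)
            con = table.entries[CategoryKey(CONCENTRIC, ANY)].mean()
            ecc = table.entries[CategoryKey(ECCENTRIC, ANY)].mean()
            diffs.append(abs(con - ecc))
        assert np.mean(diffs) < 2.0  # %MVC


class TestParamValidation:
    def test_invalid_attenuation_rejected(self):
        with pytest.raises(Exception, match="attenuation"):
            GeneratorParams(eccentric_attenuation=1.2)

    def test_default_study_counts(self):
        params = GeneratorParams()
        assert params.n_subjects == 10 and params.n_cycles == 20
        assert params.cycle_period_s == pytest.approx(9.6)
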