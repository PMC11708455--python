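import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pwave.ecg_io import STANDARD_LEADS
from pwave.synthetic_ecg import (
    SUPPORT_LEVEL, ArmPopulation, CohortConfig, MorphologyError, NoiseConfig,
    ParameterPopulation, StructureConfig, default_morphology, generate_cohort,
    generate_record, make_patient_template, morphology_from_parameters,
)
from pwave.synthetic_ecg import _draw_arm_parameters

FS = 1000.0


def small_cfg(n_a=2, n_b=2, sd=0.0, moment_match=True):
    def pop(pre, delta, psd, dsd):
        return ParameterPopulation(pre_mean=pre, pre_sd=psd, delta_mean=delta, delta_sd=dsd)

    def arm(n):
        return ArmPopulation(
            n=n,
            pwd_ms=pop(130.0, -10.0, sd, sd),
            pwv_mv=pop(1.2, 0.0, sd / 50, sd / 50),
            pwdisp_ms=pop(28.0, 0.0, sd / 2, sd / 2),
            ptfv1=pop(-3.0, -0.5, sd / 10, sd / 10),
        )

    return CohortConfig(
        arms={"success": arm(n_a), "fail": arm(n_b)},
        noise=NoiseConfig(),
        structure=StructureConfig(neg_duration_sd_ms=sd / 4),
        fs_hz=500.0,
        duration_s=20.0,
        moment_match=moment_match,
    )


class TestGroundTruthClosedForm:
    def test_ptfv1_is_depth_times_duration(self):
        morph = default_morphology(ptfv1=-3.2, neg_duration_ms=40.0)
        assert morph.v1_neg_depth == pytest.approx(0.08)
        gt = make_patient_template(morph, FS).ground_truth
        assert gt.ptfv1 == pytest.approx(-3.2)

    def test_zero_depth_gives_zero_terminal_force(self):
        gt = make_patient_template(default_morphology(ptfv1=0.0), FS).ground_truth
        assert gt.ptfv1 == 0.0
        assert gt.v1_neg_trough_ms is None

    def test_dispersion_equals_max_minus_min(self):
        gt = make_patient_template(default_morphology(), FS).ground_truth
        pwds = list(gt.pwd_ms.values())
        assert gt.pwdisp_ms == pytest.approx(max(pwds) - min(pwds))
        assert gt.global_pwd_ms == pytest.approx(max(pwds))

    def test_fiducial_ordering_per_lead(self):
        gt = make_patient_template(default_morphology(), FS).ground_truth
        for lead in STANDARD_LEADS:
            assert gt.onset_ms[lead] < gt.peak_ms[lead] < gt.offset_ms[lead]

    def test_brute_force_threshold_scan_matches_ground_truth(self, default_template):
        """Independent oracle: scan the noiseless beat for support-level
        crossings of each P lobe and compare with the closed-form fiducials."""
        tpl = default_template
        gt, morph = tpl.ground_truth, tpl.morphology
        qrs_idx = int(gt.qrs_onset_ms / 1000.0 * tpl.fs)
        for lead in STANDARD_LEADS:
            wave = tpl.beat[:qrs_idx, STANDARD_LEADS.index(lead)]
            level = SUPPORT_LEVEL * morph.p_amp[lead]
            above = np.flatnonzero(wave >= level)
            onset_ms = above[0] / tpl.fs * 1000.0
            assert onset_ms == pytest.approx(gt.onset_ms[lead], abs=1.0)
            if lead != "V1":
                offset_ms = above[-1] / tpl.fs * 1000.0
                assert offset_ms == pytest.approx(gt.offset_ms[lead], abs=1.0)
        # V1 phase boundaries tolerate the positive lobe's tail (~2 ms shift)
        v1 = tpl.beat[:qrs_idx, STANDARD_LEADS.index("V1")]
        below = np.flatnonzero(v1 <= -SUPPORT_LEVEL * morph.v1_neg_depth)
        assert below[0] / tpl.fs * 1000.0 == pytest.approx(gt.v1_neg_start_ms, abs=2.5)
        assert below[-1] / tpl.fs * 1000.0 == pytest.approx(gt.v1_neg_end_ms, abs=2.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        pwd=st.floats(100.0, 170.0),
        pwv=st.floats(0.6, 2.0),
        disp=st.floats(10.0, 45.0),
        ptf=st.floats(-6.0, -0.8),
        nd=st.floats(25.0, 60.0),
    )
    def test_parameter_solver_round_trips(self, pwd, pwv, disp, ptf, nd):
        """Morphology solved from parameter values reproduces them analytically."""
        if pwd - 0.5 * disp < nd + 55.0 or -ptf / nd > 0.3:
            return  # outside the solver's feasible region
        gt = make_patient_template(
            morphology_from_parameters(pwd, pwv, disp, ptf, nd), FS
        ).ground_truth
        assert gt.global_pwd_ms == pytest.approx(pwd, abs=1e-6)
        assert gt.pwv_mv == pytest.approx(pwv, abs=1e-9)
        assert gt.pwdisp_ms == pytest.approx(disp, abs=1e-6)
        assert gt.ptfv1 == pytest.approx(ptf, abs=1e-9)
        assert gt.pwdisp_ms >= 0.0


class TestMorphologyInvariants:
    def test_heart_rate_bounds(self):
        with pytest.raises(MorphologyError, match="heart rate"):
            dataclasses.replace(default_morphology(), heart_rate_bpm=200.0)

    def test_negative_width_rejected(self):
        morph = default_morphology()
        bad = dict(morph.p_width, II=-5.0)
        with pytest.raises(MorphologyError, match="width"):
            dataclasses.replace(morph, p_width=bad)

    def test_p_wave_cannot_cross_qrs_onset(self):
        morph = default_morphology()
        with pytest.raises(MorphologyError, match="QRS onset"):
            dataclasses.replace(morph, pr_ms=morph.pr_ms - 100.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="250"):
            make_patient_template(default_morphology(), fs=100.0)


class TestRecordGeneration:
    def test_noiseless_beats_tile_exactly(self, default_template):
        rec = generate_record(default_template, 10.0, NoiseConfig.silent(), seed=0)
        n_beat = default_template.beat.shape[0]
        for k in range(1, 10000 // n_beat):
            np.testing.assert_array_equal(
                rec.data[:n_beat], rec.data[k * n_beat:(k + 1) * n_beat]
            )

    def test_same_seed_is_bit_identical(self, default_template):
        a = generate_record(default_template, 12.0, NoiseConfig(), seed=42)
        b = generate_record(default_template, 12.0, NoiseConfig(), seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_white_noise_sd_on_tp_segment(self, default_template):
        noise = NoiseConfig(white_uv=20.0, wander_uv=0.0, mains_uv=0.0)
        rec = generate_record(default_template, 60.0, noise, seed=5)
        clean = generate_record(default_template, 60.0, NoiseConfig.silent(), seed=5)
        gt = default_template.ground_truth
        # flat TP samples: between the T support end and the next P onset
        lo = int((gt.t_peak_ms + 80.0))
        hi = int(gt.onset_ms["II"] + default_template.rr_ms - 20.0)
        resid = (rec.data - clean.data)[:, STANDARD_LEADS.index("II")]
        n_beat = default_template.beat.shape[0]
        tp = np.concatenate([
            resid[k * n_beat + lo: k * n_beat + hi] for k in range(0, 50)
        ])
        assert np.std(tp) * 1000 == pytest.approx(20.0, rel=0.10)

    def test_too_short_duration_rejected(self, default_template):
        with pytest.raises(ValueError, match="duration"):
            generate_record(default_template, 0.2, NoiseConfig.silent(), seed=0)

    def test_noise_config_validation(self):
        with pytest.raises(ValueError, match="mains"):
            NoiseConfig(mains_hz=45.0)
        with pytest.raises(ValueError, match=">= 0"):
            NoiseConfig(white_uv=-1.0)


class TestCohortGeneration:
    def test_arm_counts_72_patients(self, calibration):
        cfg = dataclasses.replace(calibration, duration_s=18.0, fs_hz=500.0)
        patients = generate_cohort(cfg, seed=3)
        assert len(patients) == 72
        arms = [p.arm for p in patients]
        assert arms.count("success") == 43 and arms.count("fail") == 29

    def test_zero_sd_gives_identical_ground_truth(self):
        cfg = small_cfg(sd=0.0)
        patients = generate_cohort(cfg, seed=0)
        succ = [p for p in patients if p.arm == "success"]
        ref = succ[0].pre.ground_truth
        for p in succ[1:]:
            assert p.pre.ground_truth == ref

    def test_cohort_is_bit_reproducible(self):
        cfg = small_cfg(n_a=1, n_b=1, sd=4.0)
        a = generate_cohort(cfg, seed=11)
        b = generate_cohort(cfg, seed=11)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.pre.record.data, pb.pre.record.data)
            np.testing.assert_array_equal(pa.post.record.data, pb.post.record.data)

    def test_moment_matched_draws_hit_population_means(self, calibration, rng):
        arm = calibration.arms["success"]
        draws = _draw_arm_parameters(rng, arm, calibration.structure, moment_match=True)
        assert np.mean(draws["ptfv1_pre"]) == pytest.approx(-3.1, abs=0.02)
        assert np.mean(draws["pwd_pre"]) == pytest.approx(136.7, abs=0.05)
        assert np.std(draws["pwd_pre"], ddof=1) == pytest.approx(13.0, rel=0.02)
        assert np.mean(draws["ptfv1_post"]) == pytest.approx(-4.4, abs=0.05)

    def test_ground_truth_respects_parameter_draws(self):
        cfg = small_cfg(sd=6.0)
        for p in generate_cohort(cfg, seed=2):
            for phase in (p.pre, p.post):
                gt = phase.ground_truth
                pwds = list(gt.pwd_ms.values())
                assert gt.pwdisp_ms == pytest.approx(max(pwds) - min(pwds))
                assert gt.ptfv1 <= 0.0
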