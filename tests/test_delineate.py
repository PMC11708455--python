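import numpy as np
import pytest

from pwave.ecg_io import EcgRecord, STANDARD_LEADS
from pwave.preprocess import apply_filters
from pwave.synthetic_ecg import (
    NoiseConfig, default_morphology, generate_record, make_patient_template,
)
from pwave.delineate import (
    AnnotationOverride, DelineationError, FlatSignalError,
    InsufficientBeatsError, NoPeakError, OverrideError, average_pwave,
    delineate_record, delineate_template, detect_beats, detect_p_peak,
    locate_onset_offset, locate_v1_negative_phase,
)
from pwave.delineate import _chord_knee

FS = 1000.0


def true_r_peaks(template, duration_s):
    n_beat = template.beat.shape[0]
    r = template.ground_truth.r_peak_ms / 1000.0 * template.fs
    total = int(duration_s * template.fs)
    return np.array([
        int(k * n_beat + r) for k in range(int(np.ceil(total / n_beat)))
        if k * n_beat + r < total
    ])


class TestBeatDetection:
    def test_beat_count_matches_heart_rate(self, default_template, noiseless_record):
        beats = detect_beats(apply_filters(noiseless_record))
        expected = len(true_r_peaks(default_template, 60.0))
        assert abs(len(beats) - expected) <= 1

    def test_r_peaks_within_10_ms_of_truth(self, default_template, noisy_record):
        beats = detect_beats(apply_filters(noisy_record))
        truth = true_r_peaks(default_template, 60.0)
        for r in beats.r_peaks:
            assert np.min(np.abs(truth - r)) <= 10

    def test_qrs_onset_precedes_r(self, noiseless_record):
        beats = detect_beats(apply_filters(noiseless_record))
        assert np.all(beats.qrs_onsets < beats.r_peaks)

    def test_flat_record_rejected(self):
        rec = EcgRecord(np.zeros((15000, 12)), fs=FS)
        with pytest.raises(FlatSignalError):
            detect_beats(rec)

    def test_short_record_rejected(self, default_template):
        rec = generate_record(default_template, 5.0, NoiseConfig.silent(), seed=0)
        with pytest.raises(DelineationError, match="shorter"):
            detect_beats(rec)

    def test_too_few_beats_for_averaging(self, default_template):
        rec = generate_record(default_template, 12.0, NoiseConfig.silent(), seed=0)
        with pytest.raises(InsufficientBeatsError, match="n_beats"):
            detect_beats(rec, min_beats=21)


class TestTemplateAveraging:
    def test_noiseless_template_equals_single_beat(self, noiseless_record):
        # unfiltered noiseless record: every beat is bit-identical, so the
        # 20-beat mean must equal any one beat's segment exactly
        beats = detect_beats(noiseless_record)
        template = average_pwave(noiseless_record, beats, n_beats=20)
        r = beats.r_peaks[5]
        seg = noiseless_record.data[
            r - template.r_offset: r - template.r_offset + template.data.shape[0]
        ]
        np.testing.assert_allclose(template.data, seg, atol=1e-12)

    def test_single_beat_average_equals_that_beat(self, noiseless_record):
        beats = detect_beats(noiseless_record)
        t1 = average_pwave(noiseless_record, beats, n_beats=1)
        t20 = average_pwave(noiseless_record, beats, n_beats=20)
        np.testing.assert_allclose(t1.data, t20.data, atol=1e-12)

    def test_residual_noise_shrinks_by_sqrt_n(self, default_template):
        sigma_uv = 15.0
        noise = NoiseConfig(white_uv=sigma_uv, wander_uv=0.0, mains_uv=0.0)
        noisy = generate_record(default_template, 60.0, noise, seed=3)
        clean = generate_record(default_template, 60.0, NoiseConfig.silent(), seed=3)
        beats = detect_beats(clean)
        t_noisy = average_pwave(noisy, beats, n_beats=20)
        t_clean = average_pwave(clean, beats, n_beats=20)
        resid = (t_noisy.data - t_clean.data) * 1000.0
        assert np.std(resid) == pytest.approx(sigma_uv / np.sqrt(20), rel=0.15)

    def test_insufficient_beats_raises(self, noiseless_record):
        filt = apply_filters(noiseless_record)
        beats = detect_beats(filt)
        with pytest.raises(InsufficientBeatsError):
            average_pwave(filt, beats, n_beats=len(beats))


def synthetic_segment(lobes, length=450, fs=FS):
    """Flat baseline plus Gaussian lobes given as (amp, center, sigma)."""
    t = np.arange(length)
    seg = np.zeros(length)
    for amp, center, sigma in lobes:
        seg += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return seg


class TestPPeakRule:
    def test_peak_at_lobe_center(self):
        seg = synthetic_segment([(0.12, 300, 15.0), (0.1, 60, 12.0)])
        peak = detect_p_peak(seg, FS, t_peak=60, qrs_onset=430, baseline=0.0)
        assert abs(peak - 300) <= 1

    def test_narrow_spike_rejected_in_favor_of_lobe(self):
        # 5-ms spike (sigma ~2) would win on amplitude but fails the width rule
        seg = synthetic_segment([(0.1, 300, 15.0), (0.25, 250, 2.0), (0.1, 60, 12.0)])
        spike_width_ms = 2.0 * 2.355  # FWHM of the spike, well under 15 ms
        assert spike_width_ms < 15.0
        peak = detect_p_peak(seg, FS, t_peak=60, qrs_onset=430, baseline=0.0)
        assert abs(peak - 300) <= 1

    def test_flat_window_raises(self):
        seg = synthetic_segment([(0.1, 60, 12.0)])
        with pytest.raises(NoPeakError):
            detect_p_peak(seg, FS, t_peak=60, qrs_onset=430, baseline=0.0)


class TestOnsetOffsetRule:
    def test_knee_matches_brute_force_distance_scan(self):
        seg = synthetic_segment([(0.08, 60, 20.0), (0.12, 300, 15.0)])
        onset, offset, _ = locate_onset_offset(
            seg, FS, t_peak=60, p_peak=300, qrs_onset=430, refine=False
        )

        def brute_force(i0, i1):
            p0 = np.array([i0, seg[i0]])
            p1 = np.array([i1, seg[i1]])
            chord = p1 - p0
            best, best_d = None, -1.0
            for i in range(i0 + 1, i1):
                v = np.array([i, seg[i]]) - p0
                d = abs(chord[0] * v[1] - chord[1] * v[0]) / np.hypot(*chord)
                if d >= best_d - 1e-12:
                    if d > best_d + 1e-12 or best is None:
                        best_d = d
                    best = i  # ties resolve to the later sample
            return best

        assert onset == brute_force(60, 300)

    def test_noiseless_recovery_within_5ms(self, default_template):
        rec = generate_record(default_template, 60.0, NoiseConfig.silent(), seed=0)
        template = delineate_record(apply_filters(rec))
        gt = default_template.ground_truth
        shift = gt.r_peak_ms - template.r_offset
        for lead in STANDARD_LEADS:
            f = template.fiducials[lead]
            assert f.measurable
            assert (f.onset + shift) == pytest.approx(gt.onset_ms[lead], abs=5.0)
            assert (f.offset + shift) == pytest.approx(gt.offset_ms[lead], abs=5.0)

    def test_symmetric_lobe_gives_symmetric_edges(self):
        seg = synthetic_segment([(0.1, 60, 12.0), (0.12, 300, 15.0)])
        onset, offset, _ = locate_onset_offset(
            seg, FS, t_peak=60, p_peak=300, qrs_onset=430
        )
        assert abs((300 - onset) - (offset - 300)) <= 1

    def test_degenerate_chord_raises(self):
        seg = synthetic_segment([(0.12, 300, 15.0)])
        with pytest.raises(DelineationError):
            locate_onset_offset(seg, FS, t_peak=300, p_peak=300, qrs_onset=430)
        with pytest.raises(DelineationError):
            _chord_knee(seg, 100, 101)

    def test_noise_robustness_10uv(self, default_template):
        """At 10-uV white noise, onset/offset errors stay <= 10 ms in >= 95%
        of lead measurements across seeded trials."""
        gt = default_template.ground_truth
        noise = NoiseConfig(white_uv=10.0, wander_uv=0.0, mains_uv=0.0)
        ok = total = 0
        for seed in range(6):
            rec = generate_record(default_template, 60.0, noise, seed=seed)
            template = delineate_record(apply_filters(rec))
            shift = gt.r_peak_ms - template.r_offset
            for lead in STANDARD_LEADS:
                f = template.fiducials[lead]
                if not f.measurable:
                    total += 2
                    continue
                for got, want in (
                    (f.onset + shift, gt.onset_ms[lead]),
                    (f.offset + shift, gt.offset_ms[lead]),
                ):
                    total += 1
                    ok += abs(got - want) <= 10.0
        assert ok / total >= 0.95


class TestV1NegativePhase:
    def test_biphasic_duration_and_trough(self):
        morph = default_morphology(ptfv1=-3.2, neg_duration_ms=40.0)
        tpl = make_patient_template(morph, FS)
        rec = generate_record(tpl, 60.0, NoiseConfig.silent(), seed=0)
        template = delineate_record(apply_filters(rec))
        f = template.fiducials["V1"]
        gt = tpl.ground_truth
        shift = gt.r_peak_ms - template.r_offset
        assert f.neg_trough is not None
        assert (f.neg_end - f.neg_start) == pytest.approx(40.0, abs=3.0)
        assert (f.neg_trough + shift) == pytest.approx(gt.v1_neg_trough_ms, abs=3.0)

    def test_monophasic_v1_has_no_negative_phase(self):
        tpl = make_patient_template(default_morphology(ptfv1=0.0), FS)
        rec = generate_record(tpl, 60.0, NoiseConfig.silent(), seed=0)
        template = delineate_record(apply_filters(rec))
        assert template.fiducials["V1"].neg_trough is None

    def test_entirely_negative_p_wave_spans_onset_to_offset(self):
        t = np.arange(450)
        seg = -0.1 * np.exp(-0.5 * ((t - 300) / 15.0) ** 2)
        res = locate_v1_negative_phase(seg, FS, p_peak=300, offset_limit=430,
                                       baseline=0.0, onset=240)
        assert res is not None
        start, trough, end = res
        assert trough == 300
        # run covers the lobe's 2-sigma support
        assert start == pytest.approx(300 - 30, abs=2)
        assert end == pytest.approx(300 + 30, abs=2)

    def test_no_dip_returns_none(self):
        seg = synthetic_segment([(0.1, 300, 15.0)])
        assert locate_v1_negative_phase(seg, FS, 300, 430, 0.0) is None


class TestAnnotationOverride:
    def test_override_honored_verbatim(self, noiseless_record):
        filt = apply_filters(noiseless_record)
        base = delineate_record(filt)
        f = base.fiducials["II"]
        ov = {"II": AnnotationOverride(onset=f.onset - 7, offset=f.offset + 4)}
        redone = delineate_record(filt, overrides=ov)
        assert redone.fiducials["II"].onset == f.onset - 7
        assert redone.fiducials["II"].offset == f.offset + 4

    def test_overrides_load_from_csv(self, noiseless_record, tmp_path):
        import pandas as pd
        from pwave.delineate import load_overrides_csv

        filt = apply_filters(noiseless_record)
        base = delineate_record(filt)
        f = base.fiducials["II"]
        path = tmp_path / "ov.csv"
        pd.DataFrame([
            {"lead": "II", "onset_ms": (f.onset - 5), "offset_ms": (f.offset + 3)}
        ]).to_csv(path, index=False)
        ov = load_overrides_csv(path, fs=filt.fs)
        redone = delineate_record(filt, overrides=ov)
        assert redone.fiducials["II"].onset == f.onset - 5
        assert redone.fiducials["II"].offset == f.offset + 3

    def test_override_violating_order_rejected(self, noiseless_record):
        filt = apply_filters(noiseless_record)
        base = delineate_record(filt)
        f = base.fiducials["II"]
        bad = {"II": AnnotationOverride(onset=f.p_peak + 5)}
        with pytest.raises(OverrideError):
            delineate_record(filt, overrides=bad)
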