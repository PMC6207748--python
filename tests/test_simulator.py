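"""Generator correctness: schedules, rendering, truth channel, presets."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zfecg
from zfecg.core import ValidationError
from zfecg.simulator import (BeatMorphology, NoiseSpec, PresetError, RhythmSpec,
                             ScenarioSpec, Timecourse, make_beat_schedule,
                             preset, render_record)


class TestTimecourse:
    def test_constant_and_step(self):
        c = Timecourse.constant(148.0)
        assert c.value(0.0) == c.value(1e6) == 148.0
        s = Timecourse.step(60.0, 155.0, 116.0)
        assert s.value(59.9) == 155.0
        assert s.value(60.0) == 116.0

    def test_ramp_interpolates(self):
        r = Timecourse.ramp([(0.0, 100.0), (10.0, 200.0)])
        assert r.value(5.0) == pytest.approx(150.0)
        assert r.value(-1.0) == 100.0
        assert r.value(11.0) == 200.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=1, max_value=300, allow_nan=False),
                    min_size=2, max_size=6, unique=True),
           st.floats(min_value=0, max_value=400))
    def test_ramp_stays_within_knot_value_range(self, times, t):
        times = sorted(times)
        values = [50.0 + 10 * i for i in range(len(times))]
        tc = Timecourse.ramp(list(zip(times, values)))
        assert min(values) <= tc.value(t) <= max(values)

    def test_bad_knots_rejected(self):
        with pytest.raises(ValidationError):
            Timecourse((0.0, 0.0), (1.0, 2.0))


class TestSchedule:
    def test_constant_rate_beat_count_and_spacing(self):
        rhythm = RhythmSpec(hr=Timecourse.constant(148.0), hrv_sd_ms=0.0)
        sched = make_beat_schedule(rhythm, 60.0, seed=0)
        assert abs(len(sched) - 148) <= 1
        np.testing.assert_allclose(np.diff(sched.times), 60.0 / 148.0, rtol=1e-12)

    def test_60_bpm_10_s_gives_10_beats_at_1_s(self):
        rhythm = RhythmSpec(hr=Timecourse.constant(60.0), hrv_sd_ms=0.0)
        sched = make_beat_schedule(rhythm, 10.0, seed=0)
        assert len(sched) == 10
        np.testing.assert_allclose(np.diff(sched.times), 1.0, rtol=1e-12)

    def test_step_changes_mean_rr(self):
        rhythm = RhythmSpec(hr=Timecourse.step(30.0, 155.0, 116.0), hrv_sd_ms=0.0)
        sched = make_beat_schedule(rhythm, 60.0, seed=0)
        rr = np.diff(sched.times) * 1000.0
        mid = np.searchsorted(sched.times[1:], 30.5)
        assert np.mean(rr[:mid - 1]) == pytest.approx(60000.0 / 155.0, abs=0.5)
        assert np.mean(rr[mid + 1:]) == pytest.approx(60000.0 / 116.0, abs=0.5)

    def test_infeasible_rhythm_names_offending_time(self):
        rhythm = RhythmSpec(hr=Timecourse.constant(250.0),
                            qt_ms=Timecourse.constant(230.0), hrv_sd_ms=0.0)
        with pytest.raises(ValidationError, match="t="):
            make_beat_schedule(rhythm, 10.0, seed=0)

    def test_dropped_flags_rate(self):
        rhythm = RhythmSpec(dropped_qrs_prob=0.3)
        sched = make_beat_schedule(rhythm, 300.0, seed=1)
        rate = sched.dropped.mean()
        assert 0.2 < rate < 0.4


class TestRender:
    def test_determinism_bit_identical(self):
        spec = preset("baseline_ab", seed=7, duration_s=20.0)
        rec1, tr1 = render_record(spec)
        rec2, tr2 = render_record(spec)
        assert np.array_equal(rec1.samples, rec2.samples)
        assert tr1.beats == tr2.beats

    def test_zero_noise_argmax_recovers_every_r_peak(self):
        spec = replace(preset("baseline_ab", seed=0, duration_s=30.0),
                       noise=NoiseSpec.none())
        rec, truth = render_record(spec)
        half = int(0.05 * rec.fs)
        for b in truth.beats:
            lo, hi = b.r_peak - half, b.r_peak + half + 1
            assert lo + int(np.argmax(rec.samples[lo:hi])) == b.r_peak

    def test_truth_interval_consistency(self):
        spec = preset("baseline_ab", seed=3, duration_s=30.0)
        _, truth = render_record(spec)
        fs = spec.fs
        for b, (_, row) in zip(truth.beats, truth.intervals.iterrows()):
            qt_from_idx = (b.t_end - b.qrs_onset) * 1000.0 / fs
            assert abs(qt_from_idx - row.qt_ms) <= 1000.0 / fs
            pr_from_idx = (b.qrs_onset - b.p_onset) * 1000.0 / fs
            assert abs(pr_from_idx - row.pr_ms) <= 1000.0 / fs

    def test_polarity_flip_is_exact_negation(self):
        spec = preset("baseline_ab", seed=5, duration_s=15.0)
        rec_up, _ = render_record(spec)
        rec_dn, _ = render_record(
            replace(spec, morphology=replace(spec.morphology, polarity=-1)))
        np.testing.assert_array_equal(rec_dn.samples, -rec_up.samples)

    def test_dropped_beats_render_p_only(self):
        spec = ScenarioSpec(name="hd", duration_s=60.0, seed=3,
                            rhythm=RhythmSpec(dropped_qrs_prob=0.3))
        rec, truth = render_record(spec)
        assert len(truth.p_events) > 0
        # conducted beats all carry the full fiducial set
        for b in truth.beats:
            assert None not in (b.p_onset, b.qrs_onset, b.qrs_end, b.t_end)
        # truth RR spans the dropped gaps, never negative
        rr = truth.intervals["rr_ms"].dropna()
        assert (rr > 0).all()

    def test_render_collision_raises(self):
        # QT so long that the next P would start inside the previous T
        rhythm = RhythmSpec(hr=Timecourse.constant(140.0),
                            qt_ms=Timecourse.constant(380.0), hrv_sd_ms=0.0)
        with pytest.raises(ValidationError):
            render_record(ScenarioSpec(name="x", duration_s=10.0, rhythm=rhythm))

    def test_morphology_validation(self):
        with pytest.raises(ValidationError):
            BeatMorphology(r_amp=0.1, t_amp=0.25)  # R not dominant
        with pytest.raises(ValidationError):
            BeatMorphology(p_width_ms=0.0)


class TestPresets:
    def test_baseline_ab_programs_reference_rhythm(self):
        spec = preset("baseline_ab")
        assert spec.rhythm.hr.value(0) == 148.0
        assert spec.rhythm.pr_ms.value(0) == 62.0
        assert spec.rhythm.qrs_ms.value(0) == 44.0
        assert spec.rhythm.qt_ms.value(0) == 215.0

    def test_baseline_rr469_mean_rr(self):
        spec = preset("baseline_rr469")
        assert 60000.0 / spec.rhythm.hr.value(0) == pytest.approx(469.0)

    def test_amiodarone_qt_constant_481(self):
        spec = preset("amiodarone_qt")
        assert spec.rhythm.qt_ms.value(0) == 481.0
        assert spec.rhythm.qrs_ms.value(0) == 79.0
        assert spec.rhythm.pr_ms.value(0) == 103.0

    def test_unknown_preset_lists_names(self):
        with pytest.raises(PresetError, match="baseline_ab"):
            preset("nonsense")

    def test_isoproterenol_dose_ladder(self):
        from zfecg.simulator import ISOPROTERENOL_FOLDS
        assert ISOPROTERENOL_FOLDS == {0.5: 1.04, 1.0: 1.12, 5.0: 1.14,
                                       7.5: 1.22, 10.0: 1.25}
        spec = preset("isoproterenol_step", dose_um=5.0)
        hr = spec.rhythm.hr
        assert hr.value(100.0) / hr.value(0.0) == pytest.approx(1.14)

    def test_every_preset_renders(self):
        for name in zfecg.list_presets():
            spec = preset(name, seed=0, duration_s=12.0)
            rec, truth = render_record(spec)
            assert len(rec) == int(12.0 * spec.fs)
            assert len(truth.beats) > 0
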