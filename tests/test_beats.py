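"""Detection, segmentation, template averaging and delineation.

The simulator's truth channel is the oracle throughout: every fiducial
the delineator reports is compared against the analytic wave positions
the generator rendered.
"""

from dataclasses import replace

import numpy as np
import pytest

import zfecg
from zfecg.beats import (DetectorConfig, annotate_beats, average_template,
                         delineate, detect_r_peaks, segment_beats)
from zfecg.core import ECGRecord, ValidationError
from zfecg.preprocess import fir_bandpass
from zfecg.simulator import NoiseSpec, preset, render_record

from conftest import SIM_FILTER

FS = 600.0


class TestDetection:
    def test_zero_noise_recovers_truth_exactly(self, clean_baseline):
        record, truth, result = clean_baseline
        det = result.r_peaks
        tru = np.array([b.r_peak for b in truth.beats])
        assert det.size == tru.size
        assert np.max(np.abs(det - tru)) <= 2

    def test_flat_signal_yields_empty_list(self):
        rec = ECGRecord(np.zeros(6000), FS)
        assert detect_r_peaks(rec).size == 0

    def test_refractory_merges_close_spikes(self):
        t = np.arange(6000) / FS
        x = (np.exp(-0.5 * ((t - 1.0) / 0.005) ** 2) +
             np.exp(-0.5 * ((t - 1.05) / 0.005) ** 2))  # 50 ms apart
        det = detect_r_peaks(ECGRecord(x, FS))
        assert det.size == 1

    def test_detected_rr_jitter_small_on_jitter_free_input(self):
        spec = replace(preset("baseline_ab", seed=0, duration_s=30.0),
                       noise=NoiseSpec.none())
        spec = replace(spec, rhythm=replace(spec.rhythm, hrv_sd_ms=0.0))
        rec, _ = render_record(spec)
        res = zfecg.analyze_record(rec, SIM_FILTER)
        rr = np.diff(res.r_peaks)
        assert np.std(rr) < 2.0  # samples

    def test_indices_strictly_increasing_and_spaced(self, baseline_runs):
        cfg = DetectorConfig()
        for _, result in baseline_runs[:3]:
            d = np.diff(result.r_peaks)
            assert (d > 0).all()
            assert d.min() >= cfg.refractory_ms * FS / 1000.0


class TestSegmentation:
    def test_windows_equal_length_and_edge_beats_dropped(self):
        rec = ECGRecord(np.zeros(6000), FS)
        r_peaks = [30, 600, 1200, 1800, 2400, 3000, 3600, 4200, 4800, 5970]
        windows, kept = segment_beats(rec, r_peaks, DetectorConfig())
        # first and last beats are within 200 ms of the edges -> dropped
        assert list(kept) == list(range(1, 9))
        assert windows.shape == (8, 241)

    def test_default_window_length_arithmetic(self):
        rec = ECGRecord(np.zeros(1000), FS)
        windows, _ = segment_beats(rec, [500], DetectorConfig())
        assert windows.shape[1] == 2 * round(0.2 * FS) + 1 == 241


class TestTemplateAveraging:
    def _beat_window(self):
        t = (np.arange(241) - 120) / FS
        return 1.0 * np.exp(-0.5 * (t / 0.008) ** 2) + 0.25 * np.exp(
            -0.5 * ((t - 0.13) / 0.028) ** 2)

    def test_identical_windows_give_smoothed_window(self):
        from zfecg.preprocess import moving_average
        w = self._beat_window()
        cfg = DetectorConfig()
        tmpl = average_template(np.tile(w, (7, 1)), cfg)
        np.testing.assert_allclose(tmpl.values,
                                   moving_average(w, cfg.template_smooth_n))
        np.testing.assert_allclose(tmpl.raw, w)

    def test_single_window_equals_smoothed_window(self):
        w = self._beat_window()
        tmpl = average_template(w[None, :], DetectorConfig())
        assert tmpl.n_beats == 1
        np.testing.assert_allclose(tmpl.raw, w)

    def test_empty_windows_raise(self):
        with pytest.raises(ValidationError, match="no beats"):
            average_template(np.empty((0, 241)), DetectorConfig())

    def test_noise_suppression_scales_with_beat_count(self):
        # law of large numbers: template RMS error ~ 1/sqrt(n)
        w = self._beat_window()
        rng = np.random.default_rng(42)
        errs = []
        for n in (10, 100, 1000):
            windows = w + rng.normal(0, 0.1, size=(n, w.size))
            tmpl = average_template(windows, DetectorConfig(template_smooth_n=1))
            errs.append(np.sqrt(np.mean((tmpl.raw - w) ** 2)))
        assert errs[0] > errs[1] > errs[2]
        # ratio should be near sqrt(10) per decade
        assert errs[0] / errs[1] == pytest.approx(np.sqrt(10), rel=0.4)
        assert errs[1] / errs[2] == pytest.approx(np.sqrt(10), rel=0.4)


class TestDelineation:
    def test_zero_noise_fiducials_within_3_ms_of_truth(self, clean_baseline):
        record, truth, result = clean_baseline
        f = result.fiducials
        # expected offsets (ms relative to R) from the generator's geometry
        expected = {"p_onset": -84.0, "p_end": -54.0, "qrs_onset": -22.0,
                    "qrs_end": 22.0, "t_end": 193.0}
        for name, exp_ms in expected.items():
            got_ms = (getattr(f, name) - f.r) * 1000.0 / record.fs
            assert got_ms == pytest.approx(exp_ms, abs=3.0), name

    def test_absent_p_wave_reported_absent(self):
        spec = replace(preset("baseline_ab", seed=1, duration_s=30.0),
                       noise=NoiseSpec.none())
        spec = replace(spec, morphology=replace(spec.morphology, p_amp=0.0))
        rec, _ = render_record(spec)
        res = zfecg.analyze_record(rec, SIM_FILTER)
        f = res.fiducials
        assert f.p_onset is None and f.p_peak is None and f.p_end is None
        assert f.qrs_onset is not None and f.t_end is not None
        assert np.isnan(res.summary.mean.get("pr_ms", np.nan))

    def test_symmetric_t_wave(self, clean_baseline):
        _, _, result = clean_baseline
        f = result.fiducials
        left = f.t_peak - f.t_start
        right = f.t_end - f.t_peak
        assert left == pytest.approx(right, abs=3.0)  # samples

    def test_r_offset_outside_template_raises(self, clean_baseline):
        _, _, result = clean_baseline
        with pytest.raises(ValidationError):
            delineate(result.template, r_offset=10**6, fs=FS)


class TestAnnotateBeats:
    def test_zero_noise_per_beat_intervals_match_truth(self, clean_baseline):
        record, truth, result = clean_baseline
        tru = truth.intervals
        got = result.intervals
        # align by R time (first/last beats may be clipped)
        tol_ms = 2 * 1000.0 / record.fs
        tru_by_r = {b.r_peak: row for b, (_, row) in
                    zip(truth.beats, tru.iterrows())}
        matched = 0
        for ann, (_, row) in zip(result.annotations, got.iterrows()):
            truth_r = min(tru_by_r, key=lambda r: abs(r - ann.r_peak))
            trow = tru_by_r[truth_r]
            assert abs(row.pr_ms - trow.pr_ms) <= tol_ms + 1e-9
            assert abs(row.qrs_ms - trow.qrs_ms) <= tol_ms + 1e-9
            assert abs(row.qt_ms - trow.qt_ms) <= tol_ms + 1e-9
            matched += 1
        assert matched > 100

    def test_constant_morphology_projection_is_rigid(self, clean_baseline):
        _, _, result = clean_baseline
        offs = {(b.qrs_onset - b.r_peak, b.t_end - b.r_peak, b.p_onset - b.r_peak)
                for b in result.annotations}
        assert len(offs) == 1  # identical offsets on every beat

    def test_edge_clipped_beats_absent(self, clean_baseline):
        record, truth, result = clean_baseline
        # re-annotate with a window too wide for the first/last beats
        from dataclasses import replace as dc_replace
        cfg = DetectorConfig(template_halfwidth_ms=500.0)
        anns = annotate_beats(record, result.r_peaks, result.fiducials, cfg)
        assert 0 < len(anns) < result.r_peaks.size
        assert anns[0].r_peak > result.r_peaks[0]
        assert anns[-1].r_peak < result.r_peaks[-1]

    def test_ordering_invariant_holds_on_noisy_beats(self, baseline_runs):
        # BeatAnnotation construction enforces ordering; reaching here
        # means every projected/refined beat satisfied it
        for _, result in baseline_runs:
            assert len(result.annotations) > 250
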