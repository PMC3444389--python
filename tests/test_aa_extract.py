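"""Beat detection and QRST cancellation against generator ground truth."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from wavectm.aa_extract import BeatSet, build_template, cancel_qrst, detect_r_peaks
from wavectm.preprocess import FilterSpec, apply_filter
from wavectm.signal_io import ECGRecord
from wavectm.synth import SynthConfig, synthesize_ecg


def prepared(record):
    """Lowpass + notch (the pre-cancellation conditioning of the pipeline)."""
    rec = apply_filter(record, FilterSpec("lowpass", 70.0, 5))
    return apply_filter(rec, FilterSpec("notch", 50.0, 35.0))


def bandpower(x, fs, lo, hi):
    f, p = sps.welch(x, fs, nperseg=4096)
    m = (f >= lo) & (f <= hi)
    return np.trapezoid(p[m], f[m])


class TestDetectRPeaks:
    def test_regular_train_detected_within_10ms(self):
        cfg = SynthConfig(seed=4, variability=0.2, rr_cv=0.0, rr_mean_s=0.5)
        record, r_true, _ = synthesize_ecg(cfg)
        beats = detect_r_peaks(prepared(record))
        det = beats.r_peaks / record.fs
        assert len(det) == len(r_true)
        assert np.max(np.abs(det - r_true)) < 0.010

    def test_irregular_train_count_matches_truth(self):
        cfg = SynthConfig(seed=5, variability=0.5, rr_cv=0.24)
        record, r_true, _ = synthesize_ecg(cfg)
        beats = detect_r_peaks(prepared(record))
        assert len(beats) == len(r_true)
        det = beats.r_peaks / record.fs
        for t in r_true:
            assert np.min(np.abs(det - t)) < 0.010

    def test_zero_signal_returns_empty_flagged(self):
        rec = ECGRecord(samples=np.zeros(4096), fs=1024.0)
        beats = detect_r_peaks(rec)
        assert len(beats) == 0
        assert beats.flags

    def test_refractory_enforced(self):
        cfg = SynthConfig(seed=6, variability=0.5)
        record, _, _ = synthesize_ecg(cfg)
        beats = detect_r_peaks(prepared(record))
        assert np.min(np.diff(beats.r_peaks)) >= int(0.200 * record.fs)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(ECGRecord(samples=np.zeros(512), fs=1024.0))


class TestBuildTemplate:
    def _beatset(self, n_beats, fs=1024.0, spacing=800):
        peaks = 400 + spacing * np.arange(n_beats)
        return BeatSet(peaks, fs, window_pre_ms=250, window_post_ms=450)

    def test_identical_beats_recovered_up_to_scale(self, rng):
        beats = self._beatset(6)
        shape = np.sin(np.linspace(0, np.pi, beats.pre_samples + beats.post_samples))
        x = np.zeros(6 * 800 + 800)
        for p in beats.r_peaks:
            x[p - beats.pre_samples : p + beats.post_samples] += 2.5 * shape
        template, gains, _ = build_template(beats, x)
        corr = abs(np.dot(template, shape)) / (np.linalg.norm(template) * np.linalg.norm(shape))
        assert corr > 1 - 1e-10
        assert np.allclose(gains, gains[0])

    def test_noisy_beats_template_correlates_with_clean_shape(self, rng):
        beats = self._beatset(20)
        width = beats.pre_samples + beats.post_samples
        shape = np.sin(np.linspace(0, np.pi, width))
        x = np.zeros(20 * 800 + 800)
        for p in beats.r_peaks:
            x[p - beats.pre_samples : p + beats.post_samples] += shape + rng.normal(0, 0.1, width)
        template, _, _ = build_template(beats, x)
        corr = abs(np.dot(template, shape)) / (np.linalg.norm(template) * np.linalg.norm(shape))
        assert corr > 0.99

    def test_rank1_residual_exceeds_rank2_for_two_morphologies(self, rng):
        beats = self._beatset(10)
        width = beats.pre_samples + beats.post_samples
        s1 = np.sin(np.linspace(0, np.pi, width))
        s2 = np.sin(np.linspace(0, 2 * np.pi, width))
        matrix = np.array([s1 if i % 2 else s2 for i in range(10)])
        u, s, vt = np.linalg.svd(matrix, full_matrices=False)
        res_rank1 = np.linalg.norm(matrix - s[0] * np.outer(u[:, 0], vt[0]))
        res_rank2 = np.linalg.norm(matrix - (matrix @ vt[:2].T) @ vt[:2])
        assert res_rank1 > res_rank2

    def test_insufficient_beats_rejected(self):
        beats = self._beatset(2)
        with pytest.raises(ValueError, match="beats"):
            build_template(beats, np.zeros(3200))


class TestCancelQrst:
    def test_self_cancellation_residual_below_5pct(self):
        # ventricular train only: cancellation should leave almost nothing
        cfg = SynthConfig(seed=2, fwave_amp_mv=0.0, turbulence_frac=0.0,
                          noise_rms_mv=0.0, powerline_amp_mv=0.0, wander_amp_mv=0.0)
        record, _, _ = synthesize_ecg(cfg)
        rec = prepared(record)
        beats = detect_r_peaks(rec)
        aa = cancel_qrst(rec, beats)
        assert np.std(aa.samples) < 0.05 * np.max(np.abs(rec.samples))

    def test_recovered_aa_correlates_with_injected_fwave(self, default_synth_record):
        cfg, record, _, clean = default_synth_record
        rec = prepared(record)
        beats = detect_r_peaks(rec)
        aa = cancel_qrst(rec, beats)
        hp = apply_filter(
            ECGRecord(samples=aa.samples, fs=rec.fs, record_id="aa"),
            FilterSpec("highpass", 0.5, 5),
        )
        assert np.corrcoef(hp.samples, clean.samples)[0, 1] > 0.9

    def test_no_beats_passthrough_flagged(self):
        rec = ECGRecord(samples=np.random.default_rng(0).normal(0, 0.01, 4096), fs=1024.0)
        beats = BeatSet(np.array([], dtype=int), 1024.0)
        aa = cancel_qrst(rec, beats)
        assert np.array_equal(aa.samples, rec.samples)
        assert aa.flags

    def test_samples_outside_windows_unchanged(self, default_synth_record):
        _, record, _, _ = default_synth_record
        rec = prepared(record)
        beats = detect_r_peaks(rec)
        aa = cancel_qrst(rec, beats)
        covered = np.zeros(len(rec.samples), dtype=bool)
        for p in beats.r_peaks:
            lo = max(0, p - beats.pre_samples)
            hi = min(len(covered), p + beats.post_samples)
            covered[lo:hi] = True
        assert np.array_equal(aa.samples[~covered], rec.samples[~covered])

    def test_qrs_band_energy_decreases(self, default_synth_record):
        _, record, _, _ = default_synth_record
        rec = prepared(record)
        beats = detect_r_peaks(rec)
        aa = cancel_qrst(rec, beats)
        before = bandpower(rec.samples, rec.fs, 10, 40)
        after = bandpower(aa.samples, rec.fs, 10, 40)
        assert after < before

    def test_output_length_invariant(self, default_synth_record):
        _, record, _, _ = default_synth_record
        rec = prepared(record)
        aa = cancel_qrst(rec, detect_r_peaks(rec))
        assert len(aa) == len(rec.samples)
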