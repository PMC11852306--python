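import dataclasses

import numpy as np
import pytest

from bpci import preprocess, synth
from bpci.preprocess import (
    DenoiseConfig,
    denoise_signal,
    detect_ppg_fiducials,
    detect_rpeaks,
    highpass_filter,
    preprocess_channel,
    segment_window,
)
from bpci.records_io import AnalysisWindow, InputError, extract_window

FS = 125.0


class TestDenoise:
    def test_constant_maps_to_zero(self):
        out = denoise_signal(np.full(2000, 7.3), FS)
        assert np.abs(out).max() < 1e-9

    @pytest.mark.parametrize("n", [1000, 2500, 2501])
    def test_length_preserved(self, n):
        x = np.random.default_rng(0).normal(size=n)
        assert len(denoise_signal(x, FS)) == n

    def test_improves_correlation_with_clean_tone(self):
        # 3 Hz tone sits in the retained detail bands (the discarded levels
        # only cover < ~0.5 Hz at 125 Hz sampling)
        rng = np.random.default_rng(3)
        t = np.arange(2500) / FS
        clean = np.sin(2 * np.pi * 3.0 * t)
        noisy = clean + rng.normal(0, 0.4, len(t))  # ~5 dB SNR
        out = denoise_signal(noisy, FS)
        r_before = np.corrcoef(noisy, clean)[0, 1]
        r_after = np.corrcoef(out, clean)[0, 1]
        assert r_after > r_before

    def test_output_finite(self):
        x = np.random.default_rng(1).normal(size=2500)
        assert np.all(np.isfinite(denoise_signal(x, FS)))

    def test_too_short_input(self):
        with pytest.raises(InputError):
            denoise_signal(np.zeros(10), FS)

    def test_config_validation(self):
        with pytest.raises(InputError):
            DenoiseConfig(level=5)  # below max discarded detail level


class TestHighpass:
    def test_dc_removed(self):
        out = highpass_filter(np.full(2500, 5.0), FS)
        assert np.abs(out).max() < 1e-6 * 5.0

    def test_stopband_and_passband(self):
        t = np.arange(0, 60, 1 / FS)
        low = np.sin(2 * np.pi * 0.05 * t)
        high = np.sin(2 * np.pi * 5.0 * t)
        mid = slice(len(t) // 4, -len(t) // 4)  # avoid edge transients
        att_low = np.abs(highpass_filter(low, FS)[mid]).max()
        att_high = np.abs(highpass_filter(high, FS)[mid]).max()
        assert 20 * np.log10(att_low) < -20  # > 20 dB attenuation at 0.05 Hz
        assert 20 * np.log10(att_high) > -1  # < 1 dB loss at 5 Hz

    def test_passband_idempotence(self):
        t = np.arange(0, 60, 1 / FS)
        tone = np.sin(2 * np.pi * 5.0 * t)
        once = highpass_filter(tone, FS)
        twice = highpass_filter(once, FS)
        mid = slice(len(t) // 4, -len(t) // 4)  # exclude forward–backward edge transients
        ratio = np.sqrt(np.mean(twice[mid] ** 2) / np.mean(once[mid] ** 2))
        assert abs(ratio - 1) < 0.02

    def test_fc_validation(self):
        with pytest.raises(InputError):
            highpass_filter(np.zeros(100), FS, fc=80.0)


def test_denoise_highpass_idempotent_on_own_output():
    # the discarded levels plus the 0.5 Hz high-pass form a linear band cut
    # whose transition region spans ~0.5–1 Hz; idempotence holds for signals
    # whose content lies in the passband (pulse fundamental above ~1.5 Hz)
    rec = synth.generate_record(
        synth.SubjectProfile(hr_bpm=105, hr_jitter=0.0, noise_sd={}), 20, FS, seed=42
    )
    once = preprocess_channel(rec.ppg, FS)
    twice = preprocess_channel(once, FS)
    rel = np.linalg.norm(twice - once) / np.linalg.norm(once)
    assert rel < 0.05


class TestRpeaks:
    def test_flat_signal_no_peaks(self):
        assert len(detect_rpeaks(np.zeros(2500), FS)) == 0

    def test_clean_record_count_and_accuracy(self, clean_record):
        ecg = preprocess_channel(clean_record.ecg, FS)
        peaks = detect_rpeaks(ecg, FS)
        truth = np.round(clean_record.truth.r_peak_times * FS).astype(int)
        assert abs(len(peaks) - 20) <= 1
        for tp in truth:
            assert np.min(np.abs(peaks - tp)) <= 3

    def test_refractory_merges_close_peaks(self):
        # two spikes 0.2 s apart (inside the 0.3 s refractory) → one detection
        ecg = np.zeros(2500)
        tpl = synth._qrs_template(FS)
        for c in (1000, 1025):
            ecg[c : c + len(tpl)] += tpl
        peaks = detect_rpeaks(ecg, FS)
        close = peaks[(peaks > 900) & (peaks < 1150)]
        assert len(close) == 1

    def test_perfect_recall_precision_across_seeds(self):
        # artifact-free records: every true R matched within ±3 samples
        hits = total_true = total_det = 0
        for seed in range(15):
            prof = synth.SubjectProfile(hr_bpm=55 + 4 * (seed % 10), hr_jitter=0.01, noise_sd={})
            rec = synth.generate_record(prof, 20, FS, seed=seed)
            peaks = detect_rpeaks(preprocess_channel(rec.ecg, FS), FS)
            truth = np.round(rec.truth.r_peak_times * FS).astype(int)
            total_true += len(truth)
            total_det += len(peaks)
            hits += sum(1 for tp in truth if len(peaks) and np.min(np.abs(peaks - tp)) <= 3)
        assert hits == total_true  # recall 1.0
        assert total_det == total_true  # precision 1.0


class TestPpgFiducials:
    def test_single_pulse_one_peak_two_troughs(self):
        t = np.arange(0, 1.2, 1 / FS)
        pulse = np.exp(-((t - 0.5) ** 2) / (2 * 0.05**2))
        fid = detect_ppg_fiducials(pulse, FS)
        assert fid.n_pulses == 1
        assert len(fid.troughs) == 2

    def test_trough_count_matches_truth(self):
        prof = synth.SubjectProfile(hr_bpm=72, hr_jitter=0.0, noise_sd={})
        rec = synth.generate_record(prof, 20, FS, seed=2)
        ppg = preprocess_channel(rec.ppg, FS)
        fid = detect_ppg_fiducials(ppg, FS)
        # interior feet (the last true foot may fall beyond the last detectable pulse)
        assert abs(len(fid.troughs) - len(rec.truth.pulse_foot_times)) <= 1

    def test_fiducial_ordering(self, clean_record):
        ppg = preprocess_channel(clean_record.ppg, FS)
        fid = detect_ppg_fiducials(ppg, FS)
        for i in range(fid.n_pulses):
            assert fid.troughs[i] <= fid.max_slope[i] < fid.peaks[i] < fid.inflection[i] <= fid.troughs[i + 1]

    def test_no_dicrotic_bump_falls_back(self):
        # triangular pulses: zero curvature on the fall, no inflection to find,
        # so the detector falls back to the 66%-decay point and flags it
        x = np.zeros(700)
        for c in (100, 300, 500):
            x[c - 40 : c] = np.linspace(0, 1, 40, endpoint=False)
            x[c : c + 160] = np.linspace(1, 0, 160, endpoint=False)
        fid = detect_ppg_fiducials(x, FS)
        assert fid.fallback.all()

    def test_flat_signal_raises(self):
        with pytest.raises(preprocess.InsufficientBeatsError):
            detect_ppg_fiducials(np.zeros(2500), FS)


class TestSegmentation:
    def _window(self, record):
        return AnalysisWindow(record.record_id, FS, 0.0, 20.0, record.ppg, record.ecg, record.abp)

    def test_segment_length_is_175_samples(self, clean_record):
        ppg = preprocess_channel(clean_record.ppg, FS)
        fid = detect_ppg_fiducials(ppg, FS)
        seg = segment_window(self._window(clean_record), fid)
        assert seg.rejected is None
        assert all(length == 175 for _, length in seg.segments)  # round(1.4 × 125)

    def test_count_capped_at_13(self, clean_record):
        # HR 60 over 20 s gives ~19 beats; the cap keeps 13
        ppg = preprocess_channel(clean_record.ppg, FS)
        fid = detect_ppg_fiducials(ppg, FS)
        seg = segment_window(self._window(clean_record), fid)
        assert seg.count == 13

    def test_too_few_beats_rejected_with_reason(self, clean_record):
        ppg = preprocess_channel(clean_record.ppg, FS)
        fid = detect_ppg_fiducials(ppg, FS)
        short = dataclasses.replace(fid, troughs=fid.troughs[:9], peaks=fid.peaks[:8],
                                    max_slope=fid.max_slope[:8], inflection=fid.inflection[:8],
                                    fallback=fid.fallback[:8])
        seg = segment_window(self._window(clean_record), short)
        assert seg.rejected == "min_segments"
        assert seg.count == 0


def test_preprocessing_preserves_length_and_finiteness(cohort_small):
    for rec in cohort_small[:2]:
        w = extract_window(rec)
        for ch in (w.ppg, w.ecg):
            out = preprocess_channel(ch, w.fs)
            assert len(out) == len(ch)
            assert np.all(np.isfinite(out))
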