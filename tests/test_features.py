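import dataclasses

import numpy as np
import pytest

from bpci import features, preprocess, synth
from bpci.features import (
    FEATURE_NAMES,
    DegeneratePulseError,
    build_dataset,
    reference_bp,
    waveform_params,
    window_features,
)
from bpci.records_io import InputError, extract_window

FS = 125.0


class TestWaveformParams:
    def test_symmetric_triangle(self):
        # 0→1→0 triangle: ps=1, pd=0, pm=0.5 (trapezoid oracle), ppgc=0.5
        up = np.linspace(0, 1, 51)
        pulse = np.concatenate([up, up[-2::-1]])
        wp = waveform_params(pulse, 0, len(pulse) - 1, FS)
        assert wp.ps == 1.0 and wp.pd == 0.0
        assert wp.pm == pytest.approx(0.5)
        assert wp.ppgc == pytest.approx(0.5)

    def test_min_shifted_to_zero(self):
        rng = np.random.default_rng(0)
        pulse = rng.uniform(3, 9, 100)
        wp = waveform_params(pulse, 0, 99, FS)
        assert wp.ppgp.min() == 0.0

    def test_duration(self):
        wp = waveform_params(np.sin(np.linspace(0, np.pi, 126)), 0, 125, FS)
        assert wp.ppgt == pytest.approx(1.0)

    def test_flat_pulse_degenerate(self):
        with pytest.raises(DegeneratePulseError):
            waveform_params(np.ones(50), 0, 49, FS)


def _rows_for(record, abp=True):
    w = extract_window(record, 0.0, 20.0)
    clean = dataclasses.replace(
        w,
        ppg=preprocess.preprocess_channel(w.ppg, FS),
        ecg=preprocess.preprocess_channel(w.ecg, FS),
    )
    fid = preprocess.detect_ppg_fiducials(clean.ppg, FS)
    rp = preprocess.detect_rpeaks(clean.ecg, FS)
    seg = preprocess.segment_window(clean, fid)
    assert seg.rejected is None
    return window_features(clean, fid, rp, seg, abp=w.abp if abp else None)


class TestExtract:
    def test_vector_has_47_features(self, clean_record):
        assert len(FEATURE_NAMES) == 47
        rows = _rows_for(clean_record)
        assert rows
        for r in rows:
            assert len(r.features.values) == 47
            assert np.all(np.isfinite(r.features.values))

    def test_hr_matches_truth(self, clean_record):
        # constant HR 60 with no jitter
        rows = _rows_for(clean_record)
        hr = np.array([r.features.as_dict()["HR"] for r in rows])
        np.testing.assert_allclose(hr, 60.0, atol=0.5)

    def test_pat3_tracks_true_ptt(self):
        # across subjects with different baseline pressure/PTT
        pat3, ptt = [], []
        for seed in range(8):
            sbp0 = 100.0 + 8 * seed
            prof = synth.SubjectProfile(hr_bpm=70, hr_jitter=0.01, sbp0=sbp0,
                                        dbp0=sbp0 - 45, noise_sd={})
            rec = synth.generate_record(prof, 20, FS, seed=seed)
            for r in _rows_for(rec):
                pat3.append(r.features.as_dict()["PAT3"])
            ptt.extend([prof.ptt0] * len(_rows_for(rec)))
        r = np.corrcoef(pat3, ptt)[0, 1]
        assert r >= 0.95

    def test_translation_invariance(self, clean_record):
        # identical fiducials, PPG shifted by a constant: every feature
        # (timing and baseline-shifted amplitude alike) must be unchanged
        w = extract_window(clean_record, 0.0, 20.0)
        ppg = preprocess.preprocess_channel(w.ppg, FS)
        fid = preprocess.detect_ppg_fiducials(ppg, FS)
        i = 3
        kw = dict(
            fs=FS, foot=int(fid.troughs[i]), next_foot=int(fid.troughs[i + 1]),
            peak=int(fid.peaks[i]), max_slope=int(fid.max_slope[i]),
            inflection=int(fid.inflection[i]), r_peak=int(fid.troughs[i]) - 30,
            rr_s=1.0,
        )
        a = features.extract_features(ppg, baseline=float(ppg.min()), **kw)
        b = features.extract_features(ppg + 5.0, baseline=float(ppg.min()) + 5.0, **kw)
        mask = np.array(FEATURE_NAMES) != "MCORR"
        np.testing.assert_allclose(a.values[mask], b.values[mask], rtol=1e-9, atol=1e-9)

    def test_sbp_anticorrelates_with_ptt_on_cohort(self, cohort_small):
        from bpci import pipeline

        ds, _ = pipeline.extract_cohort_features(cohort_small, pipeline.PipelineConfig(), seed=0)
        pat3 = ds.X[:, list(FEATURE_NAMES).index("PAT3")]
        assert np.corrcoef(ds.sbp, pat3)[0, 1] < -0.7


class TestReferenceBp:
    def test_pulse_train_extrema(self):
        t = np.arange(0, 4, 1 / FS)
        unit = 0.5 * (1 + np.sin(2 * np.pi * 1.0 * t - np.pi / 2))  # 0..1 at 1 Hz
        sbp, dbp = reference_bp(100 + 20 * unit, FS)
        assert sbp == pytest.approx(120, abs=0.5)
        assert dbp == pytest.approx(100, abs=0.5)

    def test_constant_abp_rejected(self):
        with pytest.raises(DegeneratePulseError):
            reference_bp(np.full(500, 100.0), FS)

    def test_matches_truth_within_1mmhg(self, clean_record):
        t = clean_record.truth
        fs = FS
        feet = np.round(t.pulse_foot_times * fs).astype(int)
        for k in range(3, 10):
            seg = clean_record.abp[feet[k] : feet[k] + 175]
            sbp, dbp = reference_bp(seg, fs)
            # reference extraction averages the beats whose systolic peak
            # falls inside the segment — select truth beats the same way
            beats = (t.pulse_peak_times >= feet[k] / fs) & (
                t.pulse_peak_times < (feet[k] + 175) / fs
            )
            assert abs(sbp - t.sbp[beats].mean()) < 1.0
            # each inter-peak minimum is the lower of the adjacent beats'
            # diastolic pressures (both beat ends sit at their own DBP)
            idx = np.nonzero(beats)[0]
            if len(idx) > 1:
                dbp_truth = np.mean([min(t.dbp[a], t.dbp[a + 1]) for a in idx[:-1]])
            else:
                dbp_truth = t.dbp[idx[0]]
            assert abs(dbp - dbp_truth) < 1.0


class TestBuildDataset:
    def _rows(self, n=100, subjects=10):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(n):
            feats = features.SegmentFeatures(values=rng.normal(size=47), ptt=0.25)
            rows.append(features.SegmentRow(f"s{i % subjects}", feats, 120.0 + rng.normal(), 80.0))
        return rows

    def test_split_sizes_80_10_10(self):
        ds = build_dataset(self._rows(100), seed=1)
        sizes = {tag: int(np.sum(ds.split == tag)) for tag in ("train", "val", "test")}
        assert sizes == {"train": 80, "val": 10, "test": 10}

    def test_split_deterministic(self):
        a = build_dataset(self._rows(100), seed=5)
        b = build_dataset(self._rows(100), seed=5)
        np.testing.assert_array_equal(a.split, b.split)

    def test_by_subject_partitions_subjects(self):
        ds = build_dataset(self._rows(120, subjects=12), seed=2, mode="by_subject")
        for s in np.unique(ds.subject_id):
            assert len(np.unique(ds.split[ds.subject_id == s])) == 1

    def test_range_filter_applied_first(self):
        rows = self._rows(50)
        rows[0] = dataclasses.replace(rows[0], sbp=220.0)
        ds = build_dataset(rows, seed=0)
        assert len(ds.sbp) == 49
        assert np.all(ds.sbp < 200)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            build_dataset([])

    def test_mcorr_imputation_removes_nans(self):
        rows = self._rows(60)
        j = list(FEATURE_NAMES).index("MCORR")
        for r in rows[:10]:
            r.features.values[j] = np.nan
        ds = build_dataset(rows, seed=3).impute_mcorr()
        assert np.all(np.isfinite(ds.X))

    def test_drop_mcorr_mode(self):
        ds = build_dataset(self._rows(60), seed=3).drop_mcorr()
        assert ds.X.shape[1] == 46
        assert "MCORR" not in ds.feature_names
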