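"""Per-beat feature extraction (47 features) and labeled-dataset assembly.

Each accepted 1.4-s beat segment yields one row: timing features anchored
on the ECG R peak and the PPG pulse landmarks (pulse arrival times PAT1–3,
systolic/diastolic times, heart rate), pulse-morphology features (areas,
widths at six amplitude fractions, derivative landmarks, intensity ratios),
and statistical/spectral descriptors of the pulse. Reference SBP/DBP come
from per-beat extrema of the ABP channel. Amplitude features are computed
on baseline-shifted pulses, making every feature invariant to adding a
constant to the PPG.

PTT is exposed separately (``SegmentFeatures.ptt``): operationally it is
PAT2 minus a configurable pre-ejection-period constant (0 by default — a
cuff-less system has no aortic-valve signal, so the R peak stands in for
ejection and arrival times are transit-time proxies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy import stats

from .preprocess import PpgFiducials
from .records_io import AnalysisWindow, InputError, RangeFilterPolicy, apply_range_filter

__all__ = [
    "FEATURE_NAMES",
    "WaveformParams",
    "waveform_params",
    "SegmentFeatures",
    "extract_features",
    "window_features",
    "reference_bp",
    "LabeledDataset",
    "build_dataset",
    "DegeneratePulseError",
]

_WIDTH_FRACTIONS = (0.10, 0.25, 0.33, 0.50, 0.66, 0.75)

FEATURE_NAMES: Tuple[str, ...] = (
    "ST", "DT", "PIR", "HR", "PAT1", "PAT2", "PAT3", "LASI", "AUI",
    "A1", "A2", "A3", "A4", "IPAR", "PPGk",
    "dPPG_H", "dPPG_W", "ddPPG_PH", "ddPPG_TH", "ddPPG_W", "ddPPG_H",
    "SA", "DA", "areaPPG", "IBI", "MXAP", "MIAP", "MEU", "FHR", "CT",
    "MPSD", "MCORR", "Skew", "Kurt", "Entr",
) + tuple(f"{side}{int(f*100)}" for f in _WIDTH_FRACTIONS for side in ("SW", "DW"))

assert len(FEATURE_NAMES) == 47


class DegeneratePulseError(ValueError):
    pass


@dataclass
class WaveformParams:
    """Single-pulse shape parameters: shifted pulse, duration, mean height."""

    ppgp: np.ndarray  # pulse samples, shifted so min == 0
    ppgt: float  # pulse duration, s
    pm: float  # mean height = trapezoidal area / duration
    ps: float  # max amplitude
    pd: float  # min amplitude (0 after the shift)
    ppgc: float  # normalized mean height (pm − pd)/(ps − pd)


def waveform_params(ppg, pt1: int, pt2: int, fs: float) -> WaveformParams:
    """Shape parameters of the pulse between trough indices pt1 and pt2."""
    if pt2 <= pt1:
        raise InputError("pt1 must precede pt2")
    pulse = np.asarray(ppg, dtype=float)[pt1 : pt2 + 1]
    ppgp = pulse - pulse.min()
    ps, pd = float(ppgp.max()), float(ppgp.min())
    if ps == pd:
        raise DegeneratePulseError("flat pulse: ps == pd")
    ppgt = (pt2 - pt1) / fs
    pm = float(np.trapezoid(ppgp) / (pt2 - pt1))
    return WaveformParams(ppgp, ppgt, pm, ps, pd, (pm - pd) / (ps - pd))


@dataclass
class SegmentFeatures:
    """One beat-segment's feature vector plus bookkeeping."""

    values: np.ndarray  # length 47, order of FEATURE_NAMES
    ptt: float  # PAT2 − pre-ejection constant (not a feature column)
    rejected: Optional[str] = None

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.values))


def _width_times(y: np.ndarray, pk: int, level: float, fs: float) -> Tuple[float, float]:
    """(rising-limb, falling-limb) widths at an amplitude level, in seconds."""
    rise = np.nonzero(y[: pk + 1] >= level)[0]
    sw = (pk - rise[0]) / fs if rise.size else np.nan
    fall = np.nonzero(y[pk:] <= level)[0]
    dw = fall[0] / fs if fall.size else (len(y) - 1 - pk) / fs
    return sw, dw


def extract_features(
    ppg: np.ndarray,
    fs: float,
    foot: int,
    next_foot: int,
    peak: int,
    max_slope: int,
    inflection: int,
    r_peak: Optional[int],
    rr_s: float,
    next_peak: Optional[int] = None,
    abp_segment: Optional[np.ndarray] = None,
    baseline: Optional[float] = None,
    pre_ejection_s: float = 0.0,
) -> SegmentFeatures:
    """Compute the 47 features for one pulse given its fiducials.

    ``baseline`` is the window-level PPG minimum used to shift intensity
    features (PIR, MXAP, MIAP) to a positive scale; it defaults to the
    pulse minimum. ``abp_segment`` enables MCORR (training-time feature);
    absent it is NaN and expected to be imputed downstream.
    """
    vals = {}
    wp = waveform_params(ppg, foot, next_foot, fs)
    y = wp.ppgp
    pk = peak - foot
    ms = max_slope - foot
    infl = min(inflection - foot, len(y) - 1)
    eps = 1e-12

    vals["ST"] = pk / fs
    vals["DT"] = (len(y) - 1 - pk) / fs
    vals["CT"] = wp.ppgt
    vals["HR"] = 60.0 / rr_s if rr_s > 0 else np.nan
    if r_peak is not None:
        vals["PAT1"] = (peak - r_peak) / fs
        vals["PAT2"] = (max_slope - r_peak) / fs
        vals["PAT3"] = (foot - r_peak) / fs
    else:
        vals["PAT1"] = vals["PAT2"] = vals["PAT3"] = np.nan
    vals["IBI"] = (next_peak - peak) / fs if next_peak is not None else rr_s

    shift = (np.asarray(ppg[foot], float) - baseline) if baseline is not None else 0.0
    z_peak = y[pk] + shift
    z_foot = y[0] + shift
    vals["PIR"] = z_peak / max(z_foot, eps)
    vals["MXAP"] = float(z_peak)
    vals["MIAP"] = float(min(y) + shift)

    dt_infl = (infl - pk) / fs
    vals["LASI"] = 1.0 / dt_infl if dt_infl > 0 else np.nan
    vals["AUI"] = y[infl] / max(y[pk], eps)
    vals["MEU"] = (
        np.log(max(y[pk], eps) / max(y[infl], eps)) / dt_infl if dt_infl > 0 else np.nan
    )

    a1 = float(np.trapezoid(y[: ms + 1]) / fs) if ms > 0 else 0.0
    a2 = float(np.trapezoid(y[ms : pk + 1]) / fs) if pk > ms else 0.0
    a3 = float(np.trapezoid(y[pk : infl + 1]) / fs) if infl > pk else 0.0
    a4 = float(np.trapezoid(y[infl:]) / fs) if infl < len(y) - 1 else 0.0
    vals["A1"], vals["A2"], vals["A3"], vals["A4"] = a1, a2, a3, a4
    vals["IPAR"] = a4 / max(a1 + a2 + a3, eps)
    vals["SA"] = float(np.trapezoid(y[: pk + 1]) / fs)
    vals["DA"] = float(np.trapezoid(y[pk:]) / fs)
    vals["areaPPG"] = vals["SA"] + vals["DA"]
    vals["PPGk"] = wp.ppgc

    d1 = np.diff(y) * fs
    vals["dPPG_H"] = float(d1.max()) if d1.size else np.nan
    vals["dPPG_W"] = float(np.sum(d1 >= d1.max() / 2) / fs) if d1.size else np.nan
    d2 = np.diff(y, 2) * fs * fs
    if d2.size:
        vals["ddPPG_PH"] = float(d2.max())
        vals["ddPPG_TH"] = float(d2.min())
        vals["ddPPG_H"] = vals["ddPPG_PH"] - vals["ddPPG_TH"]
        vals["ddPPG_W"] = float(np.sum(d2 >= d2.max() / 2) / fs)
    else:
        vals["ddPPG_PH"] = vals["ddPPG_TH"] = vals["ddPPG_H"] = vals["ddPPG_W"] = np.nan

    freqs, psd = sps.periodogram(y - y.mean(), fs=fs)
    if len(psd) > 1:
        vals["MPSD"] = float(psd[1:].max())
        vals["FHR"] = float(freqs[1:][np.argmax(psd[1:])])
    else:
        vals["MPSD"] = vals["FHR"] = np.nan

    if abp_segment is not None and len(abp_segment) >= len(y):
        a = np.asarray(abp_segment, float)
        ac = a - a.mean()
        yc = y - y.mean()
        cc = np.correlate(ac, yc, mode="full")
        den = np.sqrt(np.sum(ac**2) * np.sum(yc**2))
        vals["MCORR"] = float(cc.max() / den) if den > 0 else np.nan
    else:
        vals["MCORR"] = np.nan

    vals["Skew"] = float(stats.skew(y))
    vals["Kurt"] = float(stats.kurtosis(y, fisher=False))
    hist, _ = np.histogram(y / max(y.max(), eps), bins=16, range=(0, 1))
    p = hist / max(hist.sum(), 1)
    p = p[p > 0]
    vals["Entr"] = float(-np.sum(p * np.log(p)))

    for f in _WIDTH_FRACTIONS:
        sw, dw = _width_times(y, pk, f * y[pk], fs)
        vals[f"SW{int(f*100)}"] = sw
        vals[f"DW{int(f*100)}"] = dw

    vec = np.array([vals[n] for n in FEATURE_NAMES], dtype=float)
    ptt = vals["PAT2"] - pre_ejection_s if np.isfinite(vals["PAT2"]) else np.nan
    rejected = None
    if not np.all(np.isfinite(vec[np.array(FEATURE_NAMES) != "MCORR"])):
        rejected = "missing_fiducial"
    return SegmentFeatures(values=vec, ptt=ptt, rejected=rejected)


def reference_bp(abp_segment, fs: float) -> Tuple[float, float]:
    """Reference (SBP, DBP) = mean per-beat maxima / minima of the ABP slice."""
    a = np.asarray(abp_segment, dtype=float)
    span = np.ptp(a)
    if span < 1.0:  # < 1 mmHg of modulation: no beat present
        raise DegeneratePulseError("no detectable beat in ABP segment")
    peaks, _ = sps.find_peaks(a, distance=int(0.3 * fs), prominence=0.25 * span)
    if peaks.size == 0:
        raise DegeneratePulseError("no detectable beat in ABP segment")
    sbp = float(np.mean(a[peaks]))
    if peaks.size == 1:
        dbp = float(a.min())
    else:
        troughs = [a[p0:p1].min() for p0, p1 in zip(peaks[:-1], peaks[1:])]
        dbp = float(np.mean(troughs))
    return sbp, dbp


@dataclass
class SegmentRow:
    subject_id: str
    features: SegmentFeatures
    sbp: float
    dbp: float


def window_features(
    window: AnalysisWindow,
    fiducials: PpgFiducials,
    rpeaks: np.ndarray,
    segmentation,
    abp: Optional[np.ndarray] = None,
    pre_ejection_s: float = 0.0,
) -> List[SegmentRow]:
    """Extract one feature row per accepted beat segment of a window.

    ``abp`` is the raw (un-highpassed) ABP slice of the window, used for the
    reference labels and MCORR; segments without a usable R peak or with a
    degenerate pulse are skipped.
    """
    rows: List[SegmentRow] = []
    rpeaks = np.asarray(rpeaks, dtype=int)
    baseline = float(np.min(window.ppg))
    rr_all = np.diff(rpeaks) / window.fs if len(rpeaks) > 1 else np.array([0.8])
    med_rr = float(np.median(rr_all))
    seg_starts = {s for s, _ in segmentation.segments}
    feet = fiducials.troughs
    for i in range(fiducials.n_pulses):
        if int(feet[i]) not in seg_starts:
            continue
        foot, nxt = int(feet[i]), int(feet[i + 1])
        pk = int(fiducials.peaks[i])
        before = rpeaks[rpeaks < pk]
        if before.size == 0:
            continue
        r = int(before[-1])
        if (pk - r) / window.fs > 1.5 * med_rr:
            continue
        after = rpeaks[rpeaks > r]
        rr = (after[0] - r) / window.fs if after.size else med_rr
        nxt_pk = int(fiducials.peaks[i + 1]) if i + 1 < fiducials.n_pulses else None
        seg_start, seg_len = foot, segmentation.segments[0][1]
        abp_seg = abp[seg_start : seg_start + seg_len] if abp is not None else None
        try:
            feats = extract_features(
                window.ppg, window.fs, foot, nxt, pk,
                int(fiducials.max_slope[i]), int(fiducials.inflection[i]),
                r, rr, next_peak=nxt_pk, abp_segment=abp_seg,
                baseline=baseline, pre_ejection_s=pre_ejection_s,
            )
            if abp_seg is None:
                raise DegeneratePulseError("no ABP for labels")
            sbp, dbp = reference_bp(abp_seg, window.fs)
        except DegeneratePulseError:
            continue
        if feats.rejected:
            continue
        rows.append(SegmentRow(window.record_id, feats, sbp, dbp))
    return rows


@dataclass
class LabeledDataset:
    """Feature matrix with SBP/DBP targets, subject ids and split tags."""

    X: np.ndarray  # (n, 47)
    sbp: np.ndarray
    dbp: np.ndarray
    subject_id: np.ndarray
    split: np.ndarray  # 'train' | 'val' | 'test'
    feature_names: Tuple[str, ...] = FEATURE_NAMES

    def rows(self, tag: str) -> np.ndarray:
        return np.nonzero(self.split == tag)[0]

    def impute_mcorr(self) -> "LabeledDataset":
        """Replace NaN MCORR entries by the training-split median."""
        j = self.feature_names.index("MCORR")
        col = self.X[:, j]
        train_vals = col[(self.split == "train") & np.isfinite(col)]
        med = float(np.median(train_vals)) if train_vals.size else 0.0
        X = self.X.copy()
        X[~np.isfinite(col), j] = med
        return LabeledDataset(X, self.sbp, self.dbp, self.subject_id, self.split, self.feature_names)

    def drop_mcorr(self) -> "LabeledDataset":
        """Remove the ABP-dependent MCORR column (leakage-free mode)."""
        j = self.feature_names.index("MCORR")
        keep = [i for i in range(self.X.shape[1]) if i != j]
        names = tuple(n for n in self.feature_names if n != "MCORR")
        return LabeledDataset(self.X[:, keep], self.sbp, self.dbp, self.subject_id, self.split, names)


def assign_splits(
    subject_id: np.ndarray,
    n: int,
    split: Tuple[float, float, float],
    seed: int,
    mode: str,
) -> np.ndarray:
    if abs(sum(split) - 1.0) > 1e-9:
        raise InputError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    tags = np.empty(n, dtype=object)
    if mode == "by_sample":
        order = rng.permutation(n)
        b1 = int(round(split[0] * n))
        b2 = int(round((split[0] + split[1]) * n))
        tags[order[:b1]] = "train"
        tags[order[b1:b2]] = "val"
        tags[order[b2:]] = "test"
    elif mode == "by_subject":
        subjects = rng.permutation(np.unique(subject_id))
        counts = {s: int(np.sum(subject_id == s)) for s in subjects}
        cum, assign = 0, {}
        for s in subjects:
            frac = cum / n
            assign[s] = "train" if frac < split[0] else ("val" if frac < split[0] + split[1] else "test")
            cum += counts[s]
        tags[:] = [assign[s] for s in subject_id]
    else:
        raise InputError(f"unknown split mode {mode!r}")
    return tags.astype(str)


def build_dataset(
    rows: Sequence[SegmentRow],
    split: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    mode: str = "by_sample",
    range_policy: RangeFilterPolicy = RangeFilterPolicy(),
) -> LabeledDataset:
    """Assemble segment rows into a labeled dataset with an 80/10/10 split.

    The BP-range exclusion filter is applied to the labels first; the split
    is deterministic for a fixed seed, either per-row (``by_sample``) or
    keeping each subject's rows in one split (``by_subject``).
    """
    if not rows:
        raise InputError("no feature rows to assemble")
    kept, _ = apply_range_filter(list(rows), range_policy)
    if not kept:
        raise InputError("range filter removed every row")
    X = np.vstack([r.features.values for r in kept])
    sbp = np.array([r.sbp for r in kept])
    dbp = np.array([r.dbp for r in kept])
    sid = np.array([r.subject_id for r in kept])
    tags = assign_splits(sid, len(kept), split, seed, mode)
    return LabeledDataset(X, sbp, dbp, sid, tags)
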