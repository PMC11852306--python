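"""Signal-quality index: three physiological rules + adaptive template matching.

A 20-s window is labelled ``trusted`` only if (1) the extrapolated heart
rate lies in 40–180 bpm, (2) no inter-peak gap exceeds 3 s, and (3) the
max/min beat-interval ratio is below 2.2 — each checked on both the PPG and
ECG peak trains — and the mean correlation of individual beats with their
average beat template (averaged over the PPG-pulse and QRS correlations)
reaches the correlation threshold. The threshold default of 0.8 is a
package choice: it is the one substantive constant the quality-index
recipe leaves unstated, and it is exposed in the config for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .preprocess import InsufficientBeatsError, detect_ppg_fiducials, detect_rpeaks
from .records_io import AnalysisWindow

__all__ = ["SqiRules", "SqiResult", "check_rules", "template_correlation", "classify_segment"]

DEFAULT_CORR_THRESHOLD = 0.8


@dataclass(frozen=True)
class SqiRules:
    hr_lo: float = 40.0  # bpm
    hr_hi: float = 180.0  # bpm
    max_gap: float = 3.0  # s
    interval_ratio_max: float = 2.2  # unitless max/min beat-interval ratio

    def __post_init__(self) -> None:
        assert self.hr_lo < self.hr_hi and self.max_gap > 0 and self.interval_ratio_max > 1


@dataclass
class SqiResult:
    rule1_pass: bool
    rule2_pass: bool
    rule3_pass: bool
    mean_template_corr: Optional[float]  # None when rules short-circuited
    label: str  # "trusted" | "untrusted"
    reason: Optional[str] = None

    @property
    def trusted(self) -> bool:
        return self.label == "trusted"


def check_rules(
    peak_indices: np.ndarray,
    fs: float,
    window_s: float,
    rules: SqiRules = SqiRules(),
) -> Tuple[bool, bool, bool]:
    """Evaluate the three rules on one channel's peak train.

    Rule 1: beat count extrapolated to 60 s within [hr_lo, hr_hi];
    rule 2: max inter-peak interval ≤ max_gap;
    rule 3: max/min interval ratio < interval_ratio_max.
    Fewer than 2 peaks fails all three.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    peaks = np.asarray(peak_indices)
    if len(peaks) < 2:
        return (False, False, False)
    hr = len(peaks) * 60.0 / window_s
    intervals = np.diff(peaks) / fs
    rule1 = rules.hr_lo <= hr <= rules.hr_hi
    rule2 = float(np.max(intervals)) <= rules.max_gap
    rule3 = float(np.max(intervals) / np.min(intervals)) < rules.interval_ratio_max
    return (bool(rule1), bool(rule2), bool(rule3))


def template_correlation(signal, peak_indices, fs: float) -> float:
    """Mean Pearson correlation of each beat with the average-beat template.

    Beats are windows of width equal to the median beat interval, centered
    on each peak; beats truncated by the signal edges are excluded rather
    than zero-padded.
    """
    x = np.asarray(signal, dtype=float)
    peaks = np.asarray(peak_indices, dtype=int)
    if len(peaks) < 2:
        raise InsufficientBeatsError("template matching needs ≥ 2 peaks")
    width = int(np.median(np.diff(peaks)))
    half = width // 2
    beats = [
        x[p - half : p - half + width]
        for p in peaks
        if p - half >= 0 and p - half + width <= len(x)
    ]
    if not beats:
        raise InsufficientBeatsError("all beats are edge-truncated")
    B = np.vstack(beats)
    template = B.mean(axis=0)
    tc = template - template.mean()
    tden = np.sqrt(np.sum(tc**2))
    corrs = []
    for b in B:
        bc = b - b.mean()
        den = np.sqrt(np.sum(bc**2)) * tden
        corrs.append(float(np.dot(bc, tc) / den) if den > 0 else 0.0)
    return float(np.mean(corrs))


def classify_segment(
    window: AnalysisWindow,
    rules: SqiRules = SqiRules(),
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
) -> SqiResult:
    """Label a preprocessed window trusted/untrusted.

    Rules are checked on both channels' peak trains (strict: both must
    pass); any rule failure short-circuits before template matching. The
    final correlation is the mean of the PPG-pulse and QRS template
    correlations.
    """
    rpeaks = detect_rpeaks(window.ecg, window.fs)
    try:
        fid = detect_ppg_fiducials(window.ppg, window.fs)
        ppg_peaks = fid.peaks
    except InsufficientBeatsError:
        ppg_peaks = np.array([], dtype=int)

    if len(rpeaks) < 2 or len(ppg_peaks) < 2:
        return SqiResult(False, False, False, None, "untrusted", reason="insufficient_peaks")

    r_ecg = check_rules(rpeaks, window.fs, window.duration_s, rules)
    r_ppg = check_rules(ppg_peaks, window.fs, window.duration_s, rules)
    joint = tuple(a and b for a, b in zip(r_ecg, r_ppg))
    if not all(joint):
        failed = [f"rule{i+1}" for i, ok in enumerate(joint) if not ok]
        return SqiResult(*joint, None, "untrusted", reason=",".join(failed))

    try:
        c_ppg = template_correlation(window.ppg, ppg_peaks, window.fs)
        c_qrs = template_correlation(window.ecg, rpeaks, window.fs)
    except InsufficientBeatsError:
        return SqiResult(*joint, None, "untrusted", reason="template_undefined")
    corr = 0.5 * (c_ppg + c_qrs)
    label = "trusted" if corr >= corr_threshold else "untrusted"
    return SqiResult(*joint, corr, label, reason=None if label == "trusted" else "low_corr")
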