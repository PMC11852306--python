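"""End-to-end orchestration: records → features → WFD → GPR → CIs → grading.

This is the whole method in one call: preprocess each record's analysis
window, gate it through the signal-quality index, extract per-beat features
and ABP reference labels, assemble the 80/10/10 dataset, run the weighted
feature decision on the training split, fit one Gaussian process per target
(SBP, DBP), evaluate on the held-out test split and construct per-subject
confidence intervals from each subject's segment-level estimates.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import evaluation, features, gba, gpr, preprocess, selection, sqi, uncertainty
from .records_io import AnalysisWindow, SignalRecord, extract_window

log = logging.getLogger("bpci")

__all__ = ["PipelineConfig", "TargetResult", "PipelineResult", "extract_cohort_features", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    window_start_s: float = 60.0
    window_duration_s: float = 20.0
    denoise: preprocess.DenoiseConfig = preprocess.DenoiseConfig()
    sqi_rules: sqi.SqiRules = sqi.SqiRules()
    corr_threshold: float = sqi.DEFAULT_CORR_THRESHOLD
    split: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    split_mode: str = "by_sample"
    use_wfd: bool = True
    use_mcorr: bool = True  # ABP cross-correlation feature (training-time)
    gba_cfg: gba.GBAConfig = gba.GBAConfig()
    gpr_cfg: gpr.GprConfig = gpr.GprConfig(restarts=3)
    wfd_folds: int = 5
    ci_level: float = 0.95
    ci_B: int = 1000


@dataclass
class TargetResult:
    """Model, predictions and grading for one target (sbp or dbp)."""

    target: str
    chosen_features: np.ndarray
    wfd: Optional[selection.WfdResult]
    model: gpr.GprModel
    test_pred: np.ndarray
    test_ref: np.ndarray
    test_sd: np.ndarray
    stats: evaluation.ErrorStats
    aami_pass: bool
    bhs: evaluation.BhsGrade
    subject_cis: Dict[str, Dict[str, uncertainty.IntervalEstimate]]
    pred_all: np.ndarray  # predictions for every dataset row
    sd_all: np.ndarray


@dataclass
class PipelineResult:
    dataset: features.LabeledDataset
    sbp: TargetResult
    dbp: TargetResult
    n_windows_rejected: int = 0
    rejection_reasons: Dict[str, int] = field(default_factory=dict)


def process_record(
    record: SignalRecord, cfg: PipelineConfig = PipelineConfig()
) -> Tuple[Optional[List[features.SegmentRow]], Optional[str]]:
    """One record through stages 1–2, SQI and feature extraction.

    Returns (rows, None) on success or (None, reason) when the window is
    rejected (untrusted quality, too few beats, too short).
    """
    try:
        window = extract_window(record, cfg.window_start_s, cfg.window_duration_s)
    except Exception:
        return None, "too_short"
    clean = dataclasses.replace(
        window,
        ppg=preprocess.preprocess_channel(window.ppg, window.fs, cfg.denoise),
        ecg=preprocess.preprocess_channel(window.ecg, window.fs, cfg.denoise),
    )
    result = sqi.classify_segment(clean, cfg.sqi_rules, cfg.corr_threshold)
    if not result.trusted:
        return None, f"sqi:{result.reason}"
    rpeaks = preprocess.detect_rpeaks(clean.ecg, clean.fs)
    try:
        fid = preprocess.detect_ppg_fiducials(clean.ppg, clean.fs)
    except preprocess.InsufficientBeatsError:
        return None, "insufficient_beats"
    seg = preprocess.segment_window(clean, fid)
    if seg.rejected:
        return None, seg.rejected
    # raw (un-highpassed) ABP: needed for reference labels regardless of MCORR
    rows = features.window_features(clean, fid, rpeaks, seg, abp=window.abp)
    if not rows:
        return None, "no_feature_rows"
    return rows, None


def extract_cohort_features(
    records: Sequence[SignalRecord], cfg: PipelineConfig = PipelineConfig(), seed: int = 0
) -> Tuple[features.LabeledDataset, Dict[str, int]]:
    """Run stages 1–3 over a cohort and assemble the labeled dataset."""
    all_rows: List[features.SegmentRow] = []
    reasons: Dict[str, int] = {}
    for rec in records:
        rows, reason = process_record(rec, cfg)
        if rows is None:
            reasons[reason] = reasons.get(reason, 0) + 1
            log.info("record %s rejected: %s", rec.record_id, reason)
            continue
        all_rows.extend(rows)
    ds = features.build_dataset(all_rows, cfg.split, seed=seed, mode=cfg.split_mode)
    ds = ds.impute_mcorr() if cfg.use_mcorr else ds.drop_mcorr()
    return ds, reasons


def _fit_target(
    ds: features.LabeledDataset, target: str, cfg: PipelineConfig, seed: int
) -> TargetResult:
    y_all = ds.sbp if target == "sbp" else ds.dbp
    tr = ds.rows("train")
    te = ds.rows("test")
    Xtr, ytr = ds.X[tr], y_all[tr]

    wfd_res = None
    if cfg.use_wfd:
        wfd_res = selection.wfd_select(
            Xtr, ytr, folds=cfg.wfd_folds, gba_cfg=cfg.gba_cfg, seed=seed
        )
        cols = wfd_res.chosen_features
    else:
        cols = np.arange(ds.X.shape[1])

    model = gpr.fit(Xtr[:, cols], ytr, cfg.gpr_cfg, seed=seed)
    pred_all, sd_all, _, _ = gpr.predict(model, ds.X[:, cols], cfg.ci_level)
    test_pred, test_sd = pred_all[te], sd_all[te]
    stats = evaluation.error_stats(test_pred, y_all[te])
    aami_pass, _ = evaluation.aami_check(stats)
    bhs = evaluation.bhs_grade(test_pred - y_all[te])

    ests = {}
    sds = {}
    for subj in np.unique(ds.subject_id):
        m = ds.subject_id == subj
        ests[subj] = pred_all[m]
        sds[subj] = sd_all[m]
    cis = uncertainty.subject_cis(
        ests, predictive_sd_by_subject=sds, level=cfg.ci_level, B=cfg.ci_B, seed=seed
    )
    return TargetResult(
        target=target, chosen_features=np.asarray(cols), wfd=wfd_res, model=model,
        test_pred=test_pred, test_ref=y_all[te], test_sd=test_sd, stats=stats,
        aami_pass=aami_pass, bhs=bhs, subject_cis=cis, pred_all=pred_all, sd_all=sd_all,
    )


def run_pipeline(
    records: Sequence[SignalRecord], cfg: PipelineConfig = PipelineConfig(), seed: int = 0
) -> PipelineResult:
    """Full method over a cohort of records; see module docstring."""
    ds, reasons = extract_cohort_features(records, cfg, seed=seed)
    sbp_res = _fit_target(ds, "sbp", cfg, seed)
    dbp_res = _fit_target(ds, "dbp", cfg, seed + 1)
    return PipelineResult(
        dataset=ds, sbp=sbp_res, dbp=dbp_res,
        n_windows_rejected=sum(reasons.values()), rejection_reasons=reasons,
    )
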