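"""Signal record data model, file I/O, analysis-window extraction, BP-range filter.

A :class:`SignalRecord` holds synchronized PPG, ECG and arterial BP (ABP)
channels at a common sampling rate (125 Hz by convention for the bedside
monitor waveforms this package targets). Records round-trip through a simple
CSV dialect (``time,ppg,ecg,abp`` header, UTF-8, '.' decimals) or an NPZ
container; WFDB records can be adapted through the same contract if the
``wfdb`` package is installed (optional — nothing here imports it eagerly).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger("bpci")

CHANNELS = ("ppg", "ecg", "abp")


class FormatError(ValueError):
    """A file is structurally wrong (missing channel, bad header)."""


class InputError(ValueError):
    """An input violates a precondition (empty file, bad lengths)."""


@dataclass
class GroundTruth:
    """Known per-beat truth carried by synthetic records.

    Times in seconds, pressures in mmHg; times are strictly increasing and
    SBP > DBP beat-wise.
    """

    r_peak_times: np.ndarray
    pulse_foot_times: np.ndarray
    pulse_peak_times: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    ptt: np.ndarray

    def __post_init__(self) -> None:
        for name in ("r_peak_times", "pulse_foot_times", "pulse_peak_times"):
            t = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, t)
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise InputError(f"{name} must be strictly increasing")
        for name in ("sbp", "dbp", "ptt"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.ptt <= 0):
            raise InputError("PTT must be positive")
        if np.any(self.sbp <= self.dbp):
            raise InputError("SBP must exceed DBP beat-wise")


@dataclass
class SignalRecord:
    """Synchronized three-channel waveform record."""

    record_id: str
    fs: float
    ppg: np.ndarray
    ecg: np.ndarray
    abp: np.ndarray
    meta: dict = field(default_factory=dict)
    truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InputError("fs must be positive")
        for ch in CHANNELS:
            object.__setattr__(self, ch, np.asarray(getattr(self, ch), dtype=float))
        n = len(self.ppg)
        if not (len(self.ecg) == n and len(self.abp) == n):
            raise InputError("all channels must have the same length")

    @property
    def n_samples(self) -> int:
        return len(self.ppg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def drop_nan(self) -> "SignalRecord":
        """Drop any sample index that is NaN in *any* channel (keeps alignment)."""
        stacked = np.vstack([self.ppg, self.ecg, self.abp])
        keep = np.all(np.isfinite(stacked), axis=0)
        dropped = int(np.sum(~keep))
        if dropped:
            log.info("record %s: dropped %d NaN samples", self.record_id, dropped)
        return dataclasses.replace(
            self, ppg=self.ppg[keep], ecg=self.ecg[keep], abp=self.abp[keep]
        )


@dataclass
class AnalysisWindow:
    """A fixed-duration slice of a record (default 20 s starting at 60 s)."""

    record_id: str
    fs: float
    start_s: float
    duration_s: float
    ppg: np.ndarray
    ecg: np.ndarray
    abp: np.ndarray
    truth: Optional[GroundTruth] = None

    @property
    def n_samples(self) -> int:
        return len(self.ppg)


@dataclass(frozen=True)
class RangeFilterPolicy:
    """Inclusive exclusion bounds for outlier reference pressures (mmHg)."""

    sbp_hi: float = 200.0
    sbp_lo: float = 70.0
    dbp_hi: float = 150.0
    dbp_lo: float = 40.0

    def __post_init__(self) -> None:
        if not (self.sbp_hi > self.sbp_lo and self.dbp_hi > self.dbp_lo):
            raise InputError("range filter bounds require hi > lo")

    def keeps(self, sbp: float, dbp: float) -> bool:
        return (
            self.sbp_lo < sbp < self.sbp_hi and self.dbp_lo < dbp < self.dbp_hi
        )


# ---------------------------------------------------------------------------
# File I/O


def load_record(path, format: str = None, record_id: str = None) -> SignalRecord:
    """Read a record from ``csv``, ``npz`` or ``wfdb`` storage.

    NaN samples are removed consistently across channels so beat alignment
    is preserved. Format is inferred from the suffix when not given.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format is None:
        format = {".csv": "csv", ".npz": "npz"}.get(path.suffix.lower(), "wfdb")
    rid = record_id or path.stem
    if format == "csv":
        rec = _load_csv(path, rid)
    elif format == "npz":
        rec = _load_npz(path, rid)
    elif format == "wfdb":
        rec = _load_wfdb(path, rid)
    else:
        raise FormatError(f"unknown format {format!r}")
    return rec.drop_nan()


def _load_csv(path: Path, rid: str) -> SignalRecord:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise InputError(f"empty record file: {path}")
    for ch in CHANNELS:
        if ch not in df.columns:
            raise FormatError(f"missing channel column {ch!r} in {path}")
    if "time" in df.columns and len(df) > 1:
        dt = np.median(np.diff(df["time"].to_numpy()))
        fs = 1.0 / dt
    else:
        fs = 125.0
    return SignalRecord(rid, fs, df["ppg"].to_numpy(), df["ecg"].to_numpy(), df["abp"].to_numpy())


def _load_npz(path: Path, rid: str) -> SignalRecord:
    with np.load(path) as z:
        for ch in CHANNELS:
            if ch not in z:
                raise FormatError(f"missing channel array {ch!r} in {path}")
        fs = float(z["fs"]) if "fs" in z else 125.0
        if z["ppg"].size == 0:
            raise InputError(f"empty record file: {path}")
        return SignalRecord(rid, fs, z["ppg"], z["ecg"], z["abp"])


def _load_wfdb(path: Path, rid: str):  # pragma: no cover - optional adapter
    try:
        import wfdb
    except ImportError as e:
        raise FormatError("wfdb package not installed; use csv or npz") from e
    rec = wfdb.rdrecord(str(path.with_suffix("")))
    names = [s.lower() for s in rec.sig_name]
    cols = {}
    for ch, aliases in {"ppg": ("pleth", "ppg"), "ecg": ("ii", "ecg", "i"), "abp": ("abp", "art")}.items():
        idx = next((i for i, n in enumerate(names) if any(a in n for a in aliases)), None)
        if idx is None:
            raise FormatError(f"missing channel {ch!r} in WFDB record {path}")
        cols[ch] = rec.p_signal[:, idx]
    return SignalRecord(rid, float(rec.fs), cols["ppg"], cols["ecg"], cols["abp"])


def save_record(record: SignalRecord, path, format: str = None) -> None:
    """Write a record to CSV or NPZ; inverse of :func:`load_record`."""
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix.lower() == ".npz" else "csv"
    if format == "csv":
        import pandas as pd

        t = np.arange(record.n_samples) / record.fs
        # default float formatting is the shortest round-trip repr
        pd.DataFrame(
            {"time": t, "ppg": record.ppg, "ecg": record.ecg, "abp": record.abp}
        ).to_csv(path, index=False)
    elif format == "npz":
        np.savez(
            path, fs=record.fs, ppg=record.ppg, ecg=record.ecg, abp=record.abp
        )
    else:
        raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Windowing and range filter


def extract_window(
    record: SignalRecord, start_s: float = 60.0, duration_s: float = 20.0
) -> AnalysisWindow:
    """Extract the analysis window (default: 20 s starting 60 s in).

    At 125 Hz the default yields exactly 2500 samples per channel.
    """
    if duration_s <= 0:
        raise InputError("duration_s must be positive")
    n = int(round(duration_s * record.fs))
    i0 = int(round(start_s * record.fs))
    if i0 < 0 or i0 + n > record.n_samples:
        raise InputError(
            f"record {record.record_id} too short: need {(i0 + n)} samples, "
            f"have {record.n_samples}"
        )
    truth = None
    if record.truth is not None:
        truth = _slice_truth(record.truth, start_s, start_s + duration_s)
    return AnalysisWindow(
        record.record_id,
        record.fs,
        start_s,
        duration_s,
        record.ppg[i0 : i0 + n],
        record.ecg[i0 : i0 + n],
        record.abp[i0 : i0 + n],
        truth=truth,
    )


def _slice_truth(truth: GroundTruth, t0: float, t1: float) -> GroundTruth:
    # beats indexed by foot time; keep beats whose foot falls inside the window,
    # re-referenced to the window start
    keep = (truth.pulse_foot_times >= t0) & (truth.pulse_foot_times < t1)
    rk = (truth.r_peak_times >= t0) & (truth.r_peak_times < t1)
    pk = (truth.pulse_peak_times >= t0) & (truth.pulse_peak_times < t1)
    return GroundTruth(
        truth.r_peak_times[rk] - t0,
        truth.pulse_foot_times[keep] - t0,
        truth.pulse_peak_times[pk] - t0,
        truth.sbp[keep],
        truth.dbp[keep],
        truth.ptt[keep],
    )


def apply_range_filter(
    items: Sequence, policy: RangeFilterPolicy = RangeFilterPolicy()
):
    """Drop items whose (SBP, DBP) labels fall on or outside the exclusion
    bounds (SBP ≥ 200 or ≤ 70, DBP ≥ 150 or ≤ 40 mmHg by default).

    ``items`` is a sequence of ``(sbp, dbp)`` pairs or objects with ``sbp``
    and ``dbp`` attributes. Returns ``(kept_items, n_excluded)``; order is
    preserved and the operation is idempotent.
    """
    kept = []
    for it in items:
        sbp, dbp = (it.sbp, it.dbp) if hasattr(it, "sbp") else (it[0], it[1])
        if policy.keeps(float(sbp), float(dbp)):
            kept.append(it)
    n_excl = len(items) - len(kept)
    if n_excl:
        log.info("range filter excluded %d of %d items", n_excl, len(items))
    return kept, n_excl
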