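"""Synthetic three-channel record generator with known ground truth.

Emulates the bedside-monitor data the pipeline consumes: an ECG made of a
QRS template train, a two-bump PPG pulse whose foot trails each R peak by
that beat's pulse transit time (PTT), and an ABP channel oscillating
beat-wise between the beat's DBP and SBP. The physiological coupling is the
standard inverse PTT↔SBP relation SBP = a − b·PTT: stiffer (higher-pressure)
arteries propagate the pulse wave faster, shortening PTT. Per-beat SBP in
the ground truth satisfies that relation exactly; beat-to-beat variability
enters through PTT jitter, so ``b × ptt_jitter_s`` is the SD of the SBP
sequence around the subject baseline.

Everything is deterministic given (profile, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .records_io import GroundTruth, SignalRecord

__all__ = [
    "SubjectProfile",
    "ParameterError",
    "generate_record",
    "generate_cohort",
    "generate_feature_table",
    "FeatureTable",
]


class ParameterError(ValueError):
    """Infeasible or nonsensical generator parameters."""


@dataclass
class SubjectProfile:
    """Generator parameters for one synthetic subject.

    ``ptt_coupling = (a, b)`` defines SBP = a − b·PTT (mmHg, mmHg/s).
    ``artifact_spec`` entries are dicts with a ``kind`` key in
    {white_noise, baseline_wander, motion_spike, dropped_beat,
    inverted_pulse} plus kind-specific params.
    """

    hr_bpm: float = 70.0
    hr_jitter: float = 0.01  # SD of beat-interval noise, s
    sbp0: float = 120.0  # baseline systolic pressure, mmHg
    dbp0: float = 80.0  # baseline diastolic pressure, mmHg
    ptt_coupling: Tuple[float, float] = (250.0, 500.0)  # (a, b)
    ptt_jitter_s: float = 0.004  # SD of per-beat PTT noise, s
    pp_jitter: float = 0.5  # SD of per-beat pulse-pressure noise, mmHg
    noise_sd: dict = field(default_factory=dict)  # per-channel white noise SD
    artifact_spec: List[dict] = field(default_factory=list)
    dicrotic_ratio: float = 0.35  # diastolic bump amplitude / systolic

    def __post_init__(self) -> None:
        if not (20.0 < self.hr_bpm < 240.0):
            raise ParameterError(f"hr_bpm {self.hr_bpm} outside (20, 240)")
        a, b = self.ptt_coupling
        if b <= 0:
            raise ParameterError("PTT coupling slope b must be positive")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ParameterError("noise SDs must be nonnegative")
        if self.sbp0 <= self.dbp0:
            raise ParameterError("sbp0 must exceed dbp0")

    @property
    def ptt0(self) -> float:
        """Subject-mean PTT implied by the coupling and baseline SBP (s)."""
        a, b = self.ptt_coupling
        return (a - self.sbp0) / b


def _qrs_template(fs: float, width_s: float = 0.08) -> np.ndarray:
    """Biphasic QRS-like spike (Ricker wavelet), ~80 ms wide, unit peak."""
    a = width_s * fs / 5.0  # ricker scale: support ~ 5a samples
    n = int(round(width_s * fs)) | 1
    t = np.arange(n) - n // 2
    w = (1 - (t / a) ** 2) * np.exp(-(t**2) / (2 * a**2))
    return w / w.max()


def generate_record(
    profile: SubjectProfile,
    duration_s: float = 20.0,
    fs: float = 125.0,
    seed: int = 0,
    record_id: Optional[str] = None,
) -> SignalRecord:
    """Generate one synthetic record with per-beat ground truth.

    Raises :class:`ParameterError` if the profile is infeasible (PTT at or
    beyond the beat interval, or fewer than two beats fit the duration).
    """
    rng = np.random.default_rng(seed)
    ibi_mean = 60.0 / profile.hr_bpm
    if duration_s < 2 * ibi_mean:
        raise ParameterError("duration must accommodate at least 2 beats")
    a, b = profile.ptt_coupling
    if profile.ptt0 <= 0 or profile.ptt0 >= ibi_mean:
        raise ParameterError(
            f"infeasible profile: PTT {profile.ptt0:.3f}s outside (0, beat interval)"
        )

    # --- beat schedule -----------------------------------------------------
    n_beats = int(np.ceil(duration_s / ibi_mean)) + 3
    ibis = ibi_mean + rng.normal(0.0, profile.hr_jitter, n_beats)
    ibis = np.clip(ibis, 0.3 * ibi_mean, 2.0 * ibi_mean)
    r_times = 0.25 + np.concatenate([[0.0], np.cumsum(ibis[:-1])])
    r_times = r_times[r_times < duration_s - 0.05]
    n_beats = len(r_times)
    if n_beats < 2:
        raise ParameterError("fewer than 2 beats in requested duration")

    ptt = profile.ptt0 + rng.normal(0.0, profile.ptt_jitter_s, n_beats)
    ptt = np.clip(ptt, 0.02, 0.9 * ibi_mean)
    sbp = a - b * ptt  # exact coupling, by construction
    pp = (profile.sbp0 - profile.dbp0) + rng.normal(0.0, profile.pp_jitter, n_beats)
    pp = np.clip(pp, 10.0, None)
    dbp = sbp - pp

    foot_times = r_times + ptt
    # beat spans (foot to next foot); last beat closed by the mean interval
    spans = np.diff(np.concatenate([foot_times, [foot_times[-1] + ibi_mean]]))

    dropped = {
        int(art.get("index", -1))
        for art in profile.artifact_spec
        if art.get("kind") == "dropped_beat"
    }
    inverted = {
        int(art.get("index", -1))
        for art in profile.artifact_spec
        if art.get("kind") == "inverted_pulse"
    }

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    ppg = np.zeros(n)
    ecg = np.zeros(n)
    abp = np.full(n, float(np.mean(dbp)))

    qrs = _qrs_template(fs)
    half = len(qrs) // 2
    peak_times = np.empty(n_beats)

    for k in range(n_beats):
        f0, L = foot_times[k], spans[k]
        # two-bump PPG pulse: systolic wave + dicrotic (diastolic) wave.
        # Bump timing is fixed in absolute time (systole does not scale with
        # the beat interval; diastole absorbs rate changes), so the upstroke
        # onset marks the foot sharply at any heart rate.
        u = t - f0
        in_beat = (u >= 0) & (u < L)
        iu = u[in_beat]
        shape = np.zeros(n)
        shape[in_beat] = np.exp(-((iu - 0.15) ** 2) / (2 * 0.055**2))
        shape[in_beat] += profile.dicrotic_ratio * np.exp(
            -((iu - 0.34) ** 2) / (2 * 0.10**2)
        )
        # PPG amplitude tracks the beat's pulse pressure (stroke-volume proxy)
        shape *= pp[k] / 45.0
        if k in dropped:
            shape[:] = 0.0
        elif k in inverted:
            shape = -shape
        ppg += shape
        idx = np.nonzero(in_beat)[0]
        peak_times[k] = (
            t[idx[np.argmax(shape[idx])]] if idx.size and k not in dropped else f0 + 0.15
        )

        # ABP: per-beat normalization makes max == SBP and min == DBP exactly;
        # the onset-pinning term holds the waveform at DBP at the foot itself,
        # so both ends of the beat sit at that beat's diastolic pressure
        if idx.size >= 2 and k not in dropped:
            g = np.exp(-((iu - 0.15) ** 2) / (2 * 0.055**2)) + 0.30 * np.exp(
                -((iu - 0.34) ** 2) / (2 * 0.10**2)
            )
            g0 = np.exp(-(0.15**2) / (2 * 0.055**2)) + 0.30 * np.exp(
                -(0.34**2) / (2 * 0.10**2)
            )
            g = g - g0 * np.exp(-iu / 0.04)
            g = (g - g.min()) / (g.max() - g.min())
            abp[idx] = dbp[k] + (sbp[k] - dbp[k]) * g

        # ECG QRS at the R time
        if k not in dropped:
            c = int(round(r_times[k] * fs))
            lo, hi = max(c - half, 0), min(c + half + 1, n)
            ecg[lo:hi] += qrs[lo - (c - half) : len(qrs) - ((c + half + 1) - hi)]

    # channel noise
    for ch, sig in (("ppg", ppg), ("ecg", ecg), ("abp", abp)):
        sd = profile.noise_sd.get(ch, 0.0)
        if sd > 0:
            sig += rng.normal(0.0, sd, n)

    # remaining artifacts
    for art in profile.artifact_spec:
        kind = art.get("kind")
        chans = art.get("channel", "ppg")
        chans = ("ppg", "ecg", "abp") if chans == "all" else (chans,)
        targets = {"ppg": ppg, "ecg": ecg, "abp": abp}
        if kind == "white_noise":
            for ch in chans:
                targets[ch] += rng.normal(0.0, float(art.get("sd", 0.1)), n)
        elif kind == "baseline_wander":
            amp = float(art.get("amp", 0.5))
            freq = float(art.get("freq", 0.2))
            phase = rng.uniform(0, 2 * np.pi)
            for ch in chans:
                targets[ch] += amp * np.sin(2 * np.pi * freq * t + phase)
        elif kind == "motion_spike":
            t0 = float(art.get("t", duration_s / 2))
            w = float(art.get("width", 0.15))
            amp = float(art.get("amp", 3.0))
            for ch in chans:
                targets[ch] += amp * np.exp(-((t - t0) ** 2) / (2 * (w / 4) ** 2))
        elif kind in ("dropped_beat", "inverted_pulse"):
            pass  # handled during beat synthesis
        else:
            raise ParameterError(f"unknown artifact kind {kind!r}")

    keep = np.array([k not in dropped for k in range(n_beats)])
    truth = GroundTruth(
        r_peak_times=r_times[keep],
        pulse_foot_times=foot_times[keep],
        pulse_peak_times=peak_times[keep],
        sbp=sbp[keep],
        dbp=dbp[keep],
        ptt=ptt[keep],
    )
    return SignalRecord(
        record_id=record_id or f"synth-{seed}",
        fs=fs,
        ppg=ppg,
        ecg=ecg,
        abp=abp,
        meta={"synthetic": True, "seed": seed},
        truth=truth,
    )


def generate_cohort(
    n_subjects: int,
    duration_s: float = 85.0,
    fs: float = 125.0,
    seed: int = 0,
    bp_noise_sd: float = 2.0,
    sbp_range: Tuple[float, float] = (100.0, 160.0),
    pp_range: Tuple[float, float] = (35.0, 55.0),
    artifact_fraction: float = 0.0,
) -> List[SignalRecord]:
    """Generate a cohort of subjects sharing one PTT↔SBP coupling.

    Subjects differ in baseline SBP (uniform over ``sbp_range``), pulse
    pressure and heart rate; ``bp_noise_sd`` (mmHg) is the SD of each
    subject's per-beat SBP around their baseline, realized through PTT
    jitter. Records are long enough for the default 60 s + 20 s window.
    """
    rng = np.random.default_rng(seed)
    coupling = (250.0, 500.0)
    records = []
    for i in range(n_subjects):
        sbp0 = rng.uniform(*sbp_range)
        profile = SubjectProfile(
            hr_bpm=rng.uniform(55.0, 95.0),
            hr_jitter=0.015,
            sbp0=sbp0,
            dbp0=sbp0 - rng.uniform(*pp_range),
            ptt_coupling=coupling,
            ptt_jitter_s=bp_noise_sd / coupling[1],
            noise_sd={"ppg": 0.01, "ecg": 0.01, "abp": 0.1},
        )
        if artifact_fraction > 0 and rng.uniform() < artifact_fraction:
            kind = rng.choice(["white_noise", "motion_spike", "baseline_wander"])
            profile.artifact_spec.append({"kind": str(kind), "channel": "ppg", "sd": 0.5, "amp": 3.0})
        rec_seed = int(rng.integers(0, 2**31 - 1))
        records.append(
            generate_record(profile, duration_s, fs, seed=rec_seed, record_id=f"subj-{i:03d}")
        )
    return records


@dataclass
class FeatureTable:
    """A synthetic regression fixture: X, target y, and the informative columns."""

    X: np.ndarray
    y: np.ndarray
    informative: np.ndarray  # column indices y actually depends on
    coef: np.ndarray  # linear-link coefficients (empty for nonlinear)


def generate_feature_table(
    n_samples: int,
    n_features: int,
    n_informative: int,
    noise_sd: float = 0.0,
    link: str = "linear",
    seed: int = 0,
) -> FeatureTable:
    """Generate a feature matrix whose target depends only on the first
    ``n_informative`` columns, plus Gaussian noise of SD ``noise_sd``."""
    if n_samples <= 0 or n_features <= 0 or n_informative < 0:
        raise ParameterError("counts must be positive (n_informative ≥ 0)")
    if n_informative > n_features:
        raise ParameterError("n_informative must not exceed n_features")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, n_features))
    k = n_informative
    coef = np.array([])
    if k == 0:
        y = np.zeros(n_samples)
    elif link == "linear":
        coef = rng.uniform(1.0, 2.0, k) * np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        y = X[:, :k] @ coef
    elif link == "nonlinear":
        parts = []
        for j in range(k):
            x = X[:, j]
            parts.append([np.sin(2 * x), x**2 - 1.0, np.tanh(2 * x)][j % 3])
        y = np.sum(parts, axis=0)
    else:
        raise ParameterError(f"unknown link {link!r}")
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_samples)
    return FeatureTable(X=X, y=np.asarray(y, float), informative=np.arange(k), coef=coef)
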