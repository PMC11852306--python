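"""Error statistics and device-protocol grading.

ME/SD/MAE follow the device-validation conventions: per-record error
me_i = estimate_i − reference_i, ME = mean(me), MAE = mean|me|,
SD = √(Σ(ME − me_i)²/(n−1)). A device passes the AAMI/ESH criterion when
|ME| ≤ 5 mmHg and SD ≤ 8 mmHg (inclusive). BHS grades come from the
cumulative percentages of absolute errors within 5/10/15 mmHg (A: ≥60/85/95,
B: ≥50/75/90, C: ≥40/65/85, else D — all three tiers of a grade must hold).
Bland–Altman agreement limits are ME ± 2·SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .records_io import InputError

__all__ = ["ErrorStats", "error_stats", "aami_check", "BhsGrade", "bhs_grade", "bland_altman"]

_BHS_TIERS = {"A": (60.0, 85.0, 95.0), "B": (50.0, 75.0, 90.0), "C": (40.0, 65.0, 85.0)}


@dataclass
class ErrorStats:
    me: float
    sd: float
    mae: float
    n: int


def error_stats(estimates, references) -> ErrorStats:
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise InputError("estimates and references must have equal length")
    if len(est) < 2:
        raise InputError("need at least 2 pairs")
    me_i = est - ref
    me = float(np.mean(me_i))
    sd = float(np.sqrt(np.sum((me - me_i) ** 2) / (len(me_i) - 1)))
    return ErrorStats(me=me, sd=sd, mae=float(np.mean(np.abs(me_i))), n=len(est))


def aami_check(stats: ErrorStats, me_limit: float = 5.0, sd_limit: float = 8.0):
    """AAMI/ESH pass rule: |ME| ≤ 5 and SD ≤ 8 mmHg (inclusive bounds).

    Returns (passed, margins) where margins report the slack to each limit.
    """
    passed = abs(stats.me) <= me_limit and stats.sd <= sd_limit
    margins = {"me_margin": me_limit - abs(stats.me), "sd_margin": sd_limit - stats.sd}
    return bool(passed), margins


@dataclass
class BhsGrade:
    p5: float  # % of |errors| ≤ 5 mmHg
    p10: float
    p15: float
    grade: str  # A | B | C | D


def bhs_grade(abs_errors) -> BhsGrade:
    """Grade cumulative |error| percentages against the BHS tiers."""
    e = np.abs(np.asarray(abs_errors, dtype=float))
    if len(e) < 1:
        raise InputError("need at least one error")
    p5, p10, p15 = (100.0 * np.mean(e <= t) for t in (5.0, 10.0, 15.0))
    return grade_from_percentages(p5, p10, p15)


def grade_from_percentages(p5: float, p10: float, p15: float) -> BhsGrade:
    """Grade a printed/precomputed cumulative-percentage triple."""
    grade = "D"
    for g, (t5, t10, t15) in _BHS_TIERS.items():
        if p5 >= t5 and p10 >= t10 and p15 >= t15:
            grade = g
            break
    return BhsGrade(p5=float(p5), p10=float(p10), p15=float(p15), grade=grade)


def bland_altman(estimates, references) -> Tuple[float, float, float, dict]:
    """Agreement limits ME ± 2·SD plus the per-point plotting payload."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    st = error_stats(est, ref)
    payload = {"mean": (est + ref) / 2.0, "diff": est - ref}
    return st.me, st.me - 2.0 * st.sd, st.me + 2.0 * st.sd, payload
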