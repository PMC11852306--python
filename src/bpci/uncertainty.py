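"""Per-subject uncertainty budgets and confidence-interval constructions.

A subject's ~10 segment-level BP estimates from one 20-s window feed four
interval constructions:

* ``gpr`` — the model's own predictive interval: mean ± z·(mean predictive SD);
* ``uncer`` — expanded uncertainty: U = K·u_c with the root-sum-square
  combined uncertainty u_c = √(u_α² + u_β² + u_γ²), where u_α = σ̂/√n is the
  Type A (random) component, u_β the calibration bias (0 at deployment) and
  u_γ the maximum allowable reference error (±1 mmHg, the mercury-column
  convention), K = 2 for ≈95% coverage;
* ``boot`` — parametric bootstrap: Gaussian MLE (μ̂, σ̂_n) redrawn as an
  n×B matrix, column means sorted, percentile interval;
* ``monte`` — the central-limit interval μ̂ ± Ψ⁻¹((1+γ)/2)·s/√n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .records_io import InputError

__all__ = [
    "UncertaintyBudget",
    "IntervalEstimate",
    "type_a",
    "combined_uncertainty",
    "expanded_interval",
    "bootstrap_ci",
    "montecarlo_ci",
    "subject_cis",
]


@dataclass
class UncertaintyBudget:
    u_alpha: float  # Type A standard uncertainty (mmHg)
    u_beta: float = 0.0  # systematic/bias component (mmHg)
    u_gamma: float = 1.0  # maximum allowable error (mmHg)
    K: float = 2.0  # coverage factor

    def __post_init__(self) -> None:
        if min(self.u_alpha, self.u_beta, self.u_gamma) < 0 or self.K <= 0:
            raise InputError("uncertainty components must be ≥ 0 and K > 0")

    @property
    def u_c(self) -> float:
        return combined_uncertainty(self.u_alpha, self.u_beta, self.u_gamma)

    @property
    def U(self) -> float:
        return self.K * self.u_c


@dataclass
class IntervalEstimate:
    center: float
    lower: float
    upper: float
    level: float
    method: str  # gpr | boot | uncer | monte
    n_estimates: int

    def __post_init__(self) -> None:
        if not (self.lower <= self.center <= self.upper):
            raise InputError("interval must satisfy lower ≤ center ≤ upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def type_a(estimates) -> Tuple[float, float, float]:
    """(mean, sample SD, standard uncertainty u = σ̂/√n) of repeated estimates."""
    x = np.asarray(estimates, dtype=float)
    if len(x) < 2:
        raise InputError("Type A uncertainty needs n ≥ 2 estimates")
    sd = float(np.std(x, ddof=1))
    return float(np.mean(x)), sd, sd / np.sqrt(len(x))


def combined_uncertainty(u_alpha: float, u_beta: float, u_gamma: float = 1.0) -> float:
    """Root-sum-square combination u_c = √(u_α² + u_β² + u_γ²)."""
    if min(u_alpha, u_beta, u_gamma) < 0:
        raise InputError("uncertainty components must be nonnegative")
    return float(np.sqrt(u_alpha**2 + u_beta**2 + u_gamma**2))


def expanded_interval(xbar: float, u_c: float, K: float = 2.0, n: int = 0) -> IntervalEstimate:
    """x̄ ± K·u_c; at K = 2 the nominal level is reported as 0.95."""
    if u_c < 0 or K <= 0:
        raise InputError("u_c ≥ 0 and K > 0 required")
    level = 0.95 if K == 2.0 else 2 * stats.norm.cdf(K) - 1
    return IntervalEstimate(xbar, xbar - K * u_c, xbar + K * u_c, level, "uncer", n)


def bootstrap_ci(
    estimates, B: int = 1000, alpha: float = 0.025, seed: int = 0
) -> IntervalEstimate:
    """Parametric (Gaussian) bootstrap percentile CI for the subject mean.

    The Gaussian MLE (μ̂, σ̂ with n denominator) generates an n×B matrix of
    redraws μ̂ + σ̂·z; column means are sorted and the (α, 1−α) percentiles
    bound the interval, for nominal coverage 1 − 2α.
    """
    x = np.asarray(estimates, dtype=float)
    n = len(x)
    if n < 2:
        raise InputError("bootstrap needs n ≥ 2 estimates")
    if B < 100 or not (0 < alpha < 0.5):
        raise InputError("need B ≥ 100 and 0 < alpha < 0.5")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=0))  # MLE scale
    rng = np.random.default_rng(seed)
    draws = mu + sigma * rng.standard_normal((n, B))
    col_means = np.sort(draws.mean(axis=0))
    lo = float(np.percentile(col_means, 100 * alpha))
    hi = float(np.percentile(col_means, 100 * (1 - alpha)))
    center = float(np.clip(mu, lo, hi))
    return IntervalEstimate(center, lo, hi, 1 - 2 * alpha, "boot", n)


def montecarlo_ci(estimates, level: float = 0.95) -> IntervalEstimate:
    """Central-limit interval μ̂ ± Ψ⁻¹((1+level)/2) · s/√n (s: sample SD)."""
    x = np.asarray(estimates, dtype=float)
    n = len(x)
    if n < 2:
        raise InputError("need n ≥ 2 estimates")
    mu = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    z = float(stats.norm.ppf(0.5 * (1 + level)))
    h = z * s / np.sqrt(n)
    return IntervalEstimate(mu, mu - h, mu + h, level, "monte", n)


def subject_cis(
    estimates_by_subject: Dict[str, Sequence[float]],
    predictive_sd_by_subject: Optional[Dict[str, Sequence[float]]] = None,
    reference_by_subject: Optional[Dict[str, float]] = None,
    methods: Sequence[str] = ("gpr", "boot", "uncer", "monte"),
    level: float = 0.95,
    B: int = 1000,
    u_gamma: float = 1.0,
    K: float = 2.0,
    seed: int = 0,
) -> Dict[str, Dict[str, IntervalEstimate]]:
    """Per-subject intervals for every requested method.

    ``estimates_by_subject`` maps subject → segment-level BP estimates;
    ``predictive_sd_by_subject`` supplies the GPR predictive SDs for the
    ``gpr`` method; ``reference_by_subject`` (if given) supplies a
    calibration reference from which u_β = mean(estimate − reference) is
    estimated, else u_β = 0. Subjects with a single estimate are skipped.
    Interval-width sanity (7–10 mmHg SBP, 3–6 mmHg DBP) is the caller's
    concern; this function only constructs the intervals.
    """
    z = float(stats.norm.ppf(0.5 * (1 + level)))
    out: Dict[str, Dict[str, IntervalEstimate]] = {}
    rng = np.random.default_rng(seed)
    for subj, ests in estimates_by_subject.items():
        x = np.asarray(ests, dtype=float)
        if len(x) < 2:
            continue
        row: Dict[str, IntervalEstimate] = {}
        mean, sd, u_a = type_a(x)
        if "gpr" in methods:
            psd = (
                float(np.mean(predictive_sd_by_subject[subj]))
                if predictive_sd_by_subject and subj in predictive_sd_by_subject
                else sd
            )
            row["gpr"] = IntervalEstimate(mean, mean - z * psd, mean + z * psd, level, "gpr", len(x))
        if "boot" in methods:
            row["boot"] = bootstrap_ci(x, B=B, seed=int(rng.integers(0, 2**31 - 1)))
        if "uncer" in methods:
            u_b = 0.0
            if reference_by_subject and subj in reference_by_subject:
                u_b = abs(float(np.mean(x - reference_by_subject[subj])))
            row["uncer"] = expanded_interval(mean, combined_uncertainty(u_a, u_b, u_gamma), K, len(x))
        if "monte" in methods:
            row["monte"] = montecarlo_ci(x, level)
        out[subj] = row
    return out


def summarize_cis(
    cis: Dict[str, Dict[str, IntervalEstimate]]
) -> Dict[str, Dict[str, float]]:
    """Mean width and mean lower/upper bound across subjects, per method."""
    methods = sorted({m for row in cis.values() for m in row})
    summary = {}
    for m in methods:
        ivs = [row[m] for row in cis.values() if m in row]
        summary[m] = {
            "mean_width": float(np.mean([iv.width for iv in ivs])),
            "mean_lower": float(np.mean([iv.lower for iv in ivs])),
            "mean_upper": float(np.mean([iv.upper for iv in ivs])),
            "n_subjects": len(ivs),
        }
    return summary
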