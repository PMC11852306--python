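"""Feature selection: MRMR ranking and the weighted feature decision (WFD).

MRMR orders features by balancing relevance to the target against
redundancy with already-selected features, using a plug-in mutual-information
estimate on equal-frequency bins. The ranking proceeds in phases: the single
most relevant feature first; then any still-irredundant features (zero MI to
the selected set) by relevance; then the rest of the nonzero-relevance
features by the mutual-information quotient MIQ = relevance / mean
redundancy; zero-relevance features are appended last in ascending index
(a seeded shuffle is available for strict fidelity to a randomized order).

WFD then scores nested top-n prefixes of that ranking by m-fold
cross-validated gradient-boosting MSE and returns the prefix with the
smallest mean CV error (ties favour fewer features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

from . import gba
from .records_io import InputError

__all__ = ["estimate_mi", "MrmrResult", "mrmr_rank", "WfdResult", "wfd_select"]

_MI_TOL = 1e-12


def _equal_freq_bins(a: np.ndarray, bins: int) -> np.ndarray:
    ranks = stats.rankdata(a, method="ordinal") - 1
    return (ranks * bins // len(a)).astype(np.intp)


def estimate_mi(a, b, bins: int = 10) -> float:
    """Plug-in mutual information (nats) on an equal-frequency bins×bins table.

    Symmetric by construction; a constant input carries no information and
    returns 0. Rank-based binning makes the estimate invariant to strictly
    monotone rescaling of either argument.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise InputError("inputs must have equal length")
    if len(a) < bins:
        raise InputError(f"need at least {bins} samples for {bins} bins")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    ia = _equal_freq_bins(a, bins)
    ib = _equal_freq_bins(b, bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= len(a)
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))
    return max(mi, 0.0)


@dataclass
class MrmrResult:
    ranking: np.ndarray  # permutation of feature indices, best first
    relevance: np.ndarray  # MA_x per feature (original index order)
    scores: List[dict] = field(default_factory=list)  # per-pick diagnostics


def mrmr_rank(X, y, bins: int = 10, shuffle_zero_relevance: Optional[int] = None) -> MrmrResult:
    """Rank all features by the phased MRMR procedure (see module docstring)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p < 1:
        raise InputError("need at least one feature")
    relevance = np.array([estimate_mi(X[:, j], y, bins) for j in range(p)])
    # pairwise MI computed lazily and cached
    pair = np.full((p, p), np.nan)

    def mi_pair(i, j):
        if np.isnan(pair[i, j]):
            pair[i, j] = pair[j, i] = estimate_mi(X[:, i], X[:, j], bins)
        return pair[i, j]

    selected: List[int] = []
    scores: List[dict] = []
    remaining = set(range(p))

    def redundancy(j):
        if not selected:
            return 0.0
        return float(np.mean([mi_pair(j, s) for s in selected]))

    def pick(j, red, miq):
        selected.append(j)
        remaining.discard(j)
        scores.append({"feature": j, "relevance": float(relevance[j]), "redundancy": red, "miq": miq})

    # phase 1: most relevant feature
    j0 = int(np.argmax(relevance))
    pick(j0, 0.0, np.inf)

    # phase 2: relevant features still carrying zero redundancy
    while True:
        cand = [j for j in remaining if relevance[j] > _MI_TOL and redundancy(j) <= _MI_TOL]
        if not cand:
            break
        j = max(cand, key=lambda k: (relevance[k], -k))
        pick(j, redundancy(j), np.inf)

    # phase 3: mutual-information quotient
    while True:
        cand = [j for j in remaining if relevance[j] > _MI_TOL]
        if not cand:
            break
        reds = {j: max(redundancy(j), _MI_TOL) for j in cand}
        j = max(cand, key=lambda k: (relevance[k] / reds[k], -k))
        pick(j, reds[j], relevance[j] / reds[j])

    # phase 4: zero-relevance features
    rest = sorted(remaining)
    if shuffle_zero_relevance is not None:
        rest = list(np.random.default_rng(shuffle_zero_relevance).permutation(rest))
    for j in rest:
        pick(int(j), redundancy(int(j)), 0.0)

    return MrmrResult(ranking=np.array(selected, dtype=int), relevance=relevance, scores=scores)


@dataclass
class WfdResult:
    bestmse: List[Tuple[int, float]]  # (subset size n, mean CV MSE), n descending
    chosen_n: int
    chosen_features: np.ndarray  # top-n of the MRMR ranking
    ranking: np.ndarray


def _kfold_indices(n: int, folds: int, seed: int) -> List[np.ndarray]:
    order = np.random.default_rng(seed).permutation(n)
    return [order[k::folds] for k in range(folds)]


def wfd_select(
    X,
    y,
    folds: int = 5,
    gba_cfg: gba.GBAConfig = gba.GBAConfig(),
    seed: int = 0,
    bins: int = 10,
    repartition_per_n: bool = False,
) -> WfdResult:
    """Weighted feature decision: CV-scored search over MRMR prefixes.

    One shared CV partition is reused for every subset size (reduces
    comparison variance; ``repartition_per_n`` restores an independent
    partition per size). The chosen size minimizes mean CV MSE; ties go to
    the smaller subset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < folds:
        raise InputError("fewer rows than CV folds")
    ranking = mrmr_rank(X, y, bins=bins).ranking
    base_folds = _kfold_indices(n, folds, seed)
    table: List[Tuple[int, float]] = []
    for size in range(p, 0, -1):
        cols = ranking[:size]
        test_sets = (
            _kfold_indices(n, folds, seed + size) if repartition_per_n else base_folds
        )
        mses = []
        for test_idx in test_sets:
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            model = gba.fit(X[np.ix_(mask, cols)], y[mask], gba_cfg)
            pred = gba.predict(model, X[np.ix_(test_idx, cols)])
            mses.append(float(np.mean((pred - y[test_idx]) ** 2)))
        table.append((size, float(np.mean(mses))))
    best_mse = min(m for _, m in table)
    chosen_n = min(s for s, m in table if m == best_mse)
    return WfdResult(
        bestmse=table,
        chosen_n=chosen_n,
        chosen_features=ranking[:chosen_n].copy(),
        ranking=ranking,
    )
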