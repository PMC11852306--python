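"""Gaussian process regression with marginal-likelihood hyperparameter fitting.

The model is y = β(x)ᵀw + f(x) + ε with f ~ GP(0, k) and ε ~ N(0, σ²).
Hyperparameters Θ = {η (length scale), σ² (noise variance), σ_f² (signal
variance)} are found by multi-restart quasi-Newton ascent of the log
marginal likelihood in log-parameter space, with the basis weights w
profiled out in closed form (generalized least squares) at every objective
evaluation. Two isotropic kernels ship:

    squared_exponential:  k(x, x′) = σ_f² exp(−‖x−x′‖² / (2η²))
    exponential:          k(x, x′) = σ_f² exp(−‖x−x′‖ / η)

The exponential kernel is the default. All dense algebra goes through a
Cholesky factorization of K + σ²I (never an explicit inverse), with jitter
escalation on factorization failure. The MAE-optimal point prediction is
the posterior median, which for this Gaussian predictive coincides with
the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import linalg, optimize, stats
from scipy.spatial.distance import cdist

from .records_io import InputError

__all__ = ["GprConfig", "GprModel", "kernel_eval", "log_marginal", "log_marginal_grad", "fit", "predict"]


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class GprConfig:
    kernel: str = "exponential"  # or "squared_exponential"
    basis: str = "none"  # "none" | "constant" | "linear"
    standardize: bool = True
    center_y: bool = True  # internal target centering (mean added back)
    restarts: int = 5
    max_iter: int = 200
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.kernel not in ("exponential", "squared_exponential"):
            raise InputError(f"unknown kernel {self.kernel!r}")
        if self.basis not in ("none", "constant", "linear"):
            raise InputError(f"unknown basis {self.basis!r}")
        if self.jitter <= 0 or self.restarts < 1:
            raise InputError("jitter must be > 0 and restarts ≥ 1")


def kernel_eval(x, xp, eta: float, sigma_f2: float = 1.0, kind: str = "exponential") -> float:
    """Evaluate k(x, x′); symmetric in its arguments."""
    if eta <= 0:
        raise InputError("length scale η must be positive")
    d = float(np.linalg.norm(np.asarray(x, float) - np.asarray(xp, float)))
    if kind == "squared_exponential":
        return sigma_f2 * float(np.exp(-(d**2) / (2 * eta**2)))
    if kind == "exponential":
        return sigma_f2 * float(np.exp(-d / eta))
    raise InputError(f"unknown kernel {kind!r}")


def _kernel_matrix(D: np.ndarray, eta: float, sigma_f2: float, kind: str) -> np.ndarray:
    if kind == "squared_exponential":
        return sigma_f2 * np.exp(-(D**2) / (2 * eta**2))
    return sigma_f2 * np.exp(-D / eta)


def _basis_matrix(X: np.ndarray, basis: str) -> np.ndarray:
    n = len(X)
    if basis == "none":
        return np.empty((n, 0))
    if basis == "constant":
        return np.ones((n, 1))
    return np.hstack([np.ones((n, 1)), X])


def _chol(A: np.ndarray, jitter: float) -> Tuple[np.ndarray, float]:
    scale = float(np.mean(np.diag(A))) or 1.0
    j = 0.0
    for _ in range(8):
        try:
            return linalg.cholesky(A + j * np.eye(len(A)), lower=True), j
        except linalg.LinAlgError:
            j = jitter * scale if j == 0.0 else j * 10.0
    raise FitError("Cholesky factorization failed after jitter escalation")


def _profiled_w(L: np.ndarray, Om: np.ndarray, y: np.ndarray) -> np.ndarray:
    if Om.shape[1] == 0:
        return np.zeros(0)
    Ai_Om = linalg.cho_solve((L, True), Om)
    Ai_y = linalg.cho_solve((L, True), y)
    return linalg.solve(Om.T @ Ai_Om, Om.T @ Ai_y, assume_a="sym")


def log_marginal(
    theta: Tuple[float, float, float],
    X: np.ndarray,
    y: np.ndarray,
    cfg: GprConfig = GprConfig(),
    D: Optional[np.ndarray] = None,
    return_grad: bool = False,
):
    """Profiled log marginal likelihood at Θ = (η, σ², σ_f²).

    −½ log|K+σ²I| − (n/2) log 2π − ½ rᵀ(K+σ²I)⁻¹r with r = y − Ωŵ and ŵ
    the GLS weights. With ``return_grad`` also returns the gradient with
    respect to (log η, log σ², log σ_f²); the profiled ŵ is an interior
    maximizer, so the envelope theorem makes the fixed-w gradient exact.
    """
    eta, sigma2, sigma_f2 = theta
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if D is None:
        D = cdist(X, X)
    K = _kernel_matrix(D, eta, sigma_f2, cfg.kernel)
    A = K + sigma2 * np.eye(n)
    L, _ = _chol(A, cfg.jitter)
    Om = _basis_matrix(X, cfg.basis)
    w = _profiled_w(L, Om, y)
    r = y - (Om @ w if w.size else 0.0)
    alpha = linalg.cho_solve((L, True), r)
    lml = (
        -float(np.sum(np.log(np.diag(L))))
        - 0.5 * n * np.log(2 * np.pi)
        - 0.5 * float(r @ alpha)
    )
    if not return_grad:
        return lml
    Ainv = linalg.cho_solve((L, True), np.eye(n))
    M = np.outer(alpha, alpha) - Ainv
    if cfg.kernel == "squared_exponential":
        dK_dleta = K * (D**2) / eta**2
    else:
        dK_dleta = K * D / eta
    grad = np.array(
        [
            0.5 * float(np.sum(M * dK_dleta)),
            0.5 * float(np.trace(M)) * sigma2,
            0.5 * float(np.sum(M * K)),
        ]
    )
    return lml, grad


def log_marginal_grad(theta, X, y, cfg: GprConfig = GprConfig()) -> np.ndarray:
    """Gradient of the profiled log marginal w.r.t. (log η, log σ², log σ_f²)."""
    return log_marginal(theta, X, y, cfg, return_grad=True)[1]


@dataclass
class GprModel:
    config: GprConfig
    eta: float
    sigma2: float
    sigma_f2: float
    w: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    X_train: np.ndarray  # standardized
    L: np.ndarray = field(repr=False)  # Cholesky of K + σ²I
    phi: np.ndarray = field(repr=False)  # (K+σ²I)⁻¹ (y − Ωw)
    lml: float = 0.0

    @property
    def theta(self) -> dict:
        return {"eta": self.eta, "sigma2": self.sigma2, "sigma_f2": self.sigma_f2, "w": self.w}


def fit(X, y, cfg: GprConfig = GprConfig(), seed: int = 0) -> GprModel:
    """Fit hyperparameters by multi-restart L-BFGS ascent in log space.

    Restarts perturb data-driven initial points (η₀ = median pairwise
    distance, σ²₀ = 0.1·var(y), σ_f²₀ = var(y)); the best final marginal
    likelihood wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if n < 2 or len(X) != n:
        raise InputError("need n ≥ 2 with matching X rows")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    Xs = (X - x_mean) / x_scale if cfg.standardize else X.copy()
    if not cfg.standardize:
        x_mean = np.zeros(X.shape[1])
        x_scale = np.ones(X.shape[1])
    y_mean = float(np.mean(y)) if (cfg.center_y and cfg.basis == "none") else 0.0
    ys = y - y_mean

    D = cdist(Xs, Xs)
    off = D[np.triu_indices(n, 1)]
    eta0 = float(np.median(off)) if off.size and np.median(off) > 0 else 1.0
    vy = float(np.var(ys)) or 1.0
    base = np.log([eta0, 0.1 * vy, vy])
    rng = np.random.default_rng(seed)

    def neg(logtheta):
        lml, g = log_marginal(np.exp(logtheta), Xs, ys, cfg, D=D, return_grad=True)
        return -lml, -g

    best = None
    bounds = [(base[0] - 7, base[0] + 7), (np.log(vy * 1e-9), base[2] + 7), (base[2] - 9, base[2] + 7)]
    for r in range(cfg.restarts):
        x0 = base if r == 0 else base + rng.normal(0.0, 0.7, 3)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = optimize.minimize(
                neg, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": cfg.max_iter},
            )
        except FitError:
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("marginal-likelihood optimization failed at every restart")

    eta, sigma2, sigma_f2 = np.exp(best.x)
    K = _kernel_matrix(D, eta, sigma_f2, cfg.kernel)
    L, _ = _chol(K + sigma2 * np.eye(n), cfg.jitter)
    Om = _basis_matrix(Xs, cfg.basis)
    w = _profiled_w(L, Om, ys)
    r_ = ys - (Om @ w if w.size else 0.0)
    phi = linalg.cho_solve((L, True), r_)
    return GprModel(
        config=cfg, eta=float(eta), sigma2=float(sigma2), sigma_f2=float(sigma_f2),
        w=w, x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
        X_train=Xs, L=L, phi=phi, lml=-float(best.fun),
    )


def predict(
    model: GprModel, Xstar, level: float = 0.95
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Posterior predictive (mean, SD, lower, upper) per query row.

    mean = β(x*)ᵀw + Σᵢ φᵢ k(x*, xᵢ); variance = k(x*,x*) + σ² − k*ᵀ(K+σ²I)⁻¹k*;
    the level-γ interval is mean ± z_{(1+γ)/2}·SD. The mean is also the
    MAE-optimal point prediction (posterior median of a Gaussian).
    """
    X = np.asarray(Xstar, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.X_train.shape[1]:
        raise InputError("query dimension does not match training data")
    Xs = (X - model.x_mean) / model.x_scale
    Ks = _kernel_matrix(cdist(Xs, model.X_train), model.eta, model.sigma_f2, model.config.kernel)
    Om = _basis_matrix(Xs, model.config.basis)
    mean = model.y_mean + (Om @ model.w if model.w.size else 0.0) + Ks @ model.phi
    V = linalg.solve_triangular(model.L, Ks.T, lower=True)
    var = model.sigma_f2 + model.sigma2 - np.sum(V**2, axis=0)
    sd = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return np.asarray(mean), sd, mean - z * sd, mean + z * sd
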