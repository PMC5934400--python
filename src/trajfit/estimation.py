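"""Weight matrices and chi^2 minimisation.

The cost is chi^2(theta) = Lambda^T R Lambda with residuals
Lambda_i = f(t_i; theta) - ybar_i and a symmetric positive-definite weight
matrix R.  Three weight choices are provided:

* WLS:   R = diag(1 / Cbar_ii) — no matrix inversion, robust;
* CCM:   R = Cbar^{-1} — the correlated chi-square method, which requires
  the noisy sample covariance of the mean to be invertible;
* BMALS: R = K^{-1} with K_ij = min(t_i, t_j)^2, the shape of the exact
  squared-displacement covariance of Brownian motion (generalised least
  squares adapted to BM; the overall scale of R is immaterial).

Point estimates depend on R only up to scale, and so does the downstream
covariance formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .data_model import SampleStats, WeightMatrix
from .fit_functions import FitModel

__all__ = [
    "FitResult",
    "wls_weights",
    "ccm_weights",
    "bmals_weights",
    "identity_weights",
    "minimize_chi2",
    "IllConditionedError",
    "ZeroVarianceError",
]

#: Reject CCM whenever cond(Cbar) reaches the reciprocal machine epsilon —
#: the inverse is then dominated by roundoff.
DEFAULT_COND_LIMIT = 1.0 / np.finfo(float).eps

GRAD_TOL = 1e-10        # convergence: |grad chi^2| < tol * (1 + |chi^2|)
N_RESTARTS = 5          # multistart minimisations from jittered inits


class IllConditionedError(np.linalg.LinAlgError):
    """Sample covariance cannot be inverted reliably (CCM weights)."""

    def __init__(self, msg: str, condition_number: float | None = None):
        super().__init__(msg)
        self.condition_number = condition_number


class ZeroVarianceError(ValueError):
    """A sampling time has zero sample variance and cannot be weighted."""


@dataclass
class FitResult:
    """Outcome of one chi^2 minimisation."""

    theta_hat: np.ndarray
    chi2: float
    residuals: np.ndarray
    weights: WeightMatrix
    converged: bool
    n_restarts_used: int
    model: FitModel
    grad_norm: float = np.nan
    message: str = ""


def wls_weights(stats: SampleStats) -> WeightMatrix:
    """Diagonal weights R_ii = 1 / Cbar_ii (standard WLS choice)."""
    diag = np.diag(stats.cov_of_mean)
    if np.any(diag <= 0):
        bad = np.flatnonzero(diag <= 0)
        raise ZeroVarianceError(
            f"time points {bad.tolist()} have zero sample variance; remove "
            "them before fitting (e.g. drop the t=0 point of displacement "
            "data, which is identically zero)"
        )
    return WeightMatrix(np.diag(1.0 / diag), kind="wls_diagonal")


def ccm_weights(stats: SampleStats, cond_limit: float = DEFAULT_COND_LIMIT) -> WeightMatrix:
    """Full inverse-covariance weights R = Cbar^{-1} (CCM).

    Requires M - 1 >= N (otherwise Cbar is rank deficient by construction)
    and cond(Cbar) below ``cond_limit``.
    """
    n = stats.cov_of_mean.shape[0]
    if stats.M - 1 < n:
        raise IllConditionedError(
            f"sample covariance is rank deficient: M-1 = {stats.M - 1} < N = {n}"
        )
    cond = float(np.linalg.cond(stats.cov_of_mean))
    if not np.isfinite(cond) or cond >= cond_limit:
        raise IllConditionedError(
            f"condition number {cond:.3g} exceeds limit {cond_limit:.3g}",
            condition_number=cond,
        )
    R = np.linalg.inv(stats.cov_of_mean)
    return WeightMatrix(0.5 * (R + R.T), kind="ccm_full_inverse", condition_number=cond)


def bmals_weights(times: np.ndarray) -> WeightMatrix:
    """Brownian-motion-adapted GLS weights R = K^{-1}, K_ij = min(t_i,t_j)^2.

    K is the shape (up to an irrelevant scale) of the exact covariance of
    Brownian squared displacements, Cov(y_i, y_j) propto min(t_i, t_j)^2.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("BMALS weights require all times > 0")
    if np.unique(t).size != t.size:
        raise ValueError("BMALS kernel is singular for duplicate times")
    K = np.minimum.outer(t, t) ** 2
    cond = float(np.linalg.cond(K))
    R = np.linalg.inv(K)
    return WeightMatrix(0.5 * (R + R.T), kind="bmals", condition_number=cond)


def identity_weights(n: int) -> WeightMatrix:
    """Unweighted (ordinary) least squares."""
    return WeightMatrix(np.eye(n), kind="identity")


def chi2_value(theta: np.ndarray, times: np.ndarray, ybar: np.ndarray,
               model: FitModel, R: np.ndarray) -> float:
    lam = model.value(times, theta) - ybar
    return float(lam @ R @ lam)


def minimize_chi2(
    stats: SampleStats,
    model: FitModel,
    weights: WeightMatrix,
    times: np.ndarray,
    init: np.ndarray | None = None,
    n_restarts: int = N_RESTARTS,
    grad_tol: float = GRAD_TOL,
    seed: int | None = 0,
) -> FitResult:
    """Minimise chi^2 = Lambda^T R Lambda over theta.

    Derivative-based local minimisation (BFGS, or L-BFGS-B when the model
    declares box bounds) with the analytic gradient
    2 (df/dtheta)^T R Lambda.  The default multistart perturbs the model's
    heuristic initial guess ``n_restarts`` times (seeded, deterministic) and
    keeps the lowest chi^2; ties go to the first-found minimum.  A fit that
    never reaches |grad| < grad_tol * (1 + chi^2) is returned with
    ``converged=False`` rather than silently.
    """
    times = np.asarray(times, dtype=float)
    ybar = stats.mean
    n, k = times.size, model.K
    if n < k:
        raise ValueError(f"need at least K={k} time points, got N={n}")
    R = weights.R
    if R.shape != (n, n):
        raise ValueError(f"weight matrix shape {R.shape} does not match N={n}")
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin <= -1e-10 * max(1.0, np.abs(R).max()):
        raise ValueError("weight matrix must be positive definite")

    def fun(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            lam = model.value(times, theta) - ybar
            c2 = float(lam @ R @ lam)
        return c2 if np.isfinite(c2) else 1e300

    def jac(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            lam = model.value(times, theta) - ybar
            gr = 2.0 * model.grad(times, theta).T @ (R @ lam)
        return np.where(np.isfinite(gr), gr, 0.0)

    theta0 = np.asarray(init, dtype=float) if init is not None else model.init_guess(times, ybar)
    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(theta0 * (1.0 + 0.3 * rng.standard_normal(k))
                      + 0.01 * rng.standard_normal(k))
    if model.bounds is not None:
        lo = [b[0] for b in model.bounds]
        starts = [np.maximum(s, [(-np.inf if b is None else b * 1.0 + 1e-9) for b in lo])
                  for s in starts]

    method = "BFGS" if model.bounds is None else "L-BFGS-B"
    best = None
    used = 0
    for s in starts:
        used += 1
        res = minimize(
            fun, s, jac=jac, method=method,
            bounds=model.bounds if model.bounds is not None else None,
            options={"gtol": grad_tol} if method == "BFGS" else {"ftol": 1e-15, "gtol": grad_tol},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta_hat = np.asarray(best.x, dtype=float)
    gnorm = float(np.linalg.norm(jac(theta_hat)))
    chi2 = float(best.fun)
    converged = gnorm < max(grad_tol, 1e3 * grad_tol) * (1.0 + abs(chi2)) or bool(best.success)
    lam = model.value(times, theta_hat) - ybar
    return FitResult(
        theta_hat=theta_hat,
        chi2=chi2,
        residuals=lam,
        weights=weights,
        converged=converged,
        n_restarts_used=used,
        model=model,
        grad_norm=gnorm,
        message=str(best.message),
    )
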