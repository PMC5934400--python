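"""Parameter-covariance estimation for chi^2 fits of ensemble means.

The central result implemented here is the correlation-aware covariance
estimator for parameters obtained by minimising
chi^2 = Lambda^T R Lambda, valid for any symmetric positive-definite R and
to leading order in 1/M:

    Delta_hat = phi_hat / M,
    phi_hat   = 4 h^{-1} G^T (R^T Qbar R) G h^{-1},
    h_ab      = 2 sum_ij d2f_i/dth_a dth_b R_ij Lambda_j
                + 2 sum_ij df_i/dth_a R_ij df_j/dth_b,

with G_ia = df(t_i)/dtheta_a and Qbar the full sample covariance across
trajectories.  Correlations between sampling times enter only through
Qbar, so no noisy matrix has to be inverted (h is K x K, with K the small
number of fit parameters).

Known reductions, all available here: dropping the off-diagonals of Qbar
gives the classical uncorrelated-error WLS formula (ECE); R = Cbar^{-1}
gives the correlated chi-square method (CCM); a constant fit function
recovers the textbook variance-of-a-mean result sum_ij Qbar_ij / (M N^2).

Resampling alternatives (grouped jackknife, trajectory bootstrap) are
provided for cross-checking; both refit the data many times, which the
closed-form estimator avoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import SampleStats, TrajectoryEnsemble, WeightMatrix, compute_stats
from .estimation import (
    FitResult,
    IllConditionedError,
    ZeroVarianceError,
    bmals_weights,
    ccm_weights,
    identity_weights,
    minimize_chi2,
    wls_weights,
)
from .fit_functions import FitModel

__all__ = [
    "ParamCovariance",
    "wlsice_covariance",
    "wlsece_covariance",
    "ccm_covariance",
    "jackknife_fit",
    "bootstrap_errors",
    "subsample_times",
]


@dataclass
class ParamCovariance:
    """K x K covariance estimate for fitted parameters.

    ``sigma_hat[a] = sqrt(delta_hat[a, a])``; ``phi_hat`` and ``h_hat`` are
    the intermediates of the closed-form estimator when it was used.
    """

    delta_hat: np.ndarray
    sigma_hat: np.ndarray
    method: str
    phi_hat: np.ndarray | None = None
    h_hat: np.ndarray | None = None
    n_failed: int = 0


def _curvature_matrix(
    times: np.ndarray,
    model: FitModel,
    theta: np.ndarray,
    R: np.ndarray,
    residuals: np.ndarray,
    include_hessian_term: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """h matrix (and gradient G) of the covariance formula at theta.

    ``include_hessian_term=False`` zeroes the residual x Hessian term of h,
    giving the Gauss--Newton-style curvature many standard treatments use;
    the full h is the default.
    """
    G = model.grad(times, theta)
    h = 2.0 * G.T @ R @ G
    if include_hessian_term:
        H = model.hess(times, theta)
        rl = R @ residuals
        h = h + 2.0 * np.einsum("iab,i->ab", H, rl)
    return 0.5 * (h + h.T), G


def _eq_covariance(
    stats: SampleStats,
    model: FitModel,
    weights: WeightMatrix,
    fit: FitResult,
    times: np.ndarray,
    Q: np.ndarray,
    method: str,
    include_hessian_term: bool = True,
    middle: np.ndarray | None = None,
) -> ParamCovariance:
    """Evaluate the covariance estimator with sample covariance ``Q``.

    ``middle`` overrides the inner matrix R^T Q R (used by the reduced CCM
    route, where it simplifies algebraically).
    """
    R = weights.R
    h, G = _curvature_matrix(
        times, model, fit.theta_hat, R, fit.residuals, include_hessian_term
    )
    cond_h = float(np.linalg.cond(h))
    if not np.isfinite(cond_h) or cond_h > 1.0 / np.finfo(float).eps:
        raise IllConditionedError(
            f"curvature matrix h is singular (condition number {cond_h:.3g}); "
            "the cost surface is flat in some parameter direction",
            condition_number=cond_h,
        )
    h_inv = np.linalg.inv(h)
    if middle is None:
        middle = R.T @ Q @ R
    phi = 4.0 * h_inv @ G.T @ middle @ G @ h_inv
    phi = 0.5 * (phi + phi.T)
    delta = phi / stats.M
    return ParamCovariance(
        delta_hat=delta,
        sigma_hat=np.sqrt(np.clip(np.diag(delta), 0.0, None)),
        method=method,
        phi_hat=phi,
        h_hat=h,
    )


def wlsice_covariance(
    stats: SampleStats,
    model: FitModel,
    weights: WeightMatrix,
    fit: FitResult,
    times: np.ndarray,
    include_hessian_term: bool = True,
) -> ParamCovariance:
    """Correlation-aware covariance (ICE): full sample covariance Qbar."""
    return _eq_covariance(
        stats, model, weights, fit, times, stats.cov, "wls_ice",
        include_hessian_term,
    )


def wlsece_covariance(
    stats: SampleStats,
    model: FitModel,
    weights: WeightMatrix,
    fit: FitResult,
    times: np.ndarray,
    include_hessian_term: bool = True,
) -> ParamCovariance:
    """Classical WLS covariance (ECE): off-diagonals of Qbar neglected."""
    return _eq_covariance(
        stats, model, weights, fit, times, np.diag(np.diag(stats.cov)),
        "wls_ece", include_hessian_term,
    )


def ccm_covariance(
    stats: SampleStats,
    model: FitModel,
    fit: FitResult,
    times: np.ndarray,
    cross_check_tol: float = 1e-8,
) -> ParamCovariance:
    """Covariance for the correlated chi-square method (R = Cbar^{-1}).

    With R = Cbar^{-1} and Qbar = M Cbar, the inner matrix R^T Qbar R of
    the general formula collapses to M Cbar^{-1}; both the generic route
    and this reduced route are evaluated and cross-checked.
    """
    if fit.weights.kind != "ccm_full_inverse":
        raise ValueError("ccm_covariance requires a fit made with CCM weights")
    generic = _eq_covariance(
        stats, model, fit.weights, fit, times, stats.cov, "ccm"
    )
    middle = stats.M * fit.weights.R          # R^T Qbar R == M Cbar^{-1}
    reduced = _eq_covariance(
        stats, model, fit.weights, fit, times, stats.cov, "ccm", middle=middle
    )
    scale = max(1.0, float(np.abs(generic.delta_hat).max()))
    if np.abs(generic.delta_hat - reduced.delta_hat).max() > cross_check_tol * scale:
        raise AssertionError(
            "CCM covariance cross-check failed: generic and reduced routes disagree"
        )
    return generic


# ---------------------------------------------------------------------------
# resampling

_WEIGHT_BUILDERS = {
    "wls": lambda stats, times: wls_weights(stats),
    "ccm": lambda stats, times: ccm_weights(stats),
    "bmals": lambda stats, times: bmals_weights(times),
    "identity": lambda stats, times: identity_weights(times.size),
}


def fit_ensemble(
    ensemble: TrajectoryEnsemble,
    model: FitModel,
    weight_kind: str = "wls",
    init: np.ndarray | None = None,
    seed: int | None = 0,
) -> tuple[SampleStats, FitResult]:
    """Convenience: stats -> weights -> chi^2 fit for one ensemble."""
    stats = compute_stats(ensemble)
    weights = _WEIGHT_BUILDERS[weight_kind](stats, ensemble.times)
    fit = minimize_chi2(stats, model, weights, ensemble.times, init=init, seed=seed)
    return stats, fit


def _group_indices(m: int, g: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Split trajectory indices into g near-equal contiguous blocks after a
    seeded shuffle (trajectories are exchangeable)."""
    perm = rng.permutation(m)
    return [np.sort(block) for block in np.array_split(perm, g)]


def jackknife_fit(
    ensemble: TrajectoryEnsemble,
    model: FitModel,
    weight_kind: str = "wls",
    g: int = 20,
    order: int = 1,
    seed: int | None = 0,
) -> tuple[FitResult, ParamCovariance]:
    """Grouped jackknife bias correction of the chi^2 fit.

    Trajectories are pooled into ``g`` groups; delete-one-group refits give
    the first-order corrected estimate theta_J = g theta_full -
    (g-1) mean_k theta_(-k), which removes the bias term proportional to
    1/M.  ``order=2`` additionally refits all g(g-1)/2 delete-two-group
    subsets and eliminates the 1/M^2 term as well (at g(g+1)/2 times the
    cost of a plain fit; generally not recommended — in practice it tends
    to amplify rather than reduce the residual bias).

    The closed-form covariance estimator remains valid for jackknifed
    parameters; it is evaluated at theta_J on the full-sample statistics.
    """
    if g < 2:
        raise ValueError("jackknife needs g >= 2 groups")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    m = ensemble.n_trajectories
    if g > m:
        raise ValueError(f"cannot form g={g} groups from M={m} trajectories")
    rng = np.random.default_rng(seed)
    groups = _group_indices(m, g, rng)

    stats_full = compute_stats(ensemble)
    weights_full = _WEIGHT_BUILDERS[weight_kind](stats_full, ensemble.times)
    fit_full = minimize_chi2(stats_full, model, weights_full, ensemble.times, seed=seed)
    theta_full = fit_full.theta_hat
    all_converged = fit_full.converged

    all_idx = np.arange(m)

    def _refit(drop: np.ndarray) -> np.ndarray:
        nonlocal all_converged
        keep = np.setdiff1d(all_idx, drop, assume_unique=True)
        sub = ensemble.subset(keep)
        st = compute_stats(sub)
        wt = _WEIGHT_BUILDERS[weight_kind](st, sub.times)
        fr = minimize_chi2(st, model, wt, sub.times, init=theta_full, seed=seed)
        all_converged = all_converged and fr.converged
        return fr.theta_hat

    theta_d1 = np.mean([_refit(grp) for grp in groups], axis=0)

    if order == 1:
        theta_j = g * theta_full - (g - 1) * theta_d1
    else:
        pairs = [
            np.concatenate((groups[i], groups[j]))
            for i in range(g) for j in range(i + 1, g)
        ]
        theta_d2 = np.mean([_refit(p) for p in pairs], axis=0)
        # Richardson elimination of the 1/n and 1/n^2 bias terms from the
        # estimates built on n = g, g-1, g-2 groups' worth of trajectories
        ns = np.array([g, g - 1, g - 2], dtype=float)
        V = np.vstack([np.ones(3), 1.0 / ns, 1.0 / ns ** 2])
        c = np.linalg.solve(V, np.array([1.0, 0.0, 0.0]))
        theta_j = c[0] * theta_full + c[1] * theta_d1 + c[2] * theta_d2

    residuals = model.value(ensemble.times, theta_j) - stats_full.mean
    fit_j = FitResult(
        theta_hat=theta_j,
        chi2=float(residuals @ weights_full.R @ residuals),
        residuals=residuals,
        weights=weights_full,
        converged=all_converged,
        n_restarts_used=fit_full.n_restarts_used,
        model=model,
        message=f"jackknife order {order}, g={g}",
    )
    cov = _eq_covariance(
        stats_full, model, weights_full, fit_j, ensemble.times,
        stats_full.cov, f"jackknife{order}",
    )
    return fit_j, cov


def bootstrap_errors(
    ensemble: TrajectoryEnsemble,
    model: FitModel,
    weight_kind: str = "wls",
    B: int = 100,
    seed: int | None = 0,
) -> ParamCovariance:
    """Trajectory bootstrap: resample rows with replacement, refit B times.

    Whole trajectories are resampled (never individual time points), so
    the within-trajectory correlation structure is preserved.  Replicates
    in which some time point ends up with zero sample variance are dropped
    and counted in ``n_failed``.
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2 replicates")
    rng = np.random.default_rng(seed)
    m = ensemble.n_trajectories
    thetas = []
    n_failed = 0
    for _ in range(B):
        rows = rng.integers(0, m, size=m)
        sub = ensemble.subset(rows)
        try:
            _, fr = fit_ensemble(sub, model, weight_kind, seed=seed)
        except (ZeroVarianceError, IllConditionedError):
            n_failed += 1
            continue
        thetas.append(fr.theta_hat)
    if len(thetas) < 2:
        raise RuntimeError(
            f"bootstrap failed: only {len(thetas)} of {B} replicates usable"
        )
    thetas = np.asarray(thetas)
    delta = np.atleast_2d(np.cov(thetas, rowvar=False, ddof=1))
    return ParamCovariance(
        delta_hat=delta,
        sigma_hat=np.sqrt(np.clip(np.diag(delta), 0.0, None)),
        method="bootstrap",
        n_failed=n_failed,
    )


def subsample_times(ensemble: TrajectoryEnsemble, keep_every_k: int, min_points: int = 1) -> TrajectoryEnsemble:
    """Keep every k-th sampling time (sparser grids decorrelate the data).

    Used to build error-versus-N curves; ``min_points`` guards against
    subsampling below the number of fit parameters.
    """
    k = int(keep_every_k)
    if k < 1:
        raise ValueError("keep_every_k must be >= 1")
    idx = np.arange(0, ensemble.n_times, k)
    if idx.size < min_points:
        raise ValueError(
            f"subsampling with k={k} leaves {idx.size} < {min_points} points"
        )
    return TrajectoryEnsemble(
        ensemble.times[idx], ensemble.values[:, idx],
        ensemble.observable_label, dict(ensemble.meta),
    )
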