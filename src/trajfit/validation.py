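"""Replicate-based validation of the fitting and error-estimation methods.

The protocol: generate S independent synthetic ensembles with known
ground-truth parameters theta*, fit each with each method, and compare

* the spread of the S point estimates (the "ground-truth" standard
  deviation) against the per-fit error estimates sigma_hat,
* the empirical coverage of 1- and 2-sigma intervals against the Gaussian
  68%/95% rule,
* the mean relative bias of the point estimates against zero,

plus goodness of fit (R^2) and, for CCM, the rate of ill-conditioned
sample covariances.  A phase map repeats this over a grid of (N, M) to
chart where each method is usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .data_model import TrajectoryEnsemble, compute_stats
from .estimation import (
    IllConditionedError,
    ZeroVarianceError,
    bmals_weights,
    ccm_weights,
    minimize_chi2,
    wls_weights,
)
from .fit_functions import FitModel, get_model
from .simulators import ProcessSpec, simulate
from .uncertainty import (
    bootstrap_errors,
    ccm_covariance,
    jackknife_fit,
    subsample_times,
    wlsece_covariance,
    wlsice_covariance,
)

__all__ = [
    "MethodSummary",
    "ValidationReport",
    "PhaseMapCell",
    "run_validation",
    "r_squared",
    "phase_map",
    "error_vs_n_curve",
    "KNOWN_METHODS",
]

#: method label -> (weight scheme, error scheme)
KNOWN_METHODS = (
    "wls-ice", "wls-ece", "ccm", "bmals",
    "bootstrap", "jackknife1", "jackknife2",
)


@dataclass
class MethodSummary:
    """Aggregates over the S replicates for one fitting/error method."""

    method: str
    theta_mean: np.ndarray
    theta_std: np.ndarray          # ground-truth spread of the S estimates
    sigma_mean: np.ndarray         # mean of the per-fit error estimates
    coverage_1s: np.ndarray        # fraction of replicates with |th-th*|<=sigma
    coverage_2s: np.ndarray
    rel_bias: np.ndarray           # (mean theta - theta*) / theta*
    frac_ill_conditioned: float
    n_failed: int
    mean_r_squared: float
    thetas: np.ndarray = field(repr=False, default=None)
    sigmas: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "theta_mean": self.theta_mean.tolist(),
            "theta_std": self.theta_std.tolist(),
            "sigma_mean": self.sigma_mean.tolist(),
            "coverage_1s": self.coverage_1s.tolist(),
            "coverage_2s": self.coverage_2s.tolist(),
            "rel_bias": self.rel_bias.tolist(),
            "frac_ill_conditioned": self.frac_ill_conditioned,
            "n_failed": self.n_failed,
            "mean_r_squared": self.mean_r_squared,
        }


@dataclass
class ValidationReport:
    process: str
    theta_star: np.ndarray
    N: int
    M: int
    S: int
    seed: int | None
    methods: dict[str, MethodSummary]

    def to_dict(self) -> dict[str, Any]:
        return {
            "process": self.process,
            "theta_star": self.theta_star.tolist(),
            "N": self.N, "M": self.M, "S": self.S, "seed": self.seed,
            "methods": {k: v.to_dict() for k, v in self.methods.items()},
        }


@dataclass
class PhaseMapCell:
    N: int
    M: int
    method: str
    rel_bias: np.ndarray
    acceptable: bool
    ill_conditioned_majority: bool
    frac_ill_conditioned: float
    n_failed: int


def r_squared(ybar: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot of the mean curve.

    A heuristic goodness-of-fit number for correlated data; returns NaN
    when the total sum of squares vanishes (constant data).
    """
    ss_tot = float(np.sum((ybar - ybar.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((ybar - fitted) ** 2))
    return 1.0 - ss_res / ss_tot


def _fit_one(
    ensemble: TrajectoryEnsemble,
    model: FitModel,
    method: str,
    seed: int,
):
    """One replicate, one method -> (theta_hat, sigma_hat, r2) or raises."""
    stats = compute_stats(ensemble)
    t = ensemble.times
    if method in ("wls-ice", "wls-ece"):
        w = wls_weights(stats)
        fit = minimize_chi2(stats, model, w, t, seed=seed)
        cov_fn = wlsice_covariance if method == "wls-ice" else wlsece_covariance
        cov = cov_fn(stats, model, w, fit, t)
    elif method == "ccm":
        w = ccm_weights(stats)
        fit = minimize_chi2(stats, model, w, t, seed=seed)
        cov = ccm_covariance(stats, model, fit, t)
    elif method == "bmals":
        w = bmals_weights(t)
        fit = minimize_chi2(stats, model, w, t, seed=seed)
        cov = wlsice_covariance(stats, model, w, fit, t)
    elif method == "bootstrap":
        w = wls_weights(stats)
        fit = minimize_chi2(stats, model, w, t, seed=seed)
        cov = bootstrap_errors(ensemble, model, "wls", B=100, seed=seed)
    elif method in ("jackknife1", "jackknife2"):
        order = int(method[-1])
        fit, cov = jackknife_fit(ensemble, model, "wls", g=20, order=order, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}; known: {KNOWN_METHODS}")
    r2 = r_squared(stats.mean, model.value(t, fit.theta_hat))
    return fit.theta_hat, cov.sigma_hat, r2


def _summarise(
    method: str,
    theta_star: np.ndarray,
    thetas: list[np.ndarray],
    sigmas: list[np.ndarray],
    r2s: list[float],
    n_ill: int,
    n_failed: int,
    S: int,
) -> MethodSummary:
    k = theta_star.size
    if len(thetas) >= 2:
        th = np.asarray(thetas)
        sg = np.asarray(sigmas)
        mean = th.mean(axis=0)
        std = th.std(axis=0, ddof=1)
        sig_mean = sg.mean(axis=0)
        cov1 = (np.abs(th - theta_star) <= sg).mean(axis=0)
        cov2 = (np.abs(th - theta_star) <= 2 * sg).mean(axis=0)
        bias = (mean - theta_star) / theta_star
        r2m = float(np.nanmean(r2s)) if r2s else float("nan")
    else:
        mean = std = sig_mean = cov1 = cov2 = bias = np.full(k, np.nan)
        th = sg = np.empty((0, k))
        r2m = float("nan")
    return MethodSummary(
        method=method, theta_mean=mean, theta_std=std, sigma_mean=sig_mean,
        coverage_1s=cov1, coverage_2s=cov2, rel_bias=bias,
        frac_ill_conditioned=n_ill / S, n_failed=n_failed,
        mean_r_squared=r2m, thetas=th, sigmas=sg,
    )


def run_validation(
    process_spec: ProcessSpec,
    model: FitModel | str | None = None,
    methods: Sequence[str] = ("wls-ice", "wls-ece", "ccm"),
    S: int = 500,
    seed: int | None = 0,
) -> ValidationReport:
    """Fit S independent replicate ensembles with each method.

    One master seed spawns S independent child streams, so the report is
    bit-reproducible given (spec, S, seed).  Per-replicate failures
    (ill-conditioning, zero variance, non-convergence) are counted, not
    fatal.  The sample spread of the S point estimates serves as the
    ground-truth parameter uncertainty that the per-fit sigma_hat
    estimates are judged against.
    """
    if S < 2:
        raise ValueError("need S >= 2 replicate ensembles")
    if model is None:
        model = get_model(process_spec.model_name)
    elif isinstance(model, str):
        model = get_model(model)
    theta_star = process_spec.theta_star
    children = np.random.SeedSequence(seed).spawn(S)

    acc: dict[str, dict[str, Any]] = {
        m: {"thetas": [], "sigmas": [], "r2s": [], "n_ill": 0, "n_failed": 0}
        for m in methods
    }
    for s_idx, child in enumerate(children):
        ens = simulate(process_spec, seed=child)
        for method in methods:
            slot = acc[method]
            try:
                th, sg, r2 = _fit_one(ens, model, method, seed=s_idx)
            except IllConditionedError:
                slot["n_ill"] += 1
                slot["n_failed"] += 1
                continue
            except (ZeroVarianceError, np.linalg.LinAlgError, RuntimeError):
                slot["n_failed"] += 1
                continue
            slot["thetas"].append(th)
            slot["sigmas"].append(sg)
            slot["r2s"].append(r2)

    summaries = {
        m: _summarise(m, theta_star, a["thetas"], a["sigmas"], a["r2s"],
                      a["n_ill"], a["n_failed"], S)
        for m, a in acc.items()
    }
    return ValidationReport(
        process=process_spec.process, theta_star=theta_star,
        N=process_spec.times.size, M=process_spec.M, S=S, seed=seed,
        methods=summaries,
    )


def phase_map(
    process_spec_template: ProcessSpec,
    model: FitModel | str | None = None,
    method: str = "ccm",
    N_grid: Sequence[int] = (10, 30, 100, 300),
    M_grid: Sequence[int] = (20, 100, 500, 2000),
    S: int = 100,
    seed: int | None = 0,
    bias_threshold: float = 0.10,
) -> list[PhaseMapCell]:
    """Chart the (N, M) region where a method gives acceptable fits.

    A cell is acceptable when the magnitude of the mean relative bias is at
    most ``bias_threshold`` (10% by default) on every fitted parameter; a
    cell is flagged ``ill_conditioned_majority`` when more than half of its
    S replicate covariance matrices could not be inverted.
    """
    if not len(N_grid) or not len(M_grid):
        raise ValueError("N_grid and M_grid must be nonempty")
    tmpl = process_spec_template
    t_max = float(tmpl.times[-1])
    cells = []
    cell_seeds = np.random.SeedSequence(seed).spawn(len(N_grid) * len(M_grid))
    i = 0
    for n in N_grid:
        for m in M_grid:
            spec = ProcessSpec(
                tmpl.process, dict(tmpl.params),
                times=np.linspace(t_max / n, t_max, n), M=int(m),
            )
            rep = run_validation(
                spec, model=model, methods=(method,), S=S,
                seed=cell_seeds[i].generate_state(1)[0],
            )
            i += 1
            summ = rep.methods[method]
            majority_ill = summ.frac_ill_conditioned > 0.5
            ok = (
                not majority_ill
                and summ.n_failed < S / 2
                and bool(np.all(np.abs(summ.rel_bias) <= bias_threshold))
            )
            cells.append(PhaseMapCell(
                N=int(n), M=int(m), method=method, rel_bias=summ.rel_bias,
                acceptable=ok, ill_conditioned_majority=majority_ill,
                frac_ill_conditioned=summ.frac_ill_conditioned,
                n_failed=summ.n_failed,
            ))
    return cells


def error_vs_n_curve(
    process_spec: ProcessSpec,
    model: FitModel | str | None = None,
    methods: Sequence[str] = ("wls-ice", "wls-ece"),
    N_list: Sequence[int] | None = None,
    S: int = 500,
    seed: int | None = 0,
) -> list[dict[str, Any]]:
    """Ground-truth spread and mean sigma_hat as a function of N.

    Each replicate is simulated once on the full grid, then thinned with
    :func:`subsample_times` to each requested N (the N_list entries must be
    achievable by keeping every k-th point of the full grid).  Because the
    temporal correlations never die out, the ground-truth spread does not
    shrink to zero as N grows at fixed M.
    """
    if model is None:
        model = get_model(process_spec.model_name)
    elif isinstance(model, str):
        model = get_model(model)
    n_full = process_spec.times.size
    if N_list is None:
        N_list = sorted({max(model.K + 1, n_full // k) for k in (1, 2, 5, 10)})
    ks = []
    for n in N_list:
        k = n_full // n
        if k < 1 or (n_full + k - 1) // k != n:
            raise ValueError(
                f"N={n} is not reachable by keeping every k-th of {n_full} points"
            )
        ks.append(k)

    theta_star = process_spec.theta_star
    children = np.random.SeedSequence(seed).spawn(S)
    rows = []
    acc = {
        (n, m): {"thetas": [], "sigmas": [], "r2s": [], "n_ill": 0, "n_failed": 0}
        for n in N_list for m in methods
    }
    for s_idx, child in enumerate(children):
        full = simulate(process_spec, seed=child)
        for n, k in zip(N_list, ks):
            ens = subsample_times(full, k, min_points=model.K)
            for method in methods:
                slot = acc[(n, method)]
                try:
                    th, sg, r2 = _fit_one(ens, model, method, seed=s_idx)
                except IllConditionedError:
                    slot["n_ill"] += 1
                    slot["n_failed"] += 1
                    continue
                except (ZeroVarianceError, np.linalg.LinAlgError, RuntimeError):
                    slot["n_failed"] += 1
                    continue
                slot["thetas"].append(th)
                slot["sigmas"].append(sg)
                slot["r2s"].append(r2)
    for n in N_list:
        for method in methods:
            a = acc[(n, method)]
            summ = _summarise(method, theta_star, a["thetas"], a["sigmas"],
                              a["r2s"], a["n_ill"], a["n_failed"], S)
            rows.append({
                "N": int(n), "method": method,
                "theta_std": summ.theta_std.tolist(),
                "sigma_mean": summ.sigma_mean.tolist(),
                "rel_bias": summ.rel_bias.tolist(),
                "n_failed": summ.n_failed,
            })
    return rows
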