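"""Seeded simulators for four prototype stochastic processes.

Each simulator produces a :class:`~trajfit.data_model.TrajectoryEnsemble`
with known ground-truth fit parameters ``theta_star``:

* ``bm``   — Brownian motion; observable = squared displacement,
  MSD = 2dD * t, so theta* = (2dD,).
* ``fbm``  — fractional Brownian motion with Hurst exponent H; observable =
  squared displacement, MSD = 2dK_f * t^(2H), theta* = (2dK_f, 2H).
* ``ctrw`` — continuous-time random walk with Pareto waiting times (tail
  exponent alpha) and Gaussian jumps; MSD ~ theta1* t^alpha asymptotically
  with theta2* = alpha.  The prefactor follows from the renewal theorem,
  theta1* = d sigma_j^2 sin(pi alpha) / (pi alpha tau0^alpha), and is only
  reached asymptotically.
* ``dho``  — critically damped harmonic oscillator in a heat bath;
  observable = position, mean x0 (1 + theta1 t) exp(-theta1 t),
  theta* = (theta1,).

Fixing the seed fixes the output bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.linalg import cholesky, expm, LinAlgError

from .data_model import TrajectoryEnsemble, squared_displacement

__all__ = [
    "ProcessSpec",
    "simulate",
    "simulate_bm",
    "simulate_fbm",
    "simulate_ctrw",
    "simulate_dho",
    "fbm_msd_kernel",
]

# Package-default experiment geometry: N=75 equispaced sampling times and
# M=1000 trajectories per ensemble, with S=500 replicate ensembles used by
# the validation harness.
DEFAULT_N = 75
DEFAULT_M = 1000
DEFAULT_S = 500

_DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "bm": {"D": 1.0, "d": 1},
    "fbm": {"H": 0.75, "K_f": 1.0, "d": 1},
    "ctrw": {"alpha": 0.7, "tau0": 1e-3, "sigma_j": 1.0, "d": 1},
    "dho": {"theta1": 1.0, "x0": 1.0, "noise": 0.5},
}


@dataclass
class ProcessSpec:
    """Configuration of one synthetic experiment.

    ``params`` carries the process parameters (missing entries take the
    package defaults above); ``times`` the N sampling times (all > 0, as
    needed for power-law fitting); ``M`` the number of trajectories.
    """

    process: str
    params: dict[str, Any] = field(default_factory=dict)
    times: np.ndarray | None = None
    M: int = DEFAULT_M
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.process not in _DEFAULT_PARAMS:
            raise ValueError(
                f"unknown process {self.process!r}; expected one of "
                f"{sorted(_DEFAULT_PARAMS)}"
            )
        merged = dict(_DEFAULT_PARAMS[self.process])
        merged.update(self.params)
        self.params = merged
        if self.times is None:
            self.times = np.arange(1.0, DEFAULT_N + 1.0)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.process in ("bm", "fbm", "ctrw") and np.any(self.times <= 0):
            raise ValueError(
                f"{self.process} sampling times must be > 0 (the t=0 point "
                "carries zero variance)"
            )
        p = self.params
        if self.process == "fbm" and not (0.0 < p["H"] < 1.0):
            raise ValueError("Hurst exponent H must lie in (0, 1)")
        if self.process == "ctrw" and not (0.0 < p["alpha"] < 1.0):
            raise ValueError("CTRW tail exponent alpha must lie in (0, 1)")
        if self.process == "dho" and p["theta1"] <= 0:
            raise ValueError("DHO requires theta1 > 0")

    @property
    def theta_star(self) -> np.ndarray:
        """Ground-truth parameters of the matching fit function."""
        p = self.params
        if self.process == "bm":
            return np.array([2.0 * p["d"] * p["D"]])
        if self.process == "fbm":
            return np.array([2.0 * p["d"] * p["K_f"], 2.0 * p["H"]])
        if self.process == "ctrw":
            a = p["alpha"]
            pref = (
                p["d"] * p["sigma_j"] ** 2 * np.sin(np.pi * a)
                / (np.pi * a * p["tau0"] ** a)
            )
            return np.array([pref, a])
        return np.array([p["theta1"]])

    @property
    def model_name(self) -> str:
        return {
            "bm": "linear", "fbm": "power_law",
            "ctrw": "power_law", "dho": "dho_mean",
        }[self.process]


def simulate(spec: ProcessSpec, seed: int | np.random.SeedSequence | None = None) -> TrajectoryEnsemble:
    """Dispatch to the process-specific simulator.

    ``seed`` overrides ``spec.seed`` when given (used by the replicate
    harness to stream child seeds through one spec).
    """
    fn = {
        "bm": simulate_bm, "fbm": simulate_fbm,
        "ctrw": simulate_ctrw, "dho": simulate_dho,
    }[spec.process]
    return fn(spec, seed=seed)


def _rng(spec: ProcessSpec, seed) -> np.random.Generator:
    return np.random.default_rng(spec.seed if seed is None else seed)


def _meta(spec: ProcessSpec, seed) -> dict[str, Any]:
    return {
        "process": spec.process,
        "params": dict(spec.params),
        "M": spec.M,
        "seed": spec.seed if seed is None else seed,
        "theta_star": spec.theta_star.tolist(),
    }


def simulate_bm(spec: ProcessSpec, seed=None) -> TrajectoryEnsemble:
    """Brownian motion; observable = squared displacement from the origin.

    Sampling the increments directly between consecutive sampling times is
    exact for BM (independent Gaussian increments with per-component
    variance 2 D dt), so no finer integration grid is needed.
    """
    rng = _rng(spec, seed)
    p = spec.params
    d = int(p["d"])
    t = spec.times
    dt = np.diff(np.concatenate(([0.0], t)))
    incr = rng.standard_normal((spec.M, t.size, d)) * np.sqrt(2.0 * p["D"] * dt)[None, :, None]
    pos = np.cumsum(incr, axis=1)
    ens = squared_displacement(pos, t, meta=_meta(spec, seed))
    return ens


def fbm_msd_kernel(times: np.ndarray, H: float, K_f: float = 1.0) -> np.ndarray:
    """Per-component FBM position covariance K_f (t^2H + s^2H - |t-s|^2H)."""
    t = np.asarray(times, dtype=float)
    tt, ss = np.meshgrid(t, t, indexing="ij")
    return K_f * (tt ** (2 * H) + ss ** (2 * H) - np.abs(tt - ss) ** (2 * H))


def simulate_fbm(spec: ProcessSpec, seed=None) -> TrajectoryEnsemble:
    """Fractional Brownian motion by exact covariance factorisation.

    Each spatial component is drawn as a zero-mean Gaussian vector at the
    sampling times whose covariance is the exact FBM kernel, via a Cholesky
    factor of that N x N matrix (O(N^3), exact for arbitrary grids).
    """
    rng = _rng(spec, seed)
    p = spec.params
    d = int(p["d"])
    t = spec.times
    cov = fbm_msd_kernel(t, p["H"], p["K_f"])
    try:
        L = cholesky(cov, lower=True)
    except LinAlgError:
        # tiny diagonal lift for grids that are degenerate at machine precision
        jitter = 1e-12 * np.trace(cov) / t.size
        try:
            L = cholesky(cov + jitter * np.eye(t.size), lower=True)
        except LinAlgError as exc:
            raise LinAlgError(
                f"FBM covariance factorisation failed (H={p['H']}, N={t.size})"
            ) from exc
    z = rng.standard_normal((spec.M, t.size, d))
    pos = np.einsum("ij,mjk->mik", L, z)
    return squared_displacement(pos, t, meta=_meta(spec, seed))


def simulate_ctrw(spec: ProcessSpec, seed=None) -> TrajectoryEnsemble:
    """Continuous-time random walk: Pareto waits, iid Gaussian jumps.

    Waiting times follow psi(tau) = alpha tau0^alpha / tau^(1+alpha) for
    tau >= tau0 (tail exponent alpha in (0,1), so the mean wait is
    infinite); each completed wait triggers a jump with independent
    N(0, sigma_j^2) components.  The position at sampling time T is the sum
    of all jumps completed by T; before the first wait elapses the walker
    has not moved.
    """
    rng = _rng(spec, seed)
    p = spec.params
    alpha, tau0, sigma_j, d = p["alpha"], p["tau0"], p["sigma_j"], int(p["d"])
    t = spec.times
    t_max = t[-1]
    m = spec.M

    # draw waiting times in blocks until every trajectory's renewal clock
    # has passed t_max; block size anticipates ~(t_max/tau0)^alpha events
    n_guess = int(1.3 * (t_max / tau0) ** alpha) + 16
    block = min(max(n_guess, 64), 1 << 22)
    arrival_blocks: list[np.ndarray] = []
    offset = np.zeros(m)
    while np.any(offset <= t_max):
        waits = tau0 * rng.random((m, block)) ** (-1.0 / alpha)
        arr = offset[:, None] + np.cumsum(waits, axis=1)
        arrival_blocks.append(arr)
        offset = arr[:, -1]
    arrivals = np.concatenate(arrival_blocks, axis=1)

    counts = np.empty((m, t.size), dtype=np.intp)
    for j in range(m):
        counts[j] = np.searchsorted(arrivals[j], t, side="right")
    n_max = int(counts.max())

    jumps = rng.standard_normal((m, n_max, d)) * sigma_j
    walk = np.concatenate(
        [np.zeros((m, 1, d)), np.cumsum(jumps, axis=1)], axis=1
    )
    rows = np.arange(m)[:, None]
    pos = walk[rows, np.minimum(counts, n_max)]
    return squared_displacement(pos, t, meta=_meta(spec, seed))


def _dho_step_moments(theta1: float, noise: float, dt: float):
    """Exact one-step propagator and noise covariance of the DHO SDE.

    The critically damped Langevin system d(x, v) = A (x, v) dt + (0, noise) dW
    with A = [[0, 1], [-theta1^2, -2 theta1]] is linear, so the transition
    over any dt is Gaussian with mean exp(A dt) (x, v) and covariance
    Q(dt) = int_0^dt exp(A s) G exp(A^T s) ds, G = diag(0, noise^2); both are
    computed with the van Loan block-matrix exponential.
    """
    A = np.array([[0.0, 1.0], [-theta1 ** 2, -2.0 * theta1]])
    G = np.array([[0.0, 0.0], [0.0, noise ** 2]])
    blk = np.zeros((4, 4))
    blk[:2, :2] = -A
    blk[:2, 2:] = G
    blk[2:, 2:] = A.T
    F = expm(blk * dt)
    Phi = F[2:, 2:].T
    Q = Phi @ F[:2, 2:]
    Q = 0.5 * (Q + Q.T)
    return Phi, Q


def simulate_dho(spec: ProcessSpec, seed=None, method: str = "exact") -> TrajectoryEnsemble:
    """Damped harmonic oscillator at critical damping; observable = position.

    x(0) = x0, v(0) = 0.  ``method='exact'`` uses the exact Gaussian
    one-step update of the linear SDE (no discretisation bias, stepping
    directly between sampling times); ``method='euler'`` is an
    Euler--Maruyama integrator kept as a cross-check, with step
    <= 1/(50 theta1).
    """
    rng = _rng(spec, seed)
    p = spec.params
    theta1, x0, noise = p["theta1"], p["x0"], p["noise"]
    t = spec.times
    m = spec.M

    if method == "exact":
        grid = np.concatenate(([0.0], t))
        state = np.zeros((m, 2))
        state[:, 0] = x0
        out = np.empty((m, t.size))
        moments: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        for i, dt in enumerate(np.diff(grid)):
            key = round(float(dt), 15)
            if key not in moments:
                Phi, Q = _dho_step_moments(theta1, noise, dt)
                w, V = np.linalg.eigh(Q)
                Lq = V * np.sqrt(np.clip(w, 0.0, None))
                moments[key] = (Phi, Lq)
            Phi, Lq = moments[key]
            state = state @ Phi.T + rng.standard_normal((m, 2)) @ Lq.T
            out[:, i] = state[:, 0]
    elif method == "euler":
        dt_max = 1.0 / (50.0 * theta1)
        grid = [0.0]
        for ti in t:
            prev = grid[-1]
            n_sub = max(1, int(np.ceil((ti - prev) / dt_max)))
            grid.extend(prev + (ti - prev) * np.arange(1, n_sub + 1) / n_sub)
        grid = np.asarray(grid)
        keep = np.searchsorted(grid, t)
        x = np.full(m, float(x0))
        v = np.zeros(m)
        out = np.empty((m, t.size))
        col = {k: i for i, k in enumerate(keep)}
        for j, dt in enumerate(np.diff(grid), start=1):
            a = -2.0 * theta1 * v - theta1 ** 2 * x
            x = x + v * dt
            v = v + a * dt + noise * np.sqrt(dt) * rng.standard_normal(m)
            if j in col:
                out[:, col[j]] = x
    else:
        raise ValueError("method must be 'exact' or 'euler'")

    return TrajectoryEnsemble(t, out, "position", _meta(spec, seed))
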