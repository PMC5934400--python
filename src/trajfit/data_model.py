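"""Trajectory ensembles and their sample statistics.

An ensemble is M independent trajectories of one scalar observable, all
sampled on a common, strictly increasing time grid of N points.  Every
estimator in the package consumes the sample mean ``ybar``, the (unbiased)
sample covariance ``Q`` across trajectories, and the covariance of the mean
``C = Q / M`` computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryEnsemble",
    "SampleStats",
    "WeightMatrix",
    "squared_displacement",
    "compute_stats",
    "read_ensemble",
    "write_ensemble",
]


class EnsembleError(ValueError):
    """Raised for malformed trajectory-ensemble input."""


@dataclass
class TrajectoryEnsemble:
    """M trajectories of one observable on a shared time grid.

    Parameters
    ----------
    times : ndarray, shape (N,)
        Strictly increasing sampling times, in process-time units.
    values : ndarray, shape (M, N)
        ``values[m, i]`` is the observable of trajectory ``m`` at
        ``times[i]``.  No missing entries are allowed.
    observable_label : str
        Free-text label, e.g. ``"squared_displacement"`` or ``"position"``.
    meta : dict
        Generator parameters and seed for synthetic ensembles.
    """

    times: np.ndarray
    values: np.ndarray
    observable_label: str = "observable"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.times.size < 1:
            raise EnsembleError("times must be a 1-d array with N >= 1")
        if not np.all(np.isfinite(self.times)):
            raise EnsembleError("times must be finite")
        if np.any(np.diff(self.times) <= 0):
            raise EnsembleError("times must be strictly increasing")
        if self.values.shape[1] != self.times.size:
            raise EnsembleError(
                f"values has {self.values.shape[1]} columns but there are "
                f"{self.times.size} sampling times"
            )
        if not np.all(np.isfinite(self.values)):
            raise EnsembleError("values contains missing/non-finite entries")

    @property
    def n_trajectories(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.size

    def drop_t0(self) -> "TrajectoryEnsemble":
        """Return a copy without the first sampling time.

        The t = 0 point of displacement-type observables has zero sample
        variance and cannot be used as a weight; callers drop it explicitly.
        """
        if self.n_times < 2:
            raise EnsembleError("cannot drop the only sampling time")
        return TrajectoryEnsemble(
            self.times[1:], self.values[:, 1:], self.observable_label,
            dict(self.meta),
        )

    def subset(self, rows: np.ndarray) -> "TrajectoryEnsemble":
        """Ensemble restricted to the given trajectory indices."""
        return TrajectoryEnsemble(
            self.times, self.values[np.asarray(rows)], self.observable_label,
            dict(self.meta),
        )


@dataclass
class SampleStats:
    """Sample mean and covariance of an ensemble.

    ``mean[i]`` is the ensemble average over the M trajectories at time i,
    ``cov`` is the unbiased N x N sample covariance across trajectories
    (1/(M-1) normalisation), and ``cov_of_mean = cov / M`` estimates the
    covariance of the ensemble mean itself.
    """

    mean: np.ndarray
    cov: np.ndarray
    cov_of_mean: np.ndarray
    M: int


@dataclass
class WeightMatrix:
    """Symmetric positive-definite weight matrix R for the chi^2 cost.

    ``kind`` records how it was built; ``condition_number`` is that of the
    matrix inverted to build R, when an inversion was involved.
    """

    R: np.ndarray
    kind: str
    condition_number: float | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be a square matrix")
        if not np.allclose(self.R, self.R.T, rtol=0.0, atol=1e-10 * max(1.0, np.abs(self.R).max())):
            raise ValueError("R must be symmetric")


def squared_displacement(
    positions: np.ndarray,
    times: np.ndarray,
    origin: np.ndarray | None = None,
    meta: dict[str, Any] | None = None,
) -> TrajectoryEnsemble:
    """Squared displacement |x(t) - x(0)|^2 from raw positions.

    Parameters
    ----------
    positions : ndarray, shape (M, N, d)
        Position of each trajectory at each sampling time.  A 2-d input is
        interpreted as d = 1.
    times : ndarray, shape (N,)
        The sampling times the positions were recorded at.
    origin : ndarray, shape (M, d), optional
        Per-trajectory position at t = 0.  Defaults to the origin.

    Returns
    -------
    TrajectoryEnsemble
        ``values[m, i] = sum_k (positions[m, i, k] - origin[m, k])**2``,
        labelled ``"squared_displacement"``.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[:, :, None]
    if positions.ndim != 3:
        raise EnsembleError("positions must have shape (M, N, d)")
    if not np.all(np.isfinite(positions)):
        raise EnsembleError("positions must be finite")
    m, _, d = positions.shape
    if origin is None:
        origin = np.zeros((m, d))
    origin = np.asarray(origin, dtype=float)
    if origin.ndim == 1:
        origin = origin[:, None]
    if origin.shape != (m, d):
        raise EnsembleError(
            f"origin shape {origin.shape} does not match positions (expected {(m, d)})"
        )
    disp = positions - origin[:, None, :]
    values = np.einsum("mik,mik->mi", disp, disp)
    return TrajectoryEnsemble(
        times, values, "squared_displacement", meta or {}
    )


def compute_stats(ensemble: TrajectoryEnsemble) -> SampleStats:
    """Sample mean, covariance, and covariance of the mean of an ensemble.

    Requires at least two trajectories; the covariance is the unbiased
    estimator with a 1/(M-1) factor.
    """
    m = ensemble.n_trajectories
    if m < 2:
        raise EnsembleError("at least 2 trajectories are needed for a covariance")
    mean = ensemble.values.mean(axis=0)
    dev = ensemble.values - mean
    cov = dev.T @ dev / (m - 1)
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry
    return SampleStats(mean=mean, cov=cov, cov_of_mean=cov / m, M=m)


# ---------------------------------------------------------------------------
# I/O: wide CSV/TSV is the canonical interchange format.

_FLOAT_FMT = "%.17g"


def write_ensemble(ensemble: TrajectoryEnsemble, path) -> None:
    """Write an ensemble as wide CSV: header ``t,traj_1,...,traj_M``."""
    m = ensemble.n_trajectories
    frame = pd.DataFrame(
        np.column_stack([ensemble.times, ensemble.values.T]),
        columns=["t"] + [f"traj_{j + 1}" for j in range(m)],
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_ensemble(path, format: str = "wide", observable_label: str = "observable") -> TrajectoryEnsemble:
    """Read a trajectory ensemble from delimited text.

    ``wide``: first column is time, each remaining column one trajectory.
    ``long``: columns (trajectory_id, time, value); every trajectory must be
    sampled on the identical time grid, otherwise the offending trajectory
    is named in the error.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    if format == "wide":
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
        times = frame.iloc[:, 0].to_numpy(dtype=float)
        values = frame.iloc[:, 1:].to_numpy(dtype=float).T
        return TrajectoryEnsemble(times, values, observable_label)
    if format == "long":
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
        frame.columns = ["trajectory_id", "time", "value"]
        groups = dict(list(frame.groupby("trajectory_id", sort=True)))
        ref_id = next(iter(groups))
        ref_times = np.sort(groups[ref_id]["time"].to_numpy(dtype=float))
        rows = []
        for traj_id, grp in groups.items():
            grp = grp.sort_values("time")
            t = grp["time"].to_numpy(dtype=float)
            if t.shape != ref_times.shape or not np.array_equal(t, ref_times):
                raise EnsembleError(
                    f"trajectory {traj_id!r} is not sampled on the common "
                    f"time grid of trajectory {ref_id!r}"
                )
            rows.append(grp["value"].to_numpy(dtype=float))
        return TrajectoryEnsemble(ref_times, np.vstack(rows), observable_label)
    raise ValueError(f"unknown format {format!r} (expected 'wide' or 'long')")
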