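"""Parametric fit functions f(t; theta) with analytic derivatives.

The correlation-aware covariance estimator needs the first AND second
derivatives of the fit function in the parameters, so every built-in model
carries an analytic gradient and Hessian.  User-defined models may supply
only ``value``; finite-difference derivatives are then filled in with a
logged warning.

Conventions: ``t`` is the (N,) vector of sampling times; ``value`` returns
shape (N,), ``grad`` shape (N, K), ``hess`` shape (N, K, K).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FitModel",
    "model_linear",
    "model_power_law",
    "model_dho_mean",
    "model_constant",
    "get_model",
    "finite_difference_model",
]

log = logging.getLogger(__name__)


@dataclass
class FitModel:
    """A parametric curve f(t; theta) with derivatives in theta.

    ``default_init(times, ybar)`` returns a heuristic starting point for the
    optimiser.  ``bounds`` are simple box domain constraints, one
    ``(lo, hi)`` pair (entries may be None) per parameter.
    """

    name: str
    K: int
    value: Callable[[np.ndarray, np.ndarray], np.ndarray]
    grad: Callable[[np.ndarray, np.ndarray], np.ndarray]
    hess: Callable[[np.ndarray, np.ndarray], np.ndarray]
    param_names: Sequence[str] = ()
    default_init: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    bounds: Sequence[tuple[float | None, float | None]] | None = None

    def __post_init__(self) -> None:
        if not self.param_names:
            self.param_names = tuple(f"theta_{a + 1}" for a in range(self.K))

    def init_guess(self, times: np.ndarray, ybar: np.ndarray) -> np.ndarray:
        if self.default_init is not None:
            return np.asarray(self.default_init(times, ybar), dtype=float)
        return np.ones(self.K)


def model_linear() -> FitModel:
    """f(t) = theta1 * t — the mean-squared-displacement law of free diffusion.

    For d-dimensional Brownian motion with diffusion constant D the MSD is
    2dD*t, so theta1 estimates 2dD.
    """

    def value(t, th):
        return th[0] * t

    def grad(t, th):
        return t[:, None].copy()

    def hess(t, th):
        return np.zeros((t.size, 1, 1))

    def init(times, ybar):
        denom = float(times @ times)
        return np.array([float(times @ ybar) / denom if denom > 0 else 1.0])

    return FitModel("linear", 1, value, grad, hess, ("theta_1",), init)


def model_power_law() -> FitModel:
    """f(t) = theta1 * t**theta2 — anomalous-diffusion MSD (FBM, CTRW).

    Requires t > 0 since theta2 is in general non-integer.  The starting
    point is read off a log-log regression over the last half of the time
    points, where power-law scaling is most developed.
    """

    def _check(t):
        if np.any(t <= 0):
            raise ValueError("power-law model requires t > 0")

    def value(t, th):
        _check(t)
        return th[0] * t ** th[1]

    def grad(t, th):
        _check(t)
        p = t ** th[1]
        lg = np.log(t)
        return np.column_stack([p, th[0] * p * lg])

    def hess(t, th):
        _check(t)
        p = t ** th[1]
        lg = np.log(t)
        h = np.zeros((t.size, 2, 2))
        h[:, 0, 1] = h[:, 1, 0] = p * lg
        h[:, 1, 1] = th[0] * p * lg ** 2
        return h

    def init(times, ybar):
        n = times.size
        tail = slice(max(0, n - max(2, n // 2)), n)
        t_tail, y_tail = times[tail], ybar[tail]
        ok = y_tail > 0
        if ok.sum() >= 2 and np.ptp(np.log(t_tail[ok])) > 0:
            slope, intercept = np.polyfit(np.log(t_tail[ok]), np.log(y_tail[ok]), 1)
            return np.array([np.exp(intercept), slope])
        return np.array([max(ybar[-1] / times[-1], 1e-8), 1.0])

    return FitModel(
        "power_law", 2, value, grad, hess, ("theta_1", "theta_2"), init,
        bounds=((1e-12, None), (None, None)),
    )


def model_dho_mean(x0: float = 1.0) -> FitModel:
    """f(t) = x0 (1 + theta1 t) exp(-theta1 t) — critically damped oscillator.

    Mean position of a damped harmonic oscillator at critical damping with
    x(0) = x0 and v(0) = 0; theta1 > 0 is the damping/frequency parameter.
    """

    def value(t, th):
        return x0 * (1.0 + th[0] * t) * np.exp(-th[0] * t)

    def grad(t, th):
        return (-x0 * th[0] * t ** 2 * np.exp(-th[0] * t))[:, None]

    def hess(t, th):
        return (x0 * t ** 2 * (th[0] * t - 1.0) * np.exp(-th[0] * t))[:, None, None]

    def init(times, ybar):
        # crude: the mean first crosses x0/e^1*2 near t = 1/theta1
        tmid = times[len(times) // 2]
        return np.array([1.0 / tmid if tmid > 0 else 1.0])

    return FitModel(
        "dho_mean", 1, value, grad, hess, ("theta_1",), init,
        bounds=((1e-12, None),),
    )


def model_constant() -> FitModel:
    """f(t) = theta1 — the stationary case; the fit is the data mean."""

    def value(t, th):
        return np.full(t.size, th[0])

    def grad(t, th):
        return np.ones((t.size, 1))

    def hess(t, th):
        return np.zeros((t.size, 1, 1))

    def init(times, ybar):
        return np.array([float(np.mean(ybar))])

    return FitModel("constant", 1, value, grad, hess, ("theta_1",), init)


_BUILTINS: dict[str, Callable[..., FitModel]] = {
    "linear": model_linear,
    "power_law": model_power_law,
    "dho_mean": model_dho_mean,
    "constant": model_constant,
}


def get_model(name: str, **kwargs) -> FitModel:
    """Look up a built-in model by name (linear|power_law|dho_mean|constant)."""
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; built-ins: {sorted(_BUILTINS)}"
        ) from None
    return factory(**kwargs)


def finite_difference_model(
    name: str,
    K: int,
    value: Callable[[np.ndarray, np.ndarray], np.ndarray],
    step: float = 1e-6,
    **kwargs,
) -> FitModel:
    """Wrap a bare value function with central finite-difference derivatives.

    Intended for user-defined models without analytic derivatives; the
    covariance formula then inherits O(step^2) derivative error, which is
    why a warning is logged.
    """
    log.warning(
        "model %r uses finite-difference derivatives (step=%g); "
        "analytic derivatives are preferred for covariance estimation",
        name, step,
    )

    def grad(t, th):
        th = np.asarray(th, dtype=float)
        g = np.empty((t.size, K))
        for a in range(K):
            h = step * max(1.0, abs(th[a]))
            up, dn = th.copy(), th.copy()
            up[a] += h
            dn[a] -= h
            g[:, a] = (value(t, up) - value(t, dn)) / (2 * h)
        return g

    def hess(t, th):
        th = np.asarray(th, dtype=float)
        out = np.empty((t.size, K, K))
        for a in range(K):
            ha = step * max(1.0, abs(th[a]))
            up, dn = th.copy(), th.copy()
            up[a] += ha
            dn[a] -= ha
            out[:, a, :] = (grad(t, up) - grad(t, dn)) / (2 * ha)
        return 0.5 * (out + out.transpose(0, 2, 1))

    return FitModel(name, K, value, grad, hess, **kwargs)
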