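"""Embedded Dormand-Prince 4(5) adaptive integration with dense output.

The integrator advances with the seven-stage Dormand-Prince pair: the
5th-order solution propagates, the embedded 4th-order solution provides a
local error estimate, and the step size adapts so that the weighted error
norm stays at or below 1. The error weights are

    w_i = abs_tol + rel_tol * max(|y_i|, |y_high_i|)

and the norm is the max over components of |y_high - y_low| / w (a weighted
max-norm). Accepted steps retain the endpoint derivatives (free, by the
first-same-as-last property), enabling cubic Hermite dense output on any
grid inside the integrated span.

A classical fixed-step 4th-order Runge-Kutta routine (:func:`rk4_reference`)
is included as an independent reference for tests and fixture generation;
it shares nothing with the adaptive path beyond the right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import DomainError, IntegrationError
from .model import CompartmentalModel, ParameterSet

__all__ = [
    "SolverConfig",
    "StepResult",
    "Trajectory",
    "dp45_step",
    "integrate",
    "rk4_reference",
    "sample",
]

# Dormand-Prince 4(5) Butcher tableau.
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = [
    np.array([]),
    np.array([1 / 5]),
    np.array([3 / 40, 9 / 40]),
    np.array([44 / 45, -56 / 15, 32 / 9]),
    np.array([19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729]),
    np.array([9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656]),
    np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84]),
]
# 5th-order weights (propagating solution); note b5 == A[6]: first-same-as-last.
_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
# Embedded 4th-order weights.
_B4 = np.array(
    [5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40]
)


@dataclass(frozen=True)
class SolverConfig:
    """Step-control settings for the adaptive integrator.

    Defaults reproduce the behaviour of a standard RK45 run at relative
    tolerance 1e-5: elementary controller with safety factor 0.9, step-change
    clamp [0.2, 5], automatic initial step.
    """

    rel_tol: float = 1e-5
    abs_tol: float = 1e-6
    initial_step: float | None = None
    min_step: float = 1e-12
    max_step: float = np.inf
    safety_factor: float = 0.9
    step_growth_clamp: tuple[float, float] = (0.2, 5.0)
    max_accepted_steps: int = 1_000_000

    def __post_init__(self):
        if not self.rel_tol > 0:
            raise DomainError(f"rel_tol must be > 0, got {self.rel_tol!r}")
        if self.abs_tol < 0:
            raise DomainError(f"abs_tol must be >= 0, got {self.abs_tol!r}")
        if not (0 < self.min_step <= self.max_step):
            raise DomainError(
                f"need 0 < min_step <= max_step, got {self.min_step!r}, {self.max_step!r}"
            )
        lo, hi = self.step_growth_clamp
        if not (lo <= 1.0 <= hi):
            raise DomainError(f"step_growth_clamp must contain 1, got {(lo, hi)!r}")


@dataclass(frozen=True)
class StepResult:
    """One trial Dormand-Prince step.

    ``y_high`` is the 5th-order advance, ``y_low`` the embedded 4th-order
    advance; ``error_norm`` is the weighted max-norm of their difference
    (acceptable when <= 1). ``f_start``/``f_end`` are the derivative at the
    step's endpoints (the latter reusable for the next step and for Hermite
    interpolation).
    """

    y_high: np.ndarray
    y_low: np.ndarray
    error_norm: float
    f_start: np.ndarray
    f_end: np.ndarray


def dp45_step(
    f: Callable[[float, np.ndarray], np.ndarray],
    t: float,
    y: np.ndarray,
    h: float,
    rel_tol: float = 1e-5,
    abs_tol: float = 1e-6,
    f_start: np.ndarray | None = None,
) -> StepResult:
    """Take one embedded Dormand-Prince 4(5) step of size ``h`` from ``(t, y)``.

    ``f_start`` may pass a precomputed derivative at ``(t, y)`` (the
    first-same-as-last stage of a previous accepted step).

    Raises
    ------
    IntegrationError
        If any stage evaluates to a non-finite value; the caller should
        shrink ``h`` and retry.
    """
    if not h > 0:
        raise DomainError(f"step size must be > 0, got {h!r}")
    y = np.asarray(y, dtype=float)
    k = np.empty((7, y.size))
    k[0] = f(t, y) if f_start is None else np.asarray(f_start, dtype=float)
    with np.errstate(invalid="ignore", over="ignore"):  # caught just below
        for i in range(1, 7):
            yi = y + h * (_A[i] @ k[:i])
            k[i] = f(t + _C[i] * h, yi)
    if not np.all(np.isfinite(k)):
        raise IntegrationError(f"non-finite stage value at t={t!r}, h={h!r}", t_reached=t)
    y_high = y + h * (_B5 @ k)
    y_low = y + h * (_B4 @ k)
    weights = abs_tol + rel_tol * np.maximum(np.abs(y), np.abs(y_high))
    weights = np.maximum(weights, 1e-300)  # abs_tol=0 with a zero component
    scaled = np.abs(y_high - y_low) / weights
    error_norm = float(np.max(scaled)) if scaled.size else 0.0
    if not np.isfinite(error_norm):
        error_norm = np.inf
    return StepResult(
        y_high=y_high, y_low=y_low, error_norm=error_norm, f_start=k[0], f_end=k[6]
    )


@dataclass
class Trajectory:
    """Times, states and (optionally) endpoint derivatives of an ODE solution.

    ``derivatives`` holds the right-hand side evaluated at each stored time;
    when present, :func:`sample` can interpolate with a cubic Hermite
    polynomial on each interval.
    """

    times: np.ndarray
    states: np.ndarray
    labels: tuple[str, ...]
    provenance: dict = field(default_factory=dict)
    derivatives: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(self.labels)):
            raise DomainError(
                f"states shape {self.states.shape} inconsistent with "
                f"{self.times.size} times and labels {self.labels}"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def column(self, label: str) -> np.ndarray:
        """State history of one compartment by label."""
        try:
            return self.states[:, self.labels.index(label)]
        except ValueError:
            raise KeyError(
                f"no compartment {label!r} in trajectory with labels {self.labels}"
            ) from None

    def to_dataframe(self):
        """Trajectory as a pandas DataFrame with a ``time`` column."""
        import pandas as pd

        data = {"time": self.times}
        data.update({lab: self.states[:, j] for j, lab in enumerate(self.labels)})
        return pd.DataFrame(data)


def _as_y0(y0) -> np.ndarray:
    arr = y0.as_array() if hasattr(y0, "as_array") else np.asarray(y0, dtype=float)
    arr = np.atleast_1d(arr.astype(float))
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"initial state must be finite, got {arr!r}")
    return arr


def _bind(model, params, n_ref, y0):
    """Resolve ``model`` to a plain callable f(t, y) -> ndarray plus labels."""
    if isinstance(model, CompartmentalModel):
        if n_ref is None and model.spec.incidence_n_mode == "fixed_at_initial":
            n_ref = float(np.sum(y0))
            if n_ref <= 0:
                # Incidence terms vanish with an empty system; any positive
                # denominator gives the same (zero) rates.
                n_ref = 1.0
        return model.bind(params, n_ref=n_ref), model.labels
    if callable(model):
        if params is None:
            return model, None
        return (lambda t, y: model(t, y, params)), None
    raise DomainError(f"model must be a CompartmentalModel or callable, got {model!r}")


def _initial_step(f, t0, y0, f0, direction_span, rel_tol, abs_tol):
    """Standard ||y||/||f|| heuristic for the first trial step."""
    scale = np.maximum(abs_tol + rel_tol * np.abs(y0), 1e-300)
    d0 = float(np.max(np.abs(y0) / scale)) if y0.size else 0.0
    d1 = float(np.max(np.abs(f0) / scale)) if y0.size else 0.0
    h0 = 1e-6 if (d0 < 1e-5 or d1 < 1e-5) else 0.01 * d0 / d1
    h0 = min(h0, direction_span)
    y1 = y0 + h0 * f0
    f1 = f(t0 + h0, y1)
    d2 = float(np.max(np.abs(f1 - f0) / scale)) / h0
    if max(d1, d2) <= 1e-15:
        h1 = max(1e-6, h0 * 1e-3)
    else:
        h1 = (0.01 / max(d1, d2)) ** 0.2
    return min(100 * h0, h1, direction_span)


def integrate(
    model,
    y0,
    t0: float,
    t_max: float,
    params: ParameterSet | Mapping[str, float] | None = None,
    config: SolverConfig | None = None,
    n_ref: float | None = None,
    labels: tuple[str, ...] | None = None,
) -> Trajectory:
    """Integrate ``model`` from ``t0`` to ``t_max`` with adaptive DP45 steps.

    Parameters
    ----------
    model : CompartmentalModel or callable
        Either a compiled compartmental model, or a plain right-hand side
        ``f(t, y)`` (``f(t, y, params)`` if ``params`` is given).
    y0 : StateVector or array-like
        Initial state.
    t0, t_max : float
        Integration span in days; ``t_max > t0``.
    params : ParameterSet or mapping, optional
        Model parameters (required for CompartmentalModel).
    config : SolverConfig, optional
        Tolerances and step control; defaults reproduce rel_tol 1e-5.
    n_ref : float, optional
        Incidence denominator override. If omitted, a ``fixed_at_initial``
        model freezes N at ``sum(y0)``; a ``dynamic`` model recomputes it
        every evaluation.
    labels : tuple of str, optional
        Component labels for callable models (defaults to y0..yk).

    Returns
    -------
    Trajectory
        States at every accepted step, with endpoint derivatives retained
        for dense output. The final time is exactly ``t_max``.
    """
    if not t_max > t0:
        raise DomainError(f"need t_max > t0, got {t0!r} .. {t_max!r}")
    config = config or SolverConfig()
    y = _as_y0(y0)
    f, model_labels = _bind(model, params, n_ref, y)
    if labels is None:
        labels = model_labels or tuple(f"y{i}" for i in range(y.size))

    times = [float(t0)]
    states = [y.copy()]
    f_now = np.asarray(f(t0, y), dtype=float)
    derivs = [f_now.copy()]

    span = float(t_max - t0)
    h = config.initial_step or _initial_step(
        f, t0, y, f_now, span, config.rel_tol, config.abs_tol
    )
    h = float(np.clip(h, config.min_step, min(config.max_step, span)))
    lo, hi = config.step_growth_clamp
    t = float(t0)
    accepted = 0
    end_snap = 1e-12 * max(1.0, abs(t_max))
    while t < t_max:
        h = min(h, t_max - t, config.max_step)
        if h < config.min_step and abs(t + h - t_max) > end_snap:
            raise IntegrationError(
                f"step size underflow ({h!r} < min_step) at t={t!r}", t_reached=t
            )
        try:
            step = dp45_step(
                f, t, y, h,
                rel_tol=config.rel_tol, abs_tol=config.abs_tol, f_start=f_now,
            )
            err = step.error_norm
        except IntegrationError:
            err = np.inf
            step = None
        if err <= 1.0:
            t = t_max if abs(t + h - t_max) <= end_snap else t + h
            y = step.y_high
            f_now = step.f_end
            times.append(t)
            states.append(y.copy())
            derivs.append(f_now.copy())
            accepted += 1
            if accepted > config.max_accepted_steps:
                raise IntegrationError(
                    f"exceeded max_accepted_steps={config.max_accepted_steps}",
                    t_reached=t,
                )
        # Elementary controller: h <- h * clamp(safety * err^(-1/5)).
        factor = hi if err == 0 else config.safety_factor * err ** -0.2
        h *= float(np.clip(factor, lo, hi))
        if h < config.min_step and t < t_max:
            raise IntegrationError(
                f"step size underflow ({h!r} < min_step) at t={t!r}", t_reached=t
            )

    return Trajectory(
        times=np.array(times),
        states=np.vstack(states),
        labels=tuple(labels),
        derivatives=np.vstack(derivs),
        provenance={
            "method": "dp45",
            "rel_tol": config.rel_tol,
            "abs_tol": config.abs_tol,
            "accepted_steps": accepted,
        },
    )


def sample(traj: Trajectory, grid) -> Trajectory:
    """Evaluate a trajectory on an arbitrary grid inside its span.

    Uses the cubic Hermite interpolant on each stored interval (endpoint
    values and derivatives), whose error is of the same order as the
    integration tolerance at the default settings. Grid points that coincide
    with stored times reproduce the stored states exactly.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise DomainError("grid must be a non-empty 1-D array of times")
    if np.any(np.diff(grid) <= 0):
        raise DomainError("grid times must be strictly increasing")
    t = traj.times
    if grid[0] < t[0] - 1e-12 or grid[-1] > t[-1] + 1e-12:
        raise DomainError(
            f"grid [{grid[0]!r}, {grid[-1]!r}] outside integrated span "
            f"[{t[0]!r}, {t[-1]!r}]"
        )
    if traj.derivatives is None:
        raise DomainError("trajectory has no stored derivatives; cannot interpolate")

    # Interval index for each grid point; exact node hits resolved below.
    idx = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, t.size - 2)
    h = t[idx + 1] - t[idx]
    theta = (grid - t[idx]) / h
    th2 = theta * theta
    th3 = th2 * theta
    h00 = 2 * th3 - 3 * th2 + 1
    h10 = th3 - 2 * th2 + theta
    h01 = -2 * th3 + 3 * th2
    h11 = th3 - th2
    y0 = traj.states[idx]
    y1 = traj.states[idx + 1]
    d0 = traj.derivatives[idx]
    d1 = traj.derivatives[idx + 1]
    out = (
        h00[:, None] * y0
        + (h10 * h)[:, None] * d0
        + h01[:, None] * y1
        + (h11 * h)[:, None] * d1
    )
    # Reproduce stored states exactly where the grid hits a node.
    exact = np.isclose(theta, 0.0, atol=1e-12)
    out[exact] = y0[exact]
    exact_end = np.isclose(theta, 1.0, atol=1e-12)
    out[exact_end] = y1[exact_end]

    return Trajectory(
        times=grid.copy(),
        states=out,
        labels=traj.labels,
        provenance={**traj.provenance, "sampled": True},
    )


def rk4_reference(
    model,
    y0,
    t0: float,
    t_max: float,
    h: float,
    params: ParameterSet | Mapping[str, float] | None = None,
    n_ref: float | None = None,
    labels: tuple[str, ...] | None = None,
) -> Trajectory:
    """Classical fixed-step 4th-order Runge-Kutta integration.

    Independent of the adaptive path; intended as a reference for tests and
    fixture generation. ``h`` must divide ``t_max - t0`` within rounding.
    """
    if not t_max > t0:
        raise DomainError(f"need t_max > t0, got {t0!r} .. {t_max!r}")
    if not h > 0:
        raise DomainError(f"step size must be > 0, got {h!r}")
    n_steps = round((t_max - t0) / h)
    if n_steps < 1 or abs(t0 + n_steps * h - t_max) > 1e-9 * max(1.0, abs(t_max)):
        raise DomainError(f"h={h!r} does not divide the span [{t0!r}, {t_max!r}]")

    y = _as_y0(y0)
    f, model_labels = _bind(model, params, n_ref, y)
    if labels is None:
        labels = model_labels or tuple(f"y{i}" for i in range(y.size))

    times = t0 + np.arange(n_steps + 1) * h
    times[-1] = t_max
    states = np.empty((n_steps + 1, y.size))
    derivs = np.empty((n_steps + 1, y.size))
    states[0] = y
    for i in range(n_steps):
        t = times[i]
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        derivs[i] = k1
        y = y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite state at t={times[i + 1]!r}", t_reached=float(t)
            )
        states[i + 1] = y
    derivs[-1] = f(times[-1], y)

    return Trajectory(
        times=times,
        states=states,
        labels=tuple(labels),
        derivatives=derivs,
        provenance={"method": "rk4", "h": h},
    )
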