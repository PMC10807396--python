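"""Fixed-step Adams predictor-corrector integration of the rhythm models.

Reference trajectories are produced with the classical 4th-order
Adams-Bashforth-Moulton scheme in predict-evaluate-correct-evaluate
(PECE) mode, started with three steps of the classical Runge-Kutta
method.  A fixed step is used deliberately: the surrogate network is
trained on a uniform time grid, so the integrator samples exactly the
nodes the dataset needs.

Quadratic ODEs can blow up in finite time; the integrator aborts with a
diagnostic naming the failure time as soon as any state component
exceeds a configurable bound (default 1e6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .models import QuadraticODEModel, rhs

__all__ = [
    "TimeGrid",
    "Trajectory",
    "Dataset",
    "IntegrationDivergence",
    "build_grid",
    "integrate_adams",
    "generate_dataset",
]

#: Abort threshold on |y| during integration.
BLOWUP_BOUND = 1.0e6

# Classical coefficients of the 4-step Adams-Bashforth predictor and the
# 3-step Adams-Moulton corrector (both order 4).
_AB4 = np.array([55.0, -59.0, 37.0, -9.0]) / 24.0
_AM4 = np.array([9.0, 19.0, -5.0, 1.0]) / 24.0


class IntegrationDivergence(RuntimeError):
    """Raised when a trajectory leaves the allowed amplitude bound."""

    def __init__(self, t: float, y: np.ndarray, bound: float):
        self.t = float(t)
        self.y = np.asarray(y)
        self.bound = float(bound)
        super().__init__(
            f"trajectory exceeded |y| = {bound:g} at t = {t:.6g} "
            f"(state {np.array2string(self.y, precision=4)}); the quadratic model "
            "blows up in finite time from this initial state — choose a "
            "different y0 or a shorter time span"
        )


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid covering ``[t0, t1]`` with spacing ``step``."""

    t0: float
    t1: float
    step: float
    times: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.times.shape[0]


@dataclass(frozen=True)
class Trajectory:
    """States sampled on a time grid; ``states`` is ``k x N``."""

    grid: TimeGrid
    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=float)
        if states.ndim != 2 or states.shape[1] != self.grid.n:
            raise ValueError(
                f"states must be k x {self.grid.n}, got {states.shape}"
            )
        if not np.isfinite(states).all():
            raise ValueError("trajectory states must be finite")
        object.__setattr__(self, "states", states)

    @property
    def k(self) -> int:
        return self.states.shape[0]


@dataclass(frozen=True)
class Dataset:
    """Training data for the surrogate: time inputs and state targets.

    ``inputs`` is the 1-D time vector (length N), ``targets`` the k x N
    state block — N scalar inputs map to k*N scalar targets.
    ``provenance`` records how the data were produced (model id, grid,
    initial state, integrator) for reproducibility.
    """

    inputs: np.ndarray
    targets: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        inputs = np.asarray(self.inputs, dtype=float)
        targets = np.asarray(self.targets, dtype=float)
        if inputs.ndim != 1 or targets.ndim != 2 or targets.shape[1] != inputs.shape[0]:
            raise ValueError(
                f"targets must be k x {inputs.shape[0]}, got {targets.shape}"
            )
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "targets", targets)

    @property
    def n(self) -> int:
        return self.inputs.shape[0]

    @property
    def k(self) -> int:
        return self.targets.shape[0]

    @property
    def n_scalar_targets(self) -> int:
        return self.targets.size


def build_grid(t0: float, t1: float, step: float) -> TimeGrid:
    """Build the uniform grid on ``[t0, t1]``; the node count is
    ``round((t1 - t0)/step) + 1`` so both endpoints are included."""
    if not (t1 > t0):
        raise ValueError(f"need t1 > t0, got [{t0}, {t1}]")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if step > t1 - t0:
        raise ValueError(f"step {step} exceeds the span {t1 - t0}")
    n = int(round((t1 - t0) / step)) + 1
    times = t0 + step * np.arange(n)
    return TimeGrid(t0=float(t0), t1=float(t1), step=float(step), times=times)


def _rk4_step(model: QuadraticODEModel, y: np.ndarray, h: float) -> np.ndarray:
    k1 = rhs(model, y)
    k2 = rhs(model, y + 0.5 * h * k1)
    k3 = rhs(model, y + 0.5 * h * k2)
    k4 = rhs(model, y + h * k3)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate_adams(
    model: QuadraticODEModel,
    y0: np.ndarray,
    grid: TimeGrid,
    *,
    bound: float = BLOWUP_BOUND,
) -> Trajectory:
    """Integrate the model over the grid with ABM4 in PECE mode.

    The first three steps use classical RK4 so the 4-step history needed
    by the Adams-Bashforth predictor is available at full order.  After
    the Adams-Moulton correction the right-hand side is re-evaluated at
    the corrected point (the trailing E of PECE), keeping the stored
    derivative history consistent.
    """
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (model.k,):
        raise ValueError(f"y0 must have length {model.k}, got shape {y0.shape}")
    if not np.isfinite(y0).all():
        raise ValueError("y0 must be finite")

    n = grid.n
    h = grid.step
    states = np.empty((model.k, n))
    states[:, 0] = y0
    if n == 1:
        return Trajectory(grid=grid, states=states)

    derivs = np.empty((n, model.k))
    derivs[0] = rhs(model, y0)

    def check(i: int, y: np.ndarray) -> None:
        if not np.isfinite(y).all() or np.abs(y).max() > bound:
            raise IntegrationDivergence(grid.times[i], y, bound)

    # RK4 startup for the first min(3, n-1) steps
    n_start = min(3, n - 1)
    for i in range(n_start):
        y = _rk4_step(model, states[:, i], h)
        check(i + 1, y)
        states[:, i + 1] = y
        derivs[i + 1] = rhs(model, y)

    for i in range(n_start, n - 1):
        hist = derivs[i - 3 : i + 1][::-1]  # f_i, f_{i-1}, f_{i-2}, f_{i-3}
        y_pred = states[:, i] + h * (_AB4 @ hist)
        check(i + 1, y_pred)
        f_pred = rhs(model, y_pred)
        hist_c = np.vstack([f_pred, hist[:3]])  # f*_{i+1}, f_i, f_{i-1}, f_{i-2}
        y_corr = states[:, i] + h * (_AM4 @ hist_c)
        check(i + 1, y_corr)
        states[:, i + 1] = y_corr
        derivs[i + 1] = rhs(model, y_corr)

    return Trajectory(grid=grid, states=states)


def generate_dataset(
    model: QuadraticODEModel,
    y0: np.ndarray,
    grid: TimeGrid,
    *,
    model_id: Any = None,
) -> Dataset:
    """Integrate the model and assemble the surrogate's training data
    (inputs = grid times, targets = states), with provenance recorded."""
    traj = integrate_adams(model, y0, grid)
    provenance = {
        "model_id": model_id,
        "t0": grid.t0,
        "t1": grid.t1,
        "step": grid.step,
        "y0": list(np.asarray(y0, dtype=float)),
        "integrator": "abm4-pece/rk4-start",
    }
    return Dataset(inputs=grid.times, targets=traj.states, provenance=provenance)
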