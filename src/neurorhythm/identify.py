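"""Recovering the quadratic coefficient matrix from rhythm time series.

The inverse problem: given (possibly noisy) multichannel measurements
``x_q(t_i) = y_q(t_i) + eps_q(t_i)`` of the rhythms on a uniform grid,
estimate the packed coefficient matrix D of the generating quadratic ODE
system.  The forward construction stacks one row of degree-<=2 monomials
per time sample (the design matrix Y), estimates the state derivatives
(the matrix Y-dot), and solves ``Y @ D^T ~= Y-dot`` per equation by
ordinary least squares.

Derivatives are estimated by 4th-order finite differences (central in
the interior, one-sided at the first/last two nodes); for noise-free
validation the analytic right-hand side can be used instead.  This
module doubles as the synthetic-fixture generator: it creates the noisy
measurement channels the identification stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrate import TimeGrid, Trajectory
from .models import (
    CoefficientMatrixD,
    QuadraticODEModel,
    monomial_features,
    packed_width,
    rhs,
)

__all__ = [
    "NoisyRhythms",
    "add_measurement_noise",
    "estimate_derivatives",
    "design_matrix",
    "fit_coefficients",
    "analytic_derivatives",
]


@dataclass(frozen=True)
class NoisyRhythms:
    """Measured rhythm channels: the latent trajectory plus i.i.d.
    Gaussian measurement noise of standard deviation ``sigma``."""

    grid: TimeGrid
    channels: np.ndarray  # k x N
    sigma: float
    seed: int

    @property
    def k(self) -> int:
        return self.channels.shape[0]


def add_measurement_noise(
    trajectory: Trajectory, sigma: float, seed: int
) -> NoisyRhythms:
    """Simulate EEG-style measurements ``x = y + eps``, eps ~ N(0, sigma^2)
    i.i.d. per channel and sample."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=trajectory.states.shape) if sigma > 0 else 0.0
    return NoisyRhythms(
        grid=trajectory.grid,
        channels=trajectory.states + noise,
        sigma=float(sigma),
        seed=int(seed),
    )


# 4th-order one-sided stencils for the first two nodes (mirrored and
# negated for the last two); interior uses the 5-point central stencil.
_FWD0 = np.array([-25.0, 48.0, -36.0, 16.0, -3.0]) / 12.0
_FWD1 = np.array([-3.0, -10.0, 18.0, -6.0, 1.0]) / 12.0


def estimate_derivatives(source: Trajectory | NoisyRhythms) -> np.ndarray:
    """Estimate d y / d t on the grid by 4th-order finite differences.

    Returns an N x k matrix.  Requires at least 5 samples on a uniform
    grid; exact for polynomials up to degree 4.
    """
    if isinstance(source, NoisyRhythms):
        states, grid = source.channels, source.grid
    else:
        states, grid = source.states, source.grid
    t = grid.times
    if t.size < 5:
        raise ValueError("derivative estimation needs at least 5 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
        raise ValueError("derivative estimation requires a uniform grid")
    h = float(dt[0])
    y = states  # (k, N)
    n = t.size
    d = np.empty_like(y)
    d[:, 2:-2] = (y[:, :-4] - 8 * y[:, 1:-3] + 8 * y[:, 3:-1] - y[:, 4:]) / (12 * h)
    d[:, 0] = y[:, :5] @ _FWD0 / h
    d[:, 1] = y[:, :5] @ _FWD1 / h
    d[:, -1] = -(y[:, -5:][:, ::-1] @ _FWD0) / h
    d[:, -2] = -(y[:, -5:][:, ::-1] @ _FWD1) / h
    return d.T


def analytic_derivatives(model: QuadraticODEModel, states: np.ndarray) -> np.ndarray:
    """Exact derivatives via the model right-hand side (noise-free
    validation path).  ``states`` is k x N; returns N x k."""
    return np.array([rhs(model, states[:, i]) for i in range(states.shape[1])])


def design_matrix(states: np.ndarray) -> np.ndarray:
    """Stack monomial feature rows for every sample: N x j, first column
    all ones."""
    states = np.asarray(states, dtype=float)
    return np.array([monomial_features(states[:, i]) for i in range(states.shape[1])])


def fit_coefficients(
    states: np.ndarray,
    derivatives: np.ndarray,
    *,
    ridge: float = 0.0,
    cond_max: float = 1e12,
) -> CoefficientMatrixD:
    """Least-squares estimate of the packed coefficient matrix D.

    Solves ``Y @ D^T ~= Y-dot`` with Y the N x j monomial design matrix,
    one ordinary least-squares problem per equation row (they share the
    design, so one factorization serves all rows).  An optional ridge
    penalty stabilises ill-conditioned noisy fits.

    Raises when N < j or the design is rank deficient / worse conditioned
    than ``cond_max`` (e.g. a constant trajectory, which spans a single
    point in monomial space).
    """
    states = np.asarray(states, dtype=float)
    derivatives = np.asarray(derivatives, dtype=float)
    k, n = states.shape
    if derivatives.shape != (n, k):
        raise ValueError(
            f"derivatives must be {n}x{k}, got {derivatives.shape}"
        )
    j = packed_width(k)
    if n < j:
        raise ValueError(f"need at least j = {j} samples, got {n}")
    Y = design_matrix(states)
    cond = np.linalg.cond(Y)
    if not np.isfinite(cond) or cond > cond_max:
        raise ValueError(
            f"design matrix is rank deficient or ill conditioned "
            f"(condition number {cond:.3g} > {cond_max:g}); the trajectory "
            "does not excite all quadratic monomials"
        )
    if ridge > 0:
        A = Y.T @ Y + ridge * np.eye(j)
        Dt = np.linalg.solve(A, Y.T @ derivatives)
    else:
        Dt, *_ = np.linalg.lstsq(Y, derivatives, rcond=None)
    return CoefficientMatrixD(k=k, entries=Dt.T)
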