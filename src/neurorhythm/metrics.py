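"""Surrogate-quality metrics: MSE/absolute error, regression index R,
error histograms and phase-portrait extraction.

The MSE is reported per state channel, ``MSE_yq = mean((y_q - y~_q)^2)``,
and pooled over all channels; the regression index R is the Pearson
correlation between flattened reference and predicted values (the
statistic regression scatter plots of fitting tools report, not R^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrate import Trajectory

__all__ = [
    "MetricsReport",
    "ErrorHistogram",
    "mse_per_state",
    "absolute_error",
    "regression_index",
    "error_histogram",
    "phase_portrait_data",
    "evaluate_fit",
]


@dataclass(frozen=True)
class MetricsReport:
    """Per-state and pooled error metrics on one subset of samples."""

    subset: str
    mse: np.ndarray          # (k,) per-state MSE
    mse_pooled: float
    max_abs_error: np.ndarray
    mean_abs_error: np.ndarray
    r: np.ndarray            # (k,) per-state Pearson R
    r_pooled: float

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "mse": self.mse.tolist(),
            "mse_pooled": self.mse_pooled,
            "max_abs_error": self.max_abs_error.tolist(),
            "mean_abs_error": self.mean_abs_error.tolist(),
            "r": self.r.tolist(),
            "r_pooled": self.r_pooled,
        }


@dataclass(frozen=True)
class ErrorHistogram:
    """Uniform-bin histogram of pooled residuals."""

    edges: np.ndarray
    counts: np.ndarray
    zero_bin: int
    zero_bin_center: float


def _check_shapes(reference: np.ndarray, predicted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    reference = np.asarray(reference, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if reference.shape != predicted.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs predicted {predicted.shape}"
        )
    return np.atleast_2d(reference), np.atleast_2d(predicted)


def mse_per_state(reference: np.ndarray, predicted: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-state MSE ``mean((y_q - y~_q)^2)`` and the pooled MSE over all
    k*N squared residuals."""
    reference, predicted = _check_shapes(reference, predicted)
    sq = (reference - predicted) ** 2
    return sq.mean(axis=1), float(sq.mean())


def absolute_error(reference: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Elementwise absolute error ``|y - y~|`` (k x N)."""
    reference, predicted = _check_shapes(reference, predicted)
    return np.abs(reference - predicted)


def regression_index(
    reference: np.ndarray, predicted: np.ndarray, subset: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Pearson correlation R between reference and predicted values,
    per state and pooled over all states flattened.

    Undefined (raises) when the reference is constant on the subset.
    """
    reference, predicted = _check_shapes(reference, predicted)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        reference = reference[:, subset]
        predicted = predicted[:, subset]
    if reference.shape[1] < 2:
        raise ValueError("regression index needs at least 2 samples")
    per_state = np.empty(reference.shape[0])
    for q in range(reference.shape[0]):
        if np.ptp(reference[q]) == 0:
            raise ValueError(f"reference state {q + 1} is constant — R undefined")
        per_state[q] = np.corrcoef(reference[q], predicted[q])[0, 1]
    if np.ptp(reference) == 0:
        raise ValueError("reference is constant — pooled R undefined")
    pooled = float(np.corrcoef(reference.ravel(), predicted.ravel())[0, 1])
    return per_state, pooled


def error_histogram(residuals: np.ndarray, bins: int = 20) -> ErrorHistogram:
    """Histogram of residuals over ``bins`` uniform bins spanning their
    range, reporting which bin straddles zero error and its center."""
    residuals = np.asarray(residuals, dtype=float).ravel()
    if residuals.size == 0:
        raise ValueError("residuals must be non-empty")
    lo, hi = residuals.min(), residuals.max()
    if lo == hi:  # degenerate range: one occupied bin around the value
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(residuals, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    zero_bin = int(np.clip(np.searchsorted(edges, 0.0, side="right") - 1, 0, bins - 1))
    return ErrorHistogram(
        edges=edges, counts=counts, zero_bin=zero_bin,
        zero_bin_center=float(centers[zero_bin]),
    )


def phase_portrait_data(trajectory: Trajectory) -> dict[str, np.ndarray]:
    """Pairwise and full-state point sequences of a trajectory for
    parametric (phase-portrait) plotting; no resampling."""
    y = trajectory.states
    k = y.shape[0]
    out: dict[str, np.ndarray] = {}
    for i in range(k):
        for j in range(i + 1, k):
            out[f"y{i + 1}_y{j + 1}"] = np.column_stack([y[i], y[j]])
    out["all"] = y.T.copy()
    return out


def evaluate_fit(
    reference: np.ndarray,
    predicted: np.ndarray,
    subset: np.ndarray | None = None,
    tag: str = "all",
) -> MetricsReport:
    """Bundle MSE, absolute-error and regression metrics on one subset."""
    reference, predicted = _check_shapes(reference, predicted)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        reference = reference[:, subset]
        predicted = predicted[:, subset]
    mse, pooled = mse_per_state(reference, predicted)
    ae = absolute_error(reference, predicted)
    r, r_pooled = regression_index(reference, predicted)
    return MetricsReport(
        subset=tag,
        mse=mse,
        mse_pooled=pooled,
        max_abs_error=ae.max(axis=1),
        mean_abs_error=ae.mean(axis=1),
        r=r,
        r_pooled=r_pooled,
    )
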