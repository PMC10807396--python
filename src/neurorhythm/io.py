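"""CSV/JSON artifact input and output.

All CSV artifacts use '.' decimals and repr-faithful floats (the
shortest decimal string that round-trips to the same double), so written
and re-read values are bit-identical.
"""

from __future__ import annotations

import csv
import json
from typing import Optional

import numpy as np

from .identify import NoisyRhythms
from .integrate import Dataset, TimeGrid, Trajectory, build_grid
from .models import (
    CoefficientMatrixD,
    QuadraticODEModel,
    monomial_names,
    packed_width,
)
from .training import TrainRecord

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_dataset",
    "write_train_record",
    "write_noisy_rhythms",
    "read_rhythms_csv",
    "write_packed_coefficients",
    "read_packed_coefficients",
    "write_model_json",
    "read_model_json",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def _channel_header(k: int, prefix: str) -> list[str]:
    return ["t"] + [f"{prefix}{i + 1}" for i in range(k)]


def _write_channels(path, times: np.ndarray, values: np.ndarray, prefix: str) -> None:
    k = values.shape[0]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_channel_header(k, prefix))
        for i, t in enumerate(times):
            writer.writerow([_fmt(t)] + [_fmt(values[q, i]) for q in range(k)])


def _read_channels(path, prefix: str) -> tuple[np.ndarray, np.ndarray]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        k = len(header) - 1
        expected = _channel_header(k, prefix)
        if k < 1 or header != expected:
            missing = [c for c in _channel_header(max(k, 1), prefix) if c not in header]
            what = f"missing column {missing[0]!r}" if missing else f"got {header}"
            raise ValueError(f"{path}: expected header like {expected}; {what}")
        times, rows = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != k + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {k + 1} fields, got {len(row)}"
                )
            try:
                vals = [float(v) for v in row]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            times.append(vals[0])
            rows.append(vals[1:])
    if not times:
        raise ValueError(f"{path}: no data rows")
    return np.array(times), np.array(rows).T


def _grid_from_times(path, times: np.ndarray) -> TimeGrid:
    if times.size < 2:
        return TimeGrid(t0=float(times[0]), t1=float(times[0]), step=0.0, times=times)
    step = float(times[1] - times[0])
    grid = build_grid(float(times[0]), float(times[-1]), step)
    if grid.n != times.size or not np.allclose(grid.times, times, atol=1e-9):
        raise ValueError(f"{path}: time column is not a uniform grid")
    return grid


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Trajectory CSV with header ``t,y1..yk``, one row per node."""
    _write_channels(path, trajectory.grid.times, trajectory.states, "y")


def read_trajectory(path) -> Trajectory:
    times, states = _read_channels(path, "y")
    return Trajectory(grid=_grid_from_times(path, times), states=states)


def write_dataset(data: Dataset, path, sidecar: Optional[str] = None) -> None:
    """Dataset CSV (same dialect as a trajectory) plus an optional JSON
    provenance sidecar."""
    _write_channels(path, data.inputs, data.targets, "y")
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            json.dump(data.provenance, fh, indent=2)


def write_train_record(record: TrainRecord, path, sidecar: Optional[str] = None) -> None:
    """Per-epoch telemetry CSV (+ alpha/beta/gamma columns for BR runs)
    with stop reason and best epoch in a JSON sidecar."""
    cols = ["epoch", "mse_train", "mse_val", "mse_test", "mu", "grad_norm"]
    br = record.alpha is not None
    if br:
        cols += ["alpha", "beta", "gamma"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for i in range(record.epochs_run):
            row = [i, _fmt(record.mse_train[i]), _fmt(record.mse_val[i]),
                   _fmt(record.mse_test[i]), _fmt(record.mu[i]),
                   _fmt(record.grad_norm[i])]
            if br:
                row += [_fmt(record.alpha[i]), _fmt(record.beta[i]),
                        _fmt(record.gamma[i])]
            writer.writerow(row)
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            json.dump({"stop_reason": record.stop_reason,
                       "best_epoch": record.best_epoch,
                       "epochs_run": record.epochs_run}, fh, indent=2)


def write_noisy_rhythms(rhythms: NoisyRhythms, path, sidecar: Optional[str] = None) -> None:
    """Measured-channel CSV with header ``t,x1..xk``; sigma and seed go
    in a JSON sidecar."""
    _write_channels(path, rhythms.grid.times, rhythms.channels, "x")
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            json.dump({"sigma": rhythms.sigma, "seed": rhythms.seed}, fh, indent=2)


def read_rhythms_csv(path, sigma: float = float("nan"), seed: int = -1) -> NoisyRhythms:
    times, channels = _read_channels(path, "x")
    return NoisyRhythms(grid=_grid_from_times(path, times), channels=channels,
                        sigma=sigma, seed=seed)


def write_packed_coefficients(D: CoefficientMatrixD, path) -> None:
    """Packed coefficient matrix as CSV, one row per equation, columns
    named after the monomial each coefficient multiplies."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["equation"] + monomial_names(D.k))
        for q in range(D.k):
            writer.writerow([f"dy{q + 1}/dt"] + [_fmt(v) for v in D.entries[q]])


def read_packed_coefficients(path) -> CoefficientMatrixD:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        rows = [row for row in reader if row]
    k = len(rows)
    j = packed_width(k)
    if len(header) != j + 1:
        raise ValueError(f"{path}: expected {j + 1} columns for k={k}, got {len(header)}")
    entries = np.array([[float(v) for v in row[1:]] for row in rows])
    return CoefficientMatrixD(k=k, entries=entries)


def write_model_json(model: QuadraticODEModel, path) -> None:
    """Structured coefficient file: ``{k, c, A, B}``."""
    with open(path, "w") as fh:
        json.dump({"k": model.k, "c": model.c.tolist(), "A": model.A.tolist(),
                   "B": model.B.tolist()}, fh, indent=2)


def read_model_json(path) -> QuadraticODEModel:
    with open(path) as fh:
        payload = json.load(fh)
    model = QuadraticODEModel(
        c=np.array(payload["c"], dtype=float),
        A=np.array(payload["A"], dtype=float),
        B=np.array(payload["B"], dtype=float),
    )
    if "k" in payload and model.k != payload["k"]:
        raise ValueError(f"{path}: declared k={payload['k']} but arrays have k={model.k}")
    return model
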