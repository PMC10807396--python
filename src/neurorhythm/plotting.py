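"""Optional PNG renders of the standard diagnostic figures.

Requires matplotlib (the ``plot`` extra); imported lazily so the core
library stays plot-free.
"""

from __future__ import annotations

import numpy as np

from .integrate import Dataset, Trajectory
from .metrics import ErrorHistogram, phase_portrait_data
from .network import MLPSurrogate, forward
from .training import TrainRecord


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_learning_curve(record: TrainRecord, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    epochs = np.arange(record.epochs_run)
    for label, series in (("train", record.mse_train), ("validation", record.mse_val),
                          ("test", record.mse_test)):
        ax.semilogy(epochs, series, label=label)
    ax.axvline(record.best_epoch, ls=":", color="k", lw=0.8)
    ax.set_xlabel("epoch")
    ax.set_ylabel("MSE")
    ax.legend()
    ax.set_title(f"learning curve (stop: {record.stop_reason})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_error_histogram(hist: ErrorHistogram, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = 0.5 * (hist.edges[:-1] + hist.edges[1:])
    width = hist.edges[1] - hist.edges[0]
    ax.bar(centers, hist.counts, width=width * 0.9)
    ax.axvline(0.0, color="orange", lw=1.2)
    ax.set_xlabel("error")
    ax.set_ylabel("instances")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fit_overlay(net: MLPSurrogate, data: Dataset, path) -> None:
    plt = _plt()
    pred = forward(net, data.inputs)
    fig, axes = plt.subplots(data.k, 1, figsize=(6, 2.2 * data.k), sharex=True)
    for q, ax in enumerate(np.atleast_1d(axes)):
        ax.plot(data.inputs, data.targets[q], "k-", lw=1, label="reference")
        ax.plot(data.inputs, pred[q], "r--", lw=1, label="surrogate")
        ax.set_ylabel(f"y{q + 1}")
    np.atleast_1d(axes)[0].legend()
    np.atleast_1d(axes)[-1].set_xlabel("t")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_regression(reference: np.ndarray, predicted: np.ndarray, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(reference.ravel(), predicted.ravel(), ".", ms=2)
    lims = [min(reference.min(), predicted.min()), max(reference.max(), predicted.max())]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel("target")
    ax.set_ylabel("output")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_phase_portraits(trajectory: Trajectory, path) -> None:
    plt = _plt()
    data = phase_portrait_data(trajectory)
    pairs = [kk for kk in data if kk != "all"]
    fig = plt.figure(figsize=(4 * (len(pairs) + 1), 3.6))
    for i, key in enumerate(pairs):
        ax = fig.add_subplot(1, len(pairs) + 1, i + 1)
        pts = data[key]
        ax.plot(pts[:, 0], pts[:, 1], lw=0.8)
        a, b = key.split("_")
        ax.set_xlabel(a)
        ax.set_ylabel(b)
    if trajectory.k == 3:
        ax = fig.add_subplot(1, len(pairs) + 1, len(pairs) + 1, projection="3d")
        pts = data["all"]
        ax.plot(pts[:, 0], pts[:, 1], pts[:, 2], lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
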