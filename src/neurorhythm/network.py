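"""The MLP surrogate: one time input, a logistic hidden layer, linear outputs.

The network maps a scalar time ``t`` (min-max normalised to [-1, 1] over
the fitted range) through ``H`` logistic units to ``k`` linear outputs in
raw signal units:

    out(t) = W2 @ sigma(W1 * norm(t) + b1) + b2,   sigma(z) = 1/(1 + e^-z)

Targets are deliberately left un-normalised so reported mean squared
errors are in raw signal units squared; an optional target map supports
normalised training when wanted.

Weights live in a single flat vector ordered ``[W1 (H), b1 (H),
W2 (k*H, row-major by output), b2 (k)]`` — the layout the analytic
Jacobian and the damped Gauss-Newton trainers index into.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .integrate import Dataset

__all__ = [
    "NormalizationMap",
    "MLPSurrogate",
    "init_network",
    "n_weights",
    "forward",
    "residuals",
    "jacobian",
    "get_weights",
    "set_weights",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class NormalizationMap:
    """Affine map of a raw range ``[lo, hi]`` onto ``[-1, 1]``.

    A degenerate range (lo == hi) maps everything to 0 and back to lo.
    """

    lo: float
    hi: float

    @classmethod
    def fit(cls, values: np.ndarray) -> "NormalizationMap":
        values = np.asarray(values, dtype=float)
        return cls(lo=float(values.min()), hi=float(values.max()))

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.hi == self.lo:
            return np.zeros_like(x)
        return 2.0 * (x - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.hi == self.lo:
            return np.full_like(z, self.lo)
        return self.lo + (z + 1.0) * (self.hi - self.lo) / 2.0


def _logistic(z: np.ndarray) -> np.ndarray:
    # Split by sign for overflow-free evaluation at large |z|.
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class MLPSurrogate:
    """1-H-k feedforward network with logistic hidden activation."""

    input_map: NormalizationMap
    W1: np.ndarray  # (H,)
    b1: np.ndarray  # (H,)
    W2: np.ndarray  # (k, H)
    b2: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        W1 = np.asarray(self.W1, dtype=float)
        b1 = np.asarray(self.b1, dtype=float)
        W2 = np.asarray(self.W2, dtype=float)
        b2 = np.asarray(self.b2, dtype=float)
        H = W1.shape[0]
        k = b2.shape[0]
        if b1.shape != (H,) or W2.shape != (k, H):
            raise ValueError("inconsistent layer shapes")
        for arr in (W1, b1, W2, b2):
            if not np.isfinite(arr).all():
                raise ValueError("weights must be finite")
        object.__setattr__(self, "W1", W1)
        object.__setattr__(self, "b1", b1)
        object.__setattr__(self, "W2", W2)
        object.__setattr__(self, "b2", b2)

    @property
    def hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def k(self) -> int:
        return self.b2.shape[0]

    @property
    def n_weights(self) -> int:
        return n_weights(self.hidden, self.k)


def n_weights(H: int, k: int = 3) -> int:
    """Total weight count: H input weights + H hidden biases + k*H output
    weights + k output biases (5H + 3 for the three-channel models)."""
    return H + H + k * H + k


def init_network(H: int, data: Dataset, seed: int) -> MLPSurrogate:
    """Seeded Nguyen-Widrow-style initialisation fitted to the dataset.

    Hidden-layer weights get magnitude ``0.7 * H`` (the Nguyen-Widrow
    scale for one input) with random signs, and biases spread the unit
    centres uniformly across the normalised input range so the logistic
    ramps tile [-1, 1].  Output-layer weights start small and random.
    """
    if H < 1:
        raise ValueError(f"hidden width must be >= 1, got {H}")
    if data.n < 1:
        raise ValueError("dataset must be non-empty")
    rng = np.random.default_rng(seed)
    k = data.k
    scale = 0.7 * H
    signs = rng.choice([-1.0, 1.0], size=H)
    W1 = scale * signs
    centers = np.linspace(-1.0, 1.0, H) if H > 1 else np.array([0.0])
    b1 = -W1 * centers + rng.uniform(-0.5, 0.5, size=H)
    W2 = rng.uniform(-0.5, 0.5, size=(k, H)) / np.sqrt(H)
    b2 = rng.uniform(-0.5, 0.5, size=k)
    return MLPSurrogate(
        input_map=NormalizationMap.fit(data.inputs), W1=W1, b1=b1, W2=W2, b2=b2
    )


def _hidden_activations(net: MLPSurrogate, t_batch: np.ndarray) -> np.ndarray:
    tn = net.input_map.transform(np.asarray(t_batch, dtype=float))
    z = np.outer(net.W1, tn) + net.b1[:, None]  # (H, N)
    return _logistic(z)


def forward(net: MLPSurrogate, t_batch: np.ndarray) -> np.ndarray:
    """Evaluate the network on a batch of times; returns ``k x N`` raw
    signal-unit outputs."""
    t_batch = np.atleast_1d(np.asarray(t_batch, dtype=float))
    if not np.isfinite(t_batch).all():
        raise ValueError("inputs must be finite")
    a = _hidden_activations(net, t_batch)
    return net.W2 @ a + net.b2[:, None]


def residuals(net: MLPSurrogate, data: Dataset, subset: np.ndarray) -> np.ndarray:
    """Residual vector ``e = target - output`` on a subset of samples,
    flattened state-major (all y1 residuals, then all y2, ...)."""
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    out = forward(net, data.inputs[subset])
    return (data.targets[:, subset] - out).ravel()


def jacobian(net: MLPSurrogate, data: Dataset, subset: np.ndarray) -> np.ndarray:
    """Analytic Jacobian ``d e / d w`` of the residuals on a subset.

    Shape ``(k*|subset|) x n_weights``; rows are ordered like
    :func:`residuals` (state-major), columns follow the flat weight
    layout ``[W1, b1, W2 row-major, b2]``.  Since ``e = target - out``,
    every column is the negated output derivative.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    t = data.inputs[subset]
    tn = net.input_map.transform(t)  # (N,)
    a = _hidden_activations(net, t)  # (H, N)
    da = a * (1.0 - a)  # logistic derivative, (H, N)
    H, N = a.shape
    k = net.k
    J = np.zeros((k * N, n_weights(H, k)))
    for q in range(k):
        rows = slice(q * N, (q + 1) * N)
        wda = net.W2[q][:, None] * da  # (H, N)
        J[rows, 0:H] = -(wda * tn[None, :]).T  # dW1
        J[rows, H : 2 * H] = -wda.T  # db1
        J[rows, 2 * H + q * H : 2 * H + (q + 1) * H] = -a.T  # dW2 row q
        J[rows, 2 * H + k * H + q] = -1.0  # db2_q
    return J


def get_weights(net: MLPSurrogate) -> np.ndarray:
    """Flatten the weights into the canonical vector layout."""
    return np.concatenate([net.W1, net.b1, net.W2.ravel(), net.b2])


def set_weights(net: MLPSurrogate, w: np.ndarray) -> MLPSurrogate:
    """Rebuild a network from the flat weight vector (inverse of
    :func:`get_weights`; the normalisation map is kept)."""
    H, k = net.hidden, net.k
    w = np.asarray(w, dtype=float)
    if w.shape != (n_weights(H, k),):
        raise ValueError(f"expected {n_weights(H, k)} weights, got {w.shape}")
    return replace(
        net,
        W1=w[0:H],
        b1=w[H : 2 * H],
        W2=w[2 * H : 2 * H + k * H].reshape(k, H),
        b2=w[2 * H + k * H :],
    )


def save_network(net: MLPSurrogate, path) -> None:
    """Serialise to JSON with full-precision weights."""
    payload = {
        "hidden": net.hidden,
        "k": net.k,
        "input_map": {"lo": net.input_map.lo, "hi": net.input_map.hi},
        "W1": net.W1.tolist(),
        "b1": net.b1.tolist(),
        "W2": net.W2.tolist(),
        "b2": net.b2.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_network(path) -> MLPSurrogate:
    with open(path) as fh:
        payload = json.load(fh)
    return MLPSurrogate(
        input_map=NormalizationMap(**payload["input_map"]),
        W1=np.array(payload["W1"]),
        b1=np.array(payload["b1"]),
        W2=np.array(payload["W2"]),
        b2=np.array(payload["b2"]),
    )
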