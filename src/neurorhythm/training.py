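"""Levenberg-Marquardt and Bayesian-regularization training, from scratch.

Both trainers are damped Gauss-Newton loops over the sum-of-squares
residual of the surrogate on the training subset.  Each epoch solves

    (Hessian_approx + mu * I) delta = -gradient

and retries with inflated damping ``mu`` until the objective decreases
(classic Levenberg-Marquardt trust-region-like behaviour: small ``mu``
approaches Gauss-Newton, large ``mu`` approaches scaled gradient
descent).

LM minimises the plain training MSE and early-stops on a validation
subset.  BR (Bayesian regularization, MacKay's evidence framework in the
Foresee-Hagan style) minimises ``F = beta * E_D + alpha * E_W`` where
``E_D`` is the sum of squared training residuals and ``E_W`` the sum of
squared weights, and re-estimates the hyperparameters after every
accepted step:

    gamma = N_w - 2 alpha tr(H^-1),  H = 2 beta J^T J + 2 alpha I
    alpha = gamma / (2 E_W)
    beta  = (N_D - gamma) / (2 E_D)

``gamma`` is the effective number of parameters — how many of the
``N_w`` weights the data actually constrain.  BR does not use the
validation subset for stopping (it is monitored for reporting only);
the evidence updates play the role of complexity control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .integrate import Dataset
from .network import MLPSurrogate, get_weights, jacobian, residuals, set_weights

__all__ = [
    "SplitIndices",
    "TrainConfig",
    "TrainRecord",
    "BRState",
    "split_dataset",
    "lm_step",
    "train_lm",
    "train_br",
]


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/validation/test index sets over a dataset."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    @property
    def n(self) -> int:
        return self.train.size + self.validation.size + self.test.size


@dataclass(frozen=True)
class TrainConfig:
    """Trainer settings.

    The damping schedule defaults (mu0 = 1e-3, x10 up / x0.1 down,
    ceiling 1e10) and the stopping thresholds (gradient infinity-norm
    below 1e-7, validation patience 6) are the de-facto standard
    feedforward-fitting defaults.
    """

    max_epochs: int = 1000
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    grad_min: float = 1e-7
    max_fail: int = 6
    trainer: str = "lm"

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not (self.mu0 > 0 and self.mu_inc > 1 and 0 < self.mu_dec < 1):
            raise ValueError("invalid damping schedule")
        if self.trainer not in ("lm", "br"):
            raise ValueError(f"trainer must be 'lm' or 'br', got {self.trainer!r}")


@dataclass
class TrainRecord:
    """Per-epoch telemetry of one training run."""

    mse_train: np.ndarray
    mse_val: np.ndarray
    mse_test: np.ndarray
    mu: np.ndarray
    grad_norm: np.ndarray
    best_epoch: int
    stop_reason: str
    alpha: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None
    gamma: Optional[np.ndarray] = None

    @property
    def epochs_run(self) -> int:
        return len(self.mse_train)

    @property
    def final_train_mse(self) -> float:
        return float(self.mse_train[self.best_epoch])

    @property
    def best_val_mse(self) -> float:
        return float(self.mse_val[self.best_epoch])


@dataclass
class BRState:
    """Final Bayesian-regularization hyperparameters and energies."""

    alpha: float
    beta: float
    gamma: float
    e_w: float
    e_d: float


def split_dataset(
    N: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0
) -> SplitIndices:
    """Random train/validation/test split by seeded permutation.

    Validation and test sizes are ``round(f * N)`` each; training takes
    the remainder, so every index is assigned exactly once.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n_val = int(round(f_val * N))
    n_test = int(round(f_test * N))
    n_train = N - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"N = {N} too small for a non-empty three-way split")
    perm = np.random.default_rng(seed).permutation(N)
    return SplitIndices(
        train=np.sort(perm[:n_train]),
        validation=np.sort(perm[n_train : n_train + n_val]),
        test=np.sort(perm[n_train + n_val :]),
    )


def _mse(net: MLPSurrogate, data: Dataset, subset: np.ndarray) -> float:
    e = residuals(net, data, subset)
    return float(np.mean(e * e))


def _solve_damped(JtJ: np.ndarray, g: np.ndarray, mu: float) -> np.ndarray:
    """Solve (JtJ + mu I) delta = -g via Cholesky (SPD for mu > 0)."""
    A = JtJ + mu * np.eye(JtJ.shape[0])
    return cho_solve(cho_factor(A, lower=True, check_finite=False), -g,
                     check_finite=False)


def lm_step(
    net: MLPSurrogate,
    data: Dataset,
    subset: np.ndarray,
    mu: float,
    config: TrainConfig = TrainConfig(),
) -> tuple[MLPSurrogate, float, bool]:
    """One Levenberg-Marquardt epoch: propose damped Gauss-Newton steps,
    inflating mu until the training MSE decreases.

    Returns ``(candidate net, new mu, accepted flag)``.  On acceptance
    mu is relaxed by ``mu_dec``; if mu exceeds ``mu_max`` without an
    acceptable step the incoming net is returned unchanged.
    """
    if not (0 < mu <= config.mu_max):
        raise ValueError(f"mu must be in (0, mu_max], got {mu}")
    e = residuals(net, data, subset)
    if not np.isfinite(e).all():
        raise FloatingPointError("non-finite residuals — training diverged")
    J = jacobian(net, data, subset)
    JtJ = J.T @ J
    g = J.T @ e
    mse = float(np.mean(e * e))
    if mse == 0.0:  # perfect fit: the Gauss-Newton step is exactly zero
        return net, mu, True
    w = get_weights(net)
    while mu <= config.mu_max:
        delta = _solve_damped(JtJ, g, mu)
        cand = set_weights(net, w + delta)
        cand_mse = _mse(cand, data, subset)
        if np.isfinite(cand_mse) and cand_mse < mse:
            return cand, max(mu * config.mu_dec, 1e-20), True
        mu *= config.mu_inc
    return net, mu, False


def train_lm(
    net: MLPSurrogate,
    data: Dataset,
    split: SplitIndices,
    config: TrainConfig = TrainConfig(),
) -> tuple[MLPSurrogate, TrainRecord]:
    """Levenberg-Marquardt training with validation-based early stopping.

    Stops on: gradient infinity-norm below ``grad_min``, damping above
    ``mu_max``, validation MSE failing to improve ``max_fail`` epochs in
    a row, or ``max_epochs``.  Returns the weights of the best-validation
    epoch together with the full per-epoch record.
    """
    mu = config.mu0
    hist: dict[str, list[float]] = {k: [] for k in
                                    ("mse_train", "mse_val", "mse_test", "mu", "grad")}
    best_val = np.inf
    best_net = net
    best_epoch = 0
    fails = 0
    stop = "max_epochs"
    for epoch in range(config.max_epochs):
        e = residuals(net, data, split.train)
        if not np.isfinite(e).all():
            raise FloatingPointError("non-finite residuals — training diverged")
        J = jacobian(net, data, split.train)
        g = J.T @ e
        grad_norm = float(np.abs(g).max())
        if grad_norm < config.grad_min:
            stop = "gradient"
            break
        cand, mu, accepted = lm_step(net, data, split.train, mu, config)
        if not accepted:
            stop = "mu_max"
            break
        net = cand
        hist["mse_train"].append(_mse(net, data, split.train))
        hist["mse_val"].append(_mse(net, data, split.validation))
        hist["mse_test"].append(_mse(net, data, split.test))
        hist["mu"].append(mu)
        hist["grad"].append(grad_norm)
        if hist["mse_val"][-1] < best_val:
            best_val = hist["mse_val"][-1]
            best_net = net
            best_epoch = epoch
            fails = 0
        else:
            fails += 1
            if fails >= config.max_fail:
                stop = "validation"
                break
    record = TrainRecord(
        mse_train=np.array(hist["mse_train"]),
        mse_val=np.array(hist["mse_val"]),
        mse_test=np.array(hist["mse_test"]),
        mu=np.array(hist["mu"]),
        grad_norm=np.array(hist["grad"]),
        best_epoch=best_epoch if hist["mse_train"] else 0,
        stop_reason=stop,
    )
    return best_net, record


def train_br(
    net: MLPSurrogate,
    data: Dataset,
    split: SplitIndices,
    config: TrainConfig = TrainConfig(),
) -> tuple[MLPSurrogate, TrainRecord, BRState]:
    """Bayesian-regularization training (evidence-framework updates).

    Minimises ``F = beta * E_D + alpha * E_W`` by damped Gauss-Newton
    steps; after every accepted step, re-estimates the effective number
    of parameters gamma and the hyperparameters alpha (weight prior
    precision) and beta (noise precision).  Validation and test MSE are
    recorded for reporting only — BR runs until the gradient, damping or
    epoch limit is hit.  Returns the final weights, the record and the
    hyperparameter state.
    """
    mu = config.mu0
    alpha, beta = 0.0, 1.0  # before the first re-estimation
    n_w = net.n_weights
    hist: dict[str, list[float]] = {k: [] for k in
                                    ("mse_train", "mse_val", "mse_test", "mu", "grad",
                                     "alpha", "beta", "gamma")}
    gamma = float(n_w)
    stop = "max_epochs"
    eye = np.eye(n_w)
    for _epoch in range(config.max_epochs):
        e = residuals(net, data, split.train)
        if not np.isfinite(e).all():
            raise FloatingPointError("non-finite residuals — training diverged")
        J = jacobian(net, data, split.train)
        w = get_weights(net)
        e_d = float(e @ e)
        e_w = float(w @ w)
        JtJ = J.T @ J
        # Regularised objective: Hessian approx 2*beta*JtJ + 2*alpha*I,
        # gradient 2*beta*J'e + 2*alpha*w.
        Hess = 2.0 * beta * JtJ + 2.0 * alpha * eye
        g = 2.0 * beta * (J.T @ e) + 2.0 * alpha * w
        grad_norm = float(np.abs(g).max())
        if grad_norm < config.grad_min:
            stop = "gradient"
            break
        f_cur = beta * e_d + alpha * e_w
        accepted = False
        while mu <= config.mu_max:
            delta = _solve_damped(Hess, g, mu)
            cand = set_weights(net, w + delta)
            e_new = residuals(cand, data, split.train)
            if np.isfinite(e_new).all():
                w_new = w + delta
                f_new = beta * float(e_new @ e_new) + alpha * float(w_new @ w_new)
                if f_new < f_cur:
                    accepted = True
                    net = cand
                    e_d = float(e_new @ e_new)
                    e_w = float(w_new @ w_new)
                    mu = max(mu * config.mu_dec, 1e-20)
                    break
            mu *= config.mu_inc
        if not accepted:
            stop = "mu_max"
            break
        # Evidence-framework re-estimation at the accepted point:
        # gamma = N_w - 2 alpha tr(H^-1) with H = 2 beta J'J + 2 alpha I.
        # Evaluated through the eigenvalues of J'J, which is algebraically
        # identical (gamma = sum beta*lam / (beta*lam + alpha)) and stays
        # exact when beta is huge and H too ill-conditioned to invert.
        J = jacobian(net, data, split.train)
        lam = np.clip(np.linalg.eigvalsh(J.T @ J), 0.0, None)
        if alpha > 0.0:
            gamma = float(np.sum(beta * lam / (beta * lam + alpha)))
        else:
            gamma = float(n_w)
        if e_w > 1e-30:
            alpha = gamma / (2.0 * e_w)
        n_d = split.train.size * data.k
        if e_d > 1e-300 and gamma < n_d:
            beta = (n_d - gamma) / (2.0 * e_d)
        hist["mse_train"].append(e_d / n_d)
        hist["mse_val"].append(_mse(net, data, split.validation))
        hist["mse_test"].append(_mse(net, data, split.test))
        hist["mu"].append(mu)
        hist["grad"].append(grad_norm)
        hist["alpha"].append(alpha)
        hist["beta"].append(beta)
        hist["gamma"].append(gamma)
    epochs_run = len(hist["mse_train"])
    record = TrainRecord(
        mse_train=np.array(hist["mse_train"]),
        mse_val=np.array(hist["mse_val"]),
        mse_test=np.array(hist["mse_test"]),
        mu=np.array(hist["mu"]),
        grad_norm=np.array(hist["grad"]),
        best_epoch=max(epochs_run - 1, 0),
        stop_reason=stop,
        alpha=np.array(hist["alpha"]),
        beta=np.array(hist["beta"]),
        gamma=np.array(hist["gamma"]),
    )
    e = residuals(net, data, split.train)
    w = get_weights(net)
    state = BRState(alpha=alpha, beta=beta, gamma=gamma,
                    e_w=float(w @ w), e_d=float(e @ e))
    return net, record, state
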