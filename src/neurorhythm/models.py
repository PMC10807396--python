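"""Quadratic ODE models of cortical EEG rhythms.

The dynamics of the latent rhythm vector ``y(t)`` (one component per
electrode site) follow a system of quadratic ordinary differential
equations

    dy_q/dt = c_q + sum_m a_qm * y_m + y^T B_q y,       q = 1..k,

i.e. a constant drive, a linear coupling and a full quadratic form per
state.  Three fully parameterised three-channel instances are shipped as
built-ins: model 1 describes the electrical impulses recorded at the
C3/C4/T5 scalp positions, models 2 and 3 the P3/P4/O1 triple.

Two equivalent representations are supported:

* :class:`QuadraticODEModel` — the structured triple ``(c, A, B)`` with
  each ``B_q`` stored symmetrically;
* :class:`CoefficientMatrixD` — the packed ``k x j`` coefficient matrix
  with ``j = 1 + 2k + k(k-1)/2`` columns ordered
  ``[1 | y_1..y_k | y_1^2..y_k^2 | y_1 y_2, y_1 y_3, .., y_{k-1} y_k]``.
  Cross-product columns carry the *doubled* off-diagonal coefficient
  ``2 b_ij`` so that ``D @ monomial_features(y) == rhs(y)`` exactly.

The packed form is the natural target of least-squares identification
(see :mod:`neurorhythm.identify`); the structured form is what the
integrator consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "QuadraticODEModel",
    "CoefficientMatrixD",
    "make_pdi_model",
    "rhs",
    "monomial_features",
    "monomial_names",
    "pack_coefficients",
    "unpack_coefficients",
    "packed_width",
    "PDI_MODEL_IDS",
]

PDI_MODEL_IDS = (1, 2, 3)


def packed_width(k: int) -> int:
    """Number of monomials of degree <= 2 in ``k`` variables (constant,
    linear, squares, distinct cross products)."""
    return 1 + 2 * k + k * (k - 1) // 2


@dataclass(frozen=True)
class QuadraticODEModel:
    """Structured quadratic ODE model ``dy/dt = c + A y + (y^T B_q y)_q``.

    Parameters
    ----------
    c : (k,) constant drive per equation.
    A : (k, k) linear coupling matrix, ``A[q, m] = a_qm``.
    B : (k, k, k) stack of symmetric quadratic-form matrices; ``B[q]``
        holds the quadratic coefficients of equation ``q``.
    """

    c: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        k = c.shape[0]
        if c.ndim != 1:
            raise ValueError("c must be a vector")
        if A.shape != (k, k):
            raise ValueError(f"A must be {k}x{k}, got {A.shape}")
        if B.shape != (k, k, k):
            raise ValueError(f"B must be {k}x{k}x{k}, got {B.shape}")
        if not (np.isfinite(c).all() and np.isfinite(A).all() and np.isfinite(B).all()):
            raise ValueError("model coefficients must be finite")
        if not np.allclose(B, np.swapaxes(B, 1, 2), rtol=0, atol=1e-12):
            raise ValueError("each B_q must be symmetric")
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    @property
    def k(self) -> int:
        return self.c.shape[0]


@dataclass(frozen=True)
class CoefficientMatrixD:
    """Packed ``k x j`` coefficient matrix (one row per equation).

    Row ``q`` is ``[c_q, a_q1..a_qk, b_11..b_kk, 2 b_12, 2 b_13, ..,
    2 b_{k-1,k}]`` — cross columns hold the doubled symmetric
    coefficient, so a row dotted with :func:`monomial_features` gives the
    time derivative of state ``q``.
    """

    k: int
    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        j = packed_width(self.k)
        if entries.shape != (self.k, j):
            raise ValueError(
                f"packed matrix for k={self.k} must be {self.k}x{j}, got {entries.shape}"
            )
        if not np.isfinite(entries).all():
            raise ValueError("packed coefficients must be finite")
        object.__setattr__(self, "entries", entries)

    @property
    def j(self) -> int:
        return packed_width(self.k)


# Printed coefficients of the three built-in rhythm models, one packed row
# per equation in the column order of CoefficientMatrixD.  Cross columns
# are the doubled coefficients exactly as printed.
_PDI_PACKED = {
    1: [
        [-20.93, 1.55, 6.20, -7.05, 0.016, 0.17, -0.16, -0.10, 0.13, -0.08],
        [3.87, -2.60, 2.12, -2.62, -0.01, 0.034, -0.13, -0.17, 0.32, 0.025],
        [-12.12, 1.36, 3.20, -3.56, 0.03, 0.06, -0.14, -0.14, 0.09, 0.08],
    ],
    2: [
        [-3.11, 0.19, 0.72, -1.19, 0.022, -0.04, 0.045, 0.04, -0.01, -0.06],
        [-4.58, -1.69, 0.39, 1.37, -0.03, -0.09, 0.05, 0.11, 0.08, -0.06],
        [-7.88, 6.91, -5.69, -0.71, 0.23, 0.025, 0.0, -0.17, -0.10, 0.06],
    ],
    3: [
        [-1.24, -1.15, 2.34, -0.83, -0.04, 0.0, 0.02, 0.235, -0.015, -0.12],
        [3.68, -3.91, 1.01, 2.54, -0.16, -0.08, 0.02, 0.15, 0.10, -0.04],
        [-5.9, 5.22, -6.15, -0.31, 0.13, 0.022, 0.0, -0.13, -0.28, 0.05],
    ],
}

# Model 3's first equation prints a quadratic term with a repeated y1
# factor in the slot every other equation uses for the y1*y2 cross
# product.  The default reading is positional (a y1*y2 cross term with
# doubled coefficient 0.235); the alternative reading adds 0.235 to the
# y1^2 column instead.
MODEL3_CROSS_READINGS = ("positional", "squared")


def make_pdi_model(index: int, *, model3_cross: str = "positional") -> QuadraticODEModel:
    """Return one of the three built-in cortical-rhythm models.

    Parameters
    ----------
    index : which model (1: C3/C4/T5 sites; 2 and 3: P3/P4/O1 sites).
    model3_cross : how to read the ambiguous repeated-factor quadratic
        term in model 3's first equation — ``"positional"`` (default)
        treats it as the y1*y2 cross term, ``"squared"`` as an extra
        y1^2 contribution.
    """
    if index not in PDI_MODEL_IDS:
        raise ValueError(f"model index must be one of {PDI_MODEL_IDS}, got {index!r}")
    if model3_cross not in MODEL3_CROSS_READINGS:
        raise ValueError(
            f"model3_cross must be one of {MODEL3_CROSS_READINGS}, got {model3_cross!r}"
        )
    packed = np.array(_PDI_PACKED[index], dtype=float)
    if index == 3 and model3_cross == "squared":
        packed = packed.copy()
        packed[0, 4] += packed[0, 7]  # fold 0.235 into the y1^2 column
        packed[0, 7] = 0.0
    return unpack_coefficients(CoefficientMatrixD(k=3, entries=packed))


def rhs(model: QuadraticODEModel, y: np.ndarray) -> np.ndarray:
    """Evaluate the right-hand side ``c + A y + (y^T B_q y)_q`` at ``y``."""
    y = np.asarray(y, dtype=float)
    if y.shape != (model.k,):
        raise ValueError(f"state must have length {model.k}, got shape {y.shape}")
    if not np.isfinite(y).all():
        raise ValueError("state must be finite")
    quad = np.einsum("qij,i,j->q", model.B, y, y)
    return model.c + model.A @ y + quad


def monomial_names(k: int) -> list[str]:
    """Column labels of the packed coefficient matrix, e.g. ``['1', 'y1',
    .., 'y1^2', .., 'y1*y2', ..]``."""
    names = ["1"]
    names += [f"y{i + 1}" for i in range(k)]
    names += [f"y{i + 1}^2" for i in range(k)]
    names += [f"y{i + 1}*y{j + 1}" for i, j in combinations(range(k), 2)]
    return names


def monomial_features(y: np.ndarray) -> np.ndarray:
    """Degree-<=2 monomials of the state, ordered to match the packed rows:
    ``[1, y_1..y_k, y_1^2..y_k^2, y_1 y_2, y_1 y_3, .., y_{k-1} y_k]``.

    Each cross product appears once; the factor 2 lives in the packed
    matrix, not here.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("state must be a vector")
    if not np.isfinite(y).all():
        raise ValueError("state must be finite")
    k = y.shape[0]
    cross = [y[i] * y[j] for i, j in combinations(range(k), 2)]
    return np.concatenate([[1.0], y, y * y, cross])


def pack_coefficients(model: QuadraticODEModel) -> CoefficientMatrixD:
    """Pack a structured model into the ``k x j`` coefficient matrix.

    Off-diagonal quadratic coefficients are doubled on packing (the two
    symmetric halves ``b_ij`` and ``b_ji`` collapse into one ``2 b_ij``
    column), which keeps ``entries @ monomial_features(y) == rhs(model, y)``
    an identity.
    """
    k = model.k
    iu = list(combinations(range(k), 2))
    rows = np.empty((k, packed_width(k)))
    rows[:, 0] = model.c
    rows[:, 1 : 1 + k] = model.A
    rows[:, 1 + k : 1 + 2 * k] = model.B[:, np.arange(k), np.arange(k)]
    for col, (i, j) in enumerate(iu):
        rows[:, 1 + 2 * k + col] = 2.0 * model.B[:, i, j]
    return CoefficientMatrixD(k=k, entries=rows)


def unpack_coefficients(D: CoefficientMatrixD) -> QuadraticODEModel:
    """Inverse of :func:`pack_coefficients`: halve each doubled cross
    column back into the two symmetric off-diagonal slots of ``B_q``."""
    k = D.k
    entries = D.entries
    c = entries[:, 0].copy()
    A = entries[:, 1 : 1 + k].copy()
    B = np.zeros((k, k, k))
    diag = entries[:, 1 + k : 1 + 2 * k]
    for q in range(k):
        np.fill_diagonal(B[q], diag[q])
    for col, (i, j) in enumerate(combinations(range(k), 2)):
        half = entries[:, 1 + 2 * k + col] / 2.0
        B[:, i, j] = half
        B[:, j, i] = half
    return QuadraticODEModel(c=c, A=A, B=B)
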