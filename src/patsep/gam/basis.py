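"""Cubic B-spline bases with difference penalties (P-splines).

The basis for a smooth of `x` uses `k` cubic B-splines on equally spaced
knots spanning the observed range, penalized by the squared second-order
differences of adjacent coefficients.  Smooths are centered (sum of fitted
values constrained to zero) by an orthogonal reparameterization so that
every model keeps an explicit intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "difference_penalty", "centering_transform", "row_kron"]

_DEGREE = 3


def _knot_vector(lo: float, hi: float, k: int) -> np.ndarray:
    """Equally spaced knots giving exactly k cubic B-spline functions."""
    if k < 4:
        raise ValueError("cubic spline basis needs k >= 4")
    if hi <= lo:
        raise ValueError("degenerate variable range for spline basis")
    inner = np.linspace(lo, hi, k - 2)
    h = (hi - lo) / (k - 3)
    left = lo - h * np.arange(3, 0, -1)
    right = hi + h * np.arange(1, 4)
    return np.concatenate([left, inner, right])


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """S = D'D with D the order-th difference matrix on k coefficients."""
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def centering_transform(colsums: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of the sum-to-zero constraint
    c'beta = 0, so that columns X @ Z satisfy the constraint identically."""
    c = np.asarray(colsums, dtype=float).reshape(-1, 1)
    q, _ = np.linalg.qr(c, mode="complete")
    return q[:, 1:]


def row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product (the tensor-product design)."""
    return np.einsum("ij,ik->ijk", a, b).reshape(a.shape[0], -1)


@dataclass
class SplineBasis:
    """A fitted-to-data univariate cubic B-spline basis."""

    knots: np.ndarray
    k: int
    lo: float
    hi: float

    @classmethod
    def from_data(cls, x: np.ndarray, k: int) -> "SplineBasis":
        x = np.asarray(x, dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        return cls(knots=_knot_vector(lo, hi, k), k=k, lo=lo, hi=hi)

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        m = BSpline.design_matrix(x, self.knots, _DEGREE, extrapolate=True)
        return np.asarray(m.todense())

    def penalty(self) -> np.ndarray:
        return difference_penalty(self.k)

    def out_of_range(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x < self.lo) | (x > self.hi)
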