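"""Uniform B-spline bases for the KAN layer.

A grid of ``G`` intervals over ``grid_range`` is extended by ``k``
uniform knots on each side, giving ``G + k`` order-``k`` basis functions
that form a partition of unity on the grid range. Bases and their first
derivatives are evaluated with the Cox–de Boor recursion, vectorized
over the input.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np


def knot_vector(grid_range: Tuple[float, float], G: int, k: int) -> np.ndarray:
    lo, hi = grid_range
    if not (hi > lo) or G < 1 or k < 0:
        raise ValueError("invalid B-spline grid specification")
    h = (hi - lo) / G
    return lo + h * np.arange(-k, G + k + 1, dtype=float)


def _cox_de_boor(x: np.ndarray, t: np.ndarray, k: int) -> np.ndarray:
    """All order-``k`` bases at points ``x``; shape ``(len(x), len(t)-k-1)``."""
    x = np.asarray(x, dtype=float)
    B = ((x[:, None] >= t[None, :-1]) & (x[:, None] < t[None, 1:])).astype(float)
    for d in range(1, k + 1):
        denom_l = t[d:-1] - t[: -(d + 1)]
        denom_r = t[d + 1 :] - t[1:-d]
        left = (x[:, None] - t[None, : -(d + 1)]) / denom_l[None, :] * B[:, :-1]
        right = (t[None, d + 1 :] - x[:, None]) / denom_r[None, :] * B[:, 1:]
        B = left + right
    return B


def design_matrix(
    x: np.ndarray, grid_range: Tuple[float, float], G: int, k: int
) -> np.ndarray:
    """Basis values ``B_m(x)``; ``x`` must lie inside ``grid_range``."""
    return _cox_de_boor(x, knot_vector(grid_range, G, k), k)


def design_matrix_deriv(
    x: np.ndarray, grid_range: Tuple[float, float], G: int, k: int
) -> np.ndarray:
    """First derivatives ``B_m'(x)`` of the order-``k`` bases."""
    t = knot_vector(grid_range, G, k)
    if k == 0:
        return np.zeros((len(np.atleast_1d(x)), G))
    Bm1 = _cox_de_boor(x, t, k - 1)  # (n, G + k + ... ) order k-1 bases
    n_bases = len(t) - k - 1
    D = np.zeros((Bm1.shape[0], n_bases))
    for i in range(n_bases):
        D[:, i] = k * (
            Bm1[:, i] / (t[i + k] - t[i])
            - Bm1[:, i + 1] / (t[i + k + 1] - t[i + 1])
        )
    return D
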