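"""Dynamic Time Warping: accumulated cost matrix, optimal warp path, distance.

For sequences ``X = [x_1..x_m]`` and ``Y = [y_1..y_n]`` the accumulated cost
matrix is

    D(i, j) = Dist(i, j) + min(D(i-1, j), D(i, j-1), D(i-1, j-1))

with ``Dist`` a pointwise local cost (squared difference by default, absolute
difference optionally), the first row/column accumulating along their only
predecessor. The DTW distance is the terminal accumulated cost ``D(m, n)``;
no path-length normalization is applied. The warp path is recovered by
backtracing minimal predecessors from (m, n) to (1, 1); ties prefer the
diagonal, then the vertical (i - 1), then the horizontal (j - 1) step, which
makes the path deterministic (the distance is tie-independent).

The distance of two identical sequences is exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import EmptySequenceError

CostKind = Literal["squared", "absolute"]


@dataclass(frozen=True)
class CostMatrix:
    """Accumulated m x n DTW cost matrix."""

    D: np.ndarray
    local_cost: CostKind


@dataclass(frozen=True)
class WarpPath:
    """Monotone index-pair path from (0, 0) to (m-1, n-1), 0-based."""

    steps: list[tuple[int, int]]


@dataclass(frozen=True)
class DTWResult:
    distance: float
    path: WarpPath
    matrix: CostMatrix | None = None


def local_cost(x: float, y: float, kind: CostKind = "squared") -> float:
    """Pointwise alignment cost between two samples."""
    d = x - y
    return d * d if kind == "squared" else abs(d)


def _local_cost_matrix(x: np.ndarray, y: np.ndarray, kind: CostKind) -> np.ndarray:
    diff = x[:, None] - y[None, :]
    return diff * diff if kind == "squared" else np.abs(diff)


def cost_matrix(X, Y, kind: CostKind = "squared") -> CostMatrix:
    """Dynamic-programming fill of the accumulated cost matrix."""
    x = np.asarray(X, dtype=float).ravel()
    y = np.asarray(Y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise EmptySequenceError("DTW requires nonempty sequences")
    dist = _local_cost_matrix(x, y, kind)
    m, n = dist.shape
    D = np.empty((m, n))
    D[0, :] = np.cumsum(dist[0, :])
    D[:, 0] = np.cumsum(dist[:, 0])
    for i in range(1, m):
        row_prev = D[i - 1]
        row = D[i]
        for j in range(1, n):
            row[j] = dist[i, j] + min(row_prev[j], row[j - 1], row_prev[j - 1])
    return CostMatrix(D=D, local_cost=kind)


def warp_path(matrix: CostMatrix) -> WarpPath:
    """Backtrace the minimal-cost path from the terminal corner to the origin."""
    D = matrix.D
    i, j = D.shape[0] - 1, D.shape[1] - 1
    steps = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            # tie order: diagonal, then up (i-1), then left (j-1)
            choices = (D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
            k = int(np.argmin(choices))
            if k == 0:
                i, j = i - 1, j - 1
            elif k == 1:
                i -= 1
            else:
                j -= 1
        steps.append((i, j))
    steps.reverse()
    return WarpPath(steps=steps)


def dtw_distance(X, Y, kind: CostKind = "squared") -> float:
    """Terminal accumulated cost between two sequences."""
    return float(cost_matrix(X, Y, kind).D[-1, -1])


def dtw(X, Y, kind: CostKind = "squared", keep_matrix: bool = True) -> DTWResult:
    """Full DTW: distance plus optimal warp path (and optionally the matrix)."""
    M = cost_matrix(X, Y, kind)
    return DTWResult(
        distance=float(M.D[-1, -1]),
        path=warp_path(M),
        matrix=M if keep_matrix else None,
    )
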