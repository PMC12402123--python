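"""Dynamic time warping for multivariate latent trajectories.

Classic boundary-matched DTW with steps {(1,0),(0,1),(1,1)} and squared
Euclidean frame costs; the reported distance is the square root of the
accumulated cost along the optimal monotone warping path.  Patient
trajectories here are short (at most 14 visits), so no warping-window
constraint is applied and the dynamic program runs exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["dtw_distance", "dtw_path", "dba_barycenter", "resample_to_length"]


def _frame_costs(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValueError(
            f"expected (L, T) matrices with equal L, got {A.shape}, {B.shape}")
    return cdist(A.T, B.T, metric="sqeuclidean")


def _accumulate(cost: np.ndarray) -> np.ndarray:
    Ta, Tb = cost.shape
    D = np.full((Ta, Tb), np.inf)
    D[0, 0] = cost[0, 0]
    for j in range(1, Tb):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, Ta):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        row_prev = D[i - 1]
        row = D[i]
        for j in range(1, Tb):
            row[j] = cost[i, j] + min(row_prev[j], row[j - 1],
                                      row_prev[j - 1])
    return D


def dtw_distance(A: np.ndarray, B: np.ndarray) -> float:
    """DTW distance between (L, T_a) and (L, T_b) trajectories."""
    D = _accumulate(_frame_costs(A, B))
    return float(np.sqrt(D[-1, -1]))


def dtw_path(A: np.ndarray, B: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Optimal warping path (list of (i, j) pairs) and the DTW distance."""
    cost = _frame_costs(A, B)
    D = _accumulate(cost)
    i, j = D.shape[0] - 1, D.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            choices = (D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
            k = int(np.argmin(choices))
            if k == 0:
                i, j = i - 1, j - 1
            elif k == 1:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return path, float(np.sqrt(D[-1, -1]))


def resample_to_length(A: np.ndarray, length: int) -> np.ndarray:
    """Linear-interpolation resampling of an (L, T) trajectory to (L, length)."""
    A = np.asarray(A, float)
    T = A.shape[1]
    if T == length:
        return A.copy()
    src = np.linspace(0.0, 1.0, T)
    dst = np.linspace(0.0, 1.0, length)
    return np.stack([np.interp(dst, src, A[l]) for l in range(A.shape[0])])


def dba_barycenter(members: list[np.ndarray], length: int,
                   init: np.ndarray | None = None,
                   n_iter: int = 10) -> np.ndarray:
    """DTW barycenter averaging: a fixed-length (L, length) centroid.

    Standard DBA: repeatedly align every member to the current barycenter
    and replace each barycenter frame with the mean of all member frames
    aligned to it.  Initialized from the resampled first member unless
    ``init`` is given.
    """
    if not members:
        raise ValueError("cannot average an empty member list")
    L = members[0].shape[0]
    bary = (resample_to_length(members[0], length)
            if init is None else resample_to_length(init, length))
    for _ in range(n_iter):
        sums = np.zeros((L, length))
        counts = np.zeros(length)
        for m in members:
            path, _ = dtw_path(bary, m)
            for i, j in path:
                sums[:, i] += m[:, j]
                counts[i] += 1
        new = sums / np.maximum(counts, 1.0)
        if np.allclose(new, bary):
            break
        bary = new
    return bary
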