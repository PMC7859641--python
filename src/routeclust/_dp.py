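"""Compiled dynamic-programming kernels for the path distances.

The inner loops have a sequential dependency along each row (the
horizontal move of the warping path), so they cannot be vectorised with
numpy; numba compiles them to native code instead.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def dtw_cost(a: np.ndarray, b: np.ndarray) -> float:
    """Exact DTW cost between two (n, 2) point sequences.

    Minimum over monotone alignments (pairing first with first and last
    with last) of the summed Euclidean point-pair distances.
    """
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m)
    cur = np.empty(m)
    d = np.hypot(a[0, 0] - b[0, 0], a[0, 1] - b[0, 1])
    prev[0] = d
    for j in range(1, m):
        prev[j] = prev[j - 1] + np.hypot(a[0, 0] - b[j, 0], a[0, 1] - b[j, 1])
    for i in range(1, n):
        cur[0] = prev[0] + np.hypot(a[i, 0] - b[0, 0], a[i, 1] - b[0, 1])
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = best + np.hypot(a[i, 0] - b[j, 0], a[i, 1] - b[j, 1])
        prev, cur = cur, prev
    return prev[m - 1]


@njit(cache=True)
def frechet_cost(a: np.ndarray, b: np.ndarray) -> float:
    """Discrete Frechet distance between two (n, 2) point sequences.

    Minimum over monotone couplings of the maximum paired Euclidean
    distance (the shortest sufficient leash).
    """
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m)
    cur = np.empty(m)
    prev[0] = np.hypot(a[0, 0] - b[0, 0], a[0, 1] - b[0, 1])
    for j in range(1, m):
        d = np.hypot(a[0, 0] - b[j, 0], a[0, 1] - b[j, 1])
        prev[j] = prev[j - 1] if prev[j - 1] > d else d
    for i in range(1, n):
        d = np.hypot(a[i, 0] - b[0, 0], a[i, 1] - b[0, 1])
        cur[0] = prev[0] if prev[0] > d else d
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            d = np.hypot(a[i, 0] - b[j, 0], a[i, 1] - b[j, 1])
            cur[j] = best if best > d else d
        prev, cur = cur, prev
    return prev[m - 1]
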