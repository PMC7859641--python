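"""Pairwise path distances and the similarity description matrix.

Two complementary measures are provided: dynamic time warping, which sums
point-pair distances over the best monotone alignment and so acts as a
*global* measure, and the discrete Frechet distance, which takes the
maximum over the best coupling and so acts as a *local*, extremum-based
measure.  A multilevel FastDTW approximation is available for long
sequences; its cost is that of a feasible warping path and therefore
never below the exact DTW cost.

For clustering, the N-by-N matrix of each measure is min-max normalised
to [0, 1] and the rows of all measures are concatenated, so that with two
measures every trajectory is described by 2N values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._dp import dtw_cost, frechet_cost
from .description import DescriptionMatrix
from .preprocess import ResampledTrajectory

__all__ = [
    "DistanceMatrix",
    "dtw_distance",
    "fastdtw_distance",
    "frechet_distance",
    "pairwise_distance_matrix",
    "similarity_description",
    "MEASURES",
]

DEFAULT_FASTDTW_RADIUS = 10


def _as_points(seq) -> np.ndarray:
    pts = np.asarray(seq, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError(f"point sequence must be non-empty (n, 2), got {pts.shape}")
    return np.ascontiguousarray(pts)


def dtw_distance(a, b) -> float:
    """Exact dynamic-time-warping distance between two point sequences."""
    return float(dtw_cost(_as_points(a), _as_points(b)))


def frechet_distance(a, b) -> float:
    """Discrete Frechet distance between two point sequences."""
    return float(frechet_cost(_as_points(a), _as_points(b)))


# ---------------------------------------------------------------------------
# FastDTW: coarsen -> solve -> project -> refine (radius-bounded window)

def _coarsen(pts: np.ndarray) -> np.ndarray:
    n = pts.shape[0]
    half = pts[: 2 * (n // 2)].reshape(-1, 2, 2).mean(axis=1)
    if n % 2:
        half = np.vstack([half, pts[-1]])
    return half


def _full_windowed(a: np.ndarray, b: np.ndarray, window=None):
    """DTW over an explicit cell window, with path backtracking.

    ``window`` maps row index -> (lo, hi) inclusive column bounds; None
    means the full rectangle.  Returns (cost, path).
    """
    n, m = a.shape[0], b.shape[0]
    if window is None:
        window = {i: (0, m - 1) for i in range(n)}
    INF = np.inf
    cost = {}
    parent = {}
    for i in range(n):
        lo, hi = window[i]
        for j in range(lo, hi + 1):
            d = float(np.hypot(a[i, 0] - b[j, 0], a[i, 1] - b[j, 1]))
            if i == 0 and j == 0:
                cost[(0, 0)] = d
                parent[(0, 0)] = None
                continue
            best, arg = INF, None
            for pi, pj in ((i - 1, j - 1), (i - 1, j), (i, j - 1)):
                c = cost.get((pi, pj), INF)
                if c < best:
                    best, arg = c, (pi, pj)
            if arg is None:
                continue  # unreachable cell
            cost[(i, j)] = best + d
            parent[(i, j)] = arg
    end = (n - 1, m - 1)
    if end not in cost:
        raise RuntimeError("window excludes the end cell")  # pragma: no cover
    path = []
    cell = end
    while cell is not None:
        path.append(cell)
        cell = parent[cell]
    path.reverse()
    return cost[end], path


def _expand_window(path, n: int, m: int, radius: int) -> dict[int, tuple[int, int]]:
    """Project a coarse path to the fine grid and inflate it by ``radius``."""
    lo = np.full(n, m, dtype=int)
    hi = np.full(n, -1, dtype=int)
    for ci, cj in path:
        for i in (2 * ci, 2 * ci + 1):
            for j in (2 * cj, 2 * cj + 1):
                ilo = max(i - radius, 0)
                ihi = min(i + radius, n - 1)
                jlo = max(j - radius, 0)
                jhi = min(j + radius, m - 1)
                lo[ilo : ihi + 1] = np.minimum(lo[ilo : ihi + 1], jlo)
                hi[ilo : ihi + 1] = np.maximum(hi[ilo : ihi + 1], jhi)
    # keep rows contiguous and monotone so the DP stays connected
    for i in range(1, n):
        if lo[i] > hi[i - 1] + 1:
            lo[i] = hi[i - 1] + 1
    lo[0] = 0
    hi[-1] = m - 1
    return {i: (int(lo[i]), int(hi[i])) for i in range(n)}


def _fastdtw(a: np.ndarray, b: np.ndarray, radius: int):
    min_size = radius + 2
    if a.shape[0] <= min_size or b.shape[0] <= min_size:
        return _full_windowed(a, b)
    coarse_a, coarse_b = _coarsen(a), _coarsen(b)
    _, coarse_path = _fastdtw(coarse_a, coarse_b, radius)
    window = _expand_window(coarse_path, a.shape[0], b.shape[0], radius)
    return _full_windowed(a, b, window)


def fastdtw_distance(a, b, radius: int = DEFAULT_FASTDTW_RADIUS) -> float:
    """Multilevel approximation of DTW; upper-bounds :func:`dtw_distance`.

    With ``radius >= max(len(a), len(b))`` the result equals exact DTW.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    cost, _ = _fastdtw(_as_points(a), _as_points(b), int(radius))
    return float(cost)


# ---------------------------------------------------------------------------

MEASURES = ("dtw", "fastdtw", "frechet")


@dataclass
class DistanceMatrix:
    """Symmetric all-pairs path-distance table for one measure."""

    measure: str
    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError(f"values shape {vals.shape} does not match {n} ids")
        if (vals < 0).any():
            raise ValueError("distance matrix has negative entries")
        if np.any(np.diag(vals) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.array_equal(vals, vals.T):
            raise ValueError("distance matrix must be symmetric")
        self.values = vals
        self.ids = tuple(str(i) for i in self.ids)


def pairwise_distance_matrix(
    resampled: Sequence[ResampledTrajectory],
    measure: str = "dtw",
    radius: int = DEFAULT_FASTDTW_RADIUS,
) -> DistanceMatrix:
    """All-pairs distance matrix over a consistently resampled set.

    Only the upper triangle is computed; it is mirrored so that entries
    (i, j) and (j, i) are bitwise equal and the diagonal is exactly 0.
    """
    if len(resampled) < 2:
        raise ValueError("need at least 2 trajectories")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    steps = {round(t.step_mm, 9) for t in resampled}
    if len(steps) > 1:
        raise ValueError(f"mixed resampling steps {sorted(steps)}; resample jointly")

    pts = [np.ascontiguousarray(t.positions) for t in resampled]
    n = len(pts)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if measure == "dtw":
                d = float(dtw_cost(pts[i], pts[j]))
            elif measure == "frechet":
                d = float(frechet_cost(pts[i], pts[j]))
            else:
                d = fastdtw_distance(pts[i], pts[j], radius=radius)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(
        measure=measure, values=vals, ids=tuple(t.traj_id for t in resampled)
    )


def similarity_description(matrices: Sequence[DistanceMatrix]) -> DescriptionMatrix:
    """Concatenate min-max normalised distance rows into an N x (m*N) matrix.

    Each measure's matrix is scaled to [0, 1] over all of its entries
    before concatenation, because the measures have incommensurate scales
    (a sum versus a maximum).
    """
    if not matrices:
        raise ValueError("need at least one distance matrix")
    ids = matrices[0].ids
    for dm in matrices[1:]:
        if dm.ids != ids:
            raise ValueError("distance matrices must share ids and order")

    blocks, labels = [], []
    norm: dict[str, dict[str, float]] = {}
    for dm in matrices:
        lo, hi = float(dm.values.min()), float(dm.values.max())
        if hi == lo:
            raise ValueError(
                f"degenerate normalization: {dm.measure} matrix is constant"
            )
        blocks.append((dm.values - lo) / (hi - lo))
        labels.extend(f"{dm.measure}:{tid}" for tid in ids)
        norm[dm.measure] = {"min": lo, "max": hi}
    return DescriptionMatrix(
        values=np.hstack(blocks),
        ids=ids,
        column_labels=tuple(labels),
        normalization={"scheme": "minmax-per-measure", "measures": norm},
    )
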