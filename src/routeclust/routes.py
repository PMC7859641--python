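"""Route models: t-SNE visualisation, average routes, novel assignment.

Once M3C has produced labels, each cluster is summarised by its medoid
(in description space) and an average path.  The high-dimensional
description space is projected to 2D with t-SNE to visually disambiguate
between candidate cluster numbers, and novel trajectories can be placed
into the existing clustering by computing their distances to the training
trajectories with the frozen normalisation constants and assigning them
to the nearest medoid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .characteristics import flight_characteristics
from .description import DescriptionMatrix
from .preprocess import resample_equal_arclength
from .similarity import dtw_distance, fastdtw_distance, frechet_distance
from .trajectory_io import Trajectory, TrajectorySet

logger = logging.getLogger(__name__)

__all__ = [
    "RouteModel",
    "embed_tsne",
    "average_route",
    "build_route_model",
    "assign_novel",
    "plot_routes",
    "candidate_diagnostics",
]

DEFAULT_AVERAGE_POINTS = 100

_MEASURE_FUNCS = {
    "dtw": dtw_distance,
    "fastdtw": fastdtw_distance,
    "frechet": frechet_distance,
}


def default_perplexity(n: int) -> float:
    return float(min(30.0, (n - 1) / 3.0))


def embed_tsne(
    desc: DescriptionMatrix | np.ndarray,
    perplexity: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Deterministic 2D t-SNE embedding of the description space.

    PCA initialisation and a fixed seed keep the embedding stable, since
    it arbitrates visually between candidate cluster numbers.
    """
    x = desc.values if isinstance(desc, DescriptionMatrix) else np.asarray(desc, float)
    n = x.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 rows for t-SNE, got {n}")
    if perplexity is None:
        perplexity = default_perplexity(n)
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < N = {n}")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
    )
    return np.asarray(tsne.fit_transform(x), dtype=float)


def _resample_fractional(traj: Trajectory, m: int) -> np.ndarray:
    """Resample to exactly m points at fractional arc-length positions."""
    pos = traj.positions
    steps = np.diff(pos, axis=0)
    keep = np.hypot(steps[:, 0], steps[:, 1]) > 0
    pos = pos[np.concatenate(([True], keep))]
    if pos.shape[0] < 2:
        raise ValueError(f"trajectory {traj.traj_id!r}: degenerate (single point)")
    seglen = np.hypot(*np.diff(pos, axis=0).T)
    cumlen = np.concatenate(([0.0], np.cumsum(seglen)))
    targets = np.linspace(0.0, cumlen[-1], m)
    return np.column_stack(
        [np.interp(targets, cumlen, pos[:, 0]), np.interp(targets, cumlen, pos[:, 1])]
    )


def average_route(
    members: Sequence[Trajectory], m: int = DEFAULT_AVERAGE_POINTS
) -> np.ndarray:
    """Pointwise mean path of a cluster.

    Every member is resampled to exactly ``m`` points equally spaced in
    (fractional) arc length, so that all members contribute aligned
    points; the mean is taken pointwise.
    """
    if not members:
        raise ValueError("need at least one member trajectory")
    if m < 2:
        raise ValueError("m must be >= 2")
    stacked = np.stack([_resample_fractional(t, m) for t in members])
    return stacked.mean(axis=0)


@dataclass
class RouteModel:
    """Frozen clustering result usable to classify novel trajectories."""

    labels: dict[str, int]
    medoid_ids: dict[int, str]
    medoid_vectors: dict[int, np.ndarray]
    average_paths: dict[int, np.ndarray]
    description_mode: str  # 'similarity' | 'characteristics'
    normalization: dict
    measures: tuple[str, ...] = ()
    step_mm: float | None = None

    def __post_init__(self) -> None:
        if self.description_mode not in ("similarity", "characteristics"):
            raise ValueError(f"unknown description_mode {self.description_mode!r}")
        clusters = sorted(set(self.labels.values()))
        for c in clusters:
            if c not in self.medoid_ids:
                raise ValueError(f"cluster {c} has no medoid")
            if self.labels[self.medoid_ids[c]] != c:
                raise ValueError(f"medoid of cluster {c} is not a member of it")

    @property
    def clusters(self) -> list[int]:
        return sorted(self.medoid_ids)


def build_route_model(
    tset: TrajectorySet,
    desc: DescriptionMatrix,
    labels: Mapping[str, int] | np.ndarray,
    description_mode: str,
    measures: Sequence[str] = (),
    step_mm: float | None = None,
    n_average_points: int = DEFAULT_AVERAGE_POINTS,
) -> RouteModel:
    """Assemble a :class:`RouteModel` from a labelled description matrix.

    The medoid of each cluster is the member minimising the summed
    Euclidean distance to its cluster mates in description space.
    """
    if isinstance(labels, np.ndarray):
        labels = {tid: int(lab) for tid, lab in zip(desc.ids, labels)}
    labels = {str(k): int(v) for k, v in labels.items()}
    missing = [tid for tid in desc.ids if tid not in labels]
    if missing:
        raise ValueError(f"unlabeled trajectory ids: {missing}")

    idx = {tid: i for i, tid in enumerate(desc.ids)}
    medoid_ids: dict[int, str] = {}
    medoid_vectors: dict[int, np.ndarray] = {}
    average_paths: dict[int, np.ndarray] = {}
    for c in sorted(set(labels.values())):
        member_ids = [tid for tid in desc.ids if labels[tid] == c]
        rows = desc.values[[idx[t] for t in member_ids]]
        within = np.linalg.norm(rows[:, None, :] - rows[None, :, :], axis=2)
        medoid = member_ids[int(np.argmin(within.sum(axis=1)))]
        medoid_ids[c] = medoid
        medoid_vectors[c] = desc.values[idx[medoid]].copy()
        average_paths[c] = average_route(
            [tset[t] for t in member_ids], m=n_average_points
        )
    return RouteModel(
        labels=labels,
        medoid_ids=medoid_ids,
        medoid_vectors=medoid_vectors,
        average_paths=average_paths,
        description_mode=description_mode,
        normalization=dict(desc.normalization),
        measures=tuple(measures),
        step_mm=step_mm,
    )


def _novel_similarity_vector(
    novel: Trajectory,
    tset: TrajectorySet,
    model: RouteModel,
    measures: Sequence[str],
    step_mm: float,
) -> np.ndarray:
    """Project a novel path into the frozen similarity description space."""
    novel_rs = resample_equal_arclength(novel, step_mm)
    train_rs = [resample_equal_arclength(t, step_mm) for t in tset]
    norm = model.normalization.get("measures", {})
    blocks = []
    for measure in measures:
        if measure not in _MEASURE_FUNCS:
            raise ValueError(f"unknown measure {measure!r}")
        if measure not in norm:
            raise ValueError(f"no frozen normalization for measure {measure!r}")
        func = _MEASURE_FUNCS[measure]
        dists = np.array(
            [func(novel_rs.positions, t.positions) for t in train_rs]
        )
        lo, hi = norm[measure]["min"], norm[measure]["max"]
        blocks.append((dists - lo) / (hi - lo))
    return np.concatenate(blocks)


def assign_novel(
    novel: Trajectory,
    tset: TrajectorySet,
    model: RouteModel,
    measures: Sequence[str] | None = None,
    step_mm: float | None = None,
) -> int:
    """Assign a novel trajectory to the cluster of the nearest medoid.

    In similarity mode the novel path is resampled with the training step
    and its distances to every training trajectory are normalised with
    the constants frozen at training time.  In characteristics mode the
    novel path's flight characteristics are z-scored with the training
    means/sds.  Ties break to the lowest cluster index.
    """
    measures = tuple(measures) if measures is not None else model.measures
    step = step_mm if step_mm is not None else model.step_mm
    if model.description_mode == "similarity":
        if not measures or step is None:
            raise ValueError("similarity-mode assignment needs measures and step_mm")
        vec = _novel_similarity_vector(novel, tset, model, measures, step)
    else:
        means = np.asarray(model.normalization["means"], dtype=float)
        sds = np.asarray(model.normalization["sds"], dtype=float)
        safe = np.where(sds < 1e-12, 1.0, sds)
        vec = (flight_characteristics(novel).as_array() - means) / safe

    clusters = model.clusters
    dists = np.array([np.linalg.norm(vec - model.medoid_vectors[c]) for c in clusters])
    choice = clusters[int(np.argmin(dists))]
    near_ties = [c for c, d in zip(clusters, dists) if d <= dists.min() + 1e-12]
    if len(near_ties) > 1:
        logger.info(
            "novel %r equidistant to medoids of clusters %s; tie-break to %d",
            novel.traj_id, near_ties, choice,
        )
    return int(choice)


def plot_routes(
    tset: TrajectorySet, model: RouteModel, outdir: str | Path
) -> list[Path]:
    """One panel per cluster: member paths, bold average, faded other averages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clusters = model.clusters
    cmap = plt.get_cmap("tab10")
    files: list[Path] = []

    fig, axes = plt.subplots(
        len(clusters), 1, figsize=(9, 2.2 * len(clusters)), squeeze=False
    )
    for row, c in enumerate(clusters):
        ax = axes[row, 0]
        for tid, lab in model.labels.items():
            if lab == c:
                pos = tset[tid].positions
                ax.plot(pos[:, 0], pos[:, 1], color=cmap(c % 10), alpha=0.25, lw=0.7)
        for other in clusters:
            if other != c:
                avg = model.average_paths[other]
                ax.plot(avg[:, 0], avg[:, 1], color=cmap(other % 10), alpha=0.25, lw=1.8)
        avg = model.average_paths[c]
        ax.plot(avg[:, 0], avg[:, 1], color=cmap(c % 10), lw=2.5)
        ax.set_ylabel(f"cluster {c}\ny (mm)")
    axes[-1, 0].set_xlabel("x (mm)")
    fig.tight_layout()
    combined = outdir / "routes.png"
    fig.savefig(combined, dpi=120)
    plt.close(fig)
    files.append(combined)

    for c in clusters:
        fig, ax = plt.subplots(figsize=(9, 2.5))
        for tid, lab in model.labels.items():
            if lab == c:
                pos = tset[tid].positions
                ax.plot(pos[:, 0], pos[:, 1], color=cmap(c % 10), alpha=0.3, lw=0.7)
        avg = model.average_paths[c]
        ax.plot(avg[:, 0], avg[:, 1], color=cmap(c % 10), lw=2.5)
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        fig.tight_layout()
        path = outdir / f"route_{c}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        files.append(path)
    return files


def candidate_diagnostics(
    desc: DescriptionMatrix,
    labels_per_k: Mapping[int, np.ndarray],
    candidates: Sequence[int],
    seed: int = 0,
) -> dict[int, float]:
    """Silhouette score per candidate K (added diagnostic, not a decision).

    Reported alongside the t-SNE embedding to help choose between several
    significant Ks; the tool never auto-picks one.
    """
    out: dict[int, float] = {}
    for k in candidates:
        labs = np.asarray(labels_per_k[k])
        if len(np.unique(labs)) < 2:
            out[k] = float("nan")
            continue
        out[k] = float(silhouette_score(desc.values, labs))
    return out
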