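"""Sensitivity of the clustering to the re-sampling coefficient.

The clustering pipeline is re-run for a range of re-sampling steps
``s`` and each run is compared to the reference run (``s = 6`` mm/frame
by default) through a pairwise co-clustering confusion matrix: a pair of
trajectories clustered together in both runs is a true positive, together
only in the reference a false negative, together only in the alternative
a false positive, and apart in both a true negative.  The precision
TP / (TP + FP) is then judged against a null distribution obtained from
random clusterings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .m3c import M3CConfig, consensus_cluster
from .preprocess import resample_set
from .similarity import pairwise_distance_matrix, similarity_description
from .trajectory_io import TrajectorySet

__all__ = [
    "PairConfusion",
    "RobustnessResult",
    "coclustering_confusion",
    "precision",
    "random_precision_null",
    "resampling_sweep",
]

DEFAULT_STEPS = tuple(range(2, 12))  # s in [2, 11] mm/frame
DEFAULT_REFERENCE_STEP = 6.0


@dataclass(frozen=True)
class PairConfusion:
    """Confusion counts over unordered trajectory pairs."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _labels_to_arrays(
    ref_labels: Mapping[str, int], alt_labels: Mapping[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    ref_ids, alt_ids = set(ref_labels), set(alt_labels)
    if ref_ids != alt_ids:
        only_ref = sorted(ref_ids - alt_ids)
        only_alt = sorted(alt_ids - ref_ids)
        raise ValueError(
            f"label id mismatch: only in reference {only_ref}, "
            f"only in alternative {only_alt}"
        )
    ids = sorted(ref_ids)
    return (
        np.array([ref_labels[i] for i in ids]),
        np.array([alt_labels[i] for i in ids]),
    )


def coclustering_confusion(
    ref_labels: Mapping[str, int], alt_labels: Mapping[str, int]
) -> PairConfusion:
    """Pairwise co-clustering confusion of an alternative vs a reference.

    Invariant under permutation of cluster labels in either argument.
    """
    ref, alt = _labels_to_arrays(ref_labels, alt_labels)
    iu = np.triu_indices(len(ref), k=1)
    same_ref = (ref[:, None] == ref[None, :])[iu]
    same_alt = (alt[:, None] == alt[None, :])[iu]
    return PairConfusion(
        tp=int(np.sum(same_ref & same_alt)),
        fp=int(np.sum(~same_ref & same_alt)),
        tn=int(np.sum(~same_ref & ~same_alt)),
        fn=int(np.sum(same_ref & ~same_alt)),
    )


def precision(conf: PairConfusion) -> float:
    """TP / (TP + FP); errors if the alternative co-clusters no pairs."""
    denom = conf.tp + conf.fp
    if denom == 0:
        raise ValueError(
            "precision undefined: alternative clustering has no co-clustered pairs"
        )
    return conf.tp / denom


@dataclass
class RandomPrecisionNull:
    """Null precision distribution from random clusterings."""

    null: np.ndarray
    critical_value: float  # 95th percentile

    def p_value(self, t: float) -> float:
        n = len(self.null)
        return float((1.0 + np.sum(self.null >= t)) / (1.0 + n))


def random_precision_null(
    ref_labels: Mapping[str, int],
    k_range: Sequence[int] = tuple(range(2, 11)),
    n_sims: int = 100,
    seed: int | None = None,
    fixed_k: int | None = None,
) -> RandomPrecisionNull:
    """Precision null from uniformly random clusterings of the same ids.

    Each simulation draws K uniformly from ``k_range`` (or uses
    ``fixed_k``) and assigns every trajectory independently and uniformly
    to one of the K clusters; empty clusters may occur.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    ids = sorted(ref_labels)
    ref = np.array([ref_labels[i] for i in ids])
    iu = np.triu_indices(len(ids), k=1)
    same_ref = (ref[:, None] == ref[None, :])[iu]

    rng = np.random.default_rng(seed)
    ks = np.asarray(list(k_range), dtype=int)
    null = np.empty(n_sims)
    for s in range(n_sims):
        k = int(fixed_k) if fixed_k is not None else int(rng.choice(ks))
        alt = rng.integers(0, k, size=len(ids))
        same_alt = (alt[:, None] == alt[None, :])[iu]
        tp = np.sum(same_ref & same_alt)
        fp = np.sum(~same_ref & same_alt)
        null[s] = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    return RandomPrecisionNull(
        null=null, critical_value=float(np.percentile(null, 95))
    )


@dataclass
class RobustnessResult:
    """Precision per (step, K) against the reference-step labels."""

    reference_step: float
    steps: tuple[float, ...]
    ks: tuple[int, ...]
    precision: dict[tuple[float, int], float]
    labels: dict[tuple[float, int], dict[str, int]]
    null: dict[int, RandomPrecisionNull]
    p_values: dict[tuple[float, int], float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            for k in self.ks:
                rows.append(
                    {
                        "step_mm": s,
                        "K": k,
                        "precision": self.precision[(s, k)],
                        "p_value": self.p_values[(s, k)],
                        "null_95th": self.null[k].critical_value,
                    }
                )
        return pd.DataFrame(rows)


def _labels_at_step(
    tset: TrajectorySet,
    step: float,
    cfg: M3CConfig,
    measures: Sequence[str],
) -> dict[int, dict[str, int]]:
    """Similarity pipeline at one step: consensus labels for every K."""
    resampled = resample_set(tset, step)
    matrices = [pairwise_distance_matrix(resampled, m) for m in measures]
    desc = similarity_description(matrices)
    out: dict[int, dict[str, int]] = {}
    for k in cfg.k_range:
        _, labels = consensus_cluster(desc, k, cfg)
        out[k] = {tid: int(lab) for tid, lab in zip(desc.ids, labels)}
    return out


def resampling_sweep(
    tset: TrajectorySet,
    steps: Sequence[float] = DEFAULT_STEPS,
    reference_step: float = DEFAULT_REFERENCE_STEP,
    cfg: M3CConfig | None = None,
    measures: Sequence[str] = ("dtw", "frechet"),
    n_null_sims: int = 100,
) -> RobustnessResult:
    """Re-run the similarity clustering across re-sampling steps.

    One seed (from ``cfg``) is reused across steps so differences reflect
    the step, not Monte Carlo noise.  For each step and K, the precision
    of pair co-clustering versus the reference-step labels is computed and
    compared to the random-clustering null for that K's reference.
    """
    cfg = cfg or M3CConfig()
    steps = tuple(float(s) for s in steps)
    if reference_step not in steps:
        steps = tuple(sorted(steps + (float(reference_step),)))

    per_step: dict[float, dict[int, dict[str, int]]] = {}
    for s in steps:
        per_step[s] = _labels_at_step(tset, s, cfg, measures)
    ref_labels = per_step[float(reference_step)]

    null = {
        k: random_precision_null(
            ref_labels[k], k_range=cfg.k_range, n_sims=n_null_sims,
            seed=cfg.seed + 1000 + k,
        )
        for k in cfg.k_range
    }

    prec: dict[tuple[float, int], float] = {}
    pvals: dict[tuple[float, int], float] = {}
    labels: dict[tuple[float, int], dict[str, int]] = {}
    for s in steps:
        for k in cfg.k_range:
            conf = coclustering_confusion(ref_labels[k], per_step[s][k])
            p = precision(conf)
            prec[(s, k)] = p
            pvals[(s, k)] = null[k].p_value(p)
            labels[(s, k)] = per_step[s][k]
    return RobustnessResult(
        reference_step=float(reference_step),
        steps=steps,
        ks=cfg.k_range,
        precision=prec,
        labels=labels,
        null=null,
        p_values=pvals,
    )
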