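"""Monte Carlo reference-based consensus clustering.

For each candidate cluster number K the description matrix is clustered
repeatedly on random subsamples with PAM (partition around medoids); the
consensus matrix records how often each pair of trajectories lands in the
same cluster when both are drawn.  The proportion of ambiguous clustering
(PAC) is the fraction of pairs whose consensus index falls in the
ambiguous middle of the consensus CDF.  To test whether a K is supported,
the same procedure is run on simulated single-cluster Gaussian reference
datasets whose principal-component variance structure matches the input;
the empirical tail probability of the observed PAC under that null gives
a p-value per K.  Candidate route numbers are the significant local PAC
minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .description import DescriptionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "M3CConfig",
    "ConsensusMatrix",
    "M3CResult",
    "pam",
    "consensus_cluster",
    "pac_score",
    "simulate_reference",
    "m3c_select_k",
]


@dataclass(frozen=True)
class M3CConfig:
    """Settings for the consensus-clustering run.

    ``U1``/``U2`` bound the ambiguous consensus interval of the PAC score;
    K is scanned over ``k_range`` (2..10 by default).
    """

    k_range: tuple[int, ...] = tuple(range(2, 11))
    n_consensus_iters: int = 100
    subsample_fraction: float = 0.8
    n_reference_sims: int = 100
    u1: float = 0.1
    u2: float = 0.9
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.k_range)
        if not ks or min(ks) < 2:
            raise ValueError("k_range must contain integers >= 2")
        if sorted(ks) != list(ks):
            raise ValueError("k_range must be sorted ascending")
        if not 0 <= self.u1 < self.u2 <= 1:
            raise ValueError(f"need 0 <= U1 < U2 <= 1, got {self.u1}, {self.u2}")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must be in (0, 1)")
        if self.n_consensus_iters < 1:
            raise ValueError("n_consensus_iters must be >= 1")
        object.__setattr__(self, "k_range", ks)


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering probabilities at one K.

    ``entry(i, j)`` = (#times i and j co-clustered) / (#times both were in
    the same subsample); the raw counts are kept for reproducibility.
    """

    values: np.ndarray
    K: int
    copair_counts: np.ndarray
    cosample_counts: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T):
            raise ValueError("consensus matrix must be symmetric")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("consensus entries must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("consensus diagonal must be 1")
        self.values = v


@dataclass
class M3CResult:
    """Per-K consensus output plus the candidate route numbers."""

    ks: tuple[int, ...]
    pac: dict[int, float]
    null_pac: dict[int, np.ndarray]
    p_values: dict[int, float]
    labels: dict[int, np.ndarray]
    consensus: dict[int, ConsensusMatrix]
    candidates: list[int]
    ids: tuple[str, ...] = field(default_factory=tuple)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": list(self.ks),
                "pac": [self.pac[k] for k in self.ks],
                "p_value": [self.p_values[k] for k in self.ks],
                "candidate": [k in self.candidates for k in self.ks],
            }
        )

    def labels_for(self, k: int) -> dict[str, int]:
        return {tid: int(lab) for tid, lab in zip(self.ids, self.labels[k])}


# ---------------------------------------------------------------------------
# PAM (partition around medoids): deterministic BUILD + best-swap refinement

def pam(dist: np.ndarray, k: int, max_swaps: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Cluster items given a full distance matrix; returns (labels, medoids).

    Deterministic: greedy BUILD initialisation followed by steepest-descent
    SWAP passes, ties broken toward the lowest index.
    """
    n = dist.shape[0]
    if k > n:
        raise ValueError(f"K={k} exceeds number of items {n}")
    if k == n:
        return np.arange(n), np.arange(n)

    # BUILD: first medoid minimises total distance, then greedy gain
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    nearest = dist[:, medoids[0]].copy()
    for _ in range(1, k):
        gains = np.maximum(nearest[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        m = int(np.argmax(gains))
        medoids.append(m)
        nearest = np.minimum(nearest, dist[:, m])

    med = np.array(sorted(medoids))
    for _ in range(max_swaps):
        dmed = dist[:, med]  # n x k
        order = np.argsort(dmed, axis=1)
        n1 = order[:, 0]
        d1 = dmed[np.arange(n), n1]
        d2 = dmed[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)

        # delta of assigning each point to each candidate when its medoid stays
        gain_keep = np.minimum(dist - d1[:, None], 0.0)  # n x n (candidates)
        total_keep = gain_keep.sum(axis=0)
        # delta when the point's own medoid is removed
        reassign = np.minimum(dist, d2[:, None]) - d1[:, None]  # n x n

        best_delta, best_swap = -1e-9, None
        for mi in range(k):
            mask = n1 == mi
            delta = total_keep - gain_keep[mask].sum(axis=0) + reassign[mask].sum(axis=0)
            delta[med] = np.inf  # cannot swap in an existing medoid
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_swap = float(delta[h]), (mi, h)
        if best_swap is None:
            break
        med[best_swap[0]] = best_swap[1]
        med = np.array(sorted(med))

    labels = np.argmin(dist[:, med], axis=1)
    return labels, med


# ---------------------------------------------------------------------------

def _consensus_from_dist(
    dist: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_iters: int,
    fraction: float,
) -> ConsensusMatrix:
    n = dist.shape[0]
    n_sub = int(np.ceil(fraction * n))
    copair = np.zeros((n, n))
    cosample = np.zeros((n, n))
    for _ in range(n_iters):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub_labels, _ = pam(dist[np.ix_(idx, idx)], k)
        cosample[np.ix_(idx, idx)] += 1.0
        for c in range(k):
            members = idx[sub_labels == c]
            copair[np.ix_(members, members)] += 1.0
    off = ~np.eye(n, dtype=bool)
    if (cosample[off] == 0).any():
        raise ValueError(
            "some trajectory pairs were never co-subsampled; "
            "increase n_consensus_iters or subsample_fraction"
        )
    values = np.divide(copair, cosample, out=np.ones_like(copair), where=cosample > 0)
    np.fill_diagonal(values, 1.0)
    return ConsensusMatrix(values=values, K=k, copair_counts=copair, cosample_counts=cosample)


def _labels_from_consensus(cm: ConsensusMatrix) -> np.ndarray:
    """Cut average-linkage hierarchical clustering of (1 - consensus)."""
    dissim = 1.0 - cm.values
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    labels = fcluster(z, t=cm.K, criterion="maxclust")
    if len(np.unique(labels)) != cm.K:
        logger.warning(
            "degenerate cut: %d distinct labels instead of K=%d",
            len(np.unique(labels)), cm.K,
        )
    # relabel to 0..K-1 in order of first appearance, for determinism
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def consensus_cluster(
    desc: DescriptionMatrix | np.ndarray, k: int, cfg: M3CConfig
) -> tuple[ConsensusMatrix, np.ndarray]:
    """Consensus matrix and labels at one K (seeded, deterministic).

    Subsamples ``ceil(fraction * N)`` rows without replacement
    ``n_consensus_iters`` times, clusters each subsample with PAM on
    Euclidean distances in description space, and accumulates co-cluster
    versus co-sample counts.  Final labels cut an average-linkage tree on
    (1 - consensus) into K groups.
    """
    x = desc.values if isinstance(desc, DescriptionMatrix) else np.asarray(desc, float)
    if k > x.shape[0]:
        raise ValueError(f"K={k} exceeds N={x.shape[0]}")
    rng = np.random.default_rng(cfg.seed)
    dist = cdist(x, x)
    cm = _consensus_from_dist(
        dist, k, rng, cfg.n_consensus_iters, cfg.subsample_fraction
    )
    return cm, _labels_from_consensus(cm)


def pac_score(cm: ConsensusMatrix | np.ndarray, u1: float = 0.1, u2: float = 0.9) -> float:
    """Proportion of ambiguous clustering.

    Fraction of off-diagonal unordered pairs whose consensus index falls
    in (U1, U2] — i.e. CDF(U2) - CDF(U1) of the consensus-index
    distribution.  0 for a perfectly binary consensus, 1 if every pair is
    maximally ambiguous.
    """
    values = cm.values if isinstance(cm, ConsensusMatrix) else np.asarray(cm, float)
    iu = np.triu_indices(values.shape[0], k=1)
    v = values[iu]
    return float(np.mean((v > u1) & (v <= u2)))


def simulate_reference(
    desc: DescriptionMatrix | np.ndarray,
    cfg: M3CConfig,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Single-cluster Gaussian reference datasets with matched covariance.

    Principal-component scores of the input are replaced by independent
    Gaussian draws with the observed per-component variances, rotated back
    and re-centred, giving ``n_reference_sims`` null datasets of the same
    shape as the input.
    """
    x = desc.values if isinstance(desc, DescriptionMatrix) else np.asarray(desc, float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows to simulate a reference")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mean = x.mean(axis=0)
    xc = x - mean
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    score_sd = svals / np.sqrt(n - 1)
    return [
        rng.normal(size=(n, len(svals))) * score_sd @ vt + mean
        for _ in range(cfg.n_reference_sims)
    ]


def _local_minima(ks: tuple[int, ...], pac: dict[int, float]) -> list[int]:
    """Strict local minima of PAC over K; boundaries qualify against their
    single neighbour."""
    out = []
    vals = [pac[k] for k in ks]
    for i, k in enumerate(ks):
        left_ok = i == 0 or vals[i] < vals[i - 1]
        right_ok = i == len(ks) - 1 or vals[i] < vals[i + 1]
        if len(ks) == 1 or (left_ok and right_ok):
            out.append(k)
    return out


def _stage_seed(base: int, *parts: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(base, spawn_key=tuple(parts)))


def m3c_select_k(desc: DescriptionMatrix | np.ndarray, cfg: M3CConfig) -> M3CResult:
    """Full M3C scan: per-K consensus, PAC, null PAC, p-values, candidates.

    The empirical one-sided p-value per K is
    ``(1 + #{null PAC <= observed PAC}) / (1 + n_reference_sims)`` (smaller
    PAC means more structure).  Candidates are the significant local PAC
    minima; all of them are reported, disambiguation is left to
    visualisation.
    """
    if isinstance(desc, DescriptionMatrix):
        x, ids = desc.values, desc.ids
    else:
        x = np.asarray(desc, float)
        ids = tuple(str(i) for i in range(x.shape[0]))
    ks = cfg.k_range
    dist = cdist(x, x)

    pac: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    consensus: dict[int, ConsensusMatrix] = {}
    for ki, k in enumerate(ks):
        rng = _stage_seed(cfg.seed, 0, ki)
        cm = _consensus_from_dist(
            dist, k, rng, cfg.n_consensus_iters, cfg.subsample_fraction
        )
        consensus[k] = cm
        pac[k] = pac_score(cm, cfg.u1, cfg.u2)
        labels[k] = _labels_from_consensus(cm)

    refs = simulate_reference(x, cfg, rng=_stage_seed(cfg.seed, 1))
    null_pac: dict[int, list[float]] = {k: [] for k in ks}
    for ri, ref in enumerate(refs):
        ref_dist = cdist(ref, ref)
        for ki, k in enumerate(ks):
            rng = _stage_seed(cfg.seed, 2, ri, ki)
            cm = _consensus_from_dist(
                ref_dist, k, rng, cfg.n_consensus_iters, cfg.subsample_fraction
            )
            null_pac[k].append(pac_score(cm, cfg.u1, cfg.u2))

    n_sims = len(refs)
    p_values = {
        k: (1.0 + np.sum(np.asarray(null_pac[k]) <= pac[k])) / (1.0 + n_sims)
        for k in ks
    }
    candidates = [
        k for k in _local_minima(ks, pac) if p_values[k] < cfg.alpha
    ]
    return M3CResult(
        ks=ks,
        pac=pac,
        null_pac={k: np.asarray(v) for k, v in null_pac.items()},
        p_values=p_values,
        labels=labels,
        consensus=consensus,
        candidates=candidates,
        ids=ids,
    )
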