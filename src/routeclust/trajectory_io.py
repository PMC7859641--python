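"""Reading, validating and writing trajectory tables.

Trajectories are stored in delimited-text tables with one row per video
frame and at least the columns ``traj_id``, ``frame``, ``x`` and ``y``
(``z`` and ``individual_id`` optional).  Coordinates are in millimetres:
``x`` runs along the tunnel axis, ``y`` is the lateral position, with the
origin at the tunnel entrance corner.  Column names and the delimiter are
configurable through a *dialect* mapping (plain dict or YAML file).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "TrajectorySet",
    "TrajectoryFormatError",
    "TrajectoryValidationError",
    "DEFAULT_DIALECT",
    "load_dialect",
    "read_trajectories",
    "write_trajectories",
    "write_labels",
    "read_labels",
]

#: Default column mapping and delimiter for trajectory tables.
DEFAULT_DIALECT: dict[str, str] = {
    "traj_id": "traj_id",
    "individual_id": "individual_id",
    "frame": "frame",
    "x": "x",
    "y": "y",
    "z": "z",
    "delimiter": ",",
}

DEFAULT_FRAME_RATE = 60.0  # frames per second


class TrajectoryFormatError(ValueError):
    """The input table does not have the expected columns/layout."""


class TrajectoryValidationError(ValueError):
    """A trajectory violates an invariant (ordering, finiteness, ...)."""


@dataclass(frozen=True)
class Trajectory:
    """One flight: an ordered sequence of planar positions.

    Parameters
    ----------
    traj_id
        Unique identifier of the flight.
    positions
        ``(n, 2)`` array of ``(x, y)`` positions in mm, in recording order.
    individual_id
        Identifier of the animal (may be shared between flights).
    frame_rate
        Recording frame rate in Hz.
    source_dim
        Dimensionality of the source data (3 if a ``z`` column was
        projected away, else 2).
    """

    traj_id: str
    positions: np.ndarray
    individual_id: str = ""
    frame_rate: float = DEFAULT_FRAME_RATE
    source_dim: int = 2

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise TrajectoryValidationError(
                f"trajectory {self.traj_id!r}: positions must be (n, 2), "
                f"got shape {pos.shape}"
            )
        if pos.shape[0] < 2:
            raise TrajectoryValidationError(
                f"trajectory {self.traj_id!r}: needs at least 2 positions"
            )
        if not np.isfinite(pos).all():
            raise TrajectoryValidationError(
                f"trajectory {self.traj_id!r}: non-finite coordinates"
            )
        if self.frame_rate <= 0:
            raise TrajectoryValidationError(
                f"trajectory {self.traj_id!r}: frame_rate must be positive"
            )
        object.__setattr__(self, "positions", pos)

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def arc_length(self) -> float:
        """Total polyline length in mm."""
        steps = np.diff(self.positions, axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())

    def step_lengths(self) -> np.ndarray:
        """Per-frame displacement magnitudes in mm/frame."""
        steps = np.diff(self.positions, axis=0)
        return np.hypot(steps[:, 0], steps[:, 1])


@dataclass
class TrajectorySet:
    """Ordered, id-indexed collection of :class:`Trajectory`."""

    trajectories: list[Trajectory]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [t.traj_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TrajectoryValidationError(f"duplicate traj_ids: {dupes}")
        self._index = {tid: k for k, tid in enumerate(ids)}

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(t.traj_id for t in self.trajectories)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, key: int | str) -> Trajectory:
        if isinstance(key, str):
            return self.trajectories[self._index[key]]
        return self.trajectories[key]

    def __contains__(self, traj_id: str) -> bool:
        return traj_id in self._index


def load_dialect(dialect: Mapping[str, str] | str | Path | None) -> dict[str, str]:
    """Resolve a dialect argument (mapping, YAML path or None) to a dict."""
    resolved = dict(DEFAULT_DIALECT)
    if dialect is None:
        return resolved
    if isinstance(dialect, (str, Path)):
        with open(dialect) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise TrajectoryFormatError(f"dialect file {dialect} must hold a mapping")
        resolved.update({str(k): str(v) for k, v in loaded.items()})
    else:
        resolved.update({str(k): str(v) for k, v in dialect.items()})
    return resolved


def read_trajectories(
    path: str | Path,
    dialect: Mapping[str, str] | str | Path | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> TrajectorySet:
    """Read a delimited trajectory table into a :class:`TrajectorySet`.

    Rows are grouped by trajectory id in file order.  A ``z`` column, if
    present, is dropped (planar projection).  Frame indices must be
    strictly increasing within each id; ids with fewer than 2 rows are
    skipped with a warning.
    """
    d = load_dialect(dialect)
    df = pd.read_csv(path, sep=d["delimiter"])

    required = ["traj_id", "frame", "x", "y"]
    for role in required:
        if d[role] not in df.columns:
            raise TrajectoryFormatError(
                f"{path}: missing required column {d[role]!r} (role {role!r})"
            )

    has_z = d["z"] in df.columns
    has_ind = d["individual_id"] in df.columns
    source_dim = 3 if has_z else 2

    trajectories: list[Trajectory] = []
    for tid, group in df.groupby(d["traj_id"], sort=False):
        tid = str(tid)
        if len(group) < 2:
            logger.warning("trajectory %r has <2 rows; skipped", tid)
            continue
        frames = group[d["frame"]].to_numpy()
        if not np.all(np.diff(frames) > 0):
            raise TrajectoryValidationError(
                f"trajectory {tid!r}: frame indices not strictly increasing"
            )
        positions = group[[d["x"], d["y"]]].to_numpy(dtype=float)
        individual = str(group[d["individual_id"]].iloc[0]) if has_ind else ""
        trajectories.append(
            Trajectory(
                traj_id=tid,
                positions=positions,
                individual_id=individual,
                frame_rate=frame_rate,
                source_dim=source_dim,
            )
        )
    return TrajectorySet(trajectories)


def write_trajectories(
    tset: TrajectorySet,
    path: str | Path,
    dialect: Mapping[str, str] | str | Path | None = None,
) -> None:
    """Write a :class:`TrajectorySet` back to a delimited table."""
    d = load_dialect(dialect)
    rows = []
    for traj in tset:
        for k, (x, y) in enumerate(traj.positions):
            rows.append((traj.traj_id, traj.individual_id, k, x, y))
    df = pd.DataFrame(
        rows,
        columns=[d["traj_id"], d["individual_id"], d["frame"], d["x"], d["y"]],
    )
    df.to_csv(path, sep=d["delimiter"], index=False)


def write_labels(
    tset: TrajectorySet,
    labels: Mapping[str, int],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write cluster labels as a (traj_id, individual_id, cluster) table."""
    missing = [tid for tid in tset.ids if tid not in labels]
    if missing:
        raise TrajectoryValidationError(f"unlabeled trajectory ids: {missing}")
    df = pd.DataFrame(
        {
            "traj_id": list(tset.ids),
            "individual_id": [tset[tid].individual_id for tid in tset.ids],
            "cluster": [int(labels[tid]) for tid in tset.ids],
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


def read_labels(path: str | Path, delimiter: str = ",") -> dict[str, int]:
    """Read back a label table written by :func:`write_labels`."""
    df = pd.read_csv(path, sep=delimiter)
    if "traj_id" not in df.columns or "cluster" not in df.columns:
        raise TrajectoryFormatError(f"{path}: expected columns traj_id, cluster")
    return {str(t): int(c) for t, c in zip(df["traj_id"], df["cluster"])}
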