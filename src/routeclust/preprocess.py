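"""Equal arc-length resampling and path mirroring.

Path-similarity measures iterate over every point pair, so trajectories
are first interpolated along their polyline and down-sampled to a fixed
arc-length spacing (the re-sampling coefficient ``s``, in mm per
resampled step).  By default ``s`` is the pooled median per-frame speed
across all trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import Trajectory, TrajectorySet

__all__ = [
    "ResampleConfig",
    "ResampledTrajectory",
    "TooShortError",
    "median_speed",
    "resample_equal_arclength",
    "resample_set",
    "mirror_path",
]

DEFAULT_STEP_MM = 6.0


class TooShortError(ValueError):
    """Trajectory arc length is below one resampling step."""


@dataclass(frozen=True)
class ResampleConfig:
    """Resampling settings.

    ``step_mm`` is the arc-length spacing between resampled points; if
    ``auto_step`` is true it is replaced by the pooled median per-frame
    speed of the trajectory set.
    """

    step_mm: float = DEFAULT_STEP_MM
    auto_step: bool = False

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError(f"step_mm must be positive, got {self.step_mm}")

    def resolve_step(self, tset: TrajectorySet) -> float:
        return median_speed(tset) if self.auto_step else self.step_mm


@dataclass(frozen=True)
class ResampledTrajectory:
    """A trajectory re-expressed at constant arc-length spacing.

    Points sit at arc-length positions 0, s, 2s, ... along the linearly
    interpolated source polyline; the source endpoint is always retained,
    so the final segment may be shorter than ``step_mm``.
    """

    traj_id: str
    positions: np.ndarray
    step_mm: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise ValueError(
                f"resampled {self.traj_id!r}: positions must be (n>=2, 2)"
            )
        object.__setattr__(self, "positions", pos)

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]


def median_speed(tset: TrajectorySet) -> float:
    """Pooled median per-frame displacement magnitude (mm/frame)."""
    if len(tset) == 0:
        raise ValueError("cannot compute median speed of an empty trajectory set")
    pooled = np.concatenate([traj.step_lengths() for traj in tset])
    return float(np.median(pooled))


def _dedupe(points: np.ndarray) -> np.ndarray:
    """Collapse consecutive repeated positions (zero-length segments)."""
    steps = np.diff(points, axis=0)
    keep = np.hypot(steps[:, 0], steps[:, 1]) > 0
    return points[np.concatenate(([True], keep))]


def resample_equal_arclength(
    traj: Trajectory, cfg: ResampleConfig | float
) -> ResampledTrajectory:
    """Resample a trajectory at constant arc-length steps.

    The source endpoint is appended if the total arc length is not an
    exact multiple of the step.
    """
    step = cfg.step_mm if isinstance(cfg, ResampleConfig) else float(cfg)
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")

    points = _dedupe(traj.positions)
    seglen = np.hypot(*np.diff(points, axis=0).T)
    cumlen = np.concatenate(([0.0], np.cumsum(seglen)))
    total = cumlen[-1]
    if total < step:
        raise TooShortError(
            f"trajectory {traj.traj_id!r}: arc length {total:.3f} mm is "
            f"shorter than one step ({step} mm); too short to resample"
        )

    n_full = int(np.floor(total / step + 1e-12))
    targets = step * np.arange(n_full + 1)
    xs = np.interp(targets, cumlen, points[:, 0])
    ys = np.interp(targets, cumlen, points[:, 1])
    out = np.column_stack([xs, ys])
    if total - targets[-1] > 1e-9 * max(total, 1.0):
        out = np.vstack([out, points[-1]])
    else:
        out[-1] = points[-1]  # pin exactly to the source endpoint
    out[0] = points[0]
    return ResampledTrajectory(traj_id=traj.traj_id, positions=out, step_mm=step)


def resample_set(
    tset: TrajectorySet, cfg: ResampleConfig | float
) -> list[ResampledTrajectory]:
    """Resample every trajectory in a set with a shared step."""
    if isinstance(cfg, ResampleConfig):
        step = cfg.resolve_step(tset)
    else:
        step = float(cfg)
    return [resample_equal_arclength(traj, step) for traj in tset]


def mirror_path(
    traj: Trajectory, axis: str = "y", reverse_time: bool = False
) -> Trajectory:
    """Reflect a path about the midline of its bounding box.

    ``axis='y'`` flips the lateral coordinate, ``axis='x'`` the
    along-tunnel coordinate.  With ``reverse_time`` the point order is
    reversed as well, which turns an outbound path into a comparable
    inbound one.  The id is suffixed to mark the transformation.
    """
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    col = 0 if axis == "x" else 1
    pos = traj.positions.copy()
    lo, hi = pos[:, col].min(), pos[:, col].max()
    pos[:, col] = (lo + hi) - pos[:, col]
    suffix = f"|mirror{axis}"
    if reverse_time:
        pos = pos[::-1].copy()
        suffix += "|rev"
    return Trajectory(
        traj_id=traj.traj_id + suffix,
        positions=pos,
        individual_id=traj.individual_id,
        frame_rate=traj.frame_rate,
        source_dim=traj.source_dim,
    )
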