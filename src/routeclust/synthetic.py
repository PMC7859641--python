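"""Seeded generator of planted-route trajectory datasets.

Routes are waypoint polylines through a rectangular arena (a tunnel by
default).  Each generated path jitters its route's lateral waypoint
positions, interpolates a smooth centerline through them, walks along it
with per-frame speeds drawn around a mean, and adds temporally correlated
(AR(1)) lateral noise.  Paths of the same route therefore meander around
a common corridor while differing in length and sampling; the generating
route index is returned as the ground-truth label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .trajectory_io import Trajectory, TrajectorySet

__all__ = ["SyntheticConfig", "generate_dataset", "default_benchmark"]

DEFAULT_ARENA = (1400.0, 300.0)  # mm, length x width


def _default_routes() -> list[np.ndarray]:
    """Four corridors through the default tunnel with distinct shapes."""
    xs = np.linspace(0.0, DEFAULT_ARENA[0], 8)
    return [
        np.column_stack([xs, [45, 40, 55, 45, 60, 40, 50, 45]]),
        np.column_stack([xs, [115, 130, 105, 125, 110, 130, 115, 120]]),
        np.column_stack([xs, [185, 170, 195, 180, 200, 175, 190, 185]]),
        np.column_stack([xs, [255, 245, 260, 240, 255, 265, 250, 255]]),
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings for the planted-route generator.

    Waypoint jitter and the AR(1) noise act on the lateral (y) coordinate
    only, so monotone routes stay monotone along the tunnel axis.  Speeds
    are in mm/frame.
    """

    arena: tuple[float, float] = DEFAULT_ARENA
    routes: Sequence[np.ndarray] = field(default_factory=_default_routes)
    paths_per_route: int = 20
    lateral_noise_sd: float = 6.0
    noise_corr: float = 0.95
    waypoint_jitter_sd: float = 8.0
    speed_mean: float = 6.0
    speed_sd: float = 1.5
    frame_rate: float = 60.0
    n_individuals: int = 27
    seed: int = 0

    def __post_init__(self) -> None:
        if self.paths_per_route < 1:
            raise ValueError("paths_per_route must be >= 1")
        if self.lateral_noise_sd < 0 or self.waypoint_jitter_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.noise_corr < 1:
            raise ValueError("noise_corr must be in [0, 1)")
        if self.speed_mean <= 0:
            raise ValueError("speed_mean must be positive")
        routes = [np.asarray(r, dtype=float) for r in self.routes]
        for k, r in enumerate(routes):
            if r.ndim != 2 or r.shape[1] != 2 or r.shape[0] < 2:
                raise ValueError(f"route {k}: need >=2 waypoints of (x, y)")
            if (r[:, 0] < 0).any() or (r[:, 0] > self.arena[0]).any() or (
                r[:, 1] < 0
            ).any() or (r[:, 1] > self.arena[1]).any():
                raise ValueError(f"route {k}: waypoints outside the arena")
        object.__setattr__(self, "routes", tuple(routes))


def _centerline(waypoints: np.ndarray, n_dense: int = 2000) -> np.ndarray:
    """Smooth polyline through the waypoints (chord-length cubic spline)."""
    chord = np.hypot(*np.diff(waypoints, axis=0).T)
    t = np.concatenate(([0.0], np.cumsum(chord)))
    spline_x = CubicSpline(t, waypoints[:, 0])
    spline_y = CubicSpline(t, waypoints[:, 1])
    tt = np.linspace(0.0, t[-1], n_dense)
    return np.column_stack([spline_x(tt), spline_y(tt)])


def _one_path(
    waypoints: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    wp = waypoints.copy()
    wp[:, 1] += rng.normal(0.0, cfg.waypoint_jitter_sd, size=wp.shape[0])
    wp[:, 1] = np.clip(wp[:, 1], 0.0, cfg.arena[1])
    line = _centerline(wp)

    seglen = np.hypot(*np.diff(line, axis=0).T)
    cumlen = np.concatenate(([0.0], np.cumsum(seglen)))
    total = cumlen[-1]

    # walk the centerline with per-frame speed draws
    speeds: list[float] = []
    travelled = 0.0
    while travelled < total:
        v = max(rng.normal(cfg.speed_mean, cfg.speed_sd), 0.1 * cfg.speed_mean)
        speeds.append(v)
        travelled += v
    arcs = np.concatenate(([0.0], np.cumsum(speeds)))
    arcs = np.clip(arcs, 0.0, total)
    xs = np.interp(arcs, cumlen, line[:, 0])
    ys = np.interp(arcs, cumlen, line[:, 1])

    # AR(1) lateral meander around the corridor
    n = len(arcs)
    if cfg.lateral_noise_sd > 0:
        innov_sd = cfg.lateral_noise_sd * np.sqrt(1.0 - cfg.noise_corr**2)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, cfg.lateral_noise_sd)
        for i in range(1, n):
            noise[i] = cfg.noise_corr * noise[i - 1] + rng.normal(0.0, innov_sd)
        ys = ys + noise
    ys = np.clip(ys, 0.0, cfg.arena[1])
    xs = np.clip(xs, 0.0, cfg.arena[0])
    return np.column_stack([xs, ys])


def generate_dataset(cfg: SyntheticConfig) -> tuple[TrajectorySet, dict[str, int]]:
    """Generate a planted-route dataset; returns (set, true labels).

    Fully reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    trajectories: list[Trajectory] = []
    truth: dict[str, int] = {}
    counter = 0
    for route_idx, waypoints in enumerate(cfg.routes):
        for _ in range(cfg.paths_per_route):
            tid = f"t{counter:03d}"
            positions = _one_path(np.asarray(waypoints), cfg, rng)
            trajectories.append(
                Trajectory(
                    traj_id=tid,
                    positions=positions,
                    individual_id=f"b{counter % cfg.n_individuals:02d}",
                    frame_rate=cfg.frame_rate,
                )
            )
            truth[tid] = route_idx
            counter += 1
    return TrajectorySet(trajectories), truth


#: Seed of the canonical 4-route benchmark fixture.
BENCHMARK_SEED = 2021


def default_benchmark(seed: int = BENCHMARK_SEED) -> tuple[TrajectorySet, dict[str, int]]:
    """Canonical test fixture: 4 routes x 20 paths in a 1400 x 300 mm arena."""
    return generate_dataset(SyntheticConfig(seed=seed))
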