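"""Per-trajectory flight characteristics and the 7-column description.

Each flight is summarised by seven numbers: mean speed, mean and standard
deviation of the lateral position, circular mean and circular standard
deviation of the heading, maximal lateral position, and sinuosity
(traveled distance over straight-line start-to-end distance).  Heading is
approximated by the instantaneous direction of motion, since only
positions are tracked.

Characteristics are computed on the original (non-resampled) trajectories:
resampling would destroy all speed information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .description import DescriptionMatrix
from .trajectory_io import Trajectory, TrajectorySet

logger = logging.getLogger(__name__)

__all__ = [
    "CHARACTERISTIC_NAMES",
    "FlightCharacteristics",
    "flight_characteristics",
    "characteristics_matrix",
]

#: Fixed column order of the characteristics description matrix.
CHARACTERISTIC_NAMES: tuple[str, ...] = (
    "mean_speed",
    "mean_lateral",
    "mean_gaze",
    "std_lateral",
    "std_gaze",
    "max_lateral",
    "sinuosity",
)


@dataclass(frozen=True)
class FlightCharacteristics:
    """The seven summary values of one flight.

    Units: ``mean_speed`` mm/s; lateral quantities mm; gaze quantities
    radians with ``mean_gaze`` in (-pi, pi]; ``sinuosity`` dimensionless
    and >= 1.
    """

    mean_speed: float
    mean_lateral: float
    mean_gaze: float
    std_lateral: float
    std_gaze: float
    max_lateral: float
    sinuosity: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in CHARACTERISTIC_NAMES])


def flight_characteristics(traj: Trajectory) -> FlightCharacteristics:
    """Compute the seven flight characteristics of one trajectory.

    Standard deviations use the population convention (divide by N).
    Heading statistics are circular: the mean is ``atan2`` of the averaged
    unit heading vectors and the spread is ``sqrt(-2 ln Rbar)``.
    """
    pos = traj.positions
    if pos.shape[0] < 3:
        raise ValueError(
            f"trajectory {traj.traj_id!r}: need >=3 points for heading statistics"
        )
    steps = np.diff(pos, axis=0)
    step_norms = np.hypot(steps[:, 0], steps[:, 1])

    chord = float(np.hypot(*(pos[-1] - pos[0])))
    if chord == 0.0:
        raise ValueError(
            f"trajectory {traj.traj_id!r}: start equals end point, "
            "sinuosity undefined (division by zero)"
        )

    headings = np.arctan2(steps[:, 1], steps[:, 0])
    c, s = float(np.mean(np.cos(headings))), float(np.mean(np.sin(headings)))
    rbar = min(float(np.hypot(c, s)), 1.0)
    std_gaze = float(np.sqrt(-2.0 * np.log(max(rbar, 1e-300))))

    y = pos[:, 1]
    return FlightCharacteristics(
        mean_speed=float(step_norms.mean() * traj.frame_rate),
        mean_lateral=float(y.mean()),
        mean_gaze=float(np.arctan2(s, c)),
        std_lateral=float(y.std(ddof=0)),
        std_gaze=std_gaze,
        max_lateral=float(y.max()),
        sinuosity=float(step_norms.sum() / chord),
    )


def characteristics_matrix(tset: TrajectorySet) -> DescriptionMatrix:
    """Assemble the z-scored N-by-7 characteristics description matrix.

    Each column is standardised to mean 0 and (population) standard
    deviation 1 across trajectories; a zero-variance column is set to all
    zeros with a warning.
    """
    raw = np.vstack([flight_characteristics(t).as_array() for t in tset])
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=0)
    zeroed = sds < 1e-12
    if zeroed.any():
        names = [CHARACTERISTIC_NAMES[i] for i in np.flatnonzero(zeroed)]
        logger.warning("zero-variance characteristic columns set to 0: %s", names)
    safe_sds = np.where(zeroed, 1.0, sds)
    z = (raw - means) / safe_sds
    z[:, zeroed] = 0.0
    return DescriptionMatrix(
        values=z,
        ids=tset.ids,
        column_labels=CHARACTERISTIC_NAMES,
        normalization={
            "scheme": "zscore",
            "means": means,
            "sds": sds,
            "ddof": 0,
        },
    )
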