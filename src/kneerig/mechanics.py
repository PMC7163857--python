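"""Force/moment (wrench) representation and the superposition in situ force.

The in situ force of a structure is obtained by the superposition
principle: record the joint reaction while loading the intact joint,
replay the identical 6-DOF path after the structure has been removed,
and take the Euclidean norm of the force-component difference

    F = sqrt((fx - fx')^2 + (fy - fy')^2 + (fz - fz')^2).

Moments are carried through the data model but deliberately excluded
from ``F``; :func:`in_situ_moment` exposes the analogous moment norm for
exploratory use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import Pose, compose, invert

__all__ = ["Wrench", "InSituResult", "in_situ_force", "in_situ_moment", "transform_wrench"]


@dataclass(frozen=True)
class Wrench:
    """Sensor-frame force (N) and moment (Nm) components."""

    fx: float
    fy: float
    fz: float
    mx: float = 0.0
    my: float = 0.0
    mz: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("wrench contains non-finite components")

    @property
    def force(self) -> np.ndarray:
        return np.array([self.fx, self.fy, self.fz])

    @property
    def moment(self) -> np.ndarray:
        return np.array([self.mx, self.my, self.mz])

    def as_array(self) -> np.ndarray:
        return np.array([self.fx, self.fy, self.fz, self.mx, self.my, self.mz])

    @classmethod
    def from_arrays(cls, force: np.ndarray, moment: np.ndarray | None = None) -> "Wrench":
        f = np.asarray(force, dtype=float).reshape(3)
        m = np.zeros(3) if moment is None else np.asarray(moment, dtype=float).reshape(3)
        return cls(f[0], f[1], f[2], m[0], m[1], m[2])


@dataclass(frozen=True)
class InSituResult:
    """In situ force outcome for one specimen x flexion angle x meniscal state."""

    specimen: str
    flexion_angle: float
    state: str
    force: float

    def __post_init__(self) -> None:
        if self.force < 0:
            raise ValueError("in situ force must be non-negative")


def in_situ_force(recorded: Wrench, replayed: Wrench) -> float:
    """Superposition-principle in situ force, N.

    Both wrenches must be expressed in the same (sensor) frame and taken
    at the identical path sample; pairing bookkeeping is enforced one
    level up, in the pipeline.
    """
    d = recorded.force - replayed.force
    return float(np.linalg.norm(d))


def in_situ_moment(recorded: Wrench, replayed: Wrench) -> float:
    """Norm of the moment-component difference, Nm (not part of the default report)."""
    return float(np.linalg.norm(recorded.moment - replayed.moment))


def transform_wrench(w: Wrench, from_pose: Pose, to_pose: Pose) -> Wrench:
    """Re-express a wrench given in frame ``from_pose`` in frame ``to_pose``.

    Both poses locate their frame in a common parent frame.  The force is
    rotated; the moment is rotated and corrected by the lever arm of the
    inter-origin offset: ``m_to = R m_from + p x f_to`` where ``(R, p)``
    is the transform taking ``from``-frame coordinates to ``to``-frame
    coordinates.  Force magnitude is invariant under pure rotations.
    """
    rel = compose(invert(to_pose), from_pose)
    f = rel.rotation @ w.force
    m = rel.rotation @ w.moment + np.cross(rel.translation, f)
    return Wrench.from_arrays(f, m)
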