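"""Rigid-body pose algebra and the Grood–Suntay joint coordinate system.

The tibiofemoral relationship is described by the pose of a tibial
body-fixed frame relative to a femoral body-fixed frame.  Clinical
rotations and translations are obtained with the non-orthogonal joint
coordinate system (JCS) of Grood and Suntay: a femoral body-fixed
flexion axis ``e1``, a tibial body-fixed long axis ``e3``, and the
mutually perpendicular floating axis ``e2 = e3 x e1 / |e3 x e1|``.

Frame convention (right knee)
-----------------------------
* ``x`` — flexion axis, pointing medially,
* ``z`` — long axis, pointing proximally,
* ``y = z x x`` — completes the right-handed set.

With these axes the rotation of the tibial anatomical frame relative to
the femoral frame factors as ``R = Rx(flexion) * Ry(b) * Rz(c)`` where
``varus = -b`` and ``ext_rot = -c`` (positive rotations about +y tilt
the tibial long axis medially, i.e. valgus; positive rotations about the
tibial +z are internal for a right knee).  The decomposition is singular
at ``|varus| = 90°`` where the floating axis is undefined; that region
is far outside the physiological envelope and is rejected with an error.

All coordinates are reported relative to a per-specimen *zero position*
(``ReferencePose``): the tibial anatomical frame is defined to coincide
with the femoral frame at that pose, so the reference itself maps to six
zero coordinates.  Translations are the components of the inter-origin
vector resolved on the (generally non-orthogonal) basis ``(e1, e2, e3)``.

A left knee is a mirror image; per the package convention the ``side``
flag negates the medial translation and the varus angle only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pose",
    "JcsCoordinates",
    "ReferencePose",
    "JcsSingularityError",
    "jcs_from_pose",
    "pose_from_jcs",
    "compose",
    "invert",
    "identity_pose",
]

#: Hard guard: the floating axis degenerates at |varus| = 90 deg.
VARUS_SINGULARITY_DEG = 89.0

_ORTHO_TOL = 1e-9


class JcsSingularityError(ValueError):
    """Raised when a pose or coordinate set sits at the floating-axis singularity."""


@dataclass(frozen=True)
class Pose:
    """Rigid transform of the tibia relative to the femur.

    Parameters
    ----------
    rotation
        3x3 proper orthonormal matrix; columns are the tibial body axes
        expressed in the femoral frame.
    translation
        Tibial origin in the femoral frame, mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("pose contains non-finite entries")
        err = np.max(np.abs(R.T @ R - np.eye(3)))
        if err > _ORTHO_TOL:
            raise ValueError(f"rotation not orthonormal (max |R'R - I| = {err:.3e})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 transform."""
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.translation
        return T

    def isclose(self, other: "Pose", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol, rtol=0.0)
            and np.allclose(self.translation, other.translation, atol=atol, rtol=0.0)
        )


@dataclass(frozen=True)
class JcsCoordinates:
    """Grood–Suntay clinical coordinates relative to the zero position.

    Angles in degrees, translations in mm.  Signs: flexion(+),
    varus(+)/valgus(-), external(+)/internal(-), medial(+)/lateral(-),
    anterior(+)/posterior(-), distraction(+)/compression(-).
    """

    flexion: float = 0.0
    varus: float = 0.0
    ext_rot: float = 0.0
    medial: float = 0.0
    anterior: float = 0.0
    distraction: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.flexion, self.varus, self.ext_rot,
             self.medial, self.anterior, self.distraction]
        )


@dataclass(frozen=True)
class ReferencePose:
    """Per-specimen zero position (tibia relative to femur at a stated flexion).

    ``flexion_at_zero`` records the physical flexion angle at which the
    zero position was captured (30 deg in the standard protocol); JCS
    flexion values are reported relative to it.
    """

    pose: Pose = field(default_factory=lambda: identity_pose())
    flexion_at_zero: float = 30.0
    side: str = "right"

    def __post_init__(self) -> None:
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")


def identity_pose() -> Pose:
    return Pose(np.eye(3), np.zeros(3))


def compose(a: Pose, b: Pose) -> Pose:
    """Rigid-transform composition ``a ∘ b`` (apply ``b`` first)."""
    return Pose(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


def invert(a: Pose) -> Pose:
    """Inverse rigid transform."""
    Rt = a.rotation.T
    return Pose(Rt, -Rt @ a.translation)


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _jcs_axes(R_rel: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """JCS unit axes (femoral e1, floating e2, tibial e3) in the femoral frame."""
    e1 = np.array([1.0, 0.0, 0.0])
    e3 = R_rel[:, 2]
    cross = np.cross(e3, e1)
    n = np.linalg.norm(cross)
    if n < 1e-12:
        raise JcsSingularityError("tibial long axis parallel to flexion axis")
    return e1, cross / n, e3


def _relative(pose: Pose, reference: ReferencePose) -> Pose:
    """Anatomical relative transform: identity at the reference pose.

    The tibial anatomical frame is defined to coincide with the femoral
    frame at the zero position, so the relative rotation is
    ``R_pose @ R_ref.T`` and the relative translation is the femoral-frame
    displacement of the tibial origin induced beyond that rotation.
    """
    ref = reference.pose
    R_rel = pose.rotation @ ref.rotation.T
    t_rel = pose.translation - R_rel @ ref.translation
    return Pose(R_rel, t_rel)


def jcs_from_pose(pose: Pose, reference: ReferencePose) -> JcsCoordinates:
    """Decompose a tibiofemoral pose into Grood–Suntay clinical coordinates.

    Parameters
    ----------
    pose
        Tibia-relative-to-femur pose to decompose.
    reference
        Per-specimen zero position; the returned coordinates vanish there.

    Raises
    ------
    JcsSingularityError
        If the pose sits at (or beyond the guard band of) the
        floating-axis singularity ``|varus| >= 89 deg``.
    """
    rel = _relative(pose, reference)
    R = rel.rotation
    # R = Rx(a) @ Ry(b) @ Rz(c):  R[0,2] = sin b, R[1,2] = -sin a cos b,
    # R[2,2] = cos a cos b, R[0,1] = -cos b sin c, R[0,0] = cos b cos c.
    sb = float(np.clip(R[0, 2], -1.0, 1.0))
    b = np.rad2deg(np.arcsin(sb))
    if abs(b) >= VARUS_SINGULARITY_DEG:
        raise JcsSingularityError(
            f"|varus| = {abs(b):.2f} deg at/beyond the floating-axis singularity"
        )
    a = np.rad2deg(np.arctan2(-R[1, 2], R[2, 2]))
    c = np.rad2deg(np.arctan2(-R[0, 1], R[0, 0]))

    e1, e2, e3 = _jcs_axes(R)
    # Covariant expansion t = q1 e1 + q2 e2 + q3 e3 on the non-orthogonal basis.
    q = np.linalg.solve(np.column_stack([e1, e2, e3]), rel.translation)

    varus, ext_rot = -b, -c
    medial, anterior, distraction = q[0], -q[1], q[2]
    if reference.side == "left":
        varus, medial = -varus, -medial
    return JcsCoordinates(
        flexion=a, varus=varus, ext_rot=ext_rot,
        medial=medial, anterior=anterior, distraction=distraction,
    )


def pose_from_jcs(coords: JcsCoordinates, reference: ReferencePose) -> Pose:
    """Exact inverse of :func:`jcs_from_pose` on its domain."""
    varus, medial = coords.varus, coords.medial
    if reference.side == "left":
        varus, medial = -varus, -medial
    if abs(varus) >= VARUS_SINGULARITY_DEG:
        raise JcsSingularityError(
            f"|varus| = {abs(varus):.2f} deg at/beyond the floating-axis singularity"
        )
    R = _rot_x(coords.flexion) @ _rot_y(-varus) @ _rot_z(-coords.ext_rot)
    e1, e2, e3 = _jcs_axes(R)
    t_rel = medial * e1 + (-coords.anterior) * e2 + coords.distraction * e3
    ref = reference.pose
    return Pose(R @ ref.rotation, t_rel + R @ ref.translation)
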