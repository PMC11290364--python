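"""Six-degree-of-freedom joint traces from per-frame body poses.

Joint angles follow the joint-coordinate-system (Grood & Suntay style)
hierarchy used throughout marker-based jaw-kinematics work: the Z
(lateral) axis is fixed to the proximal body, the X (anterior) axis to
the distal body, and Y floats as the mutual perpendicular.  This is
equivalent to an intrinsic Z-Y'-X'' factorisation of the zero-referenced
relative rotation:

    dR = Rz(pitch) @ Ry(yaw) @ Rx(roll)

Translations are reported as the components of the mobile ACS origin's
displacement from its zero position, expressed in the *fixed* body's ACS
axes (not along the floating axes), so Tx stays strictly anteroposterior.

Polarity (right-handed throughout): positive Rz pitches the jaw toward
occlusion (closing); positive Ry yaws the mandible toward the animal's
left (right side moves anterior); positive Rx rolls the right side
inferior; positive Tx is anterior, Ty superior, Tz toward the animal's
right.  Angles are degrees in (-180, 180], translations mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords import AnatomicalCoordinateSystem, JCSDefinition
from .errors import ComputationError, PoseUndefinedError, ValidationError
from .geometry import PoseTrajectory, RigidTransform

__all__ = [
    "DOF_NAMES",
    "JCSTrace",
    "LocatorTrace",
    "jcs_decompose",
    "jcs_compose",
    "euler_zyx_angles",
    "rotation_zyx",
    "compute_joint_trace",
    "compute_locator_trace",
]

#: Canonical 6-DOF column order used in traces, reports and CSV files.
DOF_NAMES = ("Rx", "Ry", "Rz", "Tx", "Ty", "Tz")

#: |yaw| this close (deg) to 90 deg flags gimbal proximity.
GIMBAL_MARGIN_DEG = 0.5


def rotation_zyx(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    """Rotation matrix Rz(rz) @ Ry(ry) @ Rx(rx), angles in degrees."""
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def euler_zyx_angles(R: np.ndarray) -> tuple[float, float, float, bool]:
    """Intrinsic Z-Y'-X'' angles (degrees) of a rotation matrix.

    Returns ``(rx, ry, rz, gimbal)`` where ``gimbal`` is True when |ry|
    is within :data:`GIMBAL_MARGIN_DEG` of 90 degrees (values are still
    returned; rat-jaw yaw stays far below this).
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValidationError("rotation matrix must be 3x3")
    if not np.all(np.isfinite(R)) or np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
        raise ComputationError("invalid rotation matrix in joint decomposition")
    sy = -R[2, 0]
    ry = np.arcsin(np.clip(sy, -1.0, 1.0))
    gimbal = abs(abs(np.rad2deg(ry)) - 90.0) < GIMBAL_MARGIN_DEG
    if abs(sy) < 1.0 - 1e-12:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:
        # Exact gimbal lock: only rz +/- rx is determined; report rx = 0.
        rx = 0.0
        rz = np.arctan2(-R[0, 1], R[1, 1])
    return float(np.rad2deg(rx)), float(np.rad2deg(ry)), float(np.rad2deg(rz)), bool(gimbal)


def jcs_decompose(
    relative_pose: RigidTransform, zero_pose: RigidTransform
) -> tuple[float, float, float, float, float, float, bool]:
    """Decompose a relative pose into zero-referenced 6-DOF joint values.

    ``relative_pose`` is the mobile ACS expressed in the fixed ACS at one
    instant; ``zero_pose`` the same quantity at the zero (centric
    occlusion) frame.  The zero-referenced rotation ``dR = R @ R0^T``
    acts in the fixed ACS frame and is factorised intrinsically Z-Y'-X'';
    translations are the mobile origin's displacement from its zero
    position along the fixed ACS axes.

    Returns ``(Rx, Ry, Rz, Tx, Ty, Tz, gimbal_flag)`` in degrees and mm.
    """
    dR = relative_pose.rotation @ zero_pose.rotation.T
    rx, ry, rz, gimbal = euler_zyx_angles(dR)
    dt = relative_pose.translation - zero_pose.translation
    return rx, ry, rz, float(dt[0]), float(dt[1]), float(dt[2]), gimbal


def jcs_compose(
    rx: float,
    ry: float,
    rz: float,
    tx: float,
    ty: float,
    tz: float,
    zero_pose: RigidTransform,
) -> RigidTransform:
    """Inverse of :func:`jcs_decompose`: rebuild the relative pose from
    joint values (degrees, mm) and the zero pose."""
    dR = rotation_zyx(rx, ry, rz)
    return RigidTransform(
        dR @ zero_pose.rotation,
        np.asarray([tx, ty, tz], dtype=float) + zero_pose.translation,
    )


@dataclass
class JCSTrace:
    """Per-frame 6-DOF output of one joint coordinate system.

    ``values`` is ``(n_frames, 6)`` in :data:`DOF_NAMES` order (degrees /
    mm); frames where either body pose is missing carry NaN rows and
    ``valid`` False — never zeros.
    """

    joint_name: str
    values: np.ndarray
    valid: np.ndarray
    gimbal: np.ndarray
    zero_frame: int
    frame_rate: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 6:
            raise ValidationError("JCSTrace values must be (n_frames, 6)")
        self.values = v
        self.valid = np.asarray(self.valid, dtype=bool)
        self.gimbal = np.asarray(self.gimbal, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def dof(self, name: str) -> np.ndarray:
        """One component by name ('Rx' ... 'Tz')."""
        return self.values[:, DOF_NAMES.index(name)]


@dataclass
class LocatorTrace:
    """Translation (mm) of a digital locator point relative to a
    reference ACS, zeroed at the zero frame; columns Tx, Ty, Tz."""

    name: str
    values: np.ndarray
    valid: np.ndarray
    zero_frame: int
    frame_rate: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError("LocatorTrace values must be (n_frames, 3)")
        self.values = v
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def dof(self, name: str) -> np.ndarray:
        return self.values[:, ("Tx", "Ty", "Tz").index(name)]


def compute_joint_trace(
    fixed_poses: PoseTrajectory,
    mobile_poses: PoseTrajectory,
    definition: JCSDefinition,
    zero_frame: int,
    frame_rate: float,
) -> JCSTrace:
    """Decompose the zero-referenced relative pose at every frame.

    Frames where either body's pose is missing yield missing (NaN) rows.
    The zero pose is taken from ``definition.zero_pose`` (the relative
    pose at ``zero_frame``); the zero frame itself decomposes to zeros.
    """
    if fixed_poses.n_frames != mobile_poses.n_frames:
        raise ValidationError("fixed and mobile pose sequences must share the frame clock")
    if definition.zero_pose is None:
        raise ComputationError(f"joint {definition.name!r}: no zero pose set")
    n = fixed_poses.n_frames
    values = np.full((n, 6), np.nan)
    valid = np.zeros(n, dtype=bool)
    gimbal = np.zeros(n, dtype=bool)
    for i in range(n):
        if not (fixed_poses.valid[i] and mobile_poses.valid[i]):
            continue
        rel = definition.relative_pose(fixed_poses.transform(i), mobile_poses.transform(i))
        rx, ry, rz, tx, ty, tz, g = jcs_decompose(rel, definition.zero_pose)
        values[i] = (rx, ry, rz, tx, ty, tz)
        valid[i] = True
        gimbal[i] = g
    return JCSTrace(definition.name, values, valid, gimbal, zero_frame, frame_rate)


def compute_locator_trace(
    fixed_poses: PoseTrajectory,
    mobile_poses: PoseTrajectory,
    locator_point,
    reference: AnatomicalCoordinateSystem,
    zero_frame: int,
    frame_rate: float,
    name: str = "locator",
) -> LocatorTrace:
    """Motion of a point on the mobile body, expressed in a fixed-body ACS.

    ``locator_point`` is given in the mobile body's model frame;
    ``reference`` is an ACS attached to the fixed body (e.g. the cranial
    ACS translated to the maxillary occlusal centre).  The per-frame
    locator position in reference axes is reported minus its value at
    ``zero_frame``.
    """
    locator_point = np.asarray(locator_point, dtype=float)
    if not np.all(np.isfinite(locator_point)):
        raise ValidationError("locator point must be finite")
    if fixed_poses.n_frames != mobile_poses.n_frames:
        raise ValidationError("fixed and mobile pose sequences must share the frame clock")
    n = fixed_poses.n_frames
    raw = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        if not (fixed_poses.valid[i] and mobile_poses.valid[i]):
            continue
        world = mobile_poses.transform(i).apply(locator_point)
        ref_world = reference.world_pose(fixed_poses.transform(i))
        raw[i] = ref_world.invert().apply(world)
        valid[i] = True
    if not valid[zero_frame]:
        raise PoseUndefinedError(f"locator {name!r}: no pose at zero frame {zero_frame}")
    values = raw - raw[zero_frame]
    return LocatorTrace(name, values, valid, zero_frame, frame_rate)
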