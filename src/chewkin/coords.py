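"""Anatomical and joint coordinate systems.

The cranial anatomical coordinate system (ACS) is built from the
occlusal plane fitted to the upper tooth-row cusps: X (anterior) is the
projection of the cranial long axis into the plane, Z (right) lies in
the plane orthogonal to X, and Y (superior) completes the right-handed
triad.  Mandibular ACSs are clones of the cranial ACS (identical world
orientation at a reference frame) re-expressed in each hemimandible's
model frame and translated to an anatomical origin (condyle centroid,
symphysis centroid).

A joint coordinate system (JCS) pairs a fixed-body ACS with a
mobile-body ACS plus the relative pose at a chosen zero frame; by
construction the 6-DOF decomposition at the zero frame is identically
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, DegenerateGeometryError, ValidationError
from .geometry import Plane, RigidTransform, fit_plane

__all__ = [
    "AnatomicalCoordinateSystem",
    "JCSDefinition",
    "build_cranial_acs",
    "clone_acs_to_body",
    "find_zero_frame",
    "select_representative_cycle",
]


def _unit(v: np.ndarray, context: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"{context}: degenerate (zero-length) direction")
    return v / n


@dataclass(frozen=True)
class AnatomicalCoordinateSystem:
    """Origin plus right-handed orthonormal triad, fixed to one bone.

    ``axes`` columns are the X (anterior), Y (superior) and Z
    (lateral-right) unit vectors expressed in the bone's model frame;
    ``origin`` is in the same frame (mm).
    """

    body_name: str
    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        if origin.shape != (3,) or axes.shape != (3, 3):
            raise ValidationError("ACS needs a 3-vector origin and a 3x3 axes matrix")
        if np.abs(axes.T @ axes - np.eye(3)).max() > 1e-9:
            raise ValidationError("ACS axes must be orthonormal")
        if np.abs(np.cross(axes[:, 0], axes[:, 1]) - axes[:, 2]).max() > 1e-9:
            raise ValidationError("ACS axes must be right-handed (X x Y = Z)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    def to_model(self) -> RigidTransform:
        """Transform taking ACS coordinates into the bone model frame."""
        return RigidTransform(self.axes, self.origin)

    def world_pose(self, body_pose: RigidTransform) -> RigidTransform:
        """World pose of the ACS given the bone's model-to-world pose."""
        return body_pose.compose(self.to_model())


@dataclass(frozen=True)
class JCSDefinition:
    """A fixed/mobile ACS pair with the relative pose at the zero frame.

    ``zero_pose`` is the pose of the mobile ACS expressed in the fixed
    ACS at the reference (centric-occlusion) frame; decomposing the
    zero-referenced relative pose at that frame yields (0,0,0,0,0,0).
    """

    name: str
    fixed_body: str
    mobile_body: str
    fixed_acs: AnatomicalCoordinateSystem
    mobile_acs: AnatomicalCoordinateSystem
    zero_pose: RigidTransform

    def relative_pose(
        self, fixed_pose: RigidTransform, mobile_pose: RigidTransform
    ) -> RigidTransform:
        """Pose of the mobile ACS in the fixed ACS frame at one instant."""
        wf = self.fixed_acs.world_pose(fixed_pose)
        wm = self.mobile_acs.world_pose(mobile_pose)
        return wf.invert().compose(wm)


def build_cranial_acs(
    cusp_points,
    long_axis_hint,
    right_hint,
    origin,
    body_name: str = "cranium",
) -> tuple[AnatomicalCoordinateSystem, Plane]:
    """Construct the cranial ACS from the occlusal plane.

    A total-least-squares plane is fitted to the upper tooth-row cusp
    points.  X is the unit projection of ``long_axis_hint`` (the cranial
    long axis, anterior positive) into the plane; Z is the in-plane
    direction orthogonal to X with ``dot(Z, right_hint) > 0``; Y = Z x X
    points superior.  ``origin`` is the supplied landmark in the same
    (bone model) frame.

    Returns the ACS together with the fitted plane.
    """
    long_axis_hint = np.asarray(long_axis_hint, dtype=float)
    right_hint = np.asarray(right_hint, dtype=float)
    plane_hint = np.cross(right_hint, long_axis_hint)  # approximately superior
    plane = fit_plane(cusp_points, plane_hint)
    n = plane.normal
    x_in_plane = long_axis_hint - (long_axis_hint @ n) * n
    if np.linalg.norm(x_in_plane) < 1e-9 * max(np.linalg.norm(long_axis_hint), 1.0):
        raise DegenerateGeometryError(
            "cranial long-axis hint is parallel to the occlusal plane normal"
        )
    x = _unit(x_in_plane, "anterior axis")
    z = np.cross(n, x)  # in-plane, orthogonal to X
    d = z @ right_hint
    if abs(d) < 1e-12:
        raise DegenerateGeometryError("right hint cannot orient the lateral axis")
    if d < 0:
        z = -z
    z = _unit(z, "lateral axis")
    y = np.cross(z, x)
    axes = np.column_stack([x, y, z])
    return AnatomicalCoordinateSystem(body_name, np.asarray(origin, float), axes), plane


def clone_acs_to_body(
    source: AnatomicalCoordinateSystem,
    source_pose: RigidTransform,
    target_pose: RigidTransform,
    target_body: str,
    origin,
) -> AnatomicalCoordinateSystem:
    """Attach a copy of ``source`` to another body.

    The clone's world-frame axis orientation at the reference frame
    equals the source ACS's world orientation; its origin is the
    supplied landmark in the target body's model frame.  Poses are the
    model-to-world transforms of both bodies at the reference frame.
    """
    world_axes = source_pose.rotation @ source.axes
    target_axes = target_pose.rotation.T @ world_axes
    return AnatomicalCoordinateSystem(target_body, np.asarray(origin, float), target_axes)


def find_zero_frame(pitch_trace: np.ndarray, cycle: tuple, atol: float = 1e-9) -> int:
    """Frame of peak jaw closure within a designated chew cycle.

    ``pitch_trace`` is the per-frame TMJ pitch (Rz, degrees, closing
    positive); ``cycle`` is a half-open (start, stop) frame interval.
    Returns the frame of maximum Rz (minimum gape); ties — values within
    ``atol`` degrees of the maximum, e.g. across an occlusal plateau —
    break to the earliest frame.  Missing frames are ignored.
    """
    start, stop = int(cycle[0]), int(cycle[1])
    seg = np.asarray(pitch_trace, dtype=float)[start:stop]
    if seg.size == 0 or not np.any(np.isfinite(seg)):
        raise ComputationError(
            f"cannot pick a zero frame: no valid pitch samples in frames [{start}, {stop})"
        )
    peak = np.nanmax(seg)
    with np.errstate(invalid="ignore"):
        tied = np.flatnonzero(seg >= peak - atol)
    return start + int(tied[0])


def select_representative_cycle(pitch_trace: np.ndarray, cycles) -> tuple:
    """Pick the cycle whose pitch amplitude is closest to the median amplitude.

    The zero (centric-occlusion) pose is anchored inside a representative
    chew; "representative" is operationalised as median pitch amplitude.
    Ties break to the earliest cycle.
    """
    cycles = list(cycles)
    if not cycles:
        raise ComputationError("no chew cycles to choose a representative from")
    trace = np.asarray(pitch_trace, dtype=float)
    amps = []
    for start, stop in cycles:
        seg = trace[int(start) : int(stop)]
        if not np.any(np.isfinite(seg)):
            raise ComputationError(f"cycle [{start}, {stop}) has no valid pitch samples")
        amps.append(np.nanmax(seg) - np.nanmin(seg))
    amps = np.asarray(amps)
    med = np.median(amps)
    return tuple(cycles[int(np.argmin(np.abs(amps - med)))])
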