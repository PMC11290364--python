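"""Primitive 3-D geometry for marker-based kinematics.

Rigid transforms, least-squares pose estimation from marker
constellations (orthogonal Procrustes with reflection excluded),
total-least-squares plane fitting, and zero-phase low-pass filtering of
marker trajectories.

Conventions
-----------
* Lengths are millimetres, angles degrees in all external interfaces.
* A missing marker observation is a row of NaN, never zeros.
* Rotations are proper (det = +1) 3x3 matrices; orthonormality is
  validated to 1e-9 on construction of a :class:`RigidTransform`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    PoseUndefinedError,
    ValidationError,
)

__all__ = [
    "RigidTransform",
    "MarkerConstellation",
    "MarkerTrajectoryTable",
    "Plane",
    "PoseEstimate",
    "fit_plane",
    "estimate_pose",
    "estimate_pose_trajectory",
    "lowpass_filter",
    "filter_table",
    "PoseTrajectory",
]

_ORTHONORMALITY_TOL = 1e-9
#: Default minimum smallest singular value (mm) of a centered marker
#: coordinate matrix for the constellation to count as non-collinear.
DEFAULT_COLLINEARITY_THRESHOLD = 0.1


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValidationError(f"expected a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: ``x -> rotation @ x + translation``.

    The currency of all pose math.  Composition and inversion are closed;
    construction rejects reflections and non-orthonormal matrices.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation a 3-vector")
        if not (np.all(np.isfinite(R)) and np.all(np.isfinite(t))):
            raise ValidationError("rigid transform must have finite entries")
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-7:
            raise ValidationError(f"rotation not orthonormal (|R'R - I| = {err:.2e})")
        if err > _ORTHONORMALITY_TOL:
            # Mild numerical drift: re-project onto SO(3) instead of failing.
            U, _, Vt = np.linalg.svd(R)
            R = U @ Vt
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation is a reflection (det = -1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major)."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError("homogeneous matrix must be 4x4")
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        """Return the 4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one point (3,) or many points (n, 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self`` after ``other``: (self o other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Functional alias: ``compose(a, b)(x) = a(b(x))``."""
    return a.compose(b)


def invert(a: RigidTransform) -> RigidTransform:
    return a.invert()


@dataclass(frozen=True)
class MarkerConstellation:
    """Reference marker coordinates of one rigid body in its model frame.

    At least three markers, non-collinear: the smallest singular value of
    the centered coordinate matrix must exceed ``collinearity_threshold``
    (mm).  Marker order is the canonical column order of trajectory
    tables for this body.
    """

    body_name: str
    marker_ids: tuple
    coordinates: np.ndarray  # (n_markers, 3), model frame, mm
    collinearity_threshold: float = DEFAULT_COLLINEARITY_THRESHOLD

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        ids = tuple(str(i) for i in self.marker_ids)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] != len(ids):
            raise ValidationError("coordinates must be (n_markers, 3) matching marker_ids")
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate marker ids for body {self.body_name!r}")
        if len(ids) < 3:
            raise DegenerateGeometryError(
                f"body {self.body_name!r}: need >= 3 markers, got {len(ids)}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError(f"body {self.body_name!r}: non-finite reference coordinates")
        sv = np.linalg.svd(coords - coords.mean(axis=0), compute_uv=False)
        if sv[-2] <= self.collinearity_threshold:
            raise DegenerateGeometryError(
                f"body {self.body_name!r}: markers are collinear "
                f"(second-smallest spread {sv[-2]:.3g} mm <= {self.collinearity_threshold} mm)"
            )
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "marker_ids", ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class MarkerTrajectoryTable:
    """Per-frame observed 3-D marker coordinates for several bodies.

    ``data[body]`` is an ``(n_frames, n_markers, 3)`` array in mm; a
    missing observation is a NaN row.  All bodies share one frame clock.
    """

    frame_rate: float
    data: dict  # body -> (n_frames, n_markers, 3)
    marker_ids: dict  # body -> tuple of ids, order matching axis 1 of data

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        n = {b: a.shape[0] for b, a in self.data.items()}
        if len(set(n.values())) > 1:
            raise ValidationError(f"bodies disagree on frame count: {n}")
        for b, a in self.data.items():
            a = np.asarray(a, dtype=float)
            if a.ndim != 3 or a.shape[2] != 3 or a.shape[1] != len(self.marker_ids[b]):
                raise ValidationError(f"body {b!r}: trajectory array has wrong shape {a.shape}")
            self.data[b] = a

    @property
    def n_frames(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def bodies(self) -> tuple:
        return tuple(self.data)

    def missing_mask(self, body: str) -> np.ndarray:
        """(n_frames, n_markers) boolean mask of missing observations."""
        return np.isnan(self.data[body]).any(axis=2)


@dataclass(frozen=True)
class Plane:
    """A fitted plane: centroid of the fitted points plus a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        o = _as_point(self.origin)
        n = _as_point(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise ValidationError("plane normal must be a unit vector")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n)


def fit_plane(points: Iterable, orientation_hint) -> Plane:
    """Total-least-squares plane through ``points``.

    Minimises perpendicular distances (the normal is the eigenvector of
    the centered covariance with the smallest eigenvalue).  The normal's
    sign is fixed so that ``dot(normal, orientation_hint) > 0``.
    """
    pts = np.asarray([_as_point(p) for p in points], dtype=float)
    hint = _as_point(orientation_hint)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError(f"plane fit needs >= 3 points, got {pts.shape[0]}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # Smallest-eigenvalue direction of the scatter matrix is the normal.
    evals, evecs = np.linalg.eigh(centered.T @ centered)
    if evals[1] <= 1e-12 * max(evals[2], 1.0):
        raise DegenerateGeometryError("plane fit: points are collinear")
    normal = evecs[:, 0]
    d = float(normal @ hint)
    if d == 0.0:
        raise DegenerateGeometryError("orientation hint is perpendicular to the plane normal")
    if d < 0:
        normal = -normal
    return Plane(centroid, normal / np.linalg.norm(normal))


@dataclass(frozen=True)
class PoseEstimate:
    """Result of a single-frame pose fit."""

    transform: RigidTransform
    rms_residual: float  # mm, over the markers used
    n_used: int


def estimate_pose(
    reference: MarkerConstellation,
    observed: np.ndarray,
) -> PoseEstimate:
    """Least-squares rigid transform mapping reference markers onto observations.

    ``observed`` is ``(n_markers, 3)`` aligned with ``reference.marker_ids``;
    missing markers are NaN rows and are excluded, never imputed.  The fit
    is the orthogonal Procrustes solution with reflections excluded: if
    the optimal orthogonal matrix has determinant -1, the singular axis
    with the smallest singular value is flipped.

    Raises
    ------
    PoseUndefinedError
        Fewer than three usable markers in this frame.
    DegenerateGeometryError
        The usable subset is collinear.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (reference.n_markers, 3):
        raise ValidationError(
            f"observed must be ({reference.n_markers}, 3) aligned with the reference"
        )
    usable = ~np.isnan(obs).any(axis=1)
    n_used = int(usable.sum())
    if n_used < 3:
        raise PoseUndefinedError(
            f"body {reference.body_name!r}: only {n_used} usable markers (need >= 3)"
        )
    ref = reference.coordinates[usable]
    obs = obs[usable]
    ref_mean = ref.mean(axis=0)
    obs_mean = obs.mean(axis=0)
    ref_c = ref - ref_mean
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[-2] <= reference.collinearity_threshold:
        raise DegenerateGeometryError(
            f"body {reference.body_name!r}: usable marker subset is collinear"
        )
    obs_c = obs - obs_mean
    H = ref_c.T @ obs_c
    U, _, Vt = np.linalg.svd(H)
    D = np.eye(3)
    if np.linalg.det(Vt.T @ U.T) < 0:
        D[2, 2] = -1.0  # exclude reflections: flip the weakest axis
    R = Vt.T @ D @ U.T
    t = obs_mean - R @ ref_mean
    transform = RigidTransform(R, t)
    resid = ref @ R.T + t - obs
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return PoseEstimate(transform, rms, n_used)


@dataclass
class PoseTrajectory:
    """Per-frame pose estimates of one body; invalid frames are NaN-filled."""

    body_name: str
    rotations: np.ndarray  # (n_frames, 3, 3)
    translations: np.ndarray  # (n_frames, 3)
    valid: np.ndarray  # (n_frames,) bool
    rms_residual: np.ndarray  # (n_frames,) mm, NaN where invalid
    n_used: np.ndarray  # (n_frames,) int, 0 where invalid

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]

    def transform(self, frame: int) -> RigidTransform:
        if not self.valid[frame]:
            raise PoseUndefinedError(f"body {self.body_name!r}: no pose at frame {frame}")
        return RigidTransform(self.rotations[frame], self.translations[frame])


def estimate_pose_trajectory(
    reference: MarkerConstellation, table: MarkerTrajectoryTable
) -> PoseTrajectory:
    """Estimate a pose for every frame; frames with <3 usable markers are flagged
    missing and propagate as missing downstream (no interpolation)."""
    traj = table.data[reference.body_name]
    n = traj.shape[0]
    R = np.full((n, 3, 3), np.nan)
    t = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    rms = np.full(n, np.nan)
    used = np.zeros(n, dtype=int)
    for i in range(n):
        try:
            est = estimate_pose(reference, traj[i])
        except PoseUndefinedError:
            continue
        R[i] = est.transform.rotation
        t[i] = est.transform.translation
        rms[i] = est.rms_residual
        used[i] = est.n_used
        valid[i] = True
    return PoseTrajectory(reference.body_name, R, t, valid, rms, used)


def _contiguous_runs(mask: np.ndarray):
    """Yield (start, stop) slices of True runs in a boolean vector."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    for a, b in zip(idx[::2], idx[1::2]):
        yield int(a), int(b)


def lowpass_filter(
    trace: np.ndarray,
    frame_rate: float,
    cutoff: float,
    order: int = 2,
):
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Missing (NaN) runs are not interpolated across: each contiguous valid
    segment is filtered independently with reflective end padding.
    Segments too short to pad are passed through unfiltered and reported.

    Returns
    -------
    (filtered, passthrough) : (ndarray, list of (start, stop))
        Filtered copy of ``trace`` (NaN where input was NaN) and the
        segments left unfiltered because they were shorter than the
        padding length.
    """
    x = np.asarray(trace, dtype=float).copy()
    if x.ndim != 1:
        raise ValidationError("lowpass_filter expects a 1-D trace")
    if cutoff <= 0 or cutoff >= frame_rate / 2:
        raise ConfigurationError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist = {frame_rate / 2} Hz)"
        )
    b, a = signal.butter(order, cutoff, btype="low", fs=frame_rate)
    padlen = 3 * max(len(a), len(b))
    passthrough = []
    for start, stop in _contiguous_runs(np.isfinite(x)):
        seg = x[start:stop]
        if len(seg) <= padlen:
            passthrough.append((start, stop))
            continue
        x[start:stop] = signal.filtfilt(b, a, seg, padtype="even")
    return x, passthrough


def filter_table(
    table: MarkerTrajectoryTable, cutoff: float, order: int = 2
) -> MarkerTrajectoryTable:
    """Filter every marker coordinate component of a trajectory table.

    Filtering raw marker coordinates (rather than pose parameters) keeps
    downstream rotations exactly orthonormal.  ``cutoff=None`` returns an
    unfiltered copy.
    """
    out = {}
    for body, arr in table.data.items():
        arr = arr.copy()
        if cutoff is not None:
            for m in range(arr.shape[1]):
                for axis in range(3):
                    arr[:, m, axis], _ = lowpass_filter(
                        arr[:, m, axis], table.frame_rate, cutoff, order
                    )
        out[body] = arr
    return MarkerTrajectoryTable(table.frame_rate, out, dict(table.marker_ids))
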