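"""Synthetic proal-chewing generator.

Generates ground-truth rigid-body kinematics for a three-body jaw scene
(cranium, left and right hemimandibles) together with noisy marker
trajectories and zero-relative-motion "cadaver" trials, so that every
pipeline stage is testable without recorded data.

The motion model is a pitch-dominated gape cycle with proal (anterior)
condylar translation concentrated in an occlusal plateau occupying the
middle 40% of the cycle:

* pitch Rz(phi) = -A_pitch * g(phi), where g is a raised-cosine
  open-close profile that is 0 throughout the occlusal plateau and 1 at
  full gape (phi = 0 mod 1);
* condylar Tx(phi) = A_tx * h(phi), a piecewise raised-cosine that rises
  by ``occlusal_tx_fraction`` of its excursion during occlusion,
  continues anteriorly during opening, and returns posteriorly during
  closing (rats translate the condyle anteriorly during both occlusion
  and opening);
* every other degree of freedom is a low-amplitude sinusoid at the
  cycle rate with a fixed per-DOF phase.

The left hemimandible is driven by the TMJ joint waveform about the
left condyle centroid; the right hemimandible is the left composed with
the symphyseal joint waveform about the symphysis centroid, so the left
TMJ and symphyseal traces equal the injected waveforms exactly and the
right TMJ trace follows by composition.  Optional slow whole-scene head
motion is superimposed; joint traces are invariant to it by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .geometry import (
    MarkerConstellation,
    MarkerTrajectoryTable,
    PoseTrajectory,
    RigidTransform,
)
from .kinematics import jcs_compose
from . import reference_data

__all__ = [
    "ChewModelParams",
    "SyntheticScene",
    "SimulatedTrial",
    "build_scene",
    "generate_kinematics",
    "render_markers",
    "generate_cadaver_trial",
    "simulate_individual",
    "simulate_cadaver",
    "default_study_params",
    "mirror_trial",
    "BODY_CRANIUM",
    "BODY_LEFT",
    "BODY_RIGHT",
]

BODY_CRANIUM = "cranium"
BODY_LEFT = "left_hemimandible"
BODY_RIGHT = "right_hemimandible"

#: Fixed per-DOF phase offsets (cycle fractions) of the sinusoidal DOFs.
_TMJ_PHASES = {"Rx": 0.12, "Ry": 0.40, "Ty": 0.65, "Tz": 0.88}
_SYM_PHASES = {"Rx": 0.20, "Ry": 0.45, "Rz": 0.70, "Tx": 0.05, "Ty": 0.30, "Tz": 0.55}


@dataclass(frozen=True)
class ChewModelParams:
    """Study conditions for one simulated individual.

    Amplitudes are absolute amplitudes (max - min over a cycle) in
    degrees / millimetres, matching how the analysis reports them.
    Defaults reproduce a "rat A"-like scenario drawn from the in vivo
    reference summary (:mod:`chewkin.reference_data`).
    """

    n_cycles: int = 13
    cycle_rate: float = 5.0  # Hz; chewing frequency
    frame_rate: float = 250.0  # Hz; X-ray video rate
    pitch_amplitude: float = 18.10  # deg, condylar Rz
    roll_amplitude: float = 0.80  # deg, condylar Rx
    yaw_amplitude: float = 2.86  # deg, condylar Ry
    condylar_tx_amplitude: float = 2.13  # mm
    condylar_ty_amplitude: float = 1.40  # mm
    condylar_tz_amplitude: float = 0.19  # mm
    #: Fraction of the condylar Tx excursion inside the occlusal window.
    occlusal_tx_fraction: float = 0.55
    symphyseal_rx_amplitude: float = 1.10  # deg
    symphyseal_ry_amplitude: float = 1.13  # deg
    symphyseal_rz_amplitude: float = 1.55  # deg
    symphyseal_tx_amplitude: float = 0.18  # mm
    symphyseal_ty_amplitude: float = 0.62  # mm
    symphyseal_tz_amplitude: float = 0.41  # mm
    occlusal_fraction: float = 0.40  # of the cycle, centred at mid-cycle
    #: Shallow extra closure at mid-occlusion (deg).  Makes peak closure
    #: unique at the cycle midpoint (centric occlusion) instead of a
    #: perfectly flat plateau; capped at 20% of the pitch amplitude.
    occlusal_dome_deg: float = 1.0
    head_rotation_amplitude: float = 8.0  # deg, whole-scene waving
    head_translation_amplitude: float = 15.0  # mm
    head_motion_rate: float = 0.6  # Hz
    marker_noise_sigma: float = 0.05  # mm, isotropic per coordinate
    missing_rate: float = 0.0  # probability per marker-frame
    constellation_spread_mm: float = 3.5  # RMS marker distance from centroid
    right_markers: int = 4  # 3 replicates the minimal-marker individual
    #: Lead-in/out beyond the first/last gape maximum, in cycle fractions.
    pad_fraction: float = 0.25
    cadaver_duration_s: float = 2.0
    seed: int = 0

    def __post_init__(self):
        amps = [
            self.pitch_amplitude, self.roll_amplitude, self.yaw_amplitude,
            self.condylar_tx_amplitude, self.condylar_ty_amplitude,
            self.condylar_tz_amplitude, self.symphyseal_rx_amplitude,
            self.symphyseal_ry_amplitude, self.symphyseal_rz_amplitude,
            self.symphyseal_tx_amplitude, self.symphyseal_ty_amplitude,
            self.symphyseal_tz_amplitude, self.head_rotation_amplitude,
            self.head_translation_amplitude, self.marker_noise_sigma,
        ]
        if any(a < 0 for a in amps):
            raise ValidationError("amplitudes and noise sigma must be >= 0")
        if not 0.0 < self.occlusal_fraction < 1.0:
            raise ValidationError("occlusal_fraction must lie in (0, 1)")
        if not 0.0 < self.occlusal_tx_fraction <= 1.0:
            raise ValidationError("occlusal_tx_fraction must lie in (0, 1]")
        if self.cycle_rate >= self.frame_rate / 4:
            raise ValidationError("cycle_rate must be below frame_rate / 4")
        if self.right_markers not in (3, 4):
            raise ValidationError("right_markers must be 3 or 4")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")

    @classmethod
    def for_individual(cls, individual: str, **overrides) -> "ChewModelParams":
        """Parameters for one of the reference individuals (rat_A/B/C).

        Amplitudes and cycle counts come from the in vivo reference
        summary; the minimal-marker individual (rat_B) gets a 3-marker
        right hemimandible.
        """
        a = reference_data.IN_VIVO_AMPLITUDES[individual]
        kw = dict(
            n_cycles=reference_data.IN_VIVO_CYCLE_COUNTS[individual],
            pitch_amplitude=a["condylar_Rz"],
            roll_amplitude=a["condylar_Rx"],
            yaw_amplitude=a["condylar_Ry"],
            condylar_tx_amplitude=a["condylar_Tx"],
            condylar_ty_amplitude=a["condylar_Ty"],
            condylar_tz_amplitude=a["condylar_Tz"],
            symphyseal_rx_amplitude=a["symphyseal_Rx"],
            symphyseal_ry_amplitude=a["symphyseal_Ry"],
            symphyseal_rz_amplitude=a["symphyseal_Rz"],
            symphyseal_tx_amplitude=a["symphyseal_Tx"],
            symphyseal_ty_amplitude=a["symphyseal_Ty"],
            symphyseal_tz_amplitude=a["symphyseal_Tz"],
            right_markers=3 if individual == "rat_B" else 4,
        )
        kw.update(overrides)
        return cls(**kw)


def default_study_params(seed: int = 0) -> dict:
    """The default three-individual synthetic study (13/7/18 cycles)."""
    return {
        ind: ChewModelParams.for_individual(ind, seed=int(seed) * 10 + k)
        for k, ind in enumerate(("rat_A", "rat_B", "rat_C"))
    }


@dataclass
class SyntheticScene:
    """Deterministic scene geometry: model-frame poses at the zero
    (centric occlusion) posture, landmarks and marker constellations."""

    params: ChewModelParams
    model_poses0: dict  # body -> RigidTransform (model -> world at zero)
    landmarks: dict  # body -> {name: (3,) model-frame point}
    constellations: dict  # body -> MarkerConstellation

    def world_landmark(self, body: str, name: str) -> np.ndarray:
        """Landmark position in world coordinates at the zero posture."""
        return self.model_poses0[body].apply(self.landmarks[body][name])


def _rotation_about(axis, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


# Base marker offsets (well-spread tetrahedron), re-centred and scaled to
# the requested RMS spread at build time.
_BASE_OFFSETS = np.array(
    [
        [1.2, 0.5, 0.8],
        [-1.1, 0.9, -0.7],
        [0.4, -1.2, 1.0],
        [-0.5, -0.6, -1.1],
    ]
)


def _constellation_offsets(n_markers: int, spread: float, rng) -> np.ndarray:
    base = _BASE_OFFSETS[:n_markers].copy()
    base += rng.normal(0.0, 0.05, size=base.shape)  # seeded shape jitter
    base -= base.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum(base**2, axis=1)))
    return base * (spread / rms)


def build_scene(params: ChewModelParams) -> SyntheticScene:
    """Deterministic (seeded) scene construction.

    World coordinates at the zero posture use the anatomical convention
    directly: occlusal plane y = 0, X anterior, Y superior, Z right.
    Model frames of all three bodies are offset by fixed non-trivial
    rigid transforms so that ACS construction and cloning are exercised.
    Cusp points lie exactly on the occlusal plane (in-plane jitter only).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0]))

    # --- world-frame landmarks at the zero posture (mm) ---
    cusp_world = []
    for x in (13.0, 15.0, 17.0, 19.0, 21.0):
        for z in (-4.0, 4.0):
            jx, jz = rng.uniform(-0.4, 0.4, size=2)
            cusp_world.append(np.array([x + jx, 0.0, z + jz]))  # y = 0 exactly
    world = {
        BODY_CRANIUM: {
            **{f"cusp_{i + 1}": p for i, p in enumerate(cusp_world)},
            "cranial_axis_anterior": np.array([25.0, 2.0, 0.0]),
            "cranial_axis_posterior": np.array([-15.0, 4.0, 0.0]),
            "maxillary_occlusal_center": np.array([17.0, 0.0, 0.0]),
        },
        BODY_LEFT: {
            "condyle_centroid_left": np.array([0.0, 5.0, -6.0]),
            "molar2_locator": np.array([17.0, 0.0, -4.0]),
            "symphysis_centroid": np.array([26.0, -4.0, 0.0]),
        },
        BODY_RIGHT: {
            "condyle_centroid_right": np.array([0.0, 5.0, 6.0]),
            "symphysis_centroid": np.array([26.0, -4.0, 0.0]),
        },
    }

    # --- model-frame poses at zero (fixed, non-trivial) ---
    model_poses0 = {
        BODY_CRANIUM: RigidTransform(
            _rotation_about((0.3, 1.0, 0.2), 20.0), np.array([4.0, -3.0, 7.0])
        ),
        BODY_LEFT: RigidTransform(
            _rotation_about((1.0, 0.4, -0.3), -14.0), np.array([-6.0, 2.0, 3.0])
        ),
        BODY_RIGHT: RigidTransform(
            _rotation_about((-0.2, 0.8, 1.0), 17.0), np.array([5.0, 6.0, -2.0])
        ),
    }

    landmarks = {
        body: {
            name: model_poses0[body].invert().apply(p) for name, p in pts.items()
        }
        for body, pts in world.items()
    }

    # --- marker constellations ---
    centers = {
        BODY_CRANIUM: np.array([2.0, 10.0, 0.0]),
        BODY_LEFT: np.array([12.0, -7.0, -5.0]),
        BODY_RIGHT: np.array([12.0, -7.0, 5.0]),
    }
    n_markers = {
        BODY_CRANIUM: 4,
        BODY_LEFT: 4,
        BODY_RIGHT: int(params.right_markers),
    }
    constellations = {}
    for body in (BODY_CRANIUM, BODY_LEFT, BODY_RIGHT):
        offsets = _constellation_offsets(
            n_markers[body], params.constellation_spread_mm, rng
        )
        world_markers = centers[body] + offsets
        model_markers = model_poses0[body].invert().apply(world_markers)
        constellations[body] = MarkerConstellation(
            body,
            tuple(f"m{i + 1}" for i in range(n_markers[body])),
            model_markers,
        )
    return SyntheticScene(params, model_poses0, landmarks, constellations)


# ---------------------------------------------------------------------------
# Injected waveforms
# ---------------------------------------------------------------------------

def gape_profile(phi: np.ndarray, occlusal_fraction: float) -> np.ndarray:
    """Open-close profile g: 1 at full gape (phi = 0 mod 1), 0 across the
    occlusal plateau centred at mid-cycle; raised-cosine flanks (C1)."""
    p = np.mod(phi, 1.0)
    w0 = 0.5 - occlusal_fraction / 2.0
    w1 = 0.5 + occlusal_fraction / 2.0
    g = np.zeros_like(p)
    closing = p < w0
    g[closing] = 0.5 * (1.0 + np.cos(np.pi * p[closing] / w0))
    opening = p >= w1
    g[opening] = 0.5 * (1.0 - np.cos(np.pi * (p[opening] - w1) / (1.0 - w1)))
    return g


def pitch_waveform(
    phi: np.ndarray,
    occlusal_fraction: float,
    amplitude: float,
    dome_deg: float,
) -> np.ndarray:
    """Condylar pitch Rz (deg): 0 at centric occlusion (mid-cycle),
    ``-amplitude`` at full gape.

    During occlusion the jaw dips ``dome`` below centric and returns —
    a shallow raised-cosine dome that makes peak closure unique at the
    cycle midpoint — so the zero-frame rule (maximum Rz) lands exactly
    on the zero posture.  The absolute amplitude (max - min) is exactly
    ``amplitude``.
    """
    p = np.mod(phi, 1.0)
    w0 = 0.5 - occlusal_fraction / 2.0
    w1 = 0.5 + occlusal_fraction / 2.0
    dome = min(dome_deg, 0.2 * amplitude)
    g = gape_profile(phi, occlusal_fraction)
    out = -amplitude + (amplitude - dome) * (1.0 - g)
    occl = (p >= w0) & (p < w1)
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * (p[occl] - w0) / (w1 - w0)))
    out[occl] = -dome + dome * bump
    return out


def proal_tx_profile(
    phi: np.ndarray, occlusal_fraction: float, occlusal_tx_fraction: float
) -> np.ndarray:
    """Condylar anteroposterior profile h in [0, 1].

    Posterior return during closing (1 -> 0), anterior rise of
    ``occlusal_tx_fraction`` during occlusion (0 -> f), anterior
    continuation during opening (f -> 1); raised-cosine pieces with zero
    slope at every joint, so piece extrema sit exactly at the joins.
    """
    p = np.mod(phi, 1.0)
    w0 = 0.5 - occlusal_fraction / 2.0
    w1 = 0.5 + occlusal_fraction / 2.0
    f = occlusal_tx_fraction
    h = np.zeros_like(p)
    closing = p < w0
    h[closing] = 0.5 * (1.0 + np.cos(np.pi * p[closing] / w0))
    occl = (p >= w0) & (p < w1)
    h[occl] = f * 0.5 * (1.0 - np.cos(np.pi * (p[occl] - w0) / (w1 - w0)))
    opening = p >= w1
    h[opening] = f + (1.0 - f) * 0.5 * (
        1.0 - np.cos(np.pi * (p[opening] - w1) / (1.0 - w1))
    )
    return h


def _sinusoid(phi: np.ndarray, amplitude: float, phase: float) -> np.ndarray:
    """Cycle-rate sinusoid with absolute amplitude ``amplitude`` that is
    exactly zero at centric occlusion (phi = 0.5 mod 1).

    Vanishing at mid-cycle (where pitch is also at its unique maximum)
    puts the scene exactly in its zero posture at the frame the analysis
    anchors the joint coordinate systems to; a nonzero posture there
    would mix components between degrees of freedom when axes are cloned
    and traces are zero-referenced."""
    psi = 2.0 * np.pi * phase
    return 0.5 * amplitude * (
        np.sin(2.0 * np.pi * (phi - 0.5) + psi) - np.sin(psi)
    )


def injected_joint_values(params: ChewModelParams, phi: np.ndarray) -> dict:
    """Injected 6-DOF waveforms (deg / mm) in DOF order Rx..Tz.

    ``tmj_left`` holds the condylar waveform (pitch reaches its unique
    maximum 0 at centric occlusion, mid-cycle, and -amplitude at full
    gape); ``symphysis`` the right-relative-to-left waveform.  Every
    rotational and sinusoidal DOF is exactly zero at centric occlusion,
    which is the zero posture.
    """
    h = proal_tx_profile(phi, params.occlusal_fraction, params.occlusal_tx_fraction)
    tmj = np.column_stack(
        [
            _sinusoid(phi, params.roll_amplitude, _TMJ_PHASES["Rx"]),
            _sinusoid(phi, params.yaw_amplitude, _TMJ_PHASES["Ry"]),
            pitch_waveform(
                phi, params.occlusal_fraction, params.pitch_amplitude,
                params.occlusal_dome_deg,
            ),
            params.condylar_tx_amplitude * h,
            _sinusoid(phi, params.condylar_ty_amplitude, _TMJ_PHASES["Ty"]),
            _sinusoid(phi, params.condylar_tz_amplitude, _TMJ_PHASES["Tz"]),
        ]
    )
    sym = np.column_stack(
        [
            _sinusoid(phi, params.symphyseal_rx_amplitude, _SYM_PHASES["Rx"]),
            _sinusoid(phi, params.symphyseal_ry_amplitude, _SYM_PHASES["Ry"]),
            _sinusoid(phi, params.symphyseal_rz_amplitude, _SYM_PHASES["Rz"]),
            _sinusoid(phi, params.symphyseal_tx_amplitude, _SYM_PHASES["Tx"]),
            _sinusoid(phi, params.symphyseal_ty_amplitude, _SYM_PHASES["Ty"]),
            _sinusoid(phi, params.symphyseal_tz_amplitude, _SYM_PHASES["Tz"]),
        ]
    )
    return {"tmj_left": tmj, "symphysis": sym}


def _head_motion(params: ChewModelParams, times: np.ndarray, center: np.ndarray):
    """Slow whole-scene rigid waving about the scene centre."""
    out = []
    axis = np.array([0.3, 1.0, 0.5])
    axis /= np.linalg.norm(axis)
    w = 2.0 * np.pi * params.head_motion_rate
    for t in times:
        ang = params.head_rotation_amplitude * np.sin(w * t)
        R = _rotation_about(axis, ang)
        trans = 0.5 * params.head_translation_amplitude * np.array(
            [np.sin(w * t), np.sin(w * t + 2.1), np.cos(0.8 * w * t)]
        )
        # rotate about the scene centre, then translate
        out.append(RigidTransform(R, center - R @ center + trans))
    return out


def _exact_pose_trajectory(body: str, transforms, n_markers: int) -> PoseTrajectory:
    n = len(transforms)
    R = np.stack([T.rotation for T in transforms])
    t = np.stack([T.translation for T in transforms])
    return PoseTrajectory(
        body, R, t, np.ones(n, bool), np.zeros(n), np.full(n, n_markers, int)
    )


def generate_kinematics(
    params: ChewModelParams, scene: SyntheticScene, head_motion: bool = True
):
    """Ground-truth per-frame poses and injected joint values.

    Returns ``(poses, injected, phases)`` where ``poses`` maps body name
    to an exact :class:`PoseTrajectory`, ``injected`` holds the
    ``tmj_left`` and ``symphysis`` waveforms (n_frames, 6), and
    ``phases`` gives each frame's cycle phase (gape maxima at integers).
    """
    fpc = params.frame_rate / params.cycle_rate  # frames per cycle
    # Snap the lead-in so centric occlusion (phi = 0.5: the zero posture
    # and the frame the zero-frame rule selects) falls exactly on the
    # frame grid.
    pad = np.ceil((params.pad_fraction + 0.5) * fpc) / fpc - 0.5
    n_frames = int(round((params.n_cycles + 2 * pad) * fpc)) + 1
    times = np.arange(n_frames) / params.frame_rate
    phi = times * params.cycle_rate - pad
    injected = injected_joint_values(params, phi)

    o_cl = scene.world_landmark(BODY_LEFT, "condyle_centroid_left")
    o_sym = scene.world_landmark(BODY_LEFT, "symphysis_centroid")
    W_tmj = RigidTransform(np.eye(3), o_cl)
    W_sym = RigidTransform(np.eye(3), o_sym)
    T_c0 = scene.model_poses0[BODY_CRANIUM]
    T_l0 = scene.model_poses0[BODY_LEFT]
    T_r0 = scene.model_poses0[BODY_RIGHT]
    identity = RigidTransform.identity()

    left, right, cran = [], [], []
    for i in range(n_frames):
        P_tmj = jcs_compose(*injected["tmj_left"][i], zero_pose=identity)
        P_sym = jcs_compose(*injected["symphysis"][i], zero_pose=identity)
        T_l = W_tmj @ P_tmj @ W_tmj.invert() @ T_l0
        T_r = T_l @ T_l0.invert() @ W_sym @ P_sym @ W_sym.invert() @ T_r0
        left.append(T_l)
        right.append(T_r)
        cran.append(T_c0)

    if head_motion and (
        params.head_rotation_amplitude > 0 or params.head_translation_amplitude > 0
    ):
        center = np.array([10.0, 0.0, 0.0])
        H = _head_motion(params, times, center)
        left = [h @ T for h, T in zip(H, left)]
        right = [h @ T for h, T in zip(H, right)]
        cran = [h @ T for h, T in zip(H, cran)]

    nm = {b: scene.constellations[b].n_markers for b in scene.constellations}
    poses = {
        BODY_CRANIUM: _exact_pose_trajectory(BODY_CRANIUM, cran, nm[BODY_CRANIUM]),
        BODY_LEFT: _exact_pose_trajectory(BODY_LEFT, left, nm[BODY_LEFT]),
        BODY_RIGHT: _exact_pose_trajectory(BODY_RIGHT, right, nm[BODY_RIGHT]),
    }
    return poses, injected, phi


def render_markers(
    scene: SyntheticScene,
    poses: dict,
    params: ChewModelParams,
    seed_stream: int = 1,
) -> MarkerTrajectoryTable:
    """Map reference markers through the per-frame poses and add noise.

    I.i.d. isotropic Gaussian noise of ``marker_noise_sigma`` mm is added
    per coordinate; markers are dropped to missing (NaN rows) with
    ``missing_rate`` per marker-frame.  Fully deterministic for a given
    params seed.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), int(seed_stream)])
    )
    data, ids = {}, {}
    for body, constellation in scene.constellations.items():
        traj = poses[body]
        world = (
            np.einsum("nij,mj->nmi", traj.rotations, constellation.coordinates)
            + traj.translations[:, None, :]
        )
        if params.marker_noise_sigma > 0:
            world = world + rng.normal(0.0, params.marker_noise_sigma, world.shape)
        if params.missing_rate > 0:
            drop = rng.random(world.shape[:2]) < params.missing_rate
            world[drop] = np.nan
        data[body] = world
        ids[body] = constellation.marker_ids
    return MarkerTrajectoryTable(params.frame_rate, data, ids)


@dataclass
class SimulatedTrial:
    """A self-contained synthetic trial: geometry, ground truth, markers."""

    params: ChewModelParams
    scene: SyntheticScene
    poses: dict  # body -> ground-truth PoseTrajectory
    injected: dict  # "tmj_left"/"symphysis" -> (n_frames, 6); zeros for cadaver
    phases: np.ndarray
    markers: MarkerTrajectoryTable
    kind: str = "chew"  # "chew" | "cadaver"


def simulate_individual(
    params: ChewModelParams, head_motion: bool = True
) -> SimulatedTrial:
    """Build scene, generate kinematics, render markers for one individual."""
    scene = build_scene(params)
    poses, injected, phi = generate_kinematics(params, scene, head_motion=head_motion)
    markers = render_markers(scene, poses, params, seed_stream=1)
    return SimulatedTrial(params, scene, poses, injected, phi, markers, "chew")


def generate_cadaver_trial(params: ChewModelParams) -> SimulatedTrial:
    """Zero-relative-motion trial: one rigid whole-scene waving motion.

    All bodies share the waving transform, so every joint trace is
    identically zero up to marker noise — the basis of workflow-precision
    estimation.
    """
    scene = build_scene(params)
    n_frames = int(round(params.cadaver_duration_s * params.frame_rate)) + 1
    times = np.arange(n_frames) / params.frame_rate
    H = _head_motion(params, times, center=np.array([10.0, 0.0, 0.0]))
    nm = {b: scene.constellations[b].n_markers for b in scene.constellations}
    poses = {
        body: _exact_pose_trajectory(
            body, [h @ scene.model_poses0[body] for h in H], nm[body]
        )
        for body in scene.constellations
    }
    injected = {
        "tmj_left": np.zeros((n_frames, 6)),
        "symphysis": np.zeros((n_frames, 6)),
    }
    markers = render_markers(scene, poses, params, seed_stream=2)
    return SimulatedTrial(
        params, scene, poses, injected, times * 0.0, markers, "cadaver"
    )


#: Alias matching the generator verb used elsewhere.
simulate_cadaver = generate_cadaver_trial

_MIRROR = np.diag([1.0, 1.0, -1.0])

_LANDMARK_SWAP = {
    "condyle_centroid_left": "condyle_centroid_right",
    "condyle_centroid_right": "condyle_centroid_left",
}


def _mirror_transform(T: RigidTransform) -> RigidTransform:
    return RigidTransform(_MIRROR @ T.rotation @ _MIRROR, _MIRROR @ T.translation)


def mirror_trial(trial: SimulatedTrial) -> SimulatedTrial:
    """Reflect a simulated trial left<->right across the midsagittal plane.

    World and model-frame coordinates are mirrored (z -> -z) and the two
    hemimandibles swap roles, producing a physically valid scene whose
    analysed traces must swap left/right TMJ and flip the signs of Rx,
    Ry and Tz while preserving Rz, Tx and Ty.
    """
    body_swap = {
        BODY_CRANIUM: BODY_CRANIUM,
        BODY_LEFT: BODY_RIGHT,
        BODY_RIGHT: BODY_LEFT,
    }
    scene = trial.scene
    new_model_poses = {
        body_swap[b]: _mirror_transform(T) for b, T in scene.model_poses0.items()
    }
    new_landmarks = {}
    for b, pts in scene.landmarks.items():
        new_landmarks[body_swap[b]] = {
            _LANDMARK_SWAP.get(name, name): _MIRROR @ p for name, p in pts.items()
        }
    new_constellations = {
        body_swap[b]: MarkerConstellation(
            body_swap[b], c.marker_ids, c.coordinates @ _MIRROR
        )
        for b, c in scene.constellations.items()
    }
    new_scene = SyntheticScene(
        scene.params, new_model_poses, new_landmarks, new_constellations
    )
    new_poses = {
        body_swap[b]: PoseTrajectory(
            body_swap[b],
            np.einsum("ij,njk,kl->nil", _MIRROR, p.rotations, _MIRROR),
            p.translations @ _MIRROR,
            p.valid.copy(),
            p.rms_residual.copy(),
            p.n_used.copy(),
        )
        for b, p in trial.poses.items()
    }
    new_markers = MarkerTrajectoryTable(
        trial.markers.frame_rate,
        {body_swap[b]: a @ _MIRROR for b, a in trial.markers.data.items()},
        {body_swap[b]: ids for b, ids in trial.markers.marker_ids.items()},
    )
    return SimulatedTrial(
        trial.params,
        new_scene,
        new_poses,
        dict(trial.injected),
        trial.phases.copy(),
        new_markers,
        trial.kind,
    )
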