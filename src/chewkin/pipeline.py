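"""End-to-end analysis: markers -> poses -> joint traces -> cycle report.

The stages mirror the standard marker-based workflow: low-pass filter
raw marker coordinates, estimate per-frame rigid-body poses, construct
the cranial ACS from the occlusal plane, segment chew cycles from the
provisional pitch trace, anchor the joint coordinate systems at a
centric-occlusion zero frame inside a representative chew, decompose
per-frame 6-DOF traces for both TMJs and the symphysis plus the lower
molar locator, and summarise per-cycle amplitudes with between-cycle
confidence intervals.  Zero-motion (cadaver) trials run through the
same trace machinery to yield workflow-precision CIs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import reference_data
from .coords import (
    AnatomicalCoordinateSystem,
    JCSDefinition,
    build_cranial_acs,
    clone_acs_to_body,
    find_zero_frame,
    select_representative_cycle,
)
from .cycles import (
    DEFAULT_OCCLUSAL_WINDOW,
    AmplitudeSummary,
    PrecisionReport,
    aggregate_across_individuals,
    build_cycles,
    occlusal_metrics,
    segment_cycles,
    summarize_amplitudes,
    workflow_precision,
)
from .errors import ComputationError, ConfigurationError, ValidationError
from .geometry import (
    MarkerTrajectoryTable,
    PoseTrajectory,
    estimate_pose_trajectory,
    filter_table,
)
from .kinematics import (
    DOF_NAMES,
    JCSTrace,
    LocatorTrace,
    compute_joint_trace,
    compute_locator_trace,
)

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "analyze_markers",
    "analyze_poses",
    "precision_traces",
    "precision_report_from_trials",
    "assemble_report",
    "study_report_from_entries",
    "result_entry",
    "VERSION_TAG",
]

log = logging.getLogger(__name__)

VERSION_TAG = "chewkin-0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration; every output embeds the exact values used."""

    filter_cutoff_hz: float | None = 20.0  # None disables filtering
    filter_order: int = 2
    min_cycle_amplitude_deg: float = 5.0
    max_cycle_amplitude_deg: float = 25.0
    min_prominence_deg: float = 2.0
    occlusal_window: tuple = DEFAULT_OCCLUSAL_WINDOW
    ci_mode: str = "pointwise"  # or "amplitude"
    confidence: float = 0.95
    zero_frame: int | None = None  # explicit override of the zero frame
    max_missing_fraction: float = 0.10
    condylar_side: str = "left"  # which TMJ feeds the condylar report columns
    seed: int = 0
    version: str = VERSION_TAG

    def __post_init__(self):
        if self.ci_mode not in ("pointwise", "amplitude"):
            raise ConfigurationError(f"unknown ci_mode {self.ci_mode!r}")
        if self.condylar_side not in ("left", "right"):
            raise ConfigurationError("condylar_side must be 'left' or 'right'")
        object.__setattr__(self, "occlusal_window", tuple(self.occlusal_window))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["occlusal_window"] = list(self.occlusal_window)
        return d


# ---------------------------------------------------------------------------
# Coordinate-system construction
# ---------------------------------------------------------------------------

_CUSP_RE = re.compile(r"^cusp_(\d+)$")


def _cranium_body(landmarks: dict) -> str:
    for body, pts in landmarks.items():
        if any(_CUSP_RE.match(name) for name in pts):
            return body
    raise ValidationError("no body carries cusp_* landmarks (cranium not identifiable)")


def _body_with(landmarks: dict, name: str, exclude=()) -> str:
    for body, pts in landmarks.items():
        if name in pts and body not in exclude:
            return body
    raise ValidationError(f"landmark {name!r} not found on any body")


def _first_common_valid_frame(poses: dict) -> int:
    valid = np.logical_and.reduce([p.valid for p in poses.values()])
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        raise ComputationError("no frame has valid poses for all bodies")
    return int(idx[0])


def _build_cranial_acs(landmarks: dict, poses: dict, frame: int):
    """Cranial ACS from cusp plane + long-axis landmarks; the lateral
    polarity hint comes from the two condyle centroids at ``frame``."""
    cran = _cranium_body(landmarks)
    pts = landmarks[cran]
    cusps = [
        pts[name]
        for name in sorted(pts, key=lambda n: int(_CUSP_RE.match(n).group(1))
                           if _CUSP_RE.match(n) else -1)
        if _CUSP_RE.match(name)
    ]
    if len(cusps) < 3:
        raise ValidationError("need at least 3 cusp_* landmarks for the occlusal plane")
    for req in ("cranial_axis_anterior", "cranial_axis_posterior",
                "maxillary_occlusal_center"):
        if req not in pts:
            raise ValidationError(f"missing cranial landmark {req!r}")
    long_axis = pts["cranial_axis_anterior"] - pts["cranial_axis_posterior"]

    body_l = _body_with(landmarks, "condyle_centroid_left")
    body_r = _body_with(landmarks, "condyle_centroid_right")
    T_c = poses[cran].transform(frame)
    p_l = T_c.invert().apply(
        poses[body_l].transform(frame).apply(landmarks[body_l]["condyle_centroid_left"])
    )
    p_r = T_c.invert().apply(
        poses[body_r].transform(frame).apply(landmarks[body_r]["condyle_centroid_right"])
    )
    right_hint = p_r - p_l
    acs, plane = build_cranial_acs(
        cusps, long_axis, right_hint, pts["maxillary_occlusal_center"], body_name=cran
    )
    return acs, plane


def _tmj_definition(
    side: str,
    cranial_acs: AnatomicalCoordinateSystem,
    landmarks: dict,
    poses: dict,
    frame: int,
) -> JCSDefinition:
    """TMJ JCS at the condyle centroid: cranial ACS fixed, mandibular ACS
    (cloned alignment) mobile, both origins at the condyle at ``frame``."""
    cran = cranial_acs.body_name
    lm = f"condyle_centroid_{side}"
    body = _body_with(landmarks, lm, exclude=(cran,))
    T_c = poses[cran].transform(frame)
    T_m = poses[body].transform(frame)
    condyle_world = T_m.apply(landmarks[body][lm])
    fixed = AnatomicalCoordinateSystem(
        cran, T_c.invert().apply(condyle_world), cranial_acs.axes
    )
    mobile = clone_acs_to_body(cranial_acs, T_c, T_m, body, landmarks[body][lm])
    definition = JCSDefinition(f"tmj_{side}", cran, body, fixed, mobile,
                               zero_pose=None)  # placeholder, set below
    zero = definition.relative_pose(T_c, T_m)
    return replace_definition(definition, zero)


def replace_definition(d: JCSDefinition, zero) -> JCSDefinition:
    return JCSDefinition(d.name, d.fixed_body, d.mobile_body, d.fixed_acs,
                         d.mobile_acs, zero)


def _symphysis_definition(
    cranial_acs: AnatomicalCoordinateSystem,
    landmarks: dict,
    poses: dict,
    frame: int,
) -> JCSDefinition:
    """Symphyseal JCS: left hemimandible fixed, right mobile, cusp-plane-
    aligned axes, origins at the symphysis centroid (this choice only
    affects the polarity of the values, not their magnitude)."""
    cran = cranial_acs.body_name
    body_l = _body_with(landmarks, "condyle_centroid_left", exclude=(cran,))
    body_r = _body_with(landmarks, "condyle_centroid_right", exclude=(cran,))
    T_c = poses[cran].transform(frame)
    T_l = poses[body_l].transform(frame)
    T_r = poses[body_r].transform(frame)
    if "symphysis_centroid" in landmarks[body_l]:
        o_l = landmarks[body_l]["symphysis_centroid"]
    else:
        raise ValidationError(f"missing symphysis_centroid landmark on {body_l!r}")
    o_world = T_l.apply(o_l)
    o_r = landmarks[body_r].get("symphysis_centroid", T_r.invert().apply(o_world))
    fixed = clone_acs_to_body(cranial_acs, T_c, T_l, body_l, o_l)
    mobile = clone_acs_to_body(cranial_acs, T_c, T_r, body_r, o_r)
    d = JCSDefinition("symphysis", body_l, body_r, fixed, mobile, None)
    return replace_definition(d, d.relative_pose(T_l, T_r))


def _provisional_pitch(
    cranial_acs: AnatomicalCoordinateSystem,
    landmarks: dict,
    poses: dict,
    side: str,
    frame: int,
    frame_rate: float,
) -> np.ndarray:
    d = _tmj_definition(side, cranial_acs, landmarks, poses, frame)
    trace = compute_joint_trace(
        poses[d.fixed_body], poses[d.mobile_body], d, frame, frame_rate
    )
    return trace.dof("Rz")


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------


@dataclass
class AnalysisResult:
    """Everything one individual's analysis produced."""

    individual_id: str
    config: RunConfig
    frame_rate: float
    zero_frame: int
    cranial_acs: AnatomicalCoordinateSystem
    jcs_traces: dict  # "tmj_left"/"tmj_right"/"symphysis" -> JCSTrace
    molar_trace: LocatorTrace
    cycle_intervals: list
    chew_cycles: list
    summary: AmplitudeSummary
    occlusal: dict  # variable -> mean occlusal displacement / range
    frames_missing: dict  # body -> count of frames without a pose
    pose_rms: dict  # body -> mean rms residual (mm)

    @property
    def n_cycles(self) -> int:
        return len(self.chew_cycles)

    def variable_traces(self) -> dict:
        """Per-frame traces keyed by report variable name."""
        side = self.config.condylar_side
        tmj = self.jcs_traces[f"tmj_{side}"]
        out = {}
        for j, dof in enumerate(DOF_NAMES):
            out[f"condylar_{dof}"] = tmj.values[:, j]
        for j, dof in enumerate(("Tx", "Ty", "Tz")):
            out[f"molar_{dof}"] = self.molar_trace.values[:, j]
        sym = self.jcs_traces["symphysis"]
        for j, dof in enumerate(DOF_NAMES):
            out[f"symphyseal_{dof}"] = sym.values[:, j]
        return out


def analyze_poses(
    poses: dict,
    landmarks: dict,
    frame_rate: float,
    config: RunConfig = RunConfig(),
    individual_id: str = "individual",
    frames_missing: dict | None = None,
    pose_rms: dict | None = None,
) -> AnalysisResult:
    """Run the coordinate-system / trace / cycle stages on body poses.

    ``poses`` maps body name to a :class:`PoseTrajectory` (estimated or
    ground truth); ``landmarks`` maps body name to model-frame landmark
    points.  See the module docstring for the stage sequence.
    """
    r0 = _first_common_valid_frame(poses)
    cranial_acs, _ = _build_cranial_acs(landmarks, poses, r0)
    side = config.condylar_side

    pitch = _provisional_pitch(cranial_acs, landmarks, poses, side, r0, frame_rate)
    intervals = segment_cycles(
        pitch,
        frame_rate,
        min_amplitude_deg=config.min_cycle_amplitude_deg,
        max_amplitude_deg=config.max_cycle_amplitude_deg,
        min_prominence_deg=config.min_prominence_deg,
    )
    if config.zero_frame is not None:
        zero = int(config.zero_frame)
        if not all(p.valid[zero] for p in poses.values()):
            raise ComputationError(f"configured zero frame {zero} has missing poses")
    else:
        if not intervals:
            raise ComputationError(
                f"{individual_id}: no qualifying chew cycles to anchor the zero pose"
            )
        rep = select_representative_cycle(pitch, intervals)
        zero = find_zero_frame(pitch, rep)

    defs = {
        "tmj_left": _tmj_definition("left", cranial_acs, landmarks, poses, zero),
        "tmj_right": _tmj_definition("right", cranial_acs, landmarks, poses, zero),
        "symphysis": _symphysis_definition(cranial_acs, landmarks, poses, zero),
    }
    traces = {
        name: compute_joint_trace(
            poses[d.fixed_body], poses[d.mobile_body], d, zero, frame_rate
        )
        for name, d in defs.items()
    }

    cran = cranial_acs.body_name
    locator_body = _body_with(landmarks, "molar2_locator", exclude=(cran,))
    molar_ref = AnatomicalCoordinateSystem(
        cran, landmarks[cran]["maxillary_occlusal_center"], cranial_acs.axes
    )
    molar = compute_locator_trace(
        poses[cran],
        poses[locator_body],
        landmarks[locator_body]["molar2_locator"],
        molar_ref,
        zero,
        frame_rate,
        name="molar2",
    )

    # Final segmentation on the zero-referenced pitch trace.
    final_pitch = traces[f"tmj_{side}"].dof("Rz")
    intervals = segment_cycles(
        final_pitch,
        frame_rate,
        min_amplitude_deg=config.min_cycle_amplitude_deg,
        max_amplitude_deg=config.max_cycle_amplitude_deg,
        min_prominence_deg=config.min_prominence_deg,
    )

    result = AnalysisResult(
        individual_id=individual_id,
        config=config,
        frame_rate=frame_rate,
        zero_frame=zero,
        cranial_acs=cranial_acs,
        jcs_traces=traces,
        molar_trace=molar,
        cycle_intervals=intervals,
        chew_cycles=[],
        summary=None,
        occlusal={},
        frames_missing=frames_missing or {b: 0 for b in poses},
        pose_rms=pose_rms or {b: float("nan") for b in poses},
    )
    var_traces = result.variable_traces()
    cycles = build_cycles(
        var_traces,
        intervals,
        trial_id=individual_id,
        occlusal_window=config.occlusal_window,
        max_missing_fraction=config.max_missing_fraction,
    )
    result.chew_cycles = cycles
    if cycles:
        result.summary = summarize_amplitudes(
            individual_id, cycles, confidence=config.confidence, ci_mode=config.ci_mode
        )
        per_cycle = [occlusal_metrics(c) for c in cycles]
        result.occlusal = {
            name: {
                "displacement": float(np.mean([m[name]["displacement"] for m in per_cycle])),
                "range": float(np.mean([m[name]["range"] for m in per_cycle])),
            }
            for name in per_cycle[0]
        }
    return result


def _poses_from_markers(table: MarkerTrajectoryTable, constellations: dict,
                        config: RunConfig):
    filtered = filter_table(table, config.filter_cutoff_hz, config.filter_order)
    poses, missing, rms = {}, {}, {}
    for body, constellation in constellations.items():
        traj = estimate_pose_trajectory(constellation, filtered)
        poses[body] = traj
        missing[body] = int((~traj.valid).sum())
        rms[body] = float(np.nanmean(traj.rms_residual)) if traj.valid.any() else float("nan")
        if missing[body]:
            log.info("body %s: %d frames without a pose", body, missing[body])
    return poses, missing, rms


def analyze_markers(
    table: MarkerTrajectoryTable,
    constellations: dict,
    landmarks: dict,
    config: RunConfig = RunConfig(),
    individual_id: str = "individual",
) -> AnalysisResult:
    """Full pipeline from observed marker trajectories.

    Filter raw marker coordinates (keeps estimated rotations exactly
    orthonormal), estimate per-frame poses, then run
    :func:`analyze_poses`.
    """
    poses, missing, rms = _poses_from_markers(table, constellations, config)
    return analyze_poses(
        poses, landmarks, table.frame_rate, config, individual_id,
        frames_missing=missing, pose_rms=rms,
    )


# ---------------------------------------------------------------------------
# Workflow precision
# ---------------------------------------------------------------------------


def precision_traces(
    table: MarkerTrajectoryTable,
    constellations: dict,
    landmarks: dict,
    config: RunConfig = RunConfig(),
) -> dict:
    """Joint + molar traces of one zero-motion trial.

    The zero frame is the first all-valid frame (or the configured
    override); with no true relative motion every trace is pure
    workflow error.
    """
    poses, _, _ = _poses_from_markers(table, constellations, config)
    r0 = _first_common_valid_frame(poses) if config.zero_frame is None \
        else int(config.zero_frame)
    cranial_acs, _ = _build_cranial_acs(landmarks, poses, r0)
    defs = {
        "tmj_left": _tmj_definition("left", cranial_acs, landmarks, poses, r0),
        "tmj_right": _tmj_definition("right", cranial_acs, landmarks, poses, r0),
        "symphysis": _symphysis_definition(cranial_acs, landmarks, poses, r0),
    }
    out = {
        name: compute_joint_trace(
            poses[d.fixed_body], poses[d.mobile_body], d, r0, table.frame_rate
        )
        for name, d in defs.items()
    }
    cran = cranial_acs.body_name
    locator_body = _body_with(landmarks, "molar2_locator", exclude=(cran,))
    molar_ref = AnatomicalCoordinateSystem(
        cran, landmarks[cran]["maxillary_occlusal_center"], cranial_acs.axes
    )
    out["molar"] = compute_locator_trace(
        poses[cran], poses[locator_body],
        landmarks[locator_body]["molar2_locator"], molar_ref, r0,
        table.frame_rate, name="molar2",
    )
    return out


def precision_report_from_trials(trial_traces, config: RunConfig = RunConfig()) -> dict:
    """Pool zero-motion trials into per-group workflow-precision reports.

    ``trial_traces`` is a list of dicts as returned by
    :func:`precision_traces`.  Returns variable-keyed CI half-widths for
    the condylar (both TMJs pooled per side separately — the configured
    side feeds the report), molar and symphyseal variables.
    """
    side = config.condylar_side
    groups = {
        "condylar": [t[f"tmj_{side}"] for t in trial_traces],
        "symphyseal": [t["symphysis"] for t in trial_traces],
        "molar": [t["molar"] for t in trial_traces],
    }
    out = {}
    reports = {}
    for gname, traces in groups.items():
        rep = workflow_precision(traces, confidence=config.confidence)
        reports[gname] = rep
        for dof, v in rep.ci.items():
            out[f"{gname}_{dof}"] = v
    return {"ci": out, "reports": reports}


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def study_report_from_entries(
    individuals: dict,
    workflow_ci: dict | None = None,
    config: RunConfig = RunConfig(),
) -> dict:
    """Build the study report from per-individual entry dicts.

    Each entry holds ``variables`` (name -> mean_amplitude /
    between_cycle_ci / n_cycles), ``n_cycles`` and bookkeeping fields;
    this is also the JSON shape the CLI ``report`` verb merges.
    """
    summaries = [
        AmplitudeSummary.from_means(
            ind, {n: v["mean_amplitude"] for n, v in entry["variables"].items()}
        )
        for ind, entry in individuals.items()
        if entry.get("variables")
    ]
    agg = aggregate_across_individuals(
        summaries,
        groups={k: list(v) for k, v in reference_data.VARIABLE_GROUPS.items()},
    )
    report = {
        "version": config.version,
        "config": config.to_dict(),
        "individuals": individuals,
        "n_cycles_total": int(sum(e["n_cycles"] for e in individuals.values())),
        "range_across_individuals": {k: list(v) for k, v in agg["range"].items()},
        "group_means": agg["group_means"],
    }
    if workflow_ci is not None:
        report["workflow_ci"] = workflow_ci
    return report


def result_entry(r: "AnalysisResult") -> dict:
    """Per-individual report entry for :func:`study_report_from_entries`."""
    row = {}
    if r.summary is not None:
        for name, vs in r.summary.variables.items():
            row[name] = {
                "mean_amplitude": vs.mean,
                "between_cycle_ci": None if not vs.ci_defined else vs.ci,
                "n_cycles": vs.n,
            }
    return {
        "variables": row,
        "n_cycles": r.n_cycles,
        "zero_frame": r.zero_frame,
        "frames_missing": r.frames_missing,
        "occlusal": r.occlusal,
    }


def assemble_report(
    results,
    precision: dict | None = None,
    config: RunConfig = RunConfig(),
) -> dict:
    """Summary-table-shaped report across individuals.

    Rows are individuals (mean amplitude with between-cycle CI per
    variable) plus the workflow-precision row; includes across-
    individual ranges and the symphyseal grand means, unrounded and
    rounded, plus a config echo for reproducibility.
    """
    results = list(results)
    individuals = {r.individual_id: result_entry(r) for r in results}
    return study_report_from_entries(
        individuals,
        workflow_ci=None if precision is None else precision["ci"],
        config=config,
    )
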