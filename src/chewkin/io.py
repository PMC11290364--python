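"""File formats: marker trajectories, rigid transforms, joint traces,
landmarks, configuration and reports.

All CSVs use ``.`` decimals, comma separators and ``#``-prefixed
metadata lines; numbers are written with shortest round-trip formatting
so read(write(x)) is bit-exact.  Missing values are written ``NaN``.

Marker trajectory dialect (3-D points export style)::

    # frame_rate: 250.0
    frame,cranium_m1_X,cranium_m1_Y,cranium_m1_Z,...

with a 1-based integer frame column.  Rigid-transform files carry 16
columns R11..R44 holding the row-major 4x4 homogeneous transform per
frame, NaN-filled for missing poses.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import asdict

import numpy as np
import yaml

from .cycles import round_half_up
from .errors import ValidationError
from .geometry import MarkerConstellation, MarkerTrajectoryTable, PoseTrajectory
from .kinematics import DOF_NAMES, JCSTrace
from .pipeline import RunConfig
from . import reference_data

__all__ = [
    "read_marker_csv",
    "write_marker_csv",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_constellations_csv",
    "write_constellations_csv",
    "write_transforms_csv",
    "read_transforms_csv",
    "write_jcs_trace_csv",
    "read_config",
    "write_config",
    "write_report_json",
    "write_summary_csv",
    "write_fixture_dir",
]


def _fmt(x: float) -> str:
    if np.isnan(x):
        return "NaN"
    return repr(float(x))


def _read_metadata_and_rows(path: str):
    meta = {}
    rows = []
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            if line.strip():
                rows.append(line.rstrip("\n"))
    return meta, list(csv.reader(rows))


def write_marker_csv(path: str, table: MarkerTrajectoryTable, metadata: dict | None = None):
    """Write a trajectory table in the marker CSV dialect."""
    cols = []
    for body in table.bodies:
        for mid in table.marker_ids[body]:
            if "_" in mid:
                raise ValidationError(f"marker id {mid!r} must not contain '_'")
            for axis in "XYZ":
                cols.append(f"{body}_{mid}_{axis}")
    with open(path, "w", newline="") as fh:
        fh.write(f"# frame_rate: {_fmt(table.frame_rate)}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("frame," + ",".join(cols) + "\n")
        n = table.n_frames
        flat = np.hstack([table.data[b].reshape(n, -1) for b in table.bodies])
        for i in range(n):
            fh.write(str(i + 1) + "," + ",".join(_fmt(v) for v in flat[i]) + "\n")


def read_marker_csv(path: str, frame_rate: float | None = None) -> MarkerTrajectoryTable:
    """Parse a marker CSV; ``frame_rate`` falls back to the metadata block.

    Raises :class:`ValidationError` naming the offending row/column for a
    malformed header, an incomplete X/Y/Z triple, or non-contiguous
    frame numbers.
    """
    meta, rows = _read_metadata_and_rows(path)
    if frame_rate is None:
        if "frame_rate" not in meta:
            raise ValidationError(f"{path}: no frame_rate metadata and none supplied")
        frame_rate = float(meta["frame_rate"])
    if not rows:
        raise ValidationError(f"{path}: empty file")
    header = rows[0]
    if not header or header[0] != "frame":
        raise ValidationError(f"{path}: first header column must be 'frame'")
    parsed = []  # (body, marker, axis) per data column
    for col in header[1:]:
        parts = col.rsplit("_", 2)
        if len(parts) != 3 or parts[2] not in ("X", "Y", "Z"):
            raise ValidationError(f"{path}: malformed marker column {col!r}")
        parsed.append(tuple(parts))
    # group into (body, marker) triples in column order
    order = []  # (body, marker)
    triples = {}
    for idx, (body, mid, axis) in enumerate(parsed):
        key = (body, mid)
        if key not in triples:
            triples[key] = {}
            order.append(key)
        if axis in triples[key]:
            raise ValidationError(f"{path}: duplicate column {body}_{mid}_{axis}")
        triples[key][axis] = idx
    for (body, mid), axes in triples.items():
        for axis in "XYZ":
            if axis not in axes:
                raise ValidationError(f"{path}: missing column {body}_{mid}_{axis}")
    data_rows = rows[1:]
    n = len(data_rows)
    values = np.full((n, len(parsed)), np.nan)
    for i, row in enumerate(data_rows):
        if len(row) != len(header):
            raise ValidationError(f"{path}: row {i + 2} has {len(row)} cells, expected {len(header)}")
        try:
            frame = int(row[0])
        except ValueError:
            raise ValidationError(f"{path}: row {i + 2}: non-integer frame {row[0]!r}")
        if frame != i + 1:
            raise ValidationError(
                f"{path}: row {i + 2}: frame numbers must be contiguous 1-based "
                f"(got {frame}, expected {i + 1})"
            )
        for j, cell in enumerate(row[1:]):
            c = cell.strip()
            try:
                values[i, j] = float("nan") if c.lower() == "nan" else float(c)
            except ValueError:
                raise ValidationError(
                    f"{path}: row {i + 2}, column {header[j + 1]}: bad cell {cell!r}"
                )
    bodies = []
    for body, _ in order:
        if body not in bodies:
            bodies.append(body)
    # reject interleaved body groups (mixed body naming)
    seen_done = set()
    prev = None
    for body, _ in order:
        if body != prev:
            if body in seen_done:
                raise ValidationError(f"{path}: columns of body {body!r} are not contiguous")
            if prev is not None:
                seen_done.add(prev)
            prev = body
    data, ids = {}, {}
    for body in bodies:
        mids = [m for b, m in order if b == body]
        arr = np.empty((n, len(mids), 3))
        for k, mid in enumerate(mids):
            for a, axis in enumerate("XYZ"):
                arr[:, k, a] = values[:, triples[(body, mid)][axis]]
        data[body] = arr
        ids[body] = tuple(mids)
    return MarkerTrajectoryTable(frame_rate, data, ids)


# ---------------------------------------------------------------------------
# Landmarks and reference constellations
# ---------------------------------------------------------------------------


def write_landmarks_csv(path: str, landmarks: dict):
    """``body,landmark_name,X,Y,Z`` in mm, bone model frames."""
    with open(path, "w", newline="") as fh:
        fh.write("body,landmark_name,X,Y,Z\n")
        for body, pts in landmarks.items():
            for name, p in pts.items():
                fh.write(f"{body},{name}," + ",".join(_fmt(v) for v in p) + "\n")


def read_landmarks_csv(path: str) -> dict:
    _, rows = _read_metadata_and_rows(path)
    if not rows or rows[0] != ["body", "landmark_name", "X", "Y", "Z"]:
        raise ValidationError(f"{path}: expected header body,landmark_name,X,Y,Z")
    out: dict = {}
    for i, row in enumerate(rows[1:]):
        if len(row) != 5:
            raise ValidationError(f"{path}: row {i + 2} has {len(row)} cells, expected 5")
        body, name = row[0], row[1]
        try:
            p = np.array([float(v) for v in row[2:]])
        except ValueError:
            raise ValidationError(f"{path}: row {i + 2}: bad coordinates {row[2:]!r}")
        out.setdefault(body, {})[name] = p
    return out


def write_constellations_csv(path: str, constellations: dict):
    """``body,marker_id,X,Y,Z``: reference marker coordinates per bone."""
    with open(path, "w", newline="") as fh:
        fh.write("body,marker_id,X,Y,Z\n")
        for body, c in constellations.items():
            for mid, p in zip(c.marker_ids, c.coordinates):
                fh.write(f"{body},{mid}," + ",".join(_fmt(v) for v in p) + "\n")


def read_constellations_csv(path: str) -> dict:
    _, rows = _read_metadata_and_rows(path)
    if not rows or rows[0] != ["body", "marker_id", "X", "Y", "Z"]:
        raise ValidationError(f"{path}: expected header body,marker_id,X,Y,Z")
    acc: dict = {}
    for i, row in enumerate(rows[1:]):
        if len(row) != 5:
            raise ValidationError(f"{path}: row {i + 2} has {len(row)} cells, expected 5")
        body, mid = row[0], row[1]
        acc.setdefault(body, []).append((mid, [float(v) for v in row[2:]]))
    return {
        body: MarkerConstellation(
            body,
            tuple(m for m, _ in entries),
            np.array([p for _, p in entries]),
        )
        for body, entries in acc.items()
    }


# ---------------------------------------------------------------------------
# Rigid transforms and traces
# ---------------------------------------------------------------------------

_T_COLS = [f"R{i}{j}" for i in range(1, 5) for j in range(1, 5)]


def write_transforms_csv(path: str, poses: PoseTrajectory, metadata: dict | None = None):
    """Row-major 4x4 homogeneous transform per frame; NaN rows when missing."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# body: {poses.body_name}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("frame," + ",".join(_T_COLS) + "\n")
        for i in range(poses.n_frames):
            if poses.valid[i]:
                m = np.eye(4)
                m[:3, :3] = poses.rotations[i]
                m[:3, 3] = poses.translations[i]
                cells = [_fmt(v) for v in m.reshape(-1)]
            else:
                cells = ["NaN"] * 16
            fh.write(str(i + 1) + "," + ",".join(cells) + "\n")


def read_transforms_csv(path: str) -> PoseTrajectory:
    meta, rows = _read_metadata_and_rows(path)
    if not rows or rows[0] != ["frame"] + _T_COLS:
        raise ValidationError(f"{path}: expected header frame,R11..R44")
    n = len(rows) - 1
    R = np.full((n, 3, 3), np.nan)
    t = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, row in enumerate(rows[1:]):
        vals = np.array([float("nan") if c.strip().lower() == "nan" else float(c)
                         for c in row[1:]]).reshape(4, 4)
        if np.all(np.isfinite(vals)):
            R[i] = vals[:3, :3]
            t[i] = vals[:3, 3]
            valid[i] = True
    return PoseTrajectory(
        meta.get("body", "body"), R, t, valid,
        np.full(n, np.nan), np.zeros(n, dtype=int),
    )


def write_jcs_trace_csv(path: str, trace: JCSTrace, metadata: dict | None = None):
    """``frame,Rx_deg,...,Tz_mm`` with #-prefixed metadata lines."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# joint: {trace.joint_name}\n")
        fh.write(f"# zero_frame: {trace.zero_frame + 1}\n")
        fh.write(f"# frame_rate: {_fmt(trace.frame_rate)}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        header = [f"{d}_deg" if d.startswith("R") else f"{d}_mm" for d in DOF_NAMES]
        fh.write("frame," + ",".join(header) + "\n")
        for i in range(trace.n_frames):
            fh.write(str(i + 1) + "," + ",".join(_fmt(v) for v in trace.values[i]) + "\n")


# ---------------------------------------------------------------------------
# Config and reports
# ---------------------------------------------------------------------------


def write_config(path: str, config: RunConfig):
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_config(path: str) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ValidationError(f"{path}: config must be a flat key-value mapping")
    return RunConfig.from_dict(d)


def write_report_json(path: str, report: dict):
    """Machine-readable report with unrounded values; deterministic bytes
    for identical inputs (keys sorted, no timestamps)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def write_summary_csv(path: str, report: dict):
    """Summary-table-style CSV: one row per individual (``mean (CI)`` per
    variable, rounded half-up to 2 decimals) plus the workflow-CI row."""
    variables = list(reference_data.VARIABLES)
    with open(path, "w", newline="") as fh:
        fh.write(f"# version: {report.get('version', '')}\n")
        fh.write("individual," + ",".join(variables) + "\n")
        for ind, entry in report.get("individuals", {}).items():
            cells = []
            for var in variables:
                v = entry["variables"].get(var)
                if v is None:
                    cells.append("")
                    continue
                mean = round_half_up(v["mean_amplitude"], 2)
                ci = v.get("between_cycle_ci")
                cells.append(
                    f"{mean:.2f}" if ci is None else f"{mean:.2f} ({round_half_up(ci, 2):.2f})"
                )
            fh.write(f"{ind}," + ",".join(cells) + "\n")
        wf = report.get("workflow_ci")
        if wf:
            cells = []
            for var in variables:
                v = wf.get(var.replace("condylar_", "condylar_")
                           if var.startswith("condylar") else var)
                cells.append("" if v is None else repr(round(float(v), 5)))
            fh.write("workflow_CI," + ",".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Fixture directories
# ---------------------------------------------------------------------------


def write_fixture_dir(out_dir: str, trial, analysis_config: RunConfig | None = None):
    """Write a self-contained synthetic fixture directory.

    Contents: markers CSV, reference constellations, landmark file,
    ground-truth transforms per body, ground-truth (injected) joint
    waveforms, and the full simulation parameters including the seed.
    """
    os.makedirs(out_dir, exist_ok=True)
    gt_dir = os.path.join(out_dir, "ground_truth")
    os.makedirs(gt_dir, exist_ok=True)
    write_marker_csv(
        os.path.join(out_dir, "markers.csv"),
        trial.markers,
        metadata={"kind": trial.kind, "seed": trial.params.seed},
    )
    write_landmarks_csv(os.path.join(out_dir, "landmarks.csv"), trial.scene.landmarks)
    write_constellations_csv(
        os.path.join(out_dir, "constellations.csv"), trial.scene.constellations
    )
    with open(os.path.join(out_dir, "params.yaml"), "w") as fh:
        yaml.safe_dump(asdict(trial.params), fh, sort_keys=True)
    if analysis_config is not None:
        write_config(os.path.join(out_dir, "config.yaml"), analysis_config)
    for body, poses in trial.poses.items():
        write_transforms_csv(
            os.path.join(gt_dir, f"transforms_{body}.csv"), poses,
            metadata={"kind": "ground_truth"},
        )
    for joint, values in trial.injected.items():
        tr = JCSTrace(
            joint, values, np.ones(len(values), bool),
            np.zeros(len(values), bool), 0, trial.params.frame_rate,
        )
        write_jcs_trace_csv(
            os.path.join(gt_dir, f"jcs_{joint}.csv"), tr,
            metadata={"kind": "injected_waveform"},
        )
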