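"""Chew-cycle segmentation, time-normalisation and summary statistics.

A chew cycle runs from one gape maximum (jaw most open, minimum pitch
Rz) to the next.  Each cycle is cubic-spline interpolated onto 100
evenly spaced samples; the occlusal phase is taken as the middle 40% of
the normalised cycle (samples 31-70 of 1..100).  Per-cycle "absolute
amplitude" of a variable is max - min over the normalised cycle.

Between-cycle 95% confidence intervals are, by default, the average over
the 100 normalised time points of the pointwise across-cycle t-based CI
half-width of the mean (the band one would draw around a mean trace); a
per-cycle-amplitude CI is available as an alternative.  Workflow
precision is estimated from zero-relative-motion trials as the t-based
95% half-width of the pooled per-frame values about their mean — a
dispersion measure of the apparent motion produced by the measurement
chain alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

from .errors import ComputationError, ValidationError
from .kinematics import DOF_NAMES, JCSTrace

__all__ = [
    "ChewCycle",
    "VariableSummary",
    "AmplitudeSummary",
    "PrecisionReport",
    "segment_cycles",
    "normalize_cycle",
    "cycle_amplitude",
    "occlusal_metrics",
    "summarize_amplitudes",
    "aggregate_across_individuals",
    "workflow_precision",
    "build_cycles",
    "round_half_up",
    "N_SAMPLES",
    "DEFAULT_OCCLUSAL_WINDOW",
]

log = logging.getLogger(__name__)

#: Samples per time-normalised cycle.
N_SAMPLES = 100
#: Occlusal phase, 1-based inclusive sample indices of 1..100 (middle 40%).
DEFAULT_OCCLUSAL_WINDOW = (31, 70)


def segment_cycles(
    pitch_trace: np.ndarray,
    frame_rate: float,
    min_amplitude_deg: float = 5.0,
    max_amplitude_deg: float = 25.0,
    min_prominence_deg: float = 2.0,
) -> list:
    """Find chew-cycle frame intervals from a TMJ pitch (Rz) trace.

    Cycle boundaries sit at successive gape maxima (minima of Rz) with
    prominence >= ``min_prominence_deg``.  Cycles whose pitch amplitude
    falls below ``min_amplitude_deg`` (non-chew wiggles) or above
    ``max_amplitude_deg`` (food-gathering cycles, which pitch harder than
    chews) are discarded, as are the incomplete stretches before the
    first and after the last gape maximum.

    Returns a list of half-open ``(start, stop)`` frame intervals, where
    ``stop - 1`` is the closing gape maximum (shared with the next
    cycle's start).
    """
    from scipy.signal import find_peaks

    trace = np.asarray(pitch_trace, dtype=float)
    gape = np.where(np.isfinite(trace), -trace, -np.inf)
    peaks, _ = find_peaks(gape, prominence=min_prominence_deg)
    if len(peaks) < 2:
        log.info("segment_cycles: fewer than 2 gape maxima; no cycles")
        return []
    intervals = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = trace[a : b + 1]
        if not np.any(np.isfinite(seg)):
            log.info("segment_cycles: dropped [%d, %d): all samples missing", a, b + 1)
            continue
        amp = np.nanmax(seg) - np.nanmin(seg)
        if amp < min_amplitude_deg:
            log.info(
                "segment_cycles: dropped [%d, %d): amplitude %.2f deg < %.2f",
                a, b + 1, amp, min_amplitude_deg,
            )
            continue
        if amp > max_amplitude_deg:
            log.info(
                "segment_cycles: dropped [%d, %d): amplitude %.2f deg > %.2f "
                "(gathering-cycle exclusion)",
                a, b + 1, amp, max_amplitude_deg,
            )
            continue
        intervals.append((int(a), int(b) + 1))
    if not intervals:
        log.info("segment_cycles: no qualifying cycles")
    return intervals


def normalize_cycle(
    segment: np.ndarray,
    n_samples: int = N_SAMPLES,
    max_missing_fraction: float = 0.10,
) -> np.ndarray:
    """Cubic-spline a cycle segment onto ``n_samples`` even time points.

    The output spans [start, end] of the segment so endpoint values are
    preserved.  Interior missing samples are bridged by the spline, but
    a segment is rejected (ComputationError, caller drops the cycle) if
    its endpoints are missing, it has fewer than 4 valid samples, or any
    missing run exceeds ``max_missing_fraction`` of its length.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 1:
        raise ValidationError("normalize_cycle expects a 1-D segment")
    n = seg.size
    finite = np.isfinite(seg)
    if finite.sum() < 4:
        raise ComputationError(f"cycle too short: {int(finite.sum())} valid samples (< 4)")
    if not (finite[0] and finite[-1]):
        raise ComputationError("cycle endpoints are missing")
    # Longest interior missing run.
    runs = np.diff(np.flatnonzero(np.concatenate(([True], finite, [True]))))
    longest_gap = int(runs.max()) - 1 if runs.size else 0
    if longest_gap > max_missing_fraction * n:
        raise ComputationError(
            f"cycle too gappy: missing run of {longest_gap} samples "
            f"(> {max_missing_fraction:.0%} of {n})"
        )
    t = np.flatnonzero(finite).astype(float)
    spline = CubicSpline(t, seg[finite])
    return spline(np.linspace(0.0, n - 1.0, n_samples))


def cycle_amplitude(normalized_trace: np.ndarray) -> float:
    """Absolute amplitude of motion: max - min over the normalised cycle."""
    v = np.asarray(normalized_trace, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("cycle_amplitude expects a complete (no-missing) trace")
    return float(v.max() - v.min())


@dataclass
class ChewCycle:
    """One segmented, 100-sample time-normalised chew cycle.

    ``traces`` maps variable name (e.g. ``"tmj_left_Rz"``) to a
    100-sample array; ``occlusal_window`` is 1-based inclusive sample
    indices of 1..100.
    """

    trial_id: str
    start: int
    stop: int
    traces: dict
    occlusal_window: tuple = DEFAULT_OCCLUSAL_WINDOW

    def __post_init__(self):
        for name, v in self.traces.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (N_SAMPLES,):
                raise ValidationError(
                    f"cycle variable {name!r}: expected {N_SAMPLES} samples, got {v.shape}"
                )
            self.traces[name] = v
        lo, hi = self.occlusal_window
        if not (1 <= lo < hi <= N_SAMPLES):
            raise ValidationError(f"invalid occlusal window {self.occlusal_window}")

    @property
    def occlusal_slice(self) -> slice:
        lo, hi = self.occlusal_window
        return slice(lo - 1, hi)


def occlusal_metrics(cycle: ChewCycle) -> dict:
    """Per-variable displacement over the occlusal phase.

    For each variable: ``displacement`` = value at window end minus value
    at window start, and ``range`` = window max - min.
    """
    out = {}
    sl = cycle.occlusal_slice
    for name, v in cycle.traces.items():
        w = v[sl]
        out[name] = {
            "displacement": float(w[-1] - w[0]),
            "range": float(w.max() - w.min()),
        }
    return out


def build_cycles(
    variable_traces: dict,
    intervals,
    trial_id: str,
    occlusal_window: tuple = DEFAULT_OCCLUSAL_WINDOW,
    max_missing_fraction: float = 0.10,
) -> list:
    """Normalise every variable over every interval into ChewCycle objects.

    ``variable_traces`` maps variable name to a full-trial per-frame
    trace.  A cycle is dropped (with a logged reason) if any variable
    cannot be normalised over it.
    """
    cycles = []
    for start, stop in intervals:
        traces = {}
        try:
            for name, trace in variable_traces.items():
                traces[name] = normalize_cycle(
                    np.asarray(trace, float)[start:stop],
                    max_missing_fraction=max_missing_fraction,
                )
        except ComputationError as exc:
            log.info("trial %s: dropped cycle [%d, %d): %s", trial_id, start, stop, exc)
            continue
        cycles.append(ChewCycle(trial_id, start, stop, traces, occlusal_window))
    return cycles


@dataclass
class VariableSummary:
    """Per-variable amplitude summary for one individual."""

    amplitudes: np.ndarray  # per-cycle absolute amplitudes
    mean: float
    ci: float  # 95% CI half-width; NaN when undefined (n = 1)
    n: int
    ci_defined: bool


@dataclass
class AmplitudeSummary:
    """Per-individual amplitude means with between-cycle CIs (one row of a
    summary table)."""

    individual_id: str
    variables: dict  # name -> VariableSummary
    n_cycles: int = 0

    @classmethod
    def from_means(cls, individual_id: str, means: dict) -> "AmplitudeSummary":
        """Build a summary from already-computed mean amplitudes only
        (e.g. a published summary table); CIs are undefined."""
        variables = {
            name: VariableSummary(np.asarray([m], float), float(m), np.nan, 1, False)
            for name, m in means.items()
        }
        return cls(individual_id, variables, n_cycles=1)


def summarize_amplitudes(
    individual_id: str,
    cycles,
    confidence: float = 0.95,
    ci_mode: str = "pointwise",
) -> AmplitudeSummary:
    """Mean per-cycle amplitude and between-cycle CI per variable.

    ``ci_mode="pointwise"`` (default): the CI is the average over the 100
    normalised time points of the pointwise across-cycle t-based CI
    half-width of the mean trace.  ``ci_mode="amplitude"``: the t-based
    CI half-width of the per-cycle amplitude distribution.  With a
    single cycle the mean is reported and the CI flagged undefined.
    """
    cycles = list(cycles)
    if not cycles:
        raise ComputationError(f"individual {individual_id!r}: no cycles to summarise")
    if ci_mode not in ("pointwise", "amplitude"):
        raise ValidationError(f"unknown ci_mode {ci_mode!r}")
    names = list(cycles[0].traces)
    n = len(cycles)
    out = {}
    for name in names:
        stack = np.vstack([c.traces[name] for c in cycles])  # (n_cycles, 100)
        amps = np.array([cycle_amplitude(row) for row in stack])
        mean_amp = float(amps.mean())
        if n < 2:
            out[name] = VariableSummary(amps, mean_amp, np.nan, n, False)
            continue
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
        if ci_mode == "pointwise":
            s = stack.std(axis=0, ddof=1)  # pointwise across-cycle SD
            ci = float(np.mean(tcrit * s / np.sqrt(n)))
        else:
            ci = float(tcrit * amps.std(ddof=1) / np.sqrt(n))
        out[name] = VariableSummary(amps, mean_amp, ci, n, True)
    return AmplitudeSummary(individual_id, out, n_cycles=n)


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (report convention; numpy rounds half-even)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_across_individuals(
    summaries,
    groups: dict | None = None,
    decimals: int = 2,
) -> dict:
    """Across-individual ranges and grouped grand means.

    For every variable present in all summaries: the "range" is the
    (min, max) of individual mean amplitudes, rounded half-up to
    ``decimals``.  For each requested group (name -> list of variable
    names), the grand mean over all individual x variable entries is
    reported both unrounded and rounded half-up to 1 and ``decimals``
    decimals, so either reporting convention can be checked.
    """
    summaries = list(summaries)
    if not summaries:
        raise ComputationError("aggregate_across_individuals: no summaries")
    names = [n for n in summaries[0].variables if all(n in s.variables for s in summaries)]
    report = {"range": {}, "group_means": {}, "individual_means": {}}
    for s in summaries:
        report["individual_means"][s.individual_id] = {
            n: s.variables[n].mean for n in names
        }
    for n in names:
        means = [s.variables[n].mean for s in summaries]
        report["range"][n] = (
            round_half_up(min(means), decimals),
            round_half_up(max(means), decimals),
        )
    for gname, members in (groups or {}).items():
        entries = [
            s.variables[m].mean for s in summaries for m in members if m in s.variables
        ]
        if not entries:
            continue
        gm = float(np.mean(entries))
        report["group_means"][gname] = {
            "value": gm,
            "rounded": round_half_up(gm, decimals),
            "rounded_1dp": round_half_up(gm, 1),
            "n_entries": len(entries),
        }
    return report


@dataclass
class PrecisionReport:
    """Workflow 95% CI per 6-DOF variable from zero-motion trials."""

    ci: dict  # DOF name -> half-width (deg or mm)
    n_frames: int
    n_trials: int
    confidence: float


def workflow_precision(zero_motion_traces, confidence: float = 0.95) -> PrecisionReport:
    """Workflow precision from trials with no true relative joint motion.

    Frames are pooled across trials per DOF; the reported value is the
    t-based ``confidence`` half-width of the per-frame values about
    their pooled mean (``t_crit * SD``).  Because true motion is zero,
    this dispersion quantifies the apparent motion injected by the
    measurement workflow alone.
    """
    traces = list(zero_motion_traces)
    if not traces:
        raise ComputationError("workflow_precision: no zero-motion traces supplied")
    # JCS traces carry 6 DOFs, locator traces 3 translations.
    ncols = {tr.values.shape[1] for tr in traces}
    if len(ncols) != 1 or ncols.pop() not in (3, 6):
        raise ValidationError(
            "workflow_precision expects traces with a common 3- or 6-DOF layout"
        )
    names = DOF_NAMES if traces[0].values.shape[1] == 6 else ("Tx", "Ty", "Tz")
    pooled = {name: [] for name in names}
    for tr in traces:
        for j, name in enumerate(names):
            pooled[name].append(tr.values[tr.valid, j])
    ci = {}
    n_frames = 0
    for name in names:
        v = np.concatenate(pooled[name])
        if v.size < 2:
            raise ComputationError(
                f"workflow_precision: fewer than 2 pooled frames for {name}"
            )
        n_frames = max(n_frames, v.size)
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, v.size - 1)
        ci[name] = float(tcrit * v.std(ddof=1))
    return PrecisionReport(ci, n_frames, len(traces), confidence)
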