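"""Cycle segmentation, normalisation, amplitudes, CIs and precision."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chewkin.cycles import (
    AmplitudeSummary,
    ChewCycle,
    aggregate_across_individuals,
    build_cycles,
    cycle_amplitude,
    normalize_cycle,
    occlusal_metrics,
    round_half_up,
    segment_cycles,
    summarize_amplitudes,
    workflow_precision,
)
from chewkin.errors import ComputationError, ValidationError
from chewkin.kinematics import JCSTrace
from chewkin.simulate import ChewModelParams, injected_joint_values


def _pitch_trace(n_cycles=10, fpc=50, amp=15.0, pad=0.26):
    params = ChewModelParams(
        n_cycles=n_cycles, pitch_amplitude=amp, seed=0, occlusal_dome_deg=1.0
    )
    n = int(round((n_cycles + 2 * pad) * fpc)) + 1
    phi = np.arange(n) / fpc - pad
    return injected_joint_values(params, phi)["tmj_left"][:, 2], phi


class TestSegmentCycles:
    def test_synthetic_ten_cycle_trial(self):
        """Exactly 10 intervals with boundaries within 1 frame of the
        ground-truth gape maxima (integer phases)."""
        trace, phi = _pitch_trace(n_cycles=10)
        intervals = segment_cycles(trace, 250.0)
        assert len(intervals) == 10
        for k, (a, b) in enumerate(intervals):
            assert abs(phi[a] - k) < 1.5 / 50
            assert abs(phi[b - 1] - (k + 1)) < 1.5 / 50

    def test_flat_trace_yields_no_cycles(self):
        assert segment_cycles(np.zeros(500), 250.0) == []

    def test_gathering_cycle_excluded_by_ceiling(self):
        """One 30-deg cycle among 12-deg chews is discarded with the
        default 25-deg gathering ceiling."""
        fpc = 50
        phi = np.arange(int(6.5 * fpc)) / fpc - 0.25
        amps = {0: 12.0, 1: 12.0, 2: 30.0, 3: 12.0, 4: 12.0, 5: 12.0}
        trace = np.empty_like(phi)
        for i, p in enumerate(phi):
            k = int(np.floor(p))
            a = amps.get(k, 12.0)
            # common open level at integer phases; per-cycle closure height
            trace[i] = -12.0 + a * 0.5 * (1 - np.cos(2 * np.pi * p))
        intervals = segment_cycles(trace, 250.0)
        assert len(intervals) == 5
        kept_phases = [round(float(phi[a])) for a, _ in intervals]
        assert 2 not in kept_phases

    def test_small_wiggles_excluded_by_min_amplitude(self):
        t = np.arange(1000) / 250.0
        trace = -2.0 * (1 + np.sin(2 * np.pi * 5 * t))  # 4 deg amplitude
        assert segment_cycles(trace, 250.0, min_amplitude_deg=5.0) == []

    def test_missing_frames_do_not_create_boundaries(self):
        trace, _ = _pitch_trace(n_cycles=5)
        trace[120:130] = np.nan
        intervals = segment_cycles(trace, 250.0)
        assert 3 <= len(intervals) <= 5


class TestNormalizeCycle:
    def test_linear_ramp(self):
        out = normalize_cycle(np.linspace(0, 1, 37))
        np.testing.assert_allclose(out, np.linspace(0, 1, 100), atol=1e-9)

    def test_sine_against_analytic(self):
        n = 60
        x = np.sin(2 * np.pi * np.arange(n) / (n - 1))
        out = normalize_cycle(x)
        t = np.linspace(0, 1, 100)
        assert np.max(np.abs(out - np.sin(2 * np.pi * t))) < 1e-3

    def test_endpoints_preserved(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        out = normalize_cycle(x)
        assert abs(out[0] - x[0]) < 1e-9 and abs(out[-1] - x[-1]) < 1e-9

    def test_interior_gap_bridged(self):
        x = np.sin(np.linspace(0, np.pi, 50))
        x[20:23] = np.nan
        out = normalize_cycle(x)
        assert np.all(np.isfinite(out))

    def test_too_gappy_dropped(self):
        x = np.sin(np.linspace(0, np.pi, 50))
        x[10:21] = np.nan  # 11 / 50 > 10%
        with pytest.raises(ComputationError):
            normalize_cycle(x)

    def test_too_short_dropped(self):
        with pytest.raises(ComputationError):
            normalize_cycle(np.array([0.0, 1.0, 2.0]))

    def test_missing_endpoint_dropped(self):
        x = np.sin(np.linspace(0, np.pi, 50))
        x[0] = np.nan
        with pytest.raises(ComputationError):
            normalize_cycle(x)


class TestCycleAmplitude:
    def test_constant_zero(self):
        assert cycle_amplitude(np.full(100, 2.5)) == 0.0

    def test_sine_amplitude(self):
        t = np.linspace(0, 1, 100)
        a = cycle_amplitude(1.7 * np.sin(2 * np.pi * t))
        assert a == pytest.approx(2 * 1.7, rel=1e-3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_time_reversal_invariance(self, seed):
        v = np.random.default_rng(seed).normal(size=100)
        assert cycle_amplitude(v) == pytest.approx(cycle_amplitude(v[::-1]))

    def test_missing_rejected(self):
        v = np.ones(100)
        v[3] = np.nan
        with pytest.raises(ValidationError):
            cycle_amplitude(v)


class TestOcclusalMetrics:
    def _cycle(self, traces):
        return ChewCycle("t", 0, 100, traces)

    def test_monotone_ramp_displacement(self):
        """A 2.0-unit ramp across the whole cycle yields ~0.8 (the middle
        40%) over the occlusal window."""
        cycle = self._cycle({"v": np.linspace(0, 2.0, 100)})
        m = occlusal_metrics(cycle)["v"]
        assert m["displacement"] == pytest.approx(0.8, abs=0.015)
        assert m["range"] == pytest.approx(0.8, abs=0.015)

    def test_flat_variable_zero(self):
        m = occlusal_metrics(self._cycle({"v": np.ones(100)}))["v"]
        assert m["displacement"] == 0.0 and m["range"] == 0.0

    def test_window_bounds(self):
        c = self._cycle({"v": np.arange(100.0)})
        assert c.occlusal_slice == slice(30, 70)
        m = occlusal_metrics(c)["v"]
        assert m["displacement"] == pytest.approx(39.0)


class TestSummarize:
    def _cycles(self, stack):
        return [
            ChewCycle("t", 0, 100, {"v": row}) for row in stack
        ]

    def test_identical_cycles_zero_ci(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 100))
        s = summarize_amplitudes("a", self._cycles([base] * 5))
        assert s.variables["v"].ci == pytest.approx(0.0, abs=1e-12)
        assert s.variables["v"].mean == pytest.approx(2.0, rel=1e-3)

    def test_two_cycle_closed_form(self):
        """Two cycles offset by +/-d: pointwise SD = sqrt(2) d, so the CI
        half-width is t(0.975, 1) * d exactly."""
        base = np.sin(np.linspace(0, 2 * np.pi, 100))
        d = 0.35
        s = summarize_amplitudes("a", self._cycles([base + d, base - d]))
        expected = stats.t.ppf(0.975, 1) * np.sqrt(2) * d / np.sqrt(2)
        assert s.variables["v"].ci == pytest.approx(expected, rel=1e-9)

    def test_single_cycle_ci_undefined(self):
        s = summarize_amplitudes("a", self._cycles([np.ones(100)]))
        v = s.variables["v"]
        assert not v.ci_defined and np.isnan(v.ci) and v.n == 1

    def test_ci_shrinks_as_inverse_sqrt_n(self):
        """The standard-error component of the between-cycle CI scales as
        n^-0.5 at fixed noise (the t quantile adds extra shrinkage at
        small n, so the raw CI falls slightly faster); the raw CI is
        strictly decreasing in n."""
        rng = np.random.default_rng(5)
        base = np.sin(np.linspace(0, 2 * np.pi, 100))
        ns, cis = [4, 8, 16, 32, 64], []
        for n in ns:
            reps = 40
            vals = []
            for _ in range(reps):
                stack = base + rng.normal(0, 0.2, (n, 100))
                s = summarize_amplitudes("a", self._cycles(list(stack)))
                vals.append(s.variables["v"].ci)
            cis.append(np.mean(vals))
        assert all(a > b for a, b in zip(cis, cis[1:]))
        tcrit = np.array([stats.t.ppf(0.975, n - 1) for n in ns])
        slope = np.polyfit(np.log(ns), np.log(np.array(cis) / tcrit), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_amplitude_ci_mode(self):
        rng = np.random.default_rng(8)
        stack = [np.sin(np.linspace(0, 2 * np.pi, 100)) * rng.uniform(0.8, 1.2)
                 for _ in range(6)]
        s = summarize_amplitudes("a", self._cycles(stack), ci_mode="amplitude")
        amps = np.array([cycle_amplitude(v) for v in stack])
        expected = stats.t.ppf(0.975, 5) * amps.std(ddof=1) / np.sqrt(6)
        assert s.variables["v"].ci == pytest.approx(expected, rel=1e-9)


class TestAggregate:
    def test_symphyseal_rotation_grand_mean(self):
        """The nine per-individual symphyseal rotation means average to
        1.1567 deg (1.16 rounded; 1.2 at 1 dp)."""
        means = {
            "a": {"sr": None}, }
        rows = [
            ("a", {"Rx": 1.10, "Ry": 1.13, "Rz": 1.55}),
            ("b", {"Rx": 2.09, "Ry": 0.60, "Rz": 0.63}),
            ("c", {"Rx": 0.99, "Ry": 1.50, "Rz": 0.82}),
        ]
        summaries = [AmplitudeSummary.from_means(i, m) for i, m in rows]
        rep = aggregate_across_individuals(
            summaries, groups={"rot": ["Rx", "Ry", "Rz"]}
        )
        gm = rep["group_means"]["rot"]
        assert gm["value"] == pytest.approx(10.41 / 9, abs=1e-12)
        assert gm["rounded"] == 1.16
        assert gm["n_entries"] == 9

    def test_symphyseal_translation_grand_mean(self):
        rows = [
            ("a", {"Tx": 0.18, "Ty": 0.62, "Tz": 0.41}),
            ("b", {"Tx": 0.04, "Ty": 0.36, "Tz": 0.20}),
            ("c", {"Tx": 0.04, "Ty": 0.06, "Tz": 0.08}),
        ]
        summaries = [AmplitudeSummary.from_means(i, m) for i, m in rows]
        rep = aggregate_across_individuals(
            summaries, groups={"trans": ["Tx", "Ty", "Tz"]}
        )
        gm = rep["group_means"]["trans"]
        assert gm["value"] == pytest.approx(1.99 / 9, abs=1e-12)
        assert gm["rounded_1dp"] == 0.2

    def test_single_individual_range_collapses(self):
        s = AmplitudeSummary.from_means("only", {"v": 3.14159})
        rep = aggregate_across_individuals([s])
        lo, hi = rep["range"]["v"]
        assert lo == hi == 3.14

    def test_round_half_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(1.155, 2) == 1.16
        assert round_half_up(0.22111, 1) == 0.2


def _zero_motion_trace(rng, sigma, n=400):
    values = rng.normal(0, sigma, (n, 6))
    return JCSTrace("j", values, np.ones(n, bool), np.zeros(n, bool), 0, 250.0)


class TestWorkflowPrecision:
    def test_noiseless_traces_give_zero_ci(self):
        tr = JCSTrace("j", np.zeros((200, 6)), np.ones(200, bool),
                      np.zeros(200, bool), 0, 250.0)
        rep = workflow_precision([tr])
        assert all(v < 1e-12 for v in rep.ci.values())

    def test_matches_t_sd_formula(self, rng):
        tr = _zero_motion_trace(rng, 0.1)
        rep = workflow_precision([tr])
        v = tr.values[:, 0]
        expected = stats.t.ppf(0.975, v.size - 1) * v.std(ddof=1)
        assert rep.ci["Rx"] == pytest.approx(expected, rel=1e-12)

    def test_pools_frames_across_trials(self, rng):
        t1, t2 = _zero_motion_trace(rng, 0.1), _zero_motion_trace(rng, 0.1)
        rep = workflow_precision([t1, t2])
        pooled = np.concatenate([t1.values[:, 0], t2.values[:, 0]])
        expected = stats.t.ppf(0.975, pooled.size - 1) * pooled.std(ddof=1)
        assert rep.ci["Rx"] == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_noise(self, rng):
        cis = [workflow_precision([_zero_motion_trace(rng, s)]).ci["Tz"]
               for s in (0.01, 0.05, 0.1)]
        assert cis[0] < cis[1] < cis[2]

    def test_empty_input_rejected(self):
        with pytest.raises(ComputationError):
            workflow_precision([])


class TestBuildCycles:
    def test_drops_cycle_when_any_variable_fails(self):
        trace_good = np.sin(np.linspace(0, 4 * np.pi, 200))
        trace_bad = trace_good.copy()
        trace_bad[60:100] = np.nan  # large gap inside the second interval
        cycles = build_cycles(
            {"good": trace_good, "bad": trace_bad},
            [(0, 50), (50, 110), (110, 160)],
            "t",
        )
        assert len(cycles) == 2
        assert all(set(c.traces) == {"good", "bad"} for c in cycles)
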