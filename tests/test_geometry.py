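"""Rigid transforms, pose estimation, plane fitting and filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal
from scipy.optimize import least_squares

from chewkin.errors import (
    ConfigurationError,
    DegenerateGeometryError,
    PoseUndefinedError,
    ValidationError,
)
from chewkin.geometry import (
    MarkerConstellation,
    MarkerTrajectoryTable,
    RigidTransform,
    compose,
    estimate_pose,
    estimate_pose_trajectory,
    filter_table,
    fit_plane,
    invert,
    lowpass_filter,
)

from conftest import random_rotation, random_transform


class TestRigidTransform:
    def test_rejects_reflection(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValidationError):
            RigidTransform(R, np.zeros(3))

    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))

    def test_identity_composition(self, rng):
        T = random_transform(rng)
        for composed in (compose(RigidTransform.identity(), T),
                         compose(T, RigidTransform.identity())):
            np.testing.assert_allclose(composed.rotation, T.rotation, atol=1e-12)
            np.testing.assert_allclose(composed.translation, T.translation, atol=1e-12)

    def test_double_inversion(self, rng):
        T = random_transform(rng)
        back = invert(invert(T))
        np.testing.assert_allclose(back.rotation, T.rotation, atol=1e-12)
        np.testing.assert_allclose(back.translation, T.translation, atol=1e-12)

    def test_compose_invert_roundtrip_chain(self, rng):
        """A chain of 100 random proper transforms followed by its inverse
        chain returns to the identity within 1e-9."""
        chain = [random_transform(rng) for _ in range(100)]
        acc = RigidTransform.identity()
        for T in chain:
            acc = compose(acc, T)
        for T in reversed(chain):
            acc = compose(acc, invert(T))
        np.testing.assert_allclose(acc.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(acc.translation, 0.0, atol=1e-9)

    def test_matrix_roundtrip(self, rng):
        T = random_transform(rng)
        back = RigidTransform.from_matrix(T.as_matrix())
        np.testing.assert_allclose(back.rotation, T.rotation, atol=1e-15)


class TestFitPlane:
    def test_exact_coplanar_triangle(self):
        plane = fit_plane([(0, 0, 0), (1, 0, 0), (0, 1, 0)], (0, 0, 1))
        np.testing.assert_allclose(plane.origin, [1 / 3, 1 / 3, 0], atol=1e-12)
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)

    def test_orientation_hint_flips_sign_only(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)]
        up = fit_plane(pts, (0, 0, 1))
        down = fit_plane(pts, (0, 0, -1))
        np.testing.assert_allclose(up.normal, -down.normal, atol=1e-12)
        np.testing.assert_allclose(up.origin, down.origin, atol=1e-12)

    def test_matches_svd_oracle_with_noise(self, rng):
        """TLS plane equals the smallest-right-singular-vector of the
        centered coordinate matrix; near-flat data stays within 0.2 deg
        of the true normal."""
        pts = np.column_stack(
            [
                rng.uniform(-5, 5, 20),
                rng.uniform(-5, 5, 20),
                rng.normal(0, 0.01, 20),
            ]
        )
        plane = fit_plane(pts, (0, 0, 1))
        centered = pts - pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(centered)
        oracle = Vt[-1]
        if oracle @ np.array([0, 0, 1.0]) < 0:
            oracle = -oracle
        np.testing.assert_allclose(plane.normal, oracle, atol=1e-9)
        angle = np.degrees(np.arccos(np.clip(plane.normal @ [0, 0, 1], -1, 1)))
        assert angle < 0.2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.column_stack(
            [rng.uniform(-3, 3, 8), rng.uniform(-3, 3, 8), rng.normal(0, 0.1, 8)]
        )
        base = fit_plane(pts, (0, 0, 1))
        perm = fit_plane(pts[rng.permutation(8)], (0, 0, 1))
        np.testing.assert_allclose(base.normal, perm.normal, atol=1e-9)
        np.testing.assert_allclose(base.origin, perm.origin, atol=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateGeometryError):
            fit_plane([(0, 0, 0), (1, 1, 1)], (0, 0, 1))
        with pytest.raises(DegenerateGeometryError):
            fit_plane([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)], (0, 0, 1))


def _brute_force_pose(ref, obs):
    """Nonlinear least-squares oracle over (rotation vector, translation)."""

    def rotvec_to_matrix(v):
        angle = np.linalg.norm(v)
        if angle < 1e-12:
            return np.eye(3)
        axis = v / angle
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)

    def residuals(x):
        R = rotvec_to_matrix(x[:3])
        return (ref @ R.T + x[3:] - obs).ravel()

    x0 = np.concatenate([np.zeros(3), obs.mean(axis=0) - ref.mean(axis=0)])
    sol = least_squares(residuals, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    R = rotvec_to_matrix(sol.x[:3])
    rms = np.sqrt(np.mean(np.sum((ref @ R.T + sol.x[3:] - obs) ** 2, axis=1)))
    return R, sol.x[3:], rms


class TestEstimatePose:
    def test_identity(self, tetra_constellation):
        est = estimate_pose(tetra_constellation, tetra_constellation.coordinates)
        np.testing.assert_allclose(est.transform.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(est.transform.translation, 0.0, atol=1e-12)
        assert est.rms_residual < 1e-12
        assert est.n_used == 4

    def test_exact_synthetic_transform(self, tetra_constellation):
        c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        t = np.array([1.0, 2.0, 3.0])
        obs = tetra_constellation.coordinates @ R.T + t
        est = estimate_pose(tetra_constellation, obs)
        np.testing.assert_allclose(est.transform.rotation, R, atol=1e-9)
        np.testing.assert_allclose(est.transform.translation, t, atol=1e-9)
        assert est.rms_residual < 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_under_noise(self, tetra_constellation, seed):
        """The closed-form fit agrees with a numerical minimiser of the sum
        of squared marker distances to < 1e-6 in angle, translation and rms."""
        rng = np.random.default_rng(seed)
        T = random_transform(rng, max_angle_deg=120.0)
        obs = T.apply(tetra_constellation.coordinates) + rng.normal(
            0, 0.05, (4, 3)
        )
        est = estimate_pose(tetra_constellation, obs)
        R_o, t_o, rms_o = _brute_force_pose(tetra_constellation.coordinates, obs)
        dR = est.transform.rotation @ R_o.T
        angle = np.arccos(np.clip((np.trace(dR) - 1) / 2, -1, 1))
        assert angle < 1e-6
        np.testing.assert_allclose(est.transform.translation, t_o, atol=1e-6)
        assert abs(est.rms_residual - rms_o) < 1e-6

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_equivariance(self, seed):
        """Transforming all observations by a rigid T yields pose
        compose(T, original) to 1e-9."""
        rng = np.random.default_rng(seed)
        coords = np.array(
            [[2.0, 0.5, 0.8], [-1.5, 1.2, -1.0], [0.3, -1.4, 1.6], [-0.8, -0.3, -1.4]]
        )
        ref = MarkerConstellation("b", ("m1", "m2", "m3", "m4"), coords)
        obs = coords + rng.normal(0, 0.05, coords.shape)
        base = estimate_pose(ref, obs)
        T = random_transform(rng)
        moved = estimate_pose(ref, T.apply(obs))
        expected = compose(T, base.transform)
        np.testing.assert_allclose(moved.transform.rotation, expected.rotation, atol=1e-9)
        np.testing.assert_allclose(
            moved.transform.translation, expected.translation, atol=1e-9
        )
        assert abs(moved.rms_residual - base.rms_residual) < 1e-9

    def test_missing_marker_excluded_not_imputed(self, tetra_constellation, rng):
        T = random_transform(rng)
        obs = T.apply(tetra_constellation.coordinates)
        obs[1] = np.nan
        est = estimate_pose(tetra_constellation, obs)
        assert est.n_used == 3
        np.testing.assert_allclose(est.transform.rotation, T.rotation, atol=1e-9)

    def test_fewer_than_three_markers_fails(self, tetra_constellation):
        obs = tetra_constellation.coordinates.copy()
        obs[0] = obs[1] = np.nan
        with pytest.raises(PoseUndefinedError):
            estimate_pose(tetra_constellation, obs)

    def test_collinear_subset_fails(self):
        coords = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [0.0, 2.0, 0]]
        )
        ref = MarkerConstellation("b", ("m1", "m2", "m3", "m4"), coords)
        obs = coords.copy()
        obs[3] = np.nan  # leaves only the collinear trio
        with pytest.raises(DegenerateGeometryError):
            estimate_pose(ref, obs)

    def test_constellation_invariants(self):
        with pytest.raises(DegenerateGeometryError):
            MarkerConstellation("b", ("m1", "m2"), np.zeros((2, 3)))
        with pytest.raises(DegenerateGeometryError):
            MarkerConstellation(
                "b", ("m1", "m2", "m3"), np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
            )

    def test_trajectory_missing_pose_flagged(self, tetra_constellation):
        n = 5
        data = np.tile(tetra_constellation.coordinates, (n, 1, 1))
        data[2, :2] = np.nan  # frame 2: only 2 usable markers
        table = MarkerTrajectoryTable(
            250.0, {"bone": data}, {"bone": tetra_constellation.marker_ids}
        )
        traj = estimate_pose_trajectory(tetra_constellation, table)
        assert traj.valid.tolist() == [True, True, False, True, True]
        assert np.isnan(traj.rotations[2]).all()


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        x = np.full(200, 3.7)
        y, flagged = lowpass_filter(x, 250.0, 20.0)
        np.testing.assert_allclose(y, x, atol=1e-9)
        assert flagged == []

    @staticmethod
    def _sin_amplitude(y, t, f):
        basis = np.column_stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        return float(np.hypot(*coef))

    def test_passband_and_stopband_gains(self):
        """2 Hz passes within 1%; 80 Hz attenuates to the squared analytic
        magnitude response of the filter (forward-backward doubles the
        attenuation in dB) within 5% relative."""
        fs, fc, order = 250.0, 20.0, 2
        b, a = signal.butter(order, fc, btype="low", fs=fs)
        t = np.arange(1500) / fs
        for f in (2.0, 80.0):
            x = np.sin(2 * np.pi * f * t)
            y, _ = lowpass_filter(x, fs, fc, order)
            mid = slice(300, 1200)  # avoid edge transients
            measured = self._sin_amplitude(y[mid], t[mid], f)
            _, h = signal.freqz(b, a, worN=[f], fs=fs)
            expected = float(np.abs(h[0]) ** 2)  # squared: zero-phase pass
            if f < fc:
                assert measured > 0.99
            assert abs(measured - expected) / expected < 0.05

    def test_zero_phase_pulse(self):
        x = np.zeros(301)
        x[150] = 1.0
        y, _ = lowpass_filter(x, 250.0, 20.0)
        assert int(np.argmax(y)) == 150

    def test_missing_runs_filtered_independently(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=120)
        b = rng.normal(size=150)
        joined = np.concatenate([a, [np.nan] * 5, b])
        y, _ = lowpass_filter(joined, 250.0, 20.0)
        ya, _ = lowpass_filter(a, 250.0, 20.0)
        yb, _ = lowpass_filter(b, 250.0, 20.0)
        np.testing.assert_allclose(y[:120], ya, atol=1e-12)
        np.testing.assert_allclose(y[125:], yb, atol=1e-12)
        assert np.isnan(y[120:125]).all()

    def test_short_segment_passthrough_flagged(self):
        x = np.concatenate([np.full(5, 2.0), [np.nan], np.ones(100)])
        y, flagged = lowpass_filter(x, 250.0, 20.0)
        assert (0, 5) in flagged
        np.testing.assert_allclose(y[:5], 2.0)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            lowpass_filter(np.ones(100), 250.0, 125.0)
        with pytest.raises(ConfigurationError):
            lowpass_filter(np.ones(100), 250.0, 0.0)

    def test_idempotent_attenuation(self):
        """Filtering twice with the same cutoff never increases any
        frequency component's amplitude."""
        fs = 250.0
        t = np.arange(2000) / fs
        freqs = (2.0, 10.0, 18.0, 30.0, 60.0)
        x = sum(np.sin(2 * np.pi * f * t + 0.3 * k) for k, f in enumerate(freqs))
        y1, _ = lowpass_filter(x, fs, 20.0)
        y2, _ = lowpass_filter(y1, fs, 20.0)
        mid = slice(400, 1600)
        for f in freqs:
            a1 = self._sin_amplitude(y1[mid], t[mid], f)
            a2 = self._sin_amplitude(y2[mid], t[mid], f)
            assert a2 <= a1 * (1 + 1e-6)

    def test_filter_table_preserves_missing_mask(self, tetra_constellation, rng):
        n = 300
        data = np.tile(tetra_constellation.coordinates, (n, 1, 1))
        data += rng.normal(0, 0.05, data.shape)
        data[10:20, 1] = np.nan
        table = MarkerTrajectoryTable(
            250.0, {"bone": data}, {"bone": tetra_constellation.marker_ids}
        )
        out = filter_table(table, 20.0)
        assert np.array_equal(
            np.isnan(out.data["bone"]), np.isnan(table.data["bone"])
        )
        # noise is attenuated
        assert out.data["bone"][:, 0, 0].std() < table.data["bone"][:, 0, 0].std()
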