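"""Backbone smoothing, tangents, parallel transport, and flattening."""

import numpy as np
import pytest

import lrrwind as lw
from lrrwind.errors import DegenerateGeometryError, ValidationError
from lrrwind.geometry import _initial_frame


class TestGaussianSmooth:
    def test_constant_curve_preserved_exactly(self):
        c = np.tile([1.5, -2.0, 7.0], (50, 1))
        out = lw.gaussian_smooth(c, sigma=20.0)
        np.testing.assert_allclose(out, c, rtol=0, atol=1e-12)

    def test_interior_of_linear_curve_unchanged(self):
        t = np.arange(200.0)
        curve = np.column_stack([t, np.zeros(200), np.zeros(200)])
        out = lw.gaussian_smooth(curve, sigma=20.0)
        # symmetric kernel annihilates the odd part where its +-4*sigma
        # support (radius 80) lies fully inside the curve
        np.testing.assert_allclose(out[80:120, 0], t[80:120], atol=1e-9)

    def test_helix_attenuation_to_axis(self, bare_helix):
        # oracle: a sinusoid of period p under a Gaussian of width sigma is
        # attenuated by exp(-(2*pi*sigma/p)^2/2) ~ 3e-6 for p=25, sigma=20
        trace, _ = bare_helix
        out = lw.gaussian_smooth(trace.coords, sigma=20.0)
        radial = np.hypot(out[:, 0], out[:, 1])
        assert radial.max() < 0.5

    def test_rejects_non_finite(self):
        c = np.zeros((10, 3))
        c[3, 1] = np.nan
        with pytest.raises(ValidationError):
            lw.gaussian_smooth(c, sigma=2.0)

    def test_rejects_bad_sigma(self):
        with pytest.raises(ValidationError):
            lw.gaussian_smooth(np.zeros((10, 3)), sigma=0.0)


class TestGaussianTangent:
    def test_linear_curve_gives_unit_slope(self):
        t = np.arange(300.0)
        curve = np.column_stack([t, -0.5 * t, np.zeros(300)])
        out = lw.gaussian_tangent(curve, sigma=20.0)
        np.testing.assert_allclose(out[:, 0], 1.0, atol=1e-9)
        np.testing.assert_allclose(out[:, 1], -0.5, atol=1e-9)

    def test_constant_curve_gives_zero(self):
        c = np.tile([3.0, 1.0, -4.0], (80, 1))
        out = lw.gaussian_tangent(c, sigma=5.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_finite_differences_of_smoothed(self, rng):
        # convolution commutes with differentiation; on a band-limited
        # curve (min period 700) the discretization error is ~(2pi/700)^3/6
        n = 1500
        t = np.arange(n, dtype=float)
        base = np.column_stack([
            np.sin(2 * np.pi * t / 700.0 + rng.uniform(0, 2 * np.pi)),
            np.cos(2 * np.pi * t / 900.0 + rng.uniform(0, 2 * np.pi)),
            np.sin(2 * np.pi * t / 1100.0 + rng.uniform(0, 2 * np.pi)),
        ])
        smooth = lw.gaussian_smooth(base, sigma=15.0)
        tang = lw.gaussian_tangent(base, sigma=15.0)
        fd = (smooth[2:] - smooth[:-2]) / 2.0
        interior = slice(80, n - 160)
        np.testing.assert_allclose(
            tang[1:-1][interior], fd[interior], atol=1e-6
        )


class TestParallelTransport:
    def test_constant_tangent_keeps_frame(self):
        tangents = np.tile([0.0, 0.0, 1.0], (40, 1))
        ff = lw.parallel_transport_frames(tangents)
        for a in ff.frames:
            np.testing.assert_allclose(a, ff.frames[0], atol=1e-12)

    def test_frame_invariants_on_solenoid(self, clean_solenoid):
        trace, _ = clean_solenoid
        bb = lw.smooth_backbone(trace.coords, 20.0)
        ff = lw.parallel_transport_frames(bb.tangents)
        for t in range(len(ff)):
            a = ff.frames[t]
            np.testing.assert_allclose(a.T @ a, np.eye(2), atol=1e-8)
            g = bb.tangents[t]
            assert np.abs(a.T @ g).max() <= 1e-6 * np.linalg.norm(g)

    def test_circle_holonomy_matches_fine_resampling(self):
        # planar circle traversed once: compare the net frame rotation
        # against the same recurrence run at 100x angular resolution
        def tangents(n):
            # closed traversal: first and last tangent coincide
            ang = np.linspace(0.0, 2.0 * np.pi, n + 1)
            return np.column_stack([-np.sin(ang), np.cos(ang), np.zeros(n + 1)])

        def net_rotation(n):
            ff = lw.parallel_transport_frames(tangents(n))
            a0, a1 = ff.frames[0], ff.frames[-1]
            c = float(np.clip((a0[:, 0] @ a1[:, 0]), -1, 1))
            return np.arccos(c)

        coarse = net_rotation(720)
        fine = net_rotation(72000)
        assert abs(coarse - fine) < 1e-3

    def test_zero_tangent_raises_with_index(self):
        tangents = np.tile([0.0, 0.0, 1.0], (10, 1))
        tangents[4] = 0.0
        with pytest.raises(DegenerateGeometryError, match="t=4"):
            lw.parallel_transport_frames(tangents)

    def test_right_angle_tangent_jump_raises(self):
        # a ~90 degree jump sends one frame column into the tangent line,
        # collapsing the projected frame to rank 1
        tangents = np.tile([0.0, 0.0, 1.0], (10, 1))
        tangents[5:] = [1.0, 0.0, 0.0]
        with pytest.raises(DegenerateGeometryError):
            lw.parallel_transport_frames(tangents)

    def test_initial_frame_is_orthonormal_completion(self):
        for v in ([1.0, 0, 0], [0.3, -0.9, 0.1], [1.0, 1.0, 1.0]):
            u = np.asarray(v) / np.linalg.norm(v)
            a = _initial_frame(np.asarray(v, dtype=float))
            np.testing.assert_allclose(a.T @ a, np.eye(2), atol=1e-12)
            np.testing.assert_allclose(a.T @ u, 0.0, atol=1e-12)


class TestFlatten:
    def test_zero_offset_gives_origin(self):
        t = np.arange(60.0)
        curve = np.column_stack([t, t, t])
        bb = lw.BackboneCurve(points=curve, tangents=np.tile([1.0, 1, 1], (60, 1)), sigma=1.0)
        ff = lw.parallel_transport_frames(bb.tangents)
        flat = lw.flatten(curve, bb, ff)
        np.testing.assert_allclose(flat.points, 0.0, atol=1e-12)

    def test_solenoid_radius_recovered(self):
        spec = lw.SolenoidSpec(n_pre=0, period=25, n_turns=8, radius=3.0, n_post=0)
        trace, _ = lw.generate(spec)
        bb = lw.smooth_backbone(trace.coords, 20.0)
        ff = lw.parallel_transport_frames(bb.tangents)
        flat = lw.flatten(trace, bb, ff)
        r = np.linalg.norm(flat.points, axis=1)
        interior = slice(80, len(trace) - 80)
        np.testing.assert_allclose(r[interior], 3.0, atol=0.2)

    def test_rotation_equivariance(self, clean_solenoid):
        trace, _ = clean_solenoid
        bb = lw.smooth_backbone(trace.coords, 20.0)
        ff = lw.parallel_transport_frames(bb.tangents)
        flat = lw.flatten(trace, bb, ff)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        ff_rot = lw.FrameField(frames=np.einsum("tik,kj->tij", ff.frames, rot))
        flat_rot = lw.flatten(trace, bb, ff_rot)
        np.testing.assert_allclose(flat_rot.points, flat.points @ rot, atol=1e-9)

    def test_isometry_on_normal_plane(self, clean_solenoid):
        trace, _ = clean_solenoid
        bb = lw.smooth_backbone(trace.coords, 20.0)
        ff = lw.parallel_transport_frames(bb.tangents)
        flat = lw.flatten(trace, bb, ff)
        offset = trace.coords - bb.points
        for t in range(0, len(trace), 37):
            a = ff.frames[t]
            proj = a @ (a.T @ offset[t])
            assert abs(np.linalg.norm(flat.points[t]) - np.linalg.norm(proj)) < 1e-8

    def test_length_mismatch_raises(self):
        curve = np.zeros((10, 3))
        bb = lw.BackboneCurve(points=np.zeros((9, 3)), tangents=np.ones((9, 3)), sigma=1.0)
        ff = lw.parallel_transport_frames(np.ones((9, 3)))
        with pytest.raises(ValidationError):
            lw.flatten(curve, bb, ff)

    def test_pipeline_deterministic(self, clean_solenoid):
        trace, _ = clean_solenoid

        def run():
            bb = lw.smooth_backbone(trace.coords, 20.0)
            ff = lw.parallel_transport_frames(bb.tangents)
            return lw.flatten(trace, bb, ff).points

        np.testing.assert_array_equal(run(), run())
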