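"""Sliding-window embedding, mutual-kNN graph, Laplacian phase, SWL2D."""

import networkx as nx
import numpy as np
import pytest

import lrrwind as lw
from lrrwind.errors import GraphConnectivityError, ValidationError
from lrrwind.laplacian_phase import laplacian_phase, phase_from_trace


class TestLocalTangents:
    def test_straight_segment_constant_tangents(self):
        t = np.arange(100.0)
        coords = np.column_stack([2.0 * t, np.zeros(100), np.zeros(100)])
        tang = lw.local_tangents(coords, (10, 90))
        np.testing.assert_allclose(tang, [[2.0, 0.0, 0.0]] * 80, atol=1e-9)

    def test_sigma_is_one_not_backbone_sigma(self):
        # with sigma=1 a period-25 helix keeps nearly full tangent
        # amplitude (attenuation exp(-(2*pi/25)^2/2) ~ 0.97); sigma=20
        # would crush it by ~3e-6
        spec = lw.SolenoidSpec(n_pre=0, period=25, n_turns=8, radius=3.0, n_post=0)
        trace, _ = lw.generate(spec)
        tang = lw.local_tangents(trace, (20, 180))
        amp = np.hypot(tang[:, 0], tang[:, 1]).mean()
        analytic = 2 * np.pi * 3.0 / 25.0
        assert amp == pytest.approx(analytic, rel=0.1)

    def test_agreement_with_central_differences(self):
        # noise-free helix: sigma=1 derivative kernel vs central
        # differences agree to a few percent (5% tolerance)
        spec = lw.SolenoidSpec(n_pre=0, period=25, n_turns=10, n_post=0, noise_sd=0.0)
        trace, truth = lw.generate(spec)
        a, b = 10, len(trace) - 10
        tang = lw.local_tangents(trace, (a, b))
        fd = (trace.coords[a + 1 : b + 1] - trace.coords[a - 1 : b - 1]) / 2.0
        ratio = np.linalg.norm(tang, axis=1) / np.linalg.norm(fd, axis=1)
        assert np.abs(ratio - 1.0).max() < 0.05

    def test_short_span_raises(self):
        with pytest.raises(ValidationError):
            lw.local_tangents(np.zeros((100, 3)), (10, 12))


class TestSlidingWindowEmbed:
    def test_embedded_dimension_75(self):
        v = np.random.default_rng(0).standard_normal((100, 3))
        emb = lw.sliding_window_embed(v, window=24)
        assert emb.shape == (76, 75)

    def test_constant_field_identical_points(self):
        v = np.tile([1.0, 2.0, 3.0], (50, 1))
        emb = lw.sliding_window_embed(v, window=10)
        assert np.ptp(emb, axis=0).max() == 0.0

    def test_period_matched_sinusoid_is_planar(self):
        # oracle: PCA residual of the analytic embedding
        t = np.arange(200.0)
        v = np.column_stack(
            [np.cos(2 * np.pi * t / 24.0), np.sin(2 * np.pi * t / 24.0), np.zeros(200)]
        )
        emb = lw.sliding_window_embed(v, window=24)
        centered = emb - emb.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        assert s[2] / s[0] < 1e-8  # rank 2: a closed planar ellipse

    def test_too_short_raises(self):
        with pytest.raises(ValidationError):
            lw.sliding_window_embed(np.zeros((10, 3)), window=24)


class TestMutualKnnGraph:
    def test_three_collinear_points_k1(self):
        # brute force: only the two closest-by-tie points are mutual
        pts = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        g = lw.mutual_knn_graph(pts, k=1)
        # 1's nearest is 0 (tie broken toward smaller index), so 0-1 is
        # mutual while 1-2 is not
        assert set(map(tuple, map(sorted, g.edges()))) == {(0, 1)}

    def test_subgraph_of_directed_knn(self, rng):
        pts = rng.standard_normal((40, 5))
        k = 6
        g = lw.mutual_knn_graph(pts, k=k)
        from scipy.spatial.distance import cdist

        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]
        for i, j in g.edges():
            assert j in nn[i] and i in nn[j]

    def test_dense_circle_connected_and_banded(self):
        ang = 2 * np.pi * np.arange(400) / 400
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        g = lw.mutual_knn_graph(pts, k=50)
        assert nx.is_connected(g)
        # locally banded: every edge spans < 30 positions around the circle
        for i, j in g.edges():
            assert min((i - j) % 400, (j - i) % 400) <= 30

    def test_k_too_large_raises(self):
        with pytest.raises(ValidationError):
            lw.mutual_knn_graph(np.zeros((10, 2)), k=10)


class TestLaplacianPhase:
    def test_cycle_graph_matches_closed_form(self):
        # closed form for C_n: eigenvalue 2 - 2 cos(2 pi / n) with a
        # sine/cosine eigenvector pair
        n = 60
        g = nx.cycle_graph(n)
        pts = np.zeros((n, 2))
        prof = laplacian_phase(g, pts, window=0)
        lam = 2.0 - 2.0 * np.cos(2.0 * np.pi / n)
        np.testing.assert_allclose(prof.eigvals, lam, atol=1e-9)
        # subspace angle between computed pair and the analytic pair
        t = np.arange(n)
        analytic = np.column_stack(
            [np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n)]
        )
        q1, _ = np.linalg.qr(prof.eigvecs)
        q2, _ = np.linalg.qr(analytic)
        s = np.linalg.svd(q1.T @ q2, compute_uv=False)
        assert np.arccos(np.clip(s.min(), -1, 1)) < 1e-6
        # phase strictly monotone mod 2 pi around the cycle
        unwrapped = np.unwrap(prof.phase)
        diffs = np.diff(unwrapped)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_constant_vector_excluded(self):
        g = nx.cycle_graph(30)
        prof = laplacian_phase(g, np.zeros((30, 2)), window=0)
        assert prof.eigvals.min() > 1e-6  # not the zero mode
        for v in prof.eigvecs.T:
            assert abs(v.sum()) < 1e-8  # orthogonal to the constant vector

    def test_disconnected_graph_raises(self):
        g = nx.union(nx.cycle_graph(20), nx.cycle_graph(15), rename=("a", "b"))
        g = nx.convert_node_labels_to_integers(g)
        with pytest.raises(GraphConnectivityError):
            laplacian_phase(g, np.zeros((35, 2)), window=0)

    def test_solenoid_phase_wraps_match_turn_count(self, clean_solenoid):
        trace, truth = clean_solenoid
        prof = phase_from_trace(trace, truth["lrr_span"])
        wraps = abs(prof.laplacian_winding[-1])
        span_len = truth["lrr_span"][1] - truth["lrr_span"][0]
        expected = (span_len - prof.window) / truth["period"]
        assert abs(wraps - expected) <= 1.0

    def test_phase_consistent_across_repeat_units(self, clean_solenoid):
        # ground-truth phase and laplacian phase agree up to a global
        # rotation/reflection: circular correlation > 0.9
        trace, truth = clean_solenoid
        a, b = truth["lrr_span"]
        prof = phase_from_trace(trace, (a, b))
        gt = truth["phase"][prof.residue_indices]
        est = prof.phase
        corr = np.abs(np.mean(np.exp(1j * (est - gt))))
        corr_ref = np.abs(np.mean(np.exp(1j * (-est - gt))))
        assert max(corr, corr_ref) > 0.9


class TestSwl2d:
    def test_exactly_linear_is_zero(self):
        w = np.arange(300.0) / 25.0
        prof = lw.swl2d(w, 1 / 25.0, window=24)
        np.testing.assert_allclose(prof.swl2d, 0.0, atol=1e-12)

    def test_plateau_localized_within_window(self):
        w = (np.arange(500.0) / 25.0).copy()
        w[255:] -= 10 / 25.0
        w[245:255] = w[245]
        prof = lw.swl2d(w, 1 / 25.0, window=24)
        amax = int(np.argmax(prof.swl2d))
        assert 245 - prof.window <= amax <= 255 + prof.window
        # flagged anomaly interval covers the plateau
        assert any(a <= 245 and b >= 255 for a, b in prof.anomalies)

    def test_homogeneity_under_scaling(self, rng):
        w = np.arange(200.0) / 25.0 + 0.1 * rng.standard_normal(200)
        base = lw.swl2d(w, 1 / 25.0, window=20)
        scaled = lw.swl2d(3.0 * w, 3.0 / 25.0, window=20)
        np.testing.assert_allclose(scaled.swl2d, 3.0 * base.swl2d, atol=1e-10)

    def test_too_short_raises(self):
        with pytest.raises(ValidationError):
            lw.swl2d(np.zeros(10), 0.0, window=24)
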