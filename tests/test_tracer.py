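"""Tracer: preprocessing, scoring, gradients, refinement, full traces."""

import numpy as np
import pytest

from minicircle.curves import ClosedCurve, align_closed_curves, curve_rmsd
from minicircle.synthetic import PopulationSpec, ShapeSpec, make_curve, rasterize
from minicircle.tracer import (Tracer, TracerConfig, _angle_penalty_gradient,
                               _interior_angles, _length_penalty_gradient,
                               preprocess, refine, score_polygon, subdivide,
                               trace)
from minicircle.volume import DensityVolume

L = 336 * 3.4


def _regular_polygon(n, perimeter, center=(0.0, 0.0, 0.0)):
    r = perimeter / (2 * n * np.sin(np.pi / n))
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    v = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(n)])
    return ClosedCurve(v + np.asarray(center))


def _zero_volume(edge=96, voxel=4.52):
    half = (edge - 1) / 2 * voxel
    return DensityVolume(np.zeros((edge, edge, edge), np.float32), voxel,
                         origin=np.array([-half, -half, -half]))


class TestConfig:
    def test_vertex_doubling_schedule_enforced(self):
        TracerConfig(n_init=5, n_final=20)  # 5 * 2^2
        with pytest.raises(ValueError, match="2\\*\\*k"):
            TracerConfig(n_init=5, n_final=12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            TracerConfig(w_length=-1.0)


class TestPreprocess:
    def test_zero_mean_unit_sd(self, circle_volume):
        cfg = TracerConfig(lowpass_sigma=5.0)
        out = preprocess(circle_volume, cfg)
        # no secondary components in a clean phantom: pure normalization
        assert abs(float(out.data.mean())) < 1e-6
        assert abs(float(out.data.std()) - 1.0) < 1e-6

    def test_lowpass_zero_is_identity_filter(self, circle_volume):
        out = preprocess(circle_volume, TracerConfig(lowpass_sigma=0.0))
        ref = circle_volume.data.astype(np.float64)
        ref = (ref - ref.mean()) / ref.std()
        assert np.allclose(out.data, ref, atol=1e-6)

    def test_distant_blob_removed(self, circle_curve, trace_pop):
        vol = rasterize(circle_curve, trace_pop)
        data = vol.data.copy()
        data[3:7, 3:7, 3:7] = 5.0  # disconnected bright blob in a corner
        noisy = DensityVolume(data, vol.voxel_size, vol.origin)
        out = preprocess(noisy, TracerConfig(lowpass_sigma=5.0))
        assert np.all(out.data[3:7, 3:7, 3:7] == 0.0)
        # the tube itself survives
        assert out.interpolate(circle_curve.vertices[0]) > 1.0

    def test_constant_volume_raises(self):
        flat = DensityVolume(np.ones((16, 16, 16), np.float32), 4.52)
        with pytest.raises(ValueError, match="no density"):
            preprocess(flat, TracerConfig())


class TestScorePolygon:
    def test_regular_polygon_in_zero_volume_scores_zero(self):
        cfg = TracerConfig(contour_length=1000.0)
        poly = _regular_polygon(20, 1000.0)
        sb = score_polygon(poly, _zero_volume(), cfg)
        assert sb.density == pytest.approx(0.0, abs=1e-12)
        assert sb.length_penalty == pytest.approx(0.0, abs=1e-9)
        assert sb.angle_penalty == pytest.approx(0.0, abs=1e-9)

    def test_displaced_vertex_increases_penalties(self):
        cfg = TracerConfig(contour_length=1000.0)
        poly = _regular_polygon(20, 1000.0)
        v = poly.vertices.copy()
        v[0] *= 1.3
        sb = score_polygon(ClosedCurve(v), _zero_volume(), cfg)
        assert sb.length_penalty > 0
        assert sb.angle_penalty > 0

    def test_density_term_on_circle_axis(self, circle_curve, circle_volume):
        cfg = TracerConfig(contour_length=L)
        poly = circle_curve.resample(20)
        sb = score_polygon(poly, circle_volume, cfg)
        # trilinear interpolation smooths the curved Gaussian peak by a few
        # percent (voxel 4.52 A against tube sigma 10 A)
        assert sb.density == pytest.approx(cfg.w_density * 20 * 1.0, rel=0.05)

    def test_vertex_outside_volume_identified(self, circle_volume):
        poly = _regular_polygon(20, 1000.0,
                                center=(0.0, 0.0, 10_000.0))
        with pytest.raises(ValueError, match="vertex 0"):
            score_polygon(poly, circle_volume, TracerConfig())


class TestPenaltyGradients:
    def test_match_numerical_differentiation(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(8, 3)) * 50
        lbar, tbar = 60.0, np.pi - 2 * np.pi / 8
        gl = _length_penalty_gradient(v, lbar)
        ga = _angle_penalty_gradient(v, tbar)
        eps = 1e-6

        def pens(vv):
            c = ClosedCurve(vv)
            return (np.sum((c.edge_lengths - lbar) ** 2),
                    np.sum((_interior_angles(vv) - tbar) ** 2))

        for i in range(8):
            for k in range(3):
                vp, vm = v.copy(), v.copy()
                vp[i, k] += eps
                vm[i, k] -= eps
                (lp, ap), (lm, am) = pens(vp), pens(vm)
                assert gl[i, k] == pytest.approx((lp - lm) / (2 * eps),
                                                 rel=1e-4, abs=1e-5)
                assert ga[i, k] == pytest.approx((ap - am) / (2 * eps),
                                                 rel=1e-3, abs=1e-6)


class TestSubdivide:
    def test_five_to_twenty(self):
        p = _regular_polygon(5, 1000.0)
        assert subdivide(p).n_vertices == 10
        assert subdivide(subdivide(p)).n_vertices == 20

    def test_square_perimeter_preserved(self):
        sq = ClosedCurve([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]])
        assert subdivide(sq).arc_length() == pytest.approx(40.0)


class TestRefine:
    def test_zero_volume_converges_toward_regular_polygon(self):
        cfg = TracerConfig(contour_length=1000.0, max_iters=400)
        rng = np.random.default_rng(2)
        v = _regular_polygon(10, 1000.0).vertices
        v = v + rng.normal(size=v.shape) * 15.0
        start = ClosedCurve(v)
        out, _, _ = refine(start, _zero_volume(), cfg)
        assert out.edge_lengths.var() < start.edge_lengths.var()
        assert (_interior_angles(out.vertices).var()
                < _interior_angles(start.vertices).var())

    def test_score_never_decreases(self, circle_curve, circle_volume):
        cfg = TracerConfig(contour_length=L)
        vol = preprocess(circle_volume, cfg)
        start = circle_curve.resample(20)
        s0 = score_polygon(start, vol, cfg).total
        out, _, _ = refine(start, vol, cfg)
        assert score_polygon(out, vol, cfg).total >= s0 - 1e-9

    def test_fixed_point_after_convergence(self, circle_curve,
                                           circle_volume):
        cfg = TracerConfig(contour_length=L, max_iters=500)
        vol = preprocess(circle_volume, cfg)
        once, _, _ = refine(circle_curve.resample(20), vol, cfg)
        twice, _, _ = refine(once, vol, cfg)
        move = np.linalg.norm(twice.vertices - once.vertices, axis=1).max()
        assert move < 0.1

    def test_displaced_circle_rmsd_decreases(self, circle_curve,
                                             circle_volume):
        cfg = TracerConfig(contour_length=L, max_iters=1)
        vol = preprocess(circle_volume, cfg)
        poly = ClosedCurve(circle_curve.resample(20).vertices
                           + np.array([20.0, 0.0, 0.0]))
        rmsds = [curve_rmsd(poly, circle_curve)]
        for _ in range(40):
            poly, _, _ = refine(poly, vol, cfg)
            rmsds.append(curve_rmsd(poly, circle_curve))
        assert rmsds[-1] < 2.0
        # essentially monotone approach to the axis
        assert all(b <= a + 0.3 for a, b in zip(rmsds, rmsds[1:]))


class TestTrace:
    def test_clean_circle_recovery(self, circle_curve, circle_volume):
        result = Tracer(circle_volume, contour_length=L).fit(seed=1)
        assert curve_rmsd(result.curve, circle_curve) < 5.0
        assert abs(result.curve.arc_length() - L) / L < 0.05
        assert result.converged
        assert result.curve.n_vertices == 20

    def test_summary_mentions_key_fields(self, circle_volume):
        result = Tracer(circle_volume, contour_length=L).fit(seed=1)
        text = result.summary()
        for token in ("perimeter", "agreement", "converged", "density"):
            assert token in text

    def test_empty_volume_raises(self):
        rng = np.random.default_rng(0)
        noise = DensityVolume(
            rng.normal(size=(32, 32, 32)).astype(np.float32), 4.52)
        # pure noise has no coherent component; tracing may or may not
        # converge, but a constant volume must fail loudly
        flat = DensityVolume(np.zeros((32, 32, 32), np.float32), 4.52)
        with pytest.raises(ValueError):
            trace(flat, TracerConfig())

    def test_double_length_contour(self):
        spec = ShapeSpec("open_circle", contour_length=672 * 3.4)
        curve = make_curve(spec, seed=2)
        pop = PopulationSpec(counts={}, margin=40.0,
                             contour_length=672 * 3.4)
        vol = rasterize(curve, pop)
        cfg = TracerConfig(contour_length=672 * 3.4, n_final=40)
        result = Tracer(vol, config=cfg).fit(seed=1)
        target = 672 * 3.4
        assert abs(result.curve.arc_length() - target) / target < 0.02


class TestAlignment:
    def test_multi_start_agreement_small_on_clean_circle(self, circle_volume):
        result = Tracer(circle_volume, contour_length=L).fit(seed=3)
        assert result.agreement < 10.0

    def test_align_handles_index_origin_ambiguity(self, circle_curve):
        a = circle_curve.resample(20)
        b = ClosedCurve(np.roll(a.vertices, 5, axis=0))
        d, shift, rev = align_closed_curves(a, b)
        assert d < 1e-9
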