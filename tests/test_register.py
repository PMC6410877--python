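"""Two-channel registration: affine fits, fiducial pairing, piecewise
correction, and TRE statistics."""

import numpy as np
import pytest

from nanodist import (
    AffineTransform,
    PiecewiseAffineModel,
    RegistrationModel,
    UncorrectableRegionError,
    build_registration,
    compute_tre,
    fit_affine,
    pair_fiducials,
    piecewise_transform,
)
from nanodist.simulate import quadratic_warp, simulate_fiducial_field


def _rot(deg):
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


class TestFitAffine:
    def test_identity(self):
        pts = np.random.default_rng(0).uniform(0, 1000, (20, 2))
        tr = fit_affine(pts, pts)
        assert np.allclose(tr.matrix, np.eye(2), atol=1e-9)
        assert np.allclose(tr.translation, 0, atol=1e-6)

    def test_exact_rotation_translation(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 80000, (50, 2))
        dst = src @ _rot(30).T + np.array([100.0, -50.0])
        tr = fit_affine(src, dst)
        assert np.max(np.abs(tr.apply(src) - dst)) < 1e-9

    def test_noisy_residual_rms(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(0, 80000, (100, 2))
        dst = src + rng.normal(0, 1.0, src.shape)  # 1 nm isotropic noise
        tr = fit_affine(src, dst)
        resid = dst - tr.apply(src)
        rms = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
        assert 0.9 <= rms <= 1.5

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_affine(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_collinear_rejected(self):
        src = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError):
            fit_affine(src, src)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(np.zeros((2, 2)), np.zeros(2))


class TestPairFiducials:
    def test_identical_sets_all_self_paired(self):
        pts = np.random.default_rng(3).uniform(0, 10000, (25, 2))
        pairs = pair_fiducials(pts, pts, max_pairing_dist=50.0)
        assert sorted(pairs) == [(i, i) for i in range(25)]

    def test_points_beyond_tolerance_unpaired(self):
        p1 = np.array([[0.0, 0.0]])
        p2 = np.array([[500.0, 0.0], [0.0, 500.0]])
        with pytest.raises(ValueError):
            pair_fiducials(p1, p2, max_pairing_dist=100.0)

    def test_simulated_offsets_paired_correctly(self):
        rng = np.random.default_rng(4)
        p1 = rng.uniform(0, 80000, (25, 2))
        p2 = p1 + rng.uniform(-10, 10, p1.shape)  # <= 10 nm offsets
        pairs = pair_fiducials(p1, p2, max_pairing_dist=200.0)
        assert sorted(pairs) == [(i, i) for i in range(25)]


class TestPiecewise:
    def test_equals_global_affine_for_affine_distortion(self):
        rng = np.random.default_rng(5)
        src = rng.uniform(0, 20000, (300, 2))
        affine = AffineTransform(_rot(2) * 1.001, np.array([30.0, -20.0]))
        dst = affine.apply(src)
        model = PiecewiseAffineModel(src=src, dst=dst, min_points=10,
                                     max_points=100, max_dist=5000.0)
        queries = rng.uniform(2000, 18000, (50, 2))
        out = piecewise_transform(model, queries)
        assert np.max(np.abs(out - affine.apply(queries))) < 1e-6

    def test_uncorrectable_region_reports_count(self):
        src = np.random.default_rng(6).uniform(0, 100, (12, 2))
        model = PiecewiseAffineModel(src=src, dst=src, min_points=10,
                                     max_points=100, max_dist=200.0)
        with pytest.raises(UncorrectableRegionError) as err:
            piecewise_transform(model, np.array([50000.0, 50000.0]))
        assert err.value.n_found == 0

    def test_leave_self_out_at_control_points(self):
        # a control point with a grossly wrong destination must not vote on
        # its own correction
        rng = np.random.default_rng(7)
        src = rng.uniform(0, 1000, (40, 2))
        dst = src.copy()
        dst[0] += 500.0  # corrupted control pair
        model = PiecewiseAffineModel(src=src, dst=dst, min_points=10,
                                     max_points=100, max_dist=5000.0)
        out = piecewise_transform(model, src[0])
        assert np.linalg.norm(out - src[0]) < np.linalg.norm(dst[0] - src[0]) / 2

    def test_parameter_validation(self):
        src = np.zeros((12, 2))
        with pytest.raises(ValueError):
            PiecewiseAffineModel(src=src, dst=src, min_points=20, max_points=10)
        with pytest.raises(ValueError):
            PiecewiseAffineModel(src=src, dst=src, max_dist=-1.0)


class TestTre:
    def test_pure_offset_gives_eq1_sigma_reg(self):
        # residual means (3, 4) nm -> sigma_reg = 5, not accepted
        model = RegistrationModel(affine=AffineTransform.identity())
        src = np.random.default_rng(8).uniform(0, 1000, (30, 2))
        q = compute_tre(model, src, src + np.array([3.0, 4.0]))
        assert q.mu_x == pytest.approx(3.0)
        assert q.mu_y == pytest.approx(4.0)
        assert q.sigma_reg == pytest.approx(5.0)
        assert not q.accepted

    def test_perfect_registration_accepted(self):
        model = RegistrationModel(affine=AffineTransform.identity())
        src = np.random.default_rng(9).uniform(0, 1000, (30, 2))
        q = compute_tre(model, src, src)
        assert q.sigma_reg == pytest.approx(0.0, abs=1e-12)
        assert q.accepted

    def test_eq1_identity_holds_on_noisy_data(self):
        rng = np.random.default_rng(10)
        model = RegistrationModel(affine=AffineTransform.identity())
        src = rng.uniform(0, 1000, (200, 2))
        q = compute_tre(model, src, src + rng.normal(0.5, 2.0, src.shape))
        assert q.sigma_reg == pytest.approx(np.hypot(q.mu_x, q.mu_y), abs=1e-12)


class TestEndToEnd:
    def test_composition_on_affine_distortion_is_exact(self):
        rng = np.random.default_rng(11)
        ch1 = rng.uniform(0, 20000, (400, 2))
        warp = AffineTransform(_rot(1) * 0.999, np.array([80.0, 40.0]))
        ch2 = warp.apply(ch1)
        model = build_registration(ch1, ch2, max_pairing_dist=300.0,
                                   max_dist=5000.0)
        resid = ch1 - model.transform(ch2)
        assert np.max(np.abs(resid)) < 1e-6

    def test_piecewise_beats_global_on_smooth_warp(self):
        # smooth nonlinear distortion over an 80 um field at bead densities
        # where every 2 um neighborhood holds enough control points
        warp = quadratic_warp(20.0, 80000.0)
        ch1a, ch2a = simulate_fiducial_field(8000, 80000.0, warp, 0.5, seed=1)
        ch1b, ch2b = simulate_fiducial_field(1200, 80000.0, warp, 0.5, seed=2)
        model_pw = build_registration(ch1a.points, ch2a.points,
                                      max_pairing_dist=300.0)
        model_gl = RegistrationModel(affine=model_pw.affine)
        pairs = pair_fiducials(ch1b.points, model_gl.transform(ch2b.points), 300.0)
        i1 = [i for i, _ in pairs]
        i2 = [j for _, j in pairs]
        q_gl = compute_tre(model_gl, ch2b.points[i2], ch1b.points[i1])
        q_pw = compute_tre(model_pw, ch2b.points[i2], ch1b.points[i1])
        rms_gl = np.hypot(q_gl.sigma_x, q_gl.sigma_y)
        rms_pw = np.hypot(q_pw.sigma_x, q_pw.sigma_y)
        assert rms_pw < rms_gl
        assert q_pw.accepted
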