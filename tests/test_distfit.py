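"""Distance estimators: error composition, MLE and NLLSQ fits, SEMs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanodist import (
    PairObservation,
    ParticleTrack,
    VectorDistance,
    combine_sigma_d,
    fit_p2d,
    fit_sigma_p2d,
    fit_vector,
    fit_vector_p2d,
    sem_bootstrap,
    sem_fisher,
    vector_average,
)


def _track(vectors, sigma=1.0, pid=0):
    obs = tuple(
        PairObservation(dx=dx, dy=dy, r=float(np.hypot(dx, dy)),
                        sigma_loc1_sq=sigma**2 / 2, sigma_loc2_sq=sigma**2 / 2,
                        sigma_reg=0.0, frame=i, particle_id=pid)
        for i, (dx, dy) in enumerate(vectors)
    )
    return ParticleTrack(particle_id=pid, observations=obs)


class TestCombineSigmaD:
    @pytest.mark.parametrize("args,expected", [
        ((0.0, 3.0, 4.0), 5.0),
        ((0.0, 0.0, 0.0), 0.0),
        ((1.0, 2.0, 2.0), 3.0),
    ])
    def test_quadrature_sum(self, args, expected):
        assert combine_sigma_d(*args) == pytest.approx(expected, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            combine_sigma_d(-1.0, 1.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0, 1e3), st.floats(0, 1e3), st.floats(0, 1e3),
           st.floats(1e-3, 1e3))
    def test_scale_equivariant_and_dominates_components(self, a, b, c, k):
        s = combine_sigma_d(a, b, c)
        assert combine_sigma_d(k * a, k * b, k * c) == pytest.approx(k * s, rel=1e-9)
        assert s >= max(a, b, c) - 1e-12


class TestPairObservation:
    def test_inconsistent_r_rejected(self):
        with pytest.raises(ValueError):
            PairObservation(dx=3.0, dy=4.0, r=6.0, sigma_loc1_sq=1.0,
                            sigma_loc2_sq=1.0, sigma_reg=0.0)

    def test_sigma_d_composition(self):
        o = PairObservation(dx=3.0, dy=4.0, r=5.0, sigma_loc1_sq=9.0,
                            sigma_loc2_sq=16.0, sigma_reg=0.0)
        assert o.sigma_d == pytest.approx(5.0)

    def test_track_requires_consistent_particle_id(self):
        o = PairObservation(dx=1.0, dy=0.0, r=1.0, sigma_loc1_sq=1.0,
                            sigma_loc2_sq=1.0, sigma_reg=0.0, particle_id=3)
        with pytest.raises(ValueError):
            ParticleTrack(particle_id=1, observations=(o,))


class TestFitP2D:
    def test_recovers_well_separated_distance(self, rice_sample):
        r = rice_sample(10.0, 1.0, 5000, seed=42)
        res = fit_p2d(r)
        assert res.converged
        assert res.mu_hat == pytest.approx(10.0, abs=0.1)
        assert res.sigma_d_hat == pytest.approx(1.0, abs=0.1)

    def test_degenerate_input_flagged(self):
        res = fit_p2d(np.full(10, 5.0))
        assert not res.converged

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValueError):
            fit_p2d([1.0, 2.0])

    def test_scale_equivariance(self, rice_sample):
        r = rice_sample(5.0, 2.0, 500, seed=7)
        c = 137.0
        res1 = fit_p2d(r)
        res2 = fit_p2d(c * r)
        assert res2.mu_hat == pytest.approx(c * res1.mu_hat, rel=1e-6)
        assert res2.sigma_d_hat == pytest.approx(c * res1.sigma_d_hat, rel=1e-6)


class TestFitSigmaP2D:
    def test_recovers_distance_equal_to_uncertainty(self, rice_sample):
        # d = 1, sigma_d = 1: the regime where the two-parameter fit fails
        r = rice_sample(1.0, 1.0, 10000, seed=1)
        res = fit_sigma_p2d((r, 1.0))
        assert res.converged
        assert res.mu_hat == pytest.approx(1.0, abs=0.06)

    def test_noise_free_limit(self):
        r0 = 7.5
        res = fit_sigma_p2d(([r0] * 20, [1e-9] * 20))
        assert res.mu_hat == pytest.approx(r0, rel=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            fit_sigma_p2d(([1.0, 2.0], [1.0, 0.0]))

    def test_heterogeneous_sigma_calibrated_coverage(self):
        # per-pair sigma_d from a Gamma variance mixture: mu_hat within 2 SEM
        # of the truth in >= 95% of independent runs
        d, n_runs = 10.0, 100
        hits = 0
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            var = rng.gamma(4.0, 6.25, size=500)  # mean variance 25 nm^2
            sigma = np.sqrt(var)
            r = np.hypot(d + rng.normal(0, sigma), rng.normal(0, sigma))
            res = fit_sigma_p2d((r, sigma))
            if abs(res.mu_hat - d) <= 2 * res.sem:
                hits += 1
        # nominal 2-SEM coverage is ~95%; allow one-sided binomial scatter
        assert hits >= 90

    def test_accepts_pair_observation_records(self):
        obs = [
            PairObservation(dx=10.0, dy=0.0, r=10.0, sigma_loc1_sq=0.5,
                            sigma_loc2_sq=0.5, sigma_reg=0.0)
        ] * 5
        res = fit_sigma_p2d(obs)
        assert res.mu_hat == pytest.approx(np.sqrt(10.0**2 - 1.0), abs=0.5)


class TestVectorAverage:
    def test_single_frame_is_frame_distance(self):
        v = vector_average(_track([(3.0, 4.0)]))
        assert v.r_vec == pytest.approx(5.0)
        assert v.n_frames == 1

    def test_component_wise_mean_beats_distance_mean(self):
        # frames (3,0) and (0,4): frame distances average to 3.5 while the
        # averaged vector is (1.5, 2) with norm 2.5
        v = vector_average(_track([(3.0, 0.0), (0.0, 4.0)]))
        assert v.r_vec == pytest.approx(2.5)

    def test_opposite_vectors_cancel(self):
        v = vector_average(_track([(2.0, 0.0), (-2.0, 0.0)]))
        assert v.r_vec == pytest.approx(0.0)

    def test_variance_reduction_against_frame_distances(self):
        rng = np.random.default_rng(3)
        d, sigma, P, F = 5.0, 4.0, 400, 8
        dx = d + rng.normal(0, sigma, (P, F))
        dy = rng.normal(0, sigma, (P, F))
        frame_r = np.hypot(dx, dy)
        r_vec = np.hypot(dx.mean(axis=1), dy.mean(axis=1))
        assert r_vec.std() < frame_r.std()


class TestFitVector:
    def test_symmetric_sample_centered(self):
        rng = np.random.default_rng(0)
        rv = rng.normal(10.0, 1.0, 500)
        res = fit_vector(rv, n_boot=0)
        assert res.mu_hat == pytest.approx(10.0, abs=0.15)

    def test_constant_sample(self):
        res = fit_vector(np.array([4.2, 4.2, 4.2]), n_boot=0)
        assert res.mu_hat == pytest.approx(4.2)

    def test_bootstrap_requires_seed(self):
        with pytest.raises(ValueError):
            fit_vector(np.array([1.0, 2.0, 3.0]), n_boot=10, seed=None)


class TestFitVectorP2D:
    def test_agrees_with_mle_on_clean_sample(self, rice_sample):
        rv = rice_sample(10.0, 3.0, 1000, seed=11)
        nllsq = fit_vector_p2d(rv, n_boot=200, seed=5)
        mle = fit_p2d(rv)
        assert abs(nllsq.mu_hat - mle.mu_hat) <= 2 * max(nllsq.sem, 1e-6)

    def test_robust_to_uniform_outliers(self, rice_sample):
        # 5% background on [0, 4d] shifts the NLLSQ estimate by no more than
        # the MLE estimate on the same data (paired comparison, 5 seeds)
        d = 10.0
        nllsq_disc, mle_disc = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            rv = rice_sample(d, 2.0 * d / np.sqrt(20), 1000, seed=100 + seed)
            n_out = 50
            rv[:n_out] = rng.uniform(0, 4 * d, n_out)
            nllsq_disc.append(fit_vector_p2d(rv, n_boot=0).mu_hat / d - 1)
            mle_disc.append(fit_p2d(rv).mu_hat / d - 1)
        assert abs(np.mean(nllsq_disc)) <= abs(np.mean(mle_disc)) + 0.02

    def test_cutoff_drops_gross_outliers(self, rice_sample):
        rv = np.concatenate([rice_sample(10.0, 1.0, 500, seed=2), [500.0]])
        res = fit_vector_p2d(rv, n_boot=0, cutoff=50.0)
        assert res.n_used == 500

    def test_accepts_vector_distance_records(self):
        vds = [VectorDistance(particle_id=i, r_vec=10.0 + 0.1 * (i % 5),
                              n_frames=3, sigma_d_vec=1.0) for i in range(30)]
        res = fit_vector_p2d(vds, n_boot=0)
        assert res.mu_hat == pytest.approx(10.2, abs=0.3)


class TestSems:
    def test_fisher_matches_gaussian_limit(self, rice_sample):
        # sigma_d << mu: information is Gaussian, SEM ~ sigma / sqrt(n)
        mu, sigma, n = 50.0, 1.0, 400
        r = rice_sample(mu, sigma, n, seed=3)
        res = fit_sigma_p2d((r, sigma))
        assert res.sem == pytest.approx(sigma / np.sqrt(n), rel=0.10)

    def test_fisher_single_observation(self, rice_sample):
        r = rice_sample(50.0, 2.0, 1, seed=4)
        res = fit_sigma_p2d((r, 2.0))
        assert res.sem == pytest.approx(2.0, rel=0.10)

    def test_fisher_scales_with_root_n(self, rice_sample):
        mu, sigma = 20.0, 2.0
        sems = []
        for n in (500, 1000, 2000):
            r = rice_sample(mu, sigma, n, seed=n)
            sems.append(fit_sigma_p2d((r, sigma)).sem)
        assert sems[0] / sems[1] == pytest.approx(np.sqrt(2.0), rel=0.10)
        assert sems[1] / sems[2] == pytest.approx(np.sqrt(2.0), rel=0.10)

    def test_bootstrap_deterministic_and_degenerate(self):
        data = np.full(50, 3.3)
        fitter = lambda d: fit_vector(d, n_boot=0)
        a = sem_bootstrap(data, fitter, n_boot=50, seed=9)
        b = sem_bootstrap(data, fitter, n_boot=50, seed=9)
        assert a == b
        assert a == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_matches_fisher_when_well_posed(self, rice_sample):
        mu, sigma, n = 20.0, 4.0, 300
        r = rice_sample(mu, sigma, n, seed=8)
        res = fit_sigma_p2d((r, sigma))
        boot = sem_bootstrap(
            np.asarray(r), lambda d: fit_sigma_p2d((d, sigma)),
            n_boot=200, seed=1,
        )
        assert boot == pytest.approx(res.sem, rel=0.30)

    def test_bootstrap_rejects_tiny_n_boot(self):
        with pytest.raises(ValueError):
            sem_bootstrap(np.arange(5.0), lambda d: fit_vector(d, n_boot=0),
                          n_boot=1, seed=0)

    def test_sem_fisher_public_wrapper(self, rice_sample):
        r = rice_sample(30.0, 2.0, 500, seed=12)
        res = fit_sigma_p2d((r, 2.0))
        assert sem_fisher(res, (r, 2.0)) == pytest.approx(res.sem, rel=1e-6)
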