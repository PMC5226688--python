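"""Spatial covariance, GLS/kriging oracles, and ML parameter recovery."""

import numpy as np
import pytest
from scipy import linalg

from histexpo.kriging import (CovarianceParams, UniversalKriging, exponential_covariance,
                              fit_covariance_pooled, great_circle_km,
                              pairwise_distances_km, simple_krige)


def toy_layout(n, seed=0, span=5.0):
    rng = np.random.default_rng(seed)
    lon = -100.0 + span * rng.random(n)
    lat = 35.0 + span * rng.random(n)
    return np.column_stack([lon, lat])


class TestDistances:
    def test_identity_and_symmetry(self):
        assert great_circle_km(-100, 40, -100, 40) == 0.0
        pts = toy_layout(6, seed=1, span=40)
        D = pairwise_distances_km(pts)
        np.testing.assert_allclose(D, D.T, atol=1e-9)
        assert (np.diag(D) == 0).all()

    def test_quarter_meridian(self):
        # pole-to-equator along a meridian: pi/2 * R
        d = great_circle_km(0, 0, 0, 90)
        assert d == pytest.approx(np.pi / 2 * 6371.0088, rel=1e-12)


class TestCovarianceFunction:
    def test_nugget_only_at_zero_distance(self):
        p = CovarianceParams(100.0, 2.0, 0.5)
        d = np.array([0.0, 1e-9, 50.0])
        c = exponential_covariance(d, p)
        assert c[0] == pytest.approx(2.5)
        assert c[1] == pytest.approx(2.0 * np.exp(-1e-9 / 100.0))

    def test_monotone_nonincreasing(self):
        p = CovarianceParams(150.0, 1.0, 0.2)
        h = np.linspace(1e-6, 2000, 200)
        c = exponential_covariance(h, p)
        assert (np.diff(c) <= 0).all()

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            CovarianceParams(-1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            CovarianceParams(10.0, -0.1, 0.1)


class TestGLSOracle:
    def test_profiled_alpha_equals_closed_form_gls(self):
        # n=6, fixed covariance: alpha must equal (X' S^-1 X)^-1 X' S^-1 y
        coords = toy_layout(6, seed=2)
        rng = np.random.default_rng(3)
        design = np.column_stack([np.ones(6), rng.standard_normal((6, 2))])
        y = rng.standard_normal(6) + design @ np.array([1.0, 0.5, -0.3])
        p = CovarianceParams(80.0, 1.2, 0.3)
        uk = UniversalKriging(optimize=False, range_km=80.0, partial_sill=1.2, nugget=0.3,
                              jitter=0.0)
        uk.fit(np.column_stack([coords, design[:, 1:]]), y)
        D = pairwise_distances_km(coords)
        S = 1.2 * np.exp(-D / 80.0) + 0.3 * np.eye(6)
        Si = np.linalg.inv(S)
        alpha = np.linalg.solve(design.T @ Si @ design, design.T @ Si @ y)
        np.testing.assert_allclose(uk.alpha_, alpha, atol=1e-8)

    def test_predictor_matches_kriging_equations(self):
        # n=5 toy, all parameters fixed: x0'a + c0' S^-1 (y - X a)
        coords = toy_layout(5, seed=4)
        new = toy_layout(3, seed=5)
        rng = np.random.default_rng(6)
        design = np.column_stack([np.ones(5), rng.standard_normal(5)])
        new_design = np.column_stack([np.ones(3), rng.standard_normal(3)])
        y = rng.standard_normal(5)
        uk = UniversalKriging(optimize=False, range_km=120.0, partial_sill=0.8,
                              nugget=0.2, jitter=0.0)
        uk.fit(np.column_stack([coords, design[:, 1:]]), y)
        pred = uk.predict(np.column_stack([new, new_design[:, 1:]]))
        D = pairwise_distances_km(coords)
        S = 0.8 * np.exp(-D / 120.0) + 0.2 * np.eye(5)
        Si = np.linalg.inv(S)
        alpha = np.linalg.solve(design.T @ Si @ design, design.T @ Si @ y)
        c0 = 0.8 * np.exp(-pairwise_distances_km(new, coords) / 120.0)
        expect = new_design @ alpha + c0 @ Si @ (y - design @ alpha)
        np.testing.assert_allclose(pred, expect, atol=1e-10)

    def test_zero_nugget_exact_interpolation(self):
        coords = toy_layout(8, seed=7)
        rng = np.random.default_rng(8)
        y = rng.standard_normal(8)
        uk = UniversalKriging(optimize=False, range_km=200.0, partial_sill=1.0,
                              nugget=0.0, jitter=1e-12)
        uk.fit(coords, y)
        np.testing.assert_allclose(uk.predict(coords), y, atol=1e-6)

    def test_zero_sill_pure_regression(self):
        coords = toy_layout(12, seed=9)
        rng = np.random.default_rng(10)
        x = rng.standard_normal(12)
        y = 2.0 + 0.5 * x + 0.1 * rng.standard_normal(12)
        uk = UniversalKriging(optimize=False, range_km=100.0, partial_sill=0.0,
                              nugget=0.3)
        uk.fit(np.column_stack([coords, x]), y)
        new_coords = toy_layout(4, seed=11)
        xn = rng.standard_normal(4)
        pred = uk.predict(np.column_stack([new_coords, xn]))
        np.testing.assert_allclose(pred, uk.alpha_[0] + uk.alpha_[1] * xn, atol=1e-10)

    def test_duplicate_site_prediction_no_singularity(self):
        coords = toy_layout(6, seed=12)
        y = np.random.default_rng(13).standard_normal(6)
        uk = UniversalKriging(optimize=False, range_km=150.0, partial_sill=1.0,
                              nugget=0.2)
        uk.fit(coords, y)
        pred = uk.predict(coords[:1])
        assert np.isfinite(pred).all()


class TestLikelihoodFit:
    def test_loglik_not_below_initialization(self):
        coords = toy_layout(40, seed=14, span=15)
        rng = np.random.default_rng(15)
        y = rng.standard_normal(40)
        init = CovarianceParams(50.0, 0.5, 0.5)
        fixed = UniversalKriging(optimize=False, range_km=50.0, partial_sill=0.5,
                                 nugget=0.5).fit(coords, y)
        fitted = UniversalKriging(range_km=50.0, partial_sill=0.5, nugget=0.5,
                                  random_state=0).fit(coords, y)
        assert fitted.loglik_ >= fixed.loglik_ - 1e-6

    def test_parameter_recovery_ml(self):
        # simulate fields with known (phi, s2, t2) and recover by ML; a single
        # realization identifies the range weakly, so assert on the median
        # error over three independent datasets
        truth = CovarianceParams(200.0, 1.0, 0.2)
        errs = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            n = 300
            lon = rng.uniform(-120, -70, n)
            lat = rng.uniform(27, 47, n)
            # tight clustered pairs identify the nugget
            lon[225:] = lon[:75] + 0.02 * rng.standard_normal(75)
            lat[225:] = lat[:75] + 0.02 * rng.standard_normal(75)
            coords = np.column_stack([lon, lat])
            x = rng.standard_normal(n)
            D = pairwise_distances_km(coords)
            S = truth.partial_sill * np.exp(-D / truth.range_km) + truth.nugget * np.eye(n)
            y = (1.0 + 0.5 * x
                 + np.linalg.cholesky(S + 1e-10 * np.eye(n)) @ rng.standard_normal(n))
            uk = UniversalKriging(random_state=0).fit(np.column_stack([coords, x]), y)
            c = uk.covariance_
            errs.append([abs(c.range_km - truth.range_km) / truth.range_km,
                         abs(c.partial_sill - truth.partial_sill) / truth.partial_sill,
                         abs(c.nugget - truth.nugget) / truth.nugget])
            np.testing.assert_allclose(uk.alpha_, [1.0, 0.5],
                                       atol=3.0 * np.max(uk.alpha_se_))
        med = np.median(np.asarray(errs), axis=0)
        assert med[0] <= 0.5   # range
        assert med[1] <= 0.25  # partial sill
        assert med[2] <= 0.25  # nugget

    def test_rank_deficient_design_rejected(self):
        coords = toy_layout(10, seed=17)
        x = np.ones(10)  # duplicates the intercept
        with pytest.raises(ValueError, match="rank"):
            UniversalKriging().fit(np.column_stack([coords, x]), np.arange(10.0))


class TestPooledResiduals:
    def test_white_noise_attributed_to_nugget(self):
        rng = np.random.default_rng(18)
        coords = toy_layout(80, seed=18, span=40)
        coords[60:] = coords[:20] + 0.02 * rng.standard_normal((20, 2))
        groups = [(coords, 0.5 * rng.standard_normal(80)) for _ in range(12)]
        params, ll, conv = fit_covariance_pooled(groups, random_state=0)
        total = params.partial_sill + params.nugget
        assert total == pytest.approx(0.25, rel=0.15)
        assert params.partial_sill <= 0.05  # essentially no spatial structure

    def test_gp_parameter_recovery(self):
        rng = np.random.default_rng(19)
        truth = CovarianceParams(250.0, 0.8, 0.2)
        groups = []
        base = toy_layout(150, seed=20, span=40)
        base[120:] = base[:30] + 0.1 * rng.standard_normal((30, 2))
        D = pairwise_distances_km(base)
        S = truth.partial_sill * np.exp(-D / truth.range_km) + truth.nugget * np.eye(150)
        L = np.linalg.cholesky(S + 1e-10 * np.eye(150))
        for _ in range(12):
            groups.append((base, L @ rng.standard_normal(150)))
        params, _, _ = fit_covariance_pooled(groups, random_state=0)
        assert abs(params.range_km - 250.0) / 250.0 <= 0.5
        assert abs(params.partial_sill - 0.8) / 0.8 <= 0.25
        assert abs(params.nugget - 0.2) / 0.2 <= 0.25

    def test_pooled_likelihood_equals_bruteforce_sum(self):
        # two independent years: summed objective equals the joint
        # block-diagonal Gaussian log-likelihood
        rng = np.random.default_rng(21)
        g1 = (toy_layout(7, seed=22), rng.standard_normal(7))
        g2 = (toy_layout(9, seed=23), rng.standard_normal(9))
        p = CovarianceParams(100.0, 0.7, 0.3)

        def gauss_ll(coords, v):
            S = 0.7 * np.exp(-pairwise_distances_km(coords) / 100.0) + 0.3 * np.eye(len(v))
            sign, logdet = np.linalg.slogdet(S)
            return -0.5 * (logdet + v @ np.linalg.solve(S, v) + len(v) * np.log(2 * np.pi))

        from histexpo.kriging import _nll_profile
        theta = np.log([100.0, 0.7, 0.3])
        total = sum(_nll_profile(theta, pairwise_distances_km(c), None, v, "ml", 0.0)
                    for c, v in [g1, g2])
        brute = -(gauss_ll(*g1) + gauss_ll(*g2))
        assert total == pytest.approx(brute, abs=1e-8)


def test_simple_krige_zero_mean_interpolation():
    coords = toy_layout(10, seed=24)
    vals = np.random.default_rng(25).standard_normal(10)
    p = CovarianceParams(150.0, 1.0, 0.0)
    np.testing.assert_allclose(simple_krige(p, coords, vals, coords, jitter=1e-12),
                               vals, atol=1e-6)
    far = np.array([[-60.0, 70.0]])  # thousands of km away: shrink to prior mean 0
    assert abs(simple_krige(p, coords, vals, far)[0]) < 0.05


def test_reml_fit_runs_and_matches_ml_closely():
    # on a moderately sized field REML and ML agree on the variance scale
    rng = np.random.default_rng(30)
    n = 120
    coords = toy_layout(n, seed=31, span=30)
    coords[100:] = coords[:20] + 0.02 * rng.standard_normal((20, 2))
    x = rng.standard_normal(n)
    truth = CovarianceParams(150.0, 0.5, 0.1)
    D = pairwise_distances_km(coords)
    S = truth.partial_sill * np.exp(-D / truth.range_km) + truth.nugget * np.eye(n)
    y = 0.5 * x + np.linalg.cholesky(S + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
    X = np.column_stack([coords, x])
    ml = UniversalKriging(method="ml", random_state=0).fit(X, y)
    reml = UniversalKriging(method="reml", random_state=0).fit(X, y)
    assert reml.covariance_.sill() == pytest.approx(ml.covariance_.sill(), rel=0.3)
    np.testing.assert_allclose(reml.alpha_, ml.alpha_, atol=0.2)
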