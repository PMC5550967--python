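"""MCAP core: metamodel fit, error separation, cut-off, CI extraction."""

import numpy as np
import pytest
from scipy import stats

from mcprofile import (
    ProfilePoints,
    combine_se,
    compute_cutoff,
    extract_ci,
    fit_quadratic_metamodel,
    mcap,
    se_mc_delta_method,
    se_stat_from_curvature,
    smooth_profile,
)
from mcprofile.errors import InsufficientPointsError, NonConcaveFitError
from mcprofile.loess import SmootherSpec
from mcprofile.mcap import QuadraticFit

from conftest import wls_quadratic_oracle

CHI_HALF_95 = stats.chi2.ppf(0.95, 1) / 2.0  # 1.9207...


def make_fit(b, c, cov_bc):
    cov = np.zeros((3, 3))
    cov[1:, 1:] = cov_bc
    return QuadraticFit(a=0.0, b=b, c=c, cov=cov, residual_sd=1.0,
                        weights=np.ones(5))


class TestQuadraticMetamodel:
    def test_exact_quadratic_recovered_with_zero_covariance(self, quadratic_points):
        fit = fit_quadratic_metamodel(
            quadratic_points, np.ones(len(quadratic_points))
        )
        np.testing.assert_allclose(fit.coef, [-1.0, 2.0, -0.5], atol=1e-9)
        np.testing.assert_allclose(fit.cov, 0.0, atol=1e-12)
        assert fit.vertex == pytest.approx(2.0)

    def test_matches_hand_solved_normal_equations(self):
        phi = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        ll = np.array([-3.9, -1.2, 0.1, -0.8, -4.1])
        fit = fit_quadratic_metamodel(ProfilePoints(phi, ll), np.ones(5))
        expected = wls_quadratic_oracle(phi, ll, np.ones(5))
        np.testing.assert_allclose(fit.coef, expected, atol=1e-10)

    def test_precision_weights_scale_invariant(self, noisy_concave_points):
        w = np.linspace(0.5, 1.5, len(noisy_concave_points))
        f1 = fit_quadratic_metamodel(noisy_concave_points, w)
        f2 = fit_quadratic_metamodel(noisy_concave_points, 2.0 * w)
        np.testing.assert_allclose(f1.coef, f2.coef, rtol=1e-12)
        np.testing.assert_allclose(f1.cov, f2.cov, rtol=1e-9)

    def test_covariance_is_symmetric_psd(self, noisy_concave_points):
        fit = fit_quadratic_metamodel(
            noisy_concave_points, np.ones(len(noisy_concave_points))
        )
        np.testing.assert_allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) >= -1e-12)

    def test_convex_profile_rejected(self):
        phi = np.linspace(-1, 1, 8)
        points = ProfilePoints(phi, phi**2)
        with pytest.raises(NonConcaveFitError, match="widen the profile"):
            fit_quadratic_metamodel(points, np.ones(8))

    def test_too_few_positive_weights_rejected(self, quadratic_points):
        w = np.zeros(len(quadratic_points))
        w[:3] = 1.0
        with pytest.raises(InsufficientPointsError):
            fit_quadratic_metamodel(quadratic_points, w)


class TestErrorSeparation:
    @pytest.mark.parametrize(
        "c,expected", [(-0.5, 1.0), (-2.0, 0.5), (-1.0 / (2 * 0.32**2), 0.32)]
    )
    def test_se_stat_inverse_curvature(self, c, expected):
        fit = make_fit(b=0.0, c=c, cov_bc=np.zeros((2, 2)))
        assert se_stat_from_curvature(fit) == pytest.approx(expected)

    def test_se_mc_gradient_components(self):
        # Var(b)=v only: se_mc = sqrt(v)/(2|c|)
        fit = make_fit(b=0.7, c=-1.0, cov_bc=np.diag([0.09, 0.0]))
        assert se_mc_delta_method(fit) == pytest.approx(0.3 / 2.0)
        # b=0: Var(c) does not contribute
        fit = make_fit(b=0.0, c=-2.0, cov_bc=np.diag([0.04, 5.0]))
        assert se_mc_delta_method(fit) == pytest.approx(0.2 / 4.0)

    def test_se_mc_monte_carlo_oracle(self, rng):
        """Delta-method SE matches resimulated vertex spread within 5%.

        The regression covariance is built from the known noise scale so
        the check isolates the delta-method propagation itself.
        """
        phi = np.linspace(-1.0, 1.0, 41)
        a, b, c, sd = 0.0, 0.3, -1.5, 0.25
        mean_ll = a + b * phi + c * phi**2
        X = np.vander(phi, 3, increasing=True)
        cov = sd**2 * np.linalg.inv(X.T @ X)
        fit = QuadraticFit(a=a, b=b, c=c, cov=cov, residual_sd=sd,
                           weights=np.ones(phi.size))
        se_mc = se_mc_delta_method(fit)

        pinv = np.linalg.pinv(X)
        noise = rng.normal(0, sd, size=(10_000, phi.size))
        coefs = (mean_ll + noise) @ pinv.T
        vertices = -coefs[:, 1] / (2.0 * coefs[:, 2])
        assert se_mc == pytest.approx(vertices.std(), rel=0.05)

    def test_combine_se_quadrature(self):
        assert combine_se(0.3, 0.4) == pytest.approx(0.5)
        assert combine_se(0.7, 0.0) == pytest.approx(0.7)
        fit_total = combine_se(0.32, 0.151)
        assert fit_total**2 == pytest.approx(0.32**2 + 0.151**2)


class TestCutoff:
    def test_zero_mc_error_reduces_to_chi2(self):
        for s in (0.01, 0.32, 5.0):
            assert compute_cutoff(s, 0.0, 0.05) == pytest.approx(CHI_HALF_95)

    def test_monotone_in_se_mc_and_level(self):
        base = compute_cutoff(0.3, 0.1, 0.05)
        assert compute_cutoff(0.3, 0.2, 0.05) > base
        assert compute_cutoff(0.3, 0.1, 0.01) > base

    def test_invalid_inputs(self):
        with pytest.raises(NonConcaveFitError):
            compute_cutoff(0.0, 0.1, 0.05)
        with pytest.raises(ValueError):
            compute_cutoff(0.3, 0.1, 1.5)
        with pytest.raises(ValueError):
            compute_cutoff(0.3, -0.1, 0.05)


class TestExtractCI:
    def test_closed_form_level_set_on_quadratic(self):
        a, b, c = -1.0, 2.0, -0.5
        phi = np.linspace(-4.0, 8.0, 40)
        sp = smooth_profile(phi, a + b * phi + c * phi**2, SmootherSpec(0.75),
                            grid_size=4000)
        delta = 1.5
        (lo, hi), lo_open, hi_open, nonconvex = extract_ci(sp, delta)
        vertex = -b / (2 * c)
        half = np.sqrt(delta / (-c))
        assert lo == pytest.approx(vertex - half, abs=2e-3)
        assert hi == pytest.approx(vertex + half, abs=2e-3)
        assert not (lo_open or hi_open or nonconvex)

    def test_cutoff_beyond_profile_drop_gives_open_interval(self):
        phi = np.linspace(-1.0, 1.0, 20)
        sp = smooth_profile(phi, -0.1 * phi**2, SmootherSpec(1.0))
        (lo, hi), lo_open, hi_open, _ = extract_ci(sp, 50.0)
        assert (lo, hi) == (-1.0, 1.0)
        assert lo_open and hi_open

    def test_bimodal_profile_flagged_and_hull_returned(self):
        phi = np.linspace(-3.0, 3.0, 61)
        # two humps at +-1.8 with a dip at zero deeper than the cut-off
        ll = np.exp(-3 * (phi - 1.8) ** 2) + np.exp(-3 * (phi + 1.8) ** 2)
        sp = smooth_profile(phi, 10 * ll, SmootherSpec(0.25), grid_size=2000)
        (lo, hi), lo_open, hi_open, nonconvex = extract_ci(sp, 5.0)
        assert nonconvex
        assert lo < -1.0 and hi > 1.0


class TestMCAPPipeline:
    def test_noiseless_quadratic_reduces_to_exact_ci(self, quadratic_points):
        r = mcap(quadratic_points, span=0.75, grid_size=2000)
        assert r.se_mc == pytest.approx(0.0, abs=1e-7)
        assert r.delta == pytest.approx(CHI_HALF_95, rel=1e-6)
        half = np.sqrt(CHI_HALF_95 / 0.5)
        assert r.ci[0] == pytest.approx(2.0 - half, abs=2e-3)
        assert r.ci[1] == pytest.approx(2.0 + half, abs=2e-3)

    def test_recovers_metamodel_coefficients_from_noisy_profile(self, rng):
        a, b, c, sd = 5.0, -1.0, -2.0, 0.4
        phi = np.linspace(-1.5, 1.0, 40)
        ll = a + b * phi + c * phi**2 + rng.normal(0, sd, phi.size)
        r = mcap((phi, ll), span=0.9)
        ses = np.sqrt(np.diag(r.fit.cov))
        for got, truth, se in zip(r.fit.coef, (a, b, c), ses):
            assert abs(got - truth) < 3.0 * max(se, 1e-12)

    def test_ci_contains_smoothed_argmax(self, noisy_concave_points):
        r = mcap(noisy_concave_points)
        assert r.ci[0] <= r.phi_hat <= r.ci[1]

    def test_se_total_quadrature_invariant(self, noisy_concave_points):
        r = mcap(noisy_concave_points)
        assert r.se_total**2 == pytest.approx(r.se_stat**2 + r.se_mc**2)
        assert r.delta >= CHI_HALF_95

    def test_vertical_shift_equivariance(self, noisy_concave_points):
        """A constant Monte Carlo bias shifts the profile but not the CI."""
        r1 = mcap(noisy_concave_points)
        shifted = (noisy_concave_points.phi, noisy_concave_points.loglik + 137.0)
        r2 = mcap(shifted)
        assert r2.fit.a == pytest.approx(r1.fit.a + 137.0, rel=1e-9)
        assert r2.se_stat == pytest.approx(r1.se_stat, rel=1e-9)
        assert r2.se_mc == pytest.approx(r1.se_mc, rel=1e-9)
        assert r2.delta == pytest.approx(r1.delta, rel=1e-9)
        np.testing.assert_allclose(r2.ci, r1.ci, rtol=1e-7)

    def test_width_dominates_naive_cutoff(self, noisy_concave_points):
        r = mcap(noisy_concave_points)
        (nlo, nhi), *_ = extract_ci(r.smoothed, CHI_HALF_95)
        assert r.ci[0] <= nlo and r.ci[1] >= nhi

    def test_result_serializes_to_plain_json(self, noisy_concave_points):
        import json

        record = mcap(noisy_concave_points).to_dict()
        parsed = json.loads(json.dumps(record))
        assert parsed["schema"] == 1
        assert parsed["ci_lower"] < parsed["ci_upper"]


class TestProfilePoints:
    def test_sorted_and_duplicates_preserved(self):
        p = ProfilePoints([2.0, 1.0, 1.0, 3.0], [4.0, 5.0, 6.0, 7.0])
        np.testing.assert_array_equal(p.phi, [1.0, 1.0, 2.0, 3.0])
        np.testing.assert_array_equal(p.loglik, [5.0, 6.0, 4.0, 7.0])

    def test_rejects_bad_input(self):
        with pytest.raises(InsufficientPointsError):
            ProfilePoints([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            ProfilePoints([1.0, 2.0, 3.0, np.nan], [0.0] * 4)
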