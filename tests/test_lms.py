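"""Parametric LMS route: penalized likelihood objective, spline penalty
algebra, Box–Cox transforms, centiles and parameter recovery."""

import math

import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.interpolate import CubicSpline
from scipy.stats import norm

import normbench as nb
from normbench import lms as lms_mod
from normbench.lms import (
    FitError,
    LMSFitConfig,
    LMSModel,
    alpha_from_edf,
    penalty_matrix,
    spline_basis,
)


def constant_model(L, M, S, knots=(5.0, 8.0, 11.0, 14.0), alphas=(0.0, 0.0, 0.0)):
    knots = np.asarray(knots, dtype=float)
    return LMSModel(
        knots=knots,
        coef_L=np.full(knots.size, float(L)),
        coef_M=np.full(knots.size, math.log(M)),
        coef_S=np.full(knots.size, math.log(S)),
        alpha_L=alphas[0],
        alpha_M=alphas[1],
        alpha_S=alphas[2],
        age_range=(float(knots[0]), float(knots[-1])),
    )


def boxcox_loglik_oracle(y, t, L_fun, M_fun, S_fun):
    """Independent term-by-term sum of the Box–Cox log-likelihood kernel."""
    total = 0.0
    for yi, ti in zip(y, t):
        L, M, S = L_fun(ti), M_fun(ti), S_fun(ti)
        if abs(L) >= 1e-8:
            z = ((yi / M) ** L - 1.0) / (L * S)
        else:
            z = math.log(yi / M) / S
        total += L * math.log(yi / M) - math.log(S) - 0.5 * z * z
    return total


class TestPenaltyAlgebra:
    def test_gram_matrix_matches_quadrature(self, rng):
        knots = np.sort(rng.uniform(5, 15, 9))
        g = rng.normal(size=9)
        K = penalty_matrix(knots)
        cs = CubicSpline(knots, g, bc_type="natural")
        # (s'')^2 is quadratic between knots, so knot-aligned Simpson is exact
        integral = 0.0
        for a, b in zip(knots[:-1], knots[1:]):
            x = np.linspace(a, b, 3)
            integral += simpson(cs(x, 2) ** 2, x=x)
        assert g @ K @ g == pytest.approx(integral, rel=1e-9)

    def test_null_space_is_linear(self):
        knots = np.linspace(5, 15, 7)
        K = penalty_matrix(knots)
        for g in (np.ones(7), knots.copy()):
            assert abs(g @ K @ g) < 1e-9

    def test_constant_curves_zero_penalty(self, rng):
        # alpha terms contribute exactly nothing for flat curves
        y = rng.uniform(20, 30, 25)
        t = rng.uniform(5, 14, 25)
        data = nb.norm_data_from_arrays(t, y)
        m0 = constant_model(1.0, 25.0, 0.1, alphas=(0.0, 0.0, 0.0))
        m1 = constant_model(1.0, 25.0, 0.1, alphas=(7.0, 3.0, 11.0))
        assert nb.penalized_loglik(m0, data) == pytest.approx(nb.penalized_loglik(m1, data))

    def test_penalty_linear_in_alpha(self, rng):
        knots = np.linspace(5, 14, 6)
        gM = np.log(25) + 0.05 * (knots - 9.0) ** 2 / 10.0  # strictly curved
        m1 = LMSModel(knots, np.ones(6), gM, np.full(6, np.log(0.1)), 0.0, 2.0, 0.0, (5.0, 14.0))
        m2 = LMSModel(knots, np.ones(6), gM, np.full(6, np.log(0.1)), 0.0, 4.0, 0.0, (5.0, 14.0))
        data = nb.norm_data_from_arrays(rng.uniform(5, 14, 30), rng.uniform(20, 30, 30))
        K = penalty_matrix(knots)
        drop = 0.5 * 2.0 * (gM @ K @ gM)
        assert drop > 0
        assert nb.penalized_loglik(m1, data) - nb.penalized_loglik(m2, data) == pytest.approx(
            drop, rel=1e-12
        )

    def test_objective_matches_independent_sum(self, rng):
        y = rng.uniform(18, 32, 25)
        t = rng.uniform(5, 14, 25)
        data = nb.norm_data_from_arrays(t, y)
        model = constant_model(1.3, 24.0, 0.11)
        oracle = boxcox_loglik_oracle(y, t, lambda _: 1.3, lambda _: 24.0, lambda _: 0.11)
        assert nb.penalized_loglik(model, data) == pytest.approx(oracle, abs=1e-8)


class TestAlphaFromEdf:
    def test_edf_monotone_in_alpha(self, rng):
        t = rng.uniform(5, 15, 300)
        knots = np.unique(np.quantile(t, np.linspace(0, 1, 12)))
        B = spline_basis(knots, t)
        K = penalty_matrix(knots)
        alphas = [alpha_from_edf(B, K, e) for e in (2.5, 4.0, 8.0)]
        assert alphas[0] > alphas[1] > alphas[2]

    def test_target_is_attained(self, rng):
        t = rng.uniform(5, 15, 300)
        knots = np.unique(np.quantile(t, np.linspace(0, 1, 12)))
        B = spline_basis(knots, t)
        K = penalty_matrix(knots)
        a = alpha_from_edf(B, K, 4.0)
        edf = np.trace(np.linalg.solve(B.T @ B + a * K, B.T @ B))
        assert edf == pytest.approx(4.0, abs=1e-3)


class TestZScore:
    def test_median_gives_zero(self):
        for L in (-2.0, 0.0, 1.0, 3.0):
            m = constant_model(L, 20.0, 0.1)
            assert nb.z_score(m, 20.0, 8.0) == pytest.approx(0.0, abs=1e-12)

    def test_derived_arithmetic(self):
        # ((22/20)^2 - 1) / (2 * 0.1) = 1.05
        m = constant_model(2.0, 20.0, 0.1)
        assert nb.z_score(m, 22.0, 8.0) == pytest.approx(1.05, abs=1e-10)

    def test_continuity_at_L_zero(self):
        z0 = nb.z_score(constant_model(0.0, 20.0, 0.1), 23.0, 8.0)
        z1 = nb.z_score(constant_model(1e-9, 20.0, 0.1), 23.0, 8.0)
        assert abs(z0 - z1) < 1e-6

    def test_nonpositive_score_rejected(self):
        with pytest.raises(ValueError):
            nb.z_score(constant_model(1.0, 20.0, 0.1), 0.0, 8.0)

    def test_percentile_from_z(self):
        assert nb.percentile_from_z(0.0) == pytest.approx(0.5)
        assert nb.percentile_from_z(-2.0) == pytest.approx(norm.cdf(-2.0))
        z = 1.234
        assert nb.percentile_from_z(z) + nb.percentile_from_z(-z) == pytest.approx(1.0, abs=1e-12)

    def test_t_score_composition(self):
        m = constant_model(1.0, 20.0, 0.1)
        assert float(nb.predict_t_lms(m, 20.0, 8.0)) == pytest.approx(50.0)
        assert float(nb.predict_t_lms(m, 20.0 * 0.8, 8.0)) == pytest.approx(30.0)
        assert float(nb.predict_t_lms(m, 20.0 * 1.2, 8.0)) == pytest.approx(70.0)


class TestCentileCurve:
    def test_median_centile_is_M(self):
        m = constant_model(-1.5, 22.0, 0.12)
        ages = np.linspace(5, 14, 7)
        np.testing.assert_allclose(nb.centile_curve(m, 0.5, ages), 22.0)

    def test_round_trip_through_z(self):
        m = constant_model(-1.2, 22.0, 0.12)
        ages = np.linspace(5, 14, 9)
        y = nb.centile_curve(m, 0.9, ages)
        z = nb.z_score(m, y, ages)
        np.testing.assert_allclose(z, norm.ppf(0.9), atol=1e-8)

    def test_linear_case_closed_form(self):
        m = constant_model(1.0, 20.0, 0.1)
        y = nb.centile_curve(m, 0.975, np.array([8.0]))
        assert y[0] == pytest.approx(20.0 * (1.0 + norm.ppf(0.975) * 0.1))

    def test_non_crossing(self, lms_model):
        ages = np.linspace(*lms_model.age_range, 50)
        ps = [0.03, 0.10, 0.25, 0.50, 0.75, 0.90, 0.97]
        curves = np.array([nb.centile_curve(lms_model, p, ages) for p in ps])
        assert np.all(np.diff(curves, axis=0) > 0)

    def test_outside_support_flagged_nan(self):
        # L*S*z_p < -1 -> power argument <= 0: undefined, not clamped
        m = constant_model(5.0, 20.0, 0.5)
        y = nb.centile_curve(m, 0.001, np.array([8.0]))
        assert np.isnan(y[0])

    def test_norm_table_export(self, lms_model, tmp_path):
        ages = np.linspace(12.2, 18.8, 12)
        table = nb.norm_table_lms(lms_model, ages, [0.03, 0.5, 0.97])
        nb.write_norm_table(table, tmp_path / "t.csv")  # invariants enforced on write


class TestFit:
    def test_gradient_is_exact(self, rng):
        data, _ = nb.generate_sample(nb.preset_vo2max_like(), 30, seed=77)
        y, t = data.scores, data.ages
        knots = np.unique(np.quantile(t, np.linspace(0, 1, 6)))
        B = spline_basis(knots, t)
        K = penalty_matrix(knots)
        m = knots.size
        a = (2.0, 0.7, 1.3)

        def f_and_g(x):
            gL, gM, gS = x[:m], x[m:2 * m], x[2 * m:]
            ell, dL, dM, dS = lms_mod._kernel_and_grads(y, B @ gL, B @ gM, B @ gS)
            val = np.sum(ell) - 0.5 * (
                a[0] * gL @ K @ gL + a[1] * gM @ K @ gM + a[2] * gS @ K @ gS
            )
            grad = np.concatenate(
                [B.T @ dL - a[0] * K @ gL, B.T @ dM - a[1] * K @ gM, B.T @ dS - a[2] * K @ gS]
            )
            return val, grad

        x0 = np.concatenate([
            rng.uniform(0.3, 1.2, m), np.log(40) + 0.1 * rng.normal(size=m),
            np.log(0.2) + 0.1 * rng.normal(size=m),
        ])
        _, g = f_and_g(x0)
        num = np.empty_like(x0)
        for i in range(x0.size):
            e = np.zeros_like(x0)
            e[i] = 1e-6
            num[i] = (f_and_g(x0 + e)[0] - f_and_g(x0 - e)[0]) / 2e-6
        np.testing.assert_allclose(g, num, atol=1e-5)

    def test_deterministic(self, vo2_data):
        m1 = nb.fit_lms(vo2_data)
        m2 = nb.fit_lms(vo2_data)
        np.testing.assert_array_equal(m1.coef_M, m2.coef_M)
        np.testing.assert_array_equal(m1.coef_L, m2.coef_L)
        np.testing.assert_array_equal(m1.coef_S, m2.coef_S)

    def test_positivity_violation_rejected(self):
        data = nb.norm_data_from_arrays(
            np.linspace(5, 9, 40), np.concatenate([[0.0], np.ones(39) * 20])
        )
        with pytest.raises(ValueError, match="strictly positive"):
            nb.fit_lms(data)

    def test_too_few_distinct_ages(self):
        data = nb.norm_data_from_arrays([5.0] * 10 + [6.0] * 10, np.arange(20) + 10.0)
        with pytest.raises(FitError, match="distinct"):
            nb.fit_lms(data)

    def test_self_consistency_z_statistics(self, lms_model, vo2_data):
        z = nb.z_score(lms_model, vo2_data.scores, vo2_data.ages)
        assert -0.1 < np.mean(z) < 0.1
        assert 0.9 < np.std(z) < 1.1

    def test_monotone_ascent(self, vo2_data):
        trace = []
        nb.fit_lms(vo2_data, trace=trace)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-10)

    def test_model_positivity_structural(self, lms_model):
        grid = np.linspace(*lms_model.age_range, 300)
        assert np.all(lms_model.M(grid) > 0)
        assert np.all(lms_model.S(grid) > 0)
        assert np.all(np.isfinite(lms_model.L(grid)))

    def test_roughness_never_increases_with_alpha(self, vo2_data):
        rough = []
        for aM in (1e-2, 1.0, 1e2, 1e4):
            cfg = LMSFitConfig(alpha_L=1e3, alpha_M=aM, alpha_S=1e3)
            model = nb.fit_lms(vo2_data, cfg)
            rough.append(model.roughness("M"))
        assert all(b <= a + 1e-9 for a, b in zip(rough, rough[1:]))

    def test_json_round_trip(self, lms_model, rng):
        import json

        back = nb.LMSModel.from_dict(json.loads(json.dumps(lms_model.to_dict())))
        t = rng.uniform(*lms_model.age_range, 20)
        y = rng.uniform(25, 55, 20)
        np.testing.assert_allclose(nb.z_score(back, y, t), nb.z_score(lms_model, y, t))

    def test_parameter_recovery_median_errors(self):
        curves = nb.preset_vo2max_like()
        data, _ = nb.generate_sample(curves, 500, seed=31415)
        model = nb.fit_lms(data)
        grid = np.linspace(12.2, 18.8, 60)
        m_err = np.abs(model.M(grid) / curves.M(grid) - 1.0)
        s_err = np.abs(model.S(grid) / curves.S(grid) - 1.0)
        assert np.median(m_err) < 0.02
        assert np.median(s_err) < 0.15
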