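import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from greyfly import (
    FittedGreyModel,
    GeneratorSpec,
    GreyCoefficients,
    GreyHyperparams,
    GreyModelError,
    ModelKind,
    fit_grey_model,
    generate_grey_series,
    predict_restored,
)
from greyfly.grey import (
    AccumulatedSeries,
    GreyDomainError,
    ago,
    background_sequence,
    build_lsq_system,
    estimate_coefficients,
    fractional_ago,
    fractional_iago,
    iago,
    time_response,
)
from conftest import random_positive_series


class TestAccumulation:
    @pytest.mark.parametrize(
        "raw, acc",
        [([1, 2, 3], [1, 3, 6]), ([5], [5]), ([2, 2, 2, 2], [2, 4, 6, 8])],
    )
    def test_ago(self, raw, acc):
        np.testing.assert_array_equal(ago(raw).values, acc)

    @pytest.mark.parametrize(
        "acc, raw",
        [([1, 3, 6], [1, 2, 3]), ([4, 4, 4], [4, 0, 0])],
    )
    def test_iago(self, acc, raw):
        np.testing.assert_array_equal(iago(AccumulatedSeries(acc)), raw)

    def test_ago_iago_inverse(self):
        x = np.array([7.0, 11.0, 13.0])
        np.testing.assert_array_equal(iago(ago(x)), x)

    def test_empty_rejected(self):
        with pytest.raises(GreyModelError, match="empty"):
            ago([])


class TestFractionalAccumulation:
    def test_order_one_reduces_to_ago(self):
        x = [1.0, 2.0, 3.0]
        np.testing.assert_allclose(fractional_ago(x, 1.0).values, [1, 3, 6])

    def test_half_order_weights(self):
        # generalized binomial weights Gamma(j+r)/(Gamma(j+1)Gamma(r)) for
        # r=0.5: 1, 0.5, 0.375 -> cumulative 1, 1.5, 1.875 on a unit series
        np.testing.assert_allclose(
            fractional_ago([1, 1, 1], 0.5).values, [1.0, 1.5, 1.875]
        )

    def test_single_element_identity(self):
        np.testing.assert_allclose(fractional_ago([4.2], 0.3).values, [4.2])

    def test_round_trip_spec_example(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        back = fractional_iago(fractional_ago(x, 0.98), 0.98)
        np.testing.assert_allclose(back, x, rtol=1e-9)

    @given(
        values=st.lists(st.floats(0.1, 100.0), min_size=1, max_size=15),
        r=st.floats(0.05, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_property(self, values, r):
        x = np.array(values)
        back = fractional_iago(fractional_ago(x, r), r)
        np.testing.assert_allclose(back, x, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("r", [0.0, -0.2, 1.5])
    def test_invalid_order_rejected(self, r):
        with pytest.raises(GreyModelError, match="order"):
            fractional_ago([1, 2, 3], r)


class TestBackgroundAndSystem:
    def test_midpoint_background(self):
        np.testing.assert_allclose(
            background_sequence(AccumulatedSeries([1, 3, 6]), 0.5), [2.0, 4.5]
        )

    @pytest.mark.parametrize("alpha, expected", [(1.0, [3, 6]), (0.0, [1, 3])])
    def test_boundary_backgrounds(self, alpha, expected):
        np.testing.assert_allclose(
            background_sequence(AccumulatedSeries([1, 3, 6]), alpha), expected
        )

    def test_gamma_zero_design(self):
        sys_ = build_lsq_system([1, 2, 3], [2, 4.5], 0.0)
        np.testing.assert_allclose(sys_.y_vec, [2, 3])
        np.testing.assert_allclose(sys_.z_mat, [[-2, 1], [-4.5, 1]])

    def test_gamma_two_second_column(self):
        sys_ = build_lsq_system([1, 2, 3], [2, 4.5], 2.0)
        np.testing.assert_allclose(sys_.z_mat[:, 1], [4.0, 20.25])

    def test_row_count(self):
        raw = [1, 2, 3, 4, 5]
        z = background_sequence(ago(raw), 0.5)
        assert build_lsq_system(raw, z, 0.3).n_rows == 4


class TestCoefficientEstimation:
    def test_square_system_exact(self):
        # 2 equations, 2 unknowns: least squares solves exactly
        sys_ = build_lsq_system([1, 2, 3], [2, 4.5], 0.0)
        coeffs = estimate_coefficients(sys_)
        expected = np.linalg.solve(np.array([[-2.0, 1.0], [-4.5, 1.0]]), [2.0, 3.0])
        np.testing.assert_allclose([coeffs.beta1, coeffs.beta2], expected, rtol=1e-10)

    def test_closed_form_matches_lstsq_on_random_instances(self):
        """The explicit normal-equation ratios and the numerical least-squares
        solve are two independent routes to the same estimate."""
        rng = np.random.default_rng(42)
        worst = 0.0
        trials = 0
        while trials < 1000:
            n = int(rng.integers(4, 13))
            g = float(rng.uniform(-2.0, 0.9))
            x = random_positive_series(rng, n)
            z = background_sequence(ago(x), float(rng.uniform(0, 1)))
            sys_ = build_lsq_system(x, z, g)
            try:
                a = estimate_coefficients(sys_, "closed_form")
                b = estimate_coefficients(sys_, "lstsq")
            except GreyModelError:
                continue  # ill-conditioned draw, excluded by contract
            trials += 1
            for u, v in ((a.beta1, b.beta1), (a.beta2, b.beta2)):
                worst = max(worst, abs(u - v) / max(abs(v), 1e-12))
        assert worst < 1e-8

    def test_recovers_generating_coefficients(self):
        """A GM trajectory refitted with the self-consistent background
        coefficient returns the generating (beta1, beta2)."""
        b1, b2 = -0.1, 1.0
        series = generate_grey_series(
            GeneratorSpec(kind="GM", beta1=b1, beta2=b2, initial_value=1.0, n=10)
        )

        def beta_error(alpha: float) -> float:
            model = fit_grey_model(series, "GM", GreyHyperparams(alpha_bg=alpha))
            return abs(model.coeffs.beta1 - b1) + abs(model.coeffs.beta2 - b2)

        res = minimize_scalar(beta_error, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-12})
        assert res.fun < 1e-6

    def test_singular_system_diagnosed(self):
        # constant background values make the two columns collinear
        with pytest.raises(GreyModelError, match="condition"):
            estimate_coefficients(build_lsq_system([1, 1, 1, 1], [2, 2, 2], 0.0))


def _model(kind, b1, b2, gamma, y1):
    hyper = GreyHyperparams(gamma_power=gamma)
    from greyfly.grey import _integration_constant

    c = _integration_constant(y1, b1, b2, gamma)
    return FittedGreyModel(
        kind=ModelKind(kind), hyper=hyper,
        coeffs=GreyCoefficients(b1, b2, c), initial_value=y1, window_length=4,
    )


class TestTimeResponse:
    def test_initial_condition(self):
        model = _model("NGBM", -0.2, 0.7, -0.4, 4.0)
        assert time_response(model, 1) == pytest.approx(4.0, rel=1e-12)

    def test_pure_exponential_decay(self):
        model = _model("GM", 0.5, 0.0, 0.0, 1.0)
        assert time_response(model, 3) == pytest.approx(np.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("gamma", [0.5, -0.4, 0.0])
    def test_matches_whitening_ode_integration(self, gamma):
        """The closed form must agree with numerical integration of
        dy/dt = -b1*y + b2*y**gamma from the initial condition."""
        b1, b2, y1 = 0.2, 0.4, 4.0
        model = _model("NGBM", b1, b2, gamma, y1)
        sol = solve_ivp(
            lambda t, y: -b1 * y + b2 * np.sign(y) * np.abs(y) ** gamma,
            (1.0, 2.0), [y1], rtol=1e-10, atol=1e-12, dense_output=True,
        )
        assert time_response(model, 2) == pytest.approx(sol.y[0, -1], rel=1e-6)

    def test_ode_residual_along_trajectory(self):
        # central-difference derivative of the time response vs the ODE rhs
        b1, b2, gamma, y1 = -0.08, 1.5, -0.5, 3.0
        model = _model("NGBM", b1, b2, gamma, y1)
        h = 1e-5
        for k in np.linspace(2.0, 8.0, 7):
            y = time_response(model, k)
            dy = (time_response(model, k + h) - time_response(model, k - h)) / (2 * h)
            rhs = -b1 * y + b2 * y**gamma
            assert dy == pytest.approx(rhs, rel=1e-5)

    def test_beta1_zero_rejected(self):
        model = FittedGreyModel(
            kind=ModelKind.GM, hyper=GreyHyperparams(),
            coeffs=GreyCoefficients(0.0, 1.0), initial_value=1.0, window_length=4,
        )
        with pytest.raises(GreyModelError, match="beta1"):
            time_response(model, 2)

    def test_negative_base_domain_error_names_k(self):
        # decaying bracket crosses zero under a fractional exponent
        model = _model("NGBM", 0.9, -0.5, -1.0, 2.0)
        with pytest.raises(GreyDomainError, match="k="):
            time_response(model, np.arange(1, 40))


class TestFitAndPredict:
    def test_ngbm_gamma_zero_equals_gm(self, toy_series):
        h = GreyHyperparams(alpha_bg=0.31)
        gm = fit_grey_model(toy_series, "GM", h)
        ngbm = fit_grey_model(toy_series, "NGBM",
                              GreyHyperparams(alpha_bg=0.31, gamma_power=0.0))
        assert ngbm.coeffs.beta1 == pytest.approx(gm.coeffs.beta1, rel=1e-10)
        assert ngbm.coeffs.beta2 == pytest.approx(gm.coeffs.beta2, rel=1e-10)
        k = np.arange(1, toy_series.n + 3)
        np.testing.assert_allclose(
            predict_restored(ngbm, k), predict_restored(gm, k), rtol=1e-10
        )

    def test_fgm_order_one_equals_gm(self, toy_series):
        h = GreyHyperparams(alpha_bg=0.77, frac_order=1.0)
        gm = fit_grey_model(toy_series, "GM", h)
        fgm = fit_grey_model(toy_series, "FGM", h)
        k = np.arange(1, toy_series.n + 3)
        np.testing.assert_allclose(
            predict_restored(fgm, k), predict_restored(gm, k), rtol=1e-10
        )

    def test_prediction_at_k1_is_first_raw_value(self, toy_series):
        for kind, h in [
            ("GM", GreyHyperparams()),
            ("NGBM", GreyHyperparams(gamma_power=-0.3)),
            ("FGM", GreyHyperparams(frac_order=0.9)),
        ]:
            model = fit_grey_model(toy_series, kind, h)
            assert predict_restored(model, [1])[0] == pytest.approx(
                toy_series.values[0], rel=1e-9
            )

    def test_noiseless_ngbm_refit_reproduces_series(self, ngbm_series):
        """Generator/refit closure: refitting at the true exponent tracks the
        trajectory to well under 0.1%."""
        model = fit_grey_model(
            ngbm_series, "NGBM", GreyHyperparams(alpha_bg=0.5, gamma_power=-0.4)
        )
        fitted = predict_restored(model, np.arange(1, ngbm_series.n + 1))
        np.testing.assert_allclose(fitted, ngbm_series.values, rtol=1e-3)

    def test_deterministic_fit(self, toy_series):
        h = GreyHyperparams(alpha_bg=0.6, gamma_power=0.2)
        a = fit_grey_model(toy_series, "NGBM", h)
        b = fit_grey_model(toy_series, "NGBM", h)
        assert a.coeffs == b.coeffs

    def test_short_window_rejected(self):
        with pytest.raises(GreyModelError, match="n >= 4"):
            fit_grey_model(np.array([1.0, 2.0, 3.0]), "GM", GreyHyperparams())

    def test_gamma_near_one_rejected(self):
        with pytest.raises(GreyModelError, match="degenerate"):
            GreyHyperparams(gamma_power=1.0 + 1e-9)
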