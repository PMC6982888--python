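"""Linearized and nonlinear estimation of the binding constants, and the
Hofmeister ranking."""

import numpy as np
import pytest

from conftest import SALTS, noiseless_curve, random_constants
from lipocharge import (
    BindingConstants,
    Electrolyte,
    LinearFit,
    Medium,
    Membrane,
    SyntheticSpec,
    TitrationCurve,
    constants_from_linear_fits,
    estimate_constants,
    fit_linear_window,
    fit_nonlinear,
    generate_titration,
    linear_coefficients,
    model_charge_density,
    rank_hofmeister,
    theoretical_curve,
    transform_acid_branch,
    transform_base_branch,
)
from lipocharge.constants import FARADAY
from lipocharge.exceptions import (
    InsufficientDataError,
    NonPhysicalRootError,
    SignConventionError,
    TieWarning,
)


def make_curve(pH, sigma, salt="NaCl", sd=None):
    return TitrationCurve(
        pH=np.asarray(pH, float),
        sigma=np.asarray(sigma, float),
        sd=sd,
        electrolyte=Electrolyte(salt=salt),
    )


class TestBranchTransforms:
    def test_acid_point_value(self, medium):
        curve = make_curve([2.0], [1.416e-2])
        x, y = transform_acid_branch(curve, medium)
        assert x[0] == pytest.approx(10.0)
        assert y[0] == pytest.approx(1.416e-2 * 10.0 / FARADAY, rel=1e-12)
        assert y[0] == pytest.approx(1.468e-6, rel=1e-3)

    def test_base_point_value(self, medium):
        curve = make_curve([8.0], [-6.24e-3])
        x, y = transform_base_branch(curve, medium)
        assert x[0] == pytest.approx(1e5)
        assert y[0] == pytest.approx(-6.47e-3, rel=1e-3)

    def test_zero_sigma_maps_to_zero(self, medium):
        curve = make_curve([3.0, 5.0], [0.0, 0.0])
        _, ya = transform_acid_branch(curve, medium)
        _, yb = transform_base_branch(curve, medium)
        assert np.all(ya == 0.0) and np.all(yb == 0.0)

    def test_x_coordinates_follow_ph(self, medium):
        curve = make_curve([2.0, 2.3, 2.6], [1e-2, 9e-3, 8e-3])
        xa, _ = transform_acid_branch(curve, medium)
        assert np.allclose(xa, [10.0, 10**0.7, 10**0.4])
        assert np.all(np.diff(xa) < 0)  # a_H decreasing in pH
        xb, _ = transform_base_branch(curve, medium)
        assert xb[1] / xb[0] == pytest.approx(10**0.3, rel=1e-12)


class TestLinearWindowFit:
    def test_collinear_input_is_exact(self):
        x = np.linspace(0, 5, 8)
        fit = fit_linear_window(x, 3 * x + 1, np.linspace(2, 3, 8), (2, 3), "acid")
        assert fit.slope == pytest.approx(3.0, rel=1e-12)
        assert fit.intercept == pytest.approx(1.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_point_interpolation(self):
        fit = fit_linear_window(
            np.array([0.0, 1.0]), np.array([0.0, 2.0]), np.array([2.0, 2.5]), (2, 3), "acid"
        )
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-15)

    def test_matches_normal_equations(self):
        # independent closed-form OLS on 20 noisy points
        rng = np.random.default_rng(3)
        x = np.linspace(-1, 4, 20)
        y = 5 * x - 2 + rng.normal(0, 0.1, 20)
        pH = np.linspace(2, 3, 20)
        fit = fit_linear_window(x, y, pH, (2, 3), "base")
        n = len(x)
        slope_ref = (n * np.sum(x * y) - x.sum() * y.sum()) / (n * np.sum(x * x) - x.sum() ** 2)
        intercept_ref = y.mean() - slope_ref * x.mean()
        assert fit.slope == pytest.approx(slope_ref, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept_ref, rel=1e-12)

    def test_window_filtering_and_insufficient_data(self):
        x = np.arange(5.0)
        pH = np.array([2.0, 2.5, 3.0, 6.0, 7.0])
        fit = fit_linear_window(x, 2 * x, pH, (2, 3), "acid")
        assert fit.n_points == 3
        with pytest.raises(InsufficientDataError):
            fit_linear_window(x, 2 * x, pH, (9, 10), "acid")


class TestConstantsFromLinearFits:
    @staticmethod
    def analytic_fits(constants, electrolyte, membrane, medium):
        sa, ia, sb, ib = linear_coefficients(constants, electrolyte, membrane, medium)
        acid = LinearFit("acid", sa, ia, (2.0, 2.6), 3, 1.0)
        base = LinearFit("base", sb, ib, (5.5, 8.0), 9, 1.0)
        return acid, base

    @pytest.mark.parametrize("salt", SALTS)
    def test_algebraic_round_trip_is_exact(self, salt, constants_table, membrane, medium):
        K = constants_table[salt]
        elec = Electrolyte(salt=salt)
        acid, base = self.analytic_fits(K, elec, membrane, medium)
        got, diag = constants_from_linear_fits(acid, base, membrane, elec, medium)
        assert got.as_array() == pytest.approx(K.as_array(), rel=1e-9)
        assert diag["root_selection"] in ("strong_association", "unique")

    def test_round_trip_identity_on_random_draws(self, membrane, medium):
        rng = np.random.default_rng(11)
        elec = Electrolyte(salt="x", concentration=155.0)
        for _ in range(100):
            K = random_constants(rng)
            acid, base = self.analytic_fits(K, elec, membrane, medium)
            got, _ = constants_from_linear_fits(acid, base, membrane, elec, medium)
            assert got.as_array() == pytest.approx(K.as_array(), rel=1e-7)

    def test_curve_based_root_selection(self, constants_table, membrane, medium):
        # with the generating curve supplied, selection does not rely on the
        # strong-association default
        K = constants_table["NaCl"]
        elec = Electrolyte(salt="NaCl")
        acid, base = self.analytic_fits(K, elec, membrane, medium)
        curve = noiseless_curve("NaCl")
        got, diag = constants_from_linear_fits(
            acid, base, membrane, elec, medium, curve=curve, root_selection="curve_rmse"
        )
        assert diag["root_selection"] == "curve_rmse"
        assert got.as_array() == pytest.approx(K.as_array(), rel=1e-9)

    def test_unit_slope_boundary_gives_zero_kbx(self, constants_table, membrane, medium):
        # a non-adsorbing anion: K_BX = 0 makes the acid slope exactly C_PC
        ref = constants_table["NaCl"]
        K = BindingConstants(K_AH=ref.K_AH, K_ANa=ref.K_ANa, K_BOH=ref.K_BOH, K_BX=0.0)
        elec = Electrolyte(salt="NaCl")
        acid, base = self.analytic_fits(K, elec, membrane, medium)
        assert acid.slope == pytest.approx(membrane.surface_concentration, rel=1e-14)
        got, _ = constants_from_linear_fits(acid, base, membrane, elec, medium)
        assert got.K_BX == 0.0
        assert got.as_array() == pytest.approx(K.as_array(), rel=1e-9)

    def test_inconsistent_intercepts_raise(self, membrane, medium):
        # a positive acid intercept admits no positive (K_AH, K_BOH) pair
        elec = Electrolyte(salt="NaCl")
        acid = LinearFit("acid", 1e-7, +1e-6, (2, 2.6), 3, 1.0)
        base = LinearFit("base", -1e-7, 1e-4, (5.5, 8), 9, 1.0)
        with pytest.raises(NonPhysicalRootError):
            constants_from_linear_fits(acid, base, membrane, elec, medium)

    def test_sign_conventions_enforced(self, membrane, medium):
        elec = Electrolyte(salt="NaCl")
        good_acid = LinearFit("acid", 1e-7, -1e-6, (2, 2.6), 3, 1.0)
        good_base = LinearFit("base", -1e-7, 1e-4, (5.5, 8), 9, 1.0)
        with pytest.raises(SignConventionError):
            constants_from_linear_fits(
                LinearFit("acid", -1e-7, -1e-6, (2, 2.6), 3, 1.0), good_base,
                membrane, elec, medium,
            )
        with pytest.raises(SignConventionError):
            constants_from_linear_fits(
                good_acid, LinearFit("base", 1e-7, 1e-4, (5.5, 8), 9, 1.0),
                membrane, elec, medium,
            )


class TestAsymptoticConsistency:
    def test_acid_slope_limit(self, constants_table, membrane, medium):
        # numerical slope of the exact transform at a_H = 1e6 mol m^-3
        for salt in SALTS:
            K = constants_table[salt]
            elec = Electrolyte(salt=salt)

            def y(a_h):
                pH = 3.0 - np.log10(a_h)
                return model_charge_density(pH, elec, K, membrane, medium) * a_h / FARADAY

            a = 1e6
            slope = (y(a * 1.001) - y(a * 0.999)) / (a * 0.002)
            expected = membrane.surface_concentration / (1 + K.K_BX * 155.0)
            assert slope == pytest.approx(expected, rel=1e-3), salt

    def test_base_slope_limit(self, constants_table, membrane, medium):
        for salt in SALTS:
            K = constants_table[salt]
            elec = Electrolyte(salt=salt)

            def y(x):  # x = 1/a_H
                pH = 3.0 + np.log10(x)
                return model_charge_density(pH, elec, K, membrane, medium) / (FARADAY / x)

            x = 1e8
            slope = (y(x * 1.001) - y(x * 0.999)) / (x * 0.002)
            expected = -membrane.surface_concentration / (1 + K.K_ANa * 155.0)
            assert slope == pytest.approx(expected, rel=1e-3), salt


class TestNonlinearFit:
    @pytest.mark.parametrize("salt", SALTS)
    def test_noiseless_round_trip(self, salt, constants_table, membrane, medium):
        truth = constants_table[salt]
        curve = noiseless_curve(salt, pH_grid=np.arange(2.0, 8.0001, 0.3))
        init = BindingConstants.from_array(truth.as_array() * [1.7, 0.6, 2.5, 0.5])
        res = fit_nonlinear(curve, membrane, medium, init=init)
        assert res.constants.as_array() == pytest.approx(truth.as_array(), rel=1e-3)
        # far tighter in practice
        assert res.constants.as_array() == pytest.approx(truth.as_array(), rel=1e-6)

    def test_fixed_point_at_optimum(self, constants_table, membrane, medium):
        truth = constants_table["NaBr"]
        curve = noiseless_curve("NaBr")
        res = fit_nonlinear(curve, membrane, medium, init=truth)
        assert res.rmse < 1e-15
        assert res.constants.as_array() == pytest.approx(truth.as_array(), rel=1e-9)

    def test_noisy_rmse_matches_noise_scale(self, membrane, medium):
        spec = SyntheticSpec.for_salt("NaCl", noise_sd=5e-4, seed=123)
        curve = generate_titration(spec).restrict(8.0)
        res = fit_nonlinear(curve, membrane, medium)
        # replicate mean of 3 has SD noise/sqrt(3); rmse within 2x of that
        assert res.rmse < 2 * 5e-4
        assert res.rmse > 0

    def test_too_few_points_rejected(self, membrane, medium):
        curve = make_curve([2.0, 3.0, 4.0, 5.0], [1e-2, 5e-3, 0.0, -2e-3])
        with pytest.raises(InsufficientDataError):
            fit_nonlinear(curve, membrane, medium)


class TestEstimateConstants:
    def test_noiseless_nai_full_pipeline(self, constants_table, membrane, medium):
        truth = constants_table["NaI"]
        res = estimate_constants(noiseless_curve("NaI"), membrane, medium)
        assert res.method == "linearized+nonlinear"
        assert res.constants.as_array() == pytest.approx(truth.as_array(), rel=1e-3)

    def test_high_ph_curve_is_insufficient(self, membrane, medium):
        curve = make_curve([8.3, 8.6, 8.9, 9.2, 9.5], [-7e-3, -7.1e-3, -7.2e-3, -7.3e-3, -7.4e-3])
        with pytest.raises(InsufficientDataError):
            estimate_constants(curve, membrane, medium)

    def test_linearized_only_bias_characterization(self, constants_table, membrane, medium):
        # the asymptotic route carries truncation bias: slope-derived K_ANa
        # is tight, all four land within a factor of 2 for NaCl
        truth = constants_table["NaCl"]
        res = estimate_constants(noiseless_curve("NaCl"), membrane, medium, method="linearized")
        assert res.method == "linearized"
        assert res.constants.K_ANa == pytest.approx(truth.K_ANa, rel=0.10)
        ratios = res.constants.as_array() / truth.as_array()
        assert np.all((ratios > 0.5) & (ratios < 2.0))

    def test_windows_and_exclusions_reported(self, membrane, medium):
        res = estimate_constants(noiseless_curve("NaBr"), membrane, medium)
        assert res.windows["acid"] and res.windows["base"]
        assert res.excluded_points == 5  # grid points at pH 8.3..9.5
        assert res.n_points == 21


class TestTheoreticalCurve:
    def test_symmetric_constants_neutral_at_seven(self, membrane, medium):
        K = BindingConstants(K_AH=500.0, K_ANa=0.2, K_BOH=500.0, K_BX=0.2)
        curve = theoretical_curve(K, Electrolyte(salt="x"), membrane, medium, pH_grid=[7.0])
        assert curve.sigma[0] == pytest.approx(0.0, abs=1e-18)

    def test_nacl_values_on_two_point_grid(self, constants_table, membrane, medium):
        curve = theoretical_curve(
            constants_table["NaCl"], Electrolyte("NaCl"), membrane, medium, pH_grid=[2.0, 8.0]
        )
        assert curve.sigma == pytest.approx([1.416e-2, -6.24e-3], rel=1e-3)
        assert curve.provenance == "synthetic"

    def test_default_grid_has_26_points(self, constants_table, membrane, medium):
        curve = theoretical_curve(constants_table["NaCl"], Electrolyte("NaCl"), membrane, medium)
        assert len(curve) == 26
        assert curve.pH[0] == 2.0 and curve.pH[-1] == pytest.approx(9.5)


class TestHofmeisterRanking:
    def test_reference_constants_follow_series(self, constants_table):
        report = rank_hofmeister(constants_table)
        assert report["order"] == ["NaI", "NaNO3", "NaBr", "NaCl"]
        assert not report["tie"]

    def test_radius_affinity_rank_correlation(self, constants_table):
        radii = {"NaCl": 1.81, "NaBr": 1.95, "NaNO3": 1.89, "NaI": 2.16}
        report = rank_hofmeister(constants_table, radii=radii)
        # NO3- is smaller than Br- yet binds more strongly -> 0.8 overall
        assert report["spearman_radius_K_BX"] == pytest.approx(0.8, abs=1e-12)
        halides = {s: constants_table[s] for s in ("NaCl", "NaBr", "NaI")}
        sub = rank_hofmeister(halides, radii={s: radii[s] for s in halides})
        assert sub["spearman_radius_K_BX"] == pytest.approx(1.0)

    def test_tie_keeps_input_order_with_warning(self):
        a = BindingConstants(1.0, 0.1, 1e9, 0.2)
        b = BindingConstants(2.0, 0.2, 2e9, 0.2)
        with pytest.warns(TieWarning):
            report = rank_hofmeister({"saltA": a, "saltB": b})
        assert report["order"] == ["saltA", "saltB"]
        assert report["tie"]

    def test_single_salt_rejected(self, constants_table):
        with pytest.raises(InsufficientDataError):
            rank_hofmeister({"NaCl": constants_table["NaCl"]})
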