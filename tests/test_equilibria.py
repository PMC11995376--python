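import numpy as np
import pytest
from scipy.optimize import brentq

import anomer as an
from anomer.composition import ALPHA_LACTOSE, BETA_LACTOSE
from anomer.equilibria import Regime
from anomer.exceptions import CompositionError, ModelValidityError


class TestChiStoichiometry:
    def test_lactose_monohydrate_value(self):
        assert round(an.chi_stoichiometry(), 2) == 0.95
        assert an.chi_stoichiometry() == pytest.approx(342.30 / 360.31, rel=1e-12)

    def test_hypothetical_anhydrate(self):
        reg = an.SpeciesRegistry.default().with_species(
            an.Species("alpha-lactose-monohydrate", 342.30, "crystal_hydrate")
        )
        assert an.chi_stoichiometry(reg) == pytest.approx(1.0)

    def test_missing_species_rejected(self):
        reg = an.SpeciesRegistry(
            [an.Species("water", 18.015, "solvent"), an.Species("alpha-lactose", 342.3, "isomer")]
        )
        with pytest.raises(CompositionError):
            an.chi_stoichiometry(reg)


class TestSolubilityProduct:
    def test_table_value_from_equilibrium_point(self):
        ksp = an.ksp_from_equilibrium_point(
            0.9886, an.MargulesModel(-5.8), an.MutarotationModel(1.60)
        )
        assert ksp == pytest.approx(0.00494, abs=1e-5)

    def test_vanishes_at_pure_water(self):
        ksp = an.ksp_from_equilibrium_point(
            1.0, an.MargulesModel(-5.8), an.MutarotationModel(1.60)
        )
        assert ksp == 0.0

    @pytest.mark.parametrize("slope", [0.0, 1.0, 3.0])
    def test_independent_of_Kx_slope(self, slope):
        """(1 + K_x) cancels between gamma*_alpha and the alpha partition."""
        ref = an.ksp_from_equilibrium_point(
            0.9886, an.MargulesModel(-5.8), an.MutarotationModel(1.60, 0.0)
        )
        val = an.ksp_from_equilibrium_point(
            0.9886, an.MargulesModel(-5.8), an.MutarotationModel(1.60, slope)
        )
        assert abs(val - ref) <= 1e-12


class TestSaturationCurve:
    def test_alpha_saturation_at_equilibrium_point(self, lactose_model):
        assert lactose_model.x_alpha_sat(0.9886) == pytest.approx(0.0043846, abs=1e-6)

    def test_alpha_saturation_with_composition_dependent_ratio(self):
        model = an.SolubilityModel(mutarotation=an.MutarotationModel(1.60, 3.0))
        assert model.x_alpha_sat(0.9886) == pytest.approx(0.0044430, abs=1e-6)

    def test_linear_in_Ksp(self, lactose_model):
        doubled = an.SolubilityModel(K_sp=2 * lactose_model.K_sp)
        assert doubled.x_alpha_sat(0.975) == pytest.approx(
            2 * lactose_model.x_alpha_sat(0.975), rel=1e-14
        )


class TestEquilibriumSolubility:
    def test_lactose_equilibrium_water_fraction(self, lactose_model):
        eq = lactose_model.solve_equilibrium_solubility()
        assert eq.x_w == pytest.approx(0.9886, abs=2e-4)
        assert eq.x_beta / eq.x_alpha == pytest.approx(1.60, rel=1e-12)

    @pytest.mark.parametrize("slope", [1.0, 3.0])
    def test_equilibrium_independent_of_Kx_slope(self, lactose_model, slope):
        ref = lactose_model.solve_equilibrium_solubility().x_w
        alt = an.SolubilityModel(
            mutarotation=an.MutarotationModel(1.60, slope)
        ).solve_equilibrium_solubility()
        assert alt.x_w == pytest.approx(ref, abs=1e-10)

    def test_vanishing_solubility_product(self):
        tiny = an.SolubilityModel(K_sp=1e-8)
        assert tiny.solve_equilibrium_solubility().x_w == pytest.approx(1.0, abs=1e-5)

    def test_solubility_in_g_per_g_water(self, lactose_model):
        assert lactose_model.solubility_g_per_g_water() == pytest.approx(0.2191, abs=2e-4)

    def test_no_solution_outside_window(self):
        # a hypothetical hyper-soluble solid would saturate below x_w = 0.9
        with pytest.raises(an.exceptions.NoSolutionError):
            an.SolubilityModel(K_sp=0.2).solve_equilibrium_solubility()


class TestFParameter:
    def test_lactose_value_constant_Kx_mode(self, lactose_model):
        assert lactose_model.F_parameter() == pytest.approx(0.0433, abs=3e-4)

    def test_ideal_solution_gives_small_negative_F(self):
        """Without activity-coefficient feedback only the trivial dilution
        term survives: F is tiny (|F| << lactose's 0.043) and negative."""
        F = an.SolubilityModel(margules=an.MargulesModel(0.0)).F_parameter()
        assert F < 0 and abs(F) < 0.006

    def test_stronger_nonideality_increases_F(self):
        values = [
            an.SolubilityModel(margules=an.MargulesModel(A)).F_parameter()
            for A in (-2.9, -5.8, -11.6)
        ]
        assert values[0] < values[1] < values[2]

    def test_slope_inclusive_mode_differs(self):
        model = an.SolubilityModel(mutarotation=an.MutarotationModel(1.60, 3.0))
        assert model.F_parameter() != pytest.approx(
            model.F_parameter(include_kx_slope=True), rel=1e-3
        )

    def test_matches_brute_force_two_point_solve(self, lactose_model):
        """F equals -dx_alpha,sat/dx_beta from two-point saturation solves
        at x_beta,eq +/- delta with K_x frozen at its saturation value."""
        eq = lactose_model.solve_equilibrium_solubility()
        kx_eq = float(lactose_model.mutarotation.K_x(eq.x_w))
        ks = lactose_model.mutarotation.K_star
        m = lactose_model.margules

        def x_alpha_sat_at(x_beta):
            def res(x_alpha):
                x_w = 1.0 - x_alpha - x_beta
                gamma = float(m.gamma_star_group(x_w)) * (1.0 + kx_eq) / (1.0 + ks)
                return float(m.water_activity(x_w)) * gamma * x_alpha - lactose_model.K_sp

            return brentq(res, 1e-8, 0.02, xtol=1e-18)

        delta = 1e-5
        F_fd = -(x_alpha_sat_at(eq.x_beta + delta) - x_alpha_sat_at(eq.x_beta - delta)) / (
            2 * delta
        )
        assert F_fd == pytest.approx(lactose_model.F_parameter(), rel=1e-6)


class TestConvertFBasis:
    @pytest.fixture()
    def context(self):
        return an.composition_from_loading(0.2191, 1.6, {"glucose": 0.05})

    def test_same_basis_identity(self, context):
        assert an.convert_F_basis(0.0434, "mole_fraction", "mole_fraction", context) == 0.0434

    def test_equal_molar_masses_invariant(self, context):
        out = an.convert_F_basis(
            0.0434, "mole_fraction", "mass_fraction_solution", context
        )
        assert out == pytest.approx(0.0434, rel=1e-12)

    def test_glucose_depressant_scales_by_molar_mass_ratio(self, context):
        """Jacobian oracle: finite differences of the basis conversion maps
        give the molar-mass ratio for a glucose depressant."""
        out = an.convert_F_basis(
            0.0434,
            "mole_fraction",
            "g_per_g_water",
            context,
            depressant_species="glucose",
        )
        dx = 1e-9
        j_alpha = (
            an.convert_concentration(0.004 + dx, "mole_fraction", "g_per_g_water", context, ALPHA_LACTOSE)
            - an.convert_concentration(0.004, "mole_fraction", "g_per_g_water", context, ALPHA_LACTOSE)
        ) / dx
        j_glc = (
            an.convert_concentration(0.004 + dx, "mole_fraction", "g_per_g_water", context, "glucose")
            - an.convert_concentration(0.004, "mole_fraction", "g_per_g_water", context, "glucose")
        ) / dx
        assert out == pytest.approx(0.0434 * j_alpha / j_glc, rel=1e-6)
        assert out == pytest.approx(0.0434 * 342.30 / 180.16, rel=1e-6)


class TestForeignSugarDepression:
    def test_zero_loading_reduces_to_binary_solubility(self, lactose_model):
        assert lactose_model.solubility_with_foreign_sugar(0.0) == pytest.approx(
            lactose_model.solubility_g_per_g_water(), abs=1e-10
        )

    def test_strictly_decreasing_in_loading(self, lactose_model):
        loadings = np.linspace(0.0, 0.5, 11)
        sols = lactose_model.depression_curve(loadings, "sucrose")
        assert np.all(np.diff(sols) < 0)

    def test_equal_mole_loadings_give_identical_depression(self, lactose_model):
        """Only the water mole fraction enters: sugars dosed at equal molar
        amounts depress identically regardless of molar mass."""
        glucose_load = 0.10
        sucrose_load = glucose_load * 342.30 / 180.16
        s_glc = lactose_model.solubility_with_foreign_sugar(glucose_load, "glucose")
        s_suc = lactose_model.solubility_with_foreign_sugar(sucrose_load, "sucrose")
        assert s_glc == pytest.approx(s_suc, rel=1e-10)

    def test_brute_force_grid_confirms_root(self, lactose_model):
        load = 0.10
        s = lactose_model.solubility_with_foreign_sugar(load, "sucrose")
        # grid search over x_alpha as an independent check
        reg = lactose_model.registry
        r = load * reg.solvent.molar_mass / reg.molar_mass("sucrose")
        xs = np.linspace(0.97, 0.9999, 200_000)
        x_iso = 1.0 - xs * (1.0 + r)
        mask = x_iso > 0
        xs, x_iso = xs[mask], x_iso[mask]
        x_alpha = x_iso / (1.0 + np.asarray(lactose_model.mutarotation.K_x(xs)))
        resid = (
            np.asarray(lactose_model.margules.water_activity(xs))
            * np.asarray(lactose_model.gamma_star_alpha_eq(xs))
            * x_alpha
            - lactose_model.K_sp
        )
        i = np.argmin(np.abs(resid))
        s_grid = x_iso[i] * reg.molar_mass("alpha-lactose") / (xs[i] * reg.solvent.molar_mass)
        assert s == pytest.approx(s_grid, rel=1e-4)

    def test_excessive_loading_leaves_validity_window(self, lactose_model):
        with pytest.raises(ModelValidityError):
            lactose_model.solubility_with_foreign_sugar(3.0, "sucrose")

    def test_negative_loading_rejected(self, lactose_model):
        with pytest.raises(ModelValidityError):
            lactose_model.solubility_with_foreign_sugar(-0.1)


class TestRegimeClassification:
    def test_zero_loading_is_type_I(self, lactose_model):
        assert lactose_model.classify_regime(0.0) is Regime.TYPE_I

    def test_reference_suspension_density_is_type_III(self, lactose_model):
        assert lactose_model.classify_regime(0.23) is Regime.TYPE_III

    def test_between_thresholds_is_type_II(self, lactose_model):
        c_alpha, c_tot = lactose_model.saturation_g_per_g_water()
        assert lactose_model.classify_regime(c_alpha * 1.01) is Regime.TYPE_II
        assert lactose_model.classify_regime(0.5 * (c_alpha + c_tot)) is Regime.TYPE_II

    def test_thresholds_bracket_the_solubility(self, lactose_model):
        c_alpha, c_tot = lactose_model.saturation_g_per_g_water()
        assert 0 < c_alpha < c_tot
        assert c_tot == pytest.approx(lactose_model.solubility_g_per_g_water())
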