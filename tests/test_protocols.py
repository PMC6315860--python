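"""Simulation protocols: growth validation, scans, flux maps, secretion."""

import numpy as np
import pytest

from conftest import sole_carbon_medium
from cyanoflux import coremodel, protocols
from cyanoflux.netcore import ModelContractError
from cyanoflux.solver import FluxProblem, fba, fva, geometric_fba
from cyanoflux.protocols import (
    GrowthCondition,
    autotroph_condition,
    carbon_balance,
    central_flux_map,
    heterotroph_condition,
    maximize_product,
    mixotroph_condition,
    nutrient_scan,
    percent_error,
    secretion_profile,
    simulate_growth,
    validation_percent_errors,
)


@pytest.fixture(scope="module")
def scan_condition(alpha):
    """The excess-carbon autotrophic setting of the nutrient scans."""
    return autotroph_condition(alpha, hco3_uptake=1.6)


class TestSimulateGrowth:
    def test_dark_heterotroph_growth_is_zero(self, core_model, alpha):
        """Photon 0, glucose <= 0.017: all carbon pays maintenance."""
        sol = simulate_growth(core_model, heterotroph_condition(alpha))
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_no_energy_source_means_no_growth(self, core_model, alpha):
        condition = heterotroph_condition(alpha, glucose_uptake_max=0.0)
        # photon 0 and glucose 0: the LP is infeasible because even the
        # maintenance demand cannot be paid without an energy source
        with pytest.raises(protocols.ProtocolError):
            simulate_growth(core_model, condition)
        relaxed = core_model.copy()
        relaxed.reaction(coremodel.ATPM_ID).bounds = (0.0, 1000.0)
        sol = simulate_growth(relaxed, condition)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_autotroph_reproduces_calibration_anchor(self, core_model, alpha):
        """The calibrated alpha pins the reference autotroph at 0.0252 1/h."""
        sol = simulate_growth(core_model, autotroph_condition(alpha))
        assert sol.objective_value == pytest.approx(
            coremodel.REFERENCE_AUTOTROPH["growth"], abs=1e-6
        )

    def test_mixotroph_at_least_autotroph(self, core_model, alpha):
        """Adding glucose can only relax the LP: mixotroph >= autotroph."""
        auto = simulate_growth(core_model, autotroph_condition(alpha))
        mixo = simulate_growth(core_model, mixotroph_condition(alpha))
        assert mixo.objective_value >= auto.objective_value - 1e-12


class TestMaximizeProduct:
    def test_sole_carbon_nitrogen_free_glycogen_is_hco3_over_six(
        self, core_model, alpha
    ):
        """With HCO3- the sole carbon source and growth 0, carbon balance
        forces glycogen flux = uptake/6 (6 carbons per glucosyl monomer)."""
        condition = GrowthCondition(
            "N-free", alpha, photon_irradiance=1000.0, hco3_uptake=0.2,
            medium=sole_carbon_medium(coremodel.EX_NO3),
        )
        sol = maximize_product(
            core_model, coremodel.GLYCOGEN_SYNTHESIS, condition, fixed_growth=0.0
        )
        assert sol.objective_value == pytest.approx(0.2 / 6.0, abs=1e-9)

    def test_zero_carbon_sources_give_zero_product(self, core_model, alpha):
        condition = GrowthCondition(
            "no-carbon", alpha, photon_irradiance=1000.0, hco3_uptake=0.0,
            medium=sole_carbon_medium(),
        )
        sol = maximize_product(
            core_model, coremodel.GLYCOGEN_SYNTHESIS, condition, fixed_growth=0.0
        )
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unknown_product_reaction_rejected(self, core_model, alpha):
        with pytest.raises(ModelContractError):
            maximize_product(core_model, "NOPE", autotroph_condition(alpha))


class TestNutrientScan:
    @pytest.mark.parametrize("nutrient", sorted(coremodel.NUTRIENT_EXCHANGES))
    def test_growth_glycogen_tradeoff_with_threshold(
        self, core_model, scan_condition, nutrient
    ):
        """Growth rises to saturation; glycogen is strictly positive below
        the optimal uptake and exactly zero at and above it."""
        conditioned = protocols.apply_condition(core_model, scan_condition)
        u_star = coremodel.optimal_uptake(
            conditioned, coremodel.NUTRIENT_EXCHANGES[nutrient]
        )
        grid = [f * u_star for f in (0.0, 0.3, 0.6, 0.9, 1.0, 1.3)]
        result = nutrient_scan(core_model, nutrient, grid, scan_condition)
        assert result.optimal_uptake == pytest.approx(u_star, abs=1e-6)
        growth = np.array(result.growth)
        glycogen = np.array(result.glycogen)
        assert np.all(np.diff(growth) >= -1e-9)          # non-decreasing
        assert np.all(np.diff(glycogen) <= 1e-9)         # non-increasing
        below = np.array(grid) < u_star - 1e-6
        assert np.all(glycogen[below] > 1e-6)            # storage below u*
        assert np.all(np.abs(glycogen[~below]) <= 1e-6)  # none at/above u*

    def test_zero_uptake_sends_all_fixed_carbon_to_glycogen(
        self, core_model, scan_condition
    ):
        result = nutrient_scan(core_model, "NO3", [0.0], scan_condition)
        assert result.growth[0] == pytest.approx(0.0, abs=1e-9)
        assert result.glycogen[0] > 0.1

    def test_two_stage_objective_dominance(self, core_model, scan_condition):
        """The reported glycogen never trades away attainable growth."""
        conditioned = protocols.apply_condition(core_model, scan_condition)
        exchange = coremodel.NUTRIENT_EXCHANGES["NO3"]
        u_star = coremodel.optimal_uptake(conditioned, exchange)
        point = conditioned.copy()
        point.reaction(exchange).bounds = (-0.5 * u_star, 0.0)
        mu = fba(FluxProblem.from_model(point)).objective_value
        result = nutrient_scan(
            core_model, "NO3", [0.5 * u_star], scan_condition
        )
        assert result.growth[0] == pytest.approx(mu, abs=1e-9)

    def test_empty_grid_is_contract_error(self, core_model, scan_condition):
        with pytest.raises(ModelContractError, match="empty"):
            nutrient_scan(core_model, "NO3", [], scan_condition)

    def test_unsorted_grid_rejected(self, core_model, scan_condition):
        with pytest.raises(ModelContractError, match="ascending"):
            nutrient_scan(core_model, "NO3", [0.1, 0.05], scan_condition)


class TestCarbonConservation:
    def test_balance_holds_at_reported_optima(self, core_model, alpha):
        """C in = C out (biomass + secreted + CO2) at every solution."""
        solutions = [
            simulate_growth(core_model, autotroph_condition(alpha)),
            simulate_growth(core_model, heterotroph_condition(alpha)),
            simulate_growth(core_model, mixotroph_condition(alpha)),
        ]
        scan = nutrient_scan(
            core_model, "NO3", [0.05], autotroph_condition(alpha, hco3_uptake=1.6)
        )
        for sol in solutions:
            book = carbon_balance(core_model, sol)
            assert book["residual"] == pytest.approx(0.0, abs=1e-6)
            assert book["carbon_uptake"] == pytest.approx(
                book["carbon_secreted"] + book["carbon_to_biomass"], abs=1e-6
            )
        assert scan is not None  # scan executed under carbon excess


class TestCentralFluxMap:
    def test_nutrient_sufficient_control_stores_no_glycogen(
        self, core_model, scan_condition
    ):
        frame = central_flux_map(core_model, scan_condition, "NO3", 1.0)
        assert frame.loc[coremodel.GLYCOGEN_SYNTHESIS, "flux"] == pytest.approx(
            0.0, abs=1e-6
        )

    def test_nitrate_limited_map_stores_glycogen(self, core_model, scan_condition):
        frame = central_flux_map(core_model, scan_condition, "NO3", 0.5)
        assert frame.loc[coremodel.GLYCOGEN_SYNTHESIS, "flux"] > 1e-3
        subsystems = set(frame["subsystem"])
        assert subsystems == set(coremodel.CENTRAL_SUBSYSTEMS)

    def test_reported_fluxes_lie_within_fva_ranges(self, core_model, scan_condition):
        """Containment: the centered solution respects the variability box."""
        conditioned = protocols.apply_condition(core_model, scan_condition)
        exchange = coremodel.NUTRIENT_EXCHANGES["NO3"]
        u_star = coremodel.optimal_uptake(conditioned, exchange)
        conditioned.reaction(exchange).bounds = (-0.5 * u_star, 0.0)
        mu = fba(FluxProblem.from_model(conditioned)).objective_value
        conditioned.reaction(coremodel.BIOMASS_ID).bounds = (mu - 1e-9, mu)
        box = fva(FluxProblem.from_model(conditioned))
        frame = central_flux_map(core_model, scan_condition, "NO3", 0.5)
        for rid, row in frame.iterrows():
            lo, hi = box[rid]
            assert lo - 1e-5 <= row["flux"] <= hi + 1e-5


class TestSecretionProfile:
    def test_autotroph_secretes_oxygen(self, core_model, alpha):
        sol = simulate_growth(core_model, autotroph_condition(alpha))
        secreted = dict(secretion_profile(sol, core_model))
        assert secreted.get("o2_c", 0.0) > 0.01

    def test_heterotroph_secretes_co2_and_consumes_o2(self, core_model, alpha):
        conditioned = protocols.apply_condition(
            core_model, heterotroph_condition(alpha)
        )
        sol = geometric_fba(FluxProblem.from_model(conditioned))
        secreted = dict(secretion_profile(sol, core_model))
        assert secreted.get("co2_c", 0.0) > 1e-3
        assert "o2_c" not in secreted
        assert sol.fluxes[coremodel.EX_O2] < -1e-3  # consumed

    def test_closed_model_secretes_nothing(self, core_model):
        from cyanoflux.netcore import Medium, apply_medium

        closed = apply_medium(core_model, Medium("closed"))
        closed.reaction(coremodel.ATPM_ID).bounds = (0.0, 1000.0)
        sol = fba(FluxProblem.from_model(closed))
        assert secretion_profile(sol, closed) == []


class TestValidationArithmetic:
    def test_percent_errors_reproduce_printed_values(self):
        """|exp - sim|/exp x 100 recovers the printed 1.2 / 0.9 / 0.8."""
        frame = validation_percent_errors()
        for condition in ("autotroph", "autotroph_high_light", "mixotroph"):
            row = frame.loc[condition]
            assert round(row["percent_error"], 1) == pytest.approx(
                row["printed_percent_error"]
            )

    def test_percent_error_of_exact_match_is_zero(self):
        assert percent_error(0.0255, 0.0255) == 0.0
        assert percent_error(0.0, 0.0) == 0.0
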