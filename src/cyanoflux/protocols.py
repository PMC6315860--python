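"""Simulation protocols: growth validation, product maximization under
nutrient depletion, nutrient-limitation scans and central flux maps.

The growth conditions mirror the standard validation table of the organism:
autotrophic (photons + bicarbonate), heterotrophic (glucose in the dark) and
mixotrophic (both).  Photon bounds are entered in the printed unit
(umol photons/m2/s) and converted to mmol photons/gDCW/h through the
calibrated factor alpha carried in the core-model manifest.

Nutrient scans use a two-stage objective: maximize growth first, then — with
growth fixed at its optimum — maximize the glycogen synthesis flux.  A
single-stage glycogen maximization would send every fixed carbon to storage
and could never reproduce the observed growth/glycogen trade-off curves, so
the two-stage scheme is the package's documented reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .coremodel import (
    BIOMASS_ID,
    CENTRAL_SUBSYSTEMS,
    EX_GLC,
    EX_HCO3,
    EX_PHOTON,
    GLYCOGEN_SYNTHESIS,
    NUTRIENT_EXCHANGES,
    optimal_uptake as _optimal_uptake_current_bounds,
    reference_medium,
)
from .netcore import Medium, MetabolicModel, ModelContractError, apply_medium
from .solver import (
    FLUX_TOL,
    FluxProblem,
    FluxSolution,
    InfeasibleProblemError,
    fba,
    geometric_fba,
)

#: numerical slack used when fixing growth at a previously computed optimum
GROWTH_FIX_TOL = 1e-9


class ProtocolError(RuntimeError):
    """Raised when a protocol cannot be executed as specified."""


@dataclass(frozen=True)
class GrowthCondition:
    """One validation-table growth condition.

    ``photon_irradiance`` is the printed surface value (umol photons/m2/s);
    ``alpha`` converts it to a flux bound in mmol photons/gDCW/h.  Uptake
    magnitudes are non-negative; the sign convention (uptake = negative
    exchange flux) is applied internally.
    """

    name: str
    alpha: float
    photon_irradiance: float = 0.0
    hco3_uptake: float = 0.0
    glucose_uptake_max: float = 0.0
    medium: Optional[Medium] = None
    fixed_growth: Optional[float] = None
    photon_exchange: str = EX_PHOTON
    hco3_exchange: str = EX_HCO3
    glucose_exchange: str = EX_GLC

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for name in ("photon_irradiance", "hco3_uptake", "glucose_uptake_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def photon_uptake(self) -> float:
        """Photon bound in mmol photons/gDCW/h."""
        return self.alpha * self.photon_irradiance


def autotroph_condition(alpha: float, irradiance: float = 100.0,
                        hco3_uptake: float = 0.2) -> GrowthCondition:
    return GrowthCondition("autotroph", alpha, photon_irradiance=irradiance,
                           hco3_uptake=hco3_uptake)


def heterotroph_condition(alpha: float,
                          glucose_uptake_max: float = 0.017) -> GrowthCondition:
    return GrowthCondition("heterotroph", alpha, photon_irradiance=0.0,
                           hco3_uptake=0.0, glucose_uptake_max=glucose_uptake_max)


def mixotroph_condition(alpha: float, irradiance: float = 100.0,
                        hco3_uptake: float = 0.2,
                        glucose_uptake_max: float = 0.017) -> GrowthCondition:
    return GrowthCondition("mixotroph", alpha, photon_irradiance=irradiance,
                           hco3_uptake=hco3_uptake,
                           glucose_uptake_max=glucose_uptake_max)


def apply_condition(model: MetabolicModel,
                    condition: GrowthCondition) -> MetabolicModel:
    """Medium + photon/HCO3-/glucose bounds + optional growth fixing."""
    medium = condition.medium or reference_medium()
    conditioned = apply_medium(model, medium)
    for rid, magnitude in (
        (condition.photon_exchange, condition.photon_uptake),
        (condition.hco3_exchange, condition.hco3_uptake),
        (condition.glucose_exchange, condition.glucose_uptake_max),
    ):
        if not conditioned.has_reaction(rid):
            raise ModelContractError(f"condition references unknown exchange {rid!r}")
        conditioned.reaction(rid).bounds = (-magnitude, 0.0)
    if condition.fixed_growth is not None:
        _fix_growth(conditioned, condition.fixed_growth)
    return conditioned


def _fix_growth(model: MetabolicModel, value: float) -> None:
    rxn = model.reaction(model.objective_id)
    rxn.bounds = (max(0.0, value - GROWTH_FIX_TOL), max(value, 0.0))


def simulate_growth(model: MetabolicModel,
                    condition: GrowthCondition) -> FluxSolution:
    """Maximize biomass under ``condition``; growth rate is in 1/h."""
    conditioned = apply_condition(model, condition)
    sol = fba(FluxProblem.from_model(conditioned))
    if not sol.optimal:
        binding = {
            rid: conditioned.reaction(rid).bounds
            for rid in (condition.photon_exchange, condition.hco3_exchange,
                        condition.glucose_exchange)
        }
        raise ProtocolError(
            f"growth simulation {condition.name!r} is {sol.status}; "
            f"uptake constraints: {binding}"
        )
    return sol


def maximize_product(
    model: MetabolicModel,
    product_reaction_id: str,
    condition: GrowthCondition,
    fixed_growth: float = 0.0,
) -> FluxSolution:
    """Fix growth and maximize a product flux (e.g. glycogen synthesis)."""
    conditioned = apply_condition(model, condition)
    if not conditioned.has_reaction(product_reaction_id):
        raise ModelContractError(
            f"no product reaction {product_reaction_id!r} in model"
        )
    _fix_growth(conditioned, fixed_growth)
    sol = fba(FluxProblem.from_model(conditioned,
                                     objective_id=product_reaction_id))
    if not sol.optimal:
        raise ProtocolError(
            f"product maximization is {sol.status} at fixed growth "
            f"{fixed_growth}"
        )
    return sol


@dataclass
class ScanResult:
    """Growth and glycogen curves over a nutrient-uptake grid."""

    nutrient: str
    grid: List[float]
    growth: List[float]
    glycogen: List[float]
    optimal_uptake: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "uptake": self.grid,
            "growth": self.growth,
            "glycogen": self.glycogen,
        })


def _two_stage(model: MetabolicModel) -> Tuple[float, float]:
    """Maximize growth, then glycogen at fixed optimal growth."""
    sol = fba(FluxProblem.from_model(model))
    if not sol.optimal:
        raise ProtocolError(f"growth stage is {sol.status}")
    mu = max(sol.objective_value, 0.0)
    staged = model.copy()
    _fix_growth(staged, mu)
    glyc = fba(FluxProblem.from_model(staged, objective_id=GLYCOGEN_SYNTHESIS))
    if not glyc.optimal:
        raise ProtocolError(f"glycogen stage is {glyc.status}")
    return mu, max(glyc.objective_value, 0.0)


def nutrient_scan(
    model: MetabolicModel,
    nutrient: str,
    grid: Sequence[float],
    condition: GrowthCondition,
) -> ScanResult:
    """Two-stage growth/glycogen curves as a nutrient uptake cap varies.

    ``nutrient`` is one of NO3, PO4, SO4.  The grid must be sorted ascending.
    ``optimal_uptake`` is the smallest cap achieving the unconstrained-
    nutrient growth optimum; glycogen is zero at and above it.
    """
    if nutrient not in NUTRIENT_EXCHANGES:
        raise ModelContractError(
            f"unknown nutrient {nutrient!r}; choose from "
            f"{sorted(NUTRIENT_EXCHANGES)}"
        )
    grid = list(grid)
    if not grid:
        raise ModelContractError("empty uptake grid")
    if any(b < a for a, b in zip(grid, grid[1:])) or grid[0] < 0:
        raise ModelContractError("grid must be non-negative and ascending")
    exchange = NUTRIENT_EXCHANGES[nutrient]
    conditioned = apply_condition(model, condition)
    growth_curve: List[float] = []
    glycogen_curve: List[float] = []
    for uptake in grid:
        point = conditioned.copy()
        point.reaction(exchange).bounds = (-uptake, 0.0)
        mu, glyc = _two_stage(point)
        growth_curve.append(mu)
        glycogen_curve.append(glyc)
    return ScanResult(
        nutrient=nutrient,
        grid=grid,
        growth=growth_curve,
        glycogen=glycogen_curve,
        optimal_uptake=_optimal_uptake_current_bounds(conditioned, exchange),
    )


def optimal_uptake(model: MetabolicModel, nutrient: str,
                   condition: GrowthCondition) -> float:
    """Growth-saturating uptake of a nutrient under a condition."""
    if nutrient not in NUTRIENT_EXCHANGES:
        raise ModelContractError(f"unknown nutrient {nutrient!r}")
    conditioned = apply_condition(model, condition)
    return _optimal_uptake_current_bounds(conditioned, NUTRIENT_EXCHANGES[nutrient])


def central_flux_map(
    model: MetabolicModel,
    condition: GrowthCondition,
    nutrient: str,
    fraction_of_optimal: float = 0.5,
) -> pd.DataFrame:
    """Central-metabolism fluxes by geometric FBA under nutrient limitation.

    The nutrient uptake is capped at ``fraction_of_optimal`` times its
    growth-saturating value; growth is fixed at its optimum under that cap
    and the glycogen synthesis flux at its two-stage optimum (the scan
    objective), then geometric FBA centers the remaining degrees of freedom.
    The unique flux distribution is reported for the central-metabolism
    reaction set (glycolysis, carbon fixation/CCM, non-oxidative pentose
    phosphate, TCA, glycogen).
    """
    if nutrient not in NUTRIENT_EXCHANGES:
        raise ModelContractError(f"unknown nutrient {nutrient!r}")
    if not 0.0 < fraction_of_optimal <= 1.0:
        raise ValueError("fraction_of_optimal must lie in (0, 1]")
    exchange = NUTRIENT_EXCHANGES[nutrient]
    conditioned = apply_condition(model, condition)
    u_star = _optimal_uptake_current_bounds(conditioned, exchange)
    conditioned.reaction(exchange).bounds = (-fraction_of_optimal * u_star, 0.0)
    mu, glyc = _two_stage(conditioned)
    _fix_growth(conditioned, mu)
    conditioned.reaction(GLYCOGEN_SYNTHESIS).bounds = (
        max(0.0, glyc - GROWTH_FIX_TOL), max(glyc, 0.0),
    )
    solution = geometric_fba(FluxProblem.from_model(conditioned))
    rows = []
    for rxn in conditioned.reactions:
        if rxn.subsystem in CENTRAL_SUBSYSTEMS:
            rows.append({
                "reaction": rxn.id,
                "name": rxn.name,
                "subsystem": rxn.subsystem,
                "flux": solution[rxn.id],
            })
    frame = pd.DataFrame(rows).set_index("reaction")
    frame.attrs["growth"] = solution.objective_value
    frame.attrs["nutrient"] = nutrient
    frame.attrs["uptake_cap"] = fraction_of_optimal * u_star
    frame.attrs["optimal_uptake"] = u_star
    return frame


def secretion_profile(
    solution: FluxSolution,
    model: MetabolicModel,
    tolerance: float = FLUX_TOL,
) -> List[Tuple[str, float]]:
    """Secreted species: exchanges with positive flux, sorted by magnitude."""
    out = []
    for rxn in model.exchanges:
        flux = solution.fluxes.get(rxn.id, 0.0)
        if flux > tolerance:
            (met_id,) = rxn.stoichiometry
            out.append((met_id, flux))
    return sorted(out, key=lambda item: -item[1])


def carbon_balance(model: MetabolicModel, solution: FluxSolution) -> Dict[str, float]:
    """Carbon bookkeeping of a solution.

    Internal reactions are elementally balanced, so the only net carbon
    terms are boundary reactions (exchanges) and the biomass equation; their
    flux-weighted sum must vanish at any feasible steady state.
    """
    from .biomass import parse_formula

    formulas = {m.id: m.formula for m in model.metabolites}

    def net_carbon(rxn) -> float:
        total = 0.0
        for mid, coeff in rxn.stoichiometry.items():
            formula = formulas[mid]
            if formula:
                total += coeff * parse_formula(formula).get("C", 0)
        return total

    # contribution = flux x net C production: positive terms create carbon
    # inside the system (uptake), negative terms remove it (secretion or
    # biomass drain); internal reactions are balanced and contribute nothing.
    uptake = secreted = biomass_drain = 0.0
    residual = 0.0
    for rxn in model.reactions:
        nc = net_carbon(rxn)
        if nc == 0.0:
            continue
        flux = solution.fluxes.get(rxn.id, 0.0)
        contribution = flux * nc
        residual += contribution
        if rxn.kind == "exchange":
            if contribution > 0:
                uptake += contribution
            else:
                secreted += -contribution
        elif rxn.kind == "biomass":
            biomass_drain += -contribution
    return {
        "carbon_uptake": uptake,
        "carbon_secreted": secreted,
        "carbon_to_biomass": biomass_drain,
        "residual": residual,
    }


# -- validation table ---------------------------------------------------------

#: printed growth-validation rows: condition name, photon irradiance,
#: HCO3- uptake, glucose uptake max, experimental and in-silico maximal
#: specific growth rates (1/h) and the printed percent error.
GROWTH_VALIDATION_TABLE: Tuple[Dict, ...] = (
    {"condition": "autotroph", "photon": 100.0, "hco3": 0.2, "glucose": 0.0,
     "experimental": 0.0255, "in_silico": 0.0252, "printed_percent_error": 1.2},
    {"condition": "autotroph_high_light", "photon": 200.0, "hco3": 0.25,
     "glucose": 0.0, "experimental": 0.0331, "in_silico": 0.0334,
     "printed_percent_error": 0.9},
    {"condition": "heterotroph", "photon": 0.0, "hco3": 0.0, "glucose": 0.017,
     "experimental": 0.0, "in_silico": 0.0, "printed_percent_error": 0.0},
    {"condition": "mixotroph", "photon": 100.0, "hco3": 0.2, "glucose": 0.017,
     "experimental": 0.0262, "in_silico": 0.0260, "printed_percent_error": 0.8},
)


def percent_error(experimental: float, in_silico: float) -> float:
    """|experimental - in_silico| / experimental x 100."""
    if experimental == 0.0:
        return 0.0 if in_silico == 0.0 else float("inf")
    return abs(experimental - in_silico) / abs(experimental) * 100.0


def validation_percent_errors() -> pd.DataFrame:
    """Recompute the validation-table percent errors from its rate pairs."""
    rows = []
    for row in GROWTH_VALIDATION_TABLE:
        rows.append({
            "condition": row["condition"],
            "experimental": row["experimental"],
            "in_silico": row["in_silico"],
            "percent_error": percent_error(row["experimental"], row["in_silico"]),
            "printed_percent_error": row["printed_percent_error"],
        })
    return pd.DataFrame(rows).set_index("condition")
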