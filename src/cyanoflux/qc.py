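"""Model quality control.

Three audits used while curating a reconstruction:

* elemental/charge balance of every reaction (exchange, biomass, maintenance
  and artificial reactions are exempt by construction — they intentionally
  create or destroy matter);
* energy-leak tests: with every uptake closed, a curated network must not be
  able to run its ATP maintenance reaction (type-II, energy-generating
  cycles) nor a probe oxidation NAD(P)H -> NAD(P) + H (type-III, internal
  cycles);
* producibility: the biomass optimum under a medium, plus a per-precursor
  drain test that names any blocked biomass component (growth gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .biomass import FormulaError, parse_formula
from .netcore import (
    Medium,
    MetabolicModel,
    ModelContractError,
    Reaction,
    apply_medium,
)
from .solver import FLUX_TOL, FluxProblem, fba

#: flux below which a closed-system probe optimum counts as leak-free
LEAK_TOL = 1e-6

#: reaction kinds exempt from balance checking
EXEMPT_KINDS = frozenset({"exchange", "biomass", "maintenance", "artificial"})

#: cofactor pairs probed by the reducing-power leak test, as (reduced,
#: oxidized) cytoplasmic species; the probe reaction is red -> ox + H+.
NADPH_PAIRS = (("nadph_c", "nadp_c"), ("nadh_c", "nad_c"))


@dataclass
class ReactionBalance:
    """Per-reaction balance record."""

    reaction_id: str
    flag: str  # balanced | unbalanced | unverifiable | exempt
    element_imbalance: Dict[str, float] = field(default_factory=dict)
    charge_imbalance: float = 0.0


@dataclass
class BalanceReport:
    entries: Dict[str, ReactionBalance]

    @property
    def unbalanced(self) -> List[str]:
        return [rid for rid, e in self.entries.items() if e.flag == "unbalanced"]

    @property
    def unverifiable(self) -> List[str]:
        return [rid for rid, e in self.entries.items() if e.flag == "unverifiable"]

    def __getitem__(self, rid: str) -> ReactionBalance:
        return self.entries[rid]


@dataclass
class LeakReport:
    """Outcome of a closed-exchange energy probe."""

    probe: str  # "ATP" or "NAD(P)H"
    max_flux: float
    offending_cycle: List[str] = field(default_factory=list)

    @property
    def leak_free(self) -> bool:
        return self.max_flux <= LEAK_TOL


@dataclass
class ProducibilityReport:
    biomass_optimum: float
    precursor_flux: Dict[str, float]
    blocked_precursors: List[str]


def check_balance(model: MetabolicModel, tol: float = 1e-9) -> BalanceReport:
    """Elemental and charge audit of every reaction.

    For each non-exempt reaction the per-element sums of stoichiometry x
    formula and the charge sum are computed; reactions touching a species
    with an empty or unparseable formula are flagged unverifiable rather
    than failed (R-group species legitimately remain in curated models).
    Scaling a reaction's stoichiometry scales its imbalance identically.
    """
    formulas: Dict[str, Optional[Dict[str, int]]] = {}
    for met in model.metabolites:
        if not met.formula:
            formulas[met.id] = None
        else:
            try:
                formulas[met.id] = parse_formula(met.formula)
            except FormulaError:
                formulas[met.id] = None
    entries: Dict[str, ReactionBalance] = {}
    for rxn in model.reactions:
        if rxn.kind in EXEMPT_KINDS:
            entries[rxn.id] = ReactionBalance(rxn.id, "exempt")
            continue
        if any(formulas[mid] is None for mid in rxn.stoichiometry):
            entries[rxn.id] = ReactionBalance(rxn.id, "unverifiable")
            continue
        elements: Dict[str, float] = {}
        charge = 0.0
        for mid, coeff in rxn.stoichiometry.items():
            for el, count in formulas[mid].items():
                elements[el] = elements.get(el, 0.0) + coeff * count
            charge += coeff * model.metabolite(mid).charge
        imbalance = {el: v for el, v in elements.items() if abs(v) > tol}
        flag = "balanced" if not imbalance and abs(charge) <= tol else "unbalanced"
        entries[rxn.id] = ReactionBalance(
            rxn.id, flag, imbalance, charge if abs(charge) > tol else 0.0
        )
    return BalanceReport(entries)


def _closed_copy(model: MetabolicModel) -> MetabolicModel:
    """Copy with every uptake closed and maintenance demands relaxed.

    Maintenance lower bounds (NGAM) are dropped to 0: a closed system cannot
    pay them, and the leak probes ask what the network *can* produce, not
    what it must.
    """
    closed = model.copy()
    for rxn in closed.reactions:
        if rxn.kind == "exchange":
            rxn.bounds = (0.0, rxn.upper_bound)
        elif rxn.kind == "maintenance" and rxn.lower_bound > 0:
            rxn.bounds = (0.0, rxn.upper_bound)
    return closed


def _support(fluxes: Dict[str, float], exclude: Tuple[str, ...]) -> List[str]:
    return sorted(
        rid for rid, v in fluxes.items()
        if abs(v) > FLUX_TOL and rid not in exclude
    )


def leak_test_atp(model: MetabolicModel) -> LeakReport:
    """Maximize the ATP maintenance flux with all uptakes closed.

    A leak-free network yields 0: ATP cannot be regenerated without nutrient
    or photon input.  A positive optimum exposes a type-II energy-generating
    cycle; its nonzero-flux support is reported for manual inspection.
    The input model is never mutated.
    """
    maintenance = [r for r in model.reactions if r.kind == "maintenance"]
    if not maintenance:
        raise ModelContractError("model has no ATP maintenance reaction")
    target = maintenance[0]
    closed = _closed_copy(model)
    closed.reaction(target.id).bounds = (0.0, max(1000.0, target.upper_bound))
    problem = FluxProblem.from_model(closed, objective_id=target.id, sense="maximize")
    sol = fba(problem)
    if not sol.optimal:
        raise ModelContractError(f"leak LP returned status {sol.status}")
    max_flux = max(sol.objective_value, 0.0)
    offending = _support(sol.fluxes, (target.id,)) if max_flux > LEAK_TOL else []
    return LeakReport(probe="ATP", max_flux=max_flux, offending_cycle=offending)


def leak_test_nadph(model: MetabolicModel) -> LeakReport:
    """Probe NAD(P)H regeneration under closed exchanges.

    Temporarily adds an artificial oxidation ``NAD(P)H -> NAD(P) + H`` for
    each cofactor pair present, maximizes it with all uptakes closed, and
    removes the probe afterwards (the test works on a copy; the input model
    is unchanged).  The report carries the worst pair's optimum.
    """
    pairs = [
        (red, ox) for red, ox in NADPH_PAIRS
        if model.has_metabolite(red) and model.has_metabolite(ox)
    ]
    if not pairs:
        raise ModelContractError("model contains no NAD(P)H/NAD(P) cofactor pair")
    h_id = "h_c" if model.has_metabolite("h_c") else None
    worst = LeakReport(probe="NAD(P)H", max_flux=0.0)
    for red, ox in pairs:
        closed = _closed_copy(model)
        stoich = {red: -1.0, ox: 1.0}
        if h_id:
            stoich[h_id] = 1.0
        probe_id = f"__probe_{red}"
        closed.add_reaction(
            Reaction(
                id=probe_id,
                name=f"artificial {red} oxidation probe",
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=1000.0,
                kind="artificial",
            )
        )
        problem = FluxProblem.from_model(closed, objective_id=probe_id)
        sol = fba(problem)
        if not sol.optimal:
            raise ModelContractError(f"leak LP returned status {sol.status}")
        flux = max(sol.objective_value, 0.0)
        if flux >= worst.max_flux:
            offending = _support(sol.fluxes, (probe_id,)) if flux > LEAK_TOL else []
            worst = LeakReport(
                probe="NAD(P)H", max_flux=flux, offending_cycle=offending
            )
    return worst


#: conserved-moiety cofactors drained against their partner species
_COFACTOR_PARTNERS = {
    "atp_c": {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
    "nadph_c": {"nadph_c": -1.0, "nadp_c": 1.0, "h_c": 1.0},
    "nadh_c": {"nadh_c": -1.0, "nad_c": 1.0, "h_c": 1.0},
}


def _cofactor_drain(model: MetabolicModel, mid: str) -> Optional[Dict[str, float]]:
    stoich = _COFACTOR_PARTNERS.get(mid)
    if stoich and all(model.has_metabolite(m) for m in stoich):
        return dict(stoich)
    return None


def check_producibility(
    model: MetabolicModel, medium: Medium
) -> ProducibilityReport:
    """Biomass optimum under ``medium`` plus per-precursor drain maxima.

    Each biomass precursor gets a temporary drain reaction that is maximized
    with the biomass reaction silenced; precursors whose drain optimum is
    below tolerance are reported blocked (growth gaps).  Energy cofactors
    (ATP, NAD(P)H) are conserved moieties — a bare drain can never carry
    flux — so they are drained against their partner (hydrolysis/oxidation),
    probing regenerability instead.
    """
    if model.objective_id is None:
        raise ModelContractError("model declares no biomass objective")
    conditioned = apply_medium(model, medium)
    biomass_rxn = conditioned.reaction(conditioned.objective_id)
    sol = fba(FluxProblem.from_model(conditioned))
    biomass_optimum = sol.objective_value if sol.optimal else 0.0

    precursors = [mid for mid, c in biomass_rxn.stoichiometry.items() if c < 0]
    flux: Dict[str, float] = {}
    blocked: List[str] = []
    for mid in precursors:
        probe = conditioned.copy()
        probe.reaction(biomass_rxn.id).bounds = (0.0, 0.0)
        drain_id = f"__drain_{mid}"
        stoich = _cofactor_drain(probe, mid) or {mid: -1.0}
        probe.add_reaction(
            Reaction(
                id=drain_id,
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=1000.0,
                kind="artificial",
            )
        )
        drain_sol = fba(FluxProblem.from_model(probe, objective_id=drain_id))
        value = drain_sol.objective_value if drain_sol.optimal else 0.0
        flux[mid] = value
        if value <= LEAK_TOL:
            blocked.append(mid)
    return ProducibilityReport(
        biomass_optimum=biomass_optimum,
        precursor_flux=flux,
        blocked_precursors=blocked,
    )
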