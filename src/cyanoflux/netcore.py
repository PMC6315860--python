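"""Network data model for constraint-based metabolic modeling.

A metabolic network is represented as metabolites (with elemental formula,
charge and compartment), reactions (stoichiometry maps with flux bounds in
mmol/gDCW/h), and a model object that assembles the stoichiometric matrix S
whose null-space intersected with the flux bounds defines the feasible
steady-state flux cone (Sv = 0).

Sign conventions follow COBRA practice: negative stoichiometric coefficients
consume, positive produce; for exchange reactions negative flux is uptake and
positive flux is secretion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
from scipy import sparse

#: Bound magnitude standing in for "unconstrained" (the conventional +/-1000).
DEFAULT_BOUND = 1000.0

#: Allowed reaction kinds.
REACTION_KINDS = (
    "enzymatic",
    "transport",
    "exchange",
    "biomass",
    "maintenance",
    "artificial",
)

#: The six intracellular compartments of a fully compartmentalized
#: cyanobacterial reconstruction, plus the extracellular space.
COMPARTMENTS = (
    "carboxysome",
    "thylakoid lumen",
    "thylakoid membrane",
    "cytoplasmic membrane",
    "cytoplasm",
    "periplasm",
    "extracellular",
)


class ModelStructureError(ValueError):
    """Raised when a model violates a structural invariant."""


class ModelContractError(ValueError):
    """Raised when an operation's precondition is violated."""


class ParseError(ValueError):
    """Raised on malformed model files; carries a location hint."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in a specific compartment.

    ``formula`` is a Hill-style elemental formula over C, H, N, O, P, S; it
    may be empty for unspecified species (R-groups, photons, pseudo-species),
    in which case mass bookkeeping treats the species as unverifiable.
    """

    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = "cytoplasm"


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite ids to coefficients (negative =
    consumed).  Bounds are in mmol/gDCW/h; the biomass reaction's flux is the
    specific growth rate in 1/h.  ``confidence`` is the 1-4 evidence score
    carried as curation metadata only — it never affects simulation.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gpr: str = ""
    subsystem: str = ""
    confidence: Optional[int] = None
    kind: str = "enzymatic"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.kind not in REACTION_KINDS:
            raise ModelStructureError(
                f"reaction {self.id!r}: unknown kind {self.kind!r}"
            )

    @property
    def reversible(self) -> bool:
        """True iff the reaction can carry negative flux."""
        return self.lower_bound < 0

    @property
    def bounds(self) -> Tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value: Tuple[float, float]) -> None:
        lb, ub = value
        if lb > ub:
            raise ModelStructureError(
                f"reaction {self.id!r}: lower bound {lb} exceeds upper bound {ub}"
            )
        self.lower_bound, self.upper_bound = float(lb), float(ub)

    def copy(self) -> "Reaction":
        return dataclasses.replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass(frozen=True)
class Medium:
    """A named growth condition: bounds for the listed exchange reactions.

    Exchanges listed in ``exchange_bounds`` receive exactly those bounds (for
    a nutrient present in the medium the conventional entry is ``(-1000, 0)``,
    i.e. uptake between 0 and 1000).  Exchange ids in ``unconstrained`` are
    opened to ``(-1000, 1000)`` (the treatment of CO2, O2 and H2O).  Every
    other exchange is closed to uptake (lower bound 0) while its secretion
    bound is left untouched.
    """

    name: str
    exchange_bounds: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    unconstrained: frozenset = frozenset()

    def __post_init__(self) -> None:
        for rid, (lb, ub) in self.exchange_bounds.items():
            if lb > ub:
                raise ModelStructureError(
                    f"medium {self.name!r}: bounds for {rid!r} are unordered"
                )

    def without(self, *exchange_ids: str) -> "Medium":
        """A copy of this medium with the named exchanges removed (depleted)."""
        kept = {
            rid: b for rid, b in self.exchange_bounds.items()
            if rid not in exchange_ids
        }
        return Medium(
            name=f"{self.name} -{'-'.join(exchange_ids)}",
            exchange_bounds=kept,
            unconstrained=self.unconstrained,
        )


class MetabolicModel:
    """A metabolic network: metabolites, reactions and an objective."""

    def __init__(
        self,
        id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective_id: Optional[str] = None,
        compartments: Optional[Set[str]] = None,
        gene_ids: Optional[Set[str]] = None,
    ) -> None:
        self.id = id
        self.metabolites: List[Metabolite] = []
        self.reactions: List[Reaction] = []
        self._met_index: Dict[str, int] = {}
        self._rxn_index: Dict[str, int] = {}
        self.compartments: Set[str] = set(compartments or [])
        self.gene_ids: Set[str] = set(gene_ids or [])
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)
        self.objective_id = objective_id

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ModelStructureError(f"duplicate metabolite id {met.id!r}")
        if self.compartments and met.compartment not in self.compartments:
            raise ModelStructureError(
                f"metabolite {met.id!r}: compartment {met.compartment!r} not in "
                f"the model's declared compartment set"
            )
        self._met_index[met.id] = len(self.metabolites)
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ModelStructureError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        if rxn.kind == "exchange" and len(rxn.stoichiometry) != 1:
            raise ModelStructureError(
                f"exchange reaction {rxn.id!r} must touch exactly one metabolite"
            )
        self._rxn_index[rxn.id] = len(self.reactions)
        self.reactions.append(rxn)

    def remove_reaction(self, rxn_id: str) -> Reaction:
        idx = self._rxn_index.pop(rxn_id, None)
        if idx is None:
            raise KeyError(rxn_id)
        rxn = self.reactions.pop(idx)
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if self.objective_id == rxn_id:
            self.objective_id = None
        return rxn

    # -- lookup ------------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            compartments=set(self.compartments),
            gene_ids=set(self.gene_ids),
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ModelStructureError if broken."""
        if self.objective_id is not None and self.objective_id not in self._rxn_index:
            raise ModelStructureError(
                f"objective {self.objective_id!r} does not resolve to a reaction"
            )
        for rxn in self.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelStructureError(f"reaction {rxn.id!r}: unordered bounds")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


def build_stoichiometric_matrix(model: MetabolicModel, dense: bool = False):
    """Assemble the stoichiometric matrix S of ``model``.

    Entry (i, j) is the coefficient of metabolite i in reaction j; row order
    follows ``model.metabolites`` and column order follows ``model.reactions``.
    Returns a CSR sparse matrix, or an ndarray when ``dense`` is true.
    """
    n_met, n_rxn = len(model.metabolites), len(model.reactions)
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            i = met_index.get(met_id)
            if i is None:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
            rows.append(i)
            cols.append(j)
            data.append(float(coeff))
    mat = sparse.csr_matrix(
        (data, (rows, cols)), shape=(n_met, n_rxn), dtype=float
    )
    return mat.toarray() if dense else mat


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set by ``medium``.

    Listed exchanges get the medium's bounds; exchanges flagged unconstrained
    get (-1000, 1000); every other exchange is reset to secretion-only
    (0, 1000) — uptake closed, secretion allowed.  Non-exchange reactions are
    never altered.  Applying the same medium twice is idempotent.
    """
    for rid in list(medium.exchange_bounds) + list(medium.unconstrained):
        if not model.has_reaction(rid):
            raise ModelContractError(f"medium references unknown reaction {rid!r}")
        if model.reaction(rid).kind != "exchange":
            raise ModelContractError(
                f"medium entry {rid!r} resolves to a non-exchange reaction"
            )
    out = model.copy()
    for rxn in out.reactions:
        if rxn.kind != "exchange":
            continue
        if rxn.id in medium.exchange_bounds:
            rxn.bounds = medium.exchange_bounds[rxn.id]
        elif rxn.id in medium.unconstrained:
            rxn.bounds = (-DEFAULT_BOUND, DEFAULT_BOUND)
        else:
            rxn.bounds = (0.0, DEFAULT_BOUND)
    return out


# -- reaction-equation strings (TSV dialect) -------------------------------


def format_equation(rxn: Reaction) -> str:
    """Render stoichiometry as e.g. ``1 g1p_c -> 1 glycogen_c + 1 pi_c``."""

    def side(items):
        return " + ".join(f"{coeff!r} {met}" for met, coeff in items) or ""

    lhs = [(m, -c) for m, c in sorted(rxn.stoichiometry.items()) if c < 0]
    rhs = [(m, c) for m, c in sorted(rxn.stoichiometry.items()) if c > 0]
    arrow = "<=>" if rxn.reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


def parse_equation(text: str, location: str = "") -> Dict[str, float]:
    """Parse a reaction-equation string into a stoichiometry map."""
    for arrow in ("<=>", "<->", "->", "=>"):
        if arrow in text:
            lhs_text, rhs_text = text.split(arrow, 1)
            break
    else:
        raise ParseError(f"{location}: no reaction arrow in equation {text!r}")
    stoich: Dict[str, float] = {}

    def add_side(side_text: str, sign: float) -> None:
        side_text = side_text.strip()
        if not side_text:
            return
        for term in side_text.split(" + "):
            parts = term.strip().split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError as exc:
                    raise ParseError(
                        f"{location}: bad coefficient in term {term!r}"
                    ) from exc
                met = parts[1]
            else:
                raise ParseError(f"{location}: malformed term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(lhs_text, -1.0)
    add_side(rhs_text, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}
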