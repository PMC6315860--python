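"""Biomass-equation construction from macromolecular composition.

The biomass reaction is the pseudo-reaction whose flux is the specific growth
rate (1/h): per gram dry cell weight it drains the monomeric precursors of
each macromolecular pool (protein residues, glycogen monomer, lipid, NMP/dNMP
residues, pigments, mineral ions) in mmol/gDCW, plus a growth-associated
maintenance (GAM) ATP hydrolysis, and produces one unit of a biomass
pseudo-metabolite removed by a drain exchange.

For a pool with mass fraction f (%w/w) and a monomer table of mole fractions
x_k with residue molar masses M_k (g/mol, as polymerized), the coefficient of
monomer k is::

    c_k = 10 * f * x_k / sum_j(x_j * M_j)      [mmol/gDCW]

so that sum_k c_k * M_k = 10 * f mg/gDCW and the total precursor mass drained
per unit growth is 1000 * (100 - ash) / 100 mg (ash carries no precursor).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .netcore import Reaction

#: Standard atomic weights used for all mass accounting (g/mol).
ATOMIC_WEIGHTS = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: The macromolecular pools of the reference composition.
COMPONENTS = (
    "proteins",
    "carbohydrates",
    "lipids",
    "DNA",
    "RNA",
    "colorants",
    "vitamins",
    "minerals",
    "ash",
)


class CompositionError(ValueError):
    """Raised when a biomass composition violates its invariants."""


class FormulaError(ValueError):
    """Raised when an elemental formula cannot be parsed."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-style formula over C,H,N,O,P,S into element counts."""
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at offset {pos}")
        pos = match.end()
        element, digits = match.group(1), match.group(2)
        if element not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise FormulaError(f"cannot parse formula {formula!r} at offset {pos}")
    return counts


def molar_mass(formula: str) -> float:
    """Molar mass (g/mol) of an elemental formula, e.g. C6H10O5 -> 162.141."""
    counts = parse_formula(formula)
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class MonomerSpec:
    """A monomeric precursor as it sits in the polymer.

    ``molar_mass`` is the residue mass as polymerized (g/mol), e.g. the
    glycogen glucosyl monomer C6H10O5 at 162.141.  ``energy_cost`` is mmol
    ATP hydrolyzed per mmol monomer incorporated (0 when polymerization
    energy is carried by GAM instead).
    """

    metabolite_id: str
    molar_mass: float
    energy_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise CompositionError(
                f"monomer {self.metabolite_id!r}: molar mass must be positive"
            )

    @classmethod
    def from_formula(
        cls, metabolite_id: str, formula: str, energy_cost: float = 0.0
    ) -> "MonomerSpec":
        return cls(metabolite_id, molar_mass(formula), energy_cost)


MonomerTable = Sequence[Tuple[MonomerSpec, float]]


@dataclass
class BiomassComposition:
    """Macromolecular mass fractions plus monomer tables and GAM.

    ``fractions`` maps component name to %w/w and must sum to 100 +/- 0.5.
    Each monomer table's mole fractions must sum to 1 (tables are normalized
    on input, so any common scaling of a table is equivalent).  Components
    without a monomer table (ash) drain no precursor.
    """

    fractions: Dict[str, float]
    monomer_tables: Dict[str, MonomerTable] = field(default_factory=dict)
    gam: float = 30.0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 100.0) > 0.5:
            raise CompositionError(
                f"mass fractions sum to {total:.3f}%, expected 100 +/- 0.5"
            )
        if any(f < 0 for f in self.fractions.values()):
            raise CompositionError("mass fractions must be non-negative")
        normalized = {}
        for comp, table in self.monomer_tables.items():
            if comp not in self.fractions:
                raise CompositionError(f"monomer table for unknown component {comp!r}")
            total_x = sum(x for _, x in table)
            if total_x <= 0:
                raise CompositionError(f"component {comp!r}: empty monomer table")
            normalized[comp] = tuple((spec, x / total_x) for spec, x in table)
        self.monomer_tables = normalized


def polymer_coefficients(
    mass_fraction: float, monomer_table: MonomerTable
) -> Dict[str, float]:
    """Precursor coefficients (mmol/gDCW) for one macromolecular pool.

    ``mass_fraction`` is in %w/w.  Mole fractions are normalized internally,
    so scaling the whole table by a common factor changes nothing.
    """
    if not monomer_table:
        raise CompositionError("empty monomer table")
    total_x = sum(x for _, x in monomer_table)
    if total_x <= 0:
        raise CompositionError("monomer mole fractions must have a positive sum")
    mean_mass = sum(spec.molar_mass * x for spec, x in monomer_table) / total_x
    coeffs: Dict[str, float] = {}
    for spec, x in monomer_table:
        c = 10.0 * mass_fraction * (x / total_x) / mean_mass
        coeffs[spec.metabolite_id] = coeffs.get(spec.metabolite_id, 0.0) + c
    return coeffs


def precursor_mass(composition: BiomassComposition) -> float:
    """Total precursor mass drained per unit biomass flux (mg/gDCW)."""
    total = 0.0
    for comp, table in composition.monomer_tables.items():
        coeffs = polymer_coefficients(composition.fractions[comp], table)
        masses = {spec.metabolite_id: spec.molar_mass for spec, _ in table}
        total += sum(c * masses[mid] for mid, c in coeffs.items())
    return total


def build_biomass_reaction(
    composition: BiomassComposition,
    reaction_id: str = "BIOMASS",
    biomass_metabolite: str = "biomass_c",
    atp: str = "atp_c",
    adp: str = "adp_c",
    pi: str = "pi_c",
    h2o: str = "h2o_c",
    h: str = "h_c",
) -> Reaction:
    """Compile a composition into the biomass reaction (flux unit 1/h).

    Consumes the pooled monomer coefficients plus (GAM + monomer energy
    costs) ATP hydrolyzed to ADP + Pi + H, and produces 1 biomass unit.
    """
    stoich: Dict[str, float] = {}
    energy = composition.gam
    for comp, table in composition.monomer_tables.items():
        coeffs = polymer_coefficients(composition.fractions[comp], table)
        costs = {spec.metabolite_id: spec.energy_cost for spec, _ in table}
        for mid, c in coeffs.items():
            stoich[mid] = stoich.get(mid, 0.0) - c
            energy += c * costs[mid]
    for mid, coeff in (
        (atp, -energy),
        (h2o, -energy),
        (adp, +energy),
        (pi, +energy),
        (h, +energy),
    ):
        stoich[mid] = stoich.get(mid, 0.0) + coeff
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    stoich[biomass_metabolite] = 1.0
    return Reaction(
        id=reaction_id,
        name="Biomass synthesis",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="Biomass and maintenance",
        kind="biomass",
    )


def element_census(
    composition: BiomassComposition,
    formulas: Mapping[str, str],
    element: str,
) -> float:
    """mmol of ``element`` drained per gDCW by the composition's precursors.

    ``formulas`` maps monomer metabolite ids to elemental formulas; monomers
    without a formula entry contribute nothing (unverifiable species).
    """
    total = 0.0
    for comp, table in composition.monomer_tables.items():
        coeffs = polymer_coefficients(composition.fractions[comp], table)
        for mid, c in coeffs.items():
            formula = formulas.get(mid, "")
            if formula:
                total += c * parse_formula(formula).get(element, 0)
    return total


# -- reference composition ---------------------------------------------------

#: Measured macromolecular composition of exponentially growing
#: A. platensis C1 (%w/w) used as the package's reference biomass.
REFERENCE_FRACTIONS = {
    "proteins": 51.44,
    "carbohydrates": 31.62,
    "lipids": 4.98,
    "DNA": 0.88,
    "RNA": 3.12,
    "colorants": 2.84,
    "vitamins": 0.11,
    "minerals": 2.79,
    "ash": 2.27,
}

# Residue formulas as polymerized (amino acid / NMP minus water; neutral
# bookkeeping forms).  The amino-acid palette and its mole fractions are a
# genome-style frequency table reduced to six residues chosen so that N and S
# demand per gDCW are well defined; see docs/methods.md.
RESIDUE_FORMULAS = {
    "ala_res_c": "C3H5NO",
    "gly_res_c": "C2H3NO",
    "ser_res_c": "C3H5NO2",
    "cys_res_c": "C3H5NOS",
    "asp_res_c": "C4H5NO3",
    "glu_res_c": "C5H7NO3",
    "ramp_res_c": "C10H12N5O6P",
    "rump_res_c": "C9H11N2O8P",
    "dgmp_res_c": "C10H12N5O6P",
    "dtmp_res_c": "C10H13N2O7P",
    "lipid_c": "C41H79O10P",
    "pigment_c": "C33H38N4O6",
    "glycogen_bm_c": "C6H10O5",
    "so4_c": "O4S",
    "pi_c": "HPO4",
}

PROTEIN_MOLE_FRACTIONS = {
    "ala_res_c": 0.25,
    "gly_res_c": 0.15,
    "ser_res_c": 0.12,
    "cys_res_c": 0.04,
    "asp_res_c": 0.20,
    "glu_res_c": 0.24,
}

#: Default growth-associated maintenance, mmol ATP/gDCW.
DEFAULT_GAM = 30.0


def load_composition(path: str) -> BiomassComposition:
    """Read a biomass composition from a YAML config file.

    Layout::

        gam: 30.0
        fractions: {proteins: 51.44, ...}
        monomer_tables:
          proteins:
            - {metabolite: ala_res_c, formula: C3H5NO, mole_fraction: 0.25}
            - {metabolite: x_c, molar_mass: 123.4, mole_fraction: 0.75,
               energy_cost: 1.0}

    Each monomer needs either a formula or an explicit molar mass.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    tables: Dict[str, MonomerTable] = {}
    for component, entries in (raw.get("monomer_tables") or {}).items():
        rows = []
        for entry in entries:
            if "formula" in entry:
                spec = MonomerSpec.from_formula(
                    entry["metabolite"], entry["formula"],
                    entry.get("energy_cost", 0.0),
                )
            elif "molar_mass" in entry:
                spec = MonomerSpec(
                    entry["metabolite"], float(entry["molar_mass"]),
                    entry.get("energy_cost", 0.0),
                )
            else:
                raise CompositionError(
                    f"{path}: monomer {entry.get('metabolite')!r} in "
                    f"{component!r} needs a formula or molar_mass"
                )
            rows.append((spec, float(entry["mole_fraction"])))
        tables[component] = tuple(rows)
    return BiomassComposition(
        fractions={k: float(v) for k, v in raw["fractions"].items()},
        monomer_tables=tables,
        gam=float(raw.get("gam", DEFAULT_GAM)),
    )


def save_composition(composition: BiomassComposition, path: str) -> None:
    """Write a composition as a YAML config (inverse of load_composition)."""
    import yaml

    payload = {
        "gam": composition.gam,
        "fractions": dict(composition.fractions),
        "monomer_tables": {
            component: [
                {
                    "metabolite": spec.metabolite_id,
                    "molar_mass": spec.molar_mass,
                    "mole_fraction": x,
                    "energy_cost": spec.energy_cost,
                }
                for spec, x in monomers
            ]
            for component, monomers in composition.monomer_tables.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _table(entries: Mapping[str, float]) -> MonomerTable:
    return tuple(
        (MonomerSpec.from_formula(mid, RESIDUE_FORMULAS[mid]), x)
        for mid, x in entries.items()
    )


def reference_composition(gam: float = DEFAULT_GAM) -> BiomassComposition:
    """The package's reference biomass composition (Zarrouk-grown cells).

    Carbohydrate is drained as the glycogen glucosyl monomer (C6H10O5,
    162.141 g/mol); colorants and vitamins share a phycobilin-like pigment
    pseudo-monomer; minerals are drained as free sulfate + phosphate; ash
    drains nothing.
    """
    return BiomassComposition(
        fractions=dict(REFERENCE_FRACTIONS),
        monomer_tables={
            "proteins": _table(PROTEIN_MOLE_FRACTIONS),
            "carbohydrates": _table({"glycogen_bm_c": 1.0}),
            "lipids": _table({"lipid_c": 1.0}),
            "DNA": _table({"dgmp_res_c": 0.5, "dtmp_res_c": 0.5}),
            "RNA": _table({"ramp_res_c": 0.5, "rump_res_c": 0.5}),
            "colorants": _table({"pigment_c": 1.0}),
            "vitamins": _table({"pigment_c": 1.0}),
            "minerals": _table({"so4_c": 0.5, "pi_c": 0.5}),
        },
        gam=gam,
    )
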