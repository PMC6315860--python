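"""Programmatic generator of a reduced cyanobacterial core model.

The generator emulates, at desk scale, the central metabolism of a
photoautotrophic cyanobacterium (*Arthrospira platensis*-like): lumped
photosystems and cyclic electron flow, bicarbonate transport + carbonic
anhydrase (the carbon-concentrating mechanism), a Calvin–Benson–Bassham
lump, glycolysis/gluconeogenesis, the non-oxidative pentose phosphate
interconversion, the cyanobacterial TCA cycle with the 2-oxoglutarate ->
succinate bypass, nitrate/sulfate/phosphate assimilation, glycogen
synthesis/degradation/storage, overflow secretion routes (pyruvate, acetate,
lactate), an NGAM ATP maintenance reaction and a composition-derived biomass
equation.

Every internal reaction is exactly elementally and charge balanced: lumped
biosynthesis reactions are closed by an exact (rational-arithmetic) solver
over the currency species {CO2, NH4+, H2O, H+, Pi, NADPH/NADP+, SO4^2-},
whose span covers C, H, N, O, P, S and charge.  The generator is fully
deterministic: identical parameters give identical models.

Also provided: tiny named toy networks with analytically known optima (LP /
FVA / leak-test oracles) and the optimal-uptake bisection used by the
nutrient-scan protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

from . import biomass as bm
from .netcore import (
    DEFAULT_BOUND,
    Medium,
    MetabolicModel,
    Metabolite,
    ModelContractError,
    Reaction,
)
from .solver import FluxProblem, InfeasibleProblemError, fba

# -- exchange / reaction id constants -----------------------------------------

EX_PHOTON = "EX_photon"
EX_CO2 = "EX_co2"
EX_O2 = "EX_o2"
EX_H2O = "EX_h2o"
EX_H = "EX_h"
EX_HCO3 = "EX_hco3"
EX_NO3 = "EX_no3"
EX_PI = "EX_pi"
EX_SO4 = "EX_so4"
EX_GLC = "EX_glc"
EX_GLYCOGEN = "EX_glycogen"
EX_PYR = "EX_pyr"
EX_AC = "EX_ac"
EX_LAC = "EX_lac"
EX_BIOMASS = "EX_biomass"

GLYCOGEN_SYNTHESIS = "GLGA"
GLYCOGEN_UTILIZATION = "GLYCOGEN_UTIL"
GLYCOGEN_DEGRADATION = "GLGP"
GLYCOGEN_STORAGE = "GLYCOGENt"
BIOMASS_ID = "BIOMASS"
ATPM_ID = "ATPM"

#: nutrient scan keys -> exchange reaction ids
NUTRIENT_EXCHANGES = {"NO3": EX_NO3, "PO4": EX_PI, "SO4": EX_SO4}

#: exchanges treated as freely exchanged gases/water (+ protons for charge
#: closure); media flag these unconstrained
FREE_EXCHANGES = frozenset({EX_CO2, EX_O2, EX_H2O, EX_H})

#: subsystem labels of the central-metabolism flux map
CENTRAL_SUBSYSTEMS = (
    "Glycolysis/gluconeogenesis",
    "Carbon fixation (CBB/CCM)",
    "Pentose phosphate (non-oxidative)",
    "TCA cycle",
    "Glycogen metabolism",
)

#: the calibration anchor of the photon-unit conversion: the reference
#: autotrophic condition (irradiance 100, HCO3- uptake 0.2 mmol/gDCW/h)
#: is required to reproduce this growth rate.  Calibrated, not predicted.
REFERENCE_AUTOTROPH = {"irradiance": 100.0, "hco3_uptake": 0.2, "growth": 0.0252}

#: the heterotrophic maintenance-level glucose uptake (mmol/gDCW/h)
MAINTENANCE_GLUCOSE = 0.017


@dataclass
class CoreModelParams:
    """Tunable knobs of the core-model generator.

    ``photon_atp_per_nadph``: ATP coupled per NADPH in the lumped linear
    electron flow (default 1.5, i.e. 3 ATP per 2 NADPH).
    ``quantum_demand``: photons consumed per 2 NADPH in the lump (default 8).
    ``cyclic_quantum_per_atp``: photons per ATP of cyclic electron flow.
    ``resp_po_ratio``: ATP per NADH oxidized by the respiratory lump.
    ``ngam``: non-growth ATP maintenance (mmol/gDCW/h); the default equals
    the network's maximal ATP yield from the maintenance-level glucose
    uptake 0.017 mmol/gDCW/h (2 substrate-level + 12 x P/O ATP per glucose),
    which makes dark heterotrophic growth exactly zero and feasible.
    ``gam``: growth-associated maintenance (mmol ATP/gDCW).
    ``photon_alpha``: mmol photons/gDCW/h per printed umol photons/m2/s;
    None -> calibrated against REFERENCE_AUTOTROPH at generation time.
    """

    photon_atp_per_nadph: float = 1.5
    quantum_demand: float = 8.0
    cyclic_quantum_per_atp: float = 4.0
    resp_po_ratio: float = 1.5
    ngam: Optional[float] = None
    gam: float = bm.DEFAULT_GAM
    composition: Optional[bm.BiomassComposition] = None
    include_overflow: bool = True
    bounds_default: float = DEFAULT_BOUND
    photon_alpha: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "photon_atp_per_nadph", "quantum_demand", "cyclic_quantum_per_atp",
            "resp_po_ratio", "gam", "bounds_default",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def resolved_ngam(self) -> float:
        if self.ngam is not None:
            return self.ngam
        atp_per_glucose = 2.0 + 12.0 * self.resp_po_ratio
        return MAINTENANCE_GLUCOSE * atp_per_glucose


# -- metabolite registry -------------------------------------------------------

# id base, name, formula (neutral-bookkeeping/BiGG charged forms), charge
_CYTO_METS = [
    ("co2", "CO2", "CO2", 0),
    ("hco3", "bicarbonate", "CHO3", -1),
    ("h2o", "water", "H2O", 0),
    ("h", "proton", "H", 1),
    ("o2", "oxygen", "O2", 0),
    ("pi", "orthophosphate", "HPO4", -2),
    ("nh4", "ammonium", "H4N", 1),
    ("no3", "nitrate", "NO3", -1),
    ("so4", "sulfate", "O4S", -2),
    ("atp", "ATP", "C10H12N5O13P3", -4),
    ("adp", "ADP", "C10H12N5O10P2", -3),
    ("nadp", "NADP+", "C21H25N7O17P3", -3),
    ("nadph", "NADPH", "C21H26N7O17P3", -4),
    ("nad", "NAD+", "C21H26N7O14P2", -1),
    ("nadh", "NADH", "C21H27N7O14P2", -2),
    ("coa", "coenzyme A", "C21H32N7O16P3S", -4),
    ("accoa", "acetyl-CoA", "C23H34N7O17P3S", -4),
    ("g3p", "glyceraldehyde 3-phosphate", "C3H5O6P", -2),
    ("dhap", "dihydroxyacetone phosphate", "C3H5O6P", -2),
    ("fdp", "fructose 1,6-bisphosphate", "C6H10O12P2", -4),
    ("f6p", "fructose 6-phosphate", "C6H11O9P", -2),
    ("g6p", "glucose 6-phosphate", "C6H11O9P", -2),
    ("g1p", "glucose 1-phosphate", "C6H11O9P", -2),
    ("ru5p", "ribulose 5-phosphate", "C5H9O8P", -2),
    ("3pg", "3-phosphoglycerate", "C3H4O7P", -3),
    ("2pg", "2-phosphoglycerate", "C3H4O7P", -3),
    ("pep", "phosphoenolpyruvate", "C3H2O6P", -3),
    ("pyr", "pyruvate", "C3H3O3", -1),
    ("oaa", "oxaloacetate", "C4H2O5", -2),
    ("cit", "citrate", "C6H5O7", -3),
    ("akg", "2-oxoglutarate", "C5H4O5", -2),
    ("sucsal", "succinate semialdehyde", "C4H5O3", -1),
    ("succ", "succinate", "C4H4O4", -2),
    ("fum", "fumarate", "C4H2O4", -2),
    ("mal", "malate", "C4H4O5", -2),
    ("glc", "glucose", "C6H12O6", 0),
    ("glycogen", "glycogen glucosyl monomer (storage pool)", "C6H10O5", 0),
    ("glycogen_bm", "biomass carbohydrate (glycogen equivalent)", "C6H10O5", 0),
    ("lac", "lactate", "C3H5O3", -1),
    ("ac", "acetate", "C2H3O2", -1),
    # polymer residues (as polymerized, neutral bookkeeping forms)
    ("ala_res", "alanyl residue", "C3H5NO", 0),
    ("gly_res", "glycyl residue", "C2H3NO", 0),
    ("ser_res", "seryl residue", "C3H5NO2", 0),
    ("cys_res", "cysteinyl residue", "C3H5NOS", 0),
    ("asp_res", "aspartyl residue", "C4H5NO3", 0),
    ("glu_res", "glutamyl residue", "C5H7NO3", 0),
    ("ramp_res", "AMP residue (RNA)", "C10H12N5O6P", 0),
    ("rump_res", "UMP residue (RNA)", "C9H11N2O8P", 0),
    ("dgmp_res", "dGMP residue (DNA)", "C10H12N5O6P", 0),
    ("dtmp_res", "dTMP residue (DNA)", "C10H13N2O7P", 0),
    ("lipid", "membrane lipid pseudo-monomer", "C41H79O10P", 0),
    ("pigment", "pigment-vitamin pseudo-monomer", "C33H38N4O6", 0),
    ("biomass", "biomass", "", 0),
]

_EXTRA_METS = [
    ("hco3", "e"), ("no3", "e"), ("pi", "e"), ("so4", "e"), ("glc", "e"),
    ("glycogen", "e"), ("pyr", "e"), ("ac", "e"), ("lac", "e"),
]

_COMPARTMENTS = {"c": "cytoplasm", "u": "thylakoid lumen", "e": "extracellular"}

_ELEMENTS = ("C", "H", "N", "O", "P", "S")

#: currency species used to close lumped biosynthesis reactions; columns of
#: the balancing system over (C, H, N, O, P, S, charge)
_CURRENCY_COLUMNS: List[Tuple[str, Tuple[int, ...]]] = [
    ("co2_c", (1, 0, 0, 2, 0, 0, 0)),
    ("nh4_c", (0, 4, 1, 0, 0, 0, 1)),
    ("h2o_c", (0, 2, 0, 1, 0, 0, 0)),
    ("h_c", (0, 1, 0, 0, 0, 0, 1)),
    ("pi_c", (0, 1, 0, 4, 1, 0, -2)),
    ("__redox__", (0, 1, 0, 0, 0, 0, -1)),  # +1 NADPH, -1 NADP+
    ("so4_c", (0, 0, 0, 4, 0, 1, -2)),
]


class CoreModelBuilder:
    """Assembles the core network; kept separate for testability."""

    def __init__(self, params: CoreModelParams) -> None:
        self.params = params
        self.model = MetabolicModel(
            id="cyano_core", compartments=set(_COMPARTMENTS.values())
        )
        self.registry: Dict[str, Dict[str, str]] = {}
        self._species: Dict[str, Tuple[Dict[str, int], int]] = {}

    # -- plumbing ---------------------------------------------------------

    def add_met(self, base: str, name: str, formula: str, charge: int,
                comp: str) -> str:
        mid = f"{base}_{comp}"
        self.model.add_metabolite(
            Metabolite(
                id=mid, name=name, formula=formula, charge=charge,
                compartment=_COMPARTMENTS[comp],
            )
        )
        counts = bm.parse_formula(formula) if formula else {}
        self._species[mid] = (counts, charge)
        return mid

    def add_rxn(self, rid: str, name: str, stoich: Dict[str, float],
                bounds: Tuple[float, float], subsystem: str,
                kind: str = "enzymatic", gpr: str = "",
                confidence: int = 4) -> None:
        self.model.add_reaction(
            Reaction(
                id=rid, name=name, stoichiometry=dict(stoich),
                lower_bound=bounds[0], upper_bound=bounds[1],
                gpr=gpr, subsystem=subsystem,
                confidence=confidence, kind=kind,
            )
        )
        if gpr:
            self.model.gene_ids.add(gpr)
        self.registry[rid] = {"kind": kind, "subsystem": subsystem}

    def _element_vector(self, mid: str) -> Tuple[int, ...]:
        counts, charge = self._species[mid]
        return tuple(counts.get(el, 0) for el in _ELEMENTS) + (charge,)

    def balanced_lump(self, primaries: Dict[str, float],
                      atp_cost: float = 0.0) -> Dict[str, float]:
        """Close a partial stoichiometry with exact currency coefficients.

        ``primaries`` holds the fixed part (negative = consumed).  The seven
        currency coefficients solving element+charge closure are computed in
        exact rational arithmetic, then an ``atp_cost``-fold ATP hydrolysis
        (element-neutral) is added.
        """
        target = [Fraction(0)] * 7
        for mid, coeff in primaries.items():
            vec = self._element_vector(mid)
            frac = Fraction(coeff).limit_denominator(10**9)
            for k in range(7):
                target[k] += frac * vec[k]
        # solve M a = -target by Gaussian elimination over Fractions
        m = [[Fraction(col[k]) for _, col in _CURRENCY_COLUMNS] for k in range(7)]
        rhs = [-t for t in target]
        a = _solve_exact(m, rhs)
        stoich = {mid: float(c) for mid, c in primaries.items()}

        def bump(mid: str, value: Fraction) -> None:
            if value == 0:
                return
            stoich[mid] = stoich.get(mid, 0.0) + float(value)

        for (mid, _), coeff in zip(_CURRENCY_COLUMNS, a):
            if mid == "__redox__":
                bump("nadph_c", coeff)
                bump("nadp_c", -coeff)
            else:
                bump(mid, coeff)
        if atp_cost:
            for mid, sign in (
                ("atp_c", -1), ("h2o_c", -1), ("adp_c", 1), ("pi_c", 1), ("h_c", 1),
            ):
                stoich[mid] = stoich.get(mid, 0.0) + sign * atp_cost
        return {mid: c for mid, c in stoich.items() if c != 0.0}

    # -- network sections ---------------------------------------------------

    def build(self) -> MetabolicModel:
        B = self.params.bounds_default
        fwd = (0.0, B)
        rev = (-B, B)

        for base, name, formula, charge in _CYTO_METS:
            self.add_met(base, name, formula, charge, "c")
        self.add_met("photon", "photon", "", 0, "u")
        cyto = {base: f"{base}_c" for base, *_ in _CYTO_METS}
        by_base = {base: (name, formula, charge) for base, name, formula, charge
                   in _CYTO_METS}
        for base, comp in _EXTRA_METS:
            name, formula, charge = by_base[base]
            self.add_met(base, name, formula, charge, comp)

        # exchanges ------------------------------------------------------
        exchange_defaults = [
            (EX_PHOTON, "photon_u", (-B, 0.0)),
            (EX_CO2, "co2_c", rev),
            (EX_O2, "o2_c", rev),
            (EX_H2O, "h2o_c", rev),
            (EX_H, "h_c", rev),
            (EX_HCO3, "hco3_e", (-B, 0.0)),
            (EX_NO3, "no3_e", (-B, 0.0)),
            (EX_PI, "pi_e", (-B, 0.0)),
            (EX_SO4, "so4_e", (-B, 0.0)),
            (EX_GLC, "glc_e", (0.0, B)),
            (EX_GLYCOGEN, "glycogen_e", (0.0, B)),
            (EX_BIOMASS, "biomass_c", (0.0, B)),
        ]
        if self.params.include_overflow:
            exchange_defaults += [
                (EX_PYR, "pyr_e", (0.0, B)),
                (EX_AC, "ac_e", (0.0, B)),
                (EX_LAC, "lac_e", (0.0, B)),
            ]
        for rid, mid, bounds in exchange_defaults:
            self.add_rxn(rid, f"exchange of {mid}", {mid: -1.0}, bounds,
                         "Exchange", kind="exchange", confidence=4)

        # transport ---------------------------------------------------------
        abc = [
            ("HCO3t", "hco3", "bicarbonate ABC transporter", "bctA"),
            ("NO3t", "no3", "nitrate ABC transporter", "nrtA"),
            ("SO4t", "so4", "sulfate ABC transporter", "cysA"),
        ]
        for rid, base, name, gene in abc:
            self.add_rxn(
                rid, name,
                {
                    f"{base}_e": -1.0, "atp_c": -1.0, "h2o_c": -1.0,
                    f"{base}_c": 1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0,
                },
                fwd,
                "Carbon fixation (CBB/CCM)" if base == "hco3" else "Transport",
                kind="transport", gpr=gene, confidence=3,
            )
        self.add_rxn(
            "PIt", "phosphate ABC transporter",
            {"pi_e": -1.0, "atp_c": -1.0, "h2o_c": -1.0,
             "adp_c": 1.0, "h_c": 1.0, "pi_c": 2.0},
            fwd, "Transport", kind="transport", gpr="pstS", confidence=3,
        )
        self.add_rxn("GLCt", "glucose uniport", {"glc_e": -1.0, "glc_c": 1.0},
                     fwd, "Transport", kind="transport", gpr="glcP", confidence=3)
        self.add_rxn(GLYCOGEN_STORAGE, "glycogen storage/export",
                     {"glycogen_c": -1.0, "glycogen_e": 1.0}, fwd,
                     "Glycogen metabolism", kind="transport", confidence=2)
        if self.params.include_overflow:
            for base in ("pyr", "ac", "lac"):
                self.add_rxn(f"{base.upper()}t", f"{base} secretion",
                             {f"{base}_c": -1.0, f"{base}_e": 1.0}, fwd,
                             "Transport", kind="transport", confidence=2)

        # photosynthesis & energy -------------------------------------------
        q = self.params.quantum_demand
        x = 2.0 * self.params.photon_atp_per_nadph
        pset = {
            "photon_u": -q, "nadp_c": -2.0, "adp_c": -x, "pi_c": -x,
            "h_c": -(x - 2.0), "h2o_c": (x - 2.0),
            "o2_c": 1.0, "nadph_c": 2.0, "atp_c": x,
        }
        self.add_rxn("PSET", "photosystems (linear electron flow, lumped)",
                     {k: v for k, v in pset.items() if v != 0.0}, fwd,
                     "Photosynthesis", gpr="psbA", confidence=3)
        qc_ = self.params.cyclic_quantum_per_atp
        self.add_rxn("CEF", "cyclic electron flow (lumped)",
                     {"photon_u": -qc_, "adp_c": -1.0, "pi_c": -1.0,
                      "h_c": -1.0, "atp_c": 1.0, "h2o_c": 1.0},
                     fwd, "Photosynthesis", gpr="pgr5", confidence=2)
        r = self.params.resp_po_ratio
        self.add_rxn(
            "RESP", "respiratory chain (lumped)",
            {"nadh_c": -2.0, "o2_c": -1.0, "adp_c": -2.0 * r, "pi_c": -2.0 * r,
             "h_c": -(2.0 * r + 2.0), "nad_c": 2.0, "atp_c": 2.0 * r,
             "h2o_c": 2.0 * r + 2.0},
            fwd, "Oxidative phosphorylation", gpr="coxA", confidence=3,
        )
        self.add_rxn("THD", "transhydrogenase",
                     {"nadph_c": -1.0, "nad_c": -1.0,
                      "nadp_c": 1.0, "nadh_c": 1.0},
                     rev, "Oxidative phosphorylation", gpr="pntA", confidence=2)
        self.add_rxn(ATPM_ID, "ATP maintenance (NGAM)",
                     {"atp_c": -1.0, "h2o_c": -1.0,
                      "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
                     (self.params.resolved_ngam(), B),
                     "Biomass and maintenance", kind="maintenance", confidence=4)

        # CCM + Calvin cycle -------------------------------------------------
        self.add_rxn("CA", "carbonic anhydrase",
                     {"hco3_c": -1.0, "h_c": -1.0, "co2_c": 1.0, "h2o_c": 1.0},
                     rev, "Carbon fixation (CBB/CCM)", gpr="ccaA", confidence=3)
        self.add_rxn(
            "CBB", "Calvin-Benson-Bassham cycle (lumped, per G3P)",
            {"co2_c": -3.0, "atp_c": -9.0, "nadph_c": -6.0, "h2o_c": -5.0,
             "g3p_c": 1.0, "adp_c": 9.0, "pi_c": 8.0, "nadp_c": 6.0, "h_c": 3.0},
            fwd, "Carbon fixation (CBB/CCM)", gpr="rbcL", confidence=4,
        )

        # glycolysis / gluconeogenesis ----------------------------------------
        gly = "Glycolysis/gluconeogenesis"
        self.add_rxn("HEX1", "hexokinase",
                     {"glc_c": -1.0, "atp_c": -1.0,
                      "g6p_c": 1.0, "adp_c": 1.0, "h_c": 1.0},
                     fwd, gly, gpr="glk", confidence=3)
        self.add_rxn("PGI", "glucose-6-phosphate isomerase",
                     {"g6p_c": -1.0, "f6p_c": 1.0}, rev, gly, gpr="pgi")
        self.add_rxn("PGMT", "phosphoglucomutase",
                     {"g1p_c": -1.0, "g6p_c": 1.0}, rev, gly, gpr="pgm")
        self.add_rxn("PFK", "phosphofructokinase",
                     {"f6p_c": -1.0, "atp_c": -1.0,
                      "fdp_c": 1.0, "adp_c": 1.0, "h_c": 1.0},
                     fwd, gly, gpr="pfkA")
        self.add_rxn("FBP", "fructose-1,6-bisphosphatase",
                     {"fdp_c": -1.0, "h2o_c": -1.0, "f6p_c": 1.0, "pi_c": 1.0},
                     fwd, gly, gpr="fbp")
        self.add_rxn("FBA", "fructose-bisphosphate aldolase",
                     {"fdp_c": -1.0, "dhap_c": 1.0, "g3p_c": 1.0},
                     rev, gly, gpr="fbaA")
        self.add_rxn("TPI", "triose-phosphate isomerase",
                     {"dhap_c": -1.0, "g3p_c": 1.0}, rev, gly, gpr="tpiA")
        self.add_rxn(
            "GAPD_PGK", "GAPDH + phosphoglycerate kinase (lumped)",
            {"g3p_c": -1.0, "pi_c": -1.0, "nad_c": -1.0, "adp_c": -1.0,
             "3pg_c": 1.0, "nadh_c": 1.0, "atp_c": 1.0, "h_c": 1.0},
            rev, gly, gpr="gap1",
        )
        self.add_rxn("PGM", "phosphoglycerate mutase",
                     {"3pg_c": -1.0, "2pg_c": 1.0}, rev, gly, gpr="gpmA")
        self.add_rxn("ENO", "enolase",
                     {"2pg_c": -1.0, "pep_c": 1.0, "h2o_c": 1.0},
                     rev, gly, gpr="eno")
        self.add_rxn("PYK", "pyruvate kinase",
                     {"pep_c": -1.0, "adp_c": -1.0, "h_c": -1.0,
                      "pyr_c": 1.0, "atp_c": 1.0},
                     fwd, gly, gpr="pyk")
        self.add_rxn("PDH", "pyruvate dehydrogenase",
                     {"pyr_c": -1.0, "coa_c": -1.0, "nad_c": -1.0,
                      "accoa_c": 1.0, "co2_c": 1.0, "nadh_c": 1.0},
                     fwd, gly, gpr="aceE")

        # non-oxidative PPP -----------------------------------------------------
        self.add_rxn(
            "PPP_NONOX", "non-oxidative pentose phosphate lump",
            {"g3p_c": -5.0, "h2o_c": -2.0, "ru5p_c": 3.0, "pi_c": 2.0},
            rev, "Pentose phosphate (non-oxidative)", gpr="tktA",
        )

        # TCA cycle with the 2-OG -> succinate bypass ---------------------------
        tca = "TCA cycle"
        self.add_rxn("CS", "citrate synthase",
                     {"accoa_c": -1.0, "oaa_c": -1.0, "h2o_c": -1.0,
                      "cit_c": 1.0, "coa_c": 1.0, "h_c": 1.0},
                     fwd, tca, gpr="gltA")
        self.add_rxn("ICDHx", "aconitase + isocitrate dehydrogenase (lumped)",
                     {"cit_c": -1.0, "nadp_c": -1.0,
                      "akg_c": 1.0, "co2_c": 1.0, "nadph_c": 1.0},
                     fwd, tca, gpr="icd")
        self.add_rxn("OGDC", "2-oxoglutarate decarboxylase",
                     {"akg_c": -1.0, "h_c": -1.0, "sucsal_c": 1.0, "co2_c": 1.0},
                     fwd, tca, gpr="kgd", confidence=2)
        self.add_rxn("SSADH", "succinate-semialdehyde dehydrogenase",
                     {"sucsal_c": -1.0, "nad_c": -1.0, "h2o_c": -1.0,
                      "succ_c": 1.0, "nadh_c": 1.0, "h_c": 2.0},
                     fwd, tca, gpr="gabD", confidence=2)
        self.add_rxn("SUCD", "succinate dehydrogenase (lumped to NAD)",
                     {"succ_c": -1.0, "nad_c": -1.0,
                      "fum_c": 1.0, "nadh_c": 1.0, "h_c": 1.0},
                     fwd, tca, gpr="sdhA", confidence=2)
        self.add_rxn("FUM", "fumarase",
                     {"fum_c": -1.0, "h2o_c": -1.0, "mal_c": 1.0},
                     rev, tca, gpr="fumC")
        self.add_rxn("MDH", "malate dehydrogenase",
                     {"mal_c": -1.0, "nad_c": -1.0,
                      "oaa_c": 1.0, "nadh_c": 1.0, "h_c": 1.0},
                     rev, tca, gpr="mdh")
        self.add_rxn("PPC", "PEP carboxylase",
                     {"pep_c": -1.0, "co2_c": -1.0, "h2o_c": -1.0,
                      "oaa_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
                     fwd, tca, gpr="ppc")

        # assimilation -----------------------------------------------------------
        self.add_rxn(
            "NR", "nitrate -> ammonium reduction (lumped)",
            {"no3_c": -1.0, "nadph_c": -4.0, "h_c": -6.0,
             "nh4_c": 1.0, "nadp_c": 4.0, "h2o_c": 3.0},
            fwd, "Nitrogen assimilation", gpr="narB", confidence=3,
        )

        # lumped biosyntheses, closed by the exact currency balancer ------------
        biosyn = [
            ("ALA_SYN", "alanyl-residue synthesis", {"pyr_c": -1.0, "ala_res_c": 1.0}, 0.0),
            ("GLY_SYN", "glycyl-residue synthesis", {"3pg_c": -1.0, "gly_res_c": 1.0}, 0.0),
            ("SER_SYN", "seryl-residue synthesis", {"3pg_c": -1.0, "ser_res_c": 1.0}, 0.0),
            ("CYS_SYN", "cysteinyl-residue synthesis", {"3pg_c": -1.0, "cys_res_c": 1.0}, 1.0),
            ("ASP_SYN", "aspartyl-residue synthesis", {"oaa_c": -1.0, "asp_res_c": 1.0}, 0.0),
            ("GLU_SYN", "glutamyl-residue synthesis", {"akg_c": -1.0, "glu_res_c": 1.0}, 0.0),
            ("RAMP_SYN", "AMP-residue synthesis", {"ru5p_c": -1.0, "ramp_res_c": 1.0}, 6.0),
            ("RUMP_SYN", "UMP-residue synthesis", {"ru5p_c": -1.0, "oaa_c": -1.0, "rump_res_c": 1.0}, 4.0),
            ("DGMP_SYN", "dGMP-residue synthesis", {"ru5p_c": -1.0, "dgmp_res_c": 1.0}, 6.0),
            ("DTMP_SYN", "dTMP-residue synthesis", {"ru5p_c": -1.0, "oaa_c": -1.0, "dtmp_res_c": 1.0}, 4.0),
            ("LIPID_SYN", "lipid pseudo-monomer synthesis",
             {"g3p_c": -1.0, "accoa_c": -19.0, "coa_c": 19.0, "lipid_c": 1.0}, 19.0),
            ("PIGMENT_SYN", "pigment-vitamin pseudo-monomer synthesis",
             {"akg_c": -8.0, "pigment_c": 1.0}, 4.0),
        ]
        for rid, name, primaries, atp_cost in biosyn:
            self.add_rxn(rid, name, self.balanced_lump(primaries, atp_cost),
                         fwd, "Biosynthesis (lumped)", confidence=2)

        # glycogen ----------------------------------------------------------------
        self.add_rxn(GLYCOGEN_SYNTHESIS, "glycogen synthase (monomer treatment)",
                     {"g1p_c": -1.0, "glycogen_c": 1.0, "pi_c": 1.0},
                     fwd, "Glycogen metabolism", gpr="glgA", confidence=4)
        self.add_rxn(GLYCOGEN_UTILIZATION,
                     "glycogen utilization for biomass growth",
                     {"g1p_c": -1.0, "glycogen_bm_c": 1.0, "pi_c": 1.0},
                     fwd, "Glycogen metabolism", confidence=2)
        self.add_rxn(GLYCOGEN_DEGRADATION,
                     "glycogen phosphorylase (inactive autotrophically)",
                     {"glycogen_c": -1.0, "pi_c": -1.0, "g1p_c": 1.0},
                     (0.0, 0.0), "Glycogen metabolism", gpr="glgP", confidence=4)

        # overflow fermentation routes -------------------------------------------
        if self.params.include_overflow:
            self.add_rxn("LDH", "lactate dehydrogenase",
                         {"pyr_c": -1.0, "nadh_c": -1.0, "h_c": -1.0,
                          "lac_c": 1.0, "nad_c": 1.0},
                         fwd, "Overflow metabolism", gpr="ldh", confidence=2)
            self.add_rxn("ACK", "phosphotransacetylase + acetate kinase (lumped)",
                         {"accoa_c": -1.0, "adp_c": -1.0, "pi_c": -1.0,
                          "ac_c": 1.0, "coa_c": 1.0, "atp_c": 1.0},
                         fwd, "Overflow metabolism", gpr="ackA", confidence=2)

        # biomass -----------------------------------------------------------------
        composition = self.params.composition or bm.reference_composition(
            gam=self.params.gam
        )
        biomass_rxn = bm.build_biomass_reaction(composition)
        self.model.add_reaction(biomass_rxn)
        self.registry[biomass_rxn.id] = {
            "kind": "biomass", "subsystem": biomass_rxn.subsystem,
        }
        self.model.objective_id = biomass_rxn.id
        self.composition = composition
        return self.model


def _solve_exact(matrix: List[List[Fraction]], rhs: List[Fraction]) -> List[Fraction]:
    """Solve a small dense rational linear system by Gaussian elimination."""
    n = len(rhs)
    aug = [row[:] + [rhs[i]] for i, row in enumerate(matrix)]
    for col in range(n):
        pivot = next((r for r in range(col, n) if aug[r][col] != 0), None)
        if pivot is None:
            raise ValueError("singular balancing system")
        aug[col], aug[pivot] = aug[pivot], aug[col]
        inv = aug[col][col]
        aug[col] = [v / inv for v in aug[col]]
        for r in range(n):
            if r != col and aug[r][col] != 0:
                factor = aug[r][col]
                aug[r] = [v - factor * p for v, p in zip(aug[r], aug[col])]
    return [aug[i][n] for i in range(n)]


# -- medium, element demand, generation ----------------------------------------


def reference_medium() -> Medium:
    """A Zarrouk-like reference medium: nutrient uptakes open 0 to -1000,
    light available, gases/water/protons freely exchanged."""
    return Medium(
        name="Zarrouk-like reference",
        exchange_bounds={
            EX_HCO3: (-DEFAULT_BOUND, 0.0),
            EX_NO3: (-DEFAULT_BOUND, 0.0),
            EX_PI: (-DEFAULT_BOUND, 0.0),
            EX_SO4: (-DEFAULT_BOUND, 0.0),
            EX_PHOTON: (-DEFAULT_BOUND, 0.0),
        },
        unconstrained=frozenset(FREE_EXCHANGES),
    )


def biomass_element_demand(model: MetabolicModel, element: str) -> float:
    """Net mmol of ``element`` drained per unit biomass flux (per gDCW)."""
    rxn = model.reaction(model.objective_id)
    total = 0.0
    for mid, coeff in rxn.stoichiometry.items():
        formula = model.metabolite(mid).formula
        if formula:
            total -= coeff * bm.parse_formula(formula).get(element, 0)
    return total


def calibrate_photon_alpha(
    model: MetabolicModel,
    target_growth: float = REFERENCE_AUTOTROPH["growth"],
    irradiance: float = REFERENCE_AUTOTROPH["irradiance"],
    hco3_uptake: float = REFERENCE_AUTOTROPH["hco3_uptake"],
) -> float:
    """Photon-unit conversion factor alpha (calibrated, not predicted).

    Growth is piecewise linear in the photon bound P (an NGAM offset plus a
    constant light-limited slope), so alpha is obtained from two probe LPs
    and verified; a bisection fallback guards the piecewise-linear shortcut.
    """
    from .netcore import apply_medium  # local to avoid cycles in doc tools

    base = apply_medium(model, reference_medium())
    base.reaction(EX_HCO3).bounds = (-hco3_uptake, 0.0)

    def growth(photon_bound: float) -> float:
        probe = base.copy()
        probe.reaction(EX_PHOTON).bounds = (-photon_bound, 0.0)
        sol = fba(FluxProblem.from_model(probe))
        return sol.objective_value if sol.optimal else 0.0

    p1, p2 = 5.0, 10.0
    g1, g2 = growth(p1), growth(p2)
    slope = (g2 - g1) / (p2 - p1)
    if slope <= 0:
        raise ModelContractError("growth is not light-limited; cannot calibrate")
    p_star = p1 + (target_growth - g1) / slope
    if abs(growth(p_star) - target_growth) > 1e-9:
        lo, hi = 0.0, max(p_star * 4.0, 40.0)
        for _ in range(100):
            mid = (lo + hi) / 2.0
            if growth(mid) < target_growth:
                lo = mid
            else:
                hi = mid
        p_star = hi
    return p_star / irradiance


def make_core_model(
    params: Optional[CoreModelParams] = None,
) -> Tuple[MetabolicModel, Dict]:
    """Generate the reduced core model plus its manifest.

    The returned model has the reference medium applied (nutrients open,
    light available) and is guaranteed by construction to be elementally
    balanced and free of energy-generating cycles; the manifest records
    counts, the reaction registry, the calibrated photon conversion alpha,
    maintenance parameters and the per-gDCW element demands.
    """
    from .netcore import apply_medium

    params = params or CoreModelParams()
    builder = CoreModelBuilder(params)
    model = builder.build()
    model = apply_medium(model, reference_medium())
    model.id = "cyano_core"

    alpha = params.photon_alpha
    if alpha is None:
        alpha = calibrate_photon_alpha(model)

    manifest = {
        "model_id": model.id,
        "n_metabolites": len(model.metabolites),
        "n_reactions": len(model.reactions),
        "photon_alpha": alpha,
        "ngam": params.resolved_ngam(),
        "gam": params.gam,
        "objective": model.objective_id,
        "glycogen_reactions": [
            GLYCOGEN_SYNTHESIS,
            GLYCOGEN_UTILIZATION,
            GLYCOGEN_STORAGE,
            GLYCOGEN_DEGRADATION,
        ],
        "reactions": builder.registry,
        "element_demand": {
            el: biomass_element_demand(model, el) for el in ("C", "N", "P", "S")
        },
    }
    return model, manifest


# -- optimal uptake ---------------------------------------------------------------


def optimal_uptake(
    model: MetabolicModel,
    nutrient_exchange: str,
    tolerance: float = 1e-6,
) -> float:
    """Smallest uptake bound of ``nutrient_exchange`` that still achieves the
    unconstrained-nutrient growth optimum, found by bisection.

    Operates under the model's current bounds (apply the growth condition
    first).  Raises if growth is zero even with unconstrained nutrient.
    """
    if not model.has_reaction(nutrient_exchange):
        raise ModelContractError(f"no exchange {nutrient_exchange!r} in model")

    def growth(uptake: Optional[float]) -> float:
        probe = model.copy()
        bound = DEFAULT_BOUND if uptake is None else uptake
        probe.reaction(nutrient_exchange).bounds = (-bound, 0.0)
        sol = fba(FluxProblem.from_model(probe))
        return sol.objective_value if sol.optimal else 0.0

    mu_star = growth(None)
    if mu_star <= 1e-9:
        raise InfeasibleProblemError(
            "growth is zero even with unconstrained nutrient; no optimal uptake"
        )
    target = mu_star - 1e-9
    lo, hi = 0.0, 1.0
    while growth(hi) < target:
        hi *= 2.0
        if hi > DEFAULT_BOUND:
            raise InfeasibleProblemError("optimal uptake exceeds the default bound")
    if growth(lo) >= target:
        return 0.0
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if growth(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


# -- toy networks -------------------------------------------------------------------


@dataclass(frozen=True)
class ToyNetworkSpec:
    """A named tiny fixture with an analytically known optimum."""

    name: str
    size: int
    known_optimum: float
    description: str = ""


def make_toy(name: str) -> Tuple[MetabolicModel, ToyNetworkSpec]:
    """Construct a named toy network (chain, parallel, branch, futile_cycle,
    leaky_atp) with its analytically derived optimum attached."""
    if name not in TOY_NAMES:
        raise ValueError(f"unknown toy network {name!r}; choose from {TOY_NAMES}")
    return _TOY_BUILDERS[name]()


def _toy_base(mets: List[str]) -> MetabolicModel:
    model = MetabolicModel(id="toy", compartments={"cytoplasm"})
    for mid in mets:
        model.add_metabolite(Metabolite(id=mid, compartment="cytoplasm"))
    return model


def _toy_chain() -> Tuple[MetabolicModel, ToyNetworkSpec]:
    m = _toy_base(["A", "B"])
    m.add_reaction(Reaction("EX_A", {"A": -1.0}, -1.0, 0.0, kind="exchange"))
    m.add_reaction(Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("EX_B", {"B": -1.0}, 0.0, 1000.0, kind="exchange"))
    m.objective_id = "EX_B"
    # optimum = uptake capacity of A = 1
    return m, ToyNetworkSpec("chain", 3, 1.0, "single linear path")


def _toy_parallel() -> Tuple[MetabolicModel, ToyNetworkSpec]:
    m = _toy_base(["A", "B"])
    m.add_reaction(Reaction("EX_A", {"A": -1.0}, -1.0, 0.0, kind="exchange"))
    m.add_reaction(Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("R2", {"A": -1.0, "B": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("EX_B", {"B": -1.0}, 0.0, 1000.0, kind="exchange"))
    m.objective_id = "EX_B"
    # two exchangeable branches share demanded flux 1; geometric center 0.5/0.5
    return m, ToyNetworkSpec("parallel", 4, 1.0, "two identical branches")


def _toy_branch() -> Tuple[MetabolicModel, ToyNetworkSpec]:
    m = _toy_base(["A", "B", "C", "D"])
    m.add_reaction(Reaction("EX_A", {"A": -1.0}, -1.0, 0.0, kind="exchange"))
    m.add_reaction(Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 0.6))
    m.add_reaction(Reaction("R2", {"A": -1.0, "C": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("R3", {"B": -1.0, "D": 2.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("R4", {"C": -1.0, "D": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("EX_D", {"D": -1.0}, 0.0, 1000.0, kind="exchange"))
    m.objective_id = "EX_D"
    # high-yield branch capped at 0.6: optimum = 0.6*2 + 0.4*1 = 1.6
    return m, ToyNetworkSpec("branch", 6, 1.6, "capped high-yield branch")


def _toy_futile() -> Tuple[MetabolicModel, ToyNetworkSpec]:
    m = _toy_base(["A", "B"])
    inf = float("inf")
    m.add_reaction(Reaction("EX_A", {"A": -1.0}, -1.0, 0.0, kind="exchange"))
    m.add_reaction(Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, inf))
    m.add_reaction(Reaction("R2", {"B": -1.0, "A": 1.0}, 0.0, inf))
    m.add_reaction(Reaction("EX_B", {"B": -1.0}, 0.0, 1000.0, kind="exchange"))
    m.objective_id = "EX_B"
    # the R1/R2 loop is unbounded at optimum -> infinite FVA ranges
    return m, ToyNetworkSpec("futile_cycle", 4, 1.0, "unbounded internal loop")


def _toy_leaky_atp() -> Tuple[MetabolicModel, ToyNetworkSpec]:
    model = MetabolicModel(id="toy_leaky", compartments={"cytoplasm"})
    species = [
        ("atp", "C10H12N5O13P3", -4), ("adp", "C10H12N5O10P2", -3),
        ("pi", "HPO4", -2), ("h", "H", 1), ("h2o", "H2O", 0),
    ]
    for base, formula, charge in species:
        model.add_metabolite(
            Metabolite(id=f"{base}_c", formula=formula, charge=charge,
                       compartment="cytoplasm")
        )
    model.add_reaction(Reaction(
        "ATPM", {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0,
                 "h_c": 1.0},
        0.0, 1000.0, kind="maintenance",
    ))
    model.add_reaction(Reaction(  # the deliberate type-II defect
        "FREE_ATP", {"adp_c": -1.0, "pi_c": -1.0, "h_c": -1.0, "atp_c": 1.0,
                     "h2o_c": 1.0},
        0.0, 1000.0,
    ))
    model.add_reaction(Reaction("EX_h2o", {"h2o_c": -1.0}, -1000.0, 1000.0,
                                kind="exchange"))
    model.objective_id = "ATPM"
    # free regeneration caps ATPM only at its own bound: optimum 1000
    return model, ToyNetworkSpec("leaky_atp", 3, 1000.0, "free ATP regeneration")


_TOY_BUILDERS = {
    "chain": _toy_chain,
    "parallel": _toy_parallel,
    "branch": _toy_branch,
    "futile_cycle": _toy_futile,
    "leaky_atp": _toy_leaky_atp,
}

TOY_NAMES = tuple(_TOY_BUILDERS)
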