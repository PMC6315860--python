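"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's solver module: LP optima
are recomputed by brute-force vertex enumeration, FVA ranges by raw
scipy.optimize.linprog calls, element counts by a local formula parser.
"""

from __future__ import annotations

import itertools
import re
from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest
from hypothesis import settings
from scipy.optimize import linprog

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")

from cyanoflux import coremodel
from cyanoflux.netcore import Medium, MetabolicModel, build_stoichiometric_matrix


def sole_carbon_medium(*without: str) -> Medium:
    """Reference medium with CO2 uptake closed (HCO3- is the sole carbon
    source) and the named nutrient exchanges removed (depleted)."""
    base = coremodel.reference_medium().without(*without) if without else (
        coremodel.reference_medium()
    )
    return Medium(
        name=base.name + " CO2-closed",
        exchange_bounds={
            **base.exchange_bounds, coremodel.EX_CO2: (0.0, 1000.0),
        },
        unconstrained=base.unconstrained - {coremodel.EX_CO2},
    )


@pytest.fixture(scope="session")
def core():
    """The generated core model plus its manifest (shared, treated read-only)."""
    model, manifest = coremodel.make_core_model()
    return model, manifest


@pytest.fixture(scope="session")
def core_model(core) -> MetabolicModel:
    return core[0]


@pytest.fixture(scope="session")
def manifest(core) -> Dict:
    return core[1]


@pytest.fixture(scope="session")
def alpha(manifest) -> float:
    return manifest["photon_alpha"]


# -- oracle: brute-force vertex enumeration ------------------------------------


def vertex_enumeration_optimum(
    model: MetabolicModel,
    objective_id: str,
    sense: str = "maximize",
) -> Optional[float]:
    """LP optimum by enumerating basic feasible solutions of Sv=0 + bounds.

    A bounded LP attains its optimum at a vertex, i.e. a point with at least
    n - rank(S) active bound constraints; enumerate all such candidates.
    Only practical for toy networks (<= 8 reactions).
    """
    S = build_stoichiometric_matrix(model, dense=True)
    n = S.shape[1]
    lower = np.array([r.lower_bound for r in model.reactions])
    upper = np.array([r.upper_bound for r in model.reactions])
    c = np.zeros(n)
    c[[r.id for r in model.reactions].index(objective_id)] = 1.0
    rank = np.linalg.matrix_rank(S) if S.size else 0
    best = None
    better = max if sense == "maximize" else min
    for nonbasic in itertools.combinations(range(n), n - rank):
        basic = [j for j in range(n) if j not in nonbasic]
        S_basic = S[:, basic]
        if basic and np.linalg.matrix_rank(S_basic) < len(basic):
            continue
        choices = [
            [v for v in (lower[j], upper[j]) if np.isfinite(v)] for j in nonbasic
        ]
        if any(not ch for ch in choices):
            continue
        for assignment in itertools.product(*choices):
            v = np.zeros(n)
            v[list(nonbasic)] = assignment
            if basic:
                rhs = -S[:, list(nonbasic)] @ np.array(assignment)
                sol, *_ = np.linalg.lstsq(S_basic, rhs, rcond=None)
                v[basic] = sol
            if np.max(np.abs(S @ v)) > 1e-8 if S.size else False:
                continue
            if np.any(v < lower - 1e-9) or np.any(v > upper + 1e-9):
                continue
            value = float(c @ v)
            best = value if best is None else better(best, value)
    return best


# -- oracle: FVA by independent per-reaction LPs --------------------------------


def fva_by_independent_lps(
    model: MetabolicModel,
    objective_id: str,
    fraction: float = 1.0,
    reactions: Optional[List[str]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction flux ranges via raw scipy.optimize.linprog calls."""
    S = build_stoichiometric_matrix(model)
    ids = [r.id for r in model.reactions]
    n = len(ids)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    bounds = [
        (lo if np.isfinite(lo) else None, hi if np.isfinite(hi) else None)
        for lo, hi in bounds
    ]
    c_obj = np.zeros(n)
    c_obj[ids.index(objective_id)] = 1.0
    opts = {"primal_feasibility_tolerance": 1e-9,
            "dual_feasibility_tolerance": 1e-9}
    base = linprog(-c_obj, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                   method="highs", options=opts)
    assert base.status == 0, "oracle base LP failed"
    optimum = -base.fun
    A_ub = -c_obj.reshape(1, -1)
    b_ub = np.array([-fraction * optimum])
    out: Dict[str, Tuple[float, float]] = {}
    for rid in reactions or ids:
        j = ids.index(rid)
        e = np.zeros(n)
        e[j] = 1.0
        lo_res = linprog(e, A_ub=A_ub, b_ub=b_ub, A_eq=S,
                         b_eq=np.zeros(S.shape[0]), bounds=bounds,
                         method="highs", options=opts)
        hi_res = linprog(-e, A_ub=A_ub, b_ub=b_ub, A_eq=S,
                         b_eq=np.zeros(S.shape[0]), bounds=bounds,
                         method="highs", options=opts)
        lo = lo_res.fun if lo_res.status == 0 else -np.inf
        hi = -hi_res.fun if hi_res.status == 0 else np.inf
        out[rid] = (lo, hi)
    return out


# -- oracle: element counting ----------------------------------------------------

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

ORACLE_WEIGHTS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999,
                  "P": 30.974, "S": 32.06}


def count_elements(formula: str) -> Dict[str, int]:
    """Independent minimal formula parser for cross-checks."""
    counts: Dict[str, int] = {}
    for element, digits in _TOKEN.findall(formula):
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    return counts


def reaction_element_balance(model: MetabolicModel, rxn_id: str) -> Dict[str, float]:
    """Net per-element production of a reaction, by brute-force counting."""
    rxn = model.reaction(rxn_id)
    totals: Dict[str, float] = {}
    for mid, coeff in rxn.stoichiometry.items():
        for el, k in count_elements(model.metabolite(mid).formula).items():
            totals[el] = totals.get(el, 0.0) + coeff * k
    return {el: v for el, v in totals.items() if abs(v) > 1e-9}
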