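"""Linear-programming engines: FBA, FVA and geometric FBA.

Flux balance analysis solves ``max/min c.v  s.t.  S v = 0, l <= v <= u`` —
the steady-state mass-balance constraint plus flux bounds.  Flux variability
analysis reports, per reaction, the attainable flux range while holding the
objective at (a fraction of) its optimum.  Geometric FBA iteratively shrinks
the optimal-flux polytope toward the center of its variability bounding box,
yielding a unique, ordering-independent representative of the alternate
optima.

All LPs are solved through a minimal backend interface (default:
scipy.optimize.linprog with the HiGHS simplex/IPM), so backends are
swappable without touching the analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .netcore import MetabolicModel, build_stoichiometric_matrix

#: LP feasibility/optimality tolerance requested from the backend.
FEASIBILITY_TOL = 1e-9
#: Tolerance used when comparing reported fluxes.
FLUX_TOL = 1e-6


class SolverError(RuntimeError):
    """Raised when the LP backend fails or reports a non-optimal status."""


class InfeasibleProblemError(SolverError):
    """Raised when a problem required to be feasible is not."""


# -- backend ------------------------------------------------------------------


class ScipyHighsBackend:
    """Minimal LP interface over scipy.optimize.linprog (HiGHS)."""

    #: map scipy status codes to our vocabulary
    _STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
               4: "numerical_failure"}

    def solve(
        self,
        c: np.ndarray,
        A_eq: Optional[sparse.spmatrix],
        A_ub: Optional[sparse.spmatrix],
        b_ub: Optional[np.ndarray],
        bounds: List[Tuple[float, float]],
    ) -> Tuple[str, Optional[np.ndarray], Optional[float]]:
        res = linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=np.zeros(A_eq.shape[0]) if A_eq is not None else None,
            bounds=bounds,
            method="highs",
            options={
                "primal_feasibility_tolerance": FEASIBILITY_TOL,
                "dual_feasibility_tolerance": FEASIBILITY_TOL,
            },
        )
        status = self._STATUS.get(res.status, "numerical_failure")
        if status == "optimal":
            return status, res.x, float(res.fun)
        return status, None, None


_DEFAULT_BACKEND = ScipyHighsBackend()


# -- problem/solution types ----------------------------------------------------


@dataclass
class FluxProblem:
    """An FBA problem: S, bounds, a single-reaction objective, optional fixings."""

    matrix: sparse.spmatrix
    reaction_ids: List[str]
    lower: np.ndarray
    upper: np.ndarray
    objective_id: str
    sense: str = "maximize"
    fixed_fluxes: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sense not in ("maximize", "minimize"):
            raise ValueError(f"unknown sense {self.sense!r}")
        if self.objective_id not in self.reaction_ids:
            raise ValueError(f"objective {self.objective_id!r} not among reactions")
        if np.any(self.lower > self.upper):
            raise ValueError("unordered bounds")
        self._index = {rid: j for j, rid in enumerate(self.reaction_ids)}

    @classmethod
    def from_model(
        cls,
        model: MetabolicModel,
        objective_id: Optional[str] = None,
        sense: str = "maximize",
        fixed_fluxes: Optional[Mapping[str, float]] = None,
    ) -> "FluxProblem":
        objective = objective_id or model.objective_id
        if objective is None:
            raise ValueError("model declares no objective and none was given")
        return cls(
            matrix=build_stoichiometric_matrix(model),
            reaction_ids=[r.id for r in model.reactions],
            lower=np.array([r.lower_bound for r in model.reactions], dtype=float),
            upper=np.array([r.upper_bound for r in model.reactions], dtype=float),
            objective_id=objective,
            sense=sense,
            fixed_fluxes=dict(fixed_fluxes or {}),
        )

    def index(self, rxn_id: str) -> int:
        return self._index[rxn_id]

    def effective_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lo, hi = self.lower.copy(), self.upper.copy()
        for rid, value in self.fixed_fluxes.items():
            j = self.index(rid)
            lo[j] = hi[j] = value
        return lo, hi


@dataclass
class FluxSolution:
    """An LP outcome: status, objective value and the flux vector."""

    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float]
    fluxes: Dict[str, float]
    residual: float = 0.0  # ||S v||_inf at the returned vector

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FluxRange:
    """Per-reaction (min, max) flux at the stated objective fraction."""

    ranges: Dict[str, Tuple[float, float]]
    objective_fraction: float = 1.0

    def __getitem__(self, rxn_id: str) -> Tuple[float, float]:
        return self.ranges[rxn_id]

    def contains(self, fluxes: Mapping[str, float], tol: float = FLUX_TOL) -> bool:
        return all(
            lo - tol <= fluxes[rid] <= hi + tol
            for rid, (lo, hi) in self.ranges.items()
        )

    def width(self) -> float:
        return max((hi - lo) for lo, hi in self.ranges.values()) if self.ranges else 0.0


# -- FBA -----------------------------------------------------------------------


def _objective_vector(problem: FluxProblem) -> np.ndarray:
    c = np.zeros(len(problem.reaction_ids))
    c[problem.index(problem.objective_id)] = 1.0
    return c


def fba(problem: FluxProblem, backend=None) -> FluxSolution:
    """Solve the FBA LP; status faithfully reports infeasible/unbounded."""
    backend = backend or _DEFAULT_BACKEND
    lo, hi = problem.effective_bounds()
    c = _objective_vector(problem)
    sign = -1.0 if problem.sense == "maximize" else 1.0
    status, x, fun = backend.solve(
        sign * c, problem.matrix, None, None, list(zip(lo, hi))
    )
    if status == "optimal":
        residual = float(np.abs(problem.matrix @ x).max()) if x.size else 0.0
        return FluxSolution(
            status="optimal",
            objective_value=float(sign * fun),
            fluxes=dict(zip(problem.reaction_ids, map(float, x))),
            residual=residual,
        )
    if status in ("infeasible", "unbounded"):
        return FluxSolution(status=status, objective_value=None, fluxes={})
    raise SolverError(f"LP backend failed with status {status!r}")


# -- FVA -----------------------------------------------------------------------


def _with_objective_floor(
    problem: FluxProblem, fraction: float, optimum: float
) -> Tuple[sparse.spmatrix, np.ndarray]:
    """Inequality row enforcing objective >= fraction*optimum (or <= for min)."""
    c = _objective_vector(problem)
    if problem.sense == "maximize":
        row, rhs = -c, -fraction * optimum
    else:
        row, rhs = c, fraction * optimum if optimum >= 0 else optimum / fraction
    return sparse.csr_matrix(row), np.array([rhs])


def fva(
    problem: FluxProblem,
    objective_fraction: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
    backend=None,
) -> FluxRange:
    """Min/max flux per reaction subject to objective >= fraction * optimum.

    Unbounded directions (internal cycles with infinite bounds) are reported
    as -inf/+inf, never clamped.
    """
    backend = backend or _DEFAULT_BACKEND
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    base = fba(problem, backend=backend)
    if not base.optimal:
        raise InfeasibleProblemError(
            f"base FBA problem is {base.status}; FVA undefined"
        )
    A_ub, b_ub = _with_objective_floor(problem, objective_fraction, base.objective_value)
    lo, hi = problem.effective_bounds()
    bounds = list(zip(lo, hi))
    n = len(problem.reaction_ids)
    targets = list(reactions) if reactions is not None else list(problem.reaction_ids)
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        j = problem.index(rid)
        c = np.zeros(n)
        c[j] = 1.0
        lo_status, lo_x, lo_fun = backend.solve(c, problem.matrix, A_ub, b_ub, bounds)
        hi_status, hi_x, hi_fun = backend.solve(-c, problem.matrix, A_ub, b_ub, bounds)
        vmin = float(lo_fun) if lo_status == "optimal" else (
            -np.inf if lo_status == "unbounded" else None
        )
        vmax = float(-hi_fun) if hi_status == "optimal" else (
            np.inf if hi_status == "unbounded" else None
        )
        if vmin is None or vmax is None:
            raise SolverError(
                f"FVA sub-problem for {rid!r} failed ({lo_status}/{hi_status})"
            )
        ranges[rid] = (vmin, vmax)
    return FluxRange(ranges=ranges, objective_fraction=objective_fraction)


# -- geometric FBA ---------------------------------------------------------------


class GeometricConvergenceError(SolverError):
    """Raised when the bounding box fails to shrink below tolerance."""

    def __init__(self, residual_width: float, iterations: int) -> None:
        super().__init__(
            f"geometric FBA did not converge after {iterations} iterations; "
            f"residual box width {residual_width:.3e}"
        )
        self.residual_width = residual_width
        self.iterations = iterations


def geometric_fba(
    problem: FluxProblem,
    tolerance: float = 1e-6,
    max_iterations: int = 50,
    backend=None,
) -> FluxSolution:
    """A unique flux distribution central to the optimal-flux polytope.

    Fixes the objective at its FBA optimum, computes the FVA bounding box,
    solves an L1-centering LP toward the box midpoint, then re-tightens the
    box subject to the achieved L1 distance, repeating until the box width
    falls below ``tolerance``.  The result attains the FBA optimum and is
    reproducible regardless of reaction ordering.
    """
    backend = backend or _DEFAULT_BACKEND
    base = fba(problem, backend=backend)
    if not base.optimal:
        raise InfeasibleProblemError(
            f"base FBA problem is {base.status}; geometric FBA undefined"
        )
    optimum = base.objective_value

    n = len(problem.reaction_ids)
    lo, hi = problem.effective_bounds()
    j_obj = problem.index(problem.objective_id)
    lo, hi = lo.copy(), hi.copy()
    lo[j_obj] = hi[j_obj] = optimum

    # initial bounding box of the optimal polytope
    box = fva(
        FluxProblem(
            matrix=problem.matrix,
            reaction_ids=problem.reaction_ids,
            lower=lo,
            upper=hi,
            objective_id=problem.objective_id,
            sense=problem.sense,
        ),
        objective_fraction=1.0,
        backend=backend,
    )
    lo_box = np.array([box[rid][0] for rid in problem.reaction_ids])
    hi_box = np.array([box[rid][1] for rid in problem.reaction_ids])
    if not (np.all(np.isfinite(lo_box)) and np.all(np.isfinite(hi_box))):
        raise SolverError(
            "optimal polytope has unbounded flux directions; geometric FBA "
            "is undefined (close the internal cycle bounds first)"
        )

    S = problem.matrix
    S_ext = sparse.hstack([S, sparse.csr_matrix((S.shape[0], n))]).tocsr()
    eye = sparse.identity(n, format="csr")
    c_center = np.concatenate([np.zeros(n), np.ones(n)])

    def center(m: np.ndarray, blo, bhi):
        # min sum(d) s.t. S v = 0, v - d <= m, -v - d <= -m, box bounds
        A_ub = sparse.vstack([
            sparse.hstack([eye, -eye]),
            sparse.hstack([-eye, -eye]),
        ]).tocsr()
        b_ub = np.concatenate([m, -m])
        bounds = list(zip(blo, bhi)) + [(0.0, None)] * n
        status, x, fun = backend.solve(c_center, S_ext, A_ub, b_ub, bounds)
        if status != "optimal":
            raise SolverError(f"centering LP failed with status {status!r}")
        return x[:n], fun, A_ub, b_ub, bounds

    for iteration in range(max_iterations):
        midpoint = (lo_box + hi_box) / 2.0
        v_center, distance, A_ub, b_ub, bounds = center(midpoint, lo_box, hi_box)
        width = float(np.max(hi_box - lo_box))
        if width <= tolerance:
            fluxes = dict(zip(problem.reaction_ids, map(float, v_center)))
            residual = float(np.abs(S @ v_center).max()) if n else 0.0
            return FluxSolution(
                status="optimal",
                objective_value=optimum,
                fluxes=fluxes,
                residual=residual,
            )
        # re-tighten the box subject to sum(d) <= achieved L1 distance.  The
        # slack absorbs the backend's own optimality tolerance; sum|v - m|
        # <= p bounds every coordinate, so the analytic clamp below is valid
        # on its own and also backstops any numerically infeasible sub-LP.
        p_eff = distance + max(1e-7, 1e-6 * abs(distance))
        clamp_lo = np.maximum(lo_box, midpoint - p_eff)
        clamp_hi = np.minimum(hi_box, midpoint + p_eff)
        if float(np.max(clamp_hi - clamp_lo)) <= tolerance:
            lo_box, hi_box = clamp_lo, clamp_hi
            continue
        A_fva = sparse.vstack(
            [A_ub, sparse.csr_matrix(c_center)]
        ).tocsr()
        b_fva = np.concatenate([b_ub, [p_eff]])
        new_lo, new_hi = clamp_lo.copy(), clamp_hi.copy()
        for j in range(n):
            if hi_box[j] - lo_box[j] <= tolerance:
                continue
            cj = np.zeros(2 * n)
            cj[j] = 1.0
            st1, _, f1 = backend.solve(cj, S_ext, A_fva, b_fva, bounds)
            st2, _, f2 = backend.solve(-cj, S_ext, A_fva, b_fva, bounds)
            if st1 == "optimal":
                new_lo[j] = max(new_lo[j], f1)
            if st2 == "optimal":
                new_hi[j] = min(new_hi[j], -f2)
            if new_lo[j] > new_hi[j]:  # numerical crossing
                new_lo[j] = new_hi[j] = (new_lo[j] + new_hi[j]) / 2.0
        lo_box, hi_box = new_lo, new_hi
    raise GeometricConvergenceError(float(np.max(hi_box - lo_box)), max_iterations)


# -- export ---------------------------------------------------------------------


def export_fluxes_tsv(
    path: str,
    solution: FluxSolution,
    ranges: Optional[FluxRange] = None,
) -> None:
    """Write a TSV of reaction id, flux and (when given) FVA min/max."""
    with open(path, "w") as fh:
        fh.write("reaction\tflux\tmin\tmax\n")
        for rid, flux in solution.fluxes.items():
            if ranges is not None and rid in ranges.ranges:
                lo, hi = ranges[rid]
                fh.write(f"{rid}\t{flux!r}\t{lo!r}\t{hi!r}\n")
            else:
                fh.write(f"{rid}\t{flux!r}\t\t\n")
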