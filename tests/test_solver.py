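"""FBA/FVA/geometric FBA against vertex-enumeration and per-LP oracles."""

import numpy as np
import pytest

from conftest import fva_by_independent_lps, vertex_enumeration_optimum
from cyanoflux import coremodel
from cyanoflux.netcore import MetabolicModel, Metabolite, Reaction
from cyanoflux.solver import (
    FluxProblem,
    InfeasibleProblemError,
    export_fluxes_tsv,
    fba,
    fva,
    geometric_fba,
)


def conservation_residual(solution):
    return solution.residual


class TestFBA:
    @pytest.mark.parametrize("toy", list(coremodel.TOY_NAMES))
    def test_optimum_matches_vertex_enumeration(self, toy):
        """The LP optimum equals the brute-force basic-solution optimum."""
        model, spec = coremodel.make_toy(toy)
        sol = fba(FluxProblem.from_model(model))
        assert sol.optimal
        assert sol.objective_value == pytest.approx(spec.known_optimum, abs=1e-9)
        oracle = vertex_enumeration_optimum(model, model.objective_id)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-8)
        assert conservation_residual(sol) <= 1e-6

    def test_chain_single_path(self):
        model, _ = coremodel.make_toy("chain")
        sol = fba(FluxProblem.from_model(model))
        assert sol.objective_value == pytest.approx(1.0)
        assert sol["R1"] == pytest.approx(1.0)

    def test_infeasible_status_reported(self):
        model, _ = coremodel.make_toy("chain")
        model.reaction("EX_B").bounds = (2.0, 3.0)  # demands more than supply
        sol = fba(FluxProblem.from_model(model))
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_unbounded_status_reported(self):
        m = MetabolicModel(id="u", compartments={"cytoplasm"})
        m.add_metabolite(Metabolite(id="A", compartment="cytoplasm"))
        m.add_reaction(Reaction("IN", {"A": 1.0}, 0.0, float("inf")))
        m.add_reaction(Reaction("OUT", {"A": -1.0}, 0.0, float("inf")))
        m.objective_id = "OUT"
        sol = fba(FluxProblem.from_model(m))
        assert sol.status == "unbounded"

    def test_fixed_fluxes_respected(self):
        model, _ = coremodel.make_toy("parallel")
        sol = fba(FluxProblem.from_model(model, fixed_fluxes={"R1": 0.25}))
        assert sol["R1"] == pytest.approx(0.25)
        assert sol.objective_value == pytest.approx(1.0)

    def test_maximize_equals_negated_minimize_of_mirror(self):
        """Sign conventions: max f == -min(-f) via a mirrored objective."""
        model, _ = coremodel.make_toy("branch")
        mirrored = model.copy()
        obj = mirrored.reaction("EX_D")
        obj.stoichiometry = {m: -c for m, c in obj.stoichiometry.items()}
        obj.bounds = (-1000.0, 0.0)
        best = fba(FluxProblem.from_model(model))
        worst = fba(FluxProblem.from_model(mirrored, sense="minimize"))
        assert best.objective_value == pytest.approx(-worst.objective_value, abs=1e-9)

    def test_bound_relaxation_never_decreases_maximum(self):
        """LP monotonicity over a grid of capacity values."""
        previous = -np.inf
        for cap in (0.0, 0.2, 0.4, 0.6, 0.8):
            model, _ = coremodel.make_toy("branch")
            model.reaction("R1").bounds = (0.0, cap)
            value = fba(FluxProblem.from_model(model)).objective_value
            assert value >= previous - 1e-12
            previous = value

    def test_core_model_conservation(self, core_model):
        sol = fba(FluxProblem.from_model(core_model))
        assert sol.optimal
        assert conservation_residual(sol) <= 1e-6

    def test_core_model_agrees_with_cobrapy(self, core_model, tmp_path):
        """Dual-route check: an independent FBA stack on our SBML output."""
        cobra = pytest.importorskip("cobra")
        from cyanoflux.io import write_model

        path = str(tmp_path / "core.xml")
        write_model(core_model, path, dialect="sbml")
        cm = cobra.io.read_sbml_model(path)
        ours = fba(FluxProblem.from_model(core_model)).objective_value
        theirs = cm.optimize().objective_value
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestFVA:
    def test_parallel_branches_are_exchangeable(self):
        model, _ = coremodel.make_toy("parallel")
        model.reaction("EX_B").bounds = (1.0, 1000.0)  # demand at least 1
        ranges = fva(FluxProblem.from_model(model))
        assert ranges["R1"] == pytest.approx((0.0, 1.0), abs=1e-9)
        assert ranges["R2"] == pytest.approx((0.0, 1.0), abs=1e-9)

    def test_fba_solution_contained_at_fraction_one(self, core_model):
        problem = FluxProblem.from_model(core_model)
        sol = fba(problem)
        ranges = fva(problem, objective_fraction=1.0)
        assert ranges.contains(sol.fluxes)

    @pytest.mark.parametrize("toy", ["chain", "parallel", "branch"])
    @pytest.mark.parametrize("fraction", [1.0, 0.5])
    def test_matches_independent_per_reaction_lps(self, toy, fraction):
        model, _ = coremodel.make_toy(toy)
        ranges = fva(FluxProblem.from_model(model), objective_fraction=fraction)
        oracle = fva_by_independent_lps(model, model.objective_id, fraction)
        for rid, (lo, hi) in oracle.items():
            assert ranges[rid][0] == pytest.approx(lo, abs=1e-8)
            assert ranges[rid][1] == pytest.approx(hi, abs=1e-8)

    def test_core_model_matches_independent_lps(self, core_model):
        targets = ["GLGA", "CBB", "EX_photon", "ATPM", "PFK", "EX_o2"]
        ranges = fva(FluxProblem.from_model(core_model), reactions=targets)
        oracle = fva_by_independent_lps(
            core_model, core_model.objective_id, 1.0, reactions=targets
        )
        for rid in targets:
            assert ranges[rid] == pytest.approx(oracle[rid], abs=1e-6)

    def test_unbounded_cycle_reports_infinite_ranges(self):
        model, _ = coremodel.make_toy("futile_cycle")
        ranges = fva(FluxProblem.from_model(model))
        assert ranges["R1"][1] == np.inf
        assert ranges["R2"][1] == np.inf
        assert ranges["EX_B"] == pytest.approx((1.0, 1.0), abs=1e-9)

    def test_infeasible_base_problem_propagates(self):
        model, _ = coremodel.make_toy("chain")
        model.reaction("EX_B").bounds = (5.0, 6.0)
        with pytest.raises(InfeasibleProblemError):
            fva(FluxProblem.from_model(model))


def test_flux_export_tsv_round_trips_values(tmp_path):
    import pandas as pd

    model, _ = coremodel.make_toy("branch")
    problem = FluxProblem.from_model(model)
    sol = fba(problem)
    ranges = fva(problem)
    path = str(tmp_path / "fluxes.tsv")
    export_fluxes_tsv(path, sol, ranges)
    frame = pd.read_csv(path, sep="\t").set_index("reaction")
    for rid, flux in sol.fluxes.items():
        assert frame.loc[rid, "flux"] == pytest.approx(flux, abs=1e-12)
        assert frame.loc[rid, "min"] == pytest.approx(ranges[rid][0], abs=1e-12)
        assert frame.loc[rid, "max"] == pytest.approx(ranges[rid][1], abs=1e-12)


class TestGeometricFBA:
    def test_parallel_branches_split_symmetrically(self):
        model, _ = coremodel.make_toy("parallel")
        model.reaction("EX_B").bounds = (1.0, 1000.0)
        sol = geometric_fba(FluxProblem.from_model(model))
        assert sol["R1"] == pytest.approx(0.5, abs=1e-6)
        assert sol["R2"] == pytest.approx(0.5, abs=1e-6)
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)

    def test_attains_fba_optimum_and_lies_in_fva_box(self, core_model):
        problem = FluxProblem.from_model(core_model)
        base = fba(problem)
        sol = geometric_fba(problem)
        assert sol.objective_value == pytest.approx(base.objective_value, abs=1e-9)
        box = fva(problem, objective_fraction=1.0)
        assert box.contains(sol.fluxes, tol=1e-5)
        assert conservation_residual(sol) <= 1e-6

    def test_reaction_order_invariance(self, core_model):
        """Permuting reaction order changes no flux by more than 1e-6."""
        sol = geometric_fba(FluxProblem.from_model(core_model))
        permuted = MetabolicModel(
            id="perm",
            metabolites=list(core_model.metabolites),
            reactions=[r.copy() for r in reversed(core_model.reactions)],
            objective_id=core_model.objective_id,
            compartments=set(core_model.compartments),
        )
        sol_perm = geometric_fba(FluxProblem.from_model(permuted))
        for rid, flux in sol.fluxes.items():
            assert sol_perm[rid] == pytest.approx(flux, abs=2e-6)

    def test_idempotent_on_its_own_solution(self, core_model):
        problem = FluxProblem.from_model(core_model)
        sol = geometric_fba(problem)
        refixed = FluxProblem.from_model(core_model, fixed_fluxes=sol.fluxes)
        again = geometric_fba(refixed)
        for rid, flux in sol.fluxes.items():
            assert again[rid] == pytest.approx(flux, abs=1e-9)

    def test_infeasible_base_problem_propagates(self):
        model, _ = coremodel.make_toy("chain")
        model.reaction("EX_B").bounds = (5.0, 6.0)
        with pytest.raises(InfeasibleProblemError):
            geometric_fba(FluxProblem.from_model(model))
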