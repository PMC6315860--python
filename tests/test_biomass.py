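"""Biomass builder: molar masses, polymer coefficients, mass closure."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from conftest import ORACLE_WEIGHTS, count_elements
from cyanoflux import biomass as bm
from cyanoflux.biomass import (
    BiomassComposition,
    CompositionError,
    FormulaError,
    MonomerSpec,
    build_biomass_reaction,
    molar_mass,
    parse_formula,
    polymer_coefficients,
    precursor_mass,
    reference_composition,
)


class TestMolarMass:
    @pytest.mark.parametrize("formula,expected", [
        ("C6H10O5", 162.141),   # glycogen glucosyl monomer, printed value
        ("H2O", 18.015),
        ("C6H13O9P", 260.135),  # glucose-1-phosphate, neutral form
    ])
    def test_known_masses(self, formula, expected):
        assert molar_mass(formula) == pytest.approx(expected, abs=5e-4)

    def test_glycogen_monomer_exact(self):
        # 6*12.011 + 10*1.008 + 5*15.999 prints exactly as 162.141
        assert round(molar_mass("C6H10O5"), 3) == 162.141

    def test_unknown_element_rejected(self):
        with pytest.raises(FormulaError, match="Mg"):
            molar_mass("C55H72MgN4O5")

    def test_garbage_rejected(self):
        with pytest.raises(FormulaError):
            molar_mass("6CH")

    @given(st.dictionaries(
        st.sampled_from(sorted(ORACLE_WEIGHTS)),
        st.integers(min_value=1, max_value=60),
        min_size=1, max_size=6,
    ))
    @settings(max_examples=100, deadline=None)
    def test_mass_is_sum_over_counts(self, counts):
        formula = "".join(f"{el}{n}" for el, n in sorted(counts.items()))
        expected = sum(ORACLE_WEIGHTS[el] * n for el, n in counts.items())
        assert molar_mass(formula) == pytest.approx(expected, rel=1e-12)
        assert parse_formula(formula) == counts


def table(*entries):
    return tuple((MonomerSpec(mid, mass), x) for mid, mass, x in entries)


class TestPolymerCoefficients:
    def test_single_monomer_unit_case(self):
        coeffs = polymer_coefficients(100.0, table(("m", 1000.0, 1.0)))
        assert coeffs["m"] == pytest.approx(1.0)

    def test_glycogen_fraction_from_composition_table(self):
        # carbohydrate 31.62 %w/w as pure glucosyl monomer:
        # 316.2 mg / 162.141 g/mol = 1.9502 mmol/gDCW
        coeffs = polymer_coefficients(
            31.62, table(("glycogen", molar_mass("C6H10O5"), 1.0))
        )
        assert coeffs["glycogen"] == pytest.approx(316.2 / 162.141, rel=1e-9)
        assert coeffs["glycogen"] == pytest.approx(1.9502, abs=5e-5)

    def test_uniform_nucleotide_table_symmetry(self):
        # a uniform 4-monomer table at 0.88 %w/w: equal coefficients whose
        # total mass is 8.8 mg/gDCW
        masses = [313.2, 329.2, 289.2, 304.2]
        entries = table(*[(f"n{i}", m, 0.25) for i, m in enumerate(masses)])
        coeffs = polymer_coefficients(0.88, entries)
        values = list(coeffs.values())
        assert all(v == pytest.approx(values[0]) for v in values)
        total_mass = sum(coeffs[f"n{i}"] * m for i, m in enumerate(masses))
        assert total_mass == pytest.approx(8.8, rel=1e-12)

    def test_empty_table_is_contract_error(self):
        with pytest.raises(CompositionError):
            polymer_coefficients(10.0, ())

    @given(
        st.lists(
            st.tuples(st.floats(min_value=50, max_value=900),
                      st.floats(min_value=0.05, max_value=5.0)),
            min_size=1, max_size=6,
        ),
        st.floats(min_value=0.1, max_value=100.0),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=80, deadline=None)
    def test_mass_recovery_and_scale_invariance(self, entries, fraction, scale):
        t1 = tuple(
            (MonomerSpec(f"m{i}", mass), x) for i, (mass, x) in enumerate(entries)
        )
        t2 = tuple((spec, x * scale) for spec, x in t1)
        c1 = polymer_coefficients(fraction, t1)
        c2 = polymer_coefficients(fraction, t2)
        # scaling all mole fractions by a common factor changes nothing
        for mid in c1:
            assert c2[mid] == pytest.approx(c1[mid], rel=1e-9)
        # coefficients are non-negative and recover the pool mass (mg/gDCW)
        assert all(v >= 0 for v in c1.values())
        total = sum(c1[f"m{i}"] * mass for i, (mass, _) in enumerate(entries))
        assert total == pytest.approx(10.0 * fraction, rel=1e-9)


class TestCompositionConfig:
    def test_yaml_round_trip_preserves_reference_composition(self, tmp_path):
        comp = reference_composition()
        path = str(tmp_path / "composition.yaml")
        bm.save_composition(comp, path)
        back = bm.load_composition(path)
        assert back.fractions == comp.fractions
        assert back.gam == comp.gam
        for component, monomers in comp.monomer_tables.items():
            loaded = back.monomer_tables[component]
            assert [(s.metabolite_id, x) for s, x in loaded] == \
                [(s.metabolite_id, x) for s, x in monomers]
            for (a, _), (b, _) in zip(loaded, monomers):
                assert a.molar_mass == pytest.approx(b.molar_mass, rel=1e-12)
                assert a.energy_cost == b.energy_cost
        assert precursor_mass(back) == pytest.approx(precursor_mass(comp))

    def test_monomer_without_mass_or_formula_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "fractions: {carbohydrates: 100.0}\n"
            "monomer_tables:\n"
            "  carbohydrates:\n"
            "    - {metabolite: glycogen_bm_c, mole_fraction: 1.0}\n"
        )
        with pytest.raises(CompositionError, match="formula or molar_mass"):
            bm.load_composition(str(path))


class TestComposition:
    def test_fractions_must_sum_to_100(self):
        with pytest.raises(CompositionError, match="sum"):
            BiomassComposition(fractions={"proteins": 60.0, "ash": 20.0})

    def test_reference_composition_valid_and_mass_closed(self):
        comp = reference_composition()
        ash = comp.fractions["ash"]
        assert precursor_mass(comp) == pytest.approx(
            10.0 * (sum(comp.fractions.values()) - ash), rel=1e-9
        )

    def test_zero_fraction_gives_zero_coefficients(self):
        comp = reference_composition()
        coeffs = polymer_coefficients(0.0, comp.monomer_tables["proteins"])
        assert all(v == 0.0 for v in coeffs.values())


class TestBuildBiomassReaction:
    def test_precursor_mass_closure(self):
        """Drained precursor mass per unit growth is 1000*(100-ash)/100 mg."""
        comp = reference_composition()
        rxn = build_biomass_reaction(comp)
        # aggregate the per-pool coefficients independently
        expected = {}
        for component, monomers in comp.monomer_tables.items():
            for mid, c in polymer_coefficients(
                comp.fractions[component], monomers
            ).items():
                expected[mid] = expected.get(mid, 0.0) + c
        masses = {mid: bm.molar_mass(f) for mid, f in bm.RESIDUE_FORMULAS.items()}
        total_mass = sum(c * masses[mid] for mid, c in expected.items())
        closure = 1000.0 * (sum(comp.fractions.values()) - comp.fractions["ash"]) / 100.0
        assert total_mass == pytest.approx(closure, abs=1e-6)
        # the built reaction drains exactly these coefficients; Pi overlaps
        # with the GAM hydrolysis product and ATP/H2O with its substrates
        gam = comp.gam
        for mid, c in expected.items():
            adjustment = gam if mid == "pi_c" else 0.0
            assert rxn.stoichiometry[mid] == pytest.approx(-c + adjustment)
        assert rxn.stoichiometry["atp_c"] == pytest.approx(-gam)
        assert rxn.stoichiometry["h2o_c"] == pytest.approx(-gam)
        assert rxn.stoichiometry["biomass_c"] == 1.0
        assert rxn.kind == "biomass"

    def test_all_carbohydrate_composition_is_glycogen_sink_plus_gam(self):
        comp = BiomassComposition(
            fractions={"carbohydrates": 100.0},
            monomer_tables={"carbohydrates": (
                (MonomerSpec("glycogen_bm_c", molar_mass("C6H10O5")), 1.0),
            )},
            gam=5.0,
        )
        rxn = build_biomass_reaction(comp)
        assert rxn.stoichiometry["glycogen_bm_c"] == pytest.approx(-1000.0 / 162.141)
        assert rxn.stoichiometry["atp_c"] == pytest.approx(-5.0)
        consumed = {m for m, c in rxn.stoichiometry.items() if c < 0}
        assert consumed == {"glycogen_bm_c", "atp_c", "h2o_c"}

    def test_nitrogen_census_matches_brute_force_count(self):
        """Elemental N drained per gDCW equals a brute-force recount."""
        comp = reference_composition()
        rxn = build_biomass_reaction(comp)
        brute = 0.0
        for mid, coeff in rxn.stoichiometry.items():
            formula = bm.RESIDUE_FORMULAS.get(mid, "")
            if formula and coeff < 0:
                brute += -coeff * count_elements(formula).get("N", 0)
        census = bm.element_census(comp, bm.RESIDUE_FORMULAS, "N")
        assert census == pytest.approx(brute, rel=1e-9)
        # nitrogen mass per gDCW is dominated by protein at ~16% of its mass
        protein_n = 0.16 * 10.0 * comp.fractions["proteins"]  # mg/gDCW
        assert 14.007 * census == pytest.approx(protein_n, rel=0.1)

    def test_monomer_energy_cost_adds_to_gam(self):
        comp = BiomassComposition(
            fractions={"carbohydrates": 100.0},
            monomer_tables={"carbohydrates": (
                (MonomerSpec("glycogen_bm_c", 162.141, energy_cost=2.0), 1.0),
            )},
            gam=1.0,
        )
        rxn = build_biomass_reaction(comp)
        n_monomer = 1000.0 / 162.141
        assert rxn.stoichiometry["atp_c"] == pytest.approx(-(1.0 + 2.0 * n_monomer))
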