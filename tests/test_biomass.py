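"""Composition averaging, formulas, equation assembly and installation."""

import numpy as np
import pytest

from chemocal import (
    BiomassEquation,
    ElementalComposition,
    MacroComposition,
    MonomerProfile,
    ash_by_subtraction,
    average_compositions,
    build_biomass_equation,
    derive_cmol_formula,
    install_biomass,
    load_monomer_table,
    reconcile_composition,
    solve_fba,
    toy_equation_template,
)
from chemocal import datasets
from chemocal.biomass import MACRO_COMPONENTS, M_ANHYDROGLUCOSE


def _macro(**overrides):
    base = {"protein": 41.0, "carbohydrate": 35.9, "lipid": 2.5, "rna": 7.8,
            "dna": 0.19, "so4": 0.46, "h2o": 5.6, "metals": 7.0}
    base.update(overrides)
    return MacroComposition(fractions=base, sds={k: 0.5 for k in base})


# -- averaging ---------------------------------------------------------------

def test_weighted_average_hand_example():
    """(10 +- 1) and (20 +- 4) -> (10/1 + 20/4) / (1 + 1/4) = 12.0."""
    a = ElementalComposition({"C": 10, "H": 1, "N": 1, "O": 1, "S": 1},
                             sds={"C": 1, "H": 1, "N": 1, "O": 1, "S": 1})
    b = ElementalComposition({"C": 20, "H": 1, "N": 1, "O": 1, "S": 1},
                             sds={"C": 4, "H": 1, "N": 1, "O": 1, "S": 1})
    avg = average_compositions([a, b])
    assert avg.fractions["C"] == pytest.approx(12.0, rel=1e-12)


def test_average_of_identical_entries_is_identity():
    m = _macro()
    avg = average_compositions([m, m, m], renormalize=False)
    for k in MACRO_COMPONENTS:
        assert avg.fractions[k] == pytest.approx(m.fractions[k])


def test_average_permutation_invariant_and_bounded():
    comps = [datasets.get_macro_composition("glycerol", c)
             for c in datasets.conditions("glycerol")]
    fwd = average_compositions(comps, renormalize=False)
    rev = average_compositions(comps[::-1], renormalize=False)
    for k in MACRO_COMPONENTS:
        assert fwd.fractions[k] == pytest.approx(rev.fractions[k], rel=1e-12)
        vals = [c.fractions[k] for c in comps]
        assert min(vals) - 1e-9 <= fwd.fractions[k] <= max(vals) + 1e-9


def test_methanol_protein_average_matches_printed():
    """(48.6+-1.0, 50.7+-0.5, 51.5+-2.1) averages to the printed 50.1."""
    comps = [datasets.get_macro_composition("methanol", c)
             for c in datasets.conditions("methanol")]
    avg = average_compositions(comps, renormalize=False)
    assert avg.fractions["protein"] == pytest.approx(50.1, abs=0.2)


def test_missing_sd_falls_back_with_warning():
    a = _macro()
    b = _macro(protein=43.0)
    b.sds["protein"] = 0.0
    with pytest.warns(UserWarning, match="unweighted"):
        avg = average_compositions([a, b], renormalize=False)
    assert avg.fractions["protein"] == pytest.approx(42.0)


# -- ash and C-mol formula ---------------------------------------------------

def test_ash_by_subtraction_printed_averages():
    gly = datasets.get_elemental_composition("glycerol", "average")
    meoh = datasets.get_elemental_composition("methanol", "average")
    assert ash_by_subtraction(gly) == pytest.approx(7.8, abs=0.1)
    assert ash_by_subtraction(meoh) == pytest.approx(7.0, abs=0.1)


def test_ash_pure_ch2o_is_zero():
    e = ElementalComposition({"C": 40.0, "H": 6.7, "N": 0.0, "O": 53.3,
                              "S": 0.0})
    assert ash_by_subtraction(e) == pytest.approx(0.0, abs=0.05)


def test_ash_negative_is_error():
    e = ElementalComposition({"C": 50.0, "H": 10.0, "N": 10.0, "O": 35.0,
                              "S": 1.0})
    with pytest.raises(ValueError, match="inconsistent"):
        ash_by_subtraction(e)


def test_cmol_formula_glycerol_average(glycerol_biomass):
    f = glycerol_biomass.formula
    assert f["H"] == pytest.approx(1.78, abs=0.02)
    assert f["O"] == pytest.approx(0.63, abs=0.01)
    assert f["N"] == pytest.approx(0.175, abs=0.003)
    assert glycerol_biomass.c_content == pytest.approx(34.95, abs=0.05)


def test_cmol_formula_pure_ch2o():
    e = ElementalComposition({"C": 40.002, "H": 6.714, "N": 0.0, "O": 53.284,
                              "S": 0.0})
    cm = derive_cmol_formula(e)
    assert cm.formula["H"] == pytest.approx(2.0, abs=0.01)
    assert cm.formula["O"] == pytest.approx(1.0, abs=0.01)
    assert cm.gamma == pytest.approx(4.0, abs=0.02)


# -- equation assembly -------------------------------------------------------

def test_pure_carbohydrate_anhydroglucose_coefficient():
    m = MacroComposition(fractions={"carbohydrate": 100.0})
    eq = build_biomass_equation(
        m, MonomerProfile(rna_bases={"amp": 100.0}), atp_coefficient=0.0)
    assert eq.coefficients["glucose"] == pytest.approx(1000.0 / 162.14,
                                                       abs=1e-3)
    assert eq.coefficients["glucose"] == pytest.approx(
        1000.0 / M_ANHYDROGLUCOSE, rel=1e-12)


@pytest.mark.parametrize("substrate", ["glycerol", "methanol"])
def test_equation_mass_conservation_and_shares(substrate):
    """Net fixed mass is 1 g and each class contributes its mass fraction."""
    macro = datasets.get_macro_composition(substrate, "average").normalize()
    profiles = datasets.default_profiles(substrate)
    eq = build_biomass_equation(macro, profiles, atp_coefficient=70.0)
    assert eq.consumed_mass() == pytest.approx(1.0, abs=0.005)

    monomers = load_monomer_table()
    from chemocal.formulas import M_WATER
    # protein share: residues' anhydro mass must equal the protein fraction
    prot_mass = sum(
        eq.coefficients[m] * (monomers["protein"][m]["mass"] - M_WATER)
        for m in monomers["protein"] if m in eq.coefficients) / 10.0
    assert prot_mass == pytest.approx(macro.fractions["protein"], rel=1e-6)
    lip_mass = sum(
        eq.coefficients[m] * monomers["lipid"][m]["mass"]
        for m in monomers["lipid"] if m in eq.coefficients) / 10.0
    assert lip_mass == pytest.approx(macro.fractions["lipid"], rel=1e-6)


@pytest.mark.parametrize("substrate", ["glycerol", "methanol"])
def test_elemental_closure_of_built_equation(substrate):
    """The equation's implied CHNOS matches the (reconciled) elemental
    composition within 3% per element."""
    conds = datasets.conditions(substrate)
    macro = average_compositions(
        [datasets.get_macro_composition(substrate, c) for c in conds],
        renormalize=False)
    elem = average_compositions(
        [datasets.get_elemental_composition(substrate, c) for c in conds])
    profiles = datasets.default_profiles(substrate)
    macro_r, elem_r, _ = reconcile_composition(macro, elem, profiles)
    eq = build_biomass_equation(macro_r, profiles, atp_coefficient=70.0)
    implied = eq.implied_elements()
    for el in ("C", "H", "N", "O", "S"):
        assert implied[el] == pytest.approx(elem_r.fractions[el], rel=0.03), el


def test_missing_profile_for_nonzero_fraction_errors():
    m = _macro()
    with pytest.raises(ValueError, match="profile missing"):
        build_biomass_equation(m, MonomerProfile(), atp_coefficient=0.0)


def test_negative_coefficient_rejected():
    with pytest.raises(ValueError, match="negative"):
        BiomassEquation(coefficients={"glucose": -1.0}, atp_coefficient=0.0)


def test_normalization_is_gentle_on_printed_averages():
    """Raw sum 100.45 normalizes without moving any component > 0.5."""
    macro = datasets.get_macro_composition("glycerol", "average")
    assert macro.total() == pytest.approx(100.45, abs=0.01)
    norm = macro.normalize()
    assert norm.total() == pytest.approx(100.0, abs=1e-9)
    for k in MACRO_COMPONENTS:
        assert abs(norm.fractions[k] - macro.fractions[k]) < 0.5


# -- installation ------------------------------------------------------------

def test_install_makes_toy_grow(toy_model):
    eq = toy_equation_template()
    m = install_biomass(toy_model, eq, ngame=2.5, id_map={"atp": "ATP"},
                        biomass_metabolite="X")
    sol = solve_fba(m, sense="max", fixed={"EX_S": -2.0})
    assert sol.optimal and sol.objective_value > 0


def test_install_is_idempotent(toy_model):
    eq = toy_equation_template()
    m1 = install_biomass(toy_model, eq, ngame=2.5, id_map={"atp": "ATP"},
                         biomass_metabolite="X")
    m2 = install_biomass(m1, eq, ngame=2.5, id_map={"atp": "ATP"},
                         biomass_metabolite="X")
    assert len(m2.reactions) == len(m1.reactions) == len(toy_model.reactions)
    assert m2.objective_id == "biomass"


def test_install_unmapped_component_lists_ids(toy_model):
    eq = BiomassEquation(coefficients={"glucose": 1.0, "ala": 2.0},
                         atp_coefficient=10.0)
    with pytest.raises(ValueError) as err:
        install_biomass(toy_model, eq, id_map={"atp": "ATP"})
    assert "glucose" in str(err.value) and "ala" in str(err.value)


def test_growth_strictly_decreasing_in_atp_coefficient(toy_model, toy_spec):
    """Closed form: mu at fixed q_S strictly decreases in GAME."""
    mus = []
    for g in (50.0, 100.0, 150.0, 200.0):
        eq = BiomassEquation(coefficients={"P": toy_spec.p},
                             atp_coefficient=g)
        m = install_biomass(toy_model, eq, ngame=2.5, id_map={"atp": "ATP"},
                            biomass_metabolite="X")
        sol = solve_fba(m, fixed={"EX_S": -2.0})
        mus.append(sol.objective_value)
        assert sol.objective_value == pytest.approx(
            toy_spec.mu_at_uptake(2.0, g=g), abs=1e-8)
    assert all(a > b for a, b in zip(mus, mus[1:]))
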