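"""Carbon-source-specific biomass equation from measured composition.

Averages the per-growth-rate compositions (1/SD weights), reconciles the
macromolecular against the elemental side (mass closure + element
consistency), and assembles a per-gram-DCW biomass equation whose monomer
coefficients are in mmol/gDCW.  The net fixed mass must be 1.000 g and the
implied elemental makeup must match the measured CHNOS fractions.
"""

from chemocal import (average_compositions, ash_by_subtraction,
                      build_biomass_equation, datasets, derive_cmol_formula,
                      reconcile_composition)

for substrate in ("glycerol", "methanol"):
    conds = datasets.conditions(substrate)
    macro = average_compositions(
        [datasets.get_macro_composition(substrate, c) for c in conds],
        renormalize=False)
    elem = average_compositions(
        [datasets.get_elemental_composition(substrate, c) for c in conds])
    print(f"\n{substrate}: averaged over D = {conds}")
    print(f"  ash by subtraction: {ash_by_subtraction(elem):.2f} w/w %")
    print(f"  C-mol formula: {derive_cmol_formula(elem)}")

    profiles = datasets.default_profiles(substrate)
    macro_r, elem_r, res = reconcile_composition(macro, elem, profiles)
    eq = build_biomass_equation(macro_r, profiles, atp_coefficient=70.0,
                                substrate=substrate)
    print(f"  biomass equation fixes {eq.consumed_mass():.4f} g per gDCW; "
          f"{len(eq.coefficients)} monomer species")
    impl = eq.implied_elements()
    print("  implied vs measured C: "
          f"{impl['C']:.2f} vs {elem_r.fractions['C']:.2f} w/w %")
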