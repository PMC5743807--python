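"""Packaged reference data: published *P. pastoris* chemostat physiology.

Ships the reconciled steady-state rate table (glycerol and methanol
dilution-rate series) and the per-growth-rate biomass compositions used to
build the carbon-source-specific biomass equations, plus synthetic default
monomer profiles (the measured amino-acid/lipid profiles are not packaged;
the defaults are literature-typical yeast values, see the profiles file).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .biomass import (
    ELEMENTS,
    MACRO_COMPONENTS,
    CmolFormula,
    ElementalComposition,
    MacroComposition,
    MonomerProfile,
    derive_cmol_formula,
)
from .chemostat import RateVector, frame_to_rates


def _read(name: str) -> pd.DataFrame:
    with resources.files("chemocal.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_rates_frame() -> pd.DataFrame:
    """Published steady-state rate table (with printed yields and RQ)."""
    return _read("pastoris_chemostat_rates.tsv")


def load_rates(substrate: str | None = None) -> list[RateVector]:
    df = load_rates_frame()
    if substrate is not None:
        df = df[df["substrate"] == substrate].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"no rates for substrate {substrate!r}")
    return frame_to_rates(df)


def load_composition_frame() -> pd.DataFrame:
    return _read("pastoris_biomass_composition.tsv")


def _select(substrate: str, condition: str) -> pd.DataFrame:
    df = load_composition_frame()
    sel = df[(df["substrate"] == substrate) & (df["condition"] == condition)]
    if sel.empty:
        raise ValueError(f"no composition for {substrate!r} at {condition!r}")
    return sel.set_index("component")


def get_macro_composition(substrate: str, condition: str = "average"
                          ) -> MacroComposition:
    sel = _select(substrate, condition)
    return MacroComposition(
        fractions={c: float(sel.loc[c, "value"]) for c in MACRO_COMPONENTS},
        sds={c: float(sel.loc[c, "sd"]) for c in MACRO_COMPONENTS},
        label=f"{substrate}:{condition}",
    )


def get_elemental_composition(substrate: str, condition: str = "average"
                              ) -> ElementalComposition:
    sel = _select(substrate, condition)
    return ElementalComposition(
        fractions={e: float(sel.loc[e, "value"]) for e in ELEMENTS},
        sds={e: float(sel.loc[e, "sd"]) for e in ELEMENTS},
        label=f"{substrate}:{condition}",
    )


def get_ash(substrate: str, condition: str = "average") -> float:
    """Printed ash content (w/w %), determined by elemental subtraction."""
    return float(_select(substrate, condition).loc["ash", "value"])


def conditions(substrate: str) -> list[str]:
    df = load_composition_frame()
    vals = df[df["substrate"] == substrate]["condition"].unique().tolist()
    return [c for c in vals if c != "average"]


def biomass_constants(substrate: str) -> CmolFormula:
    """C-mol formula, carbon content and degree of reduction of the average
    biomass grown on ``substrate``."""
    return derive_cmol_formula(get_elemental_composition(substrate, "average"))


def default_profiles(substrate: str = "glycerol") -> MonomerProfile:
    """Synthetic default monomer profiles (literature-typical yeast values;
    stand-ins for measured amino-acid/lipid profiles)."""
    df = _read("default_monomer_profiles.synthetic.tsv")

    def prof(name: str) -> dict[str, float]:
        sel = df[df["profile"] == name]
        return dict(zip(sel["component"], sel["value"]))

    lipid_key = f"lipid_{substrate}" if substrate in ("glycerol", "methanol") \
        else "lipid_glycerol"
    return MonomerProfile(
        amino_acids=prof("amino_acids"),
        lipid_classes=prof(lipid_key),
        rna_bases=prof("rna_bases"),
    )
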