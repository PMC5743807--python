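"""Biomass composition bookkeeping and biomass-equation construction.

Covers the composition side of model calibration: weighted averaging of
macromolecular and elemental compositions across growth rates, ash by
subtraction, C-mol formula derivation, WLS reconciliation of macromolecular
vs elemental measurements, and assembly of a per-gram-DCW biomass equation
from monomer profiles, including installation into a metabolic model
together with the non-growth maintenance (ATPM) bound.

Monomer formulas (amino acids, NMP/dNMPs, anhydroglucose, representative
lipid species) ship as a packaged constants table.  Measured Asx/Glx pairs
are split 50/50 between acid and amide forms (acid-hydrolysis convention);
jointly measured PI/PS lipids are likewise split 50/50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .fluxmodel import MetNet, Reaction
from .formulas import ATOMIC_MASS, M_WATER, degree_of_reduction, molar_mass, parse_formula
from .reconcile import BalanceSystem, ReconciliationResult, reconcile_wls

MACRO_COMPONENTS = ("protein", "carbohydrate", "lipid", "rna", "dna",
                    "so4", "h2o", "metals")
ELEMENTS = ("C", "H", "N", "O", "S")

#: mass of an anhydroglucose unit, g/mol (glucose minus water)
M_ANHYDROGLUCOSE = molar_mass("C6H12O6") - M_WATER


def _as_fraction_dict(values, keys) -> dict[str, float]:
    out = {k: float(values.get(k, 0.0)) for k in keys}
    unknown = set(values) - set(keys)
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    return out


@dataclass
class MacroComposition:
    """Macromolecular biomass composition, w/w % of dry cell weight."""

    fractions: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        self.fractions = _as_fraction_dict(self.fractions, MACRO_COMPONENTS)
        if any(not 0 <= v <= 100 for v in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 100]")
        tot = self.total()
        if not 95.0 <= tot <= 105.0:
            raise ValueError(f"macromolecular fractions sum to {tot:.2f}, "
                             "outside the [95, 105] rounding tolerance")

    def total(self) -> float:
        return float(sum(self.fractions.values()))

    def normalize(self) -> "MacroComposition":
        """Rescale so the fractions sum to exactly 100."""
        f = 100.0 / self.total()
        return MacroComposition(
            fractions={k: v * f for k, v in self.fractions.items()},
            sds={k: v * f for k, v in self.sds.items()},
            label=self.label,
        )


@dataclass
class ElementalComposition:
    """CHNOS content, w/w % of dry cell weight; ash closes the balance."""

    fractions: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        self.fractions = _as_fraction_dict(self.fractions, ELEMENTS)
        if self.fractions["C"] <= 0:
            raise ValueError("carbon fraction must be positive")

    def total(self) -> float:
        return float(sum(self.fractions.values()))


def ash_by_subtraction(e: ElementalComposition) -> float:
    """Ash content as the remainder after the C, H, N, O, S fractions."""
    ash = 100.0 - e.total()
    if ash < 0:
        raise ValueError(
            f"CHNOS fractions sum to {e.total():.2f} > 100; inconsistent input"
        )
    return ash


@dataclass
class MonomerProfile:
    """Monomer profiles of the polymeric / lipid fractions.

    amino_acids and rna_bases are mol %, lipid_classes w/w % of the lipid
    fraction; each sub-profile sums to 100 (+-0.5).  DNA base composition
    follows ``dna_gc`` (fraction G+C) rather than a measured profile.
    Measured pairs (asx/glx, pi_ps) are allowed and split downstream.
    """

    amino_acids: dict[str, float] = field(default_factory=dict)
    lipid_classes: dict[str, float] = field(default_factory=dict)
    rna_bases: dict[str, float] = field(default_factory=dict)
    dna_gc: float = 0.41

    def __post_init__(self) -> None:
        for name, prof in (("amino_acids", self.amino_acids),
                           ("lipid_classes", self.lipid_classes),
                           ("rna_bases", self.rna_bases)):
            if prof and abs(sum(prof.values()) - 100.0) > 0.5:
                raise ValueError(f"{name} profile sums to "
                                 f"{sum(prof.values()):.2f}, expected 100")


def _split_pairs(profile: dict[str, float], pairs: dict[str, tuple[str, str]]
                 ) -> dict[str, float]:
    out: dict[str, float] = {}
    for key, val in profile.items():
        if key in pairs:
            a, b = pairs[key]
            out[a] = out.get(a, 0.0) + val / 2.0
            out[b] = out.get(b, 0.0) + val / 2.0
        else:
            out[key] = out.get(key, 0.0) + val
    return out


# ---------------------------------------------------------------------------
# Averaging and formula derivation
# ---------------------------------------------------------------------------

def average_compositions(series, renormalize: bool | None = None):
    """1/SD-weighted per-component average of compositions of one type.

    The combined SD reported per component is the weighted sample standard
    deviation around the weighted mean (floored by the SD of the weighted
    mean itself).  Missing or zero SDs trigger a fallback to the unweighted
    mean, with a warning.  Macromolecular averages are renormalized to sum
    to 100 unless ``renormalize`` is False.
    """
    if len(series) < 2:
        raise ValueError("averaging needs at least two compositions")
    cls = type(series[0])
    if any(type(s) is not cls for s in series):
        raise ValueError("cannot mix composition types in one average")
    keys = MACRO_COMPONENTS if cls is MacroComposition else ELEMENTS
    means, sds = {}, {}
    for k in keys:
        vals = np.array([s.fractions[k] for s in series])
        svec = np.array([s.sds.get(k, 0.0) for s in series])
        if np.any(svec <= 0):
            warnings.warn(f"missing SD for {k!r}: unweighted mean used",
                          stacklevel=2)
            w = np.ones_like(vals)
        else:
            w = 1.0 / svec
        mean = float(np.sum(w * vals) / np.sum(w))
        spread = float(np.sqrt(np.sum(w * (vals - mean) ** 2) / np.sum(w)))
        sd_of_mean = float(np.sqrt(np.sum((w * svec) ** 2)) / np.sum(w)) \
            if np.all(svec > 0) else 0.0
        means[k] = mean
        sds[k] = max(spread, sd_of_mean)
    out = cls(fractions=means, sds=sds, label="average")
    if cls is MacroComposition and renormalize is not False:
        out = out.normalize()
    return out


@dataclass
class CmolFormula:
    """Biomass C-mol formula CH_x O_y N_z S_w with derived constants."""

    formula: dict[str, float]
    c_content: float  # mmol C per gDCW
    gamma: float  # degree of reduction per C-mol

    def __str__(self) -> str:
        f = self.formula
        return (f"CH{f.get('H', 0):.3f}O{f.get('O', 0):.3f}"
                f"N{f.get('N', 0):.3f}S{f.get('S', 0):.4f}")


def derive_cmol_formula(e: ElementalComposition) -> CmolFormula:
    """Mole ratios from mass fractions; C content in mmol C per gDCW."""
    mol = {el: e.fractions[el] / ATOMIC_MASS[el] for el in ELEMENTS}
    if mol["C"] <= 0:
        raise ValueError("carbon content must be positive")
    formula = {"C": 1.0}
    formula.update({el: mol[el] / mol["C"] for el in ("H", "N", "O", "S")})
    c_content = 10.0 * e.fractions["C"] / ATOMIC_MASS["C"]  # mmol/gDCW
    return CmolFormula(
        formula=formula, c_content=c_content,
        gamma=degree_of_reduction(formula),
    )


# ---------------------------------------------------------------------------
# Monomer constants
# ---------------------------------------------------------------------------

def load_monomer_table() -> dict[str, dict[str, dict]]:
    """Packaged monomer constants: class -> id -> {formula, mass, polymerizes}."""
    with resources.files("chemocal.data").joinpath("monomers.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    table: dict[str, dict[str, dict]] = {}
    for _, row in df.iterrows():
        f = parse_formula(row["formula"])
        table.setdefault(row["class"], {})[row["id"]] = {
            "formula": f,
            "mass": molar_mass(f),
            "polymerizes": bool(row["polymerizes"]),
        }
    return table


_AA_PAIRS = {"asx": ("asp", "asn"), "glx": ("glu", "gln")}
_LIPID_PAIRS = {"pi_ps": ("pi", "ps")}


def _expanded_profile(profile: dict[str, float], klass: str,
                      monomers: dict) -> dict[str, float]:
    pairs = _AA_PAIRS if klass == "protein" else (
        _LIPID_PAIRS if klass == "lipid" else {})
    expanded = _split_pairs(profile, pairs)
    unknown = set(expanded) - set(monomers[klass])
    if unknown:
        raise ValueError(f"unknown {klass} monomers: {sorted(unknown)}")
    return expanded


def _dna_profile(gc: float) -> dict[str, float]:
    at = (1.0 - gc) / 2.0 * 100.0
    gcv = gc / 2.0 * 100.0
    return {"damp": at, "dtmp": at, "dgmp": gcv, "dcmp": gcv}


def class_element_fractions(klass: str, profile: dict[str, float],
                            monomers: dict | None = None) -> dict[str, float]:
    """Element mass fractions (g element / g component) of one macromolecule
    class, given its monomer profile.  Polymer classes use anhydro residues
    (monomer minus water); lipids are mass-weighted intact species."""
    monomers = monomers or load_monomer_table()
    entries = monomers[klass]
    prof = _expanded_profile(profile, klass, monomers)
    out = {el: 0.0 for el in ATOMIC_MASS}
    if klass == "lipid":
        for mid, share in prof.items():
            e = entries[mid]
            for el, n in e["formula"].items():
                out[el] += (share / 100.0) * n * ATOMIC_MASS[el] / e["mass"]
        return out
    # mol-%-weighted residues
    total = sum(prof.values())
    mean_mass = sum(
        (prof[mid] / total) * (entries[mid]["mass"] - M_WATER) for mid in prof
    )
    for mid, frac in prof.items():
        f = dict(entries[mid]["formula"])
        f["H"] = f.get("H", 0) - 2
        f["O"] = f.get("O", 0) - 1
        for el, n in f.items():
            out[el] += (frac / total) * n * ATOMIC_MASS[el] / mean_mass
    return out


# ---------------------------------------------------------------------------
# Composition reconciliation (mass closure + elemental consistency)
# ---------------------------------------------------------------------------

_SIMPLE_ELEMENT_FRACTIONS = {
    "so4": {el: n * ATOMIC_MASS[el] / molar_mass("O4S")
            for el, n in parse_formula("O4S").items()},
    "h2o": {el: n * ATOMIC_MASS[el] / M_WATER
            for el, n in parse_formula("H2O").items()},
    "metals": {},
}


def reconcile_composition(
    macro: MacroComposition,
    elemental: ElementalComposition,
    profiles: MonomerProfile,
    alpha: float = 0.05,
    monomers: dict | None = None,
) -> tuple[MacroComposition, ElementalComposition, ReconciliationResult]:
    """Jointly reconcile macromolecular and elemental compositions.

    Constraints: macromolecular fractions sum to 100 (mass closure), and for
    each element the content implied by the macromolecule monomer formulas
    equals the measured elemental fraction.  Variables are the 8
    macromolecular plus the 5 elemental fractions, weighted by their SDs.
    """
    monomers = monomers or load_monomer_table()
    wfrac = {
        "protein": class_element_fractions("protein", profiles.amino_acids, monomers),
        "carbohydrate": class_element_fractions("carbohydrate", {"glucose": 100.0}, monomers),
        "lipid": class_element_fractions("lipid", profiles.lipid_classes, monomers),
        "rna": class_element_fractions("rna", profiles.rna_bases, monomers),
        "dna": class_element_fractions("dna", _dna_profile(profiles.dna_gc), monomers),
        **_SIMPLE_ELEMENT_FRACTIONS,
    }
    cols = list(MACRO_COMPONENTS) + list(ELEMENTS)
    x = np.array([macro.fractions[c] for c in MACRO_COMPONENTS]
                 + [elemental.fractions[e] for e in ELEMENTS])
    sds = np.array([max(macro.sds.get(c, 0.0), 1e-3) for c in MACRO_COMPONENTS]
                   + [max(elemental.sds.get(e, 0.0), 1e-3) for e in ELEMENTS])
    rows, labels, b = [], [], []
    rows.append([1.0] * len(MACRO_COMPONENTS) + [0.0] * len(ELEMENTS))
    labels.append("mass_closure")
    b.append(100.0)
    for i, el in enumerate(ELEMENTS):
        row = [wfrac[c].get(el, 0.0) for c in MACRO_COMPONENTS]
        row += [-1.0 if j == i else 0.0 for j in range(len(ELEMENTS))]
        rows.append(row)
        labels.append(f"element_{el}")
        b.append(0.0)
    system = BalanceSystem(E=np.array(rows), row_labels=labels,
                           col_labels=cols, sds=sds)
    res = reconcile_wls(x, system, alpha=alpha, b=np.array(b))
    vals = dict(zip(cols, res.x_hat))
    new_macro = MacroComposition(
        fractions={c: vals[c] for c in MACRO_COMPONENTS},
        sds=dict(macro.sds), label=macro.label,
    )
    new_elem = ElementalComposition(
        fractions={e: vals[e] for e in ELEMENTS},
        sds=dict(elemental.sds), label=elemental.label,
    )
    return new_macro, new_elem, res


# ---------------------------------------------------------------------------
# Biomass equation
# ---------------------------------------------------------------------------

@dataclass
class BiomassEquation:
    """Per-gram-DCW biomass pseudo-reaction.

    ``coefficients`` are consumed monomers in mmol/gDCW (all >= 0);
    ``water`` is the net water term (negative = released by condensation);
    ``atp_coefficient`` is the growth-associated maintenance ATP (GAME,
    mmol/gDCW); ``mass_shares`` holds lumped pseudo-components (metals/ash)
    as g/gDCW.
    """

    coefficients: dict[str, float]
    atp_coefficient: float
    water: float = 0.0
    mass_shares: dict[str, float] = field(default_factory=dict)
    substrate: str = ""

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.coefficients.items() if v < 0}
        if bad:
            raise ValueError(f"negative consumed coefficients: {bad}")

    def consumed_mass(self, monomers: dict | None = None) -> float:
        """Net grams of matter fixed per gDCW (must be ~1)."""
        monomers = monomers or load_monomer_table()
        masses = {mid: e["mass"] for cls in monomers.values()
                  for mid, e in cls.items()}
        total = sum(coef * masses[mid] / 1000.0
                    for mid, coef in self.coefficients.items())
        total += self.water * M_WATER / 1000.0
        total += sum(self.mass_shares.values())
        return total

    def implied_elements(self, monomers: dict | None = None) -> dict[str, float]:
        """Element w/w % implied by the net consumed monomers (metals excluded)."""
        monomers = monomers or load_monomer_table()
        formulas = {mid: e["formula"] for cls in monomers.values()
                    for mid, e in cls.items()}
        out = {el: 0.0 for el in ATOMIC_MASS}
        for mid, coef in self.coefficients.items():
            for el, n in formulas[mid].items():
                out[el] += coef * n * ATOMIC_MASS[el] / 10.0  # mmol -> w/w %
        out["H"] += self.water * 2 * ATOMIC_MASS["H"] / 10.0
        out["O"] += self.water * ATOMIC_MASS["O"] / 10.0
        return out

    def validate(self, tol: float = 0.005) -> None:
        mass = self.consumed_mass()
        if abs(mass - 1.0) > tol:
            raise ValueError(f"biomass equation fixes {mass:.4f} g per gDCW "
                             f"(outside 1 +- {tol})")

    def reaction_string(self, precision: int = 4) -> str:
        lhs = [f"{v:.{precision}f} {k}" for k, v in
               sorted(self.coefficients.items())]
        lhs.append(f"{self.atp_coefficient:.{precision}f} atp")
        rhs = ["1 biomass"]
        if self.water >= 0:
            lhs.append(f"{self.water:.{precision}f} h2o")
        else:
            rhs.append(f"{-self.water:.{precision}f} h2o")
        return " + ".join(lhs) + " --> " + " + ".join(rhs)


def build_biomass_equation(
    macro: MacroComposition,
    profiles: MonomerProfile,
    atp_coefficient: float,
    monomers: dict | None = None,
    substrate: str = "",
) -> BiomassEquation:
    """Assemble the biomass equation from a (normalized) composition.

    Each macromolecule contributes exactly its mass fraction per gram DCW:
    polymer classes consume free monomers and release one water per residue
    (anhydro-monomer accounting; chain termini neglected), lipid classes are
    consumed as intact representative species mass-weighted within the lipid
    fraction, sulphate and structural water enter as such, and metals are
    carried as a mass share.
    """
    monomers = monomers or load_monomer_table()
    macro = macro.normalize()
    coeffs: dict[str, float] = {}
    water_released = 0.0

    class_profiles = {
        "protein": profiles.amino_acids,
        "carbohydrate": {"glucose": 100.0},
        "rna": profiles.rna_bases,
        "dna": _dna_profile(profiles.dna_gc),
        "lipid": profiles.lipid_classes,
    }
    for klass in ("protein", "carbohydrate", "rna", "dna"):
        grams = macro.fractions[klass] / 100.0
        if grams == 0:
            continue
        prof = class_profiles[klass]
        if not prof:
            raise ValueError(f"monomer profile missing for nonzero {klass} fraction")
        prof = _expanded_profile(prof, klass, monomers)
        total = sum(prof.values())
        mean_res = sum((prof[m] / total) * (monomers[klass][m]["mass"] - M_WATER)
                       for m in prof)
        total_mmol = 1000.0 * grams / mean_res
        for m, frac in prof.items():
            coeffs[m] = coeffs.get(m, 0.0) + (frac / total) * total_mmol
        water_released += total_mmol

    grams_lipid = macro.fractions["lipid"] / 100.0
    if grams_lipid > 0:
        if not profiles.lipid_classes:
            raise ValueError("monomer profile missing for nonzero lipid fraction")
        prof = _expanded_profile(profiles.lipid_classes, "lipid", monomers)
        for m, share in prof.items():
            coeffs[m] = coeffs.get(m, 0.0) + \
                1000.0 * grams_lipid * (share / 100.0) / monomers["lipid"][m]["mass"]

    coeffs["so4"] = 1000.0 * macro.fractions["so4"] / 100.0 / molar_mass("O4S")
    water_in = 1000.0 * macro.fractions["h2o"] / 100.0 / M_WATER

    eq = BiomassEquation(
        coefficients=coeffs,
        atp_coefficient=atp_coefficient,
        water=water_in - water_released,
        mass_shares={"metals": macro.fractions["metals"] / 100.0},
        substrate=substrate,
    )
    eq.validate()
    return eq


def install_biomass(
    model: MetNet,
    eq: BiomassEquation,
    reaction_id: str = "biomass",
    ngame: float | None = None,
    id_map: dict[str, str] | None = None,
    atpm_id: str = "ATPM",
    biomass_metabolite: str | None = None,
) -> MetNet:
    """Install (or replace) the biomass reaction and the ATPM lower bound.

    ``id_map`` maps equation component ids to model metabolite ids; special
    keys ``atp``, ``adp``, ``pi``, ``h2o`` control how ATP hydrolysis and
    water are wired (ADP/Pi products are only added when mapped).  Mass-share
    pseudo-components (metals) are skipped unless mapped.  Reinstalling
    replaces the reaction, so the operation is idempotent.  Returns a new
    model; the input is not modified.
    """
    id_map = dict(id_map or {})
    new = model.copy()
    stoich: dict[str, float] = {}

    missing = []

    def met_of(component: str, required: bool = True) -> str | None:
        mid = id_map.get(component, component)
        if mid not in new.metabolites:
            if required:
                missing.append(component)
            return None
        return mid

    for comp, coef in eq.coefficients.items():
        if coef == 0:
            continue
        mid = met_of(comp)
        if mid:
            stoich[mid] = stoich.get(mid, 0.0) - coef
    for comp in eq.mass_shares:
        mid = id_map.get(comp)
        if mid is not None:
            if mid not in new.metabolites:
                missing.append(comp)
            else:
                stoich[mid] = stoich.get(mid, 0.0) - eq.mass_shares[comp]
    if eq.atp_coefficient:
        mid = met_of("atp")
        if mid:
            stoich[mid] = stoich.get(mid, 0.0) - eq.atp_coefficient
        for prod in ("adp", "pi"):
            if prod in id_map:
                pid = met_of(prod)
                if pid:
                    stoich[pid] = stoich.get(pid, 0.0) + eq.atp_coefficient
        if "adp" in id_map and ("h2o" in id_map or "h2o" in new.metabolites):
            wid = met_of("h2o", required=False)
            if wid:
                stoich[wid] = stoich.get(wid, 0.0) - eq.atp_coefficient
    if eq.water:
        # net water: positive = consumed (enters negatively), negative = released
        wid = met_of("h2o", required=False)
        if wid:
            stoich[wid] = stoich.get(wid, 0.0) - eq.water
    if biomass_metabolite is not None:
        bid = id_map.get(biomass_metabolite, biomass_metabolite)
        if bid not in new.metabolites:
            missing.append(biomass_metabolite)
        else:
            stoich[bid] = stoich.get(bid, 0.0) + 1.0
    if missing:
        raise ValueError(
            f"biomass components without model metabolites: {sorted(set(missing))}"
        )
    if not stoich:
        raise ValueError("biomass equation maps to no model metabolites")

    new.reactions[reaction_id] = Reaction(reaction_id, stoich, 0.0, 1000.0)
    new.objective_id = reaction_id
    if ngame is not None:
        if atpm_id not in new.reactions:
            raise ValueError(f"model has no {atpm_id!r} reaction to carry NGAME")
        new.reactions[atpm_id].lb = float(ngame)
    return new
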