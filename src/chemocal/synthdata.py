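"""Synthetic chemostat data from a toy metabolic network with known energetics.

The toy network is a glycerol-like carbon source (C3H8O3, degree of
reduction 14) feeding three lumped reactions:

    catabolism:  S + a_O2 O2 -> b_CO2 CO2 + k ATP
    anabolism:   S + e_ana ATP -> P
    biomass:     p P + g ATP -> X        (flux = mu, h^-1)
    ATPM:        ATP ->                  (lb = m, the NGAME)

Because every mole of anabolized substrate carries its atoms into biomass,
FBA on this network has a closed form: the substrate uptake follows the
Pirt line

    |q_S| = (p + (g + e_ana p) / k) mu + m / k

with q_O2 = -a_O2 c, q_CO2 = b_CO2 c for the catabolized flux
c = (g mu + e_ana p mu + m) / k, and biomass carbon content 3 p
(Cmmol/gDCW, C-mol formula CH8/3O, gamma 14/3).  The defaults are chosen so
the simulated series sits in the glycerol range of real yeast chemostats
(yield ~0.6 g/g, maintenance uptake ~0.14 mmol gDCW^-1 h^-1).

Measurement noise is multiplicative Gaussian with a given CV, matching the
~1-2% relative SDs of HPLC and dry-weight analytics, and a gross-error
injector exercises the h-index consistency test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomass import CmolFormula
from .chemostat import RATE_COLUMNS, RateVector
from .fluxmodel import INF, Metabolite, MetNet, Reaction


@dataclass
class ToyModelSpec:
    """Ground-truth parameters of the toy network (all positive)."""

    p: float = 11.65  # precursor demand, mmol P per gDCW
    k: float = 18.0  # ATP per catabolized substrate
    a_o2: float = 3.5  # O2 per catabolized substrate
    b_co2: float = 3.0  # CO2 per catabolized substrate
    e_ana: float = 2.0  # ATP per anabolized substrate
    g_true: float = 70.0  # GAME, mmol ATP per gDCW
    m_true: float = 2.5  # NGAME, mmol ATP per gDCW per h

    def __post_init__(self) -> None:
        if min(self.p, self.k, self.a_o2, self.b_co2,
               self.e_ana, self.g_true, self.m_true) <= 0:
            raise ValueError("all toy parameters must be positive")

    # -- closed forms -------------------------------------------------------

    def pirt_slope(self, g: float | None = None) -> float:
        g = self.g_true if g is None else g
        return self.p + (g + self.e_ana * self.p) / self.k

    @property
    def pirt_intercept(self) -> float:
        return self.m_true / self.k

    @property
    def c_content(self) -> float:
        """Biomass carbon content, Cmmol per gDCW (substrate has 3 C)."""
        return 3.0 * self.p

    def biomass_cmol(self) -> CmolFormula:
        return CmolFormula(formula={"C": 1.0, "H": 8.0 / 3.0, "O": 1.0},
                           c_content=self.c_content, gamma=14.0 / 3.0)

    def mu_at_uptake(self, q_s_abs: float, atpm: float | None = None,
                     g: float | None = None) -> float:
        """Growth rate when |q_S| is fixed and ATPM runs at its bound."""
        m = self.m_true if atpm is None else atpm
        return (q_s_abs - m / self.k) / self.pirt_slope(g)

    def uptake_at_mu(self, mu: float, atpm: float | None = None,
                     g: float | None = None) -> float:
        m = self.m_true if atpm is None else atpm
        return self.pirt_slope(g) * mu + m / self.k

    def rates_at(self, d: float, atpm: float | None = None) -> RateVector:
        """Exact steady-state rate vector at dilution rate ``d``."""
        m = self.m_true if atpm is None else atpm
        c = (self.g_true * d + self.e_ana * self.p * d + m) / self.k
        return RateVector(
            mu=d, q_s=-self.uptake_at_mu(d, atpm=atpm),
            q_o2=-self.a_o2 * c, q_co2=self.b_co2 * c,
            q_x=self.c_content * d, substrate="toy", label=f"D={d:g}",
        )


@dataclass
class NoiseSpec:
    """Multiplicative Gaussian measurement noise with relative SD ``cv``."""

    cv: float = 0.02
    seed: int = 0
    gross_error: tuple[str, float, int] | None = None  # (column, bias in SDs, row)

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


def make_toy_model(spec: ToyModelSpec | None = None) -> MetNet:
    """Build the toy network as a MetNet; FBA on it matches the closed form."""
    s = spec or ToyModelSpec()
    mets = {
        "S": Metabolite("S", {"C": 3, "H": 8, "O": 3}),
        "O2": Metabolite("O2", {"O": 2}),
        "CO2": Metabolite("CO2", {"C": 1, "O": 2}),
        "ATP": Metabolite("ATP"),
        "P": Metabolite("P", {"C": 3, "H": 8, "O": 3}),
        "X": Metabolite("X", {"C": 3 * s.p, "H": 8 * s.p, "O": 3 * s.p}),
    }
    rxns = {
        "EX_S": Reaction("EX_S", {"S": -1}, -1000.0, 0.0),
        "EX_O2": Reaction("EX_O2", {"O2": -1}, -1000.0, 0.0),
        "EX_CO2": Reaction("EX_CO2", {"CO2": -1}, 0.0, INF),
        "EX_X": Reaction("EX_X", {"X": -1}, 0.0, INF),
        "catabolism": Reaction(
            "catabolism",
            {"S": -1, "O2": -s.a_o2, "CO2": s.b_co2, "ATP": s.k}, 0.0, INF),
        "anabolism": Reaction(
            "anabolism", {"S": -1, "ATP": -s.e_ana, "P": 1}, 0.0, INF),
        "biomass": Reaction(
            "biomass", {"P": -s.p, "ATP": -s.g_true, "X": 1}, 0.0, INF),
        "ATPM": Reaction("ATPM", {"ATP": -1}, s.m_true, INF),
    }
    return MetNet(metabolites=mets, reactions=rxns,
                  objective_id="biomass", name="toy_chemostat")


DEFAULT_D_GRID = (0.035, 0.050, 0.065, 0.100, 0.130, 0.160)


def simulate_chemostat_series(
    spec: ToyModelSpec | None = None,
    d_grid=DEFAULT_D_GRID,
    noise: NoiseSpec | None = None,
) -> pd.DataFrame:
    """Simulate a chemostat dilution-rate series in the rates TSV dialect.

    Exact closed-form rates receive multiplicative Gaussian noise (seeded);
    SD columns are cv * |value|.  Dilution rates beyond the toy's washout
    limit are dropped (flagged in ``DataFrame.attrs['dropped']``).
    """
    s = spec or ToyModelSpec()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    rows, dropped = [], []
    for d in d_grid:
        if d <= 0 or s.uptake_at_mu(d) >= 1000.0:
            dropped.append(d)
            continue
        rv = s.rates_at(d)
        vals = {c: getattr(rv, f) for c, f in
                zip(RATE_COLUMNS, ("mu", "q_s", "q_o2", "q_co2", "q_x"))}
        row = {"substrate": "toy", "D_set": d}
        for col, v in vals.items():
            obs = v * (1.0 + noise.cv * rng.standard_normal())
            row[col] = obs
            row[f"{col}_sd"] = noise.cv * abs(v) if noise.cv > 0 else 1e-6
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["dropped"] = dropped
    df.attrs["spec"] = s
    if noise.gross_error is not None:
        col, bias, irow = noise.gross_error
        df = inject_gross_error(df, col, bias, irow)
    return df


def inject_gross_error(
    table: pd.DataFrame, variable: str, bias_sds: float, row: int
) -> pd.DataFrame:
    """Add ``bias_sds`` standard deviations to one cell; provenance is kept
    in ``DataFrame.attrs['gross_errors']``."""
    if variable not in table.columns or f"{variable}_sd" not in table.columns:
        raise ValueError(f"unknown rate variable {variable!r}")
    if not 0 <= row < len(table):
        raise ValueError(f"row {row} out of range")
    out = table.copy()
    out.attrs = dict(table.attrs)
    out.iloc[row, out.columns.get_loc(variable)] += (
        bias_sds * out.iloc[row, out.columns.get_loc(f"{variable}_sd")]
    )
    notes = list(out.attrs.get("gross_errors", []))
    notes.append({"variable": variable, "bias_sds": bias_sds, "row": row})
    out.attrs["gross_errors"] = notes
    return out


def simulate_composition(
    noise: NoiseSpec | None = None,
    base: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Emit a macromolecular composition table (component, value, sd)
    compatible with the biomass module; glycerol-like defaults."""
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed + 1)
    base = base or {
        "protein": 41.0, "carbohydrate": 35.9, "lipid": 2.5, "rna": 7.8,
        "dna": 0.19, "so4": 0.46, "h2o": 5.6, "metals": 7.0,
    }
    rows = []
    for comp, v in base.items():
        obs = v * (1.0 + noise.cv * rng.standard_normal())
        rows.append({"component": comp, "value": obs,
                     "sd": max(noise.cv * v, 1e-6)})
    return pd.DataFrame(rows)
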