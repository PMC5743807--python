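"""Chemostat measurements to signed specific rates, yields and RQ.

At steady state the specific growth rate equals the experimental dilution
rate (mu = D_exp; no correction for biomass in the off-gas or outflow).
Specific rates follow the sign convention of the rate tables: uptake
negative, production positive.  Standard deviations are propagated to first
order (delta method) assuming independent measurement errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formulas import molar_mass, parse_formula

#: molar masses (g/mol) of the common chemostat carbon sources
SUBSTRATE_MW = {
    "glycerol": molar_mass("C3H8O3"),
    "methanol": molar_mass("CH4O"),
    "glucose": molar_mass("C6H12O6"),
}

SUBSTRATE_FORMULA = {
    "glycerol": "C3H8O3",
    "methanol": "CH4O",
    "glucose": "C6H12O6",
}


@dataclass
class ChemostatObservation:
    """One steady state of a carbon-limited chemostat.

    Concentrations in g/L, gas rates volumetric (mmol L^-1 h^-1).
    ``sds`` holds per-field standard deviations keyed by field name.
    """

    d_set: float
    d_exp: float
    substrate: str
    s_feed: float
    s_residual: float
    x: float
    our: float
    cer: float
    sds: dict[str, float] = field(default_factory=dict)
    mw: float | None = None  # g/mol; required for substrates not in SUBSTRATE_MW

    def __post_init__(self) -> None:
        if self.d_exp <= 0:
            raise ValueError("D_exp must be positive")
        if min(self.s_feed, self.s_residual, self.x) < 0:
            raise ValueError("concentrations must be non-negative")
        if self.s_residual > self.s_feed:
            raise ValueError("residual substrate exceeds feed concentration")
        if self.mw is None:
            self.mw = SUBSTRATE_MW.get(self.substrate.lower())

    def sd(self, name: str) -> float:
        return float(self.sds.get(name, 0.0))


@dataclass
class RateVector:
    """Signed specific rates of one steady state.

    mu in h^-1; q_s, q_o2, q_co2 in mmol gDCW^-1 h^-1 (q_s, q_o2 <= 0);
    q_x in Cmmol gDCW^-1 h^-1.  ``sds`` keyed by the same field names.
    """

    mu: float
    q_s: float
    q_o2: float
    q_co2: float
    q_x: float
    sds: dict[str, float] = field(default_factory=dict)
    substrate: str = ""
    label: str = ""

    FIELDS = ("mu", "q_s", "q_o2", "q_co2", "q_x")

    def __post_init__(self) -> None:
        if self.q_s > 0 or self.q_o2 > 0:
            raise ValueError("q_s and q_o2 must be <= 0 (uptake is negative)")
        if self.q_co2 < 0 or self.q_x < 0:
            raise ValueError("q_co2 and q_x must be >= 0")
        if not self.label:
            self.label = f"mu={self.mu:g}"

    def values(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS])

    def sd(self, name: str) -> float:
        return float(self.sds.get(name, 0.0))


@dataclass
class YieldSet:
    y_xs: float  # gDCW per g substrate
    rq: float  # mol CO2 per mol O2
    sds: dict[str, float] = field(default_factory=dict)


def _relvar(value: float, sd: float) -> float:
    return (sd / value) ** 2 if value != 0 else 0.0


def compute_specific_rates(
    obs: ChemostatObservation, biomass_c_content: float
) -> tuple[RateVector, YieldSet]:
    """Reduce one chemostat observation to specific rates and yields.

    ``biomass_c_content`` is the biomass carbon content in mmol C per gDCW
    (e.g. ~35 for yeast); it converts mu to the biomass carbon production
    rate q_x = mu * C_content.

    q_S  = -D (S_feed - S_residual) 1000 / (MW X)
    q_O2 = -OUR / X,  q_CO2 = CER / X
    Y_XS = mu / (|q_S| MW / 1000),  RQ = q_CO2 / |q_O2|
    """
    if obs.x <= 0:
        raise ValueError("biomass concentration X must be positive")
    if not obs.mw:
        raise ValueError(f"unknown substrate molar mass for {obs.substrate!r}")
    d = obs.d_exp
    ds = obs.s_feed - obs.s_residual
    q_s = -d * ds * 1000.0 / (obs.mw * obs.x)
    q_o2 = -obs.our / obs.x
    q_co2 = obs.cer / obs.x
    q_x = d * biomass_c_content

    var_ds = obs.sd("s_feed") ** 2 + obs.sd("s_residual") ** 2
    rel_qs = _relvar(d, obs.sd("d_exp")) + (var_ds / ds**2 if ds else 0.0) + _relvar(
        obs.x, obs.sd("x")
    )
    rel_qo = _relvar(obs.our, obs.sd("our")) + _relvar(obs.x, obs.sd("x"))
    rel_qc = _relvar(obs.cer, obs.sd("cer")) + _relvar(obs.x, obs.sd("x"))
    sds = {
        "mu": obs.sd("d_exp"),
        "q_s": abs(q_s) * math.sqrt(rel_qs),
        "q_o2": abs(q_o2) * math.sqrt(rel_qo),
        "q_co2": abs(q_co2) * math.sqrt(rel_qc),
        "q_x": biomass_c_content * obs.sd("d_exp"),
    }
    rv = RateVector(
        mu=d, q_s=q_s, q_o2=q_o2, q_co2=q_co2, q_x=q_x,
        sds=sds, substrate=obs.substrate, label=f"D={obs.d_set:g}",
    )
    return rv, rates_to_yields(rv, obs.mw)


def rates_to_yields(rv: RateVector, mw: float) -> YieldSet:
    """Biomass yield (g/g) and respiratory quotient from a rate vector."""
    y = rv.mu / (abs(rv.q_s) * mw / 1000.0)
    rq = rv.q_co2 / abs(rv.q_o2)
    rel_y = _relvar(rv.mu, rv.sd("mu")) + _relvar(rv.q_s, rv.sd("q_s"))
    rel_rq = _relvar(rv.q_co2, rv.sd("q_co2")) + _relvar(rv.q_o2, rv.sd("q_o2"))
    return YieldSet(
        y_xs=y, rq=rq,
        sds={"y_xs": y * math.sqrt(rel_y), "rq": rq * math.sqrt(rel_rq)},
    )


@dataclass
class WashoutFit:
    mumax: float
    slope: float
    intercept: float
    r2: float


def estimate_washout_mumax(series, d: float) -> WashoutFit:
    """Estimate mu_max from washout kinetics at D > mu_max.

    During washout X(t) = X0 exp((mu_max - D) t), so an ordinary
    least-squares fit of ln X on t has slope mu_max - D and
    mu_max = D + slope.
    """
    t = np.asarray([p[0] for p in series], dtype=float)
    x = np.asarray([p[1] for p in series], dtype=float)
    if len(t) < 3:
        raise ValueError("washout estimation needs at least 3 points")
    if np.any(x <= 0):
        raise ValueError("biomass concentrations must be positive")
    fit = stats.linregress(t, np.log(x))
    if fit.slope >= 0:
        warnings.warn(
            "biomass does not decrease over the washout series; "
            "mu_max estimate is unreliable", stacklevel=2,
        )
    return WashoutFit(
        mumax=d + fit.slope, slope=fit.slope,
        intercept=fit.intercept, r2=fit.rvalue**2,
    )


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

RATE_COLUMNS = ["mu", "q_S", "q_O2", "q_CO2", "q_X"]
_COLMAP = {"q_S": "q_s", "q_O2": "q_o2", "q_CO2": "q_co2", "q_X": "q_x"}


def frame_to_rates(df: pd.DataFrame) -> list[RateVector]:
    """Rates-dialect DataFrame (columns mu, q_S, q_O2, q_CO2, q_X with
    ``_sd`` companions, optional substrate / D_set) -> RateVectors."""
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rates table missing columns: {missing}")
    out = []
    for idx, row in df.iterrows():
        sds = {
            _COLMAP.get(c, c): float(row[f"{c}_sd"])
            for c in RATE_COLUMNS
            if f"{c}_sd" in df.columns and pd.notna(row.get(f"{c}_sd"))
        }
        if "D_set" in df.columns and pd.notna(row["D_set"]):
            label = f"D={row['D_set']:g}"
        else:
            label = f"row{idx}"
        out.append(
            RateVector(
                mu=float(row["mu"]), q_s=float(row["q_S"]),
                q_o2=float(row["q_O2"]), q_co2=float(row["q_CO2"]),
                q_x=float(row["q_X"]), sds=sds,
                substrate=str(row.get("substrate", "")), label=label,
            )
        )
    return out


def rates_to_frame(rates: list[RateVector], d_set=None) -> pd.DataFrame:
    rows = []
    for i, rv in enumerate(rates):
        row = {
            "substrate": rv.substrate,
            "D_set": d_set[i] if d_set is not None else np.nan,
            "mu": rv.mu, "q_S": rv.q_s, "q_O2": rv.q_o2,
            "q_CO2": rv.q_co2, "q_X": rv.q_x,
        }
        for c in RATE_COLUMNS:
            row[f"{c}_sd"] = rv.sd(_COLMAP.get(c, c))
        rows.append(row)
    return pd.DataFrame(rows)


def read_rates_tsv(path) -> list[RateVector]:
    return frame_to_rates(pd.read_csv(path, sep="\t"))


def read_chemostat_tsv(path) -> list[ChemostatObservation]:
    """Raw-dialect TSV: columns D_set, D_exp, substrate, S_feed, S_residual,
    X, OUR, CER plus optional ``<col>_sd`` columns."""
    df = pd.read_csv(path, sep="\t")
    need = ["D_set", "D_exp", "substrate", "S_feed", "S_residual", "X", "OUR", "CER"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"chemostat table missing columns: {missing}")
    key = {"D_exp": "d_exp", "S_feed": "s_feed", "S_residual": "s_residual",
           "X": "x", "OUR": "our", "CER": "cer"}
    out = []
    for _, row in df.iterrows():
        sds = {
            key[c]: float(row[f"{c}_sd"])
            for c in key
            if f"{c}_sd" in df.columns and pd.notna(row.get(f"{c}_sd"))
        }
        out.append(
            ChemostatObservation(
                d_set=float(row["D_set"]), d_exp=float(row["D_exp"]),
                substrate=str(row["substrate"]), s_feed=float(row["S_feed"]),
                s_residual=float(row["S_residual"]), x=float(row["X"]),
                our=float(row["OUR"]), cer=float(row["CER"]), sds=sds,
            )
        )
    return out
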