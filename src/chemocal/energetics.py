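"""Maintenance-energy estimation and FBA-based validation.

Non-growth-associated maintenance (NGAME, mmol ATP gDCW^-1 h^-1) comes from
Pirt's law: regressing |q_S| on mu gives the maintenance substrate uptake
m_s as the intercept; fixing growth to zero and substrate uptake to -m_s
and maximizing the ATP-hydrolysis (ATPM) flux converts m_s into ATP
turnover.  Growth-associated maintenance (GAME, mmol ATP gDCW^-1) is the
ATP coefficient of the biomass equation, fitted by golden-section search so
that FBA growth at the measured substrate uptakes matches the measured
growth rates with least squared error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .biomass import BiomassEquation, install_biomass
from .chemostat import RateVector
from .fluxmodel import MetNet, minimize_uptake_at_growth, solve_fba


@dataclass
class PirtFit:
    slope: float  # mmol substrate per gDCW (inverse maximal yield term)
    intercept: float  # m_s, mmol substrate gDCW^-1 h^-1
    r2: float
    excluded: list[str] = field(default_factory=list)
    n: int = 0

    @property
    def m_s(self) -> float:
        return self.intercept


@dataclass
class EnergeticParams:
    ngame: float  # mmol ATP gDCW^-1 h^-1
    game: float  # mmol ATP gDCW^-1
    substrate: str = ""
    pirt: PirtFit | None = None
    residuals: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"substrate": self.substrate, "ngame": self.ngame,
               "game": self.game, "residuals": self.residuals}
        if self.pirt is not None:
            out["pirt"] = {
                "slope": self.pirt.slope, "intercept": self.pirt.intercept,
                "r2": self.pirt.r2, "excluded": self.pirt.excluded,
            }
        return out


def _included(rates: list[RateVector], exclude) -> list[RateVector]:
    exclude = set(exclude or ())
    return [rv for rv in rates if rv.label not in exclude]


def fit_pirt(rates: list[RateVector], exclude=(), weighted: bool = False
             ) -> PirtFit:
    """Least squares of |q_S| on mu; the intercept is m_s.

    ``exclude`` lists condition labels dropped from the fit (e.g. a lowest
    dilution rate below a metabolic shift).  With ``weighted`` the points
    are weighted by 1/sd(q_S)^2 (requires per-condition SDs), which is the
    efficient choice when the uptake SDs scale with the rate; the default
    is plain OLS.
    """
    used = _included(rates, exclude)
    if len(used) < 3:
        raise ValueError("Pirt fit needs at least 3 included conditions")
    mu = np.array([rv.mu for rv in used])
    qs = np.array([abs(rv.q_s) for rv in used])
    if weighted:
        sds = np.array([rv.sd("q_s") for rv in used])
        if np.any(sds <= 0):
            raise ValueError("weighted Pirt fit requires positive q_S SDs")
        w = 1.0 / sds**2
        A = np.column_stack([np.ones_like(mu), mu])
        beta = np.linalg.solve(A.T @ (w[:, None] * A), A.T @ (w * qs))
        intercept, slope = float(beta[0]), float(beta[1])
        resid = qs - A @ beta
        ybar = float(np.sum(w * qs) / np.sum(w))
        r2 = 1.0 - float(np.sum(w * resid**2) /
                         np.sum(w * (qs - ybar) ** 2))
    else:
        fit = stats.linregress(mu, qs)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), \
            float(fit.rvalue**2)
    if intercept < 0:
        import warnings

        warnings.warn("negative Pirt intercept; maintenance indistinguishable "
                      "from zero at these conditions", stacklevel=2)
    return PirtFit(slope=slope, intercept=intercept, r2=r2,
                   excluded=list(exclude), n=len(used))


def estimate_ngame(
    model: MetNet,
    substrate_exchange: str,
    m_s: float,
    atpm_id: str = "ATPM",
    biomass_id: str | None = None,
) -> float:
    """Maximum ATP turnover at zero growth and uptake fixed to m_s.

    Pure query: the model is not modified; the returned optimum is the
    NGAME to be installed as the ATPM lower bound.
    """
    if atpm_id not in model.reactions:
        raise ValueError(f"model has no {atpm_id!r} reaction")
    work = model.copy()
    work.reactions[atpm_id].lb = 0.0  # free the maintenance flux for the query
    sol = solve_fba(
        work, sense="max",
        fixed={biomass_id or model.objective_id: 0.0,
               substrate_exchange: -abs(m_s)},
        objective_id=atpm_id,
    )
    if not sol.optimal:
        raise ValueError(
            f"ATP turnover maximization {sol.status}; check that "
            f"{substrate_exchange!r} is the right substrate exchange"
        )
    return float(sol.objective_value)


def _mu_predictions(
    model: MetNet, rates: list[RateVector], substrate_exchange: str
) -> dict[str, float]:
    out = {}
    for rv in rates:
        sol = solve_fba(model, sense="max", fixed={substrate_exchange: rv.q_s})
        out[rv.label] = sol.objective_value if sol.optimal else float("nan")
    return out


def calibrate_game(
    model: MetNet,
    eq_template: BiomassEquation,
    rates: list[RateVector],
    ngame: float,
    exclude=(),
    substrate_exchange: str = "EX_S",
    reaction_id: str = "biomass",
    id_map: dict[str, str] | None = None,
    atpm_id: str = "ATPM",
    biomass_metabolite: str | None = None,
    bracket: tuple[float, float] = (0.0, 500.0),
    tol: float = 0.01,
) -> EnergeticParams:
    """Fit the biomass ATP coefficient (GAME) to the measured growth rates.

    For a candidate coefficient g the biomass equation is installed with the
    ATPM bound at ``ngame``; each condition fixes q_S to its measured value
    and maximizes mu by FBA; the unweighted sum of squared mu residuals is
    minimized by golden-section search, after a coarse scan that checks
    unimodality and brackets the optimum.  Converges when the bracket is
    narrower than ``tol`` (mmol ATP/gDCW).
    """
    used = _included(rates, exclude)
    if len(used) < 2:
        raise ValueError("GAME calibration needs at least 2 included conditions")

    def install(g: float) -> MetNet:
        eq = BiomassEquation(
            coefficients=dict(eq_template.coefficients), atp_coefficient=g,
            water=eq_template.water, mass_shares=dict(eq_template.mass_shares),
            substrate=eq_template.substrate,
        )
        return install_biomass(
            model, eq, reaction_id=reaction_id, ngame=ngame, id_map=id_map,
            atpm_id=atpm_id, biomass_metabolite=biomass_metabolite,
        )

    def residual(g: float) -> float:
        preds = _mu_predictions(install(g), used, substrate_exchange)
        return float(sum((preds[rv.label] - rv.mu) ** 2 for rv in used))

    # coarse scan: unimodality check + tight bracket for the golden section
    grid = np.linspace(bracket[0], bracket[1], 21)
    vals = np.array([residual(g) for g in grid])
    if not np.all(np.isfinite(vals)):
        raise ValueError("GAME residual not finite over the bracket; "
                         f"trace: {dict(zip(grid, vals))}")
    k = int(np.argmin(vals))
    d1 = np.diff(vals)
    d1[np.abs(d1) < 1e-12 * max(1.0, float(np.max(vals)))] = 0.0
    signs = np.sign(d1)
    signs = signs[signs != 0]
    sign_changes = int(np.count_nonzero(np.diff(signs)))
    if sign_changes > 1:
        raise ValueError("GAME residual is not unimodal over the bracket; "
                         f"trace: {dict(zip(grid, vals))}")
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = residual(c), residual(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = residual(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = residual(d)
    game = float((a + b) / 2.0)
    preds = _mu_predictions(install(game), used, substrate_exchange)
    return EnergeticParams(
        ngame=float(ngame), game=game,
        substrate=used[0].substrate,
        residuals={lbl: preds[lbl] - rv.mu for lbl, rv in
                   zip(preds, used)},
    )


def validate_predictions(
    model: MetNet,
    rates: list[RateVector],
    mode: str = "fix_mu_min_qs",
    substrate_exchange: str = "EX_S",
    o2_exchange: str = "EX_O2",
    co2_exchange: str = "EX_CO2",
) -> tuple[pd.DataFrame, float]:
    """Compare FBA predictions with measured rates, condition by condition.

    mode "fix_mu_min_qs": growth fixed to the measured mu, |q_S| minimized;
    deviations on q_S, q_O2, q_CO2.  mode "fix_qs_max_mu": q_S fixed, mu
    maximized; deviations on mu, q_O2, q_CO2.  Returns the per-condition
    table and the overall mean absolute relative deviation (as a percent);
    infeasible conditions are reported as NaN rows, not raised.
    """
    if mode not in ("fix_mu_min_qs", "fix_qs_max_mu"):
        raise ValueError(f"unknown validation mode {mode!r}")
    rows = []
    devs = []
    for rv in rates:
        if mode == "fix_mu_min_qs":
            sol = minimize_uptake_at_growth(model, substrate_exchange, rv.mu)
            compare = [("q_S", rv.q_s), ("q_O2", rv.q_o2), ("q_CO2", rv.q_co2)]
        else:
            sol = solve_fba(model, sense="max",
                            fixed={substrate_exchange: rv.q_s})
            compare = [("mu", rv.mu), ("q_O2", rv.q_o2), ("q_CO2", rv.q_co2)]
        row = {"condition": rv.label, "status": sol.status}
        if sol.optimal:
            pred = {
                "mu": sol.fluxes[model.objective_id],
                "q_S": sol.fluxes[substrate_exchange],
                "q_O2": sol.fluxes[o2_exchange],
                "q_CO2": sol.fluxes[co2_exchange],
            }
            for name, exp in compare:
                rel = abs(pred[name] - exp) / abs(exp) if exp != 0 else (
                    0.0 if pred[name] == 0 else float("inf"))
                row[f"{name}_pred"] = pred[name]
                row[f"{name}_exp"] = exp
                row[f"{name}_reldev"] = rel
                devs.append(rel)
        rows.append(row)
    overall = 100.0 * float(np.mean(devs)) if devs else float("nan")
    return pd.DataFrame(rows), overall


def ngame_sweep(
    model: MetNet,
    condition: RateVector,
    grid,
    substrate_exchange: str = "EX_S",
    o2_exchange: str = "EX_O2",
    co2_exchange: str = "EX_CO2",
    atpm_id: str = "ATPM",
) -> pd.DataFrame:
    """Sensitivity of the low-growth prediction to the ATPM lower bound.

    For each candidate maintenance value the substrate uptake is fixed to
    the condition's q_S, growth maximized, and the mean absolute relative
    error over (mu, q_O2, q_CO2) recorded.
    """
    grid = list(grid)
    if not grid or min(grid) < 0:
        raise ValueError("grid must be non-empty and non-negative")
    rows = []
    for atpm in grid:
        work = model.copy()
        work.reactions[atpm_id].lb = float(atpm)
        sol = solve_fba(work, sense="max",
                        fixed={substrate_exchange: condition.q_s})
        row = {"atpm": atpm, "status": sol.status}
        if sol.optimal:
            row["mu"] = sol.fluxes[model.objective_id]
            row["q_O2"] = sol.fluxes[o2_exchange]
            row["q_CO2"] = sol.fluxes[co2_exchange]
            errs = [
                abs(row["mu"] - condition.mu) / abs(condition.mu),
                abs(row["q_O2"] - condition.q_o2) / abs(condition.q_o2),
                abs(row["q_CO2"] - condition.q_co2) / abs(condition.q_co2),
            ]
            row["error"] = float(np.mean(errs))
        rows.append(row)
    return pd.DataFrame(rows)
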