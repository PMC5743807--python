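"""Minimal constraint-based metabolic model with LP-based flux balance analysis.

A :class:`MetNet` is a plain stoichiometric model: metabolites with optional
elemental formulas, reactions with bounds, and one objective reaction.  FBA
solves the linear program

    max/min  v_objective
    s.t.     S v = 0,   lb <= v <= ub,   v_i = fixed_i

with scipy's HiGHS solver.  Sign convention throughout: exchange fluxes are
negative for uptake and positive for secretion; all fluxes are in
mmol gDCW^-1 h^-1 except the biomass reaction, whose flux is the specific
growth rate (h^-1) because the biomass equation consumes precursors per gram
of dry cell weight formed.

Only the optimal objective value is contractually reproducible; away from a
unique optimum individual fluxes depend on solver pivoting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .formulas import format_formula, parse_formula

INF = float("inf")

#: default LP solver tolerances handed to HiGHS
SOLVER_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

#: steady-state / bound violation tolerance asserted on optimal solutions
STEADY_STATE_TOL = 1e-6


@dataclass
class Metabolite:
    id: str
    formula: dict[str, float] = field(default_factory=dict)
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if any(n < 0 for n in self.formula.values()):
            raise ValueError(f"negative element count in formula of {self.id}")


@dataclass
class Reaction:
    """Stoichiometry as metabolite-id -> coefficient; negative = consumed."""

    id: str
    stoich: dict[str, float]
    lb: float = -1000.0
    ub: float = 1000.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")
        if not any(c != 0 for c in self.stoich.values()):
            raise ValueError(f"reaction {self.id} has empty stoichiometry")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoich) == 1


@dataclass
class MetNet:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    objective_id: str
    name: str = ""

    def __post_init__(self) -> None:
        for rxn in self.reactions.values():
            for met in rxn.stoich:
                if met not in self.metabolites:
                    raise ValueError(
                        f"reaction {rxn.id} references unknown metabolite {met}"
                    )
        if self.objective_id not in self.reactions:
            raise ValueError(f"objective reaction {self.objective_id} not in model")

    def copy(self) -> "MetNet":
        return MetNet(
            metabolites={
                k: Metabolite(m.id, dict(m.formula), m.compartment)
                for k, m in self.metabolites.items()
            },
            reactions={
                k: Reaction(r.id, dict(r.stoich), r.lb, r.ub)
                for k, r in self.reactions.items()
            },
            objective_id=self.objective_id,
            name=self.name,
        )

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S matrix (metabolites x reactions) with row/column ids."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        mi = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met, coef in self.reactions[rid].stoich.items():
                S[mi[met], j] = coef
        return S, met_ids, rxn_ids


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction_id\tflux\n")
            for rid, v in self.fluxes.items():
                fh.write(f"{rid}\t{v:.10g}\n")


_STATUS = {0: "optimal", 1: "infeasible", 2: "infeasible", 3: "unbounded", 4: "infeasible"}


def solve_fba(
    model: MetNet,
    sense: str = "max",
    fixed: dict[str, float] | None = None,
    objective_id: str | None = None,
) -> FluxSolution:
    """Solve the FBA linear program.

    Parameters
    ----------
    sense : "max" or "min" on the objective reaction flux.
    fixed : reaction-id -> flux values clamped (lb = ub = value).
    objective_id : optional override of the model's objective reaction.

    Infeasibility and unboundedness are reported through ``status`` rather
    than raised; only malformed input (unknown ids, bad sense) raises.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    obj = objective_id if objective_id is not None else model.objective_id
    if obj not in model.reactions:
        raise ValueError(f"unknown objective reaction {obj!r}")
    fixed = fixed or {}
    for rid in fixed:
        if rid not in model.reactions:
            raise ValueError(f"unknown reaction id in fixed: {rid!r}")

    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    bounds = []
    for rid in rxn_ids:
        if rid in fixed:
            v = float(fixed[rid])
            bounds.append((v, v))
        else:
            r = model.reactions[rid]
            bounds.append((r.lb if np.isfinite(r.lb) else None,
                           r.ub if np.isfinite(r.ub) else None))
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(obj)] = -1.0 if sense == "max" else 1.0

    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs", options=SOLVER_OPTIONS)
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"), fluxes={})
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxSolution(status="optimal",
                        objective_value=fluxes[obj],
                        fluxes=fluxes)


def minimize_uptake_at_growth(
    model: MetNet, substrate_exchange: str, mu: float
) -> FluxSolution:
    """Fix growth to ``mu`` and minimize the absolute substrate uptake.

    The substrate exchange must allow uptake (lb < 0 <= ub).  Because uptake
    is negative, minimizing |v| is implemented as maximizing the exchange
    flux with its upper bound clamped to zero.  The returned solution's
    ``objective_value`` is the (signed, <= 0) substrate exchange flux.
    """
    if substrate_exchange not in model.reactions:
        raise ValueError(f"unknown reaction id {substrate_exchange!r}")
    ex = model.reactions[substrate_exchange]
    if not (ex.lb < 0 <= ex.ub):
        raise ValueError(
            f"{substrate_exchange} bounds ({ex.lb}, {ex.ub}) do not allow uptake"
        )
    work = model.copy()
    work.reactions[substrate_exchange].ub = 0.0
    return solve_fba(
        work, sense="max",
        fixed={model.objective_id: mu},
        objective_id=substrate_exchange,
    )


def check_solution(model: MetNet, sol: FluxSolution, tol: float = STEADY_STATE_TOL) -> float:
    """Max |S v| over metabolites; raises if above ``tol`` or bounds violated."""
    if not sol.optimal:
        raise ValueError("can only check optimal solutions")
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    v = np.array([sol.fluxes[r] for r in rxn_ids])
    resid = float(np.max(np.abs(S @ v))) if len(met_ids) else 0.0
    if resid > tol:
        raise ValueError(f"steady-state violation {resid:g} > {tol:g}")
    for rid in rxn_ids:
        r = model.reactions[rid]
        if sol.fluxes[rid] < r.lb - tol or sol.fluxes[rid] > r.ub + tol:
            raise ValueError(f"flux bound violation on {rid}")
    return resid


# ---------------------------------------------------------------------------
# SBML import/export (delegated to cobrapy; Level 3 + FBC on write)
# ---------------------------------------------------------------------------

def to_cobra(model: MetNet):
    """Convert to a cobrapy model (used for SBML I/O and cross-checks)."""
    import cobra

    cm = cobra.Model(model.name or "model")
    mets = {}
    for m in model.metabolites.values():
        cmet = cobra.Metabolite(
            m.id, formula=format_formula(m.formula) or None,
            compartment=m.compartment or "c",
        )
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: coef for mid, coef in r.stoich.items()}
        )
    cm.objective = cm.reactions.get_by_id(model.objective_id)
    return cm


def from_cobra(cm, objective_fallback: str = "biomass") -> MetNet:
    """Convert a cobrapy model; falls back to a reaction whose id contains
    ``objective_fallback`` (case-insensitive) when no FBC objective is set."""
    mets = {
        m.id: Metabolite(m.id, parse_formula(m.formula or ""), m.compartment or "c")
        for m in cm.metabolites
    }
    rxns = {
        r.id: Reaction(
            r.id,
            {m.id: coef for m, coef in r.metabolites.items()},
            float(r.lower_bound),
            float(r.upper_bound),
        )
        for r in cm.reactions
    }
    objective_id = None
    for r in cm.reactions:
        if r.objective_coefficient:
            objective_id = r.id
            break
    if objective_id is None:
        cands = [rid for rid in rxns if objective_fallback.lower() in rid.lower()]
        if not cands:
            raise ValueError(
                "model has no objective and no reaction id matching "
                f"{objective_fallback!r}"
            )
        objective_id = sorted(cands)[0]
    return MetNet(metabolites=mets, reactions=rxns,
                  objective_id=objective_id, name=cm.id or "")


def read_sbml(path, objective_fallback: str = "biomass") -> MetNet:
    """Read an SBML model (L3/FBC preferred; cobrapy tolerates legacy
    note-encoded bounds).  Raises ValueError naming the file on parse errors."""
    from cobra.io import read_sbml_model

    try:
        cm = read_sbml_model(str(path))
    except Exception as e:
        raise ValueError(f"could not parse SBML file {path!s}: {e}") from e
    return from_cobra(cm, objective_fallback=objective_fallback)


def write_sbml(model: MetNet, path) -> None:
    """Write SBML Level 3 with FBC bounds and objective."""
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))
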