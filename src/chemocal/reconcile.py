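"""Weighted-least-squares data reconciliation under linear conservation laws.

Measured vectors x (specific rates, or biomass composition fractions) are
adjusted to satisfy E x = 0 exactly, where each row of E is a conserved
quantity (carbon, degree of reduction, nitrogen, mass closure, ...).  With
diagonal measurement covariance F = diag(sd^2) the reconciled estimate is
the WLS projection

    x_hat = x - F E' (E F E')^-1 E x

and the consistency statistic

    h = eps' (E F E')^-1 eps,      eps = E x

is chi-square distributed with rank(E) degrees of freedom when the data
contain only random errors, which gives the gross-error test: the data pass
at confidence level 1 - alpha iff h <= chi2(1 - alpha, dof).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chemostat import RateVector
from .formulas import degree_of_reduction, molar_mass, parse_formula


@dataclass
class BalanceSystem:
    """Constraint matrix E (balances x variables) with diagonal covariance."""

    E: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    sds: np.ndarray  # per-variable measurement SDs

    def __post_init__(self) -> None:
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        self.sds = np.asarray(self.sds, dtype=float)
        if self.E.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("E shape does not match labels")
        if np.any(self.sds <= 0):
            raise ValueError("all measurement SDs must be positive")
        if np.linalg.matrix_rank(self.E) < self.E.shape[0]:
            raise ValueError("constraint matrix E is row-rank deficient")

    @property
    def F(self) -> np.ndarray:
        return np.diag(self.sds**2)


@dataclass
class ReconciliationResult:
    x: np.ndarray
    x_hat: np.ndarray
    adjustments: np.ndarray
    h: float
    dof: int
    chi2_crit: float
    passed: bool
    labels: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "labels": self.labels,
            "x": self.x.tolist(),
            "x_hat": self.x_hat.tolist(),
            "adjustments": self.adjustments.tolist(),
            "h": self.h,
            "dof": self.dof,
            "chi2_crit": self.chi2_crit,
            "passed": bool(self.passed),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_balance_matrix(
    variables: list[tuple[str, str | dict]],
    balances: tuple[str, ...] = ("C", "degree_of_reduction"),
    sds: np.ndarray | list[float] | None = None,
) -> BalanceSystem:
    """Build E for species variables.

    ``variables`` is a list of (label, formula) where formula is an element
    map or string; a C-mol biomass formula (C == 1) makes the variable's
    rates per Cmmol.  Supported balances: C, N, degree_of_reduction, mass.
    Coefficients are per-unit contents; the measured rates carry the signs,
    so conservation reads E q = 0.
    """
    parsed = []
    for label, f in variables:
        if f is None:
            raise ValueError(f"variable {label!r} has no elemental formula")
        parsed.append((label, parse_formula(f) if isinstance(f, str) else dict(f)))
    rows, row_labels = [], []
    for bal in balances:
        if bal == "C":
            rows.append([f.get("C", 0.0) for _, f in parsed])
        elif bal == "N":
            rows.append([f.get("N", 0.0) for _, f in parsed])
        elif bal == "degree_of_reduction":
            rows.append([degree_of_reduction(f) for _, f in parsed])
        elif bal == "mass":
            rows.append([molar_mass(f) for _, f in parsed])
        else:
            raise ValueError(f"unknown balance {bal!r}")
        row_labels.append(bal)
    if sds is None:
        sds = np.ones(len(parsed))
    return BalanceSystem(
        E=np.array(rows), row_labels=row_labels,
        col_labels=[label for label, _ in parsed], sds=np.asarray(sds, float),
    )


def reconcile_wls(
    x: np.ndarray | list[float], system: BalanceSystem, alpha: float = 0.05,
    b: np.ndarray | list[float] | None = None,
) -> ReconciliationResult:
    """WLS projection of x onto {y : E y = b} plus the h-index test.

    ``b`` defaults to zero (homogeneous conservation laws); an affine
    right-hand side supports closure constraints such as mass fractions
    summing to 100.
    """
    x = np.asarray(x, dtype=float)
    E, F = system.E, system.F
    if x.shape[0] != E.shape[1]:
        raise ValueError("dimension mismatch between x and E")
    M = E @ F @ E.T
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "E F E' is (near-)singular; the requested balances are redundant"
        )
    eps = E @ x
    if b is not None:
        eps = eps - np.asarray(b, dtype=float)
    lam = np.linalg.solve(M, eps)
    x_hat = x - F @ E.T @ lam
    h = float(eps @ lam)
    dof = int(np.linalg.matrix_rank(E))
    crit = float(stats.chi2.ppf(1 - alpha, dof))
    return ReconciliationResult(
        x=x, x_hat=x_hat, adjustments=x_hat - x, h=h, dof=dof,
        chi2_crit=crit, passed=h <= crit, labels=list(system.col_labels),
    )


def consistency_test(result: ReconciliationResult, alpha: float = 0.05) -> bool:
    """Gross-error test: pass iff h <= chi2(1 - alpha, dof)."""
    if result.dof < 1:
        raise ValueError("consistency test needs at least one balance")
    return result.h <= stats.chi2.ppf(1 - alpha, result.dof)


def compare_profiles(a: dict, b: dict, equal_var: bool = True) -> dict[str, float]:
    """Two-tailed two-sample t-test per shared component.

    ``a`` and ``b`` map component -> replicate values (>= 2 each).  Zero
    variance in both groups with equal means gives p = 1.
    """
    out = {}
    for comp in a:
        if comp not in b:
            continue
        xa, xb = np.asarray(a[comp], float), np.asarray(b[comp], float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"component {comp!r} needs >= 2 replicates per group")
        if xa.std() == 0 and xb.std() == 0:
            out[comp] = 1.0 if xa.mean() == xb.mean() else 0.0
            continue
        out[comp] = float(stats.ttest_ind(xa, xb, equal_var=equal_var).pvalue)
    return out


def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = True,
) -> float:
    """Two-tailed two-sample t-test p-value from summary statistics."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=equal_var)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Rate-vector reconciliation (carbon + electron balances)
# ---------------------------------------------------------------------------

def rate_balance_system(
    substrate_formula: str | dict,
    biomass_cmol_formula: str | dict,
    sds: np.ndarray | list[float],
    balances: tuple[str, ...] = ("C", "degree_of_reduction"),
    include_mu: bool = True,
    biomass_c_content: float | None = None,
) -> BalanceSystem:
    """Balance system over (mu,) q_S, q_O2, q_CO2, q_X.

    With ``include_mu`` the measured growth rate joins the system through
    the definitional constraint q_X = mu * C_content (one extra row), which
    lets the reconciliation adjust mu as well.
    """
    species = [
        ("q_S", substrate_formula),
        ("q_O2", "O2"),
        ("q_CO2", "CO2"),
        ("q_X", biomass_cmol_formula),
    ]
    base = build_balance_matrix(species, balances=balances)
    E = base.E
    labels = list(base.row_labels)
    cols = list(base.col_labels)
    if include_mu:
        if biomass_c_content is None:
            raise ValueError("include_mu requires biomass_c_content")
        E = np.hstack([np.zeros((E.shape[0], 1)), E])
        link = np.zeros((1, E.shape[1]))
        link[0, 0] = biomass_c_content  # mu column
        link[0, -1] = -1.0  # q_X column
        E = np.vstack([E, link])
        labels.append("biomass_C_content")
        cols = ["mu"] + cols
    return BalanceSystem(E=E, row_labels=labels, col_labels=cols,
                         sds=np.asarray(sds, float))


def reconcile_rates(
    rv: RateVector,
    substrate_formula: str | dict,
    biomass_cmol_formula: str | dict,
    biomass_c_content: float | None = None,
    balances: tuple[str, ...] = ("C", "degree_of_reduction"),
    alpha: float = 0.05,
) -> tuple[RateVector, ReconciliationResult]:
    """Reconcile one steady state's rate vector against elemental balances.

    When ``biomass_c_content`` is given, mu is included as a fifth measured
    variable tied to q_X; otherwise only the four exchange rates enter.
    """
    include_mu = biomass_c_content is not None
    fields = ("mu", "q_s", "q_o2", "q_co2", "q_x") if include_mu else (
        "q_s", "q_o2", "q_co2", "q_x")
    sds = [rv.sd(f) for f in fields]
    if any(s <= 0 for s in sds):
        raise ValueError("reconciliation requires positive SDs for all rates")
    system = rate_balance_system(
        substrate_formula, biomass_cmol_formula, sds, balances=balances,
        include_mu=include_mu, biomass_c_content=biomass_c_content,
    )
    x = np.array([getattr(rv, f) for f in fields])
    res = reconcile_wls(x, system, alpha=alpha)
    vals = dict(zip(fields, res.x_hat))
    if not include_mu:
        vals["mu"] = rv.mu
    new = RateVector(
        mu=vals["mu"], q_s=min(vals["q_s"], 0.0), q_o2=min(vals["q_o2"], 0.0),
        q_co2=max(vals["q_co2"], 0.0), q_x=max(vals["q_x"], 0.0),
        sds=dict(rv.sds), substrate=rv.substrate, label=rv.label,
    )
    return new, res
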