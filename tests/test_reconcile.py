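"""WLS reconciliation, the h-index gross-error test and profile comparison."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from chemocal import (
    BalanceSystem,
    build_balance_matrix,
    compare_profiles,
    consistency_test,
    reconcile_rates,
    reconcile_wls,
    ttest_from_summary,
)
from chemocal import datasets
from chemocal.chemostat import SUBSTRATE_FORMULA
from chemocal.formulas import degree_of_reduction


def test_degrees_of_reduction():
    assert degree_of_reduction("C3H8O3") == pytest.approx(14.0)  # glycerol
    assert degree_of_reduction("CH4O") == pytest.approx(6.0)  # methanol
    assert degree_of_reduction("O2") == pytest.approx(-4.0)
    assert degree_of_reduction("CO2") == pytest.approx(0.0)
    assert degree_of_reduction("H3N") == pytest.approx(0.0)  # ammonia N source


def test_biomass_gamma_from_average_composition(glycerol_biomass):
    # 4 + 1.771 - 2*0.628 - 3*0.175 (+ 6*0.0027) per C-mol
    assert glycerol_biomass.gamma == pytest.approx(4.0, abs=0.02)


def test_consistent_vector_unchanged():
    system = build_balance_matrix(
        [("q_S", "C3H8O3"), ("q_CO2", "CO2"), ("q_X", {"C": 1})],
        balances=("C",), sds=[0.05, 0.11, 0.04],
    )
    x = np.array([-1.0, 1.5, 1.5])  # 3*1 = 1.5 + 1.5 exactly
    res = reconcile_wls(x, system)
    assert res.x_hat == pytest.approx(x)
    assert res.h == pytest.approx(0.0, abs=1e-24)
    assert res.passed


def test_single_balance_closed_form_adjustment():
    """One C balance: adjustment = F a' (a F a')^-1 eps, frozen by hand."""
    system = build_balance_matrix(
        [("q_S", "C3H8O3"), ("q_CO2", "CO2"), ("q_X", {"C": 1})],
        balances=("C",), sds=[0.05, 0.11, 0.04],
    )
    x = np.array([-0.60, 0.55, 1.22])
    res = reconcile_wls(x, system)
    # hand evaluation: eps = -0.03, aFa' = 0.0362, lambda = -0.82873
    assert res.x_hat == pytest.approx([-0.593785, 0.560028, 1.221326],
                                      abs=1e-6)
    assert 3 * res.x_hat[0] + res.x_hat[1] + res.x_hat[2] == pytest.approx(
        0.0, abs=1e-10)
    assert res.h == pytest.approx(0.03**2 / 0.0362, rel=1e-6)


def test_projection_idempotent_and_optimal():
    """Reconciling twice changes nothing; the projection minimizes the
    Mahalanobis distance (checked against a numeric constrained minimizer)."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        E = rng.normal(size=(2, 4))
        sds = rng.uniform(0.05, 0.5, size=4)
        system = BalanceSystem(E=E, row_labels=["b1", "b2"],
                               col_labels=list("abcd"), sds=sds)
        x = rng.normal(size=4)
        res = reconcile_wls(x, system)
        assert np.abs(E @ res.x_hat).max() < 1e-8
        again = reconcile_wls(res.x_hat, system)
        assert again.x_hat == pytest.approx(res.x_hat, abs=1e-10)
        assert again.h == pytest.approx(0.0, abs=1e-16)

        Finv = np.diag(1.0 / sds**2)
        brute = minimize(
            lambda y: (y - x) @ Finv @ (y - x), x0=x, method="SLSQP",
            constraints={"type": "eq", "fun": lambda y: E @ y},
            options={"ftol": 1e-14, "maxiter": 500},
        )
        assert res.x_hat == pytest.approx(brute.x, abs=1e-5)


def test_h_invariant_to_row_scaling():
    rng = np.random.default_rng(3)
    E = rng.normal(size=(2, 4))
    sds = rng.uniform(0.1, 0.3, size=4)
    x = rng.normal(size=4)
    base = reconcile_wls(x, BalanceSystem(E, ["a", "b"], list("wxyz"), sds))
    scaled = reconcile_wls(
        x, BalanceSystem(np.diag([3.0, 0.1]) @ E, ["a", "b"], list("wxyz"), sds))
    assert scaled.h == pytest.approx(base.h, rel=1e-10)
    assert scaled.x_hat == pytest.approx(base.x_hat, rel=1e-9)


def test_gross_error_detected_two_sided(toy_spec):
    """A 5-SD bias on one rate pushes h past chi2_0.95(dof), either sign."""
    bio = toy_spec.biomass_cmol()
    rv = toy_spec.rates_at(0.1)
    sds = {f: 0.02 * abs(getattr(rv, f)) for f in rv.FIELDS}
    for sign in (+1, -1):
        biased = type(rv)(
            mu=rv.mu, q_s=rv.q_s, q_o2=rv.q_o2,
            q_co2=rv.q_co2 + sign * 5 * sds["q_co2"], q_x=rv.q_x,
            sds=sds, substrate="toy",
        )
        _, res = reconcile_rates(biased, "C3H8O3", bio.formula,
                                 biomass_c_content=bio.c_content)
        assert res.h > stats.chi2.ppf(0.95, res.dof)
        assert not res.passed
        assert not consistency_test(res)


@pytest.mark.parametrize("substrate", ["glycerol", "methanol"])
def test_published_rows_pass_h_test(substrate):
    """No evidence of gross errors in the published reconciled rates."""
    bio = datasets.biomass_constants(substrate)
    for rv in datasets.load_rates(substrate):
        _, res = reconcile_rates(rv, SUBSTRATE_FORMULA[substrate], bio.formula,
                                 biomass_c_content=bio.c_content)
        assert res.passed, f"{substrate} {rv.label}: h={res.h:.2f}"


def test_redundant_balances_rejected():
    with pytest.raises(ValueError, match="rank"):
        BalanceSystem(E=np.array([[1.0, 1.0], [2.0, 2.0]]),
                      row_labels=["a", "b"], col_labels=["x", "y"],
                      sds=np.array([0.1, 0.1]))


def test_variable_without_formula_named():
    with pytest.raises(ValueError, match="q_mystery"):
        build_balance_matrix([("q_mystery", None)], balances=("C",))


def test_compare_profiles():
    a = {"ala": [1.0, 1.0, 1.0], "gly": [0.1, 0.2, 0.15]}
    b = {"ala": [1.0, 1.0, 1.0], "gly": [10.1, 10.0, 10.2]}
    p = compare_profiles(a, b)
    assert p["ala"] == pytest.approx(1.0)
    assert p["gly"] < 0.001
    rng = np.random.default_rng(11)
    p2 = compare_profiles({"c": rng.normal(0, 1, 5)},
                          {"c": rng.normal(10, 1, 5)})
    assert p2["c"] < 0.001


def test_protein_fraction_differs_between_carbon_sources():
    """Methanol-grown cells have a significantly higher protein fraction."""
    p = ttest_from_summary(41.0, 1.5, 4, 50.1, 0.8, 3)
    assert p < 0.05
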