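"""Pirt regression, NGAME/GAME estimation and FBA validation."""

import numpy as np
import pytest

from chemocal import (
    NoiseSpec,
    RateVector,
    ToyModelSpec,
    calibrate_game,
    estimate_ngame,
    fit_pirt,
    frame_to_rates,
    make_toy_model,
    ngame_sweep,
    recover_toy_parameters,
    simulate_chemostat_series,
    solve_fba,
    toy_equation_template,
    validate_predictions,
)


def _line_rates(slope=10.0, intercept=0.5, mus=(0.03, 0.06, 0.1, 0.15)):
    return [
        RateVector(mu=mu, q_s=-(slope * mu + intercept), q_o2=-1.0,
                   q_co2=1.0, q_x=1.0, label=f"D={mu:g}")
        for mu in mus
    ]


def test_pirt_exact_line_and_closed_form():
    fit = fit_pirt(_line_rates())
    assert fit.slope == pytest.approx(10.0, rel=1e-12)
    assert fit.intercept == pytest.approx(0.5, rel=1e-12)
    assert fit.r2 == pytest.approx(1.0)
    # equals the closed-form OLS solution to machine precision
    mus = np.array([0.03, 0.06, 0.1, 0.15])
    qs = 10.0 * mus + 0.5
    beta = np.polyfit(mus, qs, 1)
    assert fit.slope == pytest.approx(beta[0], abs=1e-12)
    assert fit.intercept == pytest.approx(beta[1], abs=1e-12)


def test_pirt_needs_three_points():
    with pytest.raises(ValueError, match="3"):
        fit_pirt(_line_rates(mus=(0.05, 0.1)))


def test_pirt_exclusion_by_label():
    rates = _line_rates()
    rates[0] = RateVector(mu=0.03, q_s=-5.0, q_o2=-1.0, q_co2=1.0, q_x=1.0,
                          label="D=0.03")  # off-trend low-growth point
    fit = fit_pirt(rates, exclude=("D=0.03",))
    assert fit.intercept == pytest.approx(0.5, rel=1e-9)
    assert fit.excluded == ["D=0.03"] and fit.n == 3


def test_pirt_intercepts_from_published_series(glycerol_rates, methanol_rates):
    """OLS on the printed pairs: m_s ~0.085 (methanol) and, excluding the
    shifted D=0.035 condition, ~0.126 (glycerol)."""
    meoh = fit_pirt(methanol_rates)
    assert meoh.intercept == pytest.approx(0.085, abs=0.003)
    gly = fit_pirt(glycerol_rates, exclude=("D=0.035",))
    assert gly.intercept == pytest.approx(0.126, abs=0.003)
    # including the shifted condition drags the intercept far off
    gly_all = fit_pirt(glycerol_rates)
    assert abs(gly_all.intercept - 0.126) > 0.02


def test_estimate_ngame_equals_k_times_ms(toy_model, toy_spec):
    """All maintenance substrate is catabolized: NGAME = k m_s exactly."""
    for m_s in (0.05, 0.139, 0.4):
        ngame = estimate_ngame(toy_model, "EX_S", m_s)
        assert ngame == pytest.approx(toy_spec.k * m_s, rel=1e-6)
    assert estimate_ngame(toy_model, "EX_S", 0.139) == pytest.approx(2.5,
                                                                     abs=0.01)


def test_estimate_ngame_is_pure_query(toy_model):
    before = toy_model.reactions["ATPM"].lb
    estimate_ngame(toy_model, "EX_S", 0.139)
    assert toy_model.reactions["ATPM"].lb == before


def test_calibrate_game_recovers_noiseless_truth():
    spec = ToyModelSpec(g_true=100.0)
    df = simulate_chemostat_series(spec, noise=NoiseSpec(cv=0.0, seed=0))
    rates = frame_to_rates(df)
    params = calibrate_game(
        make_toy_model(spec), toy_equation_template(spec), rates,
        ngame=spec.m_true, id_map={"atp": "ATP"}, biomass_metabolite="X",
    )
    assert params.game == pytest.approx(100.0, abs=0.1)
    assert max(abs(r) for r in params.residuals.values()) < 1e-3


def test_validation_zero_deviation_on_self_consistent_data(toy_model):
    df = simulate_chemostat_series(noise=NoiseSpec(cv=0.0, seed=0))
    rates = frame_to_rates(df)
    for mode in ("fix_mu_min_qs", "fix_qs_max_mu"):
        table, overall = validate_predictions(toy_model, rates, mode=mode)
        assert overall == pytest.approx(0.0, abs=1e-8)
        assert (table["status"] == "optimal").all()


def test_validation_bounded_by_noise(toy_model):
    """With CV 2% over 6 conditions the mean deviation stays below 4%."""
    df = simulate_chemostat_series(noise=NoiseSpec(cv=0.02, seed=1))
    _, overall = validate_predictions(toy_model, frame_to_rates(df),
                                      mode="fix_qs_max_mu")
    assert overall < 4.0


def test_validation_reports_infeasible_rows(toy_model):
    rates = [RateVector(mu=100.0, q_s=-1.0, q_o2=-1.0, q_co2=1.0, q_x=1.0,
                        label="impossible")]
    table, _ = validate_predictions(toy_model, rates, mode="fix_mu_min_qs")
    assert table.loc[0, "status"] == "infeasible"


def test_mu_monotone_in_ngame_and_game(toy_model, toy_spec):
    """Predicted mu at fixed q_S never increases when either maintenance
    parameter grows."""
    prev = None
    for atpm in np.linspace(0.0, 4.0, 9):
        work = toy_model.copy()
        work.reactions["ATPM"].lb = atpm
        mu = solve_fba(work, fixed={"EX_S": -2.0}).objective_value
        if prev is not None:
            assert mu <= prev + 1e-10
        prev = mu
    prev = None
    for g in np.linspace(40.0, 200.0, 9):
        mu = toy_spec.mu_at_uptake(2.0, g=g)
        if prev is not None:
            assert mu < prev
        prev = mu


def test_ngame_sweep_unimodal_with_minimum_at_truth(toy_model, toy_spec):
    cond = toy_spec.rates_at(0.035)
    sweep = ngame_sweep(toy_model, cond, np.arange(0.0, 5.01, 0.25))
    errs = sweep["error"].to_numpy()
    best = sweep.loc[sweep["error"].idxmin(), "atpm"]
    assert best == pytest.approx(toy_spec.m_true)
    k = int(np.argmin(errs))
    assert np.all(np.diff(errs[: k + 1]) <= 1e-12)
    assert np.all(np.diff(errs[k:]) >= -1e-12)


def test_recovery_pipeline_exact_at_zero_noise():
    df = simulate_chemostat_series(noise=NoiseSpec(cv=0.0, seed=4))
    rep = recover_toy_parameters(df)
    assert rep.params.ngame == pytest.approx(2.5, rel=1e-6)
    assert rep.params.game == pytest.approx(70.0, abs=0.05)
    assert rep.all_consistent
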