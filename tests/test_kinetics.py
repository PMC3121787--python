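"""Unit and property tests for the incorporation-kinetics module."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import isoturn as it
from isoturn.kinetics import (FixedEffectsDesign, RandomEffectsSpec,
                              fit_individual, fit_population)

from conftest import PHI3_9D

LN2 = math.log(2.0)

finite_delta = st.floats(min_value=-40.0, max_value=40.0,
                         allow_nan=False, allow_infinity=False)
log_rate = st.floats(min_value=-6.0, max_value=2.0,
                     allow_nan=False, allow_infinity=False)


# ---------------------------------------------------------------------------
# Forward model and half-lives
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("params, t, expected", [
    ((16.0, 8.0, -1.0), 0.0, 8.0),          # initial value at the shift
    ((16.0, 8.0, PHI3_9D), 9.0, 12.0),      # midpoint after one half-life
    ((16.0, 8.0, PHI3_9D), 18.0, 14.0),     # 1/4 of the gap after two
    ((5.0, 5.0, -0.3), 37.0, 5.0),          # flat degenerate trajectory
])
def test_one_compartment_prediction(params, t, expected):
    p = it.OneCompartmentParams(*params)
    assert it.predict_one_compartment(p, t) == pytest.approx(expected, abs=1e-9)


def test_one_compartment_rejects_bad_inputs():
    with pytest.raises(ValueError):
        it.OneCompartmentParams(math.nan, 8.0, -1.0)
    p = it.OneCompartmentParams(16.0, 8.0, -1.0)
    with pytest.raises(ValueError):
        it.predict_one_compartment(p, -1.0)


@pytest.mark.parametrize("phi3, expected", [
    (0.0, LN2),
    (math.log(LN2), 1.0),
    (PHI3_9D, 9.0),
])
def test_half_life_closed_form(phi3, expected):
    assert it.half_life_one_compartment(phi3) == pytest.approx(expected, rel=1e-9)


@given(phi3_a=log_rate, phi3_b=log_rate)
@settings(deadline=None)
def test_half_life_strictly_decreasing_in_phi3(phi3_a, phi3_b):
    if phi3_b - phi3_a > 1e-12:  # below float resolution of exp
        assert (it.half_life_one_compartment(phi3_a)
                > it.half_life_one_compartment(phi3_b))


@given(phi1=finite_delta, phi2=finite_delta, phi3=log_rate)
@settings(deadline=None)
def test_midpoint_identity(phi1, phi2, phi3):
    """The curve passes exactly through the gap midpoint at the half-life."""
    p = it.OneCompartmentParams(phi1, phi2, phi3)
    t_half = it.half_life_one_compartment(phi3)
    assert it.predict_one_compartment(p, t_half) == pytest.approx(
        0.5 * (phi1 + phi2), abs=1e-9)


def test_two_compartment_values():
    # Single active pool reduces to one-compartment.
    p = it.TwoCompartmentParams(16.0, 8.0, 1.0, math.exp(PHI3_9D), 0.01)
    assert it.predict_two_compartment(p, 9.0) == pytest.approx(12.0, abs=1e-6)
    assert it.predict_two_compartment(p, 0.0) == pytest.approx(8.0)
    # Direct evaluation of the two-pool mixture.
    q = it.TwoCompartmentParams(16.0, 8.0, 0.5, 0.2, 0.05)
    expected = 16.0 - 8.0 * (0.5 * math.exp(-2.0) + 0.5 * math.exp(-0.5))
    assert it.predict_two_compartment(q, 10.0) == pytest.approx(expected, rel=1e-12)


def test_two_compartment_invariants_enforced():
    with pytest.raises(ValueError):
        it.TwoCompartmentParams(16.0, 8.0, 1.5, 0.2, 0.05)
    with pytest.raises(ValueError):
        it.TwoCompartmentParams(16.0, 8.0, 0.5, -0.2, 0.05)
    with pytest.raises(ValueError):
        it.TwoCompartmentParams(16.0, 8.0, 0.5, 0.05, 0.2)  # k1 < k2


@given(phi1=finite_delta, phi2=finite_delta, phi3=log_rate,
       t=st.floats(min_value=0.0, max_value=200.0))
@settings(deadline=None)
def test_two_to_one_compartment_nesting(phi1, phi2, phi3, t):
    """With p = 1 the two-pool model equals the one-pool model everywhere."""
    one = it.OneCompartmentParams(phi1, phi2, phi3)
    two = it.TwoCompartmentParams(phi1, phi2, 1.0, math.exp(phi3), math.exp(phi3) / 2)
    assert abs(it.predict_two_compartment(two, t)
               - it.predict_one_compartment(one, t)) < 1e-12


def test_two_compartment_half_life_single_pool_limits():
    a = it.TwoCompartmentParams(16.0, 8.0, 1.0, LN2 / 9.0, LN2 / 40.0)
    assert it.half_life_two_compartment(a) == pytest.approx(9.0, rel=1e-9)
    b = it.TwoCompartmentParams(16.0, 8.0, 0.0, LN2 / 9.0, LN2 / 40.0)
    assert it.half_life_two_compartment(b) == pytest.approx(40.0, rel=1e-9)


def test_two_compartment_half_life_matches_bisection_oracle():
    p, k1, k2 = 0.5, 0.2, 0.05
    # Independent oracle: plain bisection on a sign change.
    lo, hi = 0.0, 500.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if p * math.exp(-k1 * mid) + (1 - p) * math.exp(-k2 * mid) > 0.5:
            lo = mid
        else:
            hi = mid
    oracle = 0.5 * (lo + hi)
    params = it.TwoCompartmentParams(16.0, 8.0, p, k1, k2)
    assert it.half_life_two_compartment(params) == pytest.approx(oracle, abs=1e-8)


def test_two_compartment_half_life_degenerate():
    with pytest.raises(ValueError, match="undefined"):
        it.half_life_two_compartment(
            it.TwoCompartmentParams(8.0, 8.0, 0.5, 0.2, 0.05))


# ---------------------------------------------------------------------------
# Isotopic clock
# ---------------------------------------------------------------------------

def test_clock_basics(canonical_params):
    assert it.time_since_diet_shift(8.0, canonical_params) == 0.0
    assert it.time_since_diet_shift(12.0, canonical_params) == pytest.approx(9.0)
    with pytest.raises(ValueError, match="outside"):
        it.time_since_diet_shift(7.0, canonical_params)
    with pytest.raises(ValueError, match="infinite"):
        it.time_since_diet_shift(16.0, canonical_params)


@given(phi1=finite_delta, phi2=finite_delta, phi3=log_rate,
       t=st.floats(min_value=0.0, max_value=200.0))
@settings(deadline=None)
def test_clock_round_trip(phi1, phi2, phi3, t):
    """Inverting the curve recovers the elapsed time exactly.

    Guarded away from the asymptote (tiny remaining gap fraction) and
    from near-flat trajectories, where the inversion is catastrophically
    ill-conditioned in floating point.
    """
    if abs(phi1 - phi2) < 0.5:
        return
    p = it.OneCompartmentParams(phi1, phi2, phi3)
    delta = it.predict_one_compartment(p, t)
    frac = (delta - phi1) / (phi2 - phi1)
    if frac < 1e-2:  # numerically at the asymptote: clock saturates
        return
    assert it.time_since_diet_shift(delta, p) == pytest.approx(t, abs=1e-9)


# ---------------------------------------------------------------------------
# Individual fitting
# ---------------------------------------------------------------------------

def test_fit_individual_exact_recovery(canonical_params, schedule):
    y = it.predict_one_compartment(canonical_params, schedule)
    fit = fit_individual(schedule, y)
    assert fit.converged
    for name, truth in zip(("phi1", "phi2", "phi3"),
                           (16.0, 8.0, canonical_params.phi3)):
        assert fit.estimates[name] == pytest.approx(truth, abs=1e-6)
    assert fit.half_life_days == pytest.approx(9.0, abs=1e-4)


def test_fit_individual_flat_data_flagged(schedule):
    fit = fit_individual(schedule, np.full(len(schedule), 5.0))
    assert fit.estimates["phi1"] == pytest.approx(5.0)
    assert fit.estimates["phi2"] == pytest.approx(5.0)
    assert not fit.rate_identifiable
    assert fit.half_life_days is None


def test_fit_individual_too_few_points():
    with pytest.raises(ValueError, match=">= 4"):
        fit_individual([0, 5, 10], [8.0, 10.0, 12.0])
    with pytest.raises(ValueError, match=">= 6"):
        fit_individual([0, 5, 10, 20, 40], [8, 10, 12, 14, 15],
                       model_kind="two_compartment")


def test_two_compartment_overparametrization_diagnosis(canonical_params, schedule):
    """A two-pool fit to single-pool data fails or hits the boundary."""
    y = it.predict_one_compartment(canonical_params, schedule)
    fit = fit_individual(schedule, y, model_kind="two_compartment")
    assert (not fit.converged) or fit.boundary or (
        fit.estimates["p"] < 0.01 or fit.estimates["p"] > 0.99)


def test_fit_individual_matches_grid_search_oracle():
    """Profiled NLS agrees with a brute-force grid search on 6 points."""
    t = np.array([0.0, 5.0, 10.0, 20.0, 40.0, 80.0])
    truth = it.OneCompartmentParams(14.0, 6.0, math.log(LN2 / 12.0))
    y = it.predict_one_compartment(truth, t)
    # Independent oracle: dense grid over all three parameters.
    phi1_grid = np.linspace(13.0, 15.0, 81)
    phi2_grid = np.linspace(5.0, 7.0, 81)
    phi3_grid = np.linspace(-4.0, -1.0, 241)
    best = (None, np.inf)
    for phi3 in phi3_grid:
        e = np.exp(-math.exp(phi3) * t)
        for phi1 in phi1_grid:
            pred_base = phi1 * (1 - e)
            sse = ((pred_base[None, :] + np.outer(phi2_grid, e) - y) ** 2).sum(axis=1)
            j = int(np.argmin(sse))
            if sse[j] < best[1]:
                best = ((phi1, phi2_grid[j], phi3), sse[j])
    fit = fit_individual(t, y)
    (g1, g2, g3), _ = best
    assert fit.estimates["phi1"] == pytest.approx(g1, abs=0.025)
    assert fit.estimates["phi2"] == pytest.approx(g2, abs=0.025)
    assert fit.estimates["phi3"] == pytest.approx(g3, abs=0.0125)


def test_aic_recomputable_from_stored_fields(shifted_dataset, schedule,
                                             canonical_params):
    rng = np.random.default_rng(1)
    y = it.predict_one_compartment(canonical_params, schedule)
    ind = fit_individual(schedule, y + rng.normal(0, 0.2, len(schedule)))
    pop = fit_population(shifted_dataset)
    for fit in (ind, pop):
        assert fit.aic == pytest.approx(-2.0 * fit.loglik + 2.0 * fit.n_params,
                                        rel=1e-12)


# ---------------------------------------------------------------------------
# Population fitting
# ---------------------------------------------------------------------------

def test_fit_population_requires_two_individuals(schedule, canonical_params):
    y = it.predict_one_compartment(canonical_params, schedule)
    data = pd.DataFrame({"individual_id": "only_one", "day": schedule,
                         "delta_permil": y})
    with pytest.raises(ValueError, match="2 individuals"):
        fit_population(data)


def test_fit_population_recovers_truth(shifted_dataset, plasma_truth):
    fit = fit_population(shifted_dataset)
    assert fit.converged
    assert fit.half_life_days == pytest.approx(9.0, rel=0.15)
    assert fit.estimates["phi1"] == pytest.approx(plasma_truth.params.phi1, abs=0.3)
    assert fit.estimates["phi2"] == pytest.approx(plasma_truth.params.phi2, abs=0.3)
    # Random-effect variance of the log-rate near the generating 0.25^2.
    assert 0.1 ** 2 < fit.re_variance["phi3"] < 0.45 ** 2


def test_fit_population_mismatched_covariate_errors(shifted_dataset):
    data = shifted_dataset.drop(columns=["sex"])
    with pytest.raises(ValueError, match="sex"):
        fit_population(data, fixed=FixedEffectsDesign(("sex",)))


def test_fit_population_sex_effect_recovered():
    shift = it.phi3_for_half_life(46.0) - it.phi3_for_half_life(36.0)
    truth = it.default_trajectory_truth(
        "blood_cells", "d15N", half_life_days=36.0,
        phi3_shift_by_sex={"F": shift})
    data = it.simulate_trajectories(it.PopulationSpec(20, 20), truth, seed=7)
    fit = fit_population(data, fixed=FixedEffectsDesign(("sex",)))
    assert fit.converged
    diff = fit.group_half_lives["F"] - fit.group_half_lives["M"]
    assert diff == pytest.approx(10.0, abs=6.0)


def test_two_stage_and_marginal_agree_on_clean_data(plasma_truth):
    """The two estimators agree closely when heterogeneity is mild."""
    truth = it.TrajectoryTruth(
        params=plasma_truth.params,
        random_effects=RandomEffectsSpec(("phi3",), {"phi3": 0.05}),
        error_sd=0.05)
    data = it.simulate_trajectories(it.PopulationSpec(20, 20), truth, seed=3)
    f_marg = fit_population(data, method="marginal")
    f_two = fit_population(data, method="two_stage")
    assert f_marg.half_life_days == pytest.approx(f_two.half_life_days, rel=0.05)


def test_laplace_estimator_close_to_quadrature(plasma_truth):
    data = it.simulate_trajectories(it.PopulationSpec(10, 10), plasma_truth, seed=11)
    f_marg = fit_population(data, method="marginal")
    f_lap = fit_population(data, method="laplace")
    assert f_lap.half_life_days == pytest.approx(f_marg.half_life_days, rel=0.05)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def _dummy_fit(aic, n_params, n_fixed=0, n_re=1, converged=True):
    return it.TurnoverFit(
        model_kind="one_compartment", estimates={}, standard_errors={}, ci={},
        half_life_days=1.0, half_life_ci=None, aic=aic,
        loglik=-(aic - 2 * n_params) / 2, n_params=n_params, converged=converged,
        re_variance={}, n_individuals=2, n_observations=10,
        n_fixed_effects=n_fixed, n_random_effects=n_re)


def test_select_model_prefers_simplest_within_two_aic():
    complex_fit = _dummy_fit(100.0, n_params=6, n_fixed=2)
    simple_fit = _dummy_fit(101.5, n_params=4, n_fixed=0)
    assert it.select_model([complex_fit, simple_fit]) is simple_fit


def test_select_model_clear_winner_and_edge_cases():
    best = _dummy_fit(100.0, n_params=6, n_fixed=2)
    worse = _dummy_fit(105.0, n_params=4)
    assert it.select_model([best, worse]) is best
    only = _dummy_fit(50.0, n_params=4)
    assert it.select_model([only]) is only
    assert it.select_model([only, _dummy_fit(40.0, 4, converged=False)]) is only
    with pytest.raises(ValueError):
        it.select_model([_dummy_fit(40.0, 4, converged=False)])


def test_one_compartment_preferred_on_one_compartment_data(schedule,
                                                           canonical_params):
    """Selection consistency: the generating model wins (or the richer
    model fails) in at least 90% of noisy replicates."""
    rng = np.random.default_rng(2024)
    y0 = it.predict_one_compartment(canonical_params, schedule)
    wins = 0
    n_rep = 40
    for _ in range(n_rep):
        y = y0 + rng.normal(0, 0.2, len(schedule))
        f1 = fit_individual(schedule, y)
        f2 = fit_individual(schedule, y, model_kind="two_compartment")
        if not f2.converged:
            wins += 1
            continue
        if it.select_model([f1, f2]).model_kind == "one_compartment":
            wins += 1
    assert wins >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

def test_half_life_ci_is_monotone_image_of_phi3_ci():
    lo, hi = -2.9, -2.2
    expect = (LN2 / math.exp(-2.2), LN2 / math.exp(-2.9))
    from isoturn.kinetics import _half_life_ci_from_phi3
    got = _half_life_ci_from_phi3((lo, hi))
    assert got == pytest.approx(expect, rel=1e-12)
    assert got[0] < got[1]
    # ln2 * e^2.2 = 6.2557, ln2 * e^2.9 = 12.5974 (closed form)
    assert got == pytest.approx((6.2557, 12.5974), abs=0.001)


def test_bootstrap_requires_seed(shifted_dataset):
    fit = fit_population(shifted_dataset)
    with pytest.raises(ValueError, match="seed"):
        it.confidence_intervals(fit, method="parametric_bootstrap", n_boot=5)


def test_bootstrap_interval_shrinks_with_noise(schedule, canonical_params):
    y = it.predict_one_compartment(canonical_params, schedule)
    fit = fit_individual(schedule, y)
    ci = it.confidence_intervals(fit, method="parametric_bootstrap",
                                 n_boot=30, seed=5)
    lo, hi = ci["half_life_days"]
    assert hi - lo < 1e-3  # zero residual noise -> vanishing interval
    assert lo <= fit.half_life_days <= hi


def test_wald_interval_contains_point_estimate(shifted_dataset):
    fit = fit_population(shifted_dataset)
    ci = it.confidence_intervals(fit, method="wald")
    for name, (lo, hi) in ci.items():
        if name == "half_life_days":
            assert lo <= fit.half_life_days <= hi
        else:
            assert lo <= fit.estimates[name] <= hi


def test_residual_normality_diagnostic(schedule, canonical_params):
    """Gaussian residuals pass the normality check; a gross outlier
    drags the p-value down.  Diagnostic only - never gates a fit."""
    rng = np.random.default_rng(4)
    y = it.predict_one_compartment(canonical_params, schedule)
    fit = fit_individual(schedule, y + rng.normal(0, 0.2, len(schedule)))
    stat, pval = it.residual_normality(fit)
    assert 0.0 <= stat <= 1.0
    assert pval > 0.05
    y_bad = y.copy()
    y_bad[5] += 5.0
    fit_bad = fit_individual(schedule, y_bad)
    _, pval_bad = it.residual_normality(fit_bad)
    assert pval_bad < pval
    assert fit_bad.converged  # the diagnostic does not gate the fit


# ---------------------------------------------------------------------------
# Equilibrium check
# ---------------------------------------------------------------------------

def test_equilibrium_flat_control_selects_constant():
    ctl = it.simulate_control_group(it.PopulationSpec(40, 20), 7.0, 0.2, seed=8)
    report = it.check_equilibrium(ctl)
    assert report.constant_selected
    assert abs(report.mean_delta - 7.0) < 0.1
    assert all(abs(s) < 0.05 for s in report.individual_slopes.values())


def test_equilibrium_trend_selects_kinetic(shifted_dataset):
    report = it.check_equilibrium(shifted_dataset)
    assert not report.constant_selected
    assert report.delta_aic < -2.0


def test_equilibrium_single_flat_individual_analytic_aic(schedule):
    """Zero-noise constant data: both models interpolate, so the AIC
    difference is exactly twice the parameter-count difference."""
    report = it.check_equilibrium([(schedule, np.full(len(schedule), 7.0))])
    assert report.delta_aic >= 2.0
    assert report.delta_aic == pytest.approx(4.0, abs=1e-6)
    assert report.constant_selected


def test_equilibrium_needs_three_time_points():
    with pytest.raises(ValueError, match="3 distinct"):
        it.check_equilibrium([(np.array([0.0, 5.0]), np.array([7.0, 7.0]))])
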