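"""Frailty-model estimation: likelihood oracles, reductions, inference tools."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import matchrisk as mr
from matchrisk.frailty import (
    CoxEngine,
    FitControl,
    ModelSpec,
    Term,
    compare_models,
    fit,
    hr_curve,
    hr_per_2sd,
    interaction_fit,
    partial_loglik,
    polynomial_select,
    variance_test,
)
from matchrisk.intervals import add_standardized, build_counting_process, build_intervals

from conftest import FIXED_BREAKS, brute_partial_loglik

FAST = FitControl(variance_se=False, outer_xatol=0.05, outer_maxfev=60)


# ---------------------------------------------------------------------------
# partial likelihood oracles
# ---------------------------------------------------------------------------


def test_null_partial_loglik_is_minus_log_risk_set_size():
    cohort = mr.make_fixture("two_players_one_injury")
    iv, _ = build_intervals(cohort, breakpoints=FIXED_BREAKS)
    ll = partial_loglik(iv, ModelSpec(terms=(), random="none"))
    assert ll == pytest.approx(-math.log(2), abs=1e-12)


@pytest.mark.parametrize("ties", ["efron", "breslow"])
@pytest.mark.parametrize("fixture", ["two_players_one_injury", "tie_break"])
def test_registry_fixtures_match_risk_set_enumeration(fixture, ties):
    cohort = mr.make_fixture(fixture)
    iv, _ = build_intervals(cohort, breakpoints=FIXED_BREAKS)
    assert len(iv) <= 6
    rng = np.random.default_rng(4)
    spec = ModelSpec(terms=("age", "one_month_fge"), random="none", ties=ties)
    for _ in range(5):
        beta = rng.normal(scale=0.3, size=2)
        got = partial_loglik(iv, spec, beta=beta)
        design_eta = (
            iv["age"].to_numpy() * beta[0] + iv["one_month_fge"].to_numpy() * beta[1]
        )
        want = brute_partial_loglik(
            design_eta, np.zeros(len(iv)), iv.duration_hours.to_numpy(), iv.event.to_numpy(), ties
        )
        assert got == pytest.approx(want, abs=1e-10)


def test_engine_matches_enumeration_on_random_counting_data():
    rng = np.random.default_rng(7)
    for trial in range(30):
        n = int(rng.integers(4, 15))
        X = rng.normal(size=(n, 2))
        start = np.round(rng.uniform(0, 3, n), 1)
        stop = start + rng.choice([0.5, 1.0, 1.0, 2.0], size=n)
        ev = rng.random(n) < 0.6
        if not ev.any():
            continue
        beta = rng.normal(size=2)
        for ties in ("efron", "breslow"):
            eng = CoxEngine(X, stop, ev, ties, [], start=start)
            got = eng.loglik(beta)
            want = brute_partial_loglik(X @ beta, start, stop, ev, ties)
            assert got == pytest.approx(want, abs=1e-10)


def test_efron_breslow_differ_by_tie_correction_on_tie_break():
    """Two tied events in a 3-interval risk set: hand-derived difference.

    At the null, Breslow gives -2 log 3 while Efron gives -(log 3 + log 2),
    because the second Efron column removes half the tied pair's weight.
    """
    cohort = mr.make_fixture("tie_break")
    iv, _ = build_intervals(cohort, breakpoints=FIXED_BREAKS)
    assert len(iv) == 3 and iv.event.sum() == 2
    ll_b = partial_loglik(iv, ModelSpec(terms=(), random="none", ties="breslow"))
    ll_e = partial_loglik(iv, ModelSpec(terms=(), random="none", ties="efron"))
    assert ll_b == pytest.approx(-2 * math.log(3), abs=1e-12)
    assert ll_e == pytest.approx(-(math.log(3) + math.log(2)), abs=1e-12)
    assert ll_e - ll_b == pytest.approx(math.log(3) - math.log(2), abs=1e-12)


def test_frailty_values_enter_linear_predictor():
    cohort = mr.make_fixture("two_players_one_injury")
    iv, _ = build_intervals(cohort, breakpoints=FIXED_BREAKS)
    spec = ModelSpec(terms=(), random="player")
    ll = partial_loglik(iv, spec, b_player={"A": 0.5, "B": 0.2})
    eta = np.where(iv.player_id == "A", 0.5, 0.2)
    want = brute_partial_loglik(
        eta, np.zeros(len(iv)), iv.duration_hours.to_numpy(), iv.event.to_numpy()
    )
    assert ll == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# fitting: reductions and cross-checks
# ---------------------------------------------------------------------------

TERMS = ("age_2sd", "height_cm_2sd", "mass_kg_2sd", "position", "prev_injury_count_2sd", "one_month_fge_2sd")


@pytest.fixture(scope="module")
def cox_fit(small_rows):
    rows, _, _ = small_rows
    return fit(rows, ModelSpec(terms=TERMS, random="none"), FAST)


def test_cox_reduction_matches_lifelines(small_rows, cox_fit):
    from lifelines import CoxPHFitter

    rows, _, _ = small_rows
    df = rows.copy()
    df["fwd"] = (df.position == "forward").astype(float)
    cols = ["age_2sd", "height_cm_2sd", "mass_kg_2sd", "fwd", "prev_injury_count_2sd", "one_month_fge_2sd"]
    cph = CoxPHFitter()
    cph.fit(
        df[cols + ["gap_start_hours", "gap_stop_hours", "event"]],
        entry_col="gap_start_hours",
        duration_col="gap_stop_hours",
        event_col="event",
    )
    np.testing.assert_allclose(cox_fit.beta, cph.params_.values, atol=2e-4)
    np.testing.assert_allclose(cox_fit.se_beta, cph.standard_errors_.values, atol=2e-5)
    assert cox_fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-4)


def test_nested_with_zero_variances_reduces_to_cox(small_rows, cox_fit):
    rows, _, _ = small_rows
    m = fit(
        rows,
        ModelSpec(terms=TERMS, random="team_player_nested"),
        FAST,
        fixed_variances={"team": 0.0, "player": 0.0},
    )
    np.testing.assert_allclose(m.beta, cox_fit.beta, rtol=1e-6, atol=1e-8)
    assert m.loglik == pytest.approx(cox_fit.loglik, abs=1e-5)


def test_nested_with_zero_team_variance_reduces_to_shared(small_rows):
    rows, _, _ = small_rows
    shared = fit(rows, ModelSpec(terms=TERMS, random="player"), FAST)
    nested0 = fit(
        rows,
        ModelSpec(terms=TERMS, random="team_player_nested"),
        FAST,
        fixed_variances={"team": 0.0},
    )
    np.testing.assert_allclose(nested0.beta, shared.beta, rtol=1e-3, atol=1e-5)
    assert nested0.sigma2_player == pytest.approx(shared.sigma2_player, rel=0.02, abs=1e-4)
    assert nested0.loglik == pytest.approx(shared.loglik, abs=0.05)


def test_time_unit_invariance(small_rows):
    """Rescaling the gap axis (hours -> minutes) leaves beta and LL unchanged."""
    rows, _, _ = small_rows
    scaled = rows.copy()
    scaled["gap_start_hours"] = scaled["gap_start_hours"] * 60.0
    scaled["gap_stop_hours"] = scaled["gap_stop_hours"] * 60.0
    a = fit(rows, ModelSpec(terms=("one_month_fge_2sd",), random="none"), FAST)
    b = fit(scaled, ModelSpec(terms=("one_month_fge_2sd",), random="none"), FAST)
    np.testing.assert_allclose(a.beta, b.beta, rtol=1e-8)
    assert a.loglik == pytest.approx(b.loglik, abs=1e-8)


def test_ppl_mode_is_a_maximum(small_rows):
    """Perturbing the fitted (beta, b) never increases the penalized loglik."""
    rows, _, _ = small_rows
    m = fit(rows, ModelSpec(terms=("one_month_fge_2sd",), random="player"), FAST)
    spec = m.spec
    base = partial_loglik(
        rows, spec, beta=m.beta, b_player=m.frailty_player
    ) - sum(v**2 for v in m.frailty_player.values()) / (2 * m.sigma2_player)
    rng = np.random.default_rng(1)
    for _ in range(5):
        bp = {k: v + rng.normal(scale=0.05) for k, v in m.frailty_player.items()}
        cand = partial_loglik(
            rows, spec, beta=m.beta + rng.normal(scale=0.02, size=len(m.beta)), b_player=bp
        ) - sum(v**2 for v in bp.values()) / (2 * m.sigma2_player)
        assert cand <= base + 1e-6
    assert m.converged


def test_laplace_against_numeric_integration():
    """Two-cluster shared frailty: Laplace ILL tracks the exact marginal."""
    cohort = mr.make_fixture("tie_break")
    iv, _ = build_intervals(cohort, breakpoints=FIXED_BREAKS)
    iv = iv.copy()
    s2 = 0.5
    spec = ModelSpec(terms=(), random="player")
    m = fit(iv, spec, FitControl(variance_se=False), fixed_variances={"player": s2})
    # exact marginal by tensor-product Gauss-Hermite over the 3 player effects
    nodes, weights = np.polynomial.hermite_e.hermegauss(25)
    players = sorted(iv.player_id.unique())
    codes = iv.player_id.map({p: i for i, p in enumerate(players)}).to_numpy()
    eng = CoxEngine(
        np.empty((len(iv), 0)),
        iv.duration_hours.to_numpy(),
        iv.event.to_numpy(),
        "efron",
        [codes],
    )
    wnorm = weights / math.sqrt(2 * math.pi)
    sd = math.sqrt(s2)
    total = 0.0
    for i, bi in enumerate(nodes):
        for j, bj in enumerate(nodes):
            for k, bk in enumerate(nodes):
                pl = eng.loglik(np.array([bi, bj, bk]) * sd)
                total += wnorm[i] * wnorm[j] * wnorm[k] * math.exp(pl)
    exact = math.log(total)
    assert m.loglik == pytest.approx(exact, abs=0.05)


def test_no_events_is_an_error(small_rows):
    rows, _, _ = small_rows
    censored = rows[~rows.event]
    with pytest.raises(Exception, match="events"):
        fit(censored, ModelSpec(terms=("one_month_fge_2sd",), random="none"), FAST)


# ---------------------------------------------------------------------------
# effect extraction
# ---------------------------------------------------------------------------


def test_hr_per_2sd_null_and_inverse(cox_fit):
    hr, lo, hi = hr_per_2sd(cox_fit, "one_month_fge_2sd")
    b, se = cox_fit.coef("one_month_fge_2sd")
    z = norm.ppf(0.95)
    assert hr == pytest.approx(math.exp(b))
    # the back-calculated SE from the CI is the exact inverse
    assert (math.log(hi) - math.log(lo)) / (2 * z) == pytest.approx(se, rel=1e-12)
    with pytest.raises(KeyError):
        hr_per_2sd(cox_fit, "not_a_term")


def test_hr_presentation_format():
    # beta = ln 1.14 with se chosen so the 90% CI prints as (1.08, 1.20)
    se = (math.log(1.20) - math.log(1.08)) / (2 * norm.ppf(0.95))
    lo = math.exp(math.log(1.14) - norm.ppf(0.95) * se)
    hi = math.exp(math.log(1.14) + norm.ppf(0.95) * se)
    assert round(lo, 2) == 1.08 and round(hi, 2) == 1.20


def test_hr_curve_reference_and_monotonicity(small_rows):
    rows, _, _ = small_rows
    m = fit(rows, ModelSpec(terms=("one_month_fge_2sd",), random="none"), FAST)
    grid = [-0.5, 0.0, 0.5, 1.0]
    curve = hr_curve(m, "one_month_fge_2sd", grid, ref=0.0)
    at_ref = curve[curve.x == 0.0].iloc[0]
    assert at_ref.hr == pytest.approx(1.0)
    assert at_ref.ci_low == pytest.approx(1.0) and at_ref.ci_high == pytest.approx(1.0)
    b = m.coef("one_month_fge_2sd")[0]
    diffs = np.diff(np.log(curve.hr.values))
    assert (diffs > 0).all() if b > 0 else (diffs < 0).all()


def test_hr_curve_flags_extrapolation(small_rows):
    rows, _, _ = small_rows
    m = fit(
        rows,
        ModelSpec(terms=(Term("twelve_month_matches", 3), "one_month_fge_2sd"), random="none"),
        FAST,
    )
    lo = rows.twelve_month_matches.min()
    hi = rows.twelve_month_matches.max()
    curve = hr_curve(m, "twelve_month_matches", [lo - 5, lo, hi, hi + 5])
    assert list(curve.extrapolated) == [True, False, False, True]


def test_polynomial_select_constrained_to_degree_one(small_rows):
    rows, _, _ = small_rows
    spec = ModelSpec(terms=(Term("twelve_month_matches", 1),), random="none")
    d, table, fits = polynomial_select(rows, "twelve_month_matches", spec, max_degree=1, control=FAST)
    assert d == 1 and len(table) == 1


# ---------------------------------------------------------------------------
# variance tests and model comparison
# ---------------------------------------------------------------------------


def test_variance_test_at_boundary(small_rows):
    rows, _, _ = small_rows
    m0 = fit(
        rows,
        ModelSpec(terms=("one_month_fge_2sd",), random="team_player_nested"),
        FAST,
        fixed_variances={"team": 0.0, "player": 0.0},
    )
    vt = variance_test(m0, "team", reduced_model=m0)
    assert vt.wald_p == 0.5
    assert vt.lr_stat == pytest.approx(0.0, abs=1e-9)
    assert vt.lr_p == 0.5


@pytest.fixture(scope="module")
def frail_rows():
    """Cohort with strong player frailty and no competing prev-injury effect."""
    cfg = mr.SimConfig(
        n_teams=4, players_per_team=15, n_seasons=2,
        sigma2_player=0.8, sigma2_team=0.0, hr_prev_2sd=1.0,
        twelve_month_coeffs=(0.0, 0.0, 0.0), quartile_ratios=(1.0, 1.0, 1.0, 1.0),
    )
    rows, _ = build_counting_process(mr.simulate(cfg, seed=21))
    rows, _ = add_standardized(rows, ["age", "one_month_fge"])
    return rows


def test_variance_test_detects_player_frailty(frail_rows):
    rows = frail_rows
    terms = ("age_2sd", "one_month_fge_2sd")
    ctrl = FitControl(outer_xatol=0.05, outer_maxfev=60)  # variance_se on
    shared = fit(rows, ModelSpec(terms=terms, random="player"), ctrl)
    cox = fit(rows, ModelSpec(terms=terms, random="none"), ctrl)
    vt = variance_test(shared, "player", reduced_model=cox)
    assert vt.sigma2 > 0.2
    assert vt.lr_p is not None and vt.lr_p < 0.05
    assert np.isfinite(vt.se) and vt.se > 0
    with pytest.raises(KeyError):
        variance_test(shared, "team")


def test_compare_models_self_comparison(cox_fit):
    table, pairwise = compare_models({"a": cox_fit, "b": cox_fit})
    assert table.delta_aic.abs().max() == 0.0
    assert table.delta_bic.abs().max() == 0.0
    row = pairwise.iloc[0]
    assert row.df == 0 and row.lr_stat == 0.0 and row.p == 1.0
    assert not row.significant


def test_compare_models_rejects_mismatched_fits(small_rows, cox_fit):
    rows, _, _ = small_rows
    other = fit(rows.iloc[: len(rows) // 2], ModelSpec(terms=TERMS, random="none"), FAST)
    with pytest.raises(ValueError, match="same interval set"):
        compare_models({"a": cox_fit, "b": other})


def test_aic_bic_definitions(cox_fit):
    k = len(cox_fit.beta)
    assert cox_fit.aic == pytest.approx(-2 * cox_fit.loglik + 2 * k)
    assert cox_fit.bic == pytest.approx(-2 * cox_fit.loglik + k * math.log(cox_fit.n_events))


# ---------------------------------------------------------------------------
# interaction
# ---------------------------------------------------------------------------


def test_interaction_requires_events_in_every_stratum(small_rows):
    rows, _, _ = small_rows
    crippled = rows[~(rows.event & (rows.twelve_month_quartile == 4))]
    with pytest.raises(ValueError, match="stratum"):
        interaction_fit(
            crippled,
            ModelSpec(terms=("one_month_fge_2sd",), random="none"),
            cont_col="one_month_fge_2sd",
        )


def test_interaction_table_layout(small_rows):
    rows, _, _ = small_rows
    model, table = interaction_fit(
        rows,
        ModelSpec(terms=("one_month_fge_2sd",), random="none"),
        cont_col="one_month_fge_2sd",
        control=FAST,
    )
    assert list(table.quartile) == sorted(rows.twelve_month_quartile.unique())
    assert table.kind.iloc[0] == "within_reference"
    assert (table.kind.iloc[1:] == "ratio_vs_reference").all()
    # hr_within = reference effect x ratio on the HR scale
    ref = table.hr_within.iloc[0]
    np.testing.assert_allclose(table.hr_within.iloc[1:], ref * table.hr.iloc[1:], rtol=1e-10)
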