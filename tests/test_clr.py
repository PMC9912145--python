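"""Conditional logistic likelihood, Newton fit, closed forms, and the
month-wise scans."""
import numpy as np
import pandas as pd
import pytest

import otcscan as o
from otcscan.clr import ConditionalLogit, fit_clr, unconditional_logistic
from conftest import make_strata


def _pairs_strata(f, g, h=0):
    """1:1 matched pairs with a binary exposure: f discordant pairs with the
    case exposed, g with the control exposed, h concordant pairs."""
    endog, exog, groups = [], [], []
    gid = 0
    for n, (yx) in ((f, [(1, 1), (0, 0)]), (g, [(1, 0), (0, 1)]),
                    (h, [(1, 1), (0, 1)])):
        for _ in range(n):
            for y, x in yx:
                endog.append(y); exog.append([x]); groups.append(gid)
            gid += 1
    return np.array(endog), np.array(exog, float), np.array(groups)


def test_loglik_at_zero_is_minus_s_log3():
    rng = np.random.default_rng(0)
    endog, exog, groups = make_strata(rng, 37, np.array([0.5]))
    m = ConditionalLogit(endog, exog, groups)
    assert m.loglike(np.zeros(1)) == pytest.approx(-37 * np.log(3), abs=1e-12)


def test_loglik_at_zero_general_sizes():
    endog = np.array([1, 0, 1, 0, 0, 0])
    exog = np.arange(6, dtype=float)[:, None]
    groups = np.array([0, 0, 1, 1, 1, 1])
    m = ConditionalLogit(endog, exog, groups)
    assert m.loglike([0.0]) == pytest.approx(-(np.log(2) + np.log(4)))


def test_gradient_matches_central_finite_differences():
    rng = np.random.default_rng(1)
    endog, exog, groups = make_strata(rng, 40, np.array([0.5, -0.3, 0.1]))
    m = ConditionalLogit(endog, exog, groups)
    for _ in range(5):
        beta = rng.normal(scale=0.7, size=3)
        g = m.score(beta)
        eps = 1e-6
        for j in range(3):
            e = np.zeros(3); e[j] = eps
            fd = (m.loglike(beta + e) - m.loglike(beta - e)) / (2 * eps)
            assert g[j] == pytest.approx(fd, rel=1e-6, abs=1e-8)


def test_hessian_matches_score_differences_and_is_nsd():
    rng = np.random.default_rng(2)
    endog, exog, groups = make_strata(rng, 30, np.array([0.2, 0.4]))
    m = ConditionalLogit(endog, exog, groups)
    for _ in range(5):
        beta = rng.normal(scale=0.5, size=2)
        H = m.hessian(beta)
        eps = 1e-6
        for j in range(2):
            e = np.zeros(2); e[j] = eps
            fd = (m.score(beta + e) - m.score(beta - e)) / (2 * eps)
            np.testing.assert_allclose(H[:, j], fd, rtol=1e-5, atol=1e-6)
        assert np.all(np.linalg.eigvalsh(H) <= 1e-9)


def test_constant_covariate_within_strata_is_flagged_zero():
    rng = np.random.default_rng(3)
    endog, exog, groups = make_strata(rng, 20, np.array([0.5]))
    const = np.repeat(rng.normal(size=20), 3)[:, None]  # stratum-constant
    X = np.column_stack([exog, const])
    fit = fit_clr(endog, X, groups, exog_names=["exposure", "flat"])
    assert "flat" in fit.nonidentified
    assert fit.params[1] == 0.0
    assert np.isnan(fit.bse[1])
    # likelihood genuinely flat along that coordinate
    m = ConditionalLogit(endog, X, groups)
    assert m.loglike([0.3, 0.0]) == pytest.approx(m.loglike([0.3, 5.0]))


def test_matched_pair_closed_form_or_equals_f_over_g():
    endog, exog, groups = _pairs_strata(f=10, g=5, h=7)
    fit = fit_clr(endog, exog, groups)
    assert fit.converged
    assert np.exp(fit.params[0]) == pytest.approx(2.0, abs=1e-8)
    endog, exog, groups = _pairs_strata(f=12, g=12)
    fit = fit_clr(endog, exog, groups)
    assert fit.params[0] == pytest.approx(0.0, abs=1e-8)


def test_separation_flagged_not_silent():
    # case always has the strictly largest exposure -> no finite MLE
    endog = np.array([1, 0, 0] * 10)
    exog = np.array([[3.0], [0.0], [1.0]] * 10)
    groups = np.repeat(np.arange(10), 3)
    fit = fit_clr(endog, exog, groups)
    assert fit.separation
    assert not fit.converged


def test_estimates_invariant_to_row_order_and_stratum_constant_shift():
    rng = np.random.default_rng(4)
    endog, exog, groups = make_strata(rng, 50, np.array([0.5]))
    fit = fit_clr(endog, exog, groups)
    perm = rng.permutation(len(endog))
    fit_p = fit_clr(endog[perm], exog[perm], groups[perm])
    assert fit_p.params[0] == pytest.approx(fit.params[0], abs=1e-9)
    shift = np.repeat(rng.normal(size=50), 3)
    fit_s = fit_clr(endog, exog + shift[:, None], groups)
    assert fit_s.params[0] == pytest.approx(fit.params[0], abs=1e-7)


def test_matches_statsmodels_conditional_logit():
    from statsmodels.discrete.conditional_models import (
        ConditionalLogit as SMCL)
    rng = np.random.default_rng(5)
    endog, exog, groups = make_strata(rng, 80, np.array([0.4, -0.2]))
    fit = fit_clr(endog, exog, groups)
    sm_fit = SMCL(endog, exog, groups=groups).fit(disp=0, method="newton",
                                                  tol=1e-12)
    np.testing.assert_allclose(fit.params, sm_fit.params, atol=1e-5)
    np.testing.assert_allclose(fit.bse, sm_fit.bse, rtol=1e-3)
    assert fit.llf == pytest.approx(sm_fit.llf, abs=1e-6)


def test_parameter_recovery_quick():
    """Short-run check that the estimator is unbiased near the truth; the
    full 200-replicate calibration lives in the acceptance suite."""
    rng = np.random.default_rng(6)
    est = []
    for _ in range(25):
        endog, exog, groups = make_strata(rng, 300, np.array([0.5]))
        est.append(fit_clr(endog, exog, groups).params[0])
    assert abs(np.mean(est) - 0.5) < 3 * np.std(est) / np.sqrt(len(est)) + 0.02


def test_bad_strata_rejected():
    with pytest.raises(ValueError, match="exactly one case"):
        ConditionalLogit([1, 1, 0], [[1.0], [2.0], [3.0]], [0, 0, 0])
    with pytest.raises(ValueError, match="non-finite"):
        ConditionalLogit([1, 0], [[np.nan], [1.0]], [0, 0])


def test_wald_ci_and_or_table_consistent():
    rng = np.random.default_rng(7)
    endog, exog, groups = make_strata(rng, 100, np.array([0.5]))
    fit = fit_clr(endog, exog, groups)
    tab = fit.or_table()
    assert tab["ci_lo"][0] < tab["or"][0] < tab["ci_hi"][0]
    assert np.log(tab["ci_hi"][0] / tab["ci_lo"][0]) == pytest.approx(
        2 * 1.959963984540054 * fit.bse[0])
    assert fit.llf <= 0


# -- scans ------------------------------------------------------------------

def test_scan_constant_adjustment_leaves_exposure_unchanged(small_panel):
    panel, eligible, _ = small_panel
    base = o.MonthlyCLRScan(panel, eligible, category=("indigestion",)).fit()
    ros = eligible.copy()
    ros["gp_visits"] = 3.0  # constant everywhere => constant within strata
    adj = o.MonthlyCLRScan(panel, ros, category=("indigestion",),
                           adjustments=("gp_visits",)).fit()
    b = base.exposure_table().set_index("month")["beta"]
    a = adj.exposure_table().set_index("month")["beta"]
    pd.testing.assert_series_equal(a, b, atol=1e-7)


def test_scan_has_all_months_and_terms(small_panel):
    panel, eligible, _ = small_panel
    res = o.MonthlyCLRScan(panel, eligible,
                           adjustments=("oc_ever", "household_size",
                                        "season", "covid_era")).fit()
    assert set(res.table["month"]) == set(range(-24, 0))
    exp = res.exposure_table()
    assert len(exp) == 24
    assert {"season_spring", "covid_era"} <= set(res.table["term"])


def test_binary_and_single_month_exposures_run(small_panel):
    panel, eligible, _ = small_panel
    for form in ("binary", "single_month"):
        res = o.MonthlyCLRScan(panel, eligible, exposure=form).fit()
        assert len(res.exposure_table()) == 24


def test_cumulative_horizon_fits(small_panel):
    panel, eligible, _ = small_panel
    cum = o.cumulative_clr(panel, eligible,
                           adjustments=("oc_ever", "household_size"))
    assert list(cum["horizon_months"]) == [6, 12, 24]
    # with a strong injected signal short horizons may separate; each row
    # either converges with a usable SE or is explicitly flagged
    for _, row in cum.iterrows():
        assert (row["converged"] and row["se"] > 0) or row["separation"]


def test_cumulative_horizons_usable_under_null():
    cfg = o.SimConfig(n_cases=25, n_controls=75, signal_ratio=1.0, seed=21)
    roster, log, _ = o.simulate_cohort(cfg)
    eligible, _ = o.apply_exclusions(roster)
    sets, _ = o.match(eligible)
    o.align_all(sets, eligible)
    panel = o.bin_monthly(log, sets)
    cum = o.cumulative_clr(panel, eligible)
    assert (cum["se"] > 0).all()
    assert cum["converged"].all()


# -- unconditional logistic -------------------------------------------------

def test_unconditional_intercept_only_recovers_prevalence():
    rng = np.random.default_rng(8)
    n = 400
    roster = pd.DataFrame({
        "arm": np.where(rng.random(n) < 0.3, "case", "control"),
        "z": np.zeros(n)})
    fit = unconditional_logistic(roster, ["z"])
    prev = (roster["arm"] == "case").mean()
    assert fit.params["const"] == pytest.approx(np.log(prev / (1 - prev)),
                                                abs=1e-6)


def test_unconditional_matches_sklearn_reference():
    from sklearn.linear_model import LogisticRegression
    rng = np.random.default_rng(9)
    n = 500
    x1, x2 = rng.normal(size=n), rng.binomial(1, 0.4, n).astype(float)
    eta = -0.5 + 0.8 * x1 - 0.6 * x2
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    roster = pd.DataFrame({"arm": np.where(y, "case", "control"),
                           "x1": x1, "x2": x2})
    fit = unconditional_logistic(roster, ["x1", "x2"])
    ref = LogisticRegression(C=np.inf, tol=1e-10, max_iter=1000).fit(
        np.column_stack([x1, x2]), y.astype(int))
    np.testing.assert_allclose(fit.params[["x1", "x2"]],
                               ref.coef_[0], atol=1e-6)
    assert fit.params["const"] == pytest.approx(ref.intercept_[0], abs=1e-6)
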