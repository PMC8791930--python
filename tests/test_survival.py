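"""Percentile grouping, Cox fits against a partial-likelihood oracle,
Kaplan-Meier estimates and the log-rank/score-test identity."""

import numpy as np
import pandas as pd
import pytest

from mitonuclear.simulate import generate_survival
from mitonuclear.survival import (
    HIGH_SMALL,
    LOW_LARGE,
    assign_groups,
    cox_fit,
    dichotomize_age,
    kaplan_meier_logrank,
)


def _efron_neg_loglik(beta, time, event, x):
    """Efron partial log-likelihood for a single covariate (oracle)."""
    ll = 0.0
    eta = beta * x
    for t in np.unique(time[event == 1]):
        deaths = (time == t) & (event == 1)
        at_risk = time >= t
        d = deaths.sum()
        sum_risk = np.exp(eta[at_risk]).sum()
        sum_death = np.exp(eta[deaths]).sum()
        ll += eta[deaths].sum()
        for j in range(d):
            ll -= np.log(sum_risk - j / d * sum_death)
    return -ll


def test_assign_groups_percentile_rules():
    rng = np.random.default_rng(0)
    expr = np.arange(100, dtype=float)
    size = np.arange(100, dtype=float)[::-1].copy()
    g = assign_groups(expr, size)
    # top-quartile expression corresponds to bottom-quartile size here
    assert (g == HIGH_SMALL).sum() > 0
    hs = np.nonzero(g == HIGH_SMALL)[0]
    e75, s25 = np.quantile(expr, 0.75), np.quantile(size, 0.25)
    assert (expr[hs] > e75).all() and (size[hs] < s25).all()

    # boundary: exactly at the 75th percentile goes to the other group
    expr2 = np.r_[np.arange(99, dtype=float), np.quantile(expr, 0.75)]
    size2 = np.zeros(100)
    g2 = assign_groups(expr2, size2)
    assert g2[-1] == LOW_LARGE


def test_assign_groups_independent_uniforms_fraction():
    rng = np.random.default_rng(1)
    expr = rng.random(40_000)
    size = rng.random(40_000)
    frac = (assign_groups(expr, size) == HIGH_SMALL).mean()
    assert frac == pytest.approx(0.25 * 0.25, abs=0.01)


def test_dichotomize_age():
    q = dichotomize_age(np.arange(1, 101, dtype=float))
    assert (q[:25] == "Q1").all()
    counts = pd.Series(q).value_counts()
    assert counts.max() - counts.min() <= 1
    with pytest.raises(ValueError):
        dichotomize_age(np.full(10, 50.0))


def test_cox_identical_groups_hr_one():
    times = np.tile(np.arange(1.0, 11.0), 2)
    tab = pd.DataFrame({
        "time": times,
        "event": np.ones(20, int),
        "group": np.r_[np.zeros(10, int), np.ones(10, int)],
    })
    fit = cox_fit(tab, ["group"])
    assert fit.hazard_ratio["group_low_large"] == pytest.approx(1.0, abs=1e-6)


def test_cox_matches_partial_likelihood_grid_oracle():
    """8-subject fixture: the fitted coefficient maximises the Efron
    partial likelihood, located independently by dense grid search."""
    tab = pd.DataFrame({
        "time": [1.0, 2.0, 3.0, 3.0, 5.0, 6.0, 8.0, 9.0],
        "event": [1, 1, 1, 0, 1, 1, 0, 1],
        "group": [1, 1, 0, 1, 0, 1, 0, 0],
    })
    fit = cox_fit(tab, ["group"])
    grid = np.linspace(-3, 3, 10_001)
    lls = [-_efron_neg_loglik(b, tab["time"].to_numpy(),
                              tab["event"].to_numpy(),
                              tab["group"].to_numpy(float)) for b in grid]
    beta_grid = grid[int(np.argmax(lls))]
    assert fit.coef["group_low_large"] == pytest.approx(beta_grid, abs=1e-4)


def test_cox_score_optimality():
    tab = generate_survival(300, 1.5, censor_rate=0.2, seed=3)
    fit = cox_fit(tab, ["group"])
    beta = fit.coef["group_low_large"]
    eps = 1e-5
    t, e, x = (tab["time"].to_numpy(), tab["event"].to_numpy(),
               tab["group"].to_numpy(float))
    score = (_efron_neg_loglik(beta - eps, t, e, x)
             - _efron_neg_loglik(beta + eps, t, e, x)) / (2 * eps)
    assert abs(score) < 1e-3


def test_cox_multivariate_df():
    tab = generate_survival(400, 1.7, censor_rate=0.3, seed=4)
    fit = cox_fit(tab, ["group", "er", "age"])
    assert fit.lrt_df == 5
    assert fit.converged


def test_cox_requires_events():
    tab = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "group": [0, 1]})
    with pytest.raises(ValueError):
        cox_fit(tab, ["group"])


def test_km_no_censoring_equals_empirical_survival():
    tab = pd.DataFrame({
        "time": np.arange(1.0, 11.0),
        "event": np.ones(10, int),
        "group": np.zeros(10, int),
    })
    res = kaplan_meier_logrank(tab.assign(group=0))
    curve = res["curves"][0]
    steps = curve.set_index("time")["survival"]
    for i, t in enumerate(np.arange(1.0, 11.0)):
        assert steps[t] == pytest.approx(1.0 - (i + 1) / 10)
    # median: first time S <= 0.5
    assert res["medians"][0] == pytest.approx(5.0)


def test_km_all_censored_is_error():
    tab = pd.DataFrame({"time": np.full(10, 7.0), "event": np.zeros(10, int),
                        "group": np.zeros(10, int)})
    with pytest.raises(ValueError):
        kaplan_meier_logrank(tab)


def test_logrank_equals_cox_score_test_identity():
    """Classical identity: for one binary covariate without ties, the
    log-rank chi-square equals the Cox partial-likelihood score test
    statistic at coefficient 0."""
    tab = generate_survival(80, 1.8, censor_rate=0.2, seed=5)
    tab["time"] += np.arange(len(tab)) * 1e-9  # break ties
    res = kaplan_meier_logrank(tab)
    t, e, x = (tab["time"].to_numpy(), tab["event"].to_numpy(),
               tab["group"].to_numpy(float))
    eps = 1e-5
    u = (_efron_neg_loglik(-eps, t, e, x) - _efron_neg_loglik(eps, t, e, x)) / (2 * eps)
    info = (_efron_neg_loglik(eps, t, e, x) - 2 * _efron_neg_loglik(0.0, t, e, x)
            + _efron_neg_loglik(-eps, t, e, x)) / eps**2
    score_stat = u**2 / info
    assert res["logrank_stat"] == pytest.approx(score_stat, rel=1e-3)


def test_logrank_null_calibration():
    rng = np.random.default_rng(6)
    hits = 0
    reps = 1000
    for i in range(reps):
        tab = generate_survival(60, 1.0, censor_rate=0.2,
                                seed=int(rng.integers(2**31)))
        if kaplan_meier_logrank(tab)["logrank_p"] < 0.05:
            hits += 1
    assert 0.03 <= hits / reps <= 0.07
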