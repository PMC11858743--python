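"""Event-history machinery: episodes, product-limit curves, the Efron Cox
fit and its diagnostics, cross-checked against hand calculations, a
brute-force likelihood oracle, and lifelines."""

import numpy as np
import pandas as pd
import pytest

from sexdem.simulate import Individual, simulate_cohort
from sexdem.survival import (
    ConvergenceError,
    Episode,
    build_episodes,
    cox_fit,
    cox_fit_arrays,
    fit_disappearance_model,
    km_estimate,
    ph_test,
)
from sexdem.survival import _efron_parts


def _ind(id, sex, entry, exit, cause, natal=None):
    return Individual(
        id=id,
        sex=sex,
        natal=(entry == 0.0) if natal is None else natal,
        entry_age=entry,
        exit_age=exit,
        exit_cause=cause,
        birth_year=2000,
    )


# ---------------------------------------------------------------------------
# episode construction


def test_episode_construction_censored_split_and_truncation():
    inds = [
        _ind("a", "male", 0.0, 5.0, "censored"),
        _ind("b", "female", 0.0, 10.0, "eviction"),
        _ind("c", "male", 4.0, 12.0, "emigration"),
    ]
    eps = build_episodes(inds, changepoint=8.0)
    by_id = {}
    for e in eps:
        by_id.setdefault(e.id, []).append(e)
    assert [(e.start_age, e.stop_age, e.event, e.young) for e in by_id["a"]] == [
        (0.0, 5.0, 0, 1)
    ]
    assert [(e.start_age, e.stop_age, e.event, e.young) for e in by_id["b"]] == [
        (0.0, 8.0, 0, 1),
        (8.0, 10.0, 1, 0),
    ]
    assert [(e.start_age, e.stop_age, e.event, e.young) for e in by_id["c"]] == [
        (4.0, 8.0, 0, 1),
        (8.0, 12.0, 1, 0),
    ]


def test_episode_validation():
    with pytest.raises(ValueError):
        build_episodes([_ind("x", "male", 3.0, 3.0, "death", natal=False)])
    with pytest.raises(ValueError):
        Episode("x", -1.0, 2.0, 1, 0, 1)


def test_unknown_sex_individuals_are_excluded():
    inds = [_ind("u", "unknown", 0.0, 0.1, "death"), _ind("m", "male", 0.0, 3.0, "death")]
    assert {e.id for e in build_episodes(inds)} == {"m"}


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_hand_computed_product_limit():
    """3 subjects, events at ages 1 and 2, one censored at 3:
    S(1) = 2/3, S(2) = 1/3."""
    eps = [
        Episode("a", 0.0, 1.0, 1, 0, 1),
        Episode("b", 0.0, 2.0, 1, 0, 1),
        Episode("c", 0.0, 3.0, 0, 0, 1),
    ]
    curve = km_estimate(eps)
    assert curve.survival == pytest.approx([2 / 3, 1 / 3])
    assert curve.n_at_risk.tolist() == [3, 2]


def test_km_all_censored_is_flat_one():
    eps = [Episode(str(i), 0.0, float(i + 1), 0, 0, 1) for i in range(4)]
    curve = km_estimate(eps)
    assert curve.times.size == 0
    assert curve.at(100.0) == 1.0


def test_km_equals_empirical_cdf_without_censoring():
    rng = np.random.default_rng(1)
    t = rng.exponential(2.0, 50)
    eps = [Episode(str(i), 0.0, float(x), 1, 0, 1) for i, x in enumerate(t)]
    curve = km_estimate(eps)
    for age in (0.5, 1.0, 3.0):
        assert curve.at(age) == pytest.approx((t > age).mean())


def test_km_invariant_to_order_and_non_event_splits():
    rng = np.random.default_rng(2)
    t = rng.exponential(2.0, 40)
    ev = rng.integers(0, 2, 40)
    eps = [Episode(str(i), 0.0, float(x), int(e), 0, 1) for i, (x, e) in enumerate(zip(t, ev))]
    if not any(ev):
        ev[0] = 1
    base = km_estimate(eps)
    shuffled = [eps[i] for i in rng.permutation(len(eps))]
    split = []
    for e in eps:  # split each episode at its midpoint (never an event age)
        mid = (e.start_age + e.stop_age) / 2
        split += [
            Episode(e.id, e.start_age, mid, 0, e.sex_male, e.young),
            Episode(e.id, mid, e.stop_age, e.event, e.sex_male, e.young),
        ]
    for other in (km_estimate(shuffled), km_estimate(split)):
        assert np.allclose(other.times, base.times)
        assert np.allclose(other.survival, base.survival)


def test_km_delayed_entry_matches_lifelines():
    from lifelines import KaplanMeierFitter

    inds = simulate_cohort(200, 0.3, 0.2, 0.2, 0.2, seed=3)
    # convert a third into delayed entries to exercise truncation
    rng = np.random.default_rng(3)
    eps = []
    for i, ind in enumerate(inds):
        entry = rng.uniform(0, 0.8 * ind.exit_age) if i % 3 == 0 else 0.0
        eps.append(Episode(ind.id, entry, ind.exit_age, ind.event, 0, 1))
    curve = km_estimate(eps)
    kmf = KaplanMeierFitter().fit(
        [e.stop_age for e in eps],
        [e.event for e in eps],
        entry=[e.start_age for e in eps],
    )
    for t, s in zip(curve.times, curve.survival):
        assert s == pytest.approx(float(kmf.predict(t)), abs=1e-10)


def test_km_empty_group_rejected():
    with pytest.raises(ValueError):
        km_estimate([], group=None)


# ---------------------------------------------------------------------------
# Cox partial likelihood


def efron_loglik_naive(start, stop, event, x, beta):
    """Explicit written-out Efron partial likelihood (loop oracle)."""
    ll = 0.0
    for t in sorted(set(stop[event == 1])):
        D = [i for i in range(len(stop)) if event[i] and stop[i] == t]
        R = [i for i in range(len(stop)) if start[i] < t <= stop[i]]
        d = len(D)
        s0d = sum(np.exp(beta * x[i]) for i in D)
        S0 = sum(np.exp(beta * x[i]) for i in R)
        ll += sum(beta * x[i] for i in D)
        for l in range(d):
            ll -= np.log(S0 - (l / d) * s0d)
    return ll


def test_loglik_matches_naive_oracle_at_arbitrary_beta():
    rng = np.random.default_rng(4)
    n = 30
    x = rng.integers(0, 2, n).astype(float)
    stop = rng.integers(1, 6, n).astype(float)
    start = np.where(rng.uniform(size=n) < 0.4, stop * rng.uniform(0, 0.9, n), 0.0)
    event = rng.integers(0, 2, n)
    event[0] = 1
    for beta in (-1.3, 0.0, 0.7):
        ll, _, _ = _efron_parts(start, stop, event, x[:, None], np.array([beta]))
        assert ll == pytest.approx(efron_loglik_naive(start, stop, event, x, beta))


def test_identical_groups_give_zero_coefficient():
    """Duplicating every subject into both covariate groups forces an
    exchangeable likelihood with maximum at zero."""
    stop = np.array([1.0, 2.0, 3.0, 4.0] * 2)
    event = np.array([1, 1, 0, 1] * 2)
    x = np.array([0.0] * 4 + [1.0] * 4)
    fit = cox_fit_arrays(np.zeros(8), stop, event, x[:, None])
    assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)
    assert fit.lr_stat == pytest.approx(0.0, abs=1e-10)


def test_cox_matches_lifelines_with_truncation_and_ties():
    from lifelines import CoxTimeVaryingFitter

    rng = np.random.default_rng(6)
    n = 400
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / np.exp(0.5 * x))
    stop = np.round(np.minimum(t, rng.uniform(0, 2, n)), 1) + 0.05
    event = (t <= stop).astype(int)
    start = np.where(rng.uniform(size=n) < 0.3, stop * rng.uniform(0, 0.5, n), 0.0)
    fit = cox_fit_arrays(start, stop, event, x[:, None])
    df = pd.DataFrame(
        {"id": np.arange(n), "start": start, "stop": stop, "event": event, "x": x}
    )
    ctv = CoxTimeVaryingFitter().fit(
        df, id_col="id", start_col="start", stop_col="stop", event_col="event"
    )
    assert fit.coef[0] == pytest.approx(float(ctv.params_.iloc[0]), abs=1e-8)
    assert fit.se[0] == pytest.approx(float(ctv.standard_errors_.iloc[0]), abs=1e-8)
    assert fit.loglik_fit == pytest.approx(float(ctv.log_likelihood_), abs=1e-6)


def test_gradient_norm_small_at_solution():
    inds = simulate_cohort(300, 0.3, 0.15, 0.2, 0.2, seed=7)
    fit = cox_fit(build_episodes(inds, 8.0), terms=["sex", "sex:young"])
    d = fit._data
    _, grad, _ = _efron_parts(d["start"], d["stop"], d["event"], d["X"], fit.coef)
    assert np.linalg.norm(grad) < 1e-6


def test_parameter_recovery_hazard_ratio_two():
    """Females simulated with twice the male hazard below age 8: the fitted
    sex:young coefficient recovers -log 2 within 2 s.e. (n = 1000)."""
    inds = simulate_cohort(1000, 0.3, 0.15, 0.2, 0.2, seed=8)
    fit = cox_fit(build_episodes(inds, 8.0), terms=["sex", "sex:young"])
    j = fit.terms.index("sex:young")
    assert abs(fit.coef[j] - (-np.log(2.0))) < 2 * fit.se[j]
    assert abs(fit.coef[fit.terms.index("sex")]) < 2 * fit.se[fit.terms.index("sex")]


def test_lr_and_wald_statistics_agree_asymptotically():
    rng = np.random.default_rng(9)
    n = 2000
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / np.exp(0.4 * x))
    c = rng.uniform(0, 3, n)
    fit = cox_fit_arrays(
        np.zeros(n), np.minimum(t, c), (t <= c).astype(int), x[:, None]
    )
    assert abs(fit.lr_stat - fit.wald_stat) / fit.lr_stat < 0.1


def test_no_events_and_separation_are_reported():
    with pytest.raises(ValueError):
        cox_fit_arrays(np.zeros(3), np.arange(1.0, 4.0), np.zeros(3, int), np.ones((3, 1)))
    # perfect separation: all x=1 events precede every x=0 event
    stop = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    event = np.ones(6, int)
    x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    with pytest.raises(ConvergenceError):
        cox_fit_arrays(np.zeros(6), stop, event, x[:, None])


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic


def test_ph_test_matches_lifelines_km_transform():
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    rng = np.random.default_rng(10)
    n = 300
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / np.exp(0.6 * x))
    c = rng.uniform(0, 2, n)
    stop = np.minimum(t, c)
    event = (t <= c).astype(int)
    fit = cox_fit_arrays(np.zeros(n), stop, event, x[:, None])
    mine = ph_test(fit, transform="km")
    df = pd.DataFrame({"T": stop, "E": event, "x": x})
    cph = CoxPHFitter().fit(df, "T", "E")
    theirs = proportional_hazard_test(cph, df, time_transform="km")
    assert mine.chi2[0] == pytest.approx(
        float(theirs.summary["test_statistic"].iloc[0]), rel=1e-6
    )
    assert mine.p[0] == pytest.approx(float(theirs.summary["p"].iloc[0]), abs=1e-6)


def test_ph_test_transforms_and_validation():
    inds = simulate_cohort(200, 0.3, 0.15, 0.2, 0.2, seed=11)
    fit = cox_fit(build_episodes(inds, 8.0, split=False), terms=["sex"])
    for transform in ("km", "identity", "rank", "log"):
        res = ph_test(fit, transform=transform)
        assert res.chi2[0] >= 0 and 0 <= res.p[0] <= 1
        assert res.global_df == 1
    with pytest.raises(ValueError):
        ph_test(fit, transform="nope")


# ---------------------------------------------------------------------------
# composed model


def test_disappearance_model_recovers_piecewise_truth():
    """Female-biased disappearance below the changepoint only: male hazard
    ratio < 1 below age 8, ~1 above, and the interaction term is negative."""
    inds = simulate_cohort(1500, 0.3, 0.15, 0.2, 0.2, seed=12)
    fit, ph = fit_disappearance_model(inds, changepoint=8.0)
    coef = dict(zip(fit.terms, fit.coef))
    se = dict(zip(fit.terms, fit.se))
    young_hr = np.exp(coef["sex"] + coef["sex:young"])
    assert young_hr < 1.0
    assert abs(coef["sex"]) < 2.5 * se["sex"]  # old-age male effect ~ 0
    assert coef["sex:young"] < 0
    assert len(ph.terms) == len(fit.terms)


def test_disappearance_model_null_when_sexes_identical():
    inds = simulate_cohort(800, 0.2, 0.2, 0.25, 0.25, seed=13)
    fit, _ = fit_disappearance_model(inds, changepoint=8.0)
    for c, s in zip(fit.coef, fit.se):
        assert abs(c) < 2.5 * s
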