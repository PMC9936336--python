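import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from catrisk.competing_risks import (
    SurvivalData,
    cif_at,
    estimate_cif,
    fine_gray_fit,
    gray_test,
    incidence_rate,
)


def cif_oracle(time, event, cause):
    """Direct product-limit evaluation with explicit loops (independent of
    the vectorized implementation)."""
    times = sorted({t for t, e in zip(time, event) if e != 0})
    surv = 1.0
    cum = 0.0
    out = []
    for u in times:
        n_at_risk = sum(1 for t in time if t >= u)
        d_all = sum(1 for t, e in zip(time, event) if t == u and e != 0)
        d_cause = sum(1 for t, e in zip(time, event) if t == u and e == cause)
        cum += surv * d_cause / n_at_risk
        surv *= 1.0 - d_all / n_at_risk
        out.append((u, cum))
    return out


class TestEstimateCif:
    def test_four_subject_hand_example(self):
        data = SurvivalData(time=[1, 2, 3, 4], event=[1, 2, 1, 0])
        c1 = estimate_cif(data, cause=1)
        c2 = estimate_cif(data, cause=2)
        np.testing.assert_allclose(cif_at(c1, 1.0)[0], 0.25)
        np.testing.assert_allclose(cif_at(c1, 2.5)[0], 0.25)
        np.testing.assert_allclose(cif_at(c1, 3.0)[0], 0.50)
        np.testing.assert_allclose(cif_at(c2, 2.0)[0], 0.25)
        assert cif_at(c1, 0.0) == (0.0, 0.0, 0.0)
        np.testing.assert_allclose(cif_at(c1, 99.0)[0], 0.50)

    def test_single_cause_no_censoring_is_empirical_cdf(self):
        t = np.array([1.0, 2.0, 2.0, 5.0, 7.0])
        data = SurvivalData(time=t, event=np.ones(5, int))
        est = estimate_cif(data, cause=1)
        for tau in (1.0, 2.0, 5.0, 7.0):
            np.testing.assert_allclose(cif_at(est, tau)[0], np.mean(t <= tau))

    def test_single_subject_event(self):
        est = estimate_cif(SurvivalData(time=[5.0], event=[1]), cause=1)
        assert cif_at(est, 4.9)[0] == 0.0
        assert cif_at(est, 5.0)[0] == 1.0

    def test_all_censored_gives_zero_cif(self):
        est = estimate_cif(SurvivalData(time=[1.0, 2.0], event=[0, 0]), cause=1)
        assert est.times.size == 0
        assert cif_at(est, 10.0) == (0.0, 0.0, 0.0)

    def test_single_cause_with_censoring_equals_one_minus_km(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 80)
        e = (rng.random(80) < 0.7).astype(int)
        est = estimate_cif(SurvivalData(time=t, event=e), cause=1)
        km = KaplanMeierFitter().fit(t, e)
        for u in est.times:
            np.testing.assert_allclose(
                cif_at(est, u)[0], 1.0 - km.predict(u), atol=1e-12
            )

    @pytest.mark.parametrize("times", [(1, 1, 2, 3, 3), (1, 2, 2, 4, 5)])
    def test_matches_oracle_over_all_event_enumerations(self, times):
        for events in itertools.product((0, 1, 2), repeat=len(times)):
            est = estimate_cif(SurvivalData(time=times, event=events), cause=1)
            for u, expected in cif_oracle(times, events, 1):
                np.testing.assert_allclose(cif_at(est, u)[0], expected, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(st.integers(min_value=1, max_value=6), st.integers(min_value=0, max_value=2)),
            min_size=1,
            max_size=6,
        )
    )
    def test_matches_oracle_on_random_small_cohorts(self, subjects):
        time = [s[0] for s in subjects]
        event = [s[1] for s in subjects]
        for cause in (1, 2):
            est = estimate_cif(SurvivalData(time=time, event=event), cause=cause)
            for u, expected in cif_oracle(time, event, cause):
                np.testing.assert_allclose(cif_at(est, u)[0], expected, atol=1e-12)

    def test_cifs_and_survivor_partition_unity_without_censoring(self):
        rng = np.random.default_rng(2)
        t = np.round(rng.exponential(5, 60), 1) + 0.1
        e = rng.integers(1, 3, 60)
        data = SurvivalData(time=t, event=e)
        c1 = estimate_cif(data, cause=1)
        c2 = estimate_cif(data, cause=2)
        km = KaplanMeierFitter().fit(t, np.ones_like(t))
        for u in c1.times:
            total = cif_at(c1, u)[0] + cif_at(c2, u)[0] + float(km.predict(u))
            np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_confidence_bounds_bracket_point_inside_unit_interval(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 100)
        e = rng.integers(0, 3, 100)
        est = estimate_cif(SurvivalData(time=t, event=e), cause=1)
        assert np.all(est.ci_low <= est.cif + 1e-12)
        assert np.all(est.cif <= est.ci_high + 1e-12)
        assert np.all((est.ci_low >= 0) & (est.ci_high <= 1))
        assert np.all(np.diff(est.cif) >= -1e-15)

    def test_grouped_estimation_returns_one_estimate_per_level(self):
        data = SurvivalData(time=[1, 2, 3, 4], event=[1, 1, 2, 0], group=["a", "a", "b", "b"])
        result = estimate_cif(data, cause=1)
        assert set(result) == {"a", "b"}
        assert result["a"].n == 2


def _competing_fixture():
    """Deterministic competing-risks data with censoring (n=150).

    The frozen Fine-Gray coefficients below were computed on this exact
    dataset with the cmprsk::crr reference implementation (R), the field's
    standard for subdistribution hazard regression.
    """
    rng = np.random.default_rng(42)
    n = 150
    X = np.column_stack([rng.binomial(1, 0.4, n), rng.normal(0, 1, n)])
    lp = 0.7 * X[:, 0] - 0.4 * X[:, 1]
    pi = 1 - (1 - 0.35) ** np.exp(lp)
    u = rng.random(n)
    isvte = u < pi
    inner = np.clip((1 - np.exp(np.exp(-lp) * np.log1p(-u))) / 0.35, 0, 1 - 1e-12)
    t1 = -np.log1p(-inner) / 0.2
    t2 = rng.exponential(1 / 0.08, n)
    tl = np.where(isvte, t1, t2)
    el = np.where(isvte, 1, 2)
    c = rng.uniform(2, 20, n)
    return np.minimum(tl, c), np.where(tl <= c, el, 0), X


class TestFineGray:
    def test_matches_crr_reference_coefficients(self):
        time, event, X = _competing_fixture()
        sd = SurvivalData(time=time, event=event, covariates=pd.DataFrame(X, columns=["x1", "x2"]))
        fit = fine_gray_fit(sd)
        assert fit.converged
        np.testing.assert_allclose(fit.coefficients, [0.566780156095, -0.392679125603], atol=1e-6)
        # robust SEs agree with the reference to within 1% (the reference
        # variance additionally carries the censoring-KM estimation term)
        np.testing.assert_allclose(fit.se, [0.267152844858, 0.151659058871], rtol=0.01)
        np.testing.assert_allclose(fit.hr, np.exp(fit.coefficients), rtol=1e-15)

    def test_reduces_to_cox_without_competing_events_or_censoring(self):
        rng = np.random.default_rng(0)
        n = 60
        X = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-0.5 * X[:, 0] + 0.3 * X[:, 1]))
        sd = SurvivalData(time=t, event=np.ones(n, int), covariates=pd.DataFrame(X, columns=["x1", "x2"]))
        fit = fine_gray_fit(sd)
        df = pd.DataFrame({"t": t, "e": 1, "x1": X[:, 0], "x2": X[:, 1]})
        cph = CoxPHFitter().fit(df, "t", "e", fit_options={"precision": 1e-12})
        np.testing.assert_allclose(fit.coefficients, cph.params_.values, atol=1e-6)

    def test_constant_covariate_has_zero_coefficient(self):
        time, event, _ = _competing_fixture()
        sd = SurvivalData(time=time, event=event, covariates=pd.DataFrame({"c": np.ones(len(time))}))
        fit = fine_gray_fit(sd)
        assert abs(fit.coefficients[0]) < 1e-9

    def test_rescaling_covariate_rescales_coefficient_only(self):
        time, event, X = _competing_fixture()
        base = fine_gray_fit(SurvivalData(time=time, event=event, covariates=pd.DataFrame(X, columns=["x1", "x2"])))
        X2 = X.copy()
        X2[:, 1] *= 10.0
        scaled = fine_gray_fit(SurvivalData(time=time, event=event, covariates=pd.DataFrame(X2, columns=["x1", "x2"])))
        np.testing.assert_allclose(scaled.coefficients[1], base.coefficients[1] / 10.0, atol=1e-8)
        np.testing.assert_allclose(scaled.p_values, base.p_values, atol=1e-8)

    def test_event_and_competing_counts(self):
        time, event, X = _competing_fixture()
        fit = fine_gray_fit(SurvivalData(time=time, event=event, covariates=pd.DataFrame(X, columns=["x1", "x2"])))
        assert fit.n_events == int(np.sum(event == 1))
        assert fit.n_competing == int(np.sum(event == 2))
        assert fit.n_events + fit.n_competing <= fit.n

    def test_complete_separation_is_flagged_not_silent(self):
        # covariate perfectly separates early events from late ones
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = fine_gray_fit(SurvivalData(time=time, event=event, covariates=pd.DataFrame({"x": x})))
        assert (not fit.converged) or fit.separation

    def test_requires_a_covariate(self):
        with pytest.raises(ValueError, match="covariate"):
            fine_gray_fit(SurvivalData(time=[1.0], event=[1]))


class TestGrayTest:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 2, 1, 0]
        data = SurvivalData(time=t + t, event=e + e, group=["a"] * 4 + ["b"] * 4)
        res = gray_test(data)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_equals_logrank_on_single_cause_uncensored_data(self):
        rng = np.random.default_rng(0)
        n = 60
        t = rng.exponential(1, n)
        g = np.repeat(["a", "b"], n // 2)
        t[g == "b"] *= 1.6
        res = gray_test(SurvivalData(time=t, event=np.ones(n, int), group=g))
        lr = multivariate_logrank_test(t, g, np.ones(n))
        np.testing.assert_allclose(res.statistic, lr.test_statistic, atol=1e-10)
        np.testing.assert_allclose(res.p_value, lr.p_value, atol=1e-10)

    def test_four_groups_have_three_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        n = 80
        data = SurvivalData(
            time=rng.exponential(5, n),
            event=rng.integers(0, 3, n),
            group=np.repeat(["a", "b", "c", "d"], n // 4),
        )
        assert gray_test(data).df == 3

    def test_single_group_is_an_error(self):
        with pytest.raises(ValueError, match="two groups"):
            gray_test(SurvivalData(time=[1.0, 2.0], event=[1, 1], group=["a", "a"]))

    def test_detects_a_real_difference(self):
        time, event, X = _competing_fixture()
        g = np.where(X[:, 0] > 0, "hi", "lo")
        res = gray_test(SurvivalData(time=time, event=event, group=g))
        assert res.p_value < 0.2  # moderate effect, moderate n


class TestIncidenceRate:
    def test_reference_arithmetic(self):
        assert round(incidence_rate(54, 4865), 1) == 1.1

    @pytest.mark.parametrize("events,pt,expected", [(0, 500.0, 0.0), (1, 100.0, 1.0)])
    def test_simple_values(self, events, pt, expected):
        assert incidence_rate(events, pt) == pytest.approx(expected)

    def test_nonpositive_person_time_is_an_error(self):
        with pytest.raises(ValueError):
            incidence_rate(5, 0.0)
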