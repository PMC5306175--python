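"""Logistic incidence models: recovery, odds ratios, scenario deltas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from wbvm.incidence import (REFERENCE_DIABETES_COEFFICIENTS, IncidenceModel,
                            SeparationError, fit_incidence, incidence_delta,
                            odds_ratio)


def test_recovers_known_betas_at_large_n():
    """Each coefficient of a known logistic law is recovered within 3 SE."""
    rng = np.random.default_rng(50)
    n = 50000
    X = pd.DataFrame({
        "ln_age": np.log(rng.uniform(20, 64, n)),
        "female": rng.integers(0, 2, n).astype(float),
        "factor_current_health": rng.integers(0, 2, n).astype(float),
    })
    truth = {"const": -6.0, "ln_age": 1.2, "female": -0.1,
             "factor_current_health": 0.8}
    eta = (truth["const"] + truth["ln_age"] * X["ln_age"]
           + truth["female"] * X["female"]
           + truth["factor_current_health"] * X["factor_current_health"])
    y = pd.Series((rng.random(n) < expit(eta)).astype(float))
    model = fit_incidence(X, y, "diabetes",
                          columns=["ln_age", "female",
                                   "factor_current_health"])
    for name, beta in truth.items():
        se = model.std_errors[name]
        assert abs(model.coefficients[name] - beta) < 3 * se, name


def test_single_covariate_beta_equals_table_log_odds_ratio():
    """Balanced 2x2 table: beta = ln[(a*d)/(b*c)]."""
    # exposed: 30 events / 70 non-events; unexposed: 10 / 90
    x = np.repeat([1.0, 0.0], 100)
    y = np.concatenate([np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)])
    model = fit_incidence(pd.DataFrame({"factor_strengths": x}),
                          pd.Series(y), "copd",
                          columns=["factor_strengths"])
    hand = np.log((30 * 90) / (70 * 10))
    assert model.coefficients["factor_strengths"] == pytest.approx(
        hand, abs=1e-6)


def test_constant_covariate_raises_separation_error():
    X = pd.DataFrame({"factor_strengths": np.ones(50)})
    y = pd.Series(np.r_[np.ones(10), np.zeros(40)])
    with pytest.raises(SeparationError, match="factor_strengths"):
        fit_incidence(X, y, "copd", columns=["factor_strengths"])


def test_zero_events_rejected():
    X = pd.DataFrame({"factor_strengths": np.r_[np.ones(25), np.zeros(25)]})
    with pytest.raises(ValueError, match="no .* events"):
        fit_incidence(X, pd.Series(np.zeros(50)), "cad",
                      columns=["factor_strengths"])


class TestOddsRatio:
    @pytest.mark.parametrize("beta,expected", [
        (0.771, 2.16), (0.0, 1.0), (0.358, 1.43)])
    def test_known_values(self, beta, expected):
        assert round(odds_ratio(beta), 2) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_monotone_and_reciprocal(self, a, b):
        if a + 1e-9 < b:
            assert odds_ratio(a) < odds_ratio(b)
        assert odds_ratio(-a) == pytest.approx(1 / odds_ratio(a))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            odds_ratio(float("inf"))


def reference_model() -> IncidenceModel:
    coef = pd.Series(REFERENCE_DIABETES_COEFFICIENTS)
    cols = [c for c in coef.index if c != "const"]
    return IncidenceModel(
        disease="diabetes", coefficients=coef,
        wald=coef * 0, p_values=coef * 0, std_errors=coef * 0,
        covariates=cols, n_obs=0, n_events=0)


def reference_cohort(n=200, seed=2) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "ln_age": np.log(rng.uniform(25, 60, n)),
        "female": rng.integers(0, 2, n).astype(float),
        "dis_copd": rng.integers(0, 2, n).astype(float) * 0.0,
        "dis_asthma": (rng.random(n) < 0.1).astype(float),
        "factor_current_health": (rng.random(n) < 0.5).astype(float),
        "factor_health_maintenance": (rng.random(n) < 0.7).astype(float),
        "factor_financial_support": (rng.random(n) < 0.25).astype(float),
    })


class TestIncidenceDelta:
    def prevs(self, ch, hm, fs):
        return {"factor_current_health": ch,
                "factor_health_maintenance": hm,
                "factor_financial_support": fs}

    def test_equal_scenarios_give_zero_delta(self):
        model, cohort = reference_model(), reference_cohort()
        p = self.prevs(0.5, 0.7, 0.25)
        d = incidence_delta(model, cohort, p, p)
        assert d.delta_p == 0.0 and d.avoided == 0.0

    def test_matches_hand_computed_inverse_logit_difference(self):
        """Single-factor model: delta equals averaged expit difference."""
        coef = pd.Series({"const": -4.0, "factor_strengths": 0.9,
                          "ln_age": 0.5})
        model = IncidenceModel("cad", coef, coef * 0, coef * 0, coef * 0,
                               ["ln_age", "factor_strengths"], 0, 0)
        cohort = pd.DataFrame({"ln_age": np.log([30.0, 40.0, 55.0]),
                               "factor_strengths": [0.0, 1.0, 0.0]})
        hi, lo = 0.6, 0.2
        d = incidence_delta(model, cohort, {"factor_strengths": hi},
                            {"factor_strengths": lo})
        eta = -4.0 + 0.5 * cohort["ln_age"]
        hand = (expit(eta + 0.9 * hi) - expit(eta + 0.9 * lo)).mean()
        assert d.delta_p == pytest.approx(hand, abs=1e-12)
        assert d.avoided == pytest.approx(hand * 3)

    def test_avoided_scales_with_population_size(self):
        """A 0.06 % incidence-rate reduction over ~5,000 non-diseased
        members rounds to a handful of avoided onsets."""
        model, cohort = reference_model(), reference_cohort()
        exp = self.prevs(0.62, 0.7, 0.25)
        act = self.prevs(0.5, 0.7, 0.25)
        d = incidence_delta(model, cohort, exp, act)
        assert d.delta_p > 0
        scaled = d.delta_p * 5023
        assert round(d.avoided) == round(d.delta_p * len(cohort))
        assert scaled == pytest.approx(d.delta_p * 5023)

    def test_monotone_in_positive_beta_prevalence(self):
        model, cohort = reference_model(), reference_cohort()
        act = self.prevs(0.5, 0.7, 0.25)
        lo = incidence_delta(model, cohort, self.prevs(0.55, 0.7, 0.25), act)
        hi = incidence_delta(model, cohort, self.prevs(0.65, 0.7, 0.25), act)
        assert hi.delta_p >= lo.delta_p

    def test_bernoulli_mixture_matches_hand_mixture(self):
        coef = pd.Series({"const": -2.0, "factor_strengths": 1.0})
        model = IncidenceModel("cad", coef, coef * 0, coef * 0, coef * 0,
                               ["factor_strengths"], 0, 0)
        cohort = pd.DataFrame({"factor_strengths": [0.0, 1.0]})
        p = 0.3
        d = incidence_delta(model, cohort, {"factor_strengths": p},
                            {"factor_strengths": 0.0}, mode="bernoulli")
        hand_p = p * expit(-1.0) + (1 - p) * expit(-2.0)
        assert d.p_expected == pytest.approx(hand_p, abs=1e-12)
        assert d.p_actual == pytest.approx(expit(-2.0), abs=1e-12)

    def test_invalid_prevalence_rejected(self):
        model, cohort = reference_model(), reference_cohort()
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            incidence_delta(model, cohort, self.prevs(1.2, 0.7, 0.25),
                            self.prevs(0.5, 0.7, 0.25))


def test_fitted_probabilities_average_to_event_rate():
    """Logistic score identity: mean fitted probability = event rate."""
    rng = np.random.default_rng(8)
    n = 2000
    X = pd.DataFrame({"factor_strengths": rng.integers(0, 2, n).astype(float),
                      "ln_age": np.log(rng.uniform(20, 64, n))})
    y = pd.Series((rng.random(n)
                   < expit(-2 + X["factor_strengths"])).astype(float))
    model = fit_incidence(X, y, "asthma",
                          columns=["ln_age", "factor_strengths"])
    assert model.predict(X).mean() == pytest.approx(y.mean(), abs=1e-8)
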