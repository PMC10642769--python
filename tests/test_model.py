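"""Mixture-model mechanics: packing, softmax proportions, the likelihood."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import espd
from espd.model import (INTERCEPT, Block, CompetingRisksDataset,
                        CoefficientVector, DataError, ESPDSpec)


def invlogit(z):
    return 1.0 / (1.0 + math.exp(-z))


def toy_exponential_spec():
    return ESPDSpec(event_names=("e1", "e2"),
                    families={"e1": "exponential", "e2": "exponential"},
                    reference_event="e2")


def make_data(t, e, X=None):
    n = len(t)
    X = X if X is not None else pd.DataFrame({INTERCEPT: np.ones(n)})
    return CompetingRisksDataset(np.asarray(t, float),
                                 np.asarray(e, object), X)


# -- layout -----------------------------------------------------------------

def test_two_risk_shared_shape_weibull_layout_has_seven_coefficients():
    """Two Weibull risks, two covariates on pi only: 3 + 2 + 2 = 7."""
    spec = ESPDSpec(event_names=("recur", "death"),
                    families={"recur": "weibull", "death": "weibull"},
                    reference_event="death",
                    pi_covariates=(INTERCEPT, "x1", "x2"))
    assert spec.n_coefficients == 7


@given(st.lists(st.floats(-5, 5), min_size=10, max_size=10))
@settings(max_examples=50, deadline=None)
def test_pack_unpack_roundtrip_is_identity(values, ):
    spec = espd.study_spec()
    cv = CoefficientVector(spec, np.array(values))
    rebuilt = CoefficientVector.from_dict(spec, cv.unpack())
    np.testing.assert_array_equal(rebuilt.packed, cv.packed)


def test_packed_length_is_checked():
    with pytest.raises(ValueError, match="does not match"):
        CoefficientVector(espd.study_spec(), np.zeros(3))


# -- mixture proportions ----------------------------------------------------

def test_softmax_of_zero_scores_is_uniform():
    spec = toy_exponential_spec()
    X = pd.DataFrame({INTERCEPT: np.ones(4)})
    pi = espd.mixture_probs(spec, CoefficientVector.zeros(spec), X)
    np.testing.assert_allclose(pi, 0.5)


def test_mixture_probs_match_logit_of_reference_truth(spec, truth):
    X = pd.DataFrame({INTERCEPT: [1.0, 1.0], "stageIB": [0.0, 0.0],
                      "stageII": [0.0, 1.0], "age_c": [0.0, 0.0]})
    pi = espd.mixture_probs(spec, truth, X)
    assert pi[0, 0] == pytest.approx(invlogit(-0.4), rel=1e-12)
    assert pi[1, 0] == pytest.approx(invlogit(-0.4 + 0.8), rel=1e-12)


@given(st.lists(st.floats(-8, 8), min_size=10, max_size=10),
       st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_mixture_rows_are_probability_vectors(coefs, seed):
    spec = espd.study_spec()
    X = espd.draw_covariates(5, np.random.default_rng(seed))
    pi = espd.mixture_probs(spec, CoefficientVector(spec, np.array(coefs)), X)
    assert np.all(pi > 0) and np.all(pi < 1)
    np.testing.assert_allclose(pi.sum(axis=1), 1.0, atol=1e-12)


def test_mixture_probs_shape_mismatch_raises():
    spec = espd.study_spec()
    X = pd.DataFrame({INTERCEPT: [1.0]})  # missing stage columns
    with pytest.raises(DataError, match="missing column"):
        espd.mixture_probs(spec, CoefficientVector.zeros(spec), X)


# -- log-likelihood ---------------------------------------------------------

def test_censored_at_time_zero_contributes_exactly_zero():
    spec = toy_exponential_spec()
    data = make_data([0.0], ["cens"])
    coefs = CoefficientVector(spec, np.array([0.7, -0.3, 0.4]))
    assert espd.loglik(data, spec, coefs) == pytest.approx(0.0, abs=1e-14)


def test_observed_event_at_zero_with_unit_exponentials():
    spec = toy_exponential_spec()
    data = make_data([0.0], ["e1"])
    ll = espd.loglik(data, spec, CoefficientVector.zeros(spec))
    assert ll == pytest.approx(math.log(0.5), abs=1e-12)


def test_all_censored_reduction_equals_mixture_survival_sum(spec, truth):
    rng = np.random.default_rng(3)
    X = espd.draw_covariates(50, rng)
    t = rng.uniform(0.1, 20.0, 50)
    data = CompetingRisksDataset(t, np.array(["cens"] * 50, object), X)
    ll = espd.loglik(data, spec, truth)
    pi = espd.mixture_probs(spec, truth, X)
    shp, sc = np.exp(0.7), np.exp(
        X[["intercept", "stageIB", "stageII"]].to_numpy()
        @ np.array([2.0, -0.2, -0.6]))
    s_rec = np.exp(-(t / sc) ** shp)
    rate = np.exp(-3.5 + 0.1 * X["age_c"].to_numpy())
    s_dth = np.exp(-(rate / 0.1) * np.expm1(0.1 * t))
    expected = np.sum(np.log(pi[:, 0] * s_rec + pi[:, 1] * s_dth))
    assert ll == pytest.approx(expected, abs=1e-10)


def test_label_permutation_leaves_loglik_unchanged():
    rng = np.random.default_rng(9)
    n = 40
    X = pd.DataFrame({INTERCEPT: np.ones(n), "z": rng.normal(size=n)})
    t = rng.uniform(0.05, 5.0, n)
    e = rng.choice(["a", "b", "cens"], n)
    spec_ab = ESPDSpec(event_names=("a", "b"),
                       families={"a": "weibull", "b": "exponential"},
                       reference_event="a",
                       pi_covariates=(INTERCEPT, "z"),
                       theta_covariates={"a": {"scale": (INTERCEPT, "z")}})
    spec_ba = ESPDSpec(event_names=("b", "a"),
                       families={"a": "weibull", "b": "exponential"},
                       reference_event="a",
                       pi_covariates=(INTERCEPT, "z"),
                       theta_covariates={"a": {"scale": (INTERCEPT, "z")}})
    vals = {"pi.b": [0.3, -0.2], "theta.a.shape": [0.4],
            "theta.a.scale": [1.1, 0.2], "theta.b.rate": [-0.5]}
    data = CompetingRisksDataset(t, e.astype(object), X)
    ll_ab = espd.loglik(data, spec_ab,
                        CoefficientVector.from_dict(spec_ab, vals))
    ll_ba = espd.loglik(data, spec_ba,
                        CoefficientVector.from_dict(spec_ba, vals))
    assert ll_ab == pytest.approx(ll_ba, abs=1e-12)


def test_underflow_returns_minus_inf_sentinel_not_nan():
    spec = toy_exponential_spec()
    data = make_data([1e6], ["e1"])
    coefs = CoefficientVector(spec, np.array([0.0, 800.0, 0.0]))  # rate e^800
    ll = espd.loglik(data, spec, coefs)
    assert ll == -np.inf and not np.isnan(ll)


def test_loglik_equals_sum_of_per_row_contributions(spec, truth):
    rng = np.random.default_rng(12)
    X = espd.draw_covariates(30, rng)
    data = espd.apply_censoring(espd.simulate_espd((spec, truth), X, rng),
                                0.3, rng)
    total = espd.loglik(data, spec, truth)
    rowsum = sum(espd.loglik(data.subset([i]), spec, truth)
                 for i in range(data.n))
    assert total == pytest.approx(rowsum, abs=1e-9)


# -- conditional event-type probabilities -----------------------------------

def test_conditional_probs_at_zero_equal_mixture(spec, truth):
    x = {"intercept": 1.0, "stageIB": 1.0, "stageII": 0.0, "age_c": 2.0}
    p0 = espd.conditional_event_probs(spec, truth, x, 0.0)
    pi = espd.mixture_probs(spec, truth, pd.DataFrame([x]))[0]
    np.testing.assert_allclose(p0, pi, atol=1e-12)
    assert p0.sum() == pytest.approx(1.0)


def test_conditional_probs_normalise_survival_products():
    spec = toy_exponential_spec()
    # equal mixture, rates chosen so S1(t)=0.8, S2(t)=0.2 at t=1
    coefs = CoefficientVector.from_dict(spec, {
        "pi.e1": [0.0],
        "theta.e1.rate": [np.log(-np.log(0.8))],
        "theta.e2.rate": [np.log(-np.log(0.2))]})
    p = espd.conditional_event_probs(spec, coefs, {INTERCEPT: 1.0}, 1.0)
    np.testing.assert_allclose(p, [0.8, 0.2], atol=1e-12)


def test_conditional_probs_match_scalar_oracle_at_reference_truth(spec, truth):
    """Stage IA, age at the mean, censored at t=5: pi1 S1 / sum."""
    t = 5.0
    pi1 = invlogit(-0.4)
    s1 = math.exp(-((t / math.exp(2.0)) ** math.exp(0.7)))
    rate = math.exp(-3.5)
    s2 = math.exp(-(rate / 0.1) * (math.exp(0.1 * t) - 1.0))
    expected = pi1 * s1 / (pi1 * s1 + (1 - pi1) * s2)
    x = {"intercept": 1.0, "stageIB": 0.0, "stageII": 0.0, "age_c": 0.0}
    p = espd.conditional_event_probs(spec, truth, x, t)
    assert p[0] == pytest.approx(expected, abs=1e-12)


def test_conditional_probs_error_when_survival_underflows():
    spec = toy_exponential_spec()
    coefs = CoefficientVector.from_dict(spec, {"pi.e1": [0.0],
                                               "theta.e1.rate": [3.0],
                                               "theta.e2.rate": [3.0]})
    with pytest.raises(FloatingPointError, match="rescal"):
        espd.conditional_event_probs(spec, coefs, {INTERCEPT: 1.0}, 1e6)


# -- dataset validation -----------------------------------------------------

def test_dataset_rejects_mismatched_lengths_and_negative_times():
    X = pd.DataFrame({INTERCEPT: [1.0, 1.0]})
    with pytest.raises(DataError):
        CompetingRisksDataset(np.array([1.0]), np.array(["e1", "e2"]), X)
    with pytest.raises(DataError):
        CompetingRisksDataset(np.array([1.0, -2.0]),
                              np.array(["e1", "e2"], object), X)


def test_unknown_event_labels_are_reported_with_rows(spec):
    X = espd.draw_covariates(3, np.random.default_rng(0))
    data = CompetingRisksDataset(np.ones(3),
                                 np.array(["recur", "dead", "cens"], object),
                                 X)
    with pytest.raises(DataError, match="dead"):
        data.validate_labels(spec)
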