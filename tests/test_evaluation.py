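"""Metrics, prevalence adjustment, Monte-Carlo tests, ROC comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hpsig import (ConfusionCounts, adjusted_ppv, baseline_rate_test,
                   confusion_metrics, performance_difference_test)
from hpsig.evaluation import compare_classifiers, roc_points, trapezoid_auc


# ---------------------------------------------------------------------------
# confusion metrics

@pytest.mark.parametrize("counts, expected", [
    # published ADNI1 MCI worked example: 87 flagged, 81 progressors,
    # cohort 147 pMCI + 88 sMCI
    (ConfusionCounts(81, 6, 82, 66),
     {"ppv": 0.9310, "specificity": 0.9318, "sensitivity": 0.5510}),
    # published ADNI2 MCI worked example: 32 flagged, 26 progressors,
    # cohort 55 pMCI + 180 sMCI
    (ConfusionCounts(26, 6, 174, 29),
     {"ppv": 0.8125, "specificity": 0.9667, "sensitivity": 0.4727,
      "accuracy": 0.8511}),
])
def test_worked_examples_from_printed_counts(counts, expected):
    m = confusion_metrics(counts).as_dict()
    for key, value in expected.items():
        assert m[key] == pytest.approx(value, abs=5e-4)


def test_perfect_prediction_and_undefined_denominators():
    m = confusion_metrics(ConfusionCounts(10, 0, 10, 0))
    assert (m.sensitivity, m.specificity, m.ppv, m.accuracy) == (1, 1, 1, 1)
    m = confusion_metrics(ConfusionCounts(0, 0, 5, 5))
    assert np.isnan(m.ppv) and m.specificity == 1.0
    with pytest.raises(ValueError):
        ConfusionCounts(0, 0, 0, 0)
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 1, 0)


# ---------------------------------------------------------------------------
# prevalence-adjusted PPV

@pytest.mark.parametrize("sens, spec, expected", [
    (81 / 147, 82 / 88, 0.804),     # ADNI1 MCI detection
    (26 / 55, 174 / 180, 0.878),    # ADNI2 MCI detection
    (0.564, 0.950, 0.851),          # cognition-only model, second cohort
    (0.429, 0.899, 0.682),          # atrophy-only model, first cohort
])
def test_adjusted_ppv_reproduces_published_values(sens, spec, expected):
    assert adjusted_ppv(sens, spec, 0.336) == pytest.approx(expected, abs=1e-3)


def test_adjusted_ppv_edge_cases():
    assert adjusted_ppv(0.5, 1.0, 0.336) == 1.0       # no false positives
    assert np.isnan(adjusted_ppv(0.0, 1.0, 0.336))    # no calls at all
    with pytest.raises(ValueError):
        adjusted_ppv(1.5, 0.5, 0.336)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(s=st.floats(0.05, 0.95), sp=st.floats(0.05, 0.95), p=st.floats(0.05, 0.95),
       eps=st.floats(0.01, 0.04))
def test_adjusted_ppv_monotone_in_each_argument(s, sp, p, eps):
    base = adjusted_ppv(s, sp, p)
    assert adjusted_ppv(s + eps, sp, p) > base
    assert adjusted_ppv(s, min(sp + eps, 1.0), p) > base
    assert adjusted_ppv(s, sp, p + eps) > base


def test_adjusted_ppv_at_sample_prevalence_equals_raw_ppv():
    counts = ConfusionCounts(26, 6, 174, 29)
    m = confusion_metrics(counts)
    prevalence = (counts.tp + counts.fn) / counts.total
    assert adjusted_ppv(m.sensitivity, m.specificity, prevalence) == pytest.approx(m.ppv)


# ---------------------------------------------------------------------------
# Bernoulli Monte-Carlo performance test

def _metrics(sens, spec):
    from hpsig.evaluation import PerformanceMetrics
    return PerformanceMetrics(sensitivity=sens, specificity=spec,
                              ppv=np.nan, accuracy=np.nan)


def test_identical_models_are_not_flagged_different():
    a = _metrics(0.7, 0.8)
    res = performance_difference_test(a, _metrics(0.7, 0.8), n_positive=200,
                                      n_negative=200, reps=20_000, seed=0)
    assert res.p_values["sensitivity"] > 0.05
    assert res.p_values["specificity"] > 0.05


def test_large_difference_matches_exact_binomial_tail():
    """Null sensitivity 0.9 vs observed 0.5 at n=100: the Monte-Carlo tail
    agrees with the exact binomial tail, and both give p < 0.001."""
    a = _metrics(0.9, 0.9)
    b = _metrics(0.5, 0.9)
    res = performance_difference_test(a, b, n_positive=100, n_negative=100,
                                      reps=100_000, seed=1)
    exact = stats.binom.cdf(50, 100, 0.9)
    assert res.p_values["sensitivity"] < 0.001 and exact < 0.001


def test_moderate_difference_matches_exact_tail_within_mc_error():
    a = _metrics(0.6, 0.8)
    b = _metrics(0.52, 0.8)
    reps = 100_000
    res = performance_difference_test(a, b, n_positive=100, n_negative=100,
                                      reps=reps, seed=2)
    exact = stats.binom.cdf(52, 100, 0.6)     # P(rep sens <= 0.52)
    se = np.sqrt(exact * (1 - exact) / reps)
    assert abs(res.p_values["sensitivity"] - exact) <= 3 * se + 2 / reps


def test_null_calibration_quick():
    """Under A == B with B's observed metrics drawn from the same Bernoulli
    model, p-values are (super-)uniform: P(p <= 0.05) stays near 0.05."""
    rng = np.random.default_rng(3)
    hits = 0
    meta = 200
    for i in range(meta):
        tp = rng.binomial(150, 0.7)
        fp = rng.binomial(150, 0.2)
        b = _metrics(tp / 150, 1 - fp / 150)
        res = performance_difference_test(_metrics(0.7, 0.8), b, 150, 150,
                                          reps=2000, seed=1000 + i)
        if res.p_values["sensitivity"] <= 0.05:
            hits += 1
    assert hits / meta <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / meta)


def test_reps_floor_enforced():
    with pytest.raises(ValueError, match="1000"):
        performance_difference_test(_metrics(0.5, 0.5), _metrics(0.5, 0.5),
                                    10, 10, reps=10)


# ---------------------------------------------------------------------------
# baseline-rate binomial test

def test_baseline_rate_test_examples():
    assert baseline_rate_test(32, 26, 0.306) < 1e-6
    # hit count at the expectation -> p near one half
    assert 0.3 < baseline_rate_test(100, 30, 0.30) < 0.7
    assert baseline_rate_test(20, 20, 1.0) == 1.0
    with pytest.raises(ValueError):
        baseline_rate_test(10, 11, 0.5)
    with pytest.raises(ValueError):
        baseline_rate_test(10, 5, 1.5)


# ---------------------------------------------------------------------------
# ROC / AUC

def test_auc_matches_exhaustive_pair_enumeration():
    rng = np.random.default_rng(4)
    truth = rng.integers(0, 2, 40).astype(bool)
    truth[0], truth[1] = True, False
    scores = rng.standard_normal(40) + truth
    pts = roc_points(truth, scores)
    auc = trapezoid_auc(pts["fpr"].to_numpy(), pts["tpr"].to_numpy())
    pairs = [(si, sj) for si, ti in zip(scores, truth) if ti
             for sj, tj in zip(scores, truth) if not tj]
    exact = np.mean([1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs])
    assert auc == pytest.approx(exact, abs=1e-12)


def test_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(5)
    truth = rng.integers(0, 2, 60).astype(bool)
    truth[:2] = [True, False]
    scores = rng.standard_normal(60) + 0.8 * truth
    a1 = trapezoid_auc(*roc_points(truth, scores).iloc[:, :2].to_numpy().T)
    a2 = trapezoid_auc(*roc_points(truth, np.exp(scores)).iloc[:, :2].to_numpy().T)
    assert a1 == pytest.approx(a2)


def test_compare_classifiers_on_separable_and_null_data(fast_config):
    from conftest import toy_feature_table

    train = toy_feature_table(n_per_class=25, sep=8.0, seed=6)
    test = toy_feature_table(n_per_class=25, sep=8.0, seed=7)
    aucs, curves = compare_classifiers(train, test, fast_config)
    assert set(aucs["model"]) == {"rbf_svm", "knn", "random_forest",
                                  "gaussian_nb", "linear_svm", "hps"}
    assert (aucs["auc"] > 0.99).all()          # separable task
    assert set(curves) == set(aucs["model"])

    # label-free features: every AUC hovers near chance
    null_train = toy_feature_table(n_per_class=100, sep=0.0, seed=8)
    null_test = toy_feature_table(n_per_class=100, sep=0.0, seed=9)
    aucs_null, _ = compare_classifiers(null_train, null_test, fast_config,
                                       fit_two_stage=False)
    assert ((aucs_null["auc"] - 0.5).abs() < 0.1).all()


def test_compare_classifiers_rejects_single_class_test(fast_config):
    from conftest import toy_feature_table

    train = toy_feature_table(n_per_class=15, sep=8.0, seed=10)
    test = toy_feature_table(n_per_class=15, sep=8.0, seed=11)
    test["diagnosis"] = "CN"
    with pytest.raises(ValueError, match="both classes"):
        compare_classifiers(train, test, fast_config)
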