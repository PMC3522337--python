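"""Gaussian Bayes classifier: fitting, thresholds, classification, severity."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from airtrapcad.classifier import (
    BayesRule,
    GaussianClassModel,
    classify,
    decision_thresholds,
    fit_class_models,
    fit_severity_lines,
    likelihood_ratio,
    load_models,
    posterior_patient,
    save_models,
    severity_score,
)
from airtrapcad.errors import FitError, ParameterError
from airtrapcad.features import FeatureRecord
from airtrapcad.phantom import COHORT_NORMAL, COHORT_PATIENT

AREA_MODELS = (
    GaussianClassModel("normal", 0.3711, 0.0825, 12 / 37),
    GaussianClassModel("patient", 0.1749, 0.2341, 25 / 37),
)
VOLUME_MODELS = (
    GaussianClassModel("normal", 0.4121, 0.0762, 12 / 37),
    GaussianClassModel("patient", 0.1996, 0.1981, 25 / 37),
)


def grid_search_crossings(models, lo, hi, step=1e-6):
    """Independent oracle: posterior log-difference sign changes on a grid."""
    m1, m2 = models
    x = np.arange(lo, hi, step)
    diff = (
        np.log(m1.prior)
        - np.log(m1.sigma)
        - 0.5 * ((x - m1.mu) / m1.sigma) ** 2
        - np.log(m2.prior)
        + np.log(m2.sigma)
        + 0.5 * ((x - m2.mu) / m2.sigma) ** 2
    )
    signs = np.sign(diff)
    idx = np.nonzero(signs[1:] * signs[:-1] < 0)[0]
    return x[idx]


# --------------------------------------------------------------------------
# Fitting

def test_fit_closed_form_and_priors():
    models = fit_class_models([0, 2, 5, 6, 7], ["normal"] * 2 + ["patient"] * 3)
    normal, patient = models
    assert normal.mu == 1.0
    assert normal.sigma == pytest.approx(math.sqrt(2))
    assert normal.prior == pytest.approx(2 / 5)
    assert patient.prior == pytest.approx(3 / 5)

    eq = fit_class_models([0, 2, 5, 6, 7], ["normal"] * 2 + ["patient"] * 3, "equal")
    assert eq[0].prior == eq[1].prior == 0.5


def test_fit_cohort_sizes_give_study_priors():
    values = list(range(37))
    labels = ["normal"] * 12 + ["patient"] * 25
    normal, patient = fit_class_models(values, labels)
    assert normal.prior == pytest.approx(12 / 37)
    assert patient.prior == pytest.approx(25 / 37)


def test_fit_errors_name_the_class():
    with pytest.raises(FitError, match="patient"):
        fit_class_models([1, 2, 3], ["normal", "normal", "patient"])
    with pytest.raises(FitError, match="normal"):
        fit_class_models([1, 1, 2, 3], ["normal", "normal", "patient", "patient"])


def test_parameter_recovery_from_large_draws():
    rng = np.random.default_rng(33)
    n = 100_000
    a = rng.normal(0.3711, 0.0825, n)
    b = rng.normal(0.1749, 0.2341, n)
    normal, patient = fit_class_models(
        np.concatenate([a, b]), ["normal"] * n + ["patient"] * n
    )
    assert normal.mu == pytest.approx(0.3711, rel=0.01)
    assert normal.sigma == pytest.approx(0.0825, rel=0.01)
    assert patient.mu == pytest.approx(0.1749, rel=0.01)
    assert patient.sigma == pytest.approx(0.2341, rel=0.01)


# --------------------------------------------------------------------------
# Likelihood ratio and thresholds

def test_likelihood_ratio_trivial_cases():
    same = (
        GaussianClassModel("normal", 0.3, 0.1, 0.5),
        GaussianClassModel("patient", 0.3, 0.1, 0.5),
    )
    rule = BayesRule("delta_V_N", same)
    for x in (-1.0, 0.0, 0.3, 2.0):
        assert likelihood_ratio(x, rule) == pytest.approx(1.0)

    sym = (
        GaussianClassModel("normal", 0.0, 1.0, 0.5),
        GaussianClassModel("patient", 2.0, 1.0, 0.5),
    )
    assert likelihood_ratio(1.0, BayesRule("delta_V_N", sym)) == pytest.approx(1.0)


def test_likelihood_ratio_matches_density_formula():
    rule = BayesRule("delta_S_N", AREA_MODELS)

    def gauss(x, mu, s):
        return math.exp(-((x - mu) ** 2) / (2 * s * s)) / (s * math.sqrt(2 * math.pi))

    for x in (-0.1, 0.05, 0.2, 0.3711, 0.5, 0.9):
        expected = gauss(x, 0.3711, 0.0825) / gauss(x, 0.1749, 0.2341)
        assert likelihood_ratio(x, rule) == pytest.approx(expected, rel=1e-12)


def test_threshold_symmetric_single_root():
    models = (
        GaussianClassModel("normal", 0.0, 1.0, 0.5),
        GaussianClassModel("patient", 2.0, 1.0, 0.5),
    )
    roots = decision_thresholds(models)
    assert len(roots) == 1
    assert roots[0] == pytest.approx(1.0)


def test_threshold_equal_means_gives_symmetric_pair():
    models = (
        GaussianClassModel("normal", 0.5, 0.1, 0.5),
        GaussianClassModel("patient", 0.5, 0.3, 0.5),
    )
    roots = decision_thresholds(models)
    assert len(roots) == 2
    assert roots[0] + roots[1] == pytest.approx(1.0)  # symmetric about 0.5


@pytest.mark.parametrize("models", [AREA_MODELS, VOLUME_MODELS])
def test_threshold_matches_grid_search_oracle(models):
    """The analytic between-means root agrees with a brute-force posterior
    crossing search at 1e-6 resolution."""
    roots = decision_thresholds(models)
    primary = roots[0]
    assert models[1].mu < primary < models[0].mu
    crossings = grid_search_crossings(models, 0.0, 1.0)
    assert min(abs(primary - c) for c in crossings) < 1e-6


@given(
    mu1=st.floats(0.25, 0.9),
    mu2=st.floats(0.0, 0.24),
    s1=st.floats(0.03, 0.4),
    s2=st.floats(0.03, 0.4),
    p1=st.floats(0.1, 0.9),
)
def test_posterior_equality_at_every_threshold(mu1, mu2, s1, s2, p1):
    models = (
        GaussianClassModel("normal", mu1, s1, p1),
        GaussianClassModel("patient", mu2, s2, 1 - p1),
    )
    for r in decision_thresholds(models):
        post = posterior_patient(r, BayesRule("delta_V_N", models))
        assert abs(post - 0.5) < 1e-8


# --------------------------------------------------------------------------
# Classification

def test_classify_at_normal_mean_is_normal():
    rule = BayesRule("delta_S_N", AREA_MODELS)
    rec = FeatureRecord("s", delta_S_N=0.3711, delta_V_N=0.0)
    label, post = classify(rec, rule)
    assert label == "normal"
    assert post < 0.5


def test_tie_at_threshold_goes_to_patient():
    models = (
        GaussianClassModel("normal", 0.0, 1.0, 0.5),
        GaussianClassModel("patient", 2.0, 1.0, 0.5),
    )
    label, post = classify(1.0, BayesRule("delta_V_N", models))
    assert post == pytest.approx(0.5)
    assert label == "patient"


@given(
    x=st.floats(-1.0, 2.0),
    mu1=st.floats(0.0, 1.0),
    mu2=st.floats(0.0, 1.0),
    s1=st.floats(0.02, 0.5),
    s2=st.floats(0.02, 0.5),
    p1=st.floats(0.05, 0.95),
)
def test_likelihood_ratio_rule_equals_posterior_rule(x, mu1, mu2, s1, s2, p1):
    """For any x and models, deciding by l_r(x) vs the prior ratio gives the
    same label as comparing posteriors."""
    models = (
        GaussianClassModel("normal", mu1, s1, p1),
        GaussianClassModel("patient", mu2, s2, 1 - p1),
    )
    rule = BayesRule("delta_V_N", models)
    lr = float(likelihood_ratio(x, rule))
    by_lr = "normal" if lr > (1 - p1) / p1 else "patient"
    by_post, _ = classify(x, rule)
    assert by_lr == by_post


# --------------------------------------------------------------------------
# Severity lines and scoring

def _records(xs, ys, label):
    return [
        FeatureRecord(f"{label}{i}", float(x), float(y), label)
        for i, (x, y) in enumerate(zip(xs, ys))
    ]


def test_ols_exact_on_constructed_line():
    xs = np.linspace(0.2, 0.5, 10)
    recs = _records(xs, 0.855 * xs + 0.095, "normal")
    recs += _records(xs, 0.626 * xs + 0.079, "patient")
    fits = fit_severity_lines(recs)
    assert fits["normal"].slope == pytest.approx(0.855, abs=1e-12)
    assert fits["normal"].intercept == pytest.approx(0.095, abs=1e-12)
    assert fits["normal"].r_squared == pytest.approx(1.0, abs=1e-12)
    assert fits["patient"].slope == pytest.approx(0.626, abs=1e-12)


def test_ols_constant_response_has_zero_slope_and_r2():
    xs = np.linspace(0.0, 1.0, 8)
    recs = _records(xs, np.full_like(xs, 0.3), "normal")
    recs += _records(xs, xs, "patient")
    fits = fit_severity_lines(recs)
    assert fits["normal"].slope == pytest.approx(0.0, abs=1e-12)
    assert fits["normal"].r_squared == pytest.approx(0.0, abs=1e-12)


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(4)
    xs = rng.uniform(0, 1, 40)
    ys = 0.7 * xs + 0.1 + rng.normal(0, 0.05, 40)
    recs = _records(xs, ys, "normal") + _records(xs, ys + 0.2, "patient")
    fits = fit_severity_lines(recs)
    # closed-form normal equations
    sxx = ((xs - xs.mean()) ** 2).sum()
    sxy = ((xs - xs.mean()) * (ys - ys.mean())).sum()
    slope = sxy / sxx
    intercept = ys.mean() - slope * xs.mean()
    assert fits["normal"].slope == pytest.approx(slope, abs=1e-10)
    assert fits["normal"].intercept == pytest.approx(intercept, abs=1e-10)


def test_ols_degenerate_x_is_fit_error():
    recs = _records([0.3] * 5, np.linspace(0, 1, 5), "normal")
    recs += _records(np.linspace(0, 1, 5), np.linspace(0, 1, 5), "patient")
    with pytest.raises(FitError):
        fit_severity_lines(recs)


def test_severity_score_fields():
    rule = BayesRule("delta_V_N", VOLUME_MODELS)
    xs = np.linspace(0.2, 0.5, 10)
    fits = fit_severity_lines(
        _records(xs, 0.855 * xs + 0.095, "normal")
        + _records(xs, 0.626 * xs + 0.079, "patient")
    )
    at_mean = FeatureRecord("a", 0.3, 0.4121)
    rep = severity_score(at_mean, rule, fits)
    assert rep["air_trapping_z"] == pytest.approx(0.0)
    one_sd = FeatureRecord("b", 0.3, 0.4121 - 0.0762)
    assert severity_score(one_sd, rule, fits)["air_trapping_z"] == pytest.approx(1.0)
    again = severity_score(at_mean, rule, fits)
    assert rep == again
    assert all(np.isfinite(v) for v in rep.values())


def test_model_json_roundtrip(tmp_path):
    rule = BayesRule("delta_V_N", VOLUME_MODELS)
    rule.thresholds = decision_thresholds(VOLUME_MODELS)
    xs = np.linspace(0.2, 0.5, 10)
    fits = fit_severity_lines(
        _records(xs, 0.855 * xs + 0.095, "normal")
        + _records(xs, 0.626 * xs + 0.079, "patient")
    )
    save_models(tmp_path / "m.json", {"delta_V_N": rule}, fits)
    rules, fits2 = load_models(tmp_path / "m.json")
    assert rules["delta_V_N"].thresholds == rule.thresholds
    assert rules["delta_V_N"].models[0].mu == 0.4121
    assert fits2["normal"].slope == fits["normal"].slope
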