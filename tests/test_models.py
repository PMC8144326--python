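"""Validity models: ML correctness, random-intercept recovery, reporting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from icfms.exceptions import ValidationError
from icfms.models import (
    LogitSpec,
    _binary_nll,
    fit_death_logit,
    fit_grade_ologit,
    model_report,
)
from icfms.synthetic import generate_clustered_binary, generate_clustered_ordinal
from numpy.polynomial.hermite import hermgauss


@pytest.fixture(scope="module")
def binary_data():
    return generate_clustered_binary(
        200, 10, {"x1": 1.0, "x2": -0.5}, intercept=-1.0, sigma_u=0.0, seed=5
    ).rename(columns={"y": "dead"})


@pytest.fixture(scope="module")
def ordinal_data():
    return generate_clustered_ordinal(
        300, 10, {"x1": 0.8}, sigma_u=0.0, seed=9
    ).rename(columns={"y": "grade"})


def test_plain_logit_matches_statsmodels(binary_data):
    r = fit_death_logit(binary_data, LogitSpec("dead", ("x1", "x2")))
    ref = sm.Logit(
        binary_data["dead"], sm.add_constant(binary_data[["x1", "x2"]])
    ).fit(disp=0)
    np.testing.assert_allclose(r.params.values, ref.params.values, atol=1e-5)
    np.testing.assert_allclose(r.bse.values, ref.bse.values, rtol=1e-3)
    assert r.loglik == pytest.approx(ref.llf, abs=1e-6)


def test_plain_ologit_matches_statsmodels(ordinal_data):
    r = fit_grade_ologit(ordinal_data, LogitSpec("grade", ("x1",)))
    ref = OrderedModel(
        ordinal_data["grade"], ordinal_data[["x1"]], distr="logit"
    ).fit(method="bfgs", disp=0)
    assert r.params["x1"] == pytest.approx(ref.params["x1"], abs=1e-4)
    ref_thresholds = ref.model.transform_threshold_params(ref.params.values)[1:-1]
    np.testing.assert_allclose(r.thresholds, ref_thresholds, atol=1e-4)
    assert r.loglik == pytest.approx(ref.llf, abs=1e-5)


def test_predictor_free_thresholds_are_cumulative_logits(ordinal_data):
    r = fit_grade_ologit(ordinal_data, LogitSpec("grade", ()))
    freq = np.bincount(ordinal_data["grade"], minlength=6)[1:]
    cum = np.cumsum(freq)[:-1] / freq.sum()
    np.testing.assert_allclose(r.thresholds, np.log(cum / (1 - cum)), atol=1e-6)
    assert np.all(np.diff(r.thresholds) > 0)


def test_constant_outcome_is_rejected():
    df = pd.DataFrame({"dead": [0] * 20, "x1": np.arange(20.0)})
    with pytest.raises(ValidationError, match="variation"):
        fit_death_logit(df, LogitSpec("dead", ("x1",)))


def test_missing_outcome_level_refused(ordinal_data):
    sub = ordinal_data[ordinal_data["grade"] != 3]
    with pytest.raises(ValidationError, match=r"\[3\]"):
        fit_grade_ologit(sub, LogitSpec("grade", ("x1",)))


def test_mixed_logit_recovers_truth():
    d = generate_clustered_binary(
        300, 12, {"x1": 1.0, "x2": -0.5}, intercept=-1.0, sigma_u=1.0, seed=7
    ).rename(columns={"y": "dead"})
    r = fit_death_logit(d, LogitSpec("dead", ("x1", "x2"), grouping="cluster"))
    for name, truth in (("const", -1.0), ("x1", 1.0), ("x2", -0.5)):
        assert abs(r.params[name] - truth) < 3 * r.bse[name]
    assert 0.4 < r.sigma2_u < 2.5
    assert r.lr_stat is not None and r.lr_stat >= 0
    assert r.n_groups == 300


def test_mixed_ologit_recovers_truth():
    thresholds = (-2.0, -0.7, 0.7, 2.0)
    d = generate_clustered_ordinal(
        300, 12, {"x1": 0.8, "x2": -0.4}, thresholds, sigma_u=1.0, seed=11
    ).rename(columns={"y": "grade"})
    r = fit_grade_ologit(d, LogitSpec("grade", ("x1", "x2"), grouping="cluster"))
    assert abs(r.params["x1"] - 0.8) < 3 * r.bse["x1"]
    assert abs(r.params["x2"] + 0.4) < 3 * r.bse["x2"]
    for k, t in enumerate(thresholds):
        assert abs(r.thresholds[k] - t) < 3 * r.threshold_bse[k]
    assert np.all(np.diff(r.thresholds) > 0)
    assert r.sigma2_u > 0.3


def test_mixed_likelihood_collapses_to_plain_at_zero_variance(binary_data):
    """GHQ marginal likelihood at sigma ~ 0 equals the ordinary logit one."""
    X = np.column_stack(
        [np.ones(len(binary_data)), binary_data[["x1", "x2"]].to_numpy()]
    )
    y = binary_data["dead"].to_numpy()
    groups = binary_data["cluster"].to_numpy()
    nodes, weights = hermgauss(15)
    theta = np.array([-1.0, 1.0, -0.5])
    plain = _binary_nll(theta, X, y, None, None, nodes, weights, 0.0)
    tiny = _binary_nll(
        np.append(theta, -30.0), X, y, groups, int(groups.max()) + 1,
        nodes, weights, None,
    )
    assert tiny == pytest.approx(plain, rel=1e-6)


def test_lr_statistic_invariant_to_predictor_order():
    d = generate_clustered_binary(
        80, 6, {"x1": 0.8, "x2": -0.3}, sigma_u=0.8, seed=13
    ).rename(columns={"y": "dead"})
    a = fit_death_logit(d, LogitSpec("dead", ("x1", "x2"), grouping="cluster"))
    b = fit_death_logit(d, LogitSpec("dead", ("x2", "x1"), grouping="cluster"))
    assert a.lr_stat == pytest.approx(b.lr_stat, abs=1e-5)
    assert a.loglik == pytest.approx(b.loglik, abs=1e-6)


def test_singleton_clusters_warn_but_fit():
    d = generate_clustered_binary(150, 1, {"x1": 1.0}, sigma_u=0.5, seed=17).rename(
        columns={"y": "dead"}
    )
    with pytest.warns(UserWarning, match="singleton"):
        r = fit_death_logit(d, LogitSpec("dead", ("x1",), grouping="cluster"))
    assert np.isfinite(r.loglik)


def test_wald_interval_coverage_near_nominal():
    """95% Wald CIs cover the true slope at the nominal rate (+- 6 pp)."""
    beta = 0.8
    covered = 0
    reps = 50
    for s in range(reps):
        d = generate_clustered_binary(
            1, 400, {"x1": beta}, intercept=-0.5, sigma_u=0.0, seed=1000 + s
        ).rename(columns={"y": "dead"})
        r = fit_death_logit(d, LogitSpec("dead", ("x1",)))
        lo = r.params["x1"] - 1.96 * r.bse["x1"]
        hi = r.params["x1"] + 1.96 * r.bse["x1"]
        covered += int(lo <= beta <= hi)
    assert covered >= int(np.ceil((0.95 - 0.06) * reps))


def test_model_report_layout():
    d = generate_clustered_ordinal(100, 8, {"x1": 0.8}, sigma_u=0.8, seed=3).rename(
        columns={"y": "grade"}
    )
    r = fit_grade_ologit(d, LogitSpec("grade", ("x1",), grouping="cluster"))
    text = model_report({"all": r})
    assert "Threshold parameter 4" in text
    assert "/lnsig2u" in text
    assert "LR test" in text
    assert "* p < 0.1, ** p < 0.05, *** p < 0.01" in text
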