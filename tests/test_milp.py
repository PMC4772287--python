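"""Best-subset LAD regression: exact cases, oracle equivalence, CV, transfer."""

import numpy as np
import pandas as pd
import pytest

from regact.errors import UndefinedCorrelationError
from regact.milp import (
    RegressionProblem,
    activity_response_correlation,
    bottom_up_scan,
    fit_lad_subset,
    loo_cv_performance,
    transfer_predict,
)
from regact.simulate import GroundTruth, generate_regulatory_dataset

from _oracles import best_subset_lad_objective


def _random_problem(rng, T, l):
    effects = pd.DataFrame(
        rng.normal(size=(T, l)),
        index=[f"TF{i}" for i in range(T)],
        columns=[f"S{j}" for j in range(l)],
    )
    response = pd.Series(rng.normal(size=l), index=effects.columns)
    return RegressionProblem(effects, response)


def test_exact_single_regulator_construction():
    """Response built as 2·eff_TF1 + 0.5 is recovered exactly at k = 1."""
    rng = np.random.default_rng(0)
    effects = pd.DataFrame(
        rng.normal(size=(3, 4)), index=["TF0", "TF1", "TF2"], columns=list("abcd")
    )
    response = 2.0 * effects.loc["TF1"] + 0.5
    model = fit_lad_subset(RegressionProblem(effects, response), k=1)
    assert model.selected == ["TF1"]
    assert model.coefficients["TF1"] == pytest.approx(2.0, abs=1e-6)
    assert model.intercept == pytest.approx(0.5, abs=1e-6)
    assert model.objective == pytest.approx(0.0, abs=1e-6)


def test_k_zero_intercept_is_median():
    effects = pd.DataFrame(np.zeros((2, 3)), index=["A", "B"], columns=list("xyz"))
    response = pd.Series([1.0, 2.0, 10.0], index=list("xyz"))
    model = fit_lad_subset(RegressionProblem(effects, response), k=0)
    assert model.intercept == pytest.approx(2.0)
    assert model.objective == pytest.approx(9.0)
    assert model.selected == []


def test_objective_monotone_in_k(small_problem):
    objs = [fit_lad_subset(small_problem, k).objective for k in range(0, 5)]
    assert all(a >= b - 1e-8 for a, b in zip(objs, objs[1:]))


def test_invalid_k_raises(small_problem):
    with pytest.raises(ValueError):
        fit_lad_subset(small_problem, k=5)
    with pytest.raises(ValueError):
        fit_lad_subset(small_problem, k=-1)


def test_milp_matches_enumeration_oracle_small():
    """MILP objective equals exhaustive best-subset LAD on random instances."""
    for seed in range(10):
        rng = np.random.default_rng(seed)
        problem = _random_problem(rng, T=6, l=10)
        A = problem.effects.to_numpy()
        y = problem.response.to_numpy()
        for k in (1, 2):
            milp_obj = fit_lad_subset(problem, k).objective
            oracle_obj = best_subset_lad_objective(A, y, k)
            assert milp_obj == pytest.approx(oracle_obj, abs=1e-6)


def test_selected_model_beats_forced_support(small_problem):
    """The chosen support is no worse than any other support of equal size."""
    best = fit_lad_subset(small_problem, k=1).objective
    A = small_problem.effects.to_numpy()
    y = small_problem.response.to_numpy()
    from _oracles import lad_objective_fixed_support

    for t in range(A.shape[0]):
        assert best <= lad_objective_fixed_support(A, y, (t,)) + 1e-6


def test_scale_consistency(small_problem):
    """Scaling the response by c > 0 scales β, β0, objective; selection fixed."""
    c = 3.7
    m1 = fit_lad_subset(small_problem, k=2)
    scaled = RegressionProblem(small_problem.effects, c * small_problem.response)
    m2 = fit_lad_subset(scaled, k=2)
    assert m1.selected == m2.selected
    assert m2.intercept == pytest.approx(c * m1.intercept, abs=1e-5)
    assert m2.objective == pytest.approx(c * m1.objective, rel=1e-6)
    pd.testing.assert_series_equal(m2.coefficients, c * m1.coefficients, atol=1e-5)


def test_non_nested_selection_possible():
    """Crafted instance where the best singleton is excluded from the best
    pair: a proxy regressor close to x1 + x2 wins at k = 1 but not at k = 2."""
    rng = np.random.default_rng(3)
    n = 12
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    proxy = (x1 + x2) / 2 + rng.normal(0, 0.05, n)
    effects = pd.DataFrame(
        [x1, x2, proxy], index=["TF1", "TF2", "PROXY"], columns=range(n)
    )
    response = pd.Series(x1 + x2, index=range(n))
    problem = RegressionProblem(effects, response)
    m1 = fit_lad_subset(problem, k=1)
    m2 = fit_lad_subset(problem, k=2)
    assert m1.selected == ["PROXY"]
    assert set(m2.selected) == {"TF1", "TF2"}
    assert m2.objective == pytest.approx(0.0, abs=1e-8)


def test_loo_cv_noise_free_planted():
    truth = GroundTruth(planted_tfs=(("TF01", 1.5),), noise_sd=0.0, bimodal={}, seed=5)
    data = generate_regulatory_dataset(truth, n_tfs=5, n_samples=20)
    problem = RegressionProblem(data.activities, data.response)
    pcc, preds = loo_cv_performance(problem, k=1)
    assert pcc >= 0.999
    assert list(preds.index) == list(problem.response.index)


def test_loo_cv_constant_response_error(small_problem):
    const = RegressionProblem(
        small_problem.effects, pd.Series(1.0, index=small_problem.effects.columns)
    )
    with pytest.raises(UndefinedCorrelationError):
        loo_cv_performance(const, k=1)


def test_loo_cv_null_mean_correlation_small():
    """With response independent of the regressors, held-out correlation
    hovers near zero (|mean r| well below chance-capitalisation levels)."""
    rs = []
    for seed in range(40):
        rng = np.random.default_rng(100 + seed)
        problem = _random_problem(rng, T=5, l=12)
        rs.append(loo_cv_performance(problem, k=1)[0])
    assert abs(np.mean(rs)) < 0.35


def test_bottom_up_scan_rows_and_errors(small_problem):
    result = bottom_up_scan(small_problem, k_max=2, cv=False)
    ks = [r["k"] for r in result.rows]
    assert ks == [1, 2]
    assert all(len(r["selected"]) <= r["k"] for r in result.rows)
    frame = result.to_frame()
    assert list(frame.columns) == ["k", "selected", "objective", "cv_pcc"]
    with pytest.raises(ValueError):
        bottom_up_scan(small_problem, k_max=10)


def test_transfer_identity_and_missing_tf(small_problem):
    model = fit_lad_subset(small_problem, k=2)
    preds, pcc = transfer_predict(model, small_problem.effects, small_problem.response)
    pd.testing.assert_series_equal(
        preds, model.predictions, check_names=False, atol=1e-9
    )
    dropped = small_problem.effects.drop(index=model.selected[0])
    with pytest.raises(KeyError, match=model.selected[0]):
        transfer_predict(model, dropped, small_problem.response)


def test_model_json_roundtrip(small_problem):
    model = fit_lad_subset(small_problem, k=1)
    from regact.milp import FittedLinearModel

    back = FittedLinearModel.from_json(model.to_json())
    assert back.intercept == pytest.approx(model.intercept)
    assert back.selected == model.selected
    pred = back.predict(small_problem.effects)
    pd.testing.assert_series_equal(pred, model.predictions, check_names=False, atol=1e-9)


def test_activity_response_correlation_properties(planted_problem, planted_dataset):
    corr = activity_response_correlation(
        planted_problem.effects, planted_problem.response
    )
    # the planted activator/inhibitor carry the signal: one of them ranks first
    planted = [tf for tf, _ in planted_dataset.truth.planted_tfs]
    assert corr.index[0] in planted
    betas = dict(planted_dataset.truth.planted_tfs)
    for tf, beta in betas.items():
        assert np.sign(corr[tf]) == np.sign(beta)
    # response equal to one TF's activity → r = 1 for that TF
    self_corr = activity_response_correlation(
        planted_problem.effects, planted_problem.effects.iloc[4]
    )
    assert self_corr.iloc[0] == pytest.approx(1.0)
    assert self_corr.index[0] == planted_problem.effects.index[4]


def test_constant_activity_row_reported_nan(small_problem):
    effects = small_problem.effects.copy()
    effects.loc["TF0"] = 1.0
    corr = activity_response_correlation(effects, small_problem.response)
    assert np.isnan(corr["TF0"])
    assert corr.index[-1] == "TF0"  # undefined rows sort last
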