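"""Estimating-equation fits checked against independent oracles.

The step/slope model is checked against an explicit normal-equations solve
and against statsmodels GEE with an independence working correlation; the
count model against statsmodels GLM-Poisson (the quasi-score solution).
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.genmod.cov_struct import Independence

import nccdid as nd
from nccdid.estimators import count_design, solve_ols, step_slope_design

from conftest import make_analysis_set


def random_panel(seed, n_persons=20, count=False):
    """Small random unbalanced panel with a binary X fixed per person."""
    rng = np.random.default_rng(seed)
    rows = {"x": [], "j": [], "y": [], "pid": [], "h": []}
    x_person = rng.permutation([0, 1] * (n_persons // 2))
    for i in range(n_persons):
        h = rng.normal()
        for j in range(rng.integers(1, 5)):
            rows["pid"].append(f"p{i}")
            rows["x"].append(x_person[i])
            rows["j"].append(j)
            rows["h"].append(h)
            if count:
                mu = np.exp(1.0 - 0.3 * x_person[i] + 0.1 * j)
                rows["y"].append(float(rng.poisson(mu)))
            else:
                rows["y"].append(50 + 3 * x_person[i] + 0.5 * j + rng.normal(0, 4))
    return rows


# -- step/slope model ----------------------------------------------------


def test_step_slope_exact_on_noise_free_data():
    """X=0: 50 + j; X=1: 55 + 2j  =>  (beta_0, St, Sl, J) = (50, 5, 1, 1)."""
    x, j, y, pid = [], [], [], []
    for i, xi in enumerate([0, 0, 1, 1]):
        for jj in range(4 if i % 2 else 3):  # uneven panel shape
            x.append(xi)
            j.append(jj)
            y.append(50 + jj if xi == 0 else 55 + 2 * jj)
            pid.append(f"p{i}")
    est = nd.fit_step_slope(make_analysis_set(x, j, y, persons=pid))
    assert np.allclose(
        [est.beta_0, est.beta_St, est.beta_Sl, est.beta_J], [50, 5, 1, 1], atol=1e-10
    )


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_step_slope_matches_normal_equations(seed):
    """Independence-working-correlation estimates equal the stacked
    least-squares normal-equations solution."""
    rows = random_panel(seed)
    est = nd.fit_step_slope(make_analysis_set(rows["x"], rows["j"], rows["y"],
                                              persons=rows["pid"]))
    x = np.asarray(rows["x"], float)
    j = np.asarray(rows["j"], float)
    design = np.column_stack([np.ones_like(x), x, x * j, j])
    beta = np.linalg.solve(design.T @ design, design.T @ np.asarray(rows["y"]))
    got = [est.beta_0, est.beta_St, est.beta_Sl, est.beta_J]
    assert np.allclose(got, beta, atol=1e-8)


def test_step_slope_matches_statsmodels_gee():
    rows = random_panel(7)
    aset = make_analysis_set(rows["x"], rows["j"], rows["y"], persons=rows["pid"])
    est = nd.fit_step_slope(aset)
    x = np.asarray(rows["x"], float)
    j = np.asarray(rows["j"], float)
    design = np.column_stack([np.ones_like(x), x, x * j, j])
    gee = sm.GEE(
        np.asarray(rows["y"]), design, groups=np.asarray(rows["pid"]),
        family=sm.families.Gaussian(), cov_struct=Independence(),
    ).fit()
    got = [est.beta_0, est.beta_St, est.beta_Sl, est.beta_J]
    assert np.allclose(got, gee.params, atol=1e-8)
    # cluster-robust sandwich diagnostic agrees with GEE's robust covariance
    se = [est.robust_se[k] for k in ("beta_0", "beta_St", "beta_Sl", "beta_J")]
    assert np.allclose(se, gee.bse, rtol=1e-4)


def test_step_slope_requires_two_x_levels():
    with pytest.raises(nd.CohortError, match="X=0"):
        make_analysis_set([1, 1, 1, 1], [0, 1, 0, 1], [1.0, 2, 3, 4])


def test_step_slope_rank_deficiency_names_columns():
    rows = random_panel(3)
    spec = nd.CovariateSpec.from_names(["h", "h2"])
    aset = make_analysis_set(
        rows["x"], rows["j"], rows["y"], persons=rows["pid"],
        cov={"h": rows["h"], "h2": [2 * v for v in rows["h"]]}, spec=spec,
    )
    with pytest.raises(nd.FitError, match="h2|h"):
        nd.fit_step_slope(aset)


def test_step_slope_order_invariance():
    rows = random_panel(11)
    aset = make_analysis_set(rows["x"], rows["j"], rows["y"], persons=rows["pid"])
    perm = np.random.default_rng(0).permutation(len(aset.data))
    shuffled = nd.AnalysisSet(
        data=aset.data.iloc[perm].reset_index(drop=True),
        contrast=aset.contrast,
        outcome_kind="continuous",
    )
    a, b = nd.fit_step_slope(aset), nd.fit_step_slope(shuffled)
    assert np.allclose(
        [a.beta_0, a.beta_St, a.beta_Sl, a.beta_J],
        [b.beta_0, b.beta_St, b.beta_Sl, b.beta_J],
        atol=1e-10,
    )


def test_step_slope_recovers_truth_at_large_n():
    """Bias shrinks with n: true (step, slope) recovered within 3 SEs."""
    cfg = nd.scenario_config("scenario1", n_g1=2000, n_g0=100, seed=9)
    cohort = nd.simulate_cohort(cfg)
    aset = nd.build_contrast(cohort, nd.ContrastKind.NTE_P)
    est = nd.fit_step_slope(aset)
    assert abs(est.beta_St - cfg.delta_St) < 3 * est.robust_se["beta_St"]
    assert abs(est.beta_Sl - cfg.delta_Sl) < 3 * est.robust_se["beta_Sl"]


# -- count model ---------------------------------------------------------


def test_count_effects_exact_on_multiplicative_data():
    """X=0 rate 10 at every visit, X=1 rates (5, 4, 3) => RRs (.5, .4, .3)."""
    x, j, y, pid = [], [], [], []
    for i in range(4):
        xi = i % 2
        for jj in range(3):
            x.append(xi)
            j.append(jj)
            y.append([10, 10, 10][jj] if xi == 0 else [5, 4, 3][jj])
            pid.append(f"p{i}")
    aset = make_analysis_set(x, j, y, persons=pid, outcome_kind="count")
    est = nd.fit_count_effects(aset)
    assert est.treatment_years == (1, 2, 3)
    assert np.allclose(est.rate_ratios, [0.5, 0.4, 0.3], atol=1e-8)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_count_effects_match_statsmodels_glm(seed):
    """IRLS quasi-score solution equals the GLM-Poisson estimate."""
    rows = random_panel(seed, count=True)
    aset = make_analysis_set(rows["x"], rows["j"], rows["y"], persons=rows["pid"],
                             outcome_kind="count")
    try:
        est = nd.fit_count_effects(aset)
    except nd.FitError:
        return  # all-zero treated cell in this draw: correctly refused
    x = np.asarray(rows["x"], float)
    j = np.asarray(rows["j"], float)
    design, names = count_design(x, j, est.treatment_years)
    glm = sm.GLM(np.asarray(rows["y"]), design, family=sm.families.Poisson()).fit()
    mine = [est.gamma_0, *est.gamma_J.values(), *est.gamma_X]
    assert np.allclose(mine, glm.params, atol=1e-6)


def test_count_effects_rejects_all_zero_cell():
    x = [0, 0, 1, 1]
    j = [0, 0, 0, 0]
    y = [3, 4, 0, 0]
    with pytest.raises(nd.FitError, match="zero"):
        nd.fit_count_effects(
            make_analysis_set(x, j, y, outcome_kind="count"), visit_terms="saturated"
        )


def test_count_effects_rejects_non_integer_outcomes():
    aset = make_analysis_set([0, 0, 1, 1], [0, 1, 0, 1], [1, 2, 3, 4],
                             outcome_kind="count")
    aset.data["outcome"] = [1.0, 2.5, 3.0, 4.0]
    with pytest.raises(nd.CohortError, match="integer"):
        nd.fit_count_effects(aset)


def test_count_effects_unbiased_under_overdispersion():
    """Gamma-frailty overdispersion must not bias the rate-ratio estimates."""
    cfg = nd.scenario_config(
        "scenario1", n_g1=1000, n_g0=100, seed=21,
        count_params=nd.CountParams(
            baseline_rate=10.0, dispersion=0.8,
            log_rr_treat=tuple(np.log([0.5, 0.4, 0.4, 0.4])),
        ),
    )
    cohort = nd.simulate_count_cohort(cfg)
    aset = nd.build_contrast(cohort, nd.ContrastKind.NTE_P)
    est = nd.fit_count_effects(aset, n_treatment_years=3)
    assert np.allclose(est.rate_ratios, [0.5, 0.4, 0.4], atol=0.05)


def test_count_linear_visit_trend_option():
    rows = random_panel(13, count=True)
    aset = make_analysis_set(rows["x"], rows["j"], rows["y"], persons=rows["pid"],
                             outcome_kind="count")
    est = nd.fit_count_effects(aset, visit_terms="linear")
    assert list(est.gamma_J) == ["gamma_J"]


# -- covariate encodings -------------------------------------------------


def test_count_baseline_encoding_two_columns_reconstructs_raw():
    spec = nd.CovariateSpec.from_names(
        ["ivd"], encodings={"ivd": "count_baseline"}
    )
    df = pd.DataFrame({"ivd": [0.0, 3.0, 0.0, 7.0]})
    mat, names = spec.encode(df)
    assert names == ["ivd_nonzero", "ivd_linear"]
    assert mat.shape == (4, 2)
    assert np.array_equal(mat[:, 0], [0, 1, 0, 1])
    # the linear column reproduces the raw covariate on nonzero entries
    assert np.array_equal(mat[:, 0] * mat[:, 1], df["ivd"].to_numpy())


def test_unknown_encoding_rejected():
    with pytest.raises(ValueError, match="encoding"):
        nd.CovariateSpec.from_names(["a"], encodings={"a": "spline"})


# -- standardization -----------------------------------------------------


def test_standardize_without_covariates_is_mean_difference():
    rng = np.random.default_rng(2)
    x = np.repeat([0, 1], 20)
    y = 50 + 4 * x + rng.normal(0, 3, 40)
    aset = make_analysis_set(x, np.zeros(40, int), y)
    got = nd.standardize_effect(aset, at_visit=0)
    expected = y[x == 1].mean() - y[x == 0].mean()
    assert np.isclose(got, expected, atol=1e-12)


def test_standardize_matches_hand_enumerated_strata():
    """One binary H: result equals the two-stratum weighted sum by hand."""
    # X=0: Y = 10 within H=0, 20 within H=1; X=1 observed means differ
    x = [0, 0, 0, 0, 1, 1, 1]
    h = [0, 0, 1, 1, 0, 1, 1]
    y = [10.0, 10.0, 20.0, 20.0, 18.0, 30.0, 30.0]
    spec = nd.CovariateSpec.from_names(["h"], encodings={"h": "binary"})
    aset = make_analysis_set(x, [0] * 7, y, cov={"h": h}, spec=spec)
    got = nd.standardize_effect(aset, at_visit=0)
    # standardized X=0 mean over the X=1 H-distribution (1/3 at H=0, 2/3 at H=1)
    expected = np.mean([18.0, 30.0, 30.0]) - (10.0 * (1 / 3) + 20.0 * (2 / 3))
    assert np.isclose(got, expected, atol=1e-10)


def test_standardize_equals_conditional_fit_under_shared_h_distribution():
    """Noise-free linear outcome with H independent of X: the standardized
    step equals the conditional step/slope model's step coefficient."""
    rng = np.random.default_rng(5)
    n = 40
    x = np.repeat([0, 1], n // 2)
    pid = [f"p{i}" for i in range(n)]
    rows = {"x": [], "j": [], "y": [], "h": [], "pid": []}
    h_vals = rng.normal(size=n)
    for i in range(n):
        for j in range(3):
            rows["x"].append(x[i])
            rows["j"].append(j)
            rows["h"].append(h_vals[i])
            rows["y"].append(40 + 6 * x[i] + 2.5 * h_vals[i] - 1.0 * j)
            rows["pid"].append(pid[i])
    spec = nd.CovariateSpec.from_names(["h"])
    aset = make_analysis_set(rows["x"], rows["j"], rows["y"], persons=rows["pid"],
                             cov={"h": rows["h"]}, spec=spec)
    standardized = nd.standardize_effect(aset, at_visit=0)
    conditional = nd.fit_step_slope(aset)
    assert np.isclose(standardized, conditional.beta_St, atol=1e-8)
    assert np.isclose(standardized, 6.0, atol=1e-8)


def test_standardize_overlap_error_for_orphan_stratum():
    x = [0, 0, 1, 1]
    h = [0, 0, 1, 1]  # H=1 never seen in X=0
    spec = nd.CovariateSpec.from_names(["h"], encodings={"h": "binary"})
    aset = make_analysis_set(x, [0] * 4, [1.0, 2, 3, 4], cov={"h": h}, spec=spec)
    with pytest.raises(nd.FitError, match="strata"):
        nd.standardize_effect(aset, at_visit=0)
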