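import numpy as np
import pandas as pd
import pytest

from oracles import ols_normal_equations, simulate_iv_data
from thalmr import mr
from thalmr.cohort import DELETION_ID, default_published_params, generate_cohort
from thalmr.errors import DomainError, NonEstimableError


# ------------------------------------------------------------------ Wald ratio


@pytest.mark.parametrize(
    "beta_gy, beta_gx, expected",
    [
        (-0.0164, -7.1828, 0.0023),  # MCH -> log total cholesterol
        (0.1306, -18.3175, -0.0071),  # MCV -> HbA1c
        (0.2629, -7.1672, -0.0367),  # MCH -> diabetes (percentage scale)
        (0.0, -7.0, 0.0),  # zero numerator
    ],
)
def test_wald_ratio_values(beta_gy, beta_gx, expected):
    beta, _ = mr.wald_ratio(beta_gy, 0.001, beta_gx, 0.05)
    assert round(beta, 4) == expected


def test_wald_ratio_zero_denominator():
    with pytest.raises(DomainError):
        mr.wald_ratio(0.1, 0.01, 0.0, 0.01)


def test_wald_ratio_delta_method_se():
    beta, se = mr.wald_ratio(0.5, 0.1, 2.0, 0.2)
    expect = np.sqrt(0.1**2 / 2.0**2 + 0.5**2 * 0.2**2 / 2.0**4)
    assert se == pytest.approx(expect, abs=1e-12)


# ------------------------------------------------------------------------ 2SLS


@pytest.mark.parametrize("seed", range(10))
def test_2sls_equals_wald_ratio_just_identified(seed):
    rng = np.random.default_rng(seed)
    g, x, y = simulate_iv_data(rng, 300, theta=0.4)
    rep = mr.two_stage_least_squares(x, y, g)
    wald, _ = mr.wald_ratio(
        rep.stage_ga_tb.beta, rep.stage_ga_tb.se, rep.stage_ga_ta.beta, rep.stage_ga_ta.se
    )
    assert rep.stage_iv.beta == pytest.approx(wald, abs=1e-10)


def test_perfect_instrument_reduces_to_ols(rng):
    """G identical to the exposure: the IV estimate equals plain OLS."""
    x = rng.normal(size=200)
    y = 0.7 * x + rng.normal(size=200)
    rep = mr.two_stage_least_squares(x, y, x)
    X = np.column_stack([np.ones(200), x])
    beta_ols, _, _ = ols_normal_equations(y, X)
    assert rep.stage_iv.beta == pytest.approx(beta_ols[1], abs=1e-10)


def test_stage_regressions_match_normal_equations(rng):
    n = 400
    g, x, y = simulate_iv_data(rng, n, theta=0.3)
    cov = pd.DataFrame({"c": rng.normal(size=n)})
    rep = mr.two_stage_least_squares(x, y, g, cov)
    X_g = np.column_stack([np.ones(n), g, cov["c"]])
    beta, se, p = ols_normal_equations(x, X_g)
    assert rep.stage_ga_ta.beta == pytest.approx(beta[1], abs=1e-10)
    assert rep.stage_ga_ta.se == pytest.approx(se[1], abs=1e-10)
    beta_y, _, _ = ols_normal_equations(y, X_g)
    assert rep.stage_ga_tb.beta == pytest.approx(beta_y[1], abs=1e-10)


def test_degenerate_instrument_rejected(rng):
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    with pytest.raises(NonEstimableError, match="instrument"):
        mr.two_stage_least_squares(x, y, np.ones(50))


def test_single_class_binary_outcome_rejected(rng):
    g = rng.binomial(2, 0.3, 50).astype(float)
    with pytest.raises(NonEstimableError, match="single-class"):
        mr.two_stage_least_squares(rng.normal(size=50), np.zeros(50), g)


def test_binary_second_stage_scales(rng):
    """Linear-probability and logistic second stages differ in scale but agree
    in sign for the same data."""
    n = 20_000
    g = rng.binomial(2, 0.3, n).astype(float)
    x = -2.0 * g + rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-2.2 + 0.3 * x)))
    y = (rng.random(n) < p).astype(float)
    lin = mr.two_stage_least_squares(x, y, g)
    logi = mr.two_stage_least_squares(x, y, g, second_stage="logistic")
    assert lin.second_stage == "linear" and logi.second_stage == "logistic"
    assert np.sign(lin.stage_iv.beta) == np.sign(logi.stage_iv.beta)
    assert abs(logi.stage_iv.beta) > abs(lin.stage_iv.beta)  # log-odds vs risk diff


def test_reduced_form_and_iv_pvalues_agree_with_strong_instrument(rng):
    """With a strong instrument the reduced-form and causal-estimate tests
    carry the same evidence (near-identical p-values)."""
    g, x, y = simulate_iv_data(rng, 20_000, beta_first=1.0, theta=0.05)
    rep = mr.two_stage_least_squares(x, y, g)
    assert np.log10(rep.stage_iv.p) == pytest.approx(np.log10(rep.stage_ga_tb.p), rel=0.05)


# ------------------------------------------------------- instrument strength


def test_f_statistic_formula():
    res = mr.instrument_strength_f(0.5, 102)
    assert res.f_stat == pytest.approx(100.0, abs=1e-12)
    assert not res.weak_instrument
    null = mr.instrument_strength_f(0.0, 1000)
    assert null.f_stat == 0.0 and null.weak_instrument
    assert mr.instrument_strength_f(0.2917, 1493).f_stat == pytest.approx(614.04, abs=0.01)
    with pytest.raises(DomainError):
        mr.instrument_strength_f(1.0, 100)


# ------------------------------------------------------------------- power


def test_power_limits():
    assert mr.power_ncp(1000, 0.05, 0.0, 0.0) == pytest.approx(0.05, abs=1e-9)
    assert mr.power_ncp(1000, 0.05, 0.5, 0.0, ncp=100.0) > 0.999
    with pytest.raises(DomainError):
        mr.power_ncp(1000, 1.5, 0.1, 0.1)
    with pytest.raises(DomainError):
        mr.power_ncp(0, 0.05, 0.1, 0.1)


def test_power_matches_monte_carlo_rejection_rate():
    """NCP-based power tracks the empirical 2SLS rejection rate (3 MC SEs)."""
    rng = np.random.default_rng(12345)
    n, reps, alpha = 2000, 3000, 0.05
    r2_target = 0.29
    beta_first = np.sqrt(r2_target / (1 - r2_target) / (2 * 0.3 * 0.7))  # var(G)=2p(1-p)
    theta_std = 0.05  # causal effect per SD exposure, in outcome SDs
    rejections = 0
    for _ in range(reps):
        g = rng.binomial(2, 0.3, n).astype(float)
        x = beta_first * g + rng.normal(size=n)
        theta = theta_std / x.std()
        y = theta * x + rng.normal(size=n)
        rep = mr.two_stage_least_squares(x, y, g)
        rejections += rep.stage_iv.p < alpha
    predicted = mr.power_ncp(n, alpha, r2_target, theta_std)
    mc_se = np.sqrt(predicted * (1 - predicted) / reps)
    assert abs(rejections / reps - predicted) < 3 * mc_se + 0.01


# -------------------------------------------------------------- attenuation


def test_attenuation_full_mediation(default_cohort_50k):
    """delta = 0: the genotype-outcome signal subsides after adjusting for the
    mediator; the adjusted beta is near zero."""
    c = default_cohort_50k
    d = c.genotypes.dosages[DELETION_ID]
    res = mr.attenuation_analysis(
        c.phenotypes["mch"], np.log(c.phenotypes["total_cholesterol"]), d,
        c.phenotypes[["age", "sex", "bmi", "smoking"]],
    )
    assert res.unadjusted.p < 1e-4
    assert abs(res.adjusted.beta) < 3 * res.adjusted.se
    assert res.verdict == "mediated"


def test_attenuation_direct_effect_detected():
    """delta != 0: the adjusted genotype beta recovers the direct effect."""
    p = default_published_params(n_participants=50_000, seed=99)
    for i, spec in enumerate(p.outcome_specs):
        if spec.name == "hba1c":
            import dataclasses

            p.outcome_specs[i] = dataclasses.replace(spec, delta=0.15)
    c = generate_cohort(p)
    d = c.genotypes.dosages[DELETION_ID]
    res = mr.attenuation_analysis(c.phenotypes["mcv"], c.phenotypes["hba1c"], d)
    assert res.verdict == "partial/direct"
    assert res.adjusted.beta == pytest.approx(0.15, abs=3 * res.adjusted.se)


def test_attenuation_without_exposure_equals_reduced_form(rng):
    g, x, y = simulate_iv_data(rng, 500, theta=0.4)
    res = mr.attenuation_analysis(x, y, g, adjust_for_exposure=False)
    assert res.adjusted.beta == res.unadjusted.beta


def test_2sls_recovers_generator_truth_single_cohort(default_cohort_50k):
    """The causal estimate for log total cholesterol per pg MCH lands on the
    generating theta = 0.0023 within its own 3 SE band."""
    c = default_cohort_50k
    rep = mr.two_stage_least_squares(
        c.phenotypes["mch"],
        np.log(c.phenotypes["total_cholesterol"]),
        c.genotypes.dosages["rs375498857"],
        c.phenotypes[["age", "sex", "bmi", "smoking"]],
    )
    assert rep.stage_iv.beta == pytest.approx(0.0023, abs=3 * rep.stage_iv.se)
    assert rep.f_stat > 10 and not rep.weak_instrument
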