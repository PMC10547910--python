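import numpy as np
import pandas as pd
import pytest

from oracles import odds_ratio_2x2, ols_normal_equations
from thalmr import assoc
from thalmr.errors import ConfigError, NonEstimableError
from thalmr.io import GenotypeMatrix


def _make_gm(dosages: pd.DataFrame) -> GenotypeMatrix:
    meta = pd.DataFrame(
        {"variant": dosages.columns, "chrom": "16",
         "pos": range(1, len(dosages.columns) + 1), "ref": "A", "alt": "C"}
    ).set_index("variant")
    return GenotypeMatrix(dosages=dosages.astype(float), variants=meta)


# ---------------------------------------------------------------- linear fits


def test_exact_fit_recovers_slope():
    d = np.array([0, 0, 1, 1, 2, 2], dtype=float)
    res = assoc.fit_additive_linear(d, 2 * d)
    assert res.beta == pytest.approx(2.0, abs=1e-12)
    assert res.model == "linear" and res.n_used == 6


@pytest.mark.parametrize("seed", range(8))
def test_linear_fit_matches_normal_equation_oracle(seed):
    """beta/se/p equal the brute-force (X'X)^-1 X'y solution on random fixtures."""
    rng = np.random.default_rng(seed)
    n = rng.integers(12, 50)
    k = rng.integers(0, 4)
    d = rng.integers(0, 3, n).astype(float)
    if np.unique(d).size < 2:
        d[0], d[1] = 0, 1
    cov = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"c{j}" for j in range(k)])
    y = 0.5 * d + cov.to_numpy() @ rng.normal(size=k) + rng.normal(size=n)
    res = assoc.fit_additive_linear(d, y, cov if k else None)
    X = np.column_stack([np.ones(n), d, cov.to_numpy()])
    beta, se, p = ols_normal_equations(y, X)
    assert res.beta == pytest.approx(beta[1], abs=1e-10)
    assert res.se == pytest.approx(se[1], abs=1e-10)
    assert res.p_value == pytest.approx(p[1], rel=1e-8)


def test_constant_dosage_not_estimable():
    with pytest.raises(NonEstimableError, match="constant dosage"):
        assoc.fit_additive_linear(np.zeros(20), np.random.default_rng(0).normal(size=20))


def test_collinear_covariates_named():
    rng = np.random.default_rng(3)
    d = rng.integers(0, 3, 30).astype(float)
    cov = pd.DataFrame({"x1": rng.normal(size=30)})
    cov["x2"] = 2 * cov["x1"]
    with pytest.raises(NonEstimableError, match="x"):
        assoc.fit_additive_linear(d, rng.normal(size=30), cov)


def test_orthogonal_covariate_leaves_beta_unchanged(rng):
    n = 200
    d = rng.integers(0, 3, n).astype(float)
    y = 0.7 * d + rng.normal(size=n)
    raw = rng.normal(size=n)
    Z = np.column_stack([np.ones(n), d])
    ortho = raw - Z @ np.linalg.lstsq(Z, raw, rcond=None)[0]
    base = assoc.fit_additive_linear(d, y)
    with_cov = assoc.fit_additive_linear(d, y, pd.DataFrame({"ortho": ortho}))
    assert with_cov.beta == pytest.approx(base.beta, abs=1e-8)


def test_log_transform_requires_positive_trait():
    d = np.array([0.0, 1, 2, 0, 1, 2])
    y = np.array([1.0, 2, 3, -1, 2, 3])
    with pytest.raises(Exception, match="positive"):
        assoc.fit_additive_linear(d, y, log_transform=True)


# -------------------------------------------------------------- logistic fits


def test_logistic_collapse_matches_2x2_odds_ratio(rng):
    n = 4000
    carrier = rng.random(n) < 0.3
    p = np.where(carrier, 0.4, 0.2)
    y = (rng.random(n) < p).astype(float)
    res = assoc.fit_logistic(carrier.astype(float), y)
    assert np.exp(res.beta) == pytest.approx(odds_ratio_2x2(y, carrier), rel=1e-6)


def test_logistic_separation_flagged():
    d = np.array([0.0] * 10 + [2.0] * 10)
    y = np.array([0.0] * 10 + [1.0] * 10)
    res = assoc.fit_logistic(d, y)
    assert res.separation and np.isnan(res.beta)


def test_logistic_single_class_outcome():
    with pytest.raises(NonEstimableError, match="single-class"):
        assoc.fit_logistic(np.array([0.0, 1, 2, 1]), np.zeros(4))


def test_logistic_null_calibration():
    """Under the null, |beta| < 3 se in at least ~95% of replicate fits."""
    rng = np.random.default_rng(42)
    inside = 0
    reps = 200
    for _ in range(reps):
        d = rng.binomial(2, 0.3, 600).astype(float)
        y = rng.binomial(1, 0.25, 600).astype(float)
        res = assoc.fit_logistic(d, y)
        inside += abs(res.beta) < 3 * res.se
    # expect ~0.997 coverage at 3 SEs; 0.95 allows generous MC slack
    assert inside / reps >= 0.95


# ------------------------------------------------------- tiers and exclusions


@pytest.mark.parametrize(
    "p, tier",
    [
        (4.57e-36, "genome_wide"),
        (2.20e-5, "subthreshold"),
        (5e-8, "subthreshold"),  # boundary: genome-wide is strict <
        (0.05, "none"),
        (float("nan"), "none"),
    ],
)
def test_significance_tiers(p, tier):
    assert assoc.classify_tier(p) == tier


def test_apply_exclusions_counts():
    ph = pd.DataFrame(
        {
            "systolic_bp": np.arange(10.0),
            "mch": np.arange(10.0),
            "history_hypertension": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
        }
    )
    out = assoc.apply_exclusions(ph, {"systolic_bp": "history_hypertension"})
    assert out["systolic_bp"].notna().sum() == 7
    assert out["mch"].notna().sum() == 10  # other traits untouched
    identical = assoc.apply_exclusions(ph, {})
    pd.testing.assert_frame_equal(identical, ph)
    with pytest.raises(ConfigError, match="history_gout"):
        assoc.apply_exclusions(ph, {"systolic_bp": "history_gout"})


def test_regional_scan_flags_failures_without_aborting(rng):
    n = 100
    dosages = pd.DataFrame(
        {"ok": rng.integers(0, 3, n).astype(float), "mono": np.zeros(n)}
    )
    gm = _make_gm(dosages)
    trait = pd.Series(0.5 * dosages["ok"] + rng.normal(size=n), name="mch")
    results = assoc.regional_scan(gm, trait)
    by_id = {r.variant: r for r in results}
    assert by_id["ok"].error is None and np.isfinite(by_id["ok"].p_value)
    assert by_id["mono"].error is not None and np.isnan(by_id["mono"].beta)
    table = assoc.scan_table(results, gm.variants)
    assert {"beta", "p", "neglog10_p", "tier", "pos"}.issubset(table.columns)


# ------------------------------------------------------------------- stepwise


def test_stepwise_rejects_perfect_duplicate(rng):
    n = 500
    x1 = rng.normal(size=n)
    y = 2.0 * x1 + rng.normal(size=n)
    cand = pd.DataFrame({"x1": x1, "x1_copy": x1})
    res = assoc.stepwise_linear(y, cand)
    assert res.entry_order == ["x1"]
    assert "x1_copy" in res.excluded


def test_stepwise_selects_true_support(rng):
    n = 10_000
    x1 = rng.normal(size=n)
    noise = rng.normal(size=n)
    y = 1.5 * x1 + rng.normal(size=n)
    res = assoc.stepwise_linear(y, pd.DataFrame({"x1": x1, "noise": noise}))
    assert res.entry_order == ["x1"]
    assert res.excluded == ["noise"]
    assert res.retained.loc["x1", "beta"] == pytest.approx(1.5, abs=0.05)


def test_stepwise_correlated_predictors_weaken_after_dominant_enters(rng):
    """One strong predictor among mutually correlated ones: the dominant one
    enters first and the weak correlates' significance degrades."""
    n = 10_000
    shared = rng.normal(size=n)
    x1 = shared + 0.3 * rng.normal(size=n)
    x2 = shared + 0.6 * rng.normal(size=n)
    x3 = shared + 0.6 * rng.normal(size=n)
    y = 2.0 * x1 + rng.normal(size=n)
    cand = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
    res = assoc.stepwise_linear(y, cand)
    assert res.entry_order[0] == "x1"
    marginal_p = assoc.fit_additive_linear(x2, y).p_value  # strongly significant alone
    assert marginal_p < 1e-10
    if "x2" in res.retained.index:
        assert res.retained.loc["x2", "p"] > marginal_p


def test_stepwise_forced_covariates_always_stay(rng):
    n = 2000
    age = rng.normal(size=n)
    x1 = rng.normal(size=n)
    y = 0.8 * x1 + rng.normal(size=n)  # age has no effect but is forced
    res = assoc.stepwise_linear(
        y, pd.DataFrame({"x1": x1}), forced=pd.DataFrame({"age": age})
    )
    assert "age" in res.retained.index and bool(res.retained.loc["age", "forced"])


def test_stepwise_no_candidate_passes_entry(rng):
    n = 500
    y = rng.normal(size=n)
    res = assoc.stepwise_linear(
        y, pd.DataFrame({"junk": rng.normal(size=n)}),
        forced=pd.DataFrame({"age": rng.normal(size=n)}),
    )
    assert res.entry_order == [] and list(res.retained.index) == ["age"]


def test_linear_type_i_error_calibrated():
    """Dosage test at alpha = 0.05 under a simulated null: rejection rate
    within 3 MC SEs of 0.05 (2,000 replicates, n = 500)."""
    rng = np.random.default_rng(77)
    reps, n, alpha = 2000, 500, 0.05
    rejections = 0
    for _ in range(reps):
        d = rng.binomial(2, 0.3, n).astype(float)
        y = rng.normal(size=n)
        rejections += assoc.fit_additive_linear(d, y).p_value < alpha
    se = np.sqrt(alpha * (1 - alpha) / reps)
    assert abs(rejections / reps - alpha) < 3 * se
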