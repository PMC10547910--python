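"""Single-instrument Mendelian randomization by two-stage least squares.

A genetic variant G (tag-SNV dosage) instruments an exposure T_A (MCV or MCH)
for an outcome T_B.  The report carries the five coefficient blocks of a
standard single-IV analysis — observational T_A-T_B, first stage G-T_A,
reduced form G-T_B, the 2SLS/Wald causal estimate, and G-T_B adjusted for
T_A (attenuation) — plus the first-stage R^2, the instrument-strength
F statistic F = R^2 (n-2) / (1 - R^2), and NCP-based power.

With one instrument and no covariates the 2SLS estimate equals the Wald
ratio (reduced form / first stage) exactly; the 2SLS standard error uses the
structural residuals y - X beta_2sls, not the naive second-stage residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import DomainError, NonEstimableError

__all__ = [
    "MRStage",
    "MRReport",
    "two_stage_least_squares",
    "wald_ratio",
    "instrument_strength_f",
    "attenuation_analysis",
    "power_ncp",
    "FStatResult",
    "AttenuationResult",
]


@dataclass(frozen=True)
class MRStage:
    beta: float
    se: float
    p: float
    n: int


@dataclass
class MRReport:
    stage_ta_tb: MRStage  # observational: T_B on T_A (+ covariates)
    stage_ga_ta: MRStage  # first stage: T_A on G
    stage_ga_tb: MRStage  # reduced form: T_B on G
    stage_iv: MRStage  # 2SLS causal estimate
    stage_adj: MRStage  # G coefficient in T_B on G + T_A (attenuation)
    f_stat: float
    r2_first_stage: float
    weak_instrument: bool
    n: int
    power: float | None = None
    second_stage: str = "linear"
    covariates: list = field(default_factory=list)


class FStatResult(NamedTuple):
    f_stat: float
    weak_instrument: bool


def _complete_cases(*arrays):
    mats = [np.asarray(a, dtype=float) for a in arrays if a is not None]
    cols = [m if m.ndim == 2 else m[:, None] for m in mats]
    keep = ~np.isnan(np.column_stack(cols)).any(axis=1)
    out = []
    for a in arrays:
        out.append(None if a is None else np.asarray(a, dtype=float)[keep])
    return out


def _ols(y, X):
    """OLS beta/se/p (t tests) plus residuals and R^2, by normal equations."""
    n, k = X.shape
    if n <= k:
        raise NonEstimableError(f"too few rows ({n}) for {k} parameters")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise NonEstimableError("rank-deficient design in OLS")
    resid = y - X @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / sst if sst > 0 else 0.0
    return beta, se, pvals, resid, float(r2)


def _stage(y, X, j, n) -> MRStage:
    beta, se, p, _, _ = _ols(y, X)
    return MRStage(beta=float(beta[j]), se=float(se[j]), p=float(p[j]), n=n)


def wald_ratio(beta_gy: float, se_gy: float, beta_gx: float, se_gx: float):
    """Single-instrument causal estimate beta_gy / beta_gx with delta-method SE.

    se = sqrt(se_gy^2 / beta_gx^2 + beta_gy^2 se_gx^2 / beta_gx^4).
    """
    if beta_gx == 0:
        raise DomainError("Wald ratio undefined: first-stage coefficient is zero")
    beta = beta_gy / beta_gx
    se = float(np.sqrt(se_gy**2 / beta_gx**2 + beta_gy**2 * se_gx**2 / beta_gx**4))
    return beta, se


def instrument_strength_f(r2: float, n: int) -> FStatResult:
    """F = R^2 (n-2) / (1 - R^2); F <= 10 flags a weak instrument."""
    if not (0 <= r2 < 1):
        raise DomainError(f"first-stage R^2 must lie in [0, 1), got {r2}")
    if n <= 2:
        raise DomainError(f"n must exceed 2, got {n}")
    f = r2 * (n - 2) / (1 - r2)
    return FStatResult(f_stat=float(f), weak_instrument=f <= 10)


def power_ncp(n: int, alpha: float, r2_first_stage: float, effect_std: float,
              ncp: float | None = None) -> float:
    """NCP-based power of the single-IV causal test.

    The noncentrality parameter defaults to n * R^2_first_stage *
    effect_std^2, with ``effect_std`` the causal effect per SD of exposure in
    outcome-SD units; power = P(chi^2_1(NCP) > chi^2_1 critical at alpha).
    Pass ``ncp`` to substitute an externally computed noncentrality.
    """
    if n <= 0:
        raise DomainError(f"n must be positive, got {n}")
    if not (0 < alpha < 1):
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if ncp is None:
        if not (0 <= r2_first_stage <= 1):
            raise DomainError(f"r2_first_stage must lie in [0, 1], got {r2_first_stage}")
        ncp = n * r2_first_stage * effect_std**2
    crit = stats.chi2.ppf(1 - alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def _build_X(n, *blocks):
    cols = [np.ones(n)]
    for b in blocks:
        if b is None:
            continue
        b = np.asarray(b, dtype=float)
        cols.append(b if b.ndim == 2 else b[:, None])
    return np.column_stack(cols)


def two_stage_least_squares(exposure, outcome, instrument, covariates=None,
                            binary_outcome: bool | None = None,
                            second_stage: str = "linear",
                            alpha: float = 0.05,
                            effect_std: float | None = None) -> MRReport:
    """Full single-instrument MR report.

    ``covariates`` (optional, n x c) are included in every stage.  Binary
    outcomes default to a linear-probability second stage (one beta on the
    risk-difference scale); ``second_stage='logistic'`` substitutes the fitted
    exposure into a logistic model instead (log-odds scale).  ``effect_std``
    (causal effect in standardized units), when given, adds NCP-based power
    at level ``alpha``.
    """
    x, y, g, cov = _complete_cases(exposure, outcome, instrument, covariates)
    n = x.size
    if n < 4:
        raise NonEstimableError(f"too few complete cases: {n}")
    if np.var(g) == 0:
        raise NonEstimableError("degenerate instrument: zero variance")
    is_binary = binary_outcome if binary_outcome is not None else set(np.unique(y)) <= {0.0, 1.0}
    if is_binary and np.unique(y).size < 2:
        raise NonEstimableError("single-class binary outcome")

    X_ta = _build_X(n, x, cov)  # [1, T_A, cov]
    X_g = _build_X(n, g, cov)  # [1, G, cov]
    X_adj = _build_X(n, g, x, cov)  # [1, G, T_A, cov]

    stage_ta_tb = _stage(y, X_ta, 1, n)
    b1, se1, p1, _, _ = _ols(x, X_g)
    stage_ga_ta = MRStage(beta=float(b1[1]), se=float(se1[1]), p=float(p1[1]), n=n)
    stage_ga_tb = _stage(y, X_g, 1, n)
    try:
        stage_adj = _stage(y, X_adj, 1, n)
    except NonEstimableError:
        # G collinear with T_A (e.g. a degenerate perfect instrument): the
        # attenuation model is not identified
        stage_adj = MRStage(beta=float("nan"), se=float("nan"), p=float("nan"), n=n)

    # first-stage R^2 attributable to the instrument (increment over covariates)
    _, _, _, _, r2_full = _ols(x, X_g)
    if cov is not None:
        _, _, _, _, r2_cov = _ols(x, _build_X(n, cov))
        r2_first = max(r2_full - r2_cov, 0.0)
    else:
        r2_first = r2_full
    fres = instrument_strength_f(min(r2_first, 1 - 1e-12), n)

    # 2SLS: just-identified IV estimator with structural-residual variance
    Z, X = X_g, X_ta
    ztx = Z.T @ X
    if abs(np.linalg.det(ztx)) < 1e-300 or stage_ga_ta.beta == 0:
        raise NonEstimableError("weak/degenerate instrument: first stage not estimable")
    beta_iv = np.linalg.solve(ztx, Z.T @ y)
    if is_binary and second_stage == "logistic":
        import statsmodels.api as sm

        xhat = X_g @ np.linalg.lstsq(X_g, x, rcond=None)[0]
        fit = sm.Logit(y, _build_X(n, xhat, cov)).fit(disp=0)
        stage_iv = MRStage(beta=float(fit.params[1]), se=float(fit.bse[1]),
                           p=float(fit.pvalues[1]), n=n)
    else:
        resid = y - X @ beta_iv
        dof = n - X.shape[1]
        sigma2 = resid @ resid / dof
        ztx_inv = np.linalg.inv(ztx)
        V = sigma2 * ztx_inv @ (Z.T @ Z) @ ztx_inv.T
        se_iv = float(np.sqrt(max(V[1, 1], 0.0)))
        t = beta_iv[1] / se_iv if se_iv > 0 else np.inf
        stage_iv = MRStage(beta=float(beta_iv[1]), se=se_iv,
                           p=float(2 * stats.t.sf(abs(t), dof)), n=n)

    power = None
    if effect_std is not None:
        power = power_ncp(n, alpha, r2_first, effect_std)
    return MRReport(
        stage_ta_tb=stage_ta_tb, stage_ga_ta=stage_ga_ta, stage_ga_tb=stage_ga_tb,
        stage_iv=stage_iv, stage_adj=stage_adj,
        f_stat=fres.f_stat, r2_first_stage=float(r2_first),
        weak_instrument=fres.weak_instrument, n=n, power=power,
        second_stage="logistic" if (is_binary and second_stage == "logistic") else "linear",
    )


@dataclass
class AttenuationResult:
    unadjusted: MRStage  # reduced form G -> T_B
    adjusted: MRStage  # G -> T_B adjusted for T_A (+ confounders)
    verdict: str  # "mediated" | "partial/direct"


def attenuation_analysis(exposure, outcome, instrument, covariates=None,
                         confounders=None, adjust_for_exposure: bool = True,
                         p_subside: float = 0.05,
                         p_signif: float = 0.05) -> AttenuationResult:
    """Does the genotype-outcome association subside after mediator adjustment?

    Fits T_B on G (+ covariates + confounders) without and with T_A in the
    model; verdict "mediated" when the unadjusted association is significant
    (p < ``p_signif``) but the adjusted one is not (p > ``p_subside``).
    ``confounders`` is an optional extra adjustment block (n x c).
    """
    x, y, g, cov, conf = _complete_cases(exposure, outcome, instrument,
                                         covariates, confounders)
    n = y.size
    X_un = _build_X(n, g, cov, conf)
    unadj = _stage(y, X_un, 1, n)
    X_ad = _build_X(n, g, x, cov, conf) if adjust_for_exposure else X_un
    adj = _stage(y, X_ad, 1, n)
    verdict = "mediated" if (unadj.p < p_signif and adj.p > p_subside) else "partial/direct"
    return AttenuationResult(unadjusted=unadj, adjusted=adj, verdict=verdict)
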