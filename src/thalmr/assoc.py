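"""Genotype-phenotype association under an additive model.

Linear and logistic regressions of a trait on the 0/1/2 minor-allele dosage
with covariate adjustment, trait-specific history exclusions, a regional scan
with genome-wide (p < 5e-8) and subthreshold (5e-8 <= p < 1e-4) tiers, and
forward-backward stepwise selection.  Fits are complete-case; lipid-like
traits may be natural-log transformed before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, DomainError, NonEstimableError
from .io import GenotypeMatrix

__all__ = [
    "AssociationResult",
    "classify_tier",
    "apply_exclusions",
    "fit_additive_linear",
    "fit_logistic",
    "regional_scan",
    "scan_table",
    "stepwise_linear",
    "StepwiseResult",
]

GENOME_WIDE_P = 5e-8
SUBTHRESHOLD_P = 1e-4


@dataclass
class AssociationResult:
    variant: str
    trait: str
    model: str  # "linear" | "logistic"
    beta: float
    se: float
    p_value: float
    n_used: int
    covariates: list = field(default_factory=list)
    partial_r2: float | None = None
    tier: str = "none"
    separation: bool = False
    error: str | None = None

    @property
    def odds_ratio(self) -> float | None:
        return float(np.exp(self.beta)) if self.model == "logistic" else None

    def or_ci(self, z: float = 1.96):
        if self.model != "logistic":
            return None
        return (float(np.exp(self.beta - z * self.se)), float(np.exp(self.beta + z * self.se)))


def classify_tier(p: float, genome_wide: float = GENOME_WIDE_P,
                  subthreshold: float = SUBTHRESHOLD_P) -> str:
    """Significance tier of a p-value: genome_wide, subthreshold or none."""
    if not np.isfinite(p):
        return "none"
    if p < genome_wide:
        return "genome_wide"
    if p < subthreshold:
        return "subthreshold"
    return "none"


def apply_exclusions(pheno: pd.DataFrame, rules: dict) -> pd.DataFrame:
    """Mask trait values for participants with the matching history flag.

    ``rules`` maps trait column -> history flag column; for each rule the
    trait is set to NaN where the flag is 1, leaving other traits untouched
    (complete-case fitting then drops those rows for that trait only).
    """
    out = pheno.copy()
    for trait, flag in rules.items():
        if flag not in out.columns:
            raise ConfigError(f"exclusion rule for {trait!r} references missing flag column {flag!r}")
        if trait not in out.columns:
            raise ConfigError(f"exclusion rule references missing trait column {trait!r}")
        out.loc[out[flag].astype(bool), trait] = np.nan
    return out


def _design(dosage, trait, covariates, log_transform):
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(trait, dtype=float)
    cov = None
    if covariates is not None and len(getattr(covariates, "columns", [])) > 0:
        cov = np.asarray(covariates, dtype=float)
        keep = ~(np.isnan(d) | np.isnan(y) | np.isnan(cov).any(axis=1))
        cov = cov[keep]
    else:
        keep = ~(np.isnan(d) | np.isnan(y))
    d, y = d[keep], y[keep]
    if log_transform:
        if np.any(y <= 0):
            raise DomainError("log transform requires strictly positive trait values")
        y = np.log(y)
    names = ["const", "dosage"] + (list(covariates.columns) if cov is not None else [])
    X = np.column_stack([np.ones(d.size), d] + ([cov] if cov is not None else []))
    return X, y, names


def _check_design(X, names, n_min_extra=2):
    if X.shape[0] < X.shape[1] + n_min_extra:
        raise NonEstimableError(
            f"too few complete cases ({X.shape[0]}) for {X.shape[1]} parameters"
        )
    if np.unique(X[:, 1]).size < 2:
        raise NonEstimableError("constant dosage: association not estimable")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear columns via near-zero diagonal of R in a QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[j] for j in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))]
        raise NonEstimableError(f"rank-deficient design; collinear column(s): {bad}")


def fit_additive_linear(dosage, trait, covariates=None, log_transform: bool = False,
                        variant: str = "", trait_name: str = "") -> AssociationResult:
    """OLS of (optionally log) trait on dosage + covariates; two-sided t test."""
    X, y, names = _design(dosage, trait, covariates, log_transform)
    _check_design(X, names)
    fit = sm.OLS(y, X).fit()
    # squared semipartial correlation of the dosage term
    r2_full = fit.rsquared
    r2_red = sm.OLS(y, np.delete(X, 1, axis=1)).fit().rsquared if X.shape[1] > 2 else 0.0
    return AssociationResult(
        variant=variant, trait=trait_name, model="linear",
        beta=float(fit.params[1]), se=float(fit.bse[1]), p_value=float(fit.pvalues[1]),
        n_used=int(fit.nobs), covariates=names[2:],
        partial_r2=float(r2_full - r2_red),
        tier=classify_tier(float(fit.pvalues[1])),
    )


def fit_logistic(dosage, outcome, covariates=None, variant: str = "",
                 trait_name: str = "", maxiter: int = 100) -> AssociationResult:
    """ML logistic fit; beta is the log-odds per allele, p is the Wald test.

    Detected separation (diverging |beta| or non-convergence) yields a result
    flagged ``separation=True`` with NaN estimates, never a silent number.
    """
    X, y, names = _design(dosage, outcome, covariates, log_transform=False)
    classes = np.unique(y)
    if classes.size < 2:
        raise NonEstimableError("single-class outcome: logistic model not estimable")
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise DomainError(f"binary outcome must be coded 0/1, got values {classes[:4]}")
    _check_design(X, names)
    flagged = AssociationResult(
        variant=variant, trait=trait_name, model="logistic",
        beta=float("nan"), se=float("nan"), p_value=float("nan"),
        n_used=int(X.shape[0]), covariates=names[2:], separation=True,
    )
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter)
    except Exception:
        return flagged
    if (not fit.mle_retvals.get("converged", False)) or np.max(np.abs(fit.params)) > 20:
        return flagged
    return AssociationResult(
        variant=variant, trait=trait_name, model="logistic",
        beta=float(fit.params[1]), se=float(fit.bse[1]), p_value=float(fit.pvalues[1]),
        n_used=int(fit.nobs), covariates=names[2:],
        tier=classify_tier(float(fit.pvalues[1])),
    )


def regional_scan(genotypes: GenotypeMatrix, trait: pd.Series, covariates=None,
                  model: str = "linear", log_transform: bool = False,
                  trait_name: str = "") -> list:
    """One association result per variant; per-variant failures become flagged
    rows (``error`` set) instead of aborting the scan."""
    fit_fn = fit_additive_linear if model == "linear" else fit_logistic
    kwargs = {"log_transform": log_transform} if model == "linear" else {}
    results = []
    for vid in genotypes.dosages.columns:
        try:
            res = fit_fn(genotypes.dosages[vid], trait, covariates,
                         variant=vid, trait_name=trait_name or trait.name, **kwargs)
        except (NonEstimableError, DomainError) as exc:
            res = AssociationResult(
                variant=vid, trait=trait_name or str(trait.name), model=model,
                beta=float("nan"), se=float("nan"), p_value=float("nan"),
                n_used=0, error=str(exc),
            )
        results.append(res)
    return results


def scan_table(results, variants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Plot-ready table (variant, position, beta, se, p, -log10 p, tier)."""
    rows = []
    for r in results:
        row = {
            "variant": r.variant, "trait": r.trait, "model": r.model,
            "beta": r.beta, "se": r.se, "p": r.p_value,
            "neglog10_p": -np.log10(r.p_value) if r.p_value and np.isfinite(r.p_value) else np.nan,
            "n": r.n_used, "tier": r.tier, "error": r.error or "",
        }
        if variants is not None and r.variant in variants.index:
            row["chrom"] = variants.loc[r.variant, "chrom"]
            row["pos"] = variants.loc[r.variant, "pos"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")


@dataclass
class StepwiseResult:
    retained: pd.DataFrame  # per retained predictor: beta, se, p, r2_increment
    excluded: list
    entry_order: list
    r2_total: float
    forced: list


def _ols_term_p(y, X, j):
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues[j]), fit


def stepwise_linear(trait, candidates: pd.DataFrame, forced: pd.DataFrame | None = None,
                    p_enter: float = 0.05, p_remove: float = 0.10) -> StepwiseResult:
    """Forward selection with backward elimination among candidate predictors.

    Forced covariates always stay in the model; a candidate enters when it has
    the smallest fitting p-value below ``p_enter`` and is removed again if its
    p-value in the growing model rises above ``p_remove``.  The retained table
    reports each predictor's final-model beta/se/p and its cumulative-r^2
    increment at entry; perfectly collinear candidates can never enter.
    """
    y = np.asarray(trait, dtype=float)
    cand = candidates.astype(float)
    forced = forced.astype(float) if forced is not None else pd.DataFrame(index=cand.index)
    mask = ~np.isnan(y)
    for df in (cand, forced):
        if len(df.columns):
            mask &= ~df.isna().any(axis=1).to_numpy()
    y = y[mask]
    cand = cand.loc[mask]
    forced = forced.loc[mask]

    def build(cols):
        parts = [np.ones(y.size)]
        names = ["const"]
        if len(forced.columns):
            parts.append(forced.to_numpy())
            names += list(forced.columns)
        for c in cols:
            parts.append(cand[c].to_numpy()[:, None])
            names.append(c)
        return np.column_stack(parts), names

    included: list = []
    entry_order: list = []
    r2_steps: dict = {}
    X0, _ = build([])
    r2_prev = sm.OLS(y, X0).fit().rsquared if X0.shape[1] > 1 else 0.0

    while True:
        best = None
        for c in cand.columns:
            if c in included:
                continue
            X, names = build(included + [c])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue  # collinear with what is already in: can never enter
            p, fit = _ols_term_p(y, X, names.index(c))
            if p < p_enter and (best is None or p < best[0]):
                best = (p, c, fit.rsquared)
        if best is None:
            break
        _, c, r2_now = best
        included.append(c)
        entry_order.append(c)
        r2_steps[c] = r2_now - r2_prev
        r2_prev = r2_now
        # backward pass over entered candidates (never forced covariates)
        removed = True
        while removed and included:
            removed = False
            X, names = build(included)
            fit = sm.OLS(y, X).fit()
            worst = max(included, key=lambda cc: fit.pvalues[names.index(cc)])
            if float(fit.pvalues[names.index(worst)]) > p_remove:
                included.remove(worst)
                r2_steps.pop(worst, None)
                removed = True
                r2_prev = sm.OLS(y, build(included)[0]).fit().rsquared

    X, names = build(included)
    fit = sm.OLS(y, X).fit()
    rows = []
    for c in list(forced.columns) + included:
        j = names.index(c)
        rows.append({
            "predictor": c,
            "beta": float(fit.params[j]), "se": float(fit.bse[j]),
            "p": float(fit.pvalues[j]),
            "r2_increment": r2_steps.get(c, np.nan),
            "forced": c in forced.columns,
        })
    retained = pd.DataFrame(rows).set_index("predictor") if rows else pd.DataFrame(
        columns=["beta", "se", "p", "r2_increment", "forced"])
    return StepwiseResult(
        retained=retained,
        excluded=[c for c in cand.columns if c not in included],
        entry_order=entry_order,
        r2_total=float(fit.rsquared),
        forced=list(forced.columns),
    )
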