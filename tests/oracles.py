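"""Independent oracles used by the test suite.

Everything here is deliberately naive (normal equations, grid search,
closed-form haplotype algebra) and independent of the library code paths it
checks.
"""

import numpy as np
from scipy import stats


def ols_normal_equations(y, X):
    """Brute-force OLS: beta = (X'X)^-1 X'y, classical SEs, two-sided t p-values."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    p = 2 * stats.t.sf(np.abs(beta / se), dof)
    return beta, se, p


def odds_ratio_2x2(outcome, exposed):
    """Cross-product odds ratio ad/bc from a 2x2 table."""
    outcome = np.asarray(outcome, bool)
    exposed = np.asarray(exposed, bool)
    a = np.sum(exposed & outcome)
    b = np.sum(exposed & ~outcome)
    c = np.sum(~exposed & outcome)
    d = np.sum(~exposed & ~outcome)
    return (a * d) / (b * c)


def grid_search_hap_mle(counts, step=0.01):
    """Exhaustive grid maximizer of the diplotype log-likelihood.

    ``counts`` is the 3x3 genotype table (rows = dosage at locus 1).  Returns
    (best haplotype frequencies [AB, Ab, aB, ab], best log-likelihood).
    """
    vals = np.arange(0.0, 1.0 + step / 2, step)
    best_ll, best_p = -np.inf, None
    for p_ab_hi in vals:  # p_AB
        for p_Ab in vals:
            if p_ab_hi + p_Ab > 1 + 1e-12:
                break
            rem = 1.0 - p_ab_hi - p_Ab
            p_aB = np.arange(0.0, rem + step / 2, step)
            p_ab = rem - p_aB
            ll = _diplotype_ll_vec(counts, p_ab_hi, p_Ab, p_aB, p_ab)
            j = int(np.argmax(ll))
            if ll[j] > best_ll:
                best_ll = float(ll[j])
                best_p = np.array([p_ab_hi, p_Ab, p_aB[j], p_ab[j]])
    return best_p, best_ll


def _diplotype_ll_vec(counts, p_AB, p_Ab, p_aB, p_ab):
    p_aB = np.asarray(p_aB, float)
    p_ab = np.asarray(p_ab, float)
    cell = {
        (0, 0): p_ab**2,
        (0, 1): 2 * p_aB * p_ab,
        (0, 2): p_aB**2,
        (1, 0): 2 * p_Ab * p_ab,
        (1, 1): 2 * p_AB * p_ab + 2 * p_Ab * p_aB,
        (1, 2): 2 * p_AB * p_aB,
        (2, 0): np.full_like(p_aB, p_Ab**2),
        (2, 1): np.full_like(p_aB, 2 * p_AB * p_Ab),
        (2, 2): np.full_like(p_aB, p_AB**2),
    }
    ll = np.zeros_like(p_aB)
    for key, prob in cell.items():
        c = counts[key]
        if c > 0:
            ll = ll + c * np.log(np.maximum(prob, 1e-300))
    return ll


def expected_pair_r2(q, p1_del, p1_nodel, p2_del=None, p2_nodel=None):
    """Closed-form haplotype-level r^2 between two tag SNVs (or tag vs the
    deletion itself when p2_* are omitted), under the generating model: each
    haplotype carries the deletion D with probability q and tag alleles
    conditionally independently given D."""
    p1 = q * p1_del + (1 - q) * p1_nodel
    if p2_del is None:  # second locus IS the deletion
        p2 = q
        p11 = q * p1_del
    else:
        p2 = q * p2_del + (1 - q) * p2_nodel
        p11 = q * p1_del * p2_del + (1 - q) * p1_nodel * p2_nodel
    d = p11 - p1 * p2
    return d * d / (p1 * (1 - p1) * p2 * (1 - p2))


def simulate_iv_data(rng, n, beta_first=1.0, theta=0.0, delta=0.0, maf=0.3):
    """Minimal IV data generator: G ~ Binom(2, maf); X = beta_first*G + e1;
    Y = theta*X + delta*G + e2 with independent standard-normal errors."""
    g = rng.binomial(2, maf, n).astype(float)
    x = beta_first * g + rng.normal(size=n)
    y = theta * x + delta * g + rng.normal(size=n)
    return g, x, y
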