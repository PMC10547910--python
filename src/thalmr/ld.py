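"""Pairwise linkage disequilibrium from unphased diploid genotypes.

Haplotype frequencies for a pair of biallelic loci are estimated with the
standard EM algorithm over the double-heterozygote phase ambiguity; D, D' and
r^2 are then computed from the fitted frequencies.  A genotype-correlation
fallback (r^2 of dosages) is available for degenerate inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedLDError

__all__ = [
    "HaplotypeFreqs",
    "LDStats",
    "EMResult",
    "ld_from_hapfreqs",
    "em_haplotype_freqs",
    "ld_pair",
    "ld_matrix",
]


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Frequencies of the four haplotypes of two biallelic loci (A/a, B/b).

    'A' and 'B' denote the counted (minor) alleles, so p_A = p_AB + p_Ab.
    """

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float

    def __post_init__(self):
        freqs = (self.p_AB, self.p_Ab, self.p_aB, self.p_ab)
        if any(f < -1e-12 or f > 1 + 1e-12 for f in freqs):
            raise DomainError(f"haplotype frequencies must lie in [0, 1]: {freqs}")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise DomainError(f"haplotype frequencies must sum to 1: {freqs}")

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB

    def as_array(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])


@dataclass(frozen=True)
class LDStats:
    D: float
    d_prime: float
    r2: float


@dataclass(frozen=True)
class EMResult:
    freqs: HaplotypeFreqs
    converged: bool
    n_iter: int
    loglik: float
    n_pairs: int


def ld_from_hapfreqs(h: HaplotypeFreqs) -> LDStats:
    """D, |D'| and r^2 from haplotype frequencies.

    D = p_AB - p_A p_B; r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)); D' = |D|/D_max
    where D_max = min(p_A(1-p_B), (1-p_A)p_B) for D > 0 and
    min(p_A p_B, (1-p_A)(1-p_B)) for D < 0.  D = 0 gives D' = 0 by convention.
    """
    p_a, p_b = h.p_A, h.p_B
    if not (0 < p_a < 1) or not (0 < p_b < 1):
        raise UndefinedLDError(
            f"LD undefined for monomorphic locus (p_A={p_a:.4g}, p_B={p_b:.4g})"
        )
    d = h.p_AB - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        return LDStats(D=0.0, d_prime=0.0, r2=r2)
    return LDStats(D=d, d_prime=abs(d) / d_max, r2=r2)


def _genotype_counts(dos1, dos2):
    d1 = np.asarray(dos1, dtype=float)
    d2 = np.asarray(dos2, dtype=float)
    if d1.shape != d2.shape:
        raise DomainError("dosage vectors must have equal length")
    keep = ~(np.isnan(d1) | np.isnan(d2))
    d1, d2 = d1[keep].astype(int), d2[keep].astype(int)
    if d1.size < 2:
        raise DomainError("need at least 2 complete genotype pairs")
    counts = np.zeros((3, 3), dtype=float)
    np.add.at(counts, (d1, d2), 1.0)
    return counts


def _loglik(counts: np.ndarray, p: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table under HWE diplotypes."""
    p_ab_, p_aB, p_Ab, p_AB = p[3], p[2], p[1], p[0]
    cell = np.empty((3, 3))
    cell[0, 0] = p_ab_**2
    cell[0, 1] = 2 * p_aB * p_ab_
    cell[0, 2] = p_aB**2
    cell[1, 0] = 2 * p_Ab * p_ab_
    cell[1, 1] = 2 * p_AB * p_ab_ + 2 * p_Ab * p_aB
    cell[1, 2] = 2 * p_AB * p_aB
    cell[2, 0] = p_Ab**2
    cell[2, 1] = 2 * p_AB * p_Ab
    cell[2, 2] = p_AB**2
    with np.errstate(divide="ignore"):
        logcell = np.where(counts > 0, np.log(np.maximum(cell, 1e-300)), 0.0)
    return float(np.sum(counts * logcell))


def em_haplotype_freqs(dos1, dos2, tol: float = 1e-10, max_iter: int = 1000) -> EMResult:
    """EM haplotype-frequency estimate for two loci from unphased dosages.

    Only the double-heterozygote cell is phase-ambiguous; every other genotype
    contributes known haplotype counts, so with no double heterozygotes the
    first E-step already yields the exact counting solution.  Initialization is
    deterministic at linkage equilibrium (products of observed allele
    frequencies); convergence when the largest frequency change is < ``tol``.
    """
    counts = _genotype_counts(dos1, dos2)
    n = counts.sum()
    # fixed haplotype contributions from unambiguous cells
    base = np.zeros(4)  # AB, Ab, aB, ab
    base[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    n_dh = counts[1, 1]

    p_a = (counts[1, :].sum() + 2 * counts[2, :].sum()) / (2 * n)
    p_b = (counts[:, 1].sum() + 2 * counts[:, 2].sum()) / (2 * n)
    p = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cis = p[0] * p[3]
        trans = p[1] * p[2]
        w = 0.5 if cis + trans == 0 else cis / (cis + trans)
        hap = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        p_new = hap / (2 * n)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            converged = True
            break
        p = p_new
    freqs = HaplotypeFreqs(*np.clip(p, 0.0, 1.0) / np.clip(p, 0.0, 1.0).sum())
    return EMResult(
        freqs=freqs, converged=converged, n_iter=it, loglik=_loglik(counts, p), n_pairs=int(n)
    )


def ld_pair(dos1, dos2, method: str = "em") -> LDStats:
    """LD statistics for one variant pair from unphased dosages.

    ``method='em'`` (default) estimates haplotype frequencies by EM;
    ``method='dosage-corr'`` reports the squared Pearson correlation of
    dosages as r^2 (D and D' are NaN in that mode).
    """
    if method == "dosage-corr":
        d1 = np.asarray(dos1, dtype=float)
        d2 = np.asarray(dos2, dtype=float)
        keep = ~(np.isnan(d1) | np.isnan(d2))
        d1, d2 = d1[keep], d2[keep]
        if d1.std() == 0 or d2.std() == 0:
            raise UndefinedLDError("dosage correlation undefined for a constant variant")
        r = float(np.corrcoef(d1, d2)[0, 1])
        return LDStats(D=float("nan"), d_prime=float("nan"), r2=r * r)
    if method != "em":
        raise DomainError(f"unknown LD method: {method!r}")
    return ld_from_hapfreqs(em_haplotype_freqs(dos1, dos2).freqs)


def ld_matrix(dosages: pd.DataFrame, variants=None, method: str = "em"):
    """Symmetric pairwise r^2 and |D'| matrices for a set of variants.

    ``dosages`` is a samples x variants DataFrame of 0/1/2 dosages.  Pairs
    whose LD is undefined (e.g. a monomorphic variant) yield NaN cells rather
    than aborting the computation.  Returns ``(r2, d_prime)`` DataFrames.
    """
    cols = list(variants) if variants is not None else list(dosages.columns)
    if len(cols) < 2:
        raise DomainError("ld_matrix needs at least 2 variants")
    r2 = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    dp = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, vi in enumerate(cols):
        for vj in cols[i + 1 :]:
            try:
                stats = ld_pair(dosages[vi], dosages[vj], method=method)
                r2.loc[vi, vj] = r2.loc[vj, vi] = stats.r2
                dp.loc[vi, vj] = dp.loc[vj, vi] = stats.d_prime
            except (UndefinedLDError, DomainError):
                r2.loc[vi, vj] = r2.loc[vj, vi] = np.nan
                dp.loc[vi, vj] = dp.loc[vj, vi] = np.nan
    return r2, dp
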