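"""Tag-SNV carrier status as a classifier for gold-standard deletion carriage.

A participant is a tag carrier when the tag dosage is >= 1; the gold standard
is PCR-confirmed --SEA deletion carriage (0/1).  The module builds the 2x2
confusion table and the four diagnostic metrics (sensitivity, specificity,
PPV, NPV) as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "ConfusionTable",
    "DiagnosticMetrics",
    "confusion_from_calls",
    "metrics",
    "evaluate_tags",
    "REFERENCE_CONFUSION_SYNTHETIC",
]


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percentages in [0, 100]; None where the denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    table: ConfusionTable

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in [
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
            ]
        }


def confusion_from_calls(carrier, deletion) -> ConfusionTable:
    """Cross-tabulate predicted carrier status against gold-standard deletion.

    Rows where the gold standard (or the call) is missing are excluded and
    counted in ``n_excluded``.
    """
    c = np.asarray(carrier, dtype=float)
    d = np.asarray(deletion, dtype=float)
    if c.shape != d.shape:
        raise DomainError(f"length mismatch: {c.shape} vs {d.shape}")
    keep = ~(np.isnan(c) | np.isnan(d))
    cb, db = c[keep].astype(bool), d[keep].astype(bool)
    return ConfusionTable(
        tp=int(np.sum(cb & db)),
        fp=int(np.sum(cb & ~db)),
        fn=int(np.sum(~cb & db)),
        tn=int(np.sum(~cb & ~db)),
        n_excluded=int(np.sum(~keep)),
    )


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(table: ConfusionTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV (percent) from a confusion table."""
    return DiagnosticMetrics(
        sensitivity=_pct(table.tp, table.tp + table.fn),
        specificity=_pct(table.tn, table.tn + table.fp),
        ppv=_pct(table.tp, table.tp + table.fp),
        npv=_pct(table.tn, table.tn + table.fn),
        table=table,
    )


def evaluate_tags(dosages: pd.DataFrame, deletion_status: pd.Series, variants=None) -> pd.DataFrame:
    """Diagnostics of each tag SNV (dosage >= 1 = carrier) vs deletion status.

    ``deletion_status`` is indexed by sample ID with values {0, 1} (NaN =
    untested, excluded).  Returns one row per variant with counts and metrics.
    """
    cols = list(variants) if variants is not None else list(dosages.columns)
    status = deletion_status.reindex(dosages.index)
    rows = []
    for v in cols:
        carrier = (dosages[v] >= 1).where(~dosages[v].isna())
        tab = confusion_from_calls(carrier.to_numpy(dtype=float), status.to_numpy(dtype=float))
        m = metrics(tab)
        rows.append(
            {
                "variant": v,
                "tp": tab.tp,
                "fp": tab.fp,
                "fn": tab.fn,
                "tn": tab.tn,
                "n": tab.n,
                "n_excluded": tab.n_excluded,
                **m.rounded(),
            }
        )
    return pd.DataFrame(rows).set_index("variant")


#: Synthetic stand-in for the published --SEA evaluation in 1,474 sequenced
#: Taiwanese adults: confusion tables reconstructed from the published carrier
#: counts (52/57/56), the 60 PCR-confirmed deletion carriers, and the printed
#: sensitivity/specificity/PPV/NPV.  Reconstructed, not an original data export.
REFERENCE_CONFUSION_SYNTHETIC = {
    "rs191086839": ConfusionTable(tp=51, fp=1, fn=9, tn=1413),  # NPRL3
    "rs372755452": ConfusionTable(tp=54, fp=3, fn=6, tn=1411),  # LUC7L
    "rs375498857": ConfusionTable(tp=51, fp=5, fn=9, tn=1409),  # PGAP6
}
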