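"""Erythrocyte indices and microcytic/anemia classification.

The three derived indices follow the standard clinical definitions:

    MCV  (fl)    = 10  * Hct / RBC
    MCH  (pg)    = 10  * Hb  / RBC
    MCHC (g/dl)  = 100 * Hb  / Hct

with Hct in %, Hb in g/dl and RBC in 10^6/ul.  The classification rules are
the ones used for Taiwanese adult cohorts: microcytic hypochromic trait when
MCV < 80 fl AND MCH < 25 pg (strict), anemia by sex-specific Hct/Hb cutoffs
(men: Hct < 40% or Hb < 13 g/dl; women: Hct < 36% or Hb < 12 g/dl), and
microcytic anemia as the conjunction of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "ErythrocytePanel",
    "derive_indices",
    "classify_microcytic_hypochromic",
    "classify_anemia",
    "classify_microcytic_anemia",
    "annotate_phenotypes",
]

MCV_MICROCYTIC_FL = 80.0
MCH_HYPOCHROMIC_PG = 25.0
HCT_ANEMIA = {"male": 40.0, "female": 36.0}
HB_ANEMIA = {"male": 13.0, "female": 12.0}


@dataclass(frozen=True)
class ErythrocytePanel:
    """One participant's red-cell panel (units: 10^6/ul, g/dl, %, fl, pg, g/dl)."""

    rbc: float
    hb: float
    hct: float
    mcv: float
    mch: float
    mchc: float
    sex: str  # "male" | "female"


def derive_indices(rbc, hb, hct):
    """Return (mcv, mch, mchc) from RBC count, hemoglobin and hematocrit.

    Accepts scalars or arrays; non-positive rbc or hct raise ``DomainError``.
    """
    rbc = np.asarray(rbc, dtype=float)
    hb = np.asarray(hb, dtype=float)
    hct = np.asarray(hct, dtype=float)
    if np.any(rbc <= 0):
        raise DomainError("rbc must be > 0 to derive erythrocyte indices")
    if np.any(hct <= 0):
        raise DomainError("hct must be > 0 to derive erythrocyte indices")
    mcv = 10.0 * hct / rbc
    mch = 10.0 * hb / rbc
    mchc = 100.0 * hb / hct
    if mcv.ndim == 0:
        return float(mcv), float(mch), float(mchc)
    return mcv, mch, mchc


def classify_microcytic_hypochromic(mcv, mch):
    """True iff MCV < 80 fl and MCH < 25 pg (both strict)."""
    mcv = np.asarray(mcv, dtype=float)
    mch = np.asarray(mch, dtype=float)
    out = (mcv < MCV_MICROCYTIC_FL) & (mch < MCH_HYPOCHROMIC_PG)
    return bool(out) if out.ndim == 0 else out


def _normalize_sex(sex):
    sex_arr = np.asarray(sex)
    if sex_arr.dtype.kind in "iub":  # 1 = male, 0 = female coding
        return np.where(sex_arr.astype(int) == 1, "male", "female")
    sex_arr = np.char.lower(sex_arr.astype(str))
    bad = ~np.isin(sex_arr, ["male", "female"])
    if np.any(bad):
        raise DomainError(f"unknown sex code(s): {np.unique(np.asarray(sex_arr)[bad])!r}")
    return sex_arr


def classify_anemia(hct, hb, sex):
    """True iff the sex-specific Hct OR Hb threshold is breached (strict <)."""
    hct = np.asarray(hct, dtype=float)
    hb = np.asarray(hb, dtype=float)
    sex_arr = _normalize_sex(sex)
    male = sex_arr == "male"
    hct_cut = np.where(male, HCT_ANEMIA["male"], HCT_ANEMIA["female"])
    hb_cut = np.where(male, HB_ANEMIA["male"], HB_ANEMIA["female"])
    out = (hct < hct_cut) | (hb < hb_cut)
    return bool(out) if out.ndim == 0 else out


def classify_microcytic_anemia(panel: ErythrocytePanel) -> bool:
    """Microcytic hypochromic trait AND anemia, from a complete panel."""
    return bool(
        classify_microcytic_hypochromic(panel.mcv, panel.mch)
        and classify_anemia(panel.hct, panel.hb, panel.sex)
    )


def annotate_phenotypes(pheno: pd.DataFrame, derive: bool = False) -> pd.DataFrame:
    """Add derived index columns and boolean flags to a phenotype table.

    Expects columns rbc, hb, hct and sex (1=male/0=female or "male"/"female");
    when ``derive`` is true, mcv/mch/mchc are recomputed from rbc/hb/hct,
    otherwise existing columns are used.  Adds mche (microcytic hypochromic
    erythrocytes), anemia and mcha (microcytic anemia) flags.
    """
    out = pheno.copy()
    if derive or not {"mcv", "mch", "mchc"}.issubset(out.columns):
        mcv, mch, mchc = derive_indices(out["rbc"], out["hb"], out["hct"])
        out["mcv"], out["mch"], out["mchc"] = mcv, mch, mchc
    out["mche"] = classify_microcytic_hypochromic(out["mcv"], out["mch"]).astype(int)
    out["anemia"] = classify_anemia(out["hct"], out["hb"], out["sex"]).astype(int)
    out["mcha"] = (out["mche"].astype(bool) & out["anemia"].astype(bool)).astype(int)
    return out
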