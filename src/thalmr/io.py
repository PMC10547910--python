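"""Readers, writers and run configuration.

Genotypes come in as a biallelic GT-bearing VCF (read with cyvcf2) or as a
TSV dosage matrix coded 0/1/2 (first column = sample ID); phenotypes as a TSV
with one row per participant.  Results go out as TSV (association, LD,
surrogate) and JSON (MR reports).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SampleMismatchError, ThalmrError

log = logging.getLogger("thalmr")

__all__ = [
    "GenotypeMatrix",
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_table",
    "write_json",
    "load_config",
    "align_samples",
]


@dataclass
class GenotypeMatrix:
    """Participants x variants additive dosage matrix with variant metadata.

    ``dosages``: DataFrame indexed by sample ID, one column per variant,
    values in {0, 1, 2} with NaN for missing genotypes.  ``variants``:
    DataFrame indexed by variant ID with columns chrom, pos, ref, alt.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self):
        missing = [v for v in self.dosages.columns if v not in self.variants.index]
        if missing:
            raise ConfigError(f"variants missing metadata: {missing}")

    @property
    def samples(self) -> list:
        return list(self.dosages.index)

    def subset(self, variant_ids) -> "GenotypeMatrix":
        bad = [v for v in variant_ids if v not in self.dosages.columns]
        if bad:
            raise ConfigError(f"unknown variant(s): {bad}")
        return GenotypeMatrix(
            dosages=self.dosages[list(variant_ids)],
            variants=self.variants.loc[list(variant_ids)],
        )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, meta, cols = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ThalmrError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} ({rec.ID}); "
                "only biallelic records are supported"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        ids.append(vid)
        cols.append(dos)
        meta.append({"variant": vid, "chrom": rec.CHROM, "pos": rec.POS,
                     "ref": rec.REF, "alt": rec.ALT[0]})
    if not ids:
        raise ThalmrError(f"no variant records in {path}")
    dosages = pd.DataFrame(np.column_stack(cols), index=samples, columns=ids)
    dosages.index.name = "sample"
    return GenotypeMatrix(dosages=dosages, variants=pd.DataFrame(meta).set_index("variant"))


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.stack().pipe(lambda s: s[~s.isin([0, 1, 2])])
    if not bad.empty:
        raise ThalmrError(
            f"non-0/1/2 dosage values in {path}: rows {list(bad.index[:3])}"
        )
    meta = pd.DataFrame(
        {"variant": df.columns, "chrom": ".", "pos": 0, "ref": ".", "alt": "."}
    ).set_index("variant")
    df.index.name = "sample"
    return GenotypeMatrix(dosages=df.astype(float), variants=meta)


def read_genotypes(path) -> GenotypeMatrix:
    """Read genotypes from a .vcf (GT field, biallelic) or a .tsv dosage matrix."""
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    return _read_dosage_tsv(path)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as VCFv4.2 text (.vcf) or a dosage TSV."""
    path = Path(path)
    if path.suffix != ".vcf":
        out = gm.dosages.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t", float_format="%g")
        return
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in gm.samples) + "\n")
        order = gm.variants.sort_values(["chrom", "pos"]).index
        for vid in order:
            m = gm.variants.loc[vid]
            gts = [gt_code.get(v, "./.") for v in gm.dosages[vid]]
            fh.write(
                f"{m['chrom']}\t{int(m['pos'])}\t{vid}\t{m['ref']}\t{m['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_phenotypes(path, required=None, index_col: str = "sample") -> pd.DataFrame:
    """Read a participant-level phenotype TSV; ``required`` columns must exist."""
    df = pd.read_csv(path, sep="\t")
    if index_col in df.columns:
        df = df.set_index(index_col)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ConfigError(f"phenotype file {path} missing column(s): {missing}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
    log.info("wrote %s (%d rows)", path, len(df))


def write_json(obj, path) -> None:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default, sort_keys=True)
        fh.write("\n")
    log.info("wrote %s", path)


def align_samples(gm: GenotypeMatrix, pheno: pd.DataFrame, allow_subset: bool = False):
    """Align genotype and phenotype tables on sample ID.

    By default any mismatch is a hard error; ``allow_subset`` restricts both
    to the common samples instead.
    """
    g_ids, p_ids = set(gm.samples), set(pheno.index)
    common = [s for s in gm.samples if s in p_ids]
    if not allow_subset and (g_ids != p_ids):
        only_g, only_p = sorted(g_ids - p_ids)[:5], sorted(p_ids - g_ids)[:5]
        raise SampleMismatchError(
            f"sample IDs differ between genotype and phenotype files "
            f"(genotypes-only: {only_g}, phenotypes-only: {only_p}); "
            "pass allow_subset=True / --allow-subset to intersect"
        )
    if not common:
        raise SampleMismatchError("no samples in common")
    return (
        GenotypeMatrix(gm.dosages.loc[common], gm.variants),
        pheno.loc[common],
    )


@dataclass
class RunConfig:
    """Structured configuration for an end-to-end run."""

    genotypes: str = ""
    phenotypes: str = ""
    gold_deletions: str = ""
    covariates: list = field(default_factory=lambda: ["age", "sex", "bmi", "smoking"])
    log_transform_traits: list = field(
        default_factory=lambda: [
            "total_cholesterol", "hdl_cholesterol", "ldl_cholesterol",
            "triglyceride", "albuminuria",
        ]
    )
    genome_wide_p: float = 5e-8
    subthreshold_p: float = 1e-4
    exclusion_rules: dict = field(default_factory=dict)  # trait -> history flag column
    mr: list = field(default_factory=list)  # list of dicts: instrument/exposure/outcome
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        for name in ("genome_wide_p", "subthreshold_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.genome_wide_p >= self.subthreshold_p:
            raise ConfigError(
                "genome_wide_p must be smaller than subthreshold_p "
                f"({self.genome_wide_p} >= {self.subthreshold_p})"
            )


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(**data)
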