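# thalmr

Tag-SNV surrogates for the --SEA alpha-thalassemia deletion and
single-instrument Mendelian randomization of erythrocyte indices against
cardiometabolic traits and diabetes.

## What this is for

The --SEA deletion removes both alpha-globin genes from one chromosome 16
haplotype and is the dominant cause of alpha-thalassemia in Taiwan. Carriers
have more, smaller, hemoglobin-poorer red cells (high RBC count, low MCV and
MCH). The deletion is invisible to SNV arrays, but three Asian-specific SNVs
(*NPRL3* rs191086839, *LUC7L* rs372755452, *PGAP6* rs375498857) sit in strong
linkage disequilibrium with it and can stand in as genotyping surrogates.
That surrogate in turn makes the deletion's MCV/MCH effect usable as a
genetic instrument: if a variant changes the outcome *only* through the
erythrocyte index, two-stage least squares (2SLS) estimates the causal
effect of the index on lipids, HbA1c, bilirubin and diabetes risk.

The package is aimed at statistical geneticists and epidemiologists who want
this analysis chain as a tested, reusable library: a synthetic cohort
generator with the full architecture (deletion haplotype, tags in LD,
mediated outcomes), hematology classification rules, additive association
scans with significance tiers, EM-based LD, surrogate diagnostics
(sensitivity/specificity/PPV/NPV), and the 2SLS/Wald MR machinery.

## The model in brief

For instrument G (tag dosage 0/1/2), exposure T_A (MCV or MCH), outcome T_B
and covariates C:

* first stage: `T_A = a0 + a1·G + a'C + e1`
* reduced form: `T_B = b0 + b1·G + b'C + e2`
* causal (2SLS / Wald): `theta = b1 / a1`, computed as `(Z'X)⁻¹Z'y` with
  structural-residual SEs
* instrument strength: `F = R²(n−2)/(1−R²)`, weak if F ≤ 10
* power: noncentral chi-square with `NCP = n·R²·effect²`
* mediation check: the G coefficient in `T_B ~ G + T_A + C` should vanish
  under full mediation.

LD between unphased variant pairs is estimated by EM over the
double-heterozygote ambiguity, giving D, |D'| and r². Full details and
assumptions are in `docs/methods.md`.

## Worked example

```python
import numpy as np
from thalmr import mr
from thalmr.cohort import default_published_params, generate_cohort

cohort = generate_cohort(default_published_params(n_participants=100_000, seed=5))
ph = cohort.phenotypes
report = mr.two_stage_least_squares(
    exposure=ph["mch"],
    outcome=np.log(ph["total_cholesterol"]),
    instrument=cohort.genotypes.dosages["rs375498857"],
    covariates=ph[["age", "sex", "bmi", "smoking"]],
)
```

Running `python examples/06_mendelian_randomization.py` (which does the
above) prints:

```
stage                      beta        SE         p
observational T_A-T_B     0.0024    0.0003    3.7e-22
first stage   G_A-T_A    -7.1266    0.0280          0
reduced form  G_A-T_B    -0.0148    0.0028   2.11e-07
causal (2SLS) IV-T_B      0.0021    0.0004   2.09e-07
G_A-T_B adj T_A           0.0041    0.0036      0.259

first-stage R^2 = 0.3569, F = 55507.2 (weak instrument: False), power = 1.000
attenuation verdict: mediated
```

Reading it: each tag allele lowers MCH by ~7.1 pg (first stage) and log
total cholesterol by ~0.015 (reduced form); their ratio, the causal
estimate, says a 1 pg higher MCH raises log total cholesterol by ~0.0021
(generating truth 0.0023). The genotype-outcome association disappears once
MCH is adjusted for (p = 0.26) — the signature of an effect fully mediated
by the erythrocyte index — and F ≫ 10 rules out weak-instrument bias.

The other scripts in `examples/` walk through cohort simulation, index
derivation and classification, the regional association scan, the LD matrix,
and the surrogate diagnostics, one capability each.

## Command line

A thin CLI wraps the same functions for file-based pipelines:

```bash
thalmr simulate --n 20000 --seed 1 --out cohort/
thalmr assoc --vcf cohort/genotypes.vcf --pheno cohort/phenotypes.tsv \
             --trait mch --covars age,sex,bmi,smoking --out assoc.tsv
thalmr ld --vcf cohort/genotypes.vcf --out ld.tsv
thalmr surrogate --vcf cohort/genotypes.vcf --gold deletions.tsv --out metrics.tsv
thalmr mr --vcf cohort/genotypes.vcf --pheno cohort/phenotypes.tsv \
          --instrument rs375498857 --exposure mch \
          --outcome total_cholesterol --log-outcome --out mr.json
thalmr report --config run.yaml   # config-driven end-to-end run
```

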