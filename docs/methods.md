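# Methods

## Scientific setting

The --SEA deletion removes both alpha-globin genes from one copy of
chromosome 16p13.3 and is the dominant cause of alpha-thalassemia in Taiwan
(carrier frequency roughly 3.5–4%). Carriers have a raised erythrocyte count
and small, hemoglobin-poor red cells (low MCV and MCH). Because the deletion
itself is invisible to SNV genotyping arrays, three Asian-specific SNVs in
strong linkage disequilibrium with the deletion haplotype — in *NPRL3*
(rs191086839), *LUC7L* (rs372755452) and *PGAP6* (rs375498857) — serve as
genotyping surrogates. Once a surrogate is in hand, the deletion's effect on
MCV/MCH becomes a natural genetic instrument for asking whether erythrocyte
indices *cause* differences in cardiometabolic traits (lipids, HbA1c, total
bilirubin) and diabetes risk, via single-instrument Mendelian randomization.

This package implements that full analysis chain — hematology rules,
additive association scans, EM-based LD, surrogate diagnostics, and 2SLS MR —
together with a synthetic cohort generator so that every stage is testable
without access to the individual-level biobank data (which is request-only).

## The synthetic cohort generator

Each participant receives two haplotypes drawn i.i.d.; a haplotype carries
the deletion allele D with probability `q` (default 0.019) and, conditional
on its D status, each tag allele independently with probability
`p_tag_given_del` or `p_tag_given_nodel`. Dosage is the sum over the two
haplotypes, so Hardy–Weinberg holds by construction. The defaults
`p_tag_given_del = 0.85 / 0.90 / 0.85` and `p_tag_given_nodel = 0.00035 /
0.00105 / 0.00175` for the three tags reproduce the published carrier-level
sensitivity (85/90/85%) and specificity (99.93/99.79/99.65%) of the tags
against PCR-confirmed deletion carriage: for a heterozygous carrier the
probability of carrying the tag is ≈ `p_tag_given_del`, and for a
non-carrier ≈ `2 · p_tag_given_nodel`. A consequence worth knowing is that
the expected haplotype-level tag–tag r² under this model is
`D'² / (p1(1-p1) p2(1-p2))` with `D = q·p1d·p2d + (1-q)·p1n·p2n − p1·p2`,
which evaluates to ≈ 0.63–0.70 for the default pairs and ≈ 0.76–0.85 for
tag–deletion pairs; the LD tests assert agreement with this closed form
rather than a round number.

Erythrocyte traits are linear in the D dosage:
`trait = baseline + beta_D · dosage + Σ beta_c (c − mean_c) + N(0, sd)`,
with per-allele betas fixed at the published additive-model estimates
(RBC +1.1133 10⁶/µl, Hb −1.3864 g/dl, Hct −2.5319%, MCV −21.6882 fl,
MCH −7.9492 pg, MCHC −1.3718 g/dl), baselines at the non-carrier medians of
the sequenced cohort (e.g. MCV 92.13 fl, MCH 29.90 pg) and covariate effects
on MCV/MCH at the published stepwise estimates. Covariates are centered in
the generating equation so baselines read directly as non-carrier means at
average covariates. Covariate distributions (age ~ Uniform(30, 70), sex ~
Bernoulli(0.5), BMI ~ Normal(23.9, 3.5²), smoking ~ Bernoulli(0.15)) match
the cohort summaries. Residual SDs (e.g. 5.5 fl for MCV, 1.5 pg for MCH) are
calibrated so trait IQRs approximate the cohort tables; they are package
defaults, not published quantities, because residual variances are never
printed. A config switch (`derive_indices_from_counts`) instead simulates
only RBC/Hb/Hct and derives MCV/MCH/MCHC exactly through the hematology
module.

Downstream outcomes follow
`y = intercept + theta · mediator + delta · dosage + covariate terms + noise`,
stored as `exp(y)` for log-scale traits (lipids) and as
`Bernoulli(expit(·))` for binary ones. `delta = 0` (the default) encodes the
MR exclusion restriction: the genotype touches the outcome only through the
mediator. Default thetas equal the published causal estimates (e.g. 0.0023
log-mg/dl total cholesterol per pg MCH; −0.0071% HbA1c per fl MCV). For
diabetes the published coefficients are only coherent on a 0–100 percentage
scale (+0.2629 per allele ≈ +0.26 percentage points, OR ≈ 1.03); the
generator stores diabetes as 0/1 with a logistic slope of −0.0043 per pg
MCH, which reproduces that per-allele risk difference at 9.46% prevalence.
Analyses that want the published scale multiply by 100.

One `numpy.random.default_rng(seed)` stream drives everything in a
documented, fixed draw order (deletion haplotypes, tag haplotypes in list
order, covariates, trait noise in rbc/hb/hct/mcv/mch/mchc order, outcomes in
list order, history flags), so cohorts are byte-stable for a given seed.
Homozygous deletion genotypes are permitted under Hardy–Weinberg by default;
`exclude_hom_deletion=True` resamples them away (--SEA homozygosity is
Hb Bart's hydrops fetalis and absent from adult cohorts), leaving the
heterozygote fraction at `2q/(1+q)`.

What the generator does **not** emulate: population structure and kinship,
genotyping/imputation error, trait skew and heavy tails (all residuals are
Gaussian), confounding between covariates, and correlated history flags.
Passing tests therefore demonstrate the estimators' correctness and
calibration under the stated model, not robustness to those real-data
features.

## Hematology

`MCV = 10·Hct/RBC` (fl), `MCH = 10·Hb/RBC` (pg), `MCHC = 100·Hb/Hct` (g/dl);
the unit constants are the standard clinical factors. All classification
thresholds are strict `<`: microcytic hypochromic requires MCV < 80 fl AND
MCH < 25 pg; anemia is Hct < 40% or Hb < 13 g/dl for men and Hct < 36% or
Hb < 12 g/dl for women; microcytic anemia is the conjunction.

## Association

Additive coding counts the minor allele (0/1/2). Linear fits are OLS with
classical SEs and two-sided t tests; lipid-like traits are natural-log
transformed before fitting (the choice of natural over base-10 log only
rescales betas by a constant). Logistic fits are ML with Wald tests;
detected separation (non-convergence or |beta| > 20 under the iteration
cap) is returned as a flagged result with NaN estimates rather than a
silent number. Missing data are handled complete-case per model.
Trait-specific history exclusions mask the trait (not the row) so other
analyses keep the participant. Tiers: p < 5e-8 genome-wide, 5e-8 ≤ p < 1e-4
subthreshold, both strict. Stepwise selection is forward entry at
p_enter = 0.05 with backward elimination at p_remove = 0.10 (the documented
defaults of the legacy statistical packages that popularized the procedure),
both configurable; forced covariates never leave, and candidates that would
make the design rank-deficient can never enter.

## Linkage disequilibrium

Haplotype frequencies for a variant pair come from EM over the
double-heterozygote phase ambiguity, initialized deterministically at
linkage equilibrium, converged when the largest frequency change is < 1e-10
(cap 1000 iterations; non-convergence is flagged with the last iterate).
`D = p_AB − p_A p_B`; `r² = D²/(p_A(1−p_A)p_B(1−p_B))`; D' is reported as
|D'| in [0, 1] with the usual positive/negative D_max normalization and
D' = 0 when D = 0. A dosage-correlation fallback (`method="dosage-corr"`)
exists for degenerate inputs. Tests pin EM to an exhaustive 0.01-step
grid-search MLE and to the closed-form generator expectation.

## Mendelian randomization

For instrument G, exposure T_A, outcome T_B, covariates C, the report fills
five coefficient blocks: observational (T_B ~ T_A + C), first stage
(T_A ~ G + C), reduced form (T_B ~ G + C), the 2SLS causal estimate, and
the attenuation model (T_B ~ G + T_A + C, reporting G). The just-identified
2SLS estimator is `(Z'X)⁻¹Z'y` with Z = [1, G, C], X = [1, T_A, C]; its
covariance uses the structural residuals `y − X·beta_2SLS`
(`σ²(Z'X)⁻¹Z'Z(X'Z)⁻¹`), not the naive second-stage residuals. With no
covariates this equals the Wald ratio `beta_GY / beta_GX` exactly (asserted
to 1e-10); the Wald SE uses the first-order delta method. First-stage R² is
the increment from adding G over the covariates; instrument strength is
`F = R²(n−2)/(1−R²)` with F ≤ 10 flagged weak. Power uses the
noncentrality-parameter approximation `NCP = n · R²_first · effect²` with
the effect in standardized (SD-of-exposure, SD-of-outcome) units and
`power = P(χ²₁(NCP) > χ²₁ crit)`; an externally computed NCP can be
substituted. Binary outcomes default to a linear-probability second stage
(one beta on the risk-difference scale, matching a single printed
coefficient); `second_stage="logistic"` substitutes the fitted exposure into
a logistic model instead — the two differ in scale (risk difference vs
log-odds) and are not interchangeable. The 2SLS SE convention for binary
outcomes is the same structural-residual form; published reports rarely
state their SE provenance, so SEs are not asserted against external values.
The attenuation verdict is "mediated" when the unadjusted genotype-outcome
p < 0.05 but the adjusted p > 0.05 (both thresholds configurable).

## Numerical and design choices

* VCF reading uses cyvcf2 (biallelic, GT-based; multi-allelic records are
  rejected with position context); VCF output is a minimal VCFv4.2 text
  emitter. Dosage TSVs round-trip exactly.
* Sample alignment between genotype and phenotype files is by ID with a
  hard error on mismatch; intersection is opt-in (`allow_subset`).
* Degenerate designs raise typed errors naming the offending columns;
  per-variant failures inside a regional scan become flagged rows.
* All p-values are two-sided.
* With a degenerate perfect instrument (G ≡ T_A) the attenuation block is
  unidentified and reported as NaN while the causal block reduces to OLS.

## Problem sizes used by the test suite

Monte-Carlo checks run at sizes chosen to keep the full suite under a
minute while leaving 3-SE bands tight enough to be meaningful: allele-
frequency recovery 100 cohorts of n = 20,000; 2SLS parameter recovery 200
cohorts of n = 20,000; type-I-error calibration 2,000 replicates of n = 500;
power-vs-simulation 3,000 replicates of n = 2,000; LD and mediation
properties on one shared cohort of n = 50,000. The acceptance script runs
the full pipeline on one cohort of n = 100,000.

## Limitations

The estimators assume the single-instrument, homogeneous-effect MR model;
there is no multi-instrument pooling (IVW, MR-Egger), no robustness to
horizontal pleiotropy beyond the explicit `delta` diagnostic, and no
summary-statistics mode. LD handling is strictly pairwise and biallelic.
The reconstructed reference confusion tables are derived from published
marginals (carrier counts, 60 PCR-confirmed deletions among 1,474 tested,
and the printed percentages), not from original data; they are labelled
synthetic in the code.
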