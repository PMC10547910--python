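"""Single-instrument Mendelian randomization: is the MCH -> total-cholesterol
association causal?  A tag SNV instruments MCH in a 2SLS analysis.
"""

import numpy as np

from thalmr import mr
from thalmr.cohort import default_published_params, generate_cohort

cohort = generate_cohort(default_published_params(n_participants=100_000, seed=5))
ph = cohort.phenotypes
covs = ph[["age", "sex", "bmi", "smoking"]]

report = mr.two_stage_least_squares(
    exposure=ph["mch"],
    outcome=np.log(ph["total_cholesterol"]),  # lipids analyzed on the log scale
    instrument=cohort.genotypes.dosages["rs375498857"],
    covariates=covs,
    effect_std=0.05,
)

print("stage                      beta        SE         p")
for label, st in [
    ("observational T_A-T_B", report.stage_ta_tb),
    ("first stage   G_A-T_A", report.stage_ga_ta),
    ("reduced form  G_A-T_B", report.stage_ga_tb),
    ("causal (2SLS) IV-T_B ", report.stage_iv),
    ("G_A-T_B adj T_A      ", report.stage_adj),
]:
    print(f"{label}  {st.beta:9.4f}  {st.se:8.4f}  {st.p:9.3g}")
print(f"\nfirst-stage R^2 = {report.r2_first_stage:.4f}, "
      f"F = {report.f_stat:.1f} (weak instrument: {report.weak_instrument}), "
      f"power = {report.power:.3f}")
# The 2SLS beta is the causal log-cholesterol change per pg MCH (generating
# truth 0.0023).  The genotype-outcome association subsides once MCH is in
# the model (adjusted row), the signature of full mediation; F >> 10 rules
# out weak-instrument bias.

att = mr.attenuation_analysis(
    ph["mch"], np.log(ph["total_cholesterol"]),
    cohort.genotypes.dosages["rs375498857"], covs,
)
print(f"attenuation verdict: {att.verdict}")
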