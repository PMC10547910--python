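"""Derive erythrocyte indices from a complete blood count and classify
microcytic hypochromic trait, anemia, and microcytic anemia.

MCV = 10*Hct/RBC (fl), MCH = 10*Hb/RBC (pg), MCHC = 100*Hb/Hct (g/dl);
microcytic hypochromic: MCV < 80 and MCH < 25; anemia by sex-specific
Hct/Hb cutoffs.
"""

from thalmr import hematology

panels = [
    # (rbc 10^6/ul, hb g/dl, hct %, sex)  -- a normal panel and a carrier-like one
    (5.0, 15.0, 45.0, "male"),
    (5.9, 12.1, 41.5, "female"),
]
for rbc, hb, hct, sex in panels:
    mcv, mch, mchc = hematology.derive_indices(rbc, hb, hct)
    panel = hematology.ErythrocytePanel(rbc, hb, hct, mcv, mch, mchc, sex)
    print(f"RBC {rbc:.1f}, Hb {hb:.1f}, Hct {hct:.1f} ({sex})")
    print(f"  MCV {mcv:.1f} fl, MCH {mch:.1f} pg, MCHC {mchc:.1f} g/dl")
    print(f"  microcytic hypochromic: {hematology.classify_microcytic_hypochromic(mcv, mch)}")
    print(f"  anemia: {hematology.classify_anemia(hct, hb, sex)}")
    print(f"  microcytic anemia: {hematology.classify_microcytic_anemia(panel)}")
# The second panel shows the deletion-carrier signature: a raised RBC count
# with small, hemoglobin-poor cells (low MCV/MCH) despite near-normal Hct.
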