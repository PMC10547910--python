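"""Pairwise linkage disequilibrium among the tag SNVs and the deletion,
estimated from unphased dosages by EM over the double-heterozygote ambiguity.
"""

from thalmr import ld
from thalmr.cohort import default_published_params, generate_cohort
from thalmr.ld import HaplotypeFreqs

# closed-form statistics from known haplotype frequencies
stats = ld.ld_from_hapfreqs(HaplotypeFreqs(0.7, 0.1, 0.1, 0.1))
print(f"hand fixture: D = {stats.D:.3f}, D' = {stats.d_prime:.3f}, r^2 = {stats.r2:.4f}")

cohort = generate_cohort(default_published_params(n_participants=50_000, seed=3))
r2, dprime = ld.ld_matrix(cohort.genotypes.dosages)
print("\nEM r^2 matrix (50,000 unphased diploid genotypes):")
print(r2.round(3).to_string())
# All tag-deletion r^2 values are high (strong LD): each tag allele almost
# always occurs on a deletion haplotype, which is what makes the tags usable
# as genotyping surrogates for the deletion.
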