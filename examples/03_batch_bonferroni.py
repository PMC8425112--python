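"""Batch pattern search: 5 SNPs against one ordinal exposure.

Uses the bundled generator that emulates the shape of a published
example dataset (n=2000, five Hardy-Weinberg SNPs, a 3-level
exposure) with interactions planted on snp2 and snp3.  The Bonferroni
threshold across the 5 pairs is 0.05/5 = 0.01.
"""

from snpxe import make_simdata2_like, snpxe_batch
from snpxe.io import format_pvalue

data = make_simdata2_like(seed=1)
res = snpxe_batch(data, [f"snp{i}" for i in range(1, 6)],
                  "env_g3", "outcome", alpha=0.05)

print(f"pairs tested: {res.m_tests}; corrected threshold: "
      f"{res.alpha_corrected:g} (= {res.alpha:g}/{res.m_tests})\n")
show = res.table[["SNP", "maj/min", "MAF", "SNP Mode", "p_SNPiv",
                  "Interaction Pattern", "p_int", "significant"]].copy()
show["MAF"] = show["MAF"].map(lambda v: f"{v:.3f}")
show["p_SNPiv"] = show["p_SNPiv"].map(format_pvalue)
show["p_int"] = show["p_int"].map(format_pvalue)
print(show.to_string(index=False))
print("\n'significant' marks pairs whose selected-pattern interaction "
      "p-value beats the Bonferroni-corrected threshold.  Interactions "
      "are planted on snp2 and snp3; snp3 is detected reliably, while "
      "snp2's effect rides on a rare allele (MAF 0.071) and only clears "
      "the corrected threshold in some realizations — a power lesson in "
      "itself.")
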