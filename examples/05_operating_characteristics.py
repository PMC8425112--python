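"""Small operating-characteristic study: calibration and recovery.

Scaled-down Monte-Carlo (a few hundred fits) illustrating the two
properties that matter for interpretation: a FIXED pattern's
interaction test is calibrated under the null, while the SEARCHED
minimum p-value is not — the price paid for scanning 27 patterns —
and best-BIC selection recovers a strongly planted pattern.
"""

from snpxe.benchmarks import pattern_recovery, type1_error

rate = type1_error(n_reps=300, n=500, alpha=0.05, seed=3)
print(f"type-I error of the fixed Full_AE_oo interaction LRT "
      f"(300 null replicates, n=500, alpha=0.05): {rate:.3f}")

rec = pattern_recovery("Int_RE_or", (4.3, 1.8), n_reps=30, n=2000, seed=3)
print(f"\nplanted Int_RE_or with ORs 4.3/1.8, n=2000, 30 replicates:")
print(f"  selected an interaction-only structure: {100 * rec['structure_rate']:.0f}%")
print(f"  selected the exact planted pattern:     {100 * rec['exact_rate']:.0f}%")
print(f"  modal selected pattern: {rec['modal_pattern']}")
print("\nA calibrated fixed test plus high recovery under the truth is "
      "what makes the searched family informative; the searched minimum "
      "p-value itself is anti-conservative and needs external validation.")
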