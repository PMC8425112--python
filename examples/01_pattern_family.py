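"""Enumerate the interaction-pattern family and decode a label.

The search space for one SNP-environment pair: 27 patterns for an
ordinal exposure, 18 for a categorical one (reversing a user-chosen
reference makes no sense, so _or/_rr labels are dropped).
"""

from snpxe import enumerate_patterns, parse_label

ordinal = enumerate_patterns("ordinal")
categorical = enumerate_patterns("categorical")
print(f"ordinal environment:     {len(ordinal)} patterns")
print(f"categorical environment: {len(categorical)} patterns")

print("\nFamily by structure:")
for structure in ("Full", "Mint_SNP", "Mint_Env", "Int"):
    labels = [s.label for s in ordinal if s.structure.value == structure]
    print(f"  {structure:9s} ({len(labels):2d}): {', '.join(labels)}")

spec = parse_label("Int_RE_ro")
print(f"\n'Int_RE_ro' decodes to: structure={spec.structure.value} "
      f"(interaction only), mode={spec.mode.value} (GG vs rest), "
      f"SNP direction={spec.snp_dir.value}, env direction={spec.env_dir.value}")
print("A pattern label therefore names a complete regression model "
      "for the pair, not just a test.")
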