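"""Resolve allele-specific copy numbers from pyrosequencing ratios.

A stallion heterozygous G/A at a 5-copy fragment with 60% G signal carries
3 G-copies and 2 A-copies (G3A2); 40% G signal means G2A3 — same genotype,
same total copy number, different paternal line.
"""

from ylineage import pattern_census, resolve_split

for rbv in (0.60, 0.40, 0.78, 0.50):
    s = resolve_split(total_cn=5, rbv=rbv, alleles=("G", "A"), locus_id="9")
    extra = f" (ambiguous, runner-up {s.alternative})" if s.ambiguous else ""
    print(f"RBV={rbv:.2f} -> {s.label}{extra}")

splits = [
    resolve_split(a + b, a / (a + b), alleles=("G", "A"), locus_id="9")
    for a, b in [(1, 1), (1, 2), (1, 4), (2, 1), (2, 3), (3, 2)]
]
census = pattern_census(splits)
print(f"\nlocus 9 combination patterns: {census['9']} "
      f"({len(census['9'])} distinct patterns)")
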