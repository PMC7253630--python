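"""Haplotype and nucleotide diversity for population samples.

Reproduces published-style diversity rows from carrier-count spectra: h is
the bias-corrected probability that two random chromosomes differ in
haplotype, with Nei's sampling standard error.
"""

from ylineage import FrequencySpectrum, haplotype_diversity, nucleotide_diversity
from ylineage.simulate import table_fixture

print("population  spectrum                h      SE")
for pop, spectrum in table_fixture("table1_spectra").items():
    h, se = (0.0, 0.0) if sum(spectrum) < 2 else haplotype_diversity(
        FrequencySpectrum(spectrum)
    )
    print(f"{pop:10s}  {str(spectrum):22s}  {h:.3f}  {se:.3f}")

pi, pi_se = nucleotide_diversity([(("G",), 6), (("A",), 1)], L=1000)
print(f"\ntwo haplotypes (6 vs 1 carriers) one site apart over 1000 sites:"
      f" pi = {pi:.6f} +/- {pi_se:.6f} per site")
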