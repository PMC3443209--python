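"""How many clones to sequence when a primer pair amplifies two gene copies.

If an individual carries two heterozygous gene copies, up to four distinct
haplotypes are mixed in one PCR product.  The probability that n clones
observe every haplotype at least once follows from multinomial
inclusion-exclusion.
"""

from tlrpop.paralog import clone_coverage_probability, min_clones_for

freqs = [0.25] * 4
for n in (12, 18, 24, 33):
    p = clone_coverage_probability(n, freqs)
    print(f"{n:>3} clones, 4 equifrequent haplotypes: coverage {p:.4f}")

print()
print("clones for 99.6% coverage of 4 haplotypes:",
      min_clones_for(freqs, 0.996))
print("clones for 99.9% coverage of 2 haplotypes:",
      min_clones_for([0.5, 0.5], 0.999))
print()
print("24 clones give 99.6% coverage, which is why two dozen clones per")
print("individual suffice to enumerate the haplotypes of a duplicated locus.")
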