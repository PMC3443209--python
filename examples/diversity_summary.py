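"""Per-locus diversity of the 12 island founders, at the protein-variant level.

Builds the founder genotype fixture shipped with the package and computes,
for each polymorphic TLR locus: the number of variants, observed
heterozygosity (fraction of heterozygous founders), Nei's unbiased expected
heterozygosity, and the exact enumeration Hardy-Weinberg p-value.
"""

from tlrpop.datasets import founder_genotype_fixture
from tlrpop.popstats import locus_summary, round_half_up

fixture = founder_genotype_fixture()
rows = [locus_summary(locus, genos).rounded() for locus, genos in fixture.items()]

print(f"{'locus':8} {'variants':>8} {'Ho':>6} {'He':>6} {'HWE p':>6}")
for r in rows:
    print(f"{r.locus:8} {r.n_variants:>8} {r.ho:>6.3f} {r.he:>6.3f} {r.hwe_p:>6.3f}")
mean_ho = round_half_up(sum(r.ho for r in rows) / len(rows))
mean_he = round_half_up(sum(r.he for r in rows) / len(rows))
print(f"{'Mean':8} {'':8} {mean_ho:>6.3f} {mean_he:>6.3f}")
print()
print("Ho and He track each other closely at every polymorphic locus: the")
print("founder cohort retains heterozygosity despite the bottleneck.  The")
print("exact p-values are enumeration-based, so they are meaningful even")
print("at n = 12 where chi-square tests are not.")
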