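"""Detecting paralog coamplification from genotype matrices and clones.

Overlays two gene copies divergent at 8 fixed sites (as when one primer
pair amplifies a duplicated locus), scans the merged genotypes for
universally heterozygous sites, and screens clone haplotypes by
PCR-replicate support to bound the gene copy number.
"""

from tlrpop.paralog import (
    all_het_trio_probability,
    constant_het_scan,
    copy_number_bound,
    replicate_supported_haplotypes,
)
from tlrpop.synthdata import SimConfig, overlay_paralogs, simulate_clones

cfg = SimConfig(seed=17, length_bp=947, paralog_divergence_sites=8)
table, truth = overlay_paralogs(cfg)
scan = constant_het_scan(table, "P1", cfg.length_bp)
print("planted divergent sites:", truth.paralog_sites["P1"])
print("constant-het sites found:", scan.constant_het_sites)
print(f"fraction of amplicon: {100 * scan.constant_fraction:.1f}%")
print("variable-het sites (within-copy polymorphism):", scan.variable_het_sites)
print("Mendelian-null probability of 15/15 all-het trios:",
      f"{all_het_trio_probability(15):.1e}")

# clone screen: 6 haplotypes drawn across 3 independent PCR replicates,
# with 5% chimeras
haps = ["AAAAACCCCC", "GGGGGTTTTT", "ACACACACAC", "GTGTGTGTGT", "AATTAATTAA"]
exp, _ = simulate_clones(haps, SimConfig(seed=4, chimera_rate=0.05,
                                         clone_draws=24, replicate_count=3))
supported, candidates = replicate_supported_haplotypes(exp)
print(f"\nclone haplotypes in >=2 replicates: {len(supported)}")
print(f"replicate-private candidates (chimeras/errors): {len(candidates)}")
print("minimum gene copies consistent with the supported set:",
      copy_number_bound(len(supported)))
print()
print("Five replicate-supported haplotypes in one individual imply at least")
print("three coamplifying gene copies (each diploid copy contributes <= 2).")
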