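# Methods

`tlrpop` implements the analysis pipeline for Sanger-genotyped coding
amplicons (Toll-like receptor genes) in a very small, pedigreed,
bottlenecked population: twelve diploid founders of an island
reintroduction, two of which died before sampling and must be inferred
from relatives.  Everything is sized for that regime — exact enumeration
rather than asymptotics, pedigree constraints rather than population-scale
statistical phasing, and desk-scale closed forms for the sampling-design
questions (how many offspring to genotype, how many clones to sequence).

## Variant model and classification (`seqvar`)

A locus is one amplicon with a reference coding sequence and a frame
offset (position within a codon of base 1, 0–2).  Coordinates are 1-based
within the amplicon, matching how SNPs are reported in amplicon
resequencing tables.  Substitutions are classified by translating the
codon containing the site under each allele with the standard genetic
code; sites in incomplete terminal codons raise an explicit error, and
variants creating stop codons are flagged rather than dropped.

Transition/transversion tallies treat a diallelic site as one
classification.  A triallelic site is decomposed into exactly two changes
through a pivot allele chosen to minimise the transversion count (ties
broken toward the reference allele, then alphabetically).  This is the
decomposition under which a site segregating A/C/T contributes one
transition plus one transversion, which is the only reading that
reconciles a 24-SNP panel containing one triallelic site with a printed
22:3 transition:transversion split.

Amino-acid changes are classed conservative/non-conservative by fixed
physicochemical categories: nonpolar {A,V,L,I,P,F,M,W,G}, polar-uncharged
{S,T,C,Y,N,Q}, positively charged {K,R,H}, negatively charged {D,E} —
the categorisation under which Asn→Asp (polar → negative) is
non-conservative while Ile→Leu is conservative.

IUPAC consensus coding maps each unordered genotype pair to the standard
single-letter code (heterozygous double peaks → two-base ambiguity codes)
and back; only the ten unordered pairs over A/C/G/T are legal.

## Built-in reference inputs (`datasets`)

Two desk-scale datasets are shipped as code rather than files:

* **SNP panel.**  The nine-locus founder panel (24 SNPs; positions,
  alleles, annotated residue changes; fragment lengths 618–1,279 bp, mean
  1,006 bp).  Reference sequences are *synthetic*: only the SNP-bearing
  codons are meaningful.  Each is realised by searching codon backgrounds
  so that substituting the published alleles reproduces the published
  residues; the search is deterministic and the frame offsets (0
  everywhere except the TLR7 amplicon, which starts mid-codon at offset 1)
  are forced by codon-position consistency of the annotations themselves.
  All downstream classification is recomputed from these sequences.

* **Founder genotype fixture.**  Variant-level genotypes of the 12
  founders at the seven polymorphic loci, reconstructed as the integer
  configurations reproducing the published per-locus observed
  heterozygosities and (under Nei's unbiased estimator) expected
  heterozygosities.  Six configurations are uniquely determined.  The
  TLR2B row is the known exception: its published He of 0.591 is not
  attainable with two variants at n = 12 (the maximum, at counts 12:12, is
  (24/23)·0.5 = 0.522), and a parity argument shows no three-variant
  integer configuration reaches it either; the fixture therefore uses the
  smallest configuration that does — four variant states with counts
  (14, 7, 2, 1) and six heterozygotes, He = 0.5906 → 0.591.  The published
  report very likely computed that entry at the SNP-haplotype level
  despite tabulating two protein variants; we document the discrepancy
  rather than force a match.  A related surfaced inconsistency: the
  fixture's per-locus heterozygote counts force a mean multilocus
  heterozygosity of 35/12 ≈ 2.92 of seven loci, while 2.83 (SD 1.4) was
  the reported value; both numbers are surfaced, neither is adjusted.

## Pedigree inference (`pedigree`)

**Trio consistency** is the exact Mendelian predicate: an offspring pair
must be formable by one allele from each parent.

**Missing-parent inference** filters every candidate genotype of the
unsampled parent (all unordered pairs over the site's alleles) through the
trio predicate against the sampled co-parent and each offspring.  Exactly
one survivor → `unique`; several → `ambiguous`; none → `inconsistent`,
which is reported, never auto-corrected, because Mendelian violation is
precisely the paralog-coamplification signal consumed downstream.  When
both parents of a brood are unsampled, inference is joint over parent
pairs.  The design maths is the half-power law: a heterozygous unsampled
parent hides its second allele from n offspring with probability (1/2)^n,
so five offspring bound the nondetection probability at 3.125 % < 3.5 %,
and the design inverse returns the smallest n beating a target α.

**Phasing** replaces population statistical phasing with what the data
structure affords: (i) candidate haplotype pairs per individual — all
2^(h−1) pairs consistent with an h-het-site genotype; (ii) arc-consistency
pruning over the pedigree until fixed point — a child's pair must be
formable from one transmissible haplotype of each genotyped parent, and a
parent must be able to supply one haplotype of every child; (iii)
individuals reduced to a single pair are flagged `certain` (the pruning is
sound: it never removes the true pair, so certain calls are guaranteed
correct when the pedigree is); (iv) residual ambiguity is resolved by an
expectation–maximisation estimate of locus haplotype frequencies (uniform
initialisation, convergence when the largest frequency change is < 1e-6,
cap 500 iterations, lexicographic tie-break), flagged `uncertain`.  At
2–5 haplotypes per ~1 kb locus EM is adequate and fully deterministic,
which is why no coalescent-prior phasing is used.  Contradictions empty a
candidate set; the individual is flagged `inconsistent` and its
genotype-only candidates restored so output always matches the genotypes.

## Paralog detection and clone design (`paralog`)

Fixed differences between coamplified gene copies appear heterozygous in
*every* individual.  The scan keys on call-level heterozygosity with a
configurable universality threshold (default 1.0); chromatogram
peak-height information is out of scope, so "variable heterozygosity"
is approximated as sites heterozygous in some but not all individuals.
The Mendelian-null companion statistic is (1/2)^n for n independent
het×het trios all yielding heterozygous offspring (15 trios → 3.1e-5).

Clone coverage uses exact inclusion–exclusion over haplotype subsets,
P(all observed) = Σ_S (−1)^|S| (1 − Σ_{i∈S} f_i)^n, practical for the
k ≤ 8 haplotypes that matter here; simulation is retained only as a test
oracle.  The design inverse compares against the target with a 1e-4
absolute slack so that targets quoted to a few significant figures behave
as quoted (a 0.996 target accepts the exact 0.995989 achieved by 24
clones over four equifrequent haplotypes).  Chimera screening keeps clone
haplotypes observed in ≥ 2 independent PCR amplifications; sequences are
compared by exact identity (no clustering), so polymerase errors surface
as replicate-private singletons.  The copy-number lower bound is ⌈n/2⌉
distinct supported haplotypes per individual.  Distinguishing "three gene
copies" from "two copies plus frequent chimeras" is explicitly out of
scope.

## Diversity statistics (`popstats`)

* Observed heterozygosity: fraction of heterozygous individuals.
* Expected heterozygosity: Nei's unbiased estimator
  He = (2n/(2n−1))(1 − Σp²) — the only estimator reproducing the printed
  founder values from integer allele counts at n = 12 (e.g. counts 11:13
  → (24/23)(286/576) = 0.518).
* Hardy–Weinberg: full enumeration of genotype configurations conditional
  on the observed allele counts, each weighted by Levene's exact
  probability n!·2^h·Πn_a! / (Πn_g!·(2n)!), with the two-sided p-value
  summing all configurations no more probable than the observed one
  (probability ordering).  Arithmetic is exact rational, so probability
  ties cost nothing and the distribution provably sums to 1 inside every
  call.  This is preferred to Markov-chain estimation because at these
  sample sizes enumeration is instant and reproducible; third-decimal
  differences from MCMC-based software (e.g. an exact 0.103 vs a reported
  0.104) are expected and documented, not matched.
* Nucleotide diversity: π = (m/(m−1)) Σ_{i<j} 2 p_i p_j d_ij / L over
  m = 2n gene copies (equivalently, the plain mean pairwise difference per
  site over distinct gene pairs).  The standard error uses Tajima's
  stochastic variance Var(π) = ((m+1)/(3(m−1)))π/L +
  (2(m²+m+3)/(9m(m−1)))π², selectable (`variance="tajima" | "none"`)
  because published reports rarely state which variance they print; the SE
  is therefore not treated as a reproduction target.
* Statistics can be computed at the amino-acid-variant level or the
  haplotype/nucleotide level; the level is an explicit caller choice.
* Report rounding is decimal half-up to 3 decimals; undefined statistics
  (monomorphic loci) render as "-".

## McDonald–Kreitman tests (`mktest`)

Columns of two codon-aligned within-species haplotype sets are classed
fixed (invariant within each species, different between), polymorphic
(variable within either species — counted once when variable in both; a
documented dialect, since the handling in the original software is
unstated) or monomorphic.  Syn/nonsyn status uses the first species-A
haplotype as codon context; columns with > 2 states are decomposed by the
same minimal-transversion pivot rule as the variant module.  The 2×2 is
tested with G = 2ΣO·ln(O/E) on 1 df (Williams-corrected variant
available), with Fisher's exact test computed alongside as the exact
companion, and NI = (Pn/Ps)/(Dn/Ds) reported when defined.  The published
between-species comparison for this system requires second-species
alignments not shipped here, so the machinery is validated on synthetic
divergence data (type-I error calibration, planted-truth recovery) and on
user-supplied alignments.

## Synthetic data (`synthdata`)

All generators fork named substreams from one global seed
(`SeedSequence(seed, spawn_key=(crc32(name),))`), so outputs are
byte-reproducible and adding a generator never perturbs existing ones.
Defaults are the emulated study conditions: 12 founders (5 female, 7
male), 1,006 bp amplicons, 2–5 haplotypes per locus with
symmetric-Dirichlet(1) frequencies, monogamous pairs with 5 (≤ 7)
offspring each, 8 fixed inter-paralog differences, 24 clone draws over 3
independent PCR replicates.

* `simulate_population`: founder haplotypes i.i.d. from pool frequencies;
  offspring by fair Mendelian transmission of whole amplicon haplotypes
  (no intra-amplicon recombination — reasonable at ~1 kb in a 3-4
  generation pedigree).
* `hide_founders`: censors founder records (alternating sexes), keeping
  ≤ 7 genotyped offspring each, for inference testing.
* `overlay_paralogs`: merges each individual's four gene copies (two per
  locus copy) into one pseudo-genotype per site.  Copy B is monomorphic
  and divergent at the planted sites; copy A segregates.  Frequencies and
  individuals are redrawn (deterministically, within the stream) until
  every segregating site has at least one homozygous-reference
  individual, because the generated phenomenon is *variable*
  heterozygosity — universal heterozygosity is reserved for the planted
  fixed differences.
* `simulate_clones`: multinomial draws per replicate; chimeras recombine
  two uniformly chosen distinct templates at a single uniform breakpoint
  (multi-breakpoint chimeras out of scope).
* `simulate_divergence`: one substitution event per codon at most, so
  each event's syn/nonsyn label is exact by construction;
  `selection_factor` > 1 enriches nonsynonymous changes among fixed
  events only.

What the generators do **not** emulate: chromatogram/peak-height signal,
base-calling error in Sanger genotypes, intra-amplicon recombination,
coalescent genealogies, mutation-model realism beyond site-labelled
substitutions, and copy-number variation among individuals.  Passing
tests therefore demonstrate correctness of the inference machinery under
clean Mendelian data, not robustness to genotyping error.

## Problem sizes used in the test suite

Monte-Carlo oracles run at 1e6 draws (probability machinery), 1e5
replicates (allele-miss-rate recovery at n ∈ {1,3,5}), 2,000 replicates
(neutral G-test calibration), 100 seeded pedigrees (phasing truth), 30
seeds (paralog-scan recovery), and a full sweep of Hardy–Weinberg tables
with ≤ 8 diploids and ≤ 3 alleles against an independent counting oracle.
These sizes give 3-SE binomial resolution around the tested rates while
keeping the whole suite under a minute of compute.

## Known limitations

* Certainty of phase calls is conditional on the pedigree being correct;
  pedigree errors masquerade as `inconsistent` flags.
* The universal-heterozygosity scan cannot separate paralogy from extreme
  balancing selection in principle; the trio-based Mendelian-null
  probability is the disambiguating evidence.
* The HWE enumeration is exponential in alleles × sample size; it is
  intended for the ≤ a-few-dozen-diploids regime it was built for.
* MK classification assumes gap-free codon alignments as inputs;
  alignment construction is out of scope.
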