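"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the study design they stand in for: a 12-founder
island population (5 females, 7 males) genotyped at ~1 kb coding amplicons
carrying 2-5 haplotypes each, Mendelian transmission to up to 7 offspring
per pair, Sanger-style IUPAC consensus genotypes, paralog coamplification
overlaying a second gene copy divergent at a handful of fixed sites,
multinomial clone sampling (24-33 clones over >= 2 independent PCR
replicates) with optional single-breakpoint chimeras, and two-species
divergence with labelled synonymous/nonsynonymous changes for
McDonald-Kreitman testing.

Every observable is reproducible byte-for-byte from (config, seed): the
global seed is forked into named per-generator streams so adding a
generator never perturbs existing output.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .paralog import CloneExperiment, CloneRead
from .pedigree import UNKNOWN, GenotypeTable, Pedigree
from .seqvar import SnpSite

__all__ = [
    "SimConfig",
    "TruthBundle",
    "SimulatedDataset",
    "simulate_population",
    "hide_founders",
    "overlay_paralogs",
    "simulate_clones",
    "simulate_divergence",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_SAFE_CODONS = sorted(
    "".join(c) for c in itertools.product(_BASES, repeat=3)
    if "".join(c) not in _STOPS
)


def stream(seed: int, name: str) -> np.random.Generator:
    """Named substream of the global seed (stable across generator additions)."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generators.

    Defaults mirror the emulated study: 12 founders (5 female), 1,006 bp
    amplicons, 2-5 haplotypes per locus, up to 7 (default 5) offspring per
    pair, 8 fixed inter-paralog differences, 24 clones over 3 independent
    PCR replicates.
    """

    seed: int = 0
    n_loci: int = 7
    length_bp: int = 1006
    n_founders: int = 12
    n_females: int = 5
    haplotypes_per_locus: tuple[int, int] = (2, 5)
    dirichlet_alpha: float = 1.0
    haplotype_freqs: tuple[float, ...] | None = None
    offspring_per_pair: int = 5
    paralog_divergence_sites: int = 8
    clone_draws: int = 24
    replicate_count: int = 3
    chimera_rate: float = 0.0
    divergence_subs: int = 40
    polymorphic_sites: int = 20
    selection_factor: float = 1.0
    n_haps_per_species: int = 8

    def __post_init__(self):
        if self.n_founders < 2 or not 0 < self.n_females < self.n_founders:
            raise ValueError("need >= 1 female and >= 1 male founder")
        if self.n_loci < 1 or self.length_bp < 3:
            raise ValueError("need >= 1 locus of >= 3 bp")
        lo, hi = self.haplotypes_per_locus
        if lo < 1 or hi < lo:
            raise ValueError("invalid haplotypes_per_locus range")
        if not 1 <= self.offspring_per_pair <= 7:
            raise ValueError("offspring_per_pair must be 1..7")
        if self.haplotype_freqs is not None:
            if abs(sum(self.haplotype_freqs) - 1.0) > 1e-9:
                raise ValueError("haplotype_freqs must sum to 1")


@dataclass
class TruthBundle:
    """Ground truth behind the emitted observables."""

    haplotype_pools: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)
    haplotype_freqs: dict[str, tuple[float, ...]] = field(default_factory=dict)
    individual_haplotypes: dict[tuple[str, str], tuple[int, int]] = field(
        default_factory=dict
    )  # (individual, locus) -> (hap index from dam side, from sire side)
    paralog_sites: dict[str, tuple[int, ...]] = field(default_factory=dict)
    hidden_genotypes: dict[str, dict[SnpSite, tuple[str, str]]] = field(
        default_factory=dict
    )


@dataclass
class SimulatedDataset:
    config: SimConfig
    table: GenotypeTable
    pedigree: Pedigree
    truth: TruthBundle
    loci: dict[str, str] = field(default_factory=dict)  # name -> reference seq


def _random_coding_sequence(rng: np.random.Generator, length_bp: int) -> str:
    n_codons = length_bp // 3 + 1
    idx = rng.integers(0, len(_SAFE_CODONS), size=n_codons)
    return "".join(_SAFE_CODONS[i] for i in idx)[:length_bp]


def _simulate_locus_pool(
    rng: np.random.Generator, cfg: SimConfig, locus_name: str
) -> tuple[str, list[SnpSite], list[tuple[str, ...]], tuple[float, ...]]:
    """Reference, SNP sites, haplotype allele vectors and frequencies."""
    ref = _random_coding_sequence(rng, cfg.length_bp)
    lo, hi = cfg.haplotypes_per_locus
    n_hap = int(rng.integers(lo, hi + 1))
    if n_hap == 1:
        return ref, [], [()], (1.0,)
    n_sites = n_hap - 1 + int(rng.integers(0, 2))
    for _ in range(200):  # retry until every site is polymorphic in the pool
        positions = sorted(
            int(p) + 1 for p in rng.choice(cfg.length_bp, n_sites, replace=False)
        )
        sites = []
        for pos in positions:
            ref_base = ref[pos - 1]
            alt = _BASES[int(rng.integers(0, 4))]
            while alt == ref_base:
                alt = _BASES[int(rng.integers(0, 4))]
            sites.append(
                SnpSite(locus=locus_name, position=pos,
                        alleles=(ref_base, alt), ref_allele=ref_base)
            )
        vectors = {tuple(s.ref_allele for s in sites)}
        for _ in range(500):
            if len(vectors) == n_hap:
                break
            vec = tuple(
                s.alleles[int(rng.integers(0, 2))] for s in sites
            )
            vectors.add(vec)
        vecs = sorted(vectors)
        polymorphic = all(
            len({v[i] for v in vecs}) > 1 for i in range(n_sites)
        )
        if len(vecs) == n_hap and polymorphic:
            break
    else:  # pragma: no cover - retry cap
        raise RuntimeError("could not build a polymorphic haplotype pool")
    if cfg.haplotype_freqs is not None and len(cfg.haplotype_freqs) == n_hap:
        freqs = tuple(cfg.haplotype_freqs)
    else:
        freqs = tuple(rng.dirichlet([cfg.dirichlet_alpha] * n_hap))
    return ref, sites, vecs, freqs


def simulate_population(cfg: SimConfig) -> SimulatedDataset:
    """Founders drawn from locus haplotype frequencies, offspring by fair
    Mendelian transmission (no intra-amplicon recombination), genotypes
    recorded as unordered allele pairs per SNP site.

    Pairing: female i is paired with male i (males cycle if fewer females),
    each pair contributing ``offspring_per_pair`` offspring.
    """
    rng = stream(cfg.seed, "population")
    truth = TruthBundle()
    ped = Pedigree()
    table_sites: list[SnpSite] = []
    loci: dict[str, str] = {}
    pools: dict[str, tuple[list[SnpSite], list[tuple[str, ...]], tuple[float, ...]]] = {}

    for li in range(cfg.n_loci):
        name = f"L{li + 1}"
        ref, sites, vecs, freqs = _simulate_locus_pool(rng, cfg, name)
        loci[name] = ref
        pools[name] = (sites, vecs, freqs)
        table_sites.extend(sites)
        truth.haplotype_pools[name] = vecs
        truth.haplotype_freqs[name] = freqs

    table = GenotypeTable(sites=table_sites)

    founders = [f"F{i + 1}" for i in range(cfg.n_founders)]
    sexes = ["F"] * cfg.n_females + ["M"] * (cfg.n_founders - cfg.n_females)
    for ind, sex in zip(founders, sexes):
        ped.add(ind, sex=sex, founder=True)
        for name, (sites, vecs, freqs) in pools.items():
            h1, h2 = rng.choice(len(vecs), size=2, p=freqs)
            truth.individual_haplotypes[(ind, name)] = (int(h1), int(h2))

    females = founders[: cfg.n_females]
    males = founders[cfg.n_females:]
    k = 0
    for i, dam in enumerate(females):
        sire = males[i % len(males)]
        for _ in range(cfg.offspring_per_pair):
            k += 1
            off = f"O{k}"
            ped.add(off, sex="FM"[int(rng.integers(0, 2))], dam=dam, sire=sire)
            for name in pools:
                dh = truth.individual_haplotypes[(dam, name)]
                sh = truth.individual_haplotypes[(sire, name)]
                pick_d = dh[int(rng.integers(0, 2))]
                pick_s = sh[int(rng.integers(0, 2))]
                truth.individual_haplotypes[(off, name)] = (pick_d, pick_s)

    for ind in ped.individuals:
        for name, (sites, vecs, freqs) in pools.items():
            h1, h2 = truth.individual_haplotypes[(ind, name)]
            for si, site in enumerate(sites):
                table.set(ind, site, (vecs[h1][si], vecs[h2][si]))

    return SimulatedDataset(
        config=cfg, table=table, pedigree=ped, truth=truth, loci=loci
    )


def hide_founders(
    dataset: SimulatedDataset,
    k: int = 2,
    offspring_kept: int = 5,
) -> SimulatedDataset:
    """Censor ``k`` founder genotype records (alternating sexes, as when one
    male and one female founder die before sampling), keeping at most
    ``offspring_kept`` genotyped offspring per hidden founder; the hidden
    genotypes move to the truth bundle for later comparison."""
    if k == 0:
        return dataset
    ped = dataset.pedigree
    founders_with_kids = [
        f for f in sorted(ped.founders) if ped.offspring_of(f)
    ]
    if k > len(founders_with_kids):
        raise ValueError("cannot hide more founders than exist with offspring")
    by_sex = {"F": [], "M": []}
    for f in founders_with_kids:
        by_sex.setdefault(ped.individuals[f], []).append(f)
    hidden: list[str] = []
    order = itertools.cycle(["F", "M"])
    while len(hidden) < k:
        sex = next(order)
        pool = [f for f in by_sex.get(sex, []) if f not in hidden]
        if pool:
            hidden.append(pool[0])
        elif all(
            not [f for f in by_sex.get(s, []) if f not in hidden]
            for s in ("F", "M")
        ):  # pragma: no cover
            break

    table = GenotypeTable(
        sites=list(dataset.table.sites),
        genotypes={
            i: dict(g) for i, g in dataset.table.genotypes.items()
        },
    )
    truth = replace(dataset.truth)
    truth.hidden_genotypes = dict(truth.hidden_genotypes)
    dropped_offspring: set[str] = set()
    for f in hidden:
        truth.hidden_genotypes[f] = table.genotypes.pop(f)
        kids = sorted(ped.offspring_of(f))
        dropped_offspring.update(kids[offspring_kept:])
    for o in dropped_offspring:
        table.genotypes.pop(o, None)
    return SimulatedDataset(
        config=dataset.config,
        table=table,
        pedigree=ped,
        truth=truth,
        loci=dataset.loci,
    )


def overlay_paralogs(
    cfg: SimConfig,
    n_individuals: int | None = None,
    locus_name: str = "P1",
) -> tuple[GenotypeTable, TruthBundle]:
    """Coamplification of two equal-length gene copies through one primer pair.

    Copy A segregates 2-5 haplotypes (within-copy polymorphism); copy B is
    monomorphic but fixed-divergent from copy A at
    ``paralog_divergence_sites`` positions.  Each individual's four gene
    copies merge into one pseudo-genotype per site: inter-copy fixed
    differences surface as universally heterozygous sites and within-copy
    polymorphism as variable heterozygosity.  Truth records the divergent
    site set.
    """
    rng = stream(cfg.seed, "paralog-overlay")
    n = n_individuals if n_individuals is not None else cfg.n_founders
    ref, poly_sites, vecs, freqs = _simulate_locus_pool(rng, cfg, locus_name)
    taken = {s.position for s in poly_sites}
    div_positions: list[int] = []
    while len(div_positions) < cfg.paralog_divergence_sites:
        pos = int(rng.integers(1, cfg.length_bp + 1))
        if pos not in taken:
            taken.add(pos)
            div_positions.append(pos)
    div_positions.sort()
    div_sites = []
    for pos in div_positions:
        ref_base = ref[pos - 1]
        alt = _BASES[int(rng.integers(0, 4))]
        while alt == ref_base:
            alt = _BASES[int(rng.integers(0, 4))]
        div_sites.append(
            SnpSite(locus=locus_name, position=pos,
                    alleles=(ref_base, alt), ref_allele=ref_base)
        )

    all_sites = sorted(poly_sites + div_sites, key=lambda s: s.position)
    table = GenotypeTable(sites=all_sites)
    truth = TruthBundle(
        haplotype_pools={locus_name: vecs},
        haplotype_freqs={locus_name: freqs},
        paralog_sites={locus_name: tuple(div_positions)},
    )
    copy_b_allele = {s.position: s.alleles[1] if s.alleles[0] == ref[s.position - 1]
                     else s.alleles[0] for s in div_sites}
    poly_positions = [s.position for s in poly_sites]
    # Draw haplotype frequencies and individuals together; re-draw if some
    # within-copy polymorphic site ends up heterozygous in *everyone* (the
    # emulated phenomenon is "variable heterozygosity" — universal
    # heterozygosity is reserved for the fixed inter-paralog differences,
    # so at least one individual must be homozygous-reference at each
    # segregating site).
    for _ in range(200):
        draws = [
            tuple(int(h) for h in rng.choice(len(vecs), size=2, p=freqs))
            for _ in range(n)
        ]
        ok = all(
            any(
                vecs[h1][si] == vecs[h2][si] == site.ref_allele
                for h1, h2 in draws
            )
            for si, site in enumerate(poly_sites)
        )
        if ok:
            break
        if cfg.haplotype_freqs is None:
            freqs = tuple(rng.dirichlet([cfg.dirichlet_alpha] * len(vecs)))
    truth.haplotype_freqs[locus_name] = freqs
    for i, (h1, h2) in enumerate(draws):
        ind = f"I{i + 1}"
        truth.individual_haplotypes[(ind, locus_name)] = (h1, h2)
        for site in all_sites:
            if site.position in copy_b_allele:
                # copy A carries the reference base, copy B the divergent one
                pair = (site.ref_allele, copy_b_allele[site.position])
            else:
                si = poly_positions.index(site.position)
                observed = {vecs[h1][si], vecs[h2][si], site.ref_allele}
                # copy B matches the reference here, so the merged call is
                # heterozygous whenever either copy-A haplotype carries alt
                if len(observed) == 1:
                    pair = (site.ref_allele, site.ref_allele)
                else:
                    pair = tuple(sorted(observed))
            table.set(ind, site, pair)
    return table, truth


def simulate_clones(
    true_haplotypes: Sequence[str],
    cfg: SimConfig,
    individual: str = "I1",
    locus: str = "L1",
    haplotype_freqs: Sequence[float] | None = None,
) -> tuple[CloneExperiment, list[dict]]:
    """Multinomial clone draws over an individual's true gene-copy haplotypes
    across independent PCR replicates, with optional chimeras.

    Each read is, with probability ``chimera_rate``, a recombinant of two
    distinct uniformly-chosen templates joined at a single uniform
    breakpoint (the dominant in-vitro artefact when paralogous templates
    coamplify).  Truth labels every read.
    """
    if not true_haplotypes:
        raise ValueError("need >= 1 true haplotype")
    rng = stream(cfg.seed, f"clones:{individual}:{locus}")
    haps = list(true_haplotypes)
    L = len(haps[0])
    if any(len(h) != L for h in haps):
        raise ValueError("true haplotypes must be equal length")
    freqs = (
        np.asarray(haplotype_freqs, dtype=float)
        if haplotype_freqs is not None
        else np.full(len(haps), 1.0 / len(haps))
    )
    reads: list[CloneRead] = []
    truth: list[dict] = []
    for r in range(cfg.replicate_count):
        label = f"rep{r + 1}"
        for _ in range(cfg.clone_draws):
            if len(haps) >= 2 and rng.random() < cfg.chimera_rate:
                i, j = rng.choice(len(haps), size=2, replace=False)
                bp = int(rng.integers(1, L))
                seq = haps[int(i)][:bp] + haps[int(j)][bp:]
                truth.append(
                    {"replicate": label, "chimera": True,
                     "templates": (int(i), int(j)), "breakpoint": bp,
                     "sequence": seq}
                )
            else:
                i = int(rng.choice(len(haps), p=freqs))
                seq = haps[i]
                truth.append(
                    {"replicate": label, "chimera": False,
                     "templates": (i,), "breakpoint": None, "sequence": seq}
                )
            reads.append(CloneRead(sequence=seq, replicate=label))
    return CloneExperiment(individual=individual, locus=locus, reads=reads), truth


def _propose_mutation(
    rng: np.random.Generator,
    seq: list[str],
    free_codons: list[int],
    enrich_nonsyn: float = 1.0,
) -> tuple[int, str, str, int]:
    """One substitution in a free codon, stop-free; nonsynonymous changes
    are accepted with relative weight ``enrich_nonsyn``.

    Returns (position 1-based, old base, new base, codon index)."""
    from .seqvar import _translate_codon

    while True:
        ci = int(free_codons[int(rng.integers(0, len(free_codons)))])
        offset = int(rng.integers(0, 3))
        pos = 3 * ci + offset  # 0-based
        old = seq[pos]
        new = _BASES[int(rng.integers(0, 4))]
        if new == old:
            continue
        codon = "".join(seq[3 * ci:3 * ci + 3])
        mutant = codon[:offset] + new + codon[offset + 1:]
        if mutant in _STOPS:
            continue
        nonsyn = _translate_codon(codon) != _translate_codon(mutant)
        w = enrich_nonsyn if nonsyn else 1.0
        cap = max(enrich_nonsyn, 1.0)
        if rng.random() < w / cap:
            return pos + 1, old, new, ci


def simulate_divergence(cfg: SimConfig) -> tuple[list[str], list[str], list[dict]]:
    """Two species' haplotype sets diverged from a common ancestral coding
    sequence, with per-site MK truth.

    ``divergence_subs`` substitutions are fixed along the two branches
    (split evenly); ``polymorphic_sites`` segregating sites are added
    within each species.  At most one event per codon, so the syn/nonsyn
    label of each event is exact.  ``selection_factor`` > 1 enriches
    nonsynonymous changes among the *fixed* events only, emulating
    directional selection.
    """
    rng = stream(cfg.seed, "divergence")
    L = cfg.length_bp - cfg.length_bp % 3
    ancestral = list(_random_coding_sequence(rng, L))
    free = list(range(L // 3))
    n_events = cfg.divergence_subs + 2 * cfg.polymorphic_sites
    if n_events > len(free):
        raise ValueError("sequence too short for the requested event count")

    from .seqvar import _translate_codon

    seq_a = list(ancestral)
    seq_b = list(ancestral)
    truth: list[dict] = []

    def record(pos, old, new, ci, spread, species):
        codon = "".join(ancestral[3 * ci:3 * ci + 3])
        off = (pos - 1) - 3 * ci
        mutant = codon[:off] + new + codon[off + 1:]
        effect = (
            "synonymous"
            if _translate_codon(codon) == _translate_codon(mutant)
            else "nonsynonymous"
        )
        truth.append(
            {"position": pos, "spread": spread, "effect": effect,
             "species": species, "from": old, "to": new}
        )

    n_a = cfg.divergence_subs // 2
    n_b = cfg.divergence_subs - n_a
    for species, target, n_fixed in (("A", seq_a, n_a), ("B", seq_b, n_b)):
        for _ in range(n_fixed):
            pos, old, new, ci = _propose_mutation(
                rng, ancestral, free, enrich_nonsyn=cfg.selection_factor
            )
            free.remove(ci)
            target[pos - 1] = new
            record(pos, old, new, ci, "fixed", species)

    n_haps = cfg.n_haps_per_species
    a_haps = [list(seq_a) for _ in range(n_haps)]
    b_haps = [list(seq_b) for _ in range(n_haps)]
    for species, base_seq, haps in (("A", seq_a, a_haps), ("B", seq_b, b_haps)):
        for _ in range(cfg.polymorphic_sites):
            pos, old, new, ci = _propose_mutation(rng, base_seq, free)
            free.remove(ci)
            n_carriers = int(rng.integers(1, n_haps))
            carriers = rng.choice(n_haps, size=n_carriers, replace=False)
            for c in carriers:
                haps[int(c)][pos - 1] = new
            record(pos, old, new, ci, "polymorphic", species)

    return (
        ["".join(h) for h in a_haps],
        ["".join(h) for h in b_haps],
        truth,
    )
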