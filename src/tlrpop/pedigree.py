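"""Pedigree representation, Mendelian checks, missing-founder inference and
pedigree-assisted haplotype phasing.

The study design this supports: a small founder cohort where some founders
died unsampled, so their genotypes are deduced from a sampled co-parent and
up to seven genotyped offspring.  With ``n`` offspring the probability that
a heterozygous unsampled parent transmits the same one of its two alleles
to every offspring — hiding the second allele — is (1/2)^n, so five
offspring keep the nondetection probability under 3.5%.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqvar import SnpSite

__all__ = [
    "UNKNOWN",
    "Pedigree",
    "GenotypeTable",
    "InferenceEntry",
    "PhasedIndividual",
    "trio_consistent",
    "infer_missing_parent",
    "nondetection_probability",
    "min_offspring_for",
    "phase_by_pedigree",
]

UNKNOWN = "UNKNOWN"

Pair = tuple[str, str]


def _as_pair(genotype) -> Pair:
    """Accept a SiteGenotype-like object or a raw 2-tuple of alleles."""
    alleles = getattr(genotype, "alleles", genotype)
    a, b = alleles
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass
class Pedigree:
    """Founder/offspring graph with trio lookups.

    ``parents`` maps offspring id -> (dam id or UNKNOWN, sire id or UNKNOWN).
    Founders have no recorded parents.
    """

    individuals: dict[str, str] = field(default_factory=dict)  # id -> sex
    parents: dict[str, tuple[str, str]] = field(default_factory=dict)
    founders: set[str] = field(default_factory=set)

    def add(self, ind: str, sex: str = "U", dam: str = UNKNOWN,
            sire: str = UNKNOWN, founder: bool = False) -> None:
        self.individuals[ind] = sex
        if founder:
            if dam != UNKNOWN or sire != UNKNOWN:
                raise ValueError(f"founder {ind} cannot have recorded parents")
            self.founders.add(ind)
        else:
            self.parents[ind] = (dam, sire)
        self._check_acyclic(ind)

    def _check_acyclic(self, start: str) -> None:
        seen = set()
        stack = [start]
        while stack:
            ind = stack.pop()
            if ind in seen:
                raise ValueError(f"pedigree cycle involving {ind}")
            seen.add(ind)
            dam, sire = self.parents.get(ind, (UNKNOWN, UNKNOWN))
            stack.extend(p for p in (dam, sire) if p != UNKNOWN)

    def parents_of(self, ind: str) -> tuple[str, str]:
        return self.parents.get(ind, (UNKNOWN, UNKNOWN))

    def offspring_of(self, parent: str) -> list[str]:
        return [o for o, (d, s) in self.parents.items() if parent in (d, s)]

    def co_parents_of(self, parent: str) -> dict[str, list[str]]:
        """Map co-parent id -> shared offspring ids."""
        broods: dict[str, list[str]] = {}
        for o, (d, s) in self.parents.items():
            if d == parent:
                broods.setdefault(s, []).append(o)
            elif s == parent:
                broods.setdefault(d, []).append(o)
        return broods

    def trios(self) -> list[tuple[str, str, str]]:
        """(offspring, dam, sire) triples with both parents recorded."""
        return [
            (o, d, s)
            for o, (d, s) in self.parents.items()
            if d != UNKNOWN and s != UNKNOWN
        ]


@dataclass
class GenotypeTable:
    """Unordered allele pairs per individual x site.

    Keys of ``genotypes`` are individual ids; values map site -> allele pair.
    Analyzed individuals are expected to be complete (no missing entries).
    """

    sites: list[SnpSite]
    genotypes: dict[str, dict[SnpSite, Pair]] = field(default_factory=dict)

    def set(self, ind: str, site: SnpSite, pair: Sequence[str]) -> None:
        self.genotypes.setdefault(ind, {})[site] = _as_pair(pair)

    def get(self, ind: str, site: SnpSite) -> Pair:
        return self.genotypes[ind][site]

    def individuals(self) -> list[str]:
        return list(self.genotypes)

    def has(self, ind: str) -> bool:
        return ind in self.genotypes

    def is_complete(self, ind: str) -> bool:
        return ind in self.genotypes and all(
            s in self.genotypes[ind] for s in self.sites
        )

    def sites_for_locus(self, locus_name: str) -> list[SnpSite]:
        return [s for s in self.sites if s.locus == locus_name]


def trio_consistent(offspring, dam, sire) -> bool:
    """True iff the offspring pair can be formed by one allele from each parent."""
    o = _as_pair(offspring)
    d = _as_pair(dam)
    s = _as_pair(sire)
    return any(
        tuple(sorted((x, y))) == o for x in set(d) for y in set(s)
    )


def nondetection_probability(n_offspring: int) -> float:
    """(1/2)^n: chance a heterozygous unsampled parent passes the same single
    allele to all ``n_offspring``, so its second allele is never observed."""
    if n_offspring < 0:
        raise ValueError("n_offspring must be >= 0")
    return 0.5 ** n_offspring


def min_offspring_for(alpha: float) -> int:
    """Smallest number of offspring with nondetection probability < alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n = 0
    while nondetection_probability(n) >= alpha:
        n += 1
    return n


@dataclass(frozen=True)
class InferenceEntry:
    """Inference result for one missing parent (or parent pair) at one site."""

    site: SnpSite
    consistent: tuple  # tuple of genotype pairs, or of (dam_pair, sire_pair)
    status: str  # "unique" | "ambiguous" | "inconsistent"
    n_offspring_used: int
    nondetection_prob: float
    joint: bool = False


def _all_genotypes(site: SnpSite) -> list[Pair]:
    return [
        tuple(sorted(p))
        for p in itertools.combinations_with_replacement(site.alleles, 2)
    ]


def infer_missing_parent(
    site: SnpSite,
    known_parent,
    offspring: Iterable,
) -> InferenceEntry:
    """Genotypes of an unsampled parent consistent with all offspring.

    ``known_parent`` is the sampled co-parent's genotype, or None when both
    parents are unsampled, in which case inference is joint over ordered
    (dam, sire) candidate pairs (reported as unordered genotype pairs).
    An empty consistent set is flagged ``inconsistent`` rather than raised:
    it is the Mendelian-violation signal the paralog screen consumes.
    """
    off = [_as_pair(o) for o in offspring]
    if not off:
        raise ValueError("at least one offspring genotype is required")
    candidates = _all_genotypes(site)

    if known_parent is not None:
        kp = _as_pair(known_parent)
        consistent = tuple(
            g for g in candidates
            if all(trio_consistent(o, kp, g) for o in off)
        )
        joint = False
    else:
        pairs = set()
        for g1, g2 in itertools.combinations_with_replacement(candidates, 2):
            if all(trio_consistent(o, g1, g2) for o in off):
                pairs.add((g1, g2))
        consistent = tuple(sorted(pairs))
        joint = True

    if not consistent:
        status = "inconsistent"
    elif len(consistent) == 1:
        status = "unique"
    else:
        status = "ambiguous"
    return InferenceEntry(
        site=site,
        consistent=consistent,
        status=status,
        n_offspring_used=len(off),
        nondetection_prob=nondetection_probability(len(off)),
        joint=joint,
    )


# --------------------------------------------------------------------------
# Pedigree-assisted phasing


@dataclass
class PhasedIndividual:
    individual: str
    hap_a: tuple[str, ...]
    hap_b: tuple[str, ...]
    certainty: str  # "certain" | "uncertain" | "inconsistent"


def _genotype_compatible_pairs(
    genotype: Sequence[Pair],
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All unordered haplotype pairs consistent with a multi-site genotype."""
    het_idx = [i for i, (a, b) in enumerate(genotype) if a != b]
    base = [g[0] for g in genotype]
    pairs = set()
    if not het_idx:
        hap = tuple(base)
        return [(hap, hap)]
    # Fix the first het site's assignment to halve the enumeration
    # (unordered pairs).
    first, rest = het_idx[0], het_idx[1:]
    for combo in itertools.product((0, 1), repeat=len(rest)):
        h1, h2 = list(base), list(base)
        h1[first], h2[first] = genotype[first]
        for idx, pick in zip(rest, combo):
            h1[idx] = genotype[idx][pick]
            h2[idx] = genotype[idx][1 - pick]
        pair = tuple(sorted((tuple(h1), tuple(h2))))
        pairs.add(pair)
    return sorted(pairs)


def _transmissible(pairs) -> set[tuple[str, ...]]:
    return {h for pair in pairs for h in pair}


def _em_haplotype_frequencies(
    candidate_sets: list[list[tuple[tuple[str, ...], tuple[str, ...]]]],
    tol: float = 1e-6,
    max_iter: int = 500,
) -> dict[tuple[str, ...], float]:
    """EM over locus haplotype frequencies given per-individual candidate pairs.

    Uniform initialisation over the haplotype universe; deterministic.
    """
    universe = sorted({h for cands in candidate_sets for pair in cands for h in pair})
    if not universe:
        return {}
    freqs = {h: 1.0 / len(universe) for h in universe}
    n_genes = 2 * len(candidate_sets)
    for _ in range(max_iter):
        expected = {h: 0.0 for h in universe}
        for cands in candidate_sets:
            weights = []
            for h1, h2 in cands:
                w = freqs[h1] * freqs[h2]
                if h1 != h2:
                    w *= 2
                weights.append(w)
            total = sum(weights)
            if total == 0:
                weights = [1.0] * len(cands)
                total = float(len(cands))
            for (h1, h2), w in zip(cands, weights):
                expected[h1] += w / total
                expected[h2] += w / total
        new = {h: expected[h] / n_genes for h in universe}
        delta = max(abs(new[h] - freqs[h]) for h in universe)
        freqs = new
        if delta < tol:
            break
    return freqs


def phase_by_pedigree(
    table: GenotypeTable,
    ped: Pedigree,
    locus_name: str,
) -> dict[str, PhasedIndividual]:
    """Phase all genotyped individuals at one locus.

    Constraint propagation first: each individual's candidate haplotype
    pairs (all pairs consistent with its genotype) are pruned against its
    parents' and offspring's candidate sets until a fixed point — a child
    pair must be formable from one transmissible haplotype of each genotyped
    parent, and a parent must be able to supply one haplotype of every
    child.  Individuals reduced to a single pair are flagged ``certain``.
    Residual ambiguity is resolved by an EM estimate of locus haplotype
    frequencies (most probable pair, lexicographic tie-break), flagged
    ``uncertain``.  A pedigree-genotype contradiction empties a candidate
    set; the individual is flagged ``inconsistent`` and its genotype-only
    candidates are restored.
    """
    sites = table.sites_for_locus(locus_name)
    inds = [i for i in table.individuals()
            if all(s in table.genotypes[i] for s in sites)]
    genotypes = {i: [table.get(i, s) for s in sites] for i in inds}
    cands: dict[str, list] = {
        i: _genotype_compatible_pairs(genotypes[i]) for i in inds
    }
    original = {i: list(c) for i, c in cands.items()}
    inconsistent: set[str] = set()

    def parent_sets(ind: str):
        dam, sire = ped.parents_of(ind)
        dam_set = _transmissible(cands[dam]) if dam in cands else None
        sire_set = _transmissible(cands[sire]) if sire in cands else None
        return dam_set, sire_set

    changed = True
    while changed:
        changed = False
        for ind in inds:
            if ind in inconsistent:
                continue
            dam_set, sire_set = parent_sets(ind)
            kept = []
            for h1, h2 in cands[ind]:
                ok = False
                for a, b in ((h1, h2), (h2, h1)):
                    dam_ok = dam_set is None or a in dam_set
                    sire_ok = sire_set is None or b in sire_set
                    if dam_ok and sire_ok:
                        ok = True
                        break
                if ok:
                    kept.append((h1, h2))
            if len(kept) < len(cands[ind]):
                if not kept:
                    inconsistent.add(ind)
                    cands[ind] = original[ind]
                else:
                    cands[ind] = kept
                    changed = True
        # prune parents against children: a parent pair must offer a
        # haplotype that each child could have received.
        for parent in inds:
            if parent in inconsistent:
                continue
            children = [
                c for c in ped.offspring_of(parent) if c in cands
            ]
            if not children:
                continue
            kept = []
            for pair in cands[parent]:
                supply = set(pair)
                ok = True
                for child in children:
                    child_haps = _transmissible(cands[child])
                    if not (supply & child_haps):
                        ok = False
                        break
                if ok:
                    kept.append(pair)
            if len(kept) < len(cands[parent]):
                if not kept:
                    inconsistent.add(parent)
                    cands[parent] = original[parent]
                else:
                    cands[parent] = kept
                    changed = True

    freqs = _em_haplotype_frequencies([cands[i] for i in inds])

    out: dict[str, PhasedIndividual] = {}
    for ind in inds:
        options = cands[ind]
        if ind in inconsistent:
            certainty = "inconsistent"
        elif len(options) == 1:
            certainty = "certain"
        else:
            certainty = "uncertain"
        if len(options) == 1:
            best = options[0]
        else:
            def weight(pair):
                h1, h2 = pair
                w = freqs.get(h1, 0.0) * freqs.get(h2, 0.0)
                if h1 != h2:
                    w *= 2
                return w
            best_w = max(weight(p) for p in options)
            best = min(p for p in options if weight(p) == best_w)
        out[ind] = PhasedIndividual(
            individual=ind, hap_a=best[0], hap_b=best[1], certainty=certainty
        )
    return out
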