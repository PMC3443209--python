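"""Small-sample diversity statistics for a handful of diploid founders.

At n = 12 diploids asymptotic estimators and chi-square Hardy-Weinberg
tests are unreliable, so everything here is exact: gene diversity carries
Nei's small-sample correction 2n/(2n-1), and the Hardy-Weinberg test fully
enumerates every genotype configuration conditional on the observed allele
counts (Louis & Dempster style probability ordering) in exact rational
arithmetic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "LocusDiversity",
    "observed_heterozygosity",
    "unbiased_gene_diversity",
    "hwe_exact_test",
    "hwe_configuration_distribution",
    "nucleotide_diversity",
    "multilocus_heterozygosity",
    "locus_summary",
    "round_half_up",
]

Pair = tuple[object, object]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding, matching report-table formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def observed_heterozygosity(genotypes: Iterable[Pair]) -> float:
    """Fraction of individuals whose two variants differ."""
    pairs = [tuple(getattr(g, "alleles", g)) for g in genotypes]
    if not pairs:
        raise ValueError("no genotypes given")
    return sum(a != b for a, b in pairs) / len(pairs)


def unbiased_gene_diversity(allele_counts: Sequence[int]) -> float:
    """Nei's unbiased expected heterozygosity.

    He = (2n / (2n - 1)) * (1 - sum p_i^2), with p_i the sample allele
    frequencies from 2n genes.  E.g. counts (11, 13) at n = 12 give
    (24/23) * (286/576) = 0.518.
    """
    counts = [int(c) for c in allele_counts]
    if any(c < 0 for c in counts):
        raise ValueError("allele counts must be nonnegative")
    total = sum(counts)
    if total < 2:
        raise ValueError("need at least 2 gene copies")
    sum_p2 = sum((c / total) ** 2 for c in counts)
    return (total / (total - 1)) * (1.0 - sum_p2)


# --------------------------------------------------------------------------
# Exact Hardy-Weinberg test by full enumeration


def _normalise_genotype_counts(
    genotype_counts: Mapping[tuple[int, int], int] | Sequence[Sequence[int]],
) -> dict[tuple[int, int], int]:
    """Accept {(i, j): count} with i <= j, or a square lower/upper matrix."""
    if isinstance(genotype_counts, Mapping):
        out: dict[tuple[int, int], int] = {}
        for (i, j), c in genotype_counts.items():
            key = (min(i, j), max(i, j))
            out[key] = out.get(key, 0) + int(c)
    else:
        mat = [list(row) for row in genotype_counts]
        k = len(mat)
        if any(len(row) != k for row in mat):
            raise ValueError("genotype-count matrix must be square")
        out = {}
        for i in range(k):
            for j in range(i, k):
                c = mat[i][j] + (mat[j][i] if i != j else 0)
                if c:
                    out[(i, j)] = int(c)
    if any(c < 0 for c in out.values()):
        raise ValueError("genotype counts must be nonnegative")
    if sum(out.values()) < 1:
        raise ValueError("need at least one individual")
    return out


def _allele_counts_from_genotypes(
    counts: Mapping[tuple[int, int], int]
) -> list[int]:
    k = max(max(i, j) for i, j in counts) + 1
    alleles = [0] * k
    for (i, j), c in counts.items():
        alleles[i] += c
        alleles[j] += c
    return alleles


def _config_probability(
    counts: Mapping[tuple[int, int], int],
    allele_counts: Sequence[int],
) -> Fraction:
    """Levene's conditional probability of a genotype configuration given
    the allele counts:  n! 2^h prod(n_a!) / (prod(n_g!) (2n)!)."""
    n = sum(counts.values())
    h = sum(c for (i, j), c in counts.items() if i != j)
    num = Fraction(math.factorial(n) * 2**h)
    for na in allele_counts:
        num *= math.factorial(na)
    den = Fraction(math.factorial(2 * n))
    for c in counts.values():
        den *= math.factorial(c)
    return num / den


def _enumerate_configurations(
    allele_counts: Sequence[int],
) -> Iterable[dict[tuple[int, int], int]]:
    """All genotype-count tables consistent with the allele-count margins."""
    k = len(allele_counts)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]

    def recurse(idx: int, remaining: list[int], current: dict):
        if idx == len(pairs):
            if all(r == 0 for r in remaining):
                yield dict(current)
            return
        i, j = pairs[idx]
        if i == j:
            cap = remaining[i] // 2
        else:
            cap = min(remaining[i], remaining[j])
        for c in range(cap + 1):
            remaining[i] -= c * (2 if i == j else 1)
            if i != j:
                remaining[j] -= c
            if c:
                current[(i, j)] = c
            yield from recurse(idx + 1, remaining, current)
            if c:
                del current[(i, j)]
            remaining[i] += c * (2 if i == j else 1)
            if i != j:
                remaining[j] += c
        return

    yield from recurse(0, list(allele_counts), {})


def hwe_configuration_distribution(
    allele_counts: Sequence[int],
) -> list[tuple[dict[tuple[int, int], int], Fraction]]:
    """Every genotype configuration with the given allele counts and its
    exact conditional probability (probabilities sum to 1)."""
    dist = [
        (cfg, _config_probability(cfg, allele_counts))
        for cfg in _enumerate_configurations(allele_counts)
    ]
    total = sum(p for _, p in dist)
    if total != 1:
        raise AssertionError(
            f"configuration probabilities sum to {total}, not 1"
        )
    return dist


def hwe_exact_test(
    genotype_counts: Mapping[tuple[int, int], int] | Sequence[Sequence[int]],
) -> float:
    """Two-sided exact Hardy-Weinberg test by full enumeration.

    Conditions on the observed allele counts, weights each genotype
    configuration by Levene's exact probability, and sums the probabilities
    of all configurations no more probable than the observed one
    (probability ordering).  Exact rational arithmetic, so ties are handled
    without floating-point fuzz.  Supports any number of alleles (intended
    for small samples, <= a few dozen diploids).
    """
    observed = _normalise_genotype_counts(genotype_counts)
    allele_counts = _allele_counts_from_genotypes(observed)
    if len([c for c in allele_counts if c > 0]) < 2:
        return 1.0  # monomorphic: a single configuration exists
    p_obs = _config_probability(observed, allele_counts)
    p_value = Fraction(0)
    for _, p in hwe_configuration_distribution(allele_counts):
        if p <= p_obs:
            p_value += p
    return float(p_value)


# --------------------------------------------------------------------------
# Nucleotide diversity


def _pairwise_differences(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("haplotype sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def nucleotide_diversity(
    haplotypes: Sequence[str],
    counts: Sequence[int],
    length_bp: int | None = None,
    variance: str = "tajima",
) -> tuple[float, float]:
    """Nucleotide diversity per site with sampling standard error.

    pi = (m / (m - 1)) * sum_{i<j} 2 p_i p_j d_ij / L over the m = sum(counts)
    sampled gene copies (sample-size-corrected mean pairwise differences per
    site).  The SE follows Tajima's stochastic variance of pi,
    Var = ((m + 1) / (3 (m - 1))) pi / L + (2 (m^2 + m + 3) / (9 m (m - 1))) pi^2,
    selectable via ``variance`` ("tajima" or "none").
    """
    if len(haplotypes) != len(counts):
        raise ValueError("haplotypes and counts differ in length")
    if not haplotypes:
        raise ValueError("no haplotypes given")
    L = length_bp if length_bp is not None else len(haplotypes[0])
    if any(len(h) != len(haplotypes[0]) for h in haplotypes):
        raise ValueError("haplotype sequences differ in length")
    m = sum(counts)
    if m < 2:
        return 0.0, 0.0
    freqs = [c / m for c in counts]
    pi = 0.0
    for (ha, pa), (hb, pb) in itertools.combinations(zip(haplotypes, freqs), 2):
        pi += 2.0 * pa * pb * _pairwise_differences(ha, hb)
    pi *= m / (m - 1) / L
    if variance == "none" or pi == 0.0:
        return pi, 0.0
    if variance != "tajima":
        raise ValueError(f"unknown variance formula: {variance!r}")
    var = ((m + 1) / (3.0 * (m - 1))) * pi / L
    var += (2.0 * (m * m + m + 3) / (9.0 * m * (m - 1))) * pi * pi
    return pi, math.sqrt(var)


def multilocus_heterozygosity(
    genotypes_by_locus: Mapping[str, Mapping[str, Pair]],
    loci: Sequence[str] | None = None,
) -> tuple[dict[str, int], float, float]:
    """Per-individual count of heterozygous loci, with mean and SD (n-1).

    ``genotypes_by_locus`` maps locus -> {individual -> variant pair}.
    Requires complete data for the listed loci.
    """
    loci = list(loci) if loci is not None else list(genotypes_by_locus)
    individuals = sorted(
        set.intersection(*(set(genotypes_by_locus[l]) for l in loci))
    ) if loci else []
    counts = {
        ind: sum(
            1 for l in loci
            if genotypes_by_locus[l][ind][0] != genotypes_by_locus[l][ind][1]
        )
        for ind in individuals
    }
    vals = list(counts.values())
    if not vals:
        return counts, 0.0, 0.0
    mean = sum(vals) / len(vals)
    sd = (
        math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        if len(vals) > 1
        else 0.0
    )
    return counts, mean, sd


# --------------------------------------------------------------------------
# Per-locus summary


@dataclass(frozen=True)
class LocusDiversity:
    """One report row: variant counts, Ho, unbiased He, exact HWE p, pi."""

    locus: str
    n_individuals: int
    n_variants: int
    allele_counts: tuple[int, ...]
    ho: float
    he: float
    hwe_p: float | None
    pi: float | None = None
    pi_se: float | None = None

    def rounded(self, ndigits: int = 3) -> "LocusDiversity":
        rnd = lambda v: None if v is None else round_half_up(v, ndigits)
        return LocusDiversity(
            locus=self.locus,
            n_individuals=self.n_individuals,
            n_variants=self.n_variants,
            allele_counts=self.allele_counts,
            ho=round_half_up(self.ho, ndigits),
            he=round_half_up(self.he, ndigits),
            hwe_p=rnd(self.hwe_p),
            pi=self.pi,
            pi_se=self.pi_se,
        )


def locus_summary(
    locus: str,
    genotypes: Sequence[Pair],
    haplotype_seqs: Mapping[object, str] | None = None,
) -> LocusDiversity:
    """Assemble the diversity row for one locus from variant-level genotypes.

    Genotypes are unordered pairs of variant labels (amino-acid variants or
    haplotypes; the analysis level is the caller's choice).  When
    ``haplotype_seqs`` maps variant labels to sequences, nucleotide
    diversity is computed as well.  Monomorphic loci report He = Ho = 0 and
    an undefined HWE p (rendered "-" in reports).
    """
    pairs = [tuple(getattr(g, "alleles", g)) for g in genotypes]
    if not pairs:
        raise ValueError("no genotypes given")
    variants = sorted({v for p in pairs for v in p}, key=str)
    index = {v: i for i, v in enumerate(variants)}
    allele_counts = [0] * len(variants)
    genotype_counts: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        allele_counts[index[a]] += 1
        allele_counts[index[b]] += 1
        key = tuple(sorted((index[a], index[b])))
        genotype_counts[key] = genotype_counts.get(key, 0) + 1

    monomorphic = len(variants) < 2
    ho = observed_heterozygosity(pairs)
    he = 0.0 if monomorphic else unbiased_gene_diversity(allele_counts)
    hwe_p = None if monomorphic else hwe_exact_test(genotype_counts)

    pi = pi_se = None
    if haplotype_seqs is not None and not monomorphic:
        seqs = [haplotype_seqs[v] for v in variants]
        pi, pi_se = nucleotide_diversity(seqs, allele_counts)

    return LocusDiversity(
        locus=locus,
        n_individuals=len(pairs),
        n_variants=len(variants),
        allele_counts=tuple(allele_counts),
        ho=ho,
        he=he,
        hwe_p=hwe_p,
        pi=pi,
        pi_se=pi_se,
    )
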