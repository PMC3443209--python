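"""Sequence and variant model for Sanger-genotyped amplicons.

A :class:`Locus` is a single PCR amplicon with a known reading frame; SNPs
within it are :class:`SnpSite` objects with 1-based amplicon coordinates
(matching how positions are reported in amplicon resequencing studies).
Substitutions are classified at the codon level with the standard genetic
code, transitions/transversions are tallied with a minimal-transversion
decomposition for triallelic sites, and heterozygous Sanger calls are
encoded as IUPAC ambiguity codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "Locus",
    "SnpSite",
    "Haplotype",
    "SiteGenotype",
    "SubstitutionEffect",
    "UntranslatableSiteError",
    "iupac_encode",
    "iupac_decode",
    "classify_substitution",
    "ti_tv_tally",
    "classify_ti_tv",
    "aa_change_class",
    "haplotypes_to_snp_table",
]

NUCLEOTIDES = frozenset("ACGT")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

# Unordered heterozygous pair -> two-base ambiguity code.
_IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_IUPAC_DECODE = {code: pair for pair, code in _IUPAC_HET.items()}
_IUPAC_DECODE.update({b: frozenset(b) for b in NUCLEOTIDES})

# Physicochemical categories (one-letter codes).
AA_CATEGORIES = {
    "nonpolar": frozenset("AVLIPFMWG"),
    "polar": frozenset("STCYNQ"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class UntranslatableSiteError(ValueError):
    """Raised when a site falls in an incomplete terminal codon."""


def _check_base(base: str) -> str:
    b = base.upper()
    if b not in NUCLEOTIDES:
        raise ValueError(f"not a nucleotide: {base!r}")
    return b


def iupac_encode(pair: Sequence[str]) -> str:
    """Collapse an unordered genotype pair to its IUPAC consensus base.

    Homozygous pairs return the base itself; heterozygous pairs return the
    standard two-base ambiguity code (the way double peaks are recorded
    from chromatograms).
    """
    a, b = (_check_base(x) for x in pair)
    if a == b:
        return a
    return _IUPAC_HET[frozenset((a, b))]


def iupac_decode(code: str) -> tuple[str, str]:
    """Expand a consensus base back to a sorted unordered allele pair."""
    c = code.upper()
    if c not in _IUPAC_DECODE:
        raise ValueError(f"not a single-base or two-base IUPAC code: {code!r}")
    bases = sorted(_IUPAC_DECODE[c])
    return (bases[0], bases[-1])


@dataclass(frozen=True)
class Locus:
    """An amplicon with a reference coding sequence and reading frame.

    ``frame_offset`` is the position within a codon (0..2) of base 1 of the
    amplicon: 0 means the amplicon starts on a codon boundary.
    """

    name: str
    reference_seq: str
    frame_offset: int = 0

    def __post_init__(self):
        seq = self.reference_seq.upper()
        if set(seq) - NUCLEOTIDES:
            raise ValueError(f"{self.name}: non-ACGT characters in reference")
        object.__setattr__(self, "reference_seq", seq)
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")

    @property
    def length_bp(self) -> int:
        return len(self.reference_seq)

    def codon_start(self, position: int) -> int:
        """1-based start of the codon containing ``position``."""
        if not 1 <= position <= self.length_bp:
            raise ValueError(f"position {position} outside 1..{self.length_bp}")
        codon_pos = (position - 1 + self.frame_offset) % 3
        return position - codon_pos

    def codon_at(self, position: int) -> tuple[str, int]:
        """Return (codon, within-codon index 0..2) for an amplicon position.

        Raises :class:`UntranslatableSiteError` for partial terminal codons.
        """
        start = self.codon_start(position)
        if start < 1 or start + 2 > self.length_bp:
            raise UntranslatableSiteError(
                f"{self.name}:{position} lies in an incomplete codon"
            )
        return self.reference_seq[start - 1:start + 2], position - start


@dataclass(frozen=True)
class SnpSite:
    """A polymorphic site within an amplicon (1-based position)."""

    locus: str
    position: int
    alleles: tuple[str, ...]
    ref_allele: str | None = None

    def __post_init__(self):
        alleles = tuple(sorted({_check_base(a) for a in self.alleles}))
        if not 2 <= len(alleles) <= 3:
            raise ValueError(f"{self.locus}:{self.position}: need 2-3 alleles")
        object.__setattr__(self, "alleles", alleles)
        if self.ref_allele is not None:
            ref = _check_base(self.ref_allele)
            if ref not in alleles:
                raise ValueError("ref_allele must be one of the site alleles")
            object.__setattr__(self, "ref_allele", ref)


@dataclass(frozen=True)
class Haplotype:
    """One allele per SNP site of a locus, in site order."""

    locus: str
    allele_vector: tuple[str, ...]
    aa_variant_id: str | None = None


@dataclass(frozen=True)
class SiteGenotype:
    """Unordered allele pair of one individual at one site."""

    individual: str
    site: SnpSite
    alleles: tuple[str, str]

    def __post_init__(self):
        pair = tuple(sorted(_check_base(a) for a in self.alleles))
        for a in pair:
            if a not in self.site.alleles:
                raise ValueError(
                    f"{self.individual} carries {a} not in site alleles "
                    f"{self.site.alleles} at {self.site.locus}:{self.site.position}"
                )
        object.__setattr__(self, "alleles", pair)

    @property
    def is_heterozygous(self) -> bool:
        return self.alleles[0] != self.alleles[1]

    @property
    def iupac(self) -> str:
        return iupac_encode(self.alleles)


@dataclass(frozen=True)
class SubstitutionEffect:
    """Outcome of a codon-level substitution classification."""

    kind: str  # "synonymous" | "nonsynonymous"
    residues: tuple[str, str]
    codons: tuple[str, str]
    introduces_stop: bool = False

    @property
    def is_synonymous(self) -> bool:
        return self.kind == "synonymous"


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_substitution(
    locus: Locus, site_position: int, allele_a: str, allele_b: str
) -> SubstitutionEffect:
    """Classify a substitution at an amplicon position as syn/nonsyn.

    The codon containing the site is read off the reference sequence under
    the locus frame and translated with each allele substituted in; the
    change is nonsynonymous iff the residues differ.  Variants creating a
    stop codon are flagged, never dropped.
    """
    a, b = _check_base(allele_a), _check_base(allele_b)
    codon, idx = locus.codon_at(site_position)
    codon_a = codon[:idx] + a + codon[idx + 1:]
    codon_b = codon[:idx] + b + codon[idx + 1:]
    res_a, res_b = _translate_codon(codon_a), _translate_codon(codon_b)
    kind = "synonymous" if res_a == res_b else "nonsynonymous"
    return SubstitutionEffect(
        kind=kind,
        residues=(res_a, res_b),
        codons=(codon_a, codon_b),
        introduces_stop="*" in (res_a, res_b),
    )


def classify_ti_tv(allele_a: str, allele_b: str) -> str:
    """'transition' for purine<->purine or pyrimidine<->pyrimidine, else 'transversion'."""
    a, b = _check_base(allele_a), _check_base(allele_b)
    if a == b:
        raise ValueError("identical alleles have no substitution class")
    same_class = ({a, b} <= PURINES) or ({a, b} <= PYRIMIDINES)
    return "transition" if same_class else "transversion"


def decompose_triallelic(site: SnpSite) -> list[tuple[str, str]]:
    """Decompose a 3-allele site into 2 pairwise changes via a pivot allele.

    The pivot is the allele minimising the number of transversions among its
    two changes; ties are broken toward the reference allele and then
    alphabetically.  A diallelic site returns its single pair unchanged.
    """
    alleles = site.alleles
    if len(alleles) == 2:
        return [alleles]

    def tv_count(pivot: str) -> int:
        return sum(
            classify_ti_tv(pivot, other) == "transversion"
            for other in alleles
            if other != pivot
        )

    def sort_key(pivot: str):
        ref_rank = 0 if pivot == site.ref_allele else 1
        return (tv_count(pivot), ref_rank, pivot)

    pivot = min(alleles, key=sort_key)
    return [tuple(sorted((pivot, o))) for o in alleles if o != pivot]


def ti_tv_tally(sites: Iterable[SnpSite]) -> tuple[int, int]:
    """Count transitions and transversions across SNP sites.

    Diallelic sites contribute one classification each; triallelic sites are
    decomposed into two changes by :func:`decompose_triallelic`, so the total
    equals n_diallelic + 2 * n_triallelic.
    """
    n_ti = n_tv = 0
    for site in sites:
        for a, b in decompose_triallelic(site):
            if classify_ti_tv(a, b) == "transition":
                n_ti += 1
            else:
                n_tv += 1
    return n_ti, n_tv


def _normalise_residue(res: str) -> str:
    r = res.strip()
    if len(r) == 1:
        r = r.upper()
        if r not in set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError(f"unknown residue: {res!r}")
        return r
    if r.upper() in _THREE_TO_ONE:
        return _THREE_TO_ONE[r.upper()]
    raise ValueError(f"unknown residue: {res!r}")


def residue_category(res: str) -> str:
    r = _normalise_residue(res)
    for cat, members in AA_CATEGORIES.items():
        if r in members:
            return cat
    raise ValueError(f"unknown residue: {res!r}")  # pragma: no cover


def aa_change_class(res_a: str, res_b: str) -> str:
    """Classify an amino-acid change as identical / conservative / non-conservative.

    Conservative means both residues fall in the same physicochemical
    category (nonpolar, polar-uncharged, positively or negatively charged);
    e.g. Asn (polar) -> Asp (negative) is non-conservative, Ile -> Leu
    (both nonpolar) is conservative.
    """
    a, b = _normalise_residue(res_a), _normalise_residue(res_b)
    if a == b:
        return "identical"
    return (
        "conservative"
        if residue_category(a) == residue_category(b)
        else "non-conservative"
    )


def haplotypes_to_snp_table(
    sequences: Mapping[str, str] | Sequence[str],
    locus_name: str = "locus",
    reference: str | None = None,
) -> tuple[list[SnpSite], dict[str, tuple[str, ...]]]:
    """Extract the SNP site list and per-haplotype allele vectors from
    aligned, gap-free, equal-length haplotype sequences.

    Returns (sites, allele_vectors) where positions are 1-based and a
    monomorphic alignment yields an empty site list.  The reference allele
    of each site is taken from ``reference`` (default: the first sequence).
    """
    if isinstance(sequences, Mapping):
        names = list(sequences)
        seqs = [sequences[n].upper() for n in names]
    else:
        seqs = [s.upper() for s in sequences]
        names = [f"hap{i + 1}" for i in range(len(seqs))]
    if not seqs:
        raise ValueError("no sequences given")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("haplotype sequences differ in length")
    for s in seqs:
        if set(s) - NUCLEOTIDES:
            raise ValueError("sequences must be gap-free A/C/G/T")
    ref = (reference or seqs[0]).upper()

    sites: list[SnpSite] = []
    for col in range(length):
        observed = {s[col] for s in seqs}
        if len(observed) > 1:
            sites.append(
                SnpSite(
                    locus=locus_name,
                    position=col + 1,
                    alleles=tuple(sorted(observed)),
                    ref_allele=ref[col] if ref[col] in observed else None,
                )
            )
    vectors = {
        name: tuple(seq[site.position - 1] for site in sites)
        for name, seq in zip(names, seqs)
    }
    return sites, vectors
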