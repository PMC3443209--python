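"""Built-in reference datasets from the Ulva Island robin founder study.

Two desk-scale inputs are shipped as code:

* the per-locus SNP panel observed across the nine genotyped Toll-like
  receptor amplicons (1-based positions, alleles and annotated residue
  changes).  Reference sequences are *synthetic*: only the SNP-bearing
  codons are meaningful, realised programmatically so that translating the
  published alleles reproduces the published residues; every other codon is
  neutral filler.  All downstream classification (synonymous vs
  nonsynonymous, transition vs transversion) is recomputed from these
  sequences, not looked up.

* the founder genotype configurations at the amino-acid-variant level for
  the seven polymorphic loci (12 diploid founders).  These are the unique
  integer configurations consistent with the published per-locus observed
  and unbiased expected heterozygosities; they make the published
  diversity table an exact regression surface for the statistics modules.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .seqvar import Locus, SnpSite, _normalise_residue, _translate_codon

__all__ = [
    "SnpAnnotation",
    "PanelLocus",
    "robin_snp_panel",
    "founder_genotype_fixture",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SnpAnnotation:
    """One published SNP: amplicon position, alleles, annotated residues."""

    position: int
    alleles: tuple[str, ...]
    residues: tuple[str, ...]  # one per distinct residue state (3-letter ok)


@dataclass(frozen=True)
class PanelLocus:
    name: str
    length_bp: int
    frame_offset: int
    n_founders_direct: int  # founders genotyped directly (others inferred)
    snps: tuple[SnpAnnotation, ...]


# Published amplicon panel: nine loci, 24 SNPs (one triallelic), and the
# per-site residue annotations.  TLR7 coamplifies a duplicated copy; the
# three SNPs listed for it are the Mendelian-consistent ones.
PANEL: tuple[PanelLocus, ...] = (
    PanelLocus("TLR1LA", 1166, 0, 10, (
        SnpAnnotation(172, ("C", "T"), ("Arg", "Trp")),
        SnpAnnotation(291, ("G", "A"), ("Ser", "Ser")),
    )),
    PanelLocus("TLR1LB", 971, 0, 10, (
        SnpAnnotation(154, ("C", "T"), ("Leu", "Leu")),
        SnpAnnotation(185, ("C", "T"), ("Ala", "Val")),
        SnpAnnotation(369, ("G", "A"), ("Val", "Val")),
    )),
    PanelLocus("TLR2A", 1034, 0, 10, (
        SnpAnnotation(891, ("C", "T"), ("Gly", "Gly")),
    )),
    PanelLocus("TLR2B", 1021, 0, 10, (
        SnpAnnotation(108, ("G", "A"), ("Glu", "Glu")),
        SnpAnnotation(324, ("C", "T"), ("Asn", "Asn")),
        SnpAnnotation(632, ("C", "T"), ("Thr", "Met")),
        SnpAnnotation(645, ("C", "T"), ("Asn", "Asn")),
        SnpAnnotation(846, ("G", "A"), ("Arg", "Arg")),
    )),
    PanelLocus("TLR3", 1087, 0, 9, ()),
    PanelLocus("TLR4", 649, 0, 10, (
        SnpAnnotation(94, ("A", "C", "T"), ("Ile", "Leu", "Phe")),
        SnpAnnotation(142, ("C", "T"), ("Leu", "Phe")),
        SnpAnnotation(220, ("A", "T"), ("Thr", "Ser")),
        SnpAnnotation(520, ("G", "A"), ("Asp", "Asn")),
    )),
    PanelLocus("TLR5", 1229, 0, 10, (
        SnpAnnotation(371, ("G", "A"), ("Arg", "Gln")),
        SnpAnnotation(817, ("G", "T"), ("Asp", "Tyr")),
    )),
    PanelLocus("TLR7", 1010, 1, 10, (
        SnpAnnotation(162, ("G", "A"), ("Asn", "Asp")),
        SnpAnnotation(672, ("C", "T"), ("Pro", "Ser")),
        SnpAnnotation(723, ("G", "A"), ("Ser", "Gly")),
    )),
    PanelLocus("TLR15", 1279, 0, 10, (
        SnpAnnotation(997, ("G", "A"), ("Asp", "Asn")),
    )),
    PanelLocus("TLR21", 618, 0, 10, (
        SnpAnnotation(118, ("G", "A"), ("Asn", "Asp")),
        SnpAnnotation(169, ("C", "T"), ("Arg", "Trp")),
        SnpAnnotation(300, ("G", "A"), ("Pro", "Pro")),
    )),
)


def _realise_codon(
    codon_pos: int, alleles: tuple[str, ...], residues: tuple[str, ...]
) -> dict[str, str]:
    """Find a codon background such that substituting each allele at
    ``codon_pos`` yields exactly the annotated residue set.

    Residue-to-allele assignment is searched too (published allele and
    residue orders are not guaranteed parallel).  Deterministic: the first
    background/assignment in lexicographic order wins.  Returns
    allele -> full codon.
    """
    wanted = tuple(_normalise_residue(r) for r in residues)
    other_idx = [i for i in range(3) if i != codon_pos]
    for bg in itertools.product(_BASES, repeat=2):
        template = ["?"] * 3
        for i, b in zip(other_idx, bg):
            template[i] = b
        codons = {}
        for a in alleles:
            template[codon_pos] = a
            codons[a] = "".join(template)
        translated = {a: _translate_codon(c) for a, c in codons.items()}
        if "*" in translated.values():
            continue
        for assignment in itertools.permutations(wanted):
            if all(
                translated[a] == res for a, res in zip(alleles, assignment)
            ):
                return codons
    raise ValueError(
        f"no codon realises alleles {alleles} as residues {residues}"
    )


def _build_reference(panel_locus: PanelLocus) -> str:
    """Synthetic reference: neutral filler plus realised SNP codons."""
    L, f = panel_locus.length_bp, panel_locus.frame_offset
    seq = ["A"] * L  # AAA = Lys filler, stop-free in frame
    for snp in panel_locus.snps:
        codon_pos = (snp.position - 1 + f) % 3
        start = snp.position - codon_pos  # 1-based codon start
        if start < 1 or start + 2 > L:
            raise ValueError(
                f"{panel_locus.name}:{snp.position} not in a complete codon"
            )
        codons = _realise_codon(codon_pos, snp.alleles, snp.residues)
        ref_codon = codons[snp.alleles[0]]  # first listed allele = reference
        seq[start - 1:start + 2] = list(ref_codon)
    return "".join(seq)


def robin_snp_panel() -> list[tuple[Locus, list[SnpSite]]]:
    """The nine-locus amplicon panel as (Locus, SNP sites) pairs.

    Monomorphic loci (TLR3) contribute an empty site list.  Reference
    sequences are synthetic codon realisations (see module docstring).
    """
    out = []
    for pl in PANEL:
        locus = Locus(
            name=pl.name,
            reference_seq=_build_reference(pl),
            frame_offset=pl.frame_offset,
        )
        sites = [
            SnpSite(
                locus=pl.name,
                position=snp.position,
                alleles=snp.alleles,
                ref_allele=snp.alleles[0],
            )
            for snp in pl.snps
        ]
        out.append((locus, sites))
    return out


def _expand(config: list[tuple[tuple[str, str], int]]) -> list[tuple[str, str]]:
    return [pair for pair, n in config for _ in range(n)]


def founder_genotype_fixture() -> dict[str, list[tuple[str, str]]]:
    """Amino-acid-variant genotypes of the 12 founders at the seven
    polymorphic loci, reconstructed from the published Ho/He values.

    Each locus maps to 12 unordered variant pairs.  For six loci the
    integer configuration is uniquely determined by the published observed
    heterozygote count and allele counts under Nei's unbiased estimator.
    TLR2B's published He (0.591) is not attainable with two variants at
    n = 12 (the maximum is 0.522); the smallest configuration reproducing
    it has four variant states with counts (14, 7, 2, 1) and six
    heterozygotes, which is what this fixture uses.
    """
    v = lambda i: f"V{i}"
    fixture = {
        # (variant pair, count); allele counts noted per locus
        "TLR1LA": [((v(1), v(1)), 3), ((v(1), v(2)), 5), ((v(2), v(2)), 4)],   # 11:13
        "TLR1LB": [((v(1), v(1)), 4), ((v(1), v(2)), 3), ((v(2), v(2)), 5)],   # 11:13
        "TLR2B": [((v(1), v(1)), 5), ((v(2), v(2)), 1), ((v(1), v(2)), 3),
                  ((v(1), v(3)), 1), ((v(2), v(3)), 1), ((v(2), v(4)), 1)],    # 14:7:2:1
        "TLR4": [((v(1), v(1)), 4), ((v(2), v(3)), 3), ((v(1), v(2)), 2),
                 ((v(1), v(4)), 1), ((v(3), v(4)), 1), ((v(4), v(5)), 1)],     # 11:5:4:3:1
        "TLR5": [((v(1), v(1)), 5), ((v(2), v(2)), 1), ((v(1), v(2)), 5),
                 ((v(1), v(3)), 1)],                                           # 16:7:1
        "TLR15": [((v(2), v(2)), 11), ((v(1), v(2)), 1)],                      # 1:23
        "TLR21": [((v(1), v(1)), 6), ((v(1), v(2)), 5), ((v(1), v(3)), 1)],    # 18:5:1
    }
    return {locus: _expand(cfg) for locus, cfg in fixture.items()}


def fragment_lengths() -> dict[str, int]:
    """Published amplicon lengths (bp) for the ten sequenced loci."""
    return {pl.name: pl.length_bp for pl in PANEL}
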