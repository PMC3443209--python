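"""McDonald-Kreitman contrasts between two species' haplotype sets.

Under neutrality the ratio of nonsynonymous to synonymous changes should be
the same among differences fixed between species and polymorphisms
segregating within them; an excess of nonsynonymous fixed differences is
the classic footprint of repeated directional selection.  Association in
the 2x2 table is tested with the log-likelihood-ratio G statistic (with an
optional Williams correction) and, as an exact companion, Fisher's test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .seqvar import Locus, classify_substitution, classify_ti_tv

__all__ = [
    "SiteClass",
    "MkTable",
    "classify_sites",
    "g_test",
    "mk_report",
]


@dataclass(frozen=True)
class SiteClass:
    """MK classification of one alignment column (or one change at it)."""

    position: int
    spread: str  # "fixed" | "polymorphic" | "monomorphic"
    effect: str | None  # "synonymous" | "nonsynonymous" | None for monomorphic
    alleles: tuple[str, ...]


def _decompose_column(alleles: set[str], ref_base: str) -> list[tuple[str, str]]:
    """Changes at a multi-state column: pivot minimising transversions,
    ties broken toward the reference base, then alphabetically."""
    alleles = sorted(alleles)
    if len(alleles) == 2:
        return [tuple(alleles)]

    def tv_count(pivot: str) -> int:
        return sum(
            classify_ti_tv(pivot, o) == "transversion"
            for o in alleles if o != pivot
        )

    pivot = min(
        alleles,
        key=lambda a: (tv_count(a), 0 if a == ref_base else 1, a),
    )
    return [tuple(sorted((pivot, o))) for o in alleles if o != pivot]


def classify_sites(
    species_a_haplotypes: Sequence[str],
    species_b_haplotypes: Sequence[str],
    frame_offset: int = 0,
) -> list[SiteClass]:
    """Classify every alignment column as fixed / polymorphic / monomorphic
    and synonymous / nonsynonymous.

    A column is *polymorphic* if variable within either species (counted
    once even if variable in both), *fixed* if invariant within each
    species but different between them.  The codon context for the
    syn/nonsyn call is the first species-A haplotype; columns with more
    than two states are decomposed into pairwise changes (each contributing
    one classification).  Sequences must be codon-aligned, equal-length and
    gap-free; alignment construction is the caller's job.
    """
    a_seqs = [s.upper() for s in species_a_haplotypes]
    b_seqs = [s.upper() for s in species_b_haplotypes]
    if not a_seqs or not b_seqs:
        raise ValueError("both species need at least one haplotype")
    length = len(a_seqs[0])
    if any(len(s) != length for s in a_seqs + b_seqs):
        raise ValueError("all sequences must be equal length (codon-aligned)")
    ref = Locus(name="speciesA", reference_seq=a_seqs[0],
                frame_offset=frame_offset)

    out: list[SiteClass] = []
    for col in range(length):
        pos = col + 1
        set_a = {s[col] for s in a_seqs}
        set_b = {s[col] for s in b_seqs}
        union = set_a | set_b
        if len(union) == 1:
            out.append(SiteClass(pos, "monomorphic", None, tuple(union)))
            continue
        if len(set_a) > 1 or len(set_b) > 1:
            spread = "polymorphic"
        else:
            spread = "fixed"
        for a, b in _decompose_column(union, ref.reference_seq[col]):
            effect = classify_substitution(ref, pos, a, b).kind
            out.append(SiteClass(pos, spread, effect, (a, b)))
    return out


@dataclass(frozen=True)
class MkTable:
    """2x2 MK table: rows fixed/polymorphic, columns synonymous/nonsynonymous."""

    locus: str
    species_pair: tuple[str, str]
    fixed_syn: int
    fixed_nonsyn: int
    poly_syn: int
    poly_nonsyn: int
    g: float | None = None
    p_g: float | None = None
    p_fisher: float | None = None
    neutrality_index: float | None = None

    @property
    def counts(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.fixed_syn, self.fixed_nonsyn),
            (self.poly_syn, self.poly_nonsyn),
        )

    @property
    def nonsyn_fraction_fixed(self) -> float | None:
        d = self.fixed_syn + self.fixed_nonsyn
        return self.fixed_nonsyn / d if d else None

    @property
    def nonsyn_fraction_poly(self) -> float | None:
        p = self.poly_syn + self.poly_nonsyn
        return self.poly_nonsyn / p if p else None

    @property
    def directional_selection_flag(self) -> bool:
        """Excess nonsynonymous fixation at the 5% level."""
        ff, fp = self.nonsyn_fraction_fixed, self.nonsyn_fraction_poly
        return (
            ff is not None and fp is not None and ff > fp
            and self.p_g is not None and self.p_g < 0.05
        )


def g_test(
    table: Sequence[Sequence[int]], williams: bool = False
) -> tuple[float, float]:
    """Log-likelihood-ratio test of independence for a 2x2 table.

    G = 2 sum O ln(O/E) over the four cells, expected counts from the
    margins (0 ln 0 := 0); p from chi-square with 1 df.  ``williams=True``
    applies the Williams small-sample correction G/q.
    """
    (a, b), (c, d) = ((int(x) for x in row) for row in table)
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("counts must be nonnegative")
    n = sum(cells)
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    if 0 in rows or 0 in cols or n == 0:
        raise ValueError("degenerate margins: G test undefined")
    g = 0.0
    for obs, (r, col) in zip(cells, [(0, 0), (0, 1), (1, 0), (1, 1)]):
        if obs:
            exp = rows[r] * cols[col] / n
            g += obs * math.log(obs / exp)
    g *= 2.0
    if williams:
        q = 1.0 + (
            (n / rows[0] + n / rows[1] - 1.0)
            * (n / cols[0] + n / cols[1] - 1.0)
            / (6.0 * n)
        )
        g /= q
    g = max(g, 0.0)
    return g, float(stats.chi2.sf(g, df=1))


def mk_report(
    species_a_haplotypes: Sequence[str],
    species_b_haplotypes: Sequence[str],
    frame_offset: int = 0,
    locus: str = "locus",
    species_pair: tuple[str, str] = ("speciesA", "speciesB"),
    williams: bool = False,
) -> MkTable:
    """Assemble the MK 2x2 with G, Fisher and the neutrality index.

    NI = (Pn/Ps) / (Dn/Ds); undefined (None) whenever a required margin is
    zero.  The G test is skipped (None) on degenerate margins, while the
    Fisher exact p is always computed from the hypergeometric tail.
    """
    sites = classify_sites(species_a_haplotypes, species_b_haplotypes,
                           frame_offset)
    counts = {"fixed": {"synonymous": 0, "nonsynonymous": 0},
              "polymorphic": {"synonymous": 0, "nonsynonymous": 0}}
    for sc in sites:
        if sc.spread in counts and sc.effect is not None:
            counts[sc.spread][sc.effect] += 1
    ds, dn = counts["fixed"]["synonymous"], counts["fixed"]["nonsynonymous"]
    ps, pn = (counts["polymorphic"]["synonymous"],
              counts["polymorphic"]["nonsynonymous"])

    table = ((ds, dn), (ps, pn))
    try:
        g, p_g = g_test(table, williams=williams)
    except ValueError:
        g = p_g = None
    if sum(ds + dn + ps + pn for _ in (1,)) > 0:
        _, p_fisher = stats.fisher_exact(table)
        p_fisher = float(p_fisher)
    else:
        p_fisher = None
    ni = None
    if ps > 0 and dn > 0 and ds > 0:
        ni = (pn / ps) / (dn / ds)
    return MkTable(
        locus=locus,
        species_pair=species_pair,
        fixed_syn=ds,
        fixed_nonsyn=dn,
        poly_syn=ps,
        poly_nonsyn=pn,
        g=g,
        p_g=p_g,
        p_fisher=p_fisher,
        neutrality_index=ni,
    )
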