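"""File formats: FASTA via Biopython, tab-separated tables via pandas.

Conventions: TSV is tab-delimited with a header row and ``#`` comments;
FASTA is wrapped at 70 columns; genotype matrices are IUPAC-coded with
rows = individuals and columns = ``locus:position``; clone-read FASTA
headers follow the grammar ``individual|locus|replicate|cloneN``;
undefined statistics render as ``-``.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .paralog import CloneExperiment, CloneRead
from .pedigree import UNKNOWN, GenotypeTable, Pedigree
from .popstats import LocusDiversity
from .seqvar import SnpSite, iupac_decode, iupac_encode

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_pedigree",
    "write_pedigree",
    "read_clone_fasta",
    "write_clone_fasta",
    "write_snp_table",
    "write_diversity_report",
    "write_phased",
]

_FASTA_WIDTH = 70


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_FASTA_WIDTH)
        writer.write_file(records)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def write_genotype_matrix(path, table: GenotypeTable) -> None:
    cols = [f"{s.locus}:{s.position}" for s in table.sites]
    rows = []
    for ind in table.individuals():
        row = {"individual": ind}
        for site, col in zip(table.sites, cols):
            if site in table.genotypes[ind]:
                row[col] = iupac_encode(table.get(ind, site))
        rows.append(row)
    pd.DataFrame(rows, columns=["individual"] + cols).to_csv(
        path, sep="\t", index=False
    )


def read_genotype_matrix(path, sites: Sequence[SnpSite]) -> GenotypeTable:
    """Decode an IUPAC matrix against a site registry (column ``locus:pos``)."""
    df = _read_tsv(path)
    by_key = {f"{s.locus}:{s.position}": s for s in sites}
    table = GenotypeTable(sites=list(sites))
    for i, row in df.iterrows():
        ind = row["individual"]
        for col in df.columns[1:]:
            if col not in by_key:
                raise ValueError(
                    f"line {i + 2}: unknown site column {col!r}"
                )
            val = row[col]
            if pd.isna(val):
                continue
            try:
                table.set(ind, by_key[col], iupac_decode(val))
            except ValueError as exc:
                raise ValueError(f"line {i + 2}, column {col}: {exc}") from exc
    return table


def write_pedigree(path, ped: Pedigree) -> None:
    rows = []
    for ind, sex in ped.individuals.items():
        dam, sire = ped.parents_of(ind)
        rows.append(
            {"id": ind, "dam": dam, "sire": sire, "sex": sex,
             "founder": int(ind in ped.founders)}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    df = _read_tsv(path)
    ped = Pedigree()
    for i, row in df.iterrows():
        try:
            ped.add(
                row["id"],
                sex=row.get("sex", "U"),
                dam=row.get("dam", UNKNOWN) or UNKNOWN,
                sire=row.get("sire", UNKNOWN) or UNKNOWN,
                founder=bool(int(row.get("founder", 0))),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"pedigree line {i + 2}: {exc}") from exc
    return ped


def write_clone_fasta(path, experiments: Iterable[CloneExperiment]) -> None:
    seqs: dict[str, str] = {}
    for exp in experiments:
        counter: dict[str, int] = {}
        for read in exp.reads:
            for _ in range(read.count):
                n = counter.get(read.replicate, 0) + 1
                counter[read.replicate] = n
                header = f"{exp.individual}|{exp.locus}|{read.replicate}|clone{n}"
                seqs[header] = read.sequence
    write_fasta(path, seqs)


def read_clone_fasta(path) -> list[CloneExperiment]:
    grouped: dict[tuple[str, str], list[CloneRead]] = {}
    for header, seq in read_fasta(path).items():
        parts = header.split("|")
        if len(parts) != 4:
            raise ValueError(
                f"clone header {header!r} does not match "
                "'individual|locus|replicate|cloneN'"
            )
        ind, locus, replicate, _ = parts
        grouped.setdefault((ind, locus), []).append(
            CloneRead(sequence=seq, replicate=replicate)
        )
    return [
        CloneExperiment(individual=ind, locus=locus, reads=reads)
        for (ind, locus), reads in sorted(grouped.items())
    ]


def write_snp_table(path, rows: Iterable[Mapping]) -> None:
    """Columns: locus, position, alleles, residues, class."""
    pd.DataFrame(
        list(rows), columns=["locus", "position", "alleles", "residues", "class"]
    ).to_csv(path, sep="\t", index=False)


def _fmt(value, ndigits=3) -> str:
    if value is None:
        return "-"
    return f"{value:.{ndigits}f}"


def write_diversity_report(
    path, rows: Sequence[LocusDiversity], json_path=None
) -> None:
    """Per-locus diversity TSV (with a mean row) plus optional JSON twin."""
    records = []
    for r in rows:
        records.append(
            {"locus": r.locus, "n": r.n_individuals, "variants": r.n_variants,
             "Ho": _fmt(r.ho), "He": _fmt(r.he), "hwe_p": _fmt(r.hwe_p),
             "pi_e4": _fmt(None if r.pi is None else r.pi * 1e4, 2),
             "pi_se_e4": _fmt(None if r.pi_se is None else r.pi_se * 1e4, 2)}
        )
    if rows:
        records.append(
            {"locus": "Mean", "n": "",
             "variants": f"{sum(r.n_variants for r in rows) / len(rows):.1f}",
             "Ho": _fmt(sum(r.ho for r in rows) / len(rows)),
             "He": _fmt(sum(r.he for r in rows) / len(rows)),
             "hwe_p": "", "pi_e4": "", "pi_se_e4": ""}
        )
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
    if json_path is not None:
        payload = [
            {"locus": r.locus, "n_individuals": r.n_individuals,
             "n_variants": r.n_variants, "allele_counts": list(r.allele_counts),
             "ho": r.ho, "he": r.he, "hwe_p": r.hwe_p, "pi": r.pi,
             "pi_se": r.pi_se}
            for r in rows
        ]
        Path(json_path).write_text(json.dumps(payload, indent=1))


def write_phased(path, phased: Mapping[str, Mapping]) -> None:
    """Phased output TSV: id, locus, hapA, hapB, certainty."""
    rows = []
    for locus, by_ind in phased.items():
        for ind, ph in by_ind.items():
            rows.append(
                {"id": ind, "locus": locus,
                 "hapA": "".join(ph.hap_a), "hapB": "".join(ph.hap_b),
                 "certainty": ph.certainty}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
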