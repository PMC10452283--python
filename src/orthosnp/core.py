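"""Core domain types and flat-file I/O.

A coding sequence (CDS) is all protein-coding exons of a gene concatenated
into one continuous nucleotide string, carried together with the exon
intervals that place each CDS base on the genome.  All genomic coordinates
are 1-based inclusive (dbSNP/VCF convention); CDS positions are 1-based.

Flat formats:

* per-species FASTA, one record per CDS (record id = cds_id);
* sidecar metadata TSV with columns ``cds_id, gene, species, chromosome,
  strand, exons`` where exons is a semicolon list of ``start-end`` intervals
  in CDS (transcription) order;
* SNP catalog TSV: ``rsid, chrom, pos_1based, major_allele, minor_alleles``
  (minor alleles comma-separated);
* association TSV: ``rsid, disease, category, gene``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
GAP = "-"

#: Human chromosome sort order used throughout (1-22, then X, then Y).
CHROM_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y"]


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key placing numeric chromosomes first (1..22), then X, then Y."""
    label = str(chrom).removeprefix("chr").removeprefix("Chr")
    try:
        return (0, f"{int(label):03d}")
    except ValueError:
        order = {"X": 0, "Y": 1}
        return (1, str(order.get(label, 2)) + label)


@dataclass(frozen=True)
class CodingSequence:
    """One species' CDS with exon structure for CDS<->genome projection.

    ``exons`` are (start, end) genomic intervals, 1-based inclusive, ordered
    5'->3' in CDS (transcription) orientation.  On the minus strand the CDS
    walks each exon from its genomic ``end`` down to its ``start``.
    """

    cds_id: str
    gene: str
    species: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"{self.cds_id}: non-IUPAC characters {sorted(bad)}")
        exon_len = sum(end - start + 1 for start, end in self.exons)
        if exon_len != len(self.sequence):
            raise ValueError(
                f"{self.cds_id}: exon span {exon_len} != sequence length "
                f"{len(self.sequence)}"
            )
        for start, end in self.exons:
            if start > end or start < 1:
                raise ValueError(f"{self.cds_id}: bad exon interval ({start},{end})")

    def __len__(self) -> int:
        return len(self.sequence)

    def genome_position(self, cds_pos: int) -> tuple[str, int]:
        """Map a 1-based CDS position to (chromosome, 1-based genomic position).

        Exons are walked in CDS order; on the minus strand positions descend
        within each exon.
        """
        if not 1 <= cds_pos <= len(self.sequence):
            raise ValueError(
                f"cds_pos {cds_pos} out of range 1..{len(self.sequence)}"
            )
        offset = cds_pos - 1
        for start, end in self.exons:
            width = end - start + 1
            if offset < width:
                if self.strand == "+":
                    return self.chromosome, start + offset
                return self.chromosome, end - offset
            offset -= width
        raise AssertionError("unreachable: exon walk exhausted")

    def genome_positions(self) -> list[int]:
        """Genomic position of every CDS base, in CDS order."""
        out: list[int] = []
        for start, end in self.exons:
            if self.strand == "+":
                out.extend(range(start, end + 1))
            else:
                out.extend(range(end, start - 1, -1))
        return out


@dataclass(frozen=True)
class SnpRecord:
    """One catalog SNP: identifier, locus, major and minor alleles."""

    rsid: str
    chrom: str
    pos: int  # 1-based
    major_allele: str
    minor_alleles: tuple[str, ...]


@dataclass
class SnpCatalog:
    """Human SNP catalog keyed by (chromosome, position)."""

    records: list[SnpRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        dups = []
        for rec in self.records:
            key = (rec.chrom, rec.pos)
            if key in seen:
                dups.append((key, seen[key], rec.rsid))
            seen[key] = rec.rsid
        if dups:
            raise ValueError(f"duplicate catalog positions: {dups}")
        self._by_locus = {(r.chrom, r.pos): r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, chrom: str, pos: int) -> SnpRecord | None:
        return self._by_locus.get((chrom, pos))


# ---------------------------------------------------------------------------
# FASTA + sidecar metadata


def _format_exons(exons: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in exons)


def _parse_exons(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for part in str(text).split(";"):
        s, _, e = part.partition("-")
        out.append((int(s), int(e)))
    return tuple(out)


def write_cds_set(
    cdss: Iterable[CodingSequence], fasta_path: Path | str, meta_path: Path | str
) -> None:
    cdss = list(cdss)
    records = [
        SeqRecord(Seq(c.sequence), id=c.cds_id, description="") for c in cdss
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    meta = pd.DataFrame(
        {
            "cds_id": [c.cds_id for c in cdss],
            "gene": [c.gene for c in cdss],
            "species": [c.species for c in cdss],
            "chromosome": [c.chromosome for c in cdss],
            "strand": [c.strand for c in cdss],
            "exons": [_format_exons(c.exons) for c in cdss],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_cds_set(fasta_path: Path | str, meta_path: Path | str) -> list[CodingSequence]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    out = []
    for row in meta.itertuples(index=False):
        if row.cds_id not in seqs:
            raise ValueError(f"{row.cds_id} in metadata but not in FASTA")
        out.append(
            CodingSequence(
                cds_id=row.cds_id,
                gene=row.gene,
                species=row.species,
                chromosome=str(row.chromosome),
                strand=row.strand,
                exons=_parse_exons(row.exons),
                sequence=seqs[row.cds_id],
            )
        )
    return out


# ---------------------------------------------------------------------------
# SNP catalog and association tables


def write_snp_catalog(catalog: SnpCatalog, path: Path | str) -> None:
    df = pd.DataFrame(
        {
            "rsid": [r.rsid for r in catalog.records],
            "chrom": [r.chrom for r in catalog.records],
            "pos_1based": [r.pos for r in catalog.records],
            "major_allele": [r.major_allele for r in catalog.records],
            "minor_alleles": [",".join(r.minor_alleles) for r in catalog.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_snp_catalog(path: Path | str) -> SnpCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = [
        SnpRecord(
            rsid=row.rsid,
            chrom=str(row.chrom),
            pos=int(row.pos_1based),
            major_allele=row.major_allele,
            minor_alleles=tuple(str(row.minor_alleles).split(",")),
        )
        for row in df.itertuples(index=False)
    ]
    return SnpCatalog(records)


def read_associations(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"rsid", "disease", "category", "gene"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    return df


def index_by_id(cdss: Iterable[CodingSequence]) -> Mapping[str, CodingSequence]:
    return {c.cds_id: c for c in cdss}
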