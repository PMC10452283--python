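"""Six-way CDS alignment, variant columns, and SNP coordinate projection.

Each conserved ortholog group is aligned with a tree-guided progressive
profile aligner (global Gotoh dynamic programming with affine gaps, profiles
merged in the guide tree's postorder).  Alignments are human-referenced:
columns gapped in the human row are never reported, CDS positions are counts
of non-gap human characters, and genomic positions come from the human exon
walk.  Catalog SNPs are located in the alignment via the inverse projection
(genome -> CDS position -> column) and a SNP is "identified in" a species
when that species' residue in the column equals the catalog major allele;
a gap never matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .core import GAP, CodingSequence, SnpCatalog
from .trees import SpeciesTree

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, GAP: 4}
# match +1 / mismatch -2 between bases; N and gap score 0 against anything
_SUB = np.full((5, 5), -2.0)
np.fill_diagonal(_SUB, 1.0)
_SUB[4, :] = 0.0
_SUB[:, 4] = 0.0

# Stiff gap costs (relative to match +1 / mismatch -2) so that short lucky
# register shifts never beat the homologous diagonal; true indels of >= 3 nt
# still align far more cheaply than forcing the whole tail out of register.
_GAP_OPEN = -16.0
_GAP_EXTEND = -4.0


@dataclass
class MsaBlock:
    """Gapped six-way alignment of one conserved ortholog group."""

    human_cds_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def degapped(self, species: str) -> str:
        return self.rows[species].replace(GAP, "")


@dataclass(frozen=True)
class MappedSnp:
    """A human catalog SNP located in an alignment block."""

    rsid: str | None
    human_cds_id: str
    column: int  # 1-based alignment column
    cds_pos: int  # 1-based human CDS position
    chrom: str
    pos: int  # 1-based genomic position
    major_allele: str
    alleles: dict[str, str]  # per non-human species: base or '-'
    match_flags: dict[str, bool]


@njit(cache=True)
def _gotoh_path(S, gap_open, gap_extend):  # pragma: no cover - numba kernel
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume row of A)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume row of B)
    pM = np.zeros((n + 1, m + 1), np.uint8)
    pX = np.zeros((n + 1, m + 1), np.uint8)
    pY = np.zeros((n + 1, m + 1), np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # into M
            a, b, c = M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            if a >= b and a >= c:
                M[i, j] = S[i - 1, j - 1] + a
                pM[i, j] = 0
            elif b >= c:
                M[i, j] = S[i - 1, j - 1] + b
                pM[i, j] = 1
            else:
                M[i, j] = S[i - 1, j - 1] + c
                pM[i, j] = 2
            # into X
            a = M[i - 1, j] + gap_open
            b = X[i - 1, j] + gap_extend
            c = Y[i - 1, j] + gap_open
            if a >= b and a >= c:
                X[i, j] = a
                pX[i, j] = 0
            elif b >= c:
                X[i, j] = b
                pX[i, j] = 1
            else:
                X[i, j] = c
                pX[i, j] = 2
            # into Y
            a = M[i, j - 1] + gap_open
            b = X[i, j - 1] + gap_open
            c = Y[i, j - 1] + gap_extend
            if a >= b and a >= c:
                Y[i, j] = a
                pY[i, j] = 0
            elif b >= c:
                Y[i, j] = b
                pY[i, j] = 1
            else:
                Y[i, j] = c
                pY[i, j] = 2
    state = 0
    best = M[n, m]
    if X[n, m] > best:
        state, best = 1, X[n, m]
    if Y[n, m] > best:
        state = 2
    ai = np.empty(n + m, np.int64)
    bi = np.empty(n + m, np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ai[k] = i - 1
            bi[k] = j - 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ai[k] = i - 1
            bi[k] = -1
            state = pX[i, j]
            i -= 1
        else:
            ai[k] = -1
            bi[k] = j - 1
            state = pY[i, j]
            j -= 1
        k += 1
    return ai[:k][::-1].copy(), bi[:k][::-1].copy()


def _profile(rows: Mapping[str, str]) -> np.ndarray:
    length = len(next(iter(rows.values())))
    counts = np.zeros((length, 5))
    for row in rows.values():
        codes = np.frombuffer(row.encode(), dtype=np.uint8)
        idx = np.empty(length, np.int64)
        for ch, code in _CODE.items():
            idx[codes == ord(ch)] = code
        counts[np.arange(length), idx] += 1
    return counts


def _merge(rows_a: dict[str, str], rows_b: dict[str, str]) -> dict[str, str]:
    prof_a, prof_b = _profile(rows_a), _profile(rows_b)
    S = prof_a[:, :4] @ _SUB[:4, :4] @ prof_b[:, :4].T
    S /= len(rows_a) * len(rows_b)
    ai, bi = _gotoh_path(S, _GAP_OPEN, _GAP_EXTEND)
    merged: dict[str, str] = {}
    for name, row in rows_a.items():
        merged[name] = "".join(row[i] if i >= 0 else GAP for i in ai)
    for name, row in rows_b.items():
        merged[name] = "".join(row[j] if j >= 0 else GAP for j in bi)
    return merged


def align_group(
    sequences: Mapping[str, CodingSequence],
    guide: SpeciesTree | None = None,
    prealigned: Mapping[str, str] | None = None,
) -> MsaBlock:
    """Align one ortholog group, one sequence per guide-tree taxon.

    ``prealigned`` bypasses alignment; rows are validated to de-gap back to
    the input sequences.
    """
    if guide is None:
        guide = SpeciesTree.default()
    taxa = set(guide.taxa())
    missing = taxa - set(sequences)
    if missing:
        raise ValueError(f"missing taxa: {sorted(missing)}")
    human_id = sequences["human"].cds_id if "human" in sequences else next(
        iter(sequences.values())
    ).cds_id
    if prealigned is not None:
        for sp in taxa:
            if prealigned[sp].replace(GAP, "") != sequences[sp].sequence:
                raise ValueError(f"pre-aligned row for {sp} does not de-gap to input")
        return MsaBlock(human_cds_id=human_id, rows=dict(prealigned))

    def _align(node) -> dict[str, str]:
        if node.is_leaf():
            name = node.taxon.label
            return {name: sequences[name].sequence}
        children = node.child_nodes()
        rows = _align(children[0])
        for child in children[1:]:
            rows = _merge(rows, _align(child))
        return rows

    return MsaBlock(human_cds_id=human_id, rows=_align(guide.tree.seed_node))


@dataclass(frozen=True)
class VariantColumn:
    column: int  # 1-based
    human_base: str
    alleles: dict[str, str]  # non-human species -> base or gap
    differing: tuple[str, ...]


def extract_variant_columns(
    block: MsaBlock, human_species: str = "human"
) -> list[VariantColumn]:
    """Columns where the human row has a base and any other row differs.

    A gap in a non-human row counts as a difference (the site varies) but can
    never match an allele.  Columns gapped in human are skipped: the human
    coordinate frame is the analysis reference.
    """
    human_row = block.rows[human_species]
    others = {sp: row for sp, row in block.rows.items() if sp != human_species}
    out = []
    for col in range(block.n_columns):
        h = human_row[col]
        if h == GAP:
            continue
        alleles = {sp: row[col] for sp, row in others.items()}
        differing = tuple(sorted(sp for sp, b in alleles.items() if b != h))
        if differing:
            out.append(
                VariantColumn(
                    column=col + 1, human_base=h, alleles=alleles, differing=differing
                )
            )
    return out


def project_column(block: MsaBlock, column: int, human_species: str = "human") -> int:
    """1-based human CDS position of an alignment column (human row not gapped)."""
    if not 1 <= column <= block.n_columns:
        raise ValueError(f"column {column} out of range 1..{block.n_columns}")
    row = block.rows[human_species]
    if row[column - 1] == GAP:
        raise ValueError(f"human row is gapped at column {column}")
    return column - row[:column].count(GAP)


def column_for_cds_pos(
    block: MsaBlock, cds_pos: int, human_species: str = "human"
) -> int:
    """Inverse of :func:`project_column`: alignment column of a CDS position."""
    row = block.rows[human_species]
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            seen += 1
            if seen == cds_pos:
                return col
    raise ValueError(f"cds_pos {cds_pos} beyond human row length {seen}")


def cds_to_genome(cds_pos: int, cds: CodingSequence) -> tuple[str, int]:
    """Map a 1-based CDS position to (chromosome, 1-based genomic position)."""
    return cds.genome_position(cds_pos)


def match_catalog(
    blocks: Iterable[MsaBlock],
    human_cds_by_id: Mapping[str, CodingSequence],
    catalog: SnpCatalog,
    human_species: str = "human",
) -> tuple[list[MappedSnp], dict[str, int], list[tuple[str, int]]]:
    """Locate every catalog SNP falling inside a block; flag allele matches.

    Returns (mapped SNPs, per-species identified counts, excluded loci).  A
    locus is excluded — logged, never silently matched — when the human base
    at the catalog position differs from the catalog major allele.
    """
    mapped: list[MappedSnp] = []
    excluded: list[tuple[str, int]] = []
    counts: dict[str, int] = {}
    for block in blocks:
        cds = human_cds_by_id[block.human_cds_id]
        gpositions = cds.genome_positions()
        human_row = block.rows[human_species]
        others = sorted(sp for sp in block.rows if sp != human_species)
        for sp in others:
            counts.setdefault(sp, 0)
        # columns of successive human bases, in CDS order
        human_cols = [i for i, ch in enumerate(human_row) if ch != GAP]
        for cds_pos0, gpos in enumerate(gpositions):
            rec = catalog.lookup(cds.chromosome, gpos)
            if rec is None:
                continue
            col = human_cols[cds_pos0]
            human_base = human_row[col]
            if human_base != rec.major_allele:
                logger.warning(
                    "catalog %s at %s:%d major allele %s != human base %s; excluded",
                    rec.rsid, rec.chrom, rec.pos, rec.major_allele, human_base,
                )
                excluded.append((rec.chrom, rec.pos))
                continue
            alleles = {sp: block.rows[sp][col] for sp in others}
            flags = {sp: alleles[sp] == rec.major_allele for sp in others}
            for sp, ok in flags.items():
                if ok:
                    counts[sp] += 1
            mapped.append(
                MappedSnp(
                    rsid=rec.rsid,
                    human_cds_id=block.human_cds_id,
                    column=col + 1,
                    cds_pos=cds_pos0 + 1,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    major_allele=rec.major_allele,
                    alleles=alleles,
                    match_flags=flags,
                )
            )
    return mapped, counts, excluded


def mapped_snps_to_frame(mapped: Sequence[MappedSnp]):
    import pandas as pd

    species = sorted(mapped[0].alleles) if mapped else []
    rows = []
    for m in mapped:
        row = {
            "rsid": m.rsid,
            "human_cds_id": m.human_cds_id,
            "column": m.column,
            "cds_pos": m.cds_pos,
            "chrom": m.chrom,
            "pos": m.pos,
            "major_allele": m.major_allele,
        }
        for sp in species:
            row[f"allele_{sp}"] = m.alleles[sp]
            row[f"match_{sp}"] = m.match_flags[sp]
        rows.append(row)
    return pd.DataFrame(rows)
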