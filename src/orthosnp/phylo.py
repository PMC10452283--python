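"""Concatenated-alignment phylogeny and human-referenced synteny maps.

Conserved-group alignments are concatenated in human chromosomal order
(1-22, X, Y; then start coordinate) into a supermatrix.  Pairwise distances
use pairwise deletion of gap sites, as raw p-distance or with the
Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3).  The tree is built by
canonical neighbor joining (Q-matrix minimisation, standard branch-length
formulas, deterministic tie-breaks); topologies are compared by the
Robinson-Foulds distance, the size of the symmetric difference of the two
trees' non-trivial bipartition sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import GAP, CodingSequence, chrom_sort_key
from .msa import MsaBlock

logger = logging.getLogger(__name__)


@dataclass
class Supermatrix:
    rows: dict[str, str]
    block_spans: dict[str, tuple[int, int]]  # human_cds_id -> 1-based (start, end)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def extract_block(self, human_cds_id: str) -> dict[str, str]:
        start, end = self.block_spans[human_cds_id]
        return {sp: row[start - 1 : end] for sp, row in self.rows.items()}


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # symmetric, zero diagonal
    model: str  # 'p' or 'jc'

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def concatenate(
    blocks: Iterable[MsaBlock],
    human_cds_by_id: Mapping[str, CodingSequence],
) -> Supermatrix:
    """Join block alignments per species, in human chromosome order."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no blocks to concatenate")
    species = set(blocks[0].rows)
    for b in blocks:
        if set(b.rows) != species:
            missing = species.symmetric_difference(b.rows)
            raise ValueError(f"block {b.human_cds_id} species mismatch: {missing}")

    def sort_key(b: MsaBlock):
        cds = human_cds_by_id[b.human_cds_id]
        return (chrom_sort_key(cds.chromosome), min(s for s, _ in cds.exons))

    ordered = sorted(blocks, key=sort_key)
    parts: dict[str, list[str]] = {sp: [] for sp in species}
    spans: dict[str, tuple[int, int]] = {}
    cursor = 1
    for b in ordered:
        width = b.n_columns
        spans[b.human_cds_id] = (cursor, cursor + width - 1)
        cursor += width
        for sp in species:
            parts[sp].append(b.rows[sp])
    return Supermatrix(
        rows={sp: "".join(chunks) for sp, chunks in parts.items()},
        block_spans=spans,
    )


def jc_distance(p: float) -> float:
    """Jukes-Cantor distance from an observed mismatch proportion."""
    if p >= 0.75:
        raise ValueError(f"p = {p} >= 0.75: Jukes-Cantor distance undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def distances(rows: Mapping[str, str] | Supermatrix, model: str = "jc") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/N sites."""
    if isinstance(rows, Supermatrix):
        rows = rows.rows
    if model not in ("p", "jc"):
        raise ValueError("model must be 'p' or 'jc'")
    labels = tuple(sorted(rows))
    arrays = {
        sp: np.frombuffer(rows[sp].encode(), dtype=np.uint8) for sp in labels
    }
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("empty alignment")
    valid = {
        sp: (a != ord(GAP)) & (a != ord("N")) for sp, a in arrays.items()
    }
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[labels[i]] & valid[labels[j]]
            sites = int(both.sum())
            if sites == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]} and {labels[j]}"
                )
            p = float(
                (arrays[labels[i]][both] != arrays[labels[j]][both]).sum() / sites
            )
            out[i, j] = out[j, i] = jc_distance(p) if model == "jc" else p
    return DistanceMatrix(labels=labels, matrix=out, model=model)


def _fmt_bl(x: float) -> str:
    return f"{x:.6g}"


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Canonical neighbor joining; returns a Newick string with branch lengths.

    Ties in the Q matrix break on the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf).  Negative
    branch lengths are clamped to zero (logged).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    newick = list(dm.labels)  # newick fragment per active cluster
    labels = list(dm.labels)  # smallest-leaf label per cluster

    def clamp(x: float) -> float:
        if x < 0:
            logger.info("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((labels[i], labels[j])))
                if best is None or (q, pair_key) < best[:2]:
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        raw_li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (len(active) - 2))
        li = clamp(raw_li)
        lj = clamp(D[i, j] - raw_li)
        new_frag = f"({newick[i]}:{_fmt_bl(li)},{newick[j]}:{_fmt_bl(lj)})"
        # distances from the new node
        new_row = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : new_row.size - 1] = new_row[:-1]
        D[: new_row.size - 1, -1] = new_row[:-1]
        newick.append(new_frag)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]
    # three remaining clusters join at a central node (three-point formulas)
    a, b, c = active
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    return (
        f"({newick[a]}:{_fmt_bl(la)},{newick[b]}:{_fmt_bl(lb)},"
        f"{newick[c]}:{_fmt_bl(lc)});"
    )


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if len(below) <= 1 or len(below) >= len(leaves) - 1:
            continue
        side = leaves - below if ref in below else below
        out.add(frozenset(side))
    return out


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Robinson-Foulds distance between two trees over the same leaf set."""
    ta = dendropy.Tree.get(data=newick_a, schema="newick")
    tb = dendropy.Tree.get(data=newick_b, schema="newick")
    la = {leaf.taxon.label for leaf in ta.leaf_node_iter()}
    lb = {leaf.taxon.label for leaf in tb.leaf_node_iter()}
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la ^ lb)}")
    return len(_bipartitions(ta) ^ _bipartitions(tb))


def synteny_map(
    orthologs: pd.DataFrame,
    human_cds_by_id: Mapping[str, CodingSequence],
    species_cds_by_id: Mapping[str, CodingSequence],
    conserved_ids: Sequence[str],
) -> pd.DataFrame:
    """Human-referenced synteny table over the conserved CDS set.

    One row per (human chromosome, species): source chromosomes ordered by
    descending mapped-CDS count (ties by chromosome label order), with an
    ``intact`` flag when a single source chromosome carries them all.
    """
    conserved = set(conserved_ids)
    sub = orthologs[orthologs["human_cds_id"].isin(conserved)].copy()
    sub["human_chrom"] = sub["human_cds_id"].map(
        lambda i: human_cds_by_id[i].chromosome
    )
    sub["species_chrom"] = sub["species_cds_id"].map(
        lambda i: species_cds_by_id[i].chromosome
    )
    rows = []
    for (hchrom, sp), grp in sub.groupby(["human_chrom", "species"]):
        counts = grp["species_chrom"].value_counts()
        ordered = sorted(
            counts.items(), key=lambda kv: (-kv[1], chrom_sort_key(kv[0]))
        )
        rows.append(
            {
                "human_chrom": hchrom,
                "species": sp,
                "n_conserved_cds": int(counts.sum()),
                "source_chroms": ",".join(c for c, _ in ordered),
                "source_counts": ",".join(str(k) for _, k in ordered),
                "intact": len(ordered) == 1,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            by=["human_chrom", "species"],
            key=lambda col: col.map(chrom_sort_key)
            if col.name == "human_chrom"
            else col,
        ).reset_index(drop=True)
    return df


def distance_matrix_to_frame(dm: DistanceMatrix) -> pd.DataFrame:
    return pd.DataFrame(dm.matrix, index=dm.labels, columns=dm.labels)
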