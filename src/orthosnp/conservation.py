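"""Pairwise CDS conservation: best-hit local alignment, filters, intersections.

Each non-human CDS is aligned locally (affine gaps) against every human CDS;
the single best subject is kept, with one highest-scoring local alignment per
subject — the blastn ``-max_hsps 1 -max_target_seqs 1`` semantics.  A hit is
"conserved" when it shares >= 50% identity with the human CDS and covers
>= 50% of the human CDS length; a human CDS conserved in all five species
comparisons enters the conserved set used by every downstream stage.

Percent identity is identities over alignment columns (gap columns included,
the blastn convention); coverage is the aligned span on the human CDS divided
by the human CDS length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .core import VALID_BASES, CodingSequence

DEFAULT_MIN_IDENTITY = 50.0
DEFAULT_MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class ScoringParams:
    """Affine local-alignment scoring.  A gap of length L costs
    ``gap_open + (L - 1) * gap_extend`` (both negative)."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class PairwiseHit:
    """Best local-alignment match of a non-human CDS to a human CDS."""

    query_cds: str
    subject_cds: str
    percent_identity: float
    alignment_length: int
    coverage: float
    score: float


def _make_aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _hit_from_alignment(query_id, subject_id, alignment, subject_len) -> PairwiseHit:
    counts = alignment.counts()
    n_columns = counts.identities + counts.mismatches + counts.gaps
    subject_span = int(alignment.coordinates[0][-1] - alignment.coordinates[0][0])
    return PairwiseHit(
        query_cds=query_id,
        subject_cds=subject_id,
        percent_identity=100.0 * counts.identities / n_columns,
        alignment_length=int(n_columns),
        coverage=subject_span / subject_len,
        score=float(alignment.score),
    )


def _shared_word_index(
    subjects: Sequence[CodingSequence], word: int
) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for i, s in enumerate(subjects):
        seq = s.sequence
        for j in range(len(seq) - word + 1):
            index.setdefault(seq[j : j + word], set()).add(i)
    return index


def best_hit(
    query: CodingSequence,
    human_set: Sequence[CodingSequence],
    scoring: ScoringParams = ScoringParams(),
    *,
    _aligner: Align.PairwiseAligner | None = None,
    _candidates: Iterable[int] | None = None,
) -> PairwiseHit | None:
    """Best-scoring human subject for one query CDS, or None.

    Ties are broken deterministically: higher score, then higher identity,
    then lexicographically smallest subject id.
    """
    if not query.sequence:
        raise ValueError("empty query")
    if not human_set:
        raise ValueError("empty human set")
    bad = set(query.sequence) - VALID_BASES
    if bad:
        raise ValueError(f"query {query.cds_id}: non-IUPAC characters {sorted(bad)}")
    aligner = _aligner or _make_aligner(scoring)
    idxs = list(_candidates) if _candidates is not None else range(len(human_set))
    scored: list[tuple[float, int]] = []
    for i in idxs:
        subject = human_set[i]
        score = aligner.score(subject.sequence, query.sequence)
        if score > 0:
            scored.append((score, i))
    if not scored:
        return None
    top = max(s for s, _ in scored)
    best: PairwiseHit | None = None
    for score, i in scored:
        if score < top:
            continue
        subject = human_set[i]
        alignment = aligner.align(subject.sequence, query.sequence)[0]
        hit = _hit_from_alignment(
            query.cds_id, subject.cds_id, alignment, len(subject.sequence)
        )
        # equal scores: higher identity wins, then smaller subject id
        if (
            best is None
            or hit.percent_identity > best.percent_identity
            or (
                hit.percent_identity == best.percent_identity
                and hit.subject_cds < best.subject_cds
            )
        ):
            best = hit
    return best


def all_best_hits(
    queries: Sequence[CodingSequence],
    human_set: Sequence[CodingSequence],
    scoring: ScoringParams = ScoringParams(),
    seed_word: int | None = None,
) -> list[PairwiseHit]:
    """Best hit for every query; exhaustive over all subjects by default.

    With ``seed_word`` set, only subjects sharing at least one exact word of
    that length with the query are aligned (blastn-style seeding); queries
    sharing no word with any subject yield no hit.  Seeding trades the
    guarantee of finding diverged short orthologs for speed.
    """
    aligner = _make_aligner(scoring)
    index = _shared_word_index(human_set, seed_word) if seed_word else None
    hits = []
    for q in queries:
        candidates = None
        if index is not None:
            cand: set[int] = set()
            seq = q.sequence
            for j in range(len(seq) - seed_word + 1):
                cand |= index.get(seq[j : j + seed_word], set())
            if not cand:
                continue
            candidates = sorted(cand)
        hit = best_hit(q, human_set, scoring, _aligner=aligner, _candidates=candidates)
        if hit is not None:
            hits.append(hit)
    return hits


def filter_hits(
    hits: Iterable[PairwiseHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[PairwiseHit]:
    """Keep hits passing both conservation filters (boundaries inclusive)."""
    if not 0 <= min_identity <= 100:
        raise ValueError("min_identity must be in [0, 100]")
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    return [
        h
        for h in hits
        if h.percent_identity >= min_identity and h.coverage >= min_coverage
    ]


@dataclass
class ConservedSet:
    """Per-human-CDS membership across the five species comparisons."""

    species: tuple[str, ...]
    membership: pd.DataFrame  # index human_cds_id; bool column per species
    orthologs: pd.DataFrame  # human_cds_id, species, species_cds_id
    pattern_counts: pd.Series  # index = 5-char '01' pattern strings

    @property
    def conserved_ids(self) -> list[str]:
        mask = self.membership[list(self.species)].all(axis=1)
        return sorted(self.membership.index[mask])


def build_conserved_set(
    hits_by_species: Mapping[str, Sequence[PairwiseHit]],
    human_ids: Sequence[str],
) -> ConservedSet:
    """Combine the five filtered hit tables into membership patterns.

    A human CDS is conserved iff it is the retained best hit of some query in
    every one of the five comparisons.  Pattern counts enumerate all observed
    non-empty 5-bit membership patterns (upset-plot style).
    """
    species = tuple(sorted(hits_by_species))
    known = set(human_ids)
    membership = pd.DataFrame(
        False, index=pd.Index(sorted(known), name="human_cds_id"), columns=species
    )
    ortho_rows = []
    for sp in species:
        for h in hits_by_species[sp]:
            if h.subject_cds not in known:
                raise ValueError(f"hit references unknown human CDS {h.subject_cds}")
            membership.loc[h.subject_cds, sp] = True
            ortho_rows.append(
                {"human_cds_id": h.subject_cds, "species": sp,
                 "species_cds_id": h.query_cds}
            )
    patterns = membership[list(species)].apply(
        lambda row: "".join("1" if v else "0" for v in row), axis=1
    )
    counts = patterns[patterns != "0" * len(species)].value_counts().sort_index()
    return ConservedSet(
        species=species,
        membership=membership,
        orthologs=pd.DataFrame(ortho_rows),
        pattern_counts=counts,
    )


def identity_stats(
    hits_by_species: Mapping[str, Sequence[PairwiseHit]],
    conserved_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Mean/median/min/max percent identity per species, for all hits and —
    when ``conserved_ids`` is given — for the conserved subset."""
    conserved = set(conserved_ids) if conserved_ids is not None else None
    rows = []
    for sp in sorted(hits_by_species):
        hits = hits_by_species[sp]
        if not hits:
            raise ValueError(f"no hits for species {sp}")
        subsets = {"all": [h.percent_identity for h in hits]}
        if conserved is not None:
            subsets["conserved"] = [
                h.percent_identity for h in hits if h.subject_cds in conserved
            ]
        for subset, vals in subsets.items():
            arr = np.asarray(vals, dtype=float)
            rows.append(
                {
                    "species": sp,
                    "subset": subset,
                    "n": arr.size,
                    "mean": arr.mean() if arr.size else np.nan,
                    "median": float(np.median(arr)) if arr.size else np.nan,
                    "min": arr.min() if arr.size else np.nan,
                    "max": arr.max() if arr.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def compare_identity_groups(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across per-species identity vectors plus Bonferroni-
    adjusted pairwise two-sample t-tests.

    Returns (F, p, pairwise table).  Degenerate all-identical input reports
    F = 0, p = 1 rather than NaN.
    """
    names = sorted(groups)
    if len(names) < 2 or any(len(groups[g]) < 2 for g in names):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if all(a.var() == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        if np.isnan(f_stat):
            f_stat, p_val = 0.0, 1.0
    pairs = list(itertools.combinations(range(len(names)), 2))
    rows = []
    for i, j in pairs:
        if arrays[i].var() == 0 and arrays[j].var() == 0:
            raw = 1.0 if arrays[i].mean() == arrays[j].mean() else 0.0
        else:
            raw = float(stats.ttest_ind(arrays[i], arrays[j]).pvalue)
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "p_raw": raw,
                "p_bonferroni": min(1.0, raw * len(pairs)),
            }
        )
    return float(f_stat), float(p_val), pd.DataFrame(rows)


def hits_to_frame(hits: Iterable[PairwiseHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query": h.query_cds,
                "subject": h.subject_cds,
                "pident": h.percent_identity,
                "length": h.alignment_length,
                "coverage": h.coverage,
                "score": h.score,
            }
            for h in hits
        ],
        columns=["query", "subject", "pident", "length", "coverage", "score"],
    )
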