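"""Independent brute-force oracles used by the test suite.

Everything here is written against the definitions, not against the package
implementation: an exhaustive Smith-Waterman dynamic program, set-pattern
enumeration, nested-loop joins, and group-by counting.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Mapping, Sequence

NEG = float("-inf")


def smith_waterman_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Exhaustive O(n*m) local alignment score with affine gaps.

    A gap of length L costs gap_open + (L-1)*gap_extend.
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, X[i][j - 1] + gap_open,
                          Y[i][j - 1] + gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return best


def pattern_counts_bruteforce(
    membership: Mapping[str, Mapping[str, bool]], species: Sequence[str]
) -> dict[str, int]:
    """Enumerate all 31 non-empty 5-bit patterns and count members of each."""
    counts: Counter[str] = Counter()
    for _, flags in membership.items():
        pattern = "".join("1" if flags[sp] else "0" for sp in species)
        if "1" in pattern:
            counts[pattern] += 1
    # include every possible non-empty pattern with a zero default
    for bits in itertools.product("01", repeat=len(species)):
        p = "".join(bits)
        if "1" in p:
            counts.setdefault(p, 0)
    return dict(counts)


def nested_loop_join(
    mapped: Sequence[dict], associations: Sequence[dict]
) -> list[tuple]:
    """Reference join: one record per (species, rsid, disease) where the SNP
    is identified in that species."""
    out = []
    for assoc in associations:
        for snp in mapped:
            if snp["rsid"] != assoc["rsid"]:
                continue
            for sp, identified in snp["match_flags"].items():
                if identified:
                    out.append(
                        (sp, assoc["rsid"], assoc["disease"].casefold(),
                         assoc["category"], assoc["gene"])
                    )
    return out


def category_percentages_bruteforce(
    diseases_with_categories: Sequence[tuple[str, str]], categories: Sequence[str]
) -> dict[str, float]:
    """Percentage of unique diseases per category."""
    seen: dict[str, str] = {}
    for disease, cat in diseases_with_categories:
        seen.setdefault(disease, cat)
    total = len(seen)
    counts = Counter(seen.values())
    return {
        c: (100.0 * counts.get(c, 0) / total if total else 0.0) for c in categories
    }


def gene_disease_counts_bruteforce(
    records: Sequence[dict],
) -> dict[tuple[str, str], int]:
    """Unique diseases per (species, gene)."""
    seen: dict[tuple[str, str], set[str]] = {}
    for r in records:
        seen.setdefault((r["species"], r["gene"]), set()).add(r["disease"])
    return {k: len(v) for k, v in seen.items()}


def synteny_ordering_bruteforce(
    assignments: Sequence[tuple[str, str]], label_key
) -> list[tuple[str, int]]:
    """Count-and-sort source chromosomes for one (human chrom, species) cell."""
    counts = Counter(chrom for _, chrom in assignments)
    return sorted(counts.items(), key=lambda kv: (-kv[1], label_key(kv[0])))
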