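"""Disease-association profiling of cross-species-identified human SNPs.

Mapped SNPs are joined to an association table (rsid, disease, category,
gene).  Diseases are compared across the five model species as sets of
case-folded disease names: a disease is *conserved* when SNPs identified in
all five species support it, and *species-specific* when only one species'
identified SNPs do.  Category profiles express, per species, the percentage
of that species' unique diseases falling in each of 24 disease categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .msa import MappedSnp

logger = logging.getLogger(__name__)


@dataclass
class SpeciesDiseaseProfile:
    species: str
    diseases: set[str]
    snp_count: int
    genes: set[str]
    category_counts: dict[str, int]
    category_pct: dict[str, float]


@dataclass
class SpecificityReport:
    conserved_diseases: set[str]
    specific_diseases: dict[str, set[str]]  # species -> diseases only there
    pattern_counts: pd.Series  # '01' membership pattern -> n diseases
    species: tuple[str, ...]
    gene_lists: dict[str, set[str]]  # disease -> supporting genes


def annotate(
    mapped: Sequence[MappedSnp],
    associations: pd.DataFrame,
    categories: Sequence[str],
) -> pd.DataFrame:
    """Per-species SNP-disease records for identified SNPs.

    One record per (species, rsid, disease, category, gene) where the SNP is
    identified in that species.  Association rows whose rsID is not among the
    mapped SNPs are ignored (counted in the log).
    """
    cat_set = set(categories)
    bad = set(associations["category"]) - cat_set
    if bad:
        raise ValueError(f"categories not among the configured 24: {sorted(bad)}")
    by_rsid: dict[str, MappedSnp] = {m.rsid: m for m in mapped if m.rsid}
    unknown = 0
    rows = []
    for assoc in associations.itertuples(index=False):
        snp = by_rsid.get(assoc.rsid)
        if snp is None:
            unknown += 1
            continue
        for sp, identified in snp.match_flags.items():
            if identified:
                rows.append(
                    {
                        "species": sp,
                        "rsid": assoc.rsid,
                        "disease": str(assoc.disease).casefold(),
                        "category": assoc.category,
                        "gene": assoc.gene,
                        "chrom": snp.chrom,
                    }
                )
    if unknown:
        logger.info("%d association rows had rsIDs not among mapped SNPs", unknown)
    return pd.DataFrame(
        rows, columns=["species", "rsid", "disease", "category", "gene", "chrom"]
    )


def specificity(disease_sets: Mapping[str, set[str]]) -> SpecificityReport:
    """Conserved (all-five) and species-specific (exactly-one) disease sets,
    plus full upset-style membership pattern counts."""
    species = tuple(sorted(disease_sets))
    universe = sorted(set().union(*disease_sets.values())) if disease_sets else []
    patterns: dict[str, str] = {}
    for d in universe:
        patterns[d] = "".join("1" if d in disease_sets[sp] else "0" for sp in species)
    all_ones = "1" * len(species)
    conserved = {d for d, p in patterns.items() if p == all_ones}
    specific: dict[str, set[str]] = {sp: set() for sp in species}
    for d, p in patterns.items():
        if p.count("1") == 1:
            specific[species[p.index("1")]].add(d)
    counts = pd.Series(list(patterns.values())).value_counts().sort_index()
    return SpecificityReport(
        conserved_diseases=conserved,
        specific_diseases=specific,
        pattern_counts=counts,
        species=species,
        gene_lists={},
    )


def category_profile(
    records: pd.DataFrame,
    categories: Sequence[str],
    per_disease: bool = True,
) -> tuple[dict[str, SpeciesDiseaseProfile], dict[str, tuple[str, ...]]]:
    """Per-species 24-category percentage profiles and the cross-species
    maximum marker per category (all tied species flagged).

    Percentages are over unique diseases by default; ``per_disease=False``
    counts (rsid, disease) pairs instead.
    """
    profiles: dict[str, SpeciesDiseaseProfile] = {}
    for sp, grp in records.groupby("species"):
        dedup = grp.drop_duplicates(["disease"]) if per_disease else grp.drop_duplicates(
            ["rsid", "disease"]
        )
        total = len(dedup)
        counts = {c: 0 for c in categories}
        for cat, n in dedup["category"].value_counts().items():
            counts[cat] = int(n)
        if total == 0:
            logger.warning("species %s has an empty disease set", sp)
            pct = {c: 0.0 for c in categories}
        else:
            pct = {c: 100.0 * counts[c] / total for c in categories}
        profiles[sp] = SpeciesDiseaseProfile(
            species=sp,
            diseases=set(grp["disease"]),
            snp_count=grp["rsid"].nunique(),
            genes=set(grp["gene"]),
            category_counts=counts,
            category_pct=pct,
        )
    max_markers: dict[str, tuple[str, ...]] = {}
    for c in categories:
        vals = {sp: p.category_pct[c] for sp, p in profiles.items()}
        if not vals:
            continue
        top = max(vals.values())
        max_markers[c] = tuple(sorted(sp for sp, v in vals.items() if v == top))
    return profiles, max_markers


def gene_summaries(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, set[str], pd.DataFrame]:
    """Per-gene unique-disease counts, genes common to all species, and the
    top disease-associated gene per human chromosome per species.

    Argmax ties break on higher count then alphabetical gene symbol.
    """
    dedup = records.drop_duplicates(["species", "gene", "disease"])
    per_gene = (
        dedup.groupby(["species", "gene"])
        .agg(n_diseases=("disease", "nunique"), chrom=("chrom", "first"))
        .reset_index()
    )
    n_species = records["species"].nunique()
    gene_species = per_gene.groupby("gene")["species"].nunique()
    common = set(gene_species[gene_species == n_species].index) if n_species else set()
    top_rows = []
    for (sp, chrom), grp in per_gene.groupby(["species", "chrom"]):
        ranked = grp.sort_values(["n_diseases", "gene"], ascending=[False, True])
        best = ranked.iloc[0]
        top_rows.append(
            {"species": sp, "chrom": chrom, "gene": best["gene"],
             "n_diseases": int(best["n_diseases"])}
        )
    return per_gene, common, pd.DataFrame(top_rows)


def disease_sets_from_records(
    records: pd.DataFrame, species: Sequence[str] | None = None
) -> dict[str, set[str]]:
    """Disease-name set per species.  ``species`` fixes the universe of sets
    so that a species with zero records still contributes an empty set (and
    thus correctly empties the all-species intersection)."""
    if species is None:
        from .trees import SPECIES

        species = [sp for sp in SPECIES if sp != "human"]
    sets: dict[str, set[str]] = {sp: set() for sp in species}
    for sp, grp in records.groupby("species"):
        sets.setdefault(sp, set()).update(grp["disease"])
    return sets


def profiles_to_frame(
    profiles: Mapping[str, SpeciesDiseaseProfile], categories: Iterable[str]
) -> pd.DataFrame:
    rows = []
    for c in categories:
        row: dict[str, object] = {"category": c}
        for sp, p in profiles.items():
            row[f"pct_{sp}"] = p.category_pct[c]
        rows.append(row)
    return pd.DataFrame(rows)
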