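"""Synthetic six-species orthologous CDS sets with planted SNP/disease catalogs.

An ancestral CDS is drawn uniformly over {A,C,G,T} and evolved independently
down a species tree under a Jukes-Cantor substitution model: on a branch of
length ``d`` (expected substitutions per site) each site mutates with
probability ``p = 3/4 * (1 - exp(-4d/3))``, the substituted base chosen
uniformly among the three alternatives.  Optional indels are Poisson events
along each branch, by default in multiples of three so the coding frame stays
plausible.  Every lineage keeps a per-site map back to ancestral coordinates,
which is what lets the generator emit exact truth labels for planted SNPs:
a species "carries" a planted human SNP's major allele iff its base at the
site descending from the same ancestral site equals the human base.

Truth tables produced here are the oracle for the whole downstream pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CodingSequence, SnpCatalog, SnpRecord
from .trees import SPECIES, SpeciesTree

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: 24 disease categories in the DisGeNET/MeSH style.
DEFAULT_CATEGORIES = (
    "Bacterial Infections and Mycoses",
    "Behavioral Disciplines and Activities",
    "Cancer",
    "Cardiovascular Diseases",
    "Congenital, Hereditary, and Neonatal Diseases and Abnormalities",
    "Digestive System Diseases",
    "Endocrine System Diseases",
    "Eye Diseases",
    "Female Urogenital Diseases and Pregnancy Complications",
    "Hemic and Lymphatic Diseases",
    "Immune System Diseases",
    "Male Urogenital Diseases",
    "Mental Disorders",
    "Musculoskeletal Diseases",
    "Nervous System Diseases",
    "Nutritional and Metabolic Diseases",
    "Occupational Diseases",
    "Otorhinolaryngologic Diseases",
    "Pathological Conditions, Signs and Symptoms",
    "Respiratory Tract Diseases",
    "Skin and Connective Tissue Diseases",
    "Stomatognathic Diseases",
    "Virus Diseases",
    "Wounds and Injuries",
)


@dataclass
class SimulationConfig:
    """Knobs for the synthetic dataset.

    Defaults describe the desk-scale study condition: 100 orthologous CDS
    groups of 300-900 nt, indel-free evolution, 500 planted catalog SNPs,
    and 40 distinct diseases spread over the 24 fixed categories.
    """

    n_cds: int = 100
    cds_length_range: tuple[int, int] = (300, 900)
    indel_rate: float = 0.0  # events per site per unit branch length
    indel_frame_preserving: bool = True
    n_snps: int = 500
    minor_allele_freq_range: tuple[float, float] = (0.05, 0.5)
    n_diseases: int = 40
    n_categories: int = 24
    chromosomes: tuple[str, ...] = ("1", "2", "3", "4", "5", "X")
    synteny_scramble: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cds < 1:
            raise ValueError("n_cds must be >= 1")
        lo, hi = self.cds_length_range
        if lo % 3 or hi % 3 or lo < 3 or hi < lo:
            raise ValueError("cds_length_range must be multiples of 3, lo <= hi")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        flo, fhi = self.minor_allele_freq_range
        if not (0 < flo <= fhi <= 0.5):
            raise ValueError("minor_allele_freq_range must lie in (0, 0.5]")
        if self.n_categories != 24:
            raise ValueError("n_categories is fixed at 24")


@dataclass
class SyntheticDataset:
    """Everything the generator knows, including the truth tables."""

    cds_sets: dict[str, list[CodingSequence]]
    ortholog_truth: pd.DataFrame  # human_cds_id, species, species_cds_id, gene
    site_maps: dict[str, list[np.ndarray]] = field(repr=False, default_factory=dict)
    catalog: SnpCatalog | None = None
    snp_truth: pd.DataFrame | None = None  # rsid, cds, pos, per-species flags
    associations: pd.DataFrame | None = None

    def human_cds(self) -> list[CodingSequence]:
        return self.cds_sets["human"]


def jc_substitution_probability(branch_length: float) -> float:
    """Expected proportion of differing sites after Jukes-Cantor evolution."""
    return 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))


def _evolve_branch(
    seq: np.ndarray,
    site_map: np.ndarray,
    branch_length: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    seq = seq.copy()
    p = jc_substitution_probability(branch_length)
    if p > 0:
        hit = rng.random(seq.size) < p
        n_hit = int(hit.sum())
        if n_hit:
            seq[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
    site_map = site_map.copy()
    if config.indel_rate > 0 and branch_length > 0:
        n_events = rng.poisson(config.indel_rate * branch_length * seq.size)
        for _ in range(n_events):
            unit = 3 if config.indel_frame_preserving else 1
            length = unit * int(rng.geometric(0.5))
            if rng.random() < 0.5:  # insertion
                at = int(rng.integers(0, seq.size + 1))
                ins = rng.integers(0, 4, size=length)
                seq = np.concatenate([seq[:at], ins, seq[at:]])
                site_map = np.concatenate(
                    [site_map[:at], np.full(length, -1, dtype=np.int64), site_map[at:]]
                )
            else:  # deletion
                if length >= seq.size:
                    logger.warning(
                        "deletion of %d would empty a %d nt CDS; event resampled",
                        length,
                        seq.size,
                    )
                    continue
                at = int(rng.integers(0, seq.size - length + 1))
                seq = np.concatenate([seq[:at], seq[at + length :]])
                site_map = np.concatenate([site_map[:at], site_map[at + length :]])
    return seq, site_map


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def _random_exons(
    length: int, cursor: int, rng: np.random.Generator
) -> tuple[tuple[tuple[int, int], ...], int]:
    """Split ``length`` CDS bases into 1-5 exons starting at genome ``cursor``."""
    n_exons = int(rng.integers(1, 6))
    n_exons = min(n_exons, length)
    if n_exons > 1:
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False))
        widths = np.diff(np.concatenate([[0], cuts, [length]]))
    else:
        widths = np.array([length])
    exons = []
    pos = cursor
    for w in widths:
        exons.append((pos, pos + int(w) - 1))
        pos += int(w) + int(rng.integers(50, 501))  # intron gap
    return tuple(exons), pos + 1000


def evolve_orthologs(
    config: SimulationConfig, tree: SpeciesTree | None = None
) -> SyntheticDataset:
    """Evolve ``config.n_cds`` ancestral CDSs down the species tree.

    Returns per-species CDS sets plus a truth table of ortholog pairings and
    the per-lineage ancestral site maps used later for planted-SNP truth.
    """
    if tree is None:
        tree = SpeciesTree.default()
    taxa = tree.taxa()
    if len(taxa) != 6:
        raise ValueError(f"species tree must have six leaves, got {len(taxa)}")
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.cds_length_range

    # per-species chromosome relabelling of the human chromosome set
    chrom_maps: dict[str, dict[str, str]] = {}
    for sp in taxa:
        if sp == "human":
            continue
        perm = rng.permutation(len(config.chromosomes))
        chrom_maps[sp] = {
            config.chromosomes[i]: config.chromosomes[perm[i]]
            for i in range(len(config.chromosomes))
        }

    cds_sets: dict[str, list[CodingSequence]] = {sp: [] for sp in taxa}
    site_maps: dict[str, list[np.ndarray]] = {sp: [] for sp in taxa}
    truth_rows = []
    human_cursors = {c: 1000 for c in config.chromosomes}
    species_cursors = {sp: {c: 1000 for c in config.chromosomes} for sp in taxa}

    for idx in range(config.n_cds):
        n_codons = rng.integers(lo // 3, hi // 3 + 1)
        length = int(n_codons) * 3
        root_seq = rng.integers(0, 4, size=length)
        root_map = np.arange(length, dtype=np.int64)

        # evolve down the tree, depth-first in dendropy's deterministic order
        leaf_results: dict[str, tuple[np.ndarray, np.ndarray]] = {}

        def _descend(node, seq, smap):
            for child in node.child_nodes():
                bl = child.edge.length or 0.0
                cseq, cmap = _evolve_branch(seq, smap, bl, config, rng)
                if child.is_leaf():
                    leaf_results[child.taxon.label] = (cseq, cmap)
                else:
                    _descend(child, cseq, cmap)

        _descend(tree.tree.seed_node, root_seq, root_map)

        gene = f"GENE{idx:04d}"
        human_chrom = config.chromosomes[idx % len(config.chromosomes)]
        strand = "+" if rng.random() < 0.5 else "-"
        for sp in taxa:
            seq, smap = leaf_results[sp]
            cds_id = f"{sp}_cds_{idx:04d}"
            if sp == "human":
                chrom = human_chrom
                exons, human_cursors[chrom] = _random_exons(
                    seq.size, human_cursors[chrom], rng
                )
                sp_strand = strand
            else:
                chrom = chrom_maps[sp][human_chrom]
                if rng.random() < config.synteny_scramble:
                    chrom = config.chromosomes[rng.integers(len(config.chromosomes))]
                cur = species_cursors[sp][chrom]
                exons = ((cur, cur + seq.size - 1),)
                species_cursors[sp][chrom] = cur + seq.size + 1000
                sp_strand = "+"
            cds_sets[sp].append(
                CodingSequence(
                    cds_id=cds_id,
                    gene=gene,
                    species=sp,
                    chromosome=chrom,
                    strand=sp_strand,
                    exons=exons,
                    sequence=_decode(seq),
                )
            )
            site_maps[sp].append(smap)
            if sp != "human":
                truth_rows.append(
                    {
                        "human_cds_id": f"human_cds_{idx:04d}",
                        "species": sp,
                        "species_cds_id": cds_id,
                        "gene": gene,
                    }
                )

    return SyntheticDataset(
        cds_sets=cds_sets,
        ortholog_truth=pd.DataFrame(truth_rows),
        site_maps=site_maps,
    )


def plant_snp_catalog(
    dataset: SyntheticDataset, config: SimulationConfig
) -> tuple[SnpCatalog, pd.DataFrame]:
    """Sample human CDS positions as catalog SNPs, with per-species truth.

    The major allele is defined as the human reference base at the sampled
    position.  The truth table records, for each planted SNP, whether each
    non-human species carries that base at the orthologous (ancestrally
    homologous) site.
    """
    rng = np.random.default_rng([config.seed, 1])
    human = dataset.cds_sets["human"]
    lengths = np.array([len(c) for c in human])
    total = int(lengths.sum())
    if config.n_snps > total:
        raise ValueError(
            f"requested {config.n_snps} SNPs but only {total} CDS positions exist"
        )
    if config.n_snps == 0:
        return SnpCatalog([]), pd.DataFrame(
            columns=["rsid", "human_cds_id", "cds_pos", "chrom", "pos", "maf"]
            + [f"identified_{sp}" for sp in SPECIES if sp != "human"]
        )
    flat = np.sort(rng.choice(total, size=config.n_snps, replace=False))
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    cds_idx = np.searchsorted(bounds, flat, side="right") - 1
    cds_pos = flat - bounds[cds_idx] + 1  # 1-based

    # orthologous-site lookup: root index -> species position, per CDS
    species = [sp for sp in SPECIES if sp != "human"]
    records = []
    truth_rows = []
    flo, fhi = config.minor_allele_freq_range
    base_order = "ACGT"
    for i in range(config.n_snps):
        ci = int(cds_idx[i])
        k = int(cds_pos[i])
        cds = human[ci]
        major = cds.sequence[k - 1]
        others = [b for b in base_order if b != major]
        n_minor = int(rng.integers(1, 3))
        minors = tuple(
            others[j] for j in sorted(rng.choice(3, size=n_minor, replace=False))
        )
        chrom, gpos = cds.genome_position(k)
        rsid = f"rs{i + 1}"
        records.append(SnpRecord(rsid, chrom, gpos, major, minors))
        root_idx = int(dataset.site_maps["human"][ci][k - 1])
        row = {
            "rsid": rsid,
            "human_cds_id": cds.cds_id,
            "cds_pos": k,
            "chrom": chrom,
            "pos": gpos,
            "maf": float(rng.uniform(flo, fhi)),
        }
        for sp in species:
            identified = False
            if root_idx >= 0:
                smap = dataset.site_maps[sp][ci]
                hits = np.nonzero(smap == root_idx)[0]
                if hits.size:
                    sp_base = dataset.cds_sets[sp][ci].sequence[int(hits[0])]
                    identified = sp_base == major
            row[f"identified_{sp}"] = identified
        truth_rows.append(row)
    catalog = SnpCatalog(records)
    truth = pd.DataFrame(truth_rows)
    dataset.catalog = catalog
    dataset.snp_truth = truth
    return catalog, truth


def make_disease_table(
    catalog: SnpCatalog,
    snp_truth: pd.DataFrame,
    config: SimulationConfig,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
) -> pd.DataFrame:
    """Link planted rsIDs to synthetic diseases, categories, and genes.

    Each disease gets exactly one of the 24 categories and one gene symbol;
    a disease is supported by one to three SNPs from that gene.
    """
    if len(categories) != 24:
        raise ValueError("exactly 24 categories required")
    if config.n_diseases == 0 or len(catalog) == 0:
        return pd.DataFrame(columns=["rsid", "disease", "category", "gene"])
    rng = np.random.default_rng([config.seed, 2])
    truth = snp_truth.copy()
    truth["gene"] = truth["human_cds_id"].str.replace(
        r"human_cds_(\d+)", lambda m: f"GENE{m.group(1)}", regex=True
    )
    by_gene = truth.groupby("gene")["rsid"].apply(list)
    genes = list(by_gene.index)
    rows = []
    for i in range(config.n_diseases):
        disease = f"disease {i:03d}"
        category = categories[int(rng.integers(24))]
        gene = genes[int(rng.integers(len(genes)))]
        rsids = by_gene[gene]
        n_links = int(rng.integers(1, min(3, len(rsids)) + 1))
        chosen = rng.choice(len(rsids), size=n_links, replace=False)
        for j in sorted(chosen):
            rows.append(
                {"rsid": rsids[int(j)], "disease": disease,
                 "category": category, "gene": gene}
            )
    return pd.DataFrame(rows)


def simulate_dataset(
    config: SimulationConfig, tree: SpeciesTree | None = None
) -> SyntheticDataset:
    """Run the full generator: orthologs, SNP catalog, disease table."""
    dataset = evolve_orthologs(config, tree)
    catalog, truth = plant_snp_catalog(dataset, config)
    dataset.associations = make_disease_table(catalog, truth, config)
    return dataset
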