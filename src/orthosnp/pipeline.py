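"""End-to-end orchestration with file-based stages and a hashed manifest.

Stages communicate only through files under the output directory, so any
stage can be re-run from cached inputs and produce bit-identical outputs.
The manifest records every written file with its SHA-256 digest plus an echo
of the configuration, which makes whole-run determinism checkable by
comparing manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .conservation import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_IDENTITY,
    ScoringParams,
    all_best_hits,
    build_conserved_set,
    compare_identity_groups,
    filter_hits,
    hits_to_frame,
    identity_stats,
    PairwiseHit,
)
from .core import (
    CodingSequence,
    index_by_id,
    read_associations,
    read_cds_set,
    read_snp_catalog,
    write_cds_set,
    write_snp_catalog,
)
from .disease import (
    annotate,
    category_profile,
    disease_sets_from_records,
    gene_summaries,
    profiles_to_frame,
    specificity,
)
from .msa import MappedSnp, MsaBlock, align_group, mapped_snps_to_frame, match_catalog
from .phylo import (
    concatenate,
    distance_matrix_to_frame,
    distances,
    neighbor_joining,
    synteny_map,
)
from .simulate import DEFAULT_CATEGORIES, SimulationConfig, simulate_dataset
from .trees import SPECIES, SpeciesTree

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "conserve", "msa", "variants", "diseases", "phylo", "synteny")


@dataclass
class PipelineConfig:
    out_dir: Path
    simulation: SimulationConfig | None = None
    input_dir: Path | None = None  # pre-existing FASTA/TSV inputs
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE
    seed_word: int | None = None
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    guide_newick: str | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulation is None and self.input_dir is None:
            raise ValueError("config needs either a simulation section or input paths")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "cds_length_range" in sim:
                sim["cds_length_range"] = tuple(sim["cds_length_range"])
            if "minor_allele_freq_range" in sim:
                sim["minor_allele_freq_range"] = tuple(sim["minor_allele_freq_range"])
            if "chromosomes" in sim:
                sim["chromosomes"] = tuple(sim["chromosomes"])
            sim = SimulationConfig(**sim)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "input_dir" in raw and raw["input_dir"] is not None:
            raw["input_dir"] = Path(raw["input_dir"])
        return cls(simulation=sim, **raw)

    def echo(self) -> dict[str, Any]:
        """Config as a plain dict for the manifest; output paths excluded so
        two runs of the same analysis to different directories compare equal."""
        d: dict[str, Any] = {
            "simulation": dataclasses.asdict(self.simulation)
            if self.simulation
            else None,
            "min_identity": self.min_identity,
            "min_coverage": self.min_coverage,
            "seed_word": self.seed_word,
            "seed": self.seed,
            "stages": list(self.stages),
            "guide_newick": self.guide_newick,
        }
        return d

    def guide_tree(self) -> SpeciesTree:
        if self.guide_newick:
            return SpeciesTree.from_newick(self.guide_newick)
        return SpeciesTree.default()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _inputs_dir(cfg: PipelineConfig) -> Path:
    return cfg.input_dir if cfg.input_dir is not None else cfg.out_dir / "inputs"


def _load_species_sets(cfg: PipelineConfig) -> dict[str, list[CodingSequence]]:
    d = _inputs_dir(cfg)
    return {
        sp: read_cds_set(d / f"{sp}.fasta", d / f"{sp}.meta.tsv") for sp in SPECIES
    }


# --------------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig) -> None:
    if cfg.simulation is None:
        raise ValueError("simulate stage requires a simulation section")
    d = cfg.out_dir / "inputs"
    d.mkdir(parents=True, exist_ok=True)
    dataset = simulate_dataset(cfg.simulation, cfg.guide_tree())
    for sp, cdss in dataset.cds_sets.items():
        write_cds_set(cdss, d / f"{sp}.fasta", d / f"{sp}.meta.tsv")
    write_snp_catalog(dataset.catalog, d / "catalog.tsv")
    dataset.associations.to_csv(d / "associations.tsv", sep="\t", index=False)
    dataset.ortholog_truth.to_csv(d / "truth_orthologs.tsv", sep="\t", index=False)
    dataset.snp_truth.to_csv(d / "truth_snps.tsv", sep="\t", index=False)


def stage_conserve(cfg: PipelineConfig) -> None:
    sets = _load_species_sets(cfg)
    human = sets["human"]
    d = cfg.out_dir / "conservation"
    d.mkdir(parents=True, exist_ok=True)
    filtered: dict[str, list[PairwiseHit]] = {}
    for sp in SPECIES:
        if sp == "human":
            continue
        hits = all_best_hits(sets[sp], human, ScoringParams(), seed_word=cfg.seed_word)
        hits_to_frame(hits).to_csv(d / f"hits_{sp}.tsv", sep="\t", index=False)
        filtered[sp] = filter_hits(hits, cfg.min_identity, cfg.min_coverage)
    conserved = build_conserved_set(filtered, [c.cds_id for c in human])
    membership = conserved.membership.copy()
    membership["pattern"] = membership.apply(
        lambda row: "".join("1" if row[sp] else "0" for sp in conserved.species), axis=1
    )
    membership.to_csv(d / "conserved_set.tsv", sep="\t")
    conserved.pattern_counts.rename("count").to_csv(d / "pattern_counts.tsv", sep="\t")
    # one ortholog per (human CDS, species): the retained best-scoring query
    ortho = conserved.orthologs.drop_duplicates(["human_cds_id", "species"])
    ortho.to_csv(d / "orthologs.tsv", sep="\t", index=False)
    pd.Series(conserved.conserved_ids, name="human_cds_id").to_csv(
        d / "conserved_ids.tsv", sep="\t", index=False
    )
    stats = identity_stats(filtered, conserved.conserved_ids)
    stats.to_csv(d / "identity_stats.tsv", sep="\t", index=False)
    groups = {
        sp: [h.percent_identity for h in hits] for sp, hits in filtered.items()
    }
    if all(len(v) >= 2 for v in groups.values()) and len(groups) >= 2:
        f_stat, p_val, pairwise = compare_identity_groups(groups)
        pairwise.to_csv(d / "identity_anova_pairwise.tsv", sep="\t", index=False)
        (d / "identity_anova.json").write_text(
            json.dumps({"F": f_stat, "p": p_val}, sort_keys=True) + "\n"
        )


def _load_orthologs(cfg: PipelineConfig) -> tuple[pd.DataFrame, list[str]]:
    d = cfg.out_dir / "conservation"
    ortho = pd.read_csv(d / "orthologs.tsv", sep="\t")
    ids = pd.read_csv(d / "conserved_ids.tsv", sep="\t")["human_cds_id"].tolist()
    return ortho, ids


def stage_msa(cfg: PipelineConfig) -> None:
    sets = _load_species_sets(cfg)
    by_id = {sp: index_by_id(sets[sp]) for sp in sets}
    ortho, conserved_ids = _load_orthologs(cfg)
    guide = cfg.guide_tree()
    d = cfg.out_dir / "msa"
    d.mkdir(parents=True, exist_ok=True)
    ortho_idx = ortho.set_index(["human_cds_id", "species"])["species_cds_id"]
    for hid in conserved_ids:
        group = {"human": by_id["human"][hid]}
        for sp in SPECIES:
            if sp == "human":
                continue
            group[sp] = by_id[sp][ortho_idx.loc[(hid, sp)]]
        block = align_group(group, guide)
        with open(d / f"{hid}.afa", "w") as fh:
            for sp in sorted(block.rows):
                fh.write(f">{sp}\n{block.rows[sp]}\n")


def _load_blocks(cfg: PipelineConfig) -> list[MsaBlock]:
    d = cfg.out_dir / "msa"
    blocks = []
    for path in sorted(d.glob("*.afa")):
        rows: dict[str, str] = {}
        name = None
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                name = line[1:].strip()
                rows[name] = ""
            elif name:
                rows[name] += line.strip()
        blocks.append(MsaBlock(human_cds_id=path.stem, rows=rows))
    return blocks


def stage_variants(cfg: PipelineConfig) -> None:
    sets = _load_species_sets(cfg)
    human_by_id = index_by_id(sets["human"])
    catalog = read_snp_catalog(_inputs_dir(cfg) / "catalog.tsv")
    blocks = _load_blocks(cfg)
    d = cfg.out_dir / "variants"
    d.mkdir(parents=True, exist_ok=True)
    mapped, counts, excluded = match_catalog(blocks, human_by_id, catalog)
    mapped_snps_to_frame(mapped).to_csv(d / "mapped_snps.tsv", sep="\t", index=False)
    (d / "identified_counts.json").write_text(
        json.dumps(dict(sorted(counts.items())), sort_keys=True) + "\n"
    )
    pd.DataFrame(excluded, columns=["chrom", "pos"]).to_csv(
        d / "excluded_loci.tsv", sep="\t", index=False
    )


def _load_mapped(cfg: PipelineConfig) -> list[MappedSnp]:
    df = pd.read_csv(
        cfg.out_dir / "variants" / "mapped_snps.tsv", sep="\t", dtype={"chrom": str}
    )
    species = [c.removeprefix("allele_") for c in df.columns if c.startswith("allele_")]
    out = []
    for row in df.itertuples(index=False):
        rd = row._asdict()
        out.append(
            MappedSnp(
                rsid=rd["rsid"],
                human_cds_id=rd["human_cds_id"],
                column=int(rd["column"]),
                cds_pos=int(rd["cds_pos"]),
                chrom=str(rd["chrom"]),
                pos=int(rd["pos"]),
                major_allele=rd["major_allele"],
                alleles={sp: rd[f"allele_{sp}"] for sp in species},
                match_flags={sp: bool(rd[f"match_{sp}"]) for sp in species},
            )
        )
    return out


def stage_diseases(cfg: PipelineConfig) -> None:
    mapped = _load_mapped(cfg)
    associations = read_associations(_inputs_dir(cfg) / "associations.tsv")
    d = cfg.out_dir / "diseases"
    d.mkdir(parents=True, exist_ok=True)
    records = annotate(mapped, associations, DEFAULT_CATEGORIES)
    records.to_csv(d / "records.tsv", sep="\t", index=False)
    report = specificity(disease_sets_from_records(records))
    spec_rows = [
        {"disease": dz, "class": "conserved", "species": ""}
        for dz in sorted(report.conserved_diseases)
    ]
    for sp in report.species:
        spec_rows.extend(
            {"disease": dz, "class": "specific", "species": sp}
            for dz in sorted(report.specific_diseases[sp])
        )
    pd.DataFrame(spec_rows, columns=["disease", "class", "species"]).to_csv(
        d / "specificity.tsv", sep="\t", index=False
    )
    report.pattern_counts.rename("count").to_csv(d / "disease_patterns.tsv", sep="\t")
    profiles, markers = category_profile(records, DEFAULT_CATEGORIES)
    prof_df = profiles_to_frame(profiles, DEFAULT_CATEGORIES)
    prof_df["max_species"] = [",".join(markers[c]) for c in DEFAULT_CATEGORIES]
    prof_df.to_csv(d / "category_profiles.tsv", sep="\t", index=False)
    per_gene, common, top = gene_summaries(records)
    per_gene.to_csv(d / "gene_counts.tsv", sep="\t", index=False)
    pd.Series(sorted(common), name="gene").to_csv(
        d / "common_genes.tsv", sep="\t", index=False
    )
    top.to_csv(d / "top_gene_per_chromosome.tsv", sep="\t", index=False)


def stage_phylo(cfg: PipelineConfig) -> None:
    sets = _load_species_sets(cfg)
    human_by_id = index_by_id(sets["human"])
    blocks = _load_blocks(cfg)
    d = cfg.out_dir / "phylo"
    d.mkdir(parents=True, exist_ok=True)
    sm = concatenate(blocks, human_by_id)
    dm = distances(sm, model="jc")
    distance_matrix_to_frame(dm).to_csv(d / "distances.tsv", sep="\t")
    newick = neighbor_joining(dm)
    (d / "tree.nwk").write_text(newick + "\n")


def stage_synteny(cfg: PipelineConfig) -> None:
    sets = _load_species_sets(cfg)
    human_by_id = index_by_id(sets["human"])
    species_by_id = {
        c.cds_id: c for sp in SPECIES if sp != "human" for c in sets[sp]
    }
    ortho, conserved_ids = _load_orthologs(cfg)
    d = cfg.out_dir / "synteny"
    d.mkdir(parents=True, exist_ok=True)
    table = synteny_map(ortho, human_by_id, species_by_id, conserved_ids)
    table.to_csv(d / "synteny.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "conserve": stage_conserve,
    "msa": stage_msa,
    "variants": stage_variants,
    "diseases": stage_diseases,
    "phylo": stage_phylo,
    "synteny": stage_synteny,
}


def run(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute enabled stages in order; write and return the manifest."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.1fs", stage, timings[stage])
    files = {}
    for path in sorted(cfg.out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            files[str(path.relative_to(cfg.out_dir))] = _sha256(path)
    manifest = {
        "version": __version__,
        "config": cfg.echo(),
        "stages_run": [s for s in ALL_STAGES if s in cfg.stages],
        "files": files,
    }
    (cfg.out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
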