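from __future__ import annotations

import numpy as np
import pytest

from orthosnp.core import CodingSequence
from orthosnp.pipeline import PipelineConfig, run
from orthosnp.simulate import SimulationConfig


def make_cds(
    sequence: str,
    cds_id: str = "cds1",
    species: str = "human",
    gene: str = "GENE",
    chromosome: str = "1",
    strand: str = "+",
    exons: tuple[tuple[int, int], ...] | None = None,
) -> CodingSequence:
    if exons is None:
        exons = ((1, len(sequence)),)
    return CodingSequence(
        cds_id=cds_id,
        gene=gene,
        species=species,
        chromosome=chromosome,
        strand=strand,
        exons=exons,
        sequence=sequence,
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic study condition
    (100 CDSs of 300-900 nt, indel-free, 500 planted SNPs, seed 7)."""
    out = tmp_path_factory.mktemp("pipeline_default")
    cfg = PipelineConfig(
        out_dir=out, simulation=SimulationConfig(seed=7), seed=7
    )
    manifest = run(cfg)
    return cfg, manifest
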