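import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthosnp.core import SnpCatalog, SnpRecord
from orthosnp.msa import (
    MsaBlock,
    align_group,
    cds_to_genome,
    column_for_cds_pos,
    extract_variant_columns,
    match_catalog,
    project_column,
)
from orthosnp.simulate import SimulationConfig, evolve_orthologs, plant_snp_catalog
from orthosnp.trees import SPECIES, SpeciesTree

from .conftest import make_cds

OTHERS = ("macaque", "marmoset", "mouse", "pig", "rat")


def _group(seqs: dict[str, str]):
    return {
        sp: make_cds(seq, cds_id=f"{sp}_1", species=sp) for sp, seq in seqs.items()
    }


def _block(rows: dict[str, str], hid="human_1") -> MsaBlock:
    return MsaBlock(human_cds_id=hid, rows=rows)


def test_identical_sequences_align_gap_free():
    seq = "ACGTACGTACGT"
    block = align_group(_group({sp: seq for sp in SPECIES}))
    assert block.n_columns == len(seq)
    assert all(row == seq for row in block.rows.values())


def test_single_deletion_produces_one_gap():
    seqs = {sp: "ACGT" for sp in SPECIES}
    seqs["rat"] = "ACT"
    block = align_group(_group(seqs))
    assert block.n_columns == 4
    assert block.rows["rat"].count("-") == 1
    assert block.rows["rat"].replace("-", "") == "ACT"
    for sp in SPECIES:
        if sp != "rat":
            assert block.rows[sp] == "ACGT"


def test_degapping_any_row_reproduces_input():
    cfg = SimulationConfig(
        n_cds=6, cds_length_range=(120, 240), indel_rate=0.15, seed=17, n_snps=0
    )
    ds = evolve_orthologs(cfg)
    for i in range(cfg.n_cds):
        group = {sp: ds.cds_sets[sp][i] for sp in SPECIES}
        block = align_group(group)
        for sp in SPECIES:
            assert block.degapped(sp) == group[sp].sequence


def test_variant_columns_match_simulator_truth_substitutions():
    """Indel-free groups: differing columns are exactly the substituted sites."""
    cfg = SimulationConfig(n_cds=10, cds_length_range=(120, 300), seed=19, n_snps=0)
    ds = evolve_orthologs(cfg)
    for i in range(cfg.n_cds):
        group = {sp: ds.cds_sets[sp][i] for sp in SPECIES}
        block = align_group(group)
        human = group["human"].sequence
        truth_cols = {
            k + 1
            for k in range(len(human))
            for sp in OTHERS
            if group[sp].sequence[k] != human[k]
        }
        got = {v.column for v in extract_variant_columns(block)}
        assert got == truth_cols


def test_variant_column_rules():
    rows = {"human": "ACGT", **{sp: "ACGT" for sp in OTHERS}}
    assert extract_variant_columns(_block(rows)) == []
    rows = dict(rows)
    rows["mouse"] = "GCGT"
    rows["rat"] = "-CGT"
    cols = extract_variant_columns(_block(rows))
    assert len(cols) == 1 and cols[0].column == 1
    assert cols[0].differing == ("mouse", "rat")
    # human-gapped columns are skipped entirely
    rows = {"human": "A-GT", **{sp: "ACGT" for sp in OTHERS}}
    cols = extract_variant_columns(_block(rows))
    assert [c.column for c in cols] == []


def test_variant_columns_invariant_to_row_order():
    rng = np.random.default_rng(5)
    rows = {
        sp: "".join(rng.choice(list("ACGT-"), size=30))
        for sp in ("human", *OTHERS)
    }
    rows["human"] = rows["human"].replace("-", "A")
    a = extract_variant_columns(_block(rows))
    b = extract_variant_columns(_block(dict(reversed(list(rows.items())))))
    assert a == b


def test_project_column_examples_and_round_trip():
    rows = {"human": "AC-GT", **{sp: "ACGGT" for sp in OTHERS}}
    block = _block(rows)
    assert project_column(block, 4) == 3
    with pytest.raises(ValueError, match="gapped"):
        project_column(block, 3)
    gap_free = _block({"human": "ACGT", **{sp: "ACGT" for sp in OTHERS}})
    for k in (1, 2, 3, 4):
        assert project_column(gap_free, k) == k
    for col in (1, 2, 4, 5):
        assert column_for_cds_pos(block, project_column(block, col)) == col


@settings(derandomize=True, max_examples=60)
@given(
    st.text(alphabet="ACGT-", min_size=1, max_size=60).filter(
        lambda s: s.replace("-", "")
    )
)
def test_project_column_round_trip_property(human_row):
    """Column -> CDS position -> column is the identity on non-gap columns."""
    rows = {"human": human_row, **{sp: "A" * len(human_row) for sp in OTHERS}}
    block = _block(rows)
    for col, ch in enumerate(human_row, start=1):
        if ch == "-":
            with pytest.raises(ValueError):
                project_column(block, col)
        else:
            assert column_for_cds_pos(block, project_column(block, col)) == col


def test_cds_to_genome_plus_strand():
    cds = make_cds("AAACCCT", exons=((100, 102), (200, 203)))
    assert cds_to_genome(3, cds) == ("1", 102)
    assert cds_to_genome(4, cds) == ("1", 200)
    with pytest.raises(ValueError):
        cds_to_genome(8, cds)
    with pytest.raises(ValueError):
        cds_to_genome(0, cds)


def test_cds_to_genome_minus_strand_full_enumeration():
    cds = make_cds("AAACCCT", exons=((200, 203), (100, 102)), strand="-")
    # brute force: walk exons in CDS order, descending within each exon
    expected = [203, 202, 201, 200, 102, 101, 100]
    got = [cds_to_genome(k, cds)[1] for k in range(1, 8)]
    assert got == expected
    assert got == cds.genome_positions()


def test_match_catalog_flags_and_gap_rule():
    human = make_cds("ACGT", cds_id="human_1")
    rows = {"human": "ACGT", **{sp: "ACGT" for sp in OTHERS}}
    rows["mouse"] = "AGGT"   # mismatch at column 2
    rows["rat"] = "A-GT"     # gap at column 2: never a match
    catalog = SnpCatalog([SnpRecord("rs1", "1", 2, "C", ("T",))])
    mapped, counts, excluded = match_catalog(
        [_block(rows)], {"human_1": human}, catalog
    )
    assert excluded == []
    assert len(mapped) == 1
    snp = mapped[0]
    assert snp.rsid == "rs1" and snp.cds_pos == 2 and snp.pos == 2
    assert snp.match_flags == {
        "macaque": True, "marmoset": True, "mouse": False, "pig": True, "rat": False
    }
    assert counts == {"macaque": 1, "marmoset": 1, "mouse": 0, "pig": 1, "rat": 0}


def test_match_catalog_excludes_major_allele_mismatch():
    human = make_cds("ACGT", cds_id="human_1")
    rows = {"human": "ACGT", **{sp: "ACGT" for sp in OTHERS}}
    catalog = SnpCatalog([SnpRecord("rs9", "1", 2, "G", ("T",))])  # human has C
    mapped, counts, excluded = match_catalog([_block(rows)], {"human_1": human}, catalog)
    assert mapped == [] and excluded == [("1", 2)]


def test_duplicate_catalog_positions_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        SnpCatalog(
            [SnpRecord("rs1", "1", 2, "C", ("T",)), SnpRecord("rs2", "1", 2, "A", ("G",))]
        )


def test_match_catalog_counts_equal_truth_on_indel_free_data():
    cfg = SimulationConfig(n_cds=12, cds_length_range=(150, 300), n_snps=80, seed=23)
    ds = evolve_orthologs(cfg)
    catalog, truth = plant_snp_catalog(ds, cfg)
    blocks = []
    human_by_id = {}
    for i in range(cfg.n_cds):
        group = {sp: ds.cds_sets[sp][i] for sp in SPECIES}
        blocks.append(align_group(group))
        human_by_id[group["human"].cds_id] = group["human"]
    mapped, counts, excluded = match_catalog(blocks, human_by_id, catalog)
    assert excluded == []
    assert len(mapped) == cfg.n_snps
    for sp in OTHERS:
        assert counts[sp] == int(truth[f"identified_{sp}"].sum())


def test_align_group_missing_taxon_and_bad_prealignment():
    seqs = {sp: "ACGT" for sp in SPECIES if sp != "rat"}
    with pytest.raises(ValueError, match="missing taxa"):
        align_group(_group(seqs))
    full = _group({sp: "ACGT" for sp in SPECIES})
    pre = {sp: "AC-GT" for sp in SPECIES}
    pre["pig"] = "ACGTT"  # same length, de-gaps to the wrong sequence
    with pytest.raises(ValueError, match="de-gap"):
        align_group(full, prealigned=pre)
    pre_ok = {sp: "ACGT" for sp in SPECIES}
    block = align_group(full, prealigned=pre_ok)
    assert block.n_columns == 4
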