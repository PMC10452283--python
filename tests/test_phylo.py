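import math

import dendropy
import numpy as np
import pytest

from orthosnp.msa import MsaBlock
from orthosnp.phylo import (
    DistanceMatrix,
    concatenate,
    distances,
    jc_distance,
    neighbor_joining,
    rf_distance,
    synteny_map,
)
from orthosnp.simulate import SimulationConfig, evolve_orthologs
from orthosnp.trees import SPECIES, SpeciesTree

from .conftest import make_cds

SIX = tuple(SPECIES)


def _block(hid, rows):
    return MsaBlock(human_cds_id=hid, rows=rows)


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree with uniform(0.1, 1) branch lengths; returns its
    newick and the exact additive leaf-to-leaf distance matrix."""
    taxa = [f"T{i}" for i in range(n_taxa)]

    def build(group):
        if len(group) == 1:
            return group[0]
        k = int(rng.integers(1, len(group)))
        left, right = group[:k], group[k:]
        bl, br = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        return f"({build(left)}:{bl:.6f},{build(right)}:{br:.6f})"

    shuffled = [taxa[i] for i in rng.permutation(n_taxa)]
    newick = build(shuffled) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    ns = {t.label: t for t in tree.taxon_namespace}
    labels = tuple(sorted(taxa))
    mat = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                mat[i, j] = pdm.patristic_distance(ns[a], ns[b])
    return newick, DistanceMatrix(labels=labels, matrix=mat, model="p")


# ------------------------------------------------------------ concatenation


def test_concatenate_widths_and_spans():
    rows1 = {sp: "ACGT" for sp in SIX}
    rows2 = {sp: "GGGTTT" for sp in SIX}
    human = {
        "h1": make_cds("ACGT", cds_id="h1", chromosome="1", exons=((10, 13),)),
        "h2": make_cds("GGGTTT", cds_id="h2", chromosome="2", exons=((5, 10),)),
    }
    sm = concatenate([_block("h2", rows2), _block("h1", rows1)], human)
    assert sm.n_columns == 10
    assert sm.block_spans == {"h1": (1, 4), "h2": (5, 10)}
    for b, rows in (("h1", rows1), ("h2", rows2)):
        assert sm.extract_block(b) == rows


def test_concatenate_orders_by_human_chromosome_then_position():
    human = {
        "a": make_cds("AA", cds_id="a", chromosome="X", exons=((1, 2),)),
        "b": make_cds("CC", cds_id="b", chromosome="2", exons=((50, 51),)),
        "c": make_cds("GG", cds_id="c", chromosome="2", exons=((10, 11),)),
        "d": make_cds("TT", cds_id="d", chromosome="10", exons=((1, 2),)),
    }
    blocks = [_block(i, {sp: human[i].sequence for sp in SIX}) for i in human]
    sm = concatenate(blocks, human)
    assert sm.rows["human"] == "GGCCTTAA"  # chr2:10, chr2:50, chr10, chrX


def test_concatenate_single_block_is_identity():
    rows = {sp: "ACGTAC" for sp in SIX}
    human = {"h1": make_cds("ACGTAC", cds_id="h1")}
    sm = concatenate([_block("h1", rows)], human)
    assert sm.rows == rows


def test_concatenate_rejects_missing_species():
    rows_ok = {sp: "ACGT" for sp in SIX}
    rows_bad = {sp: "ACGT" for sp in SIX if sp != "rat"}
    human = {
        "h1": make_cds("ACGT", cds_id="h1"),
        "h2": make_cds("ACGT", cds_id="h2", exons=((100, 103),)),
    }
    with pytest.raises(ValueError, match="mismatch"):
        concatenate([_block("h1", rows_ok), _block("h2", rows_bad)], human)


# --------------------------------------------------------------- distances


def test_identical_rows_give_zero_distance():
    dm = distances({"a": "ACGTACGT", "b": "ACGTACGT"}, model="jc")
    assert dm.get("a", "b") == 0.0


def test_jc_distance_closed_form_at_p_03():
    assert jc_distance(0.3) == pytest.approx(-0.75 * math.log(0.6), abs=1e-9)
    assert jc_distance(0.3) == pytest.approx(0.383119, abs=1e-6)
    rows = {"a": "A" * 10, "b": "C" * 3 + "A" * 7}  # exactly p = 0.3
    dm = distances(rows, model="jc")
    assert dm.get("a", "b") == pytest.approx(0.383119, abs=1e-6)


def test_jc_undefined_beyond_saturation():
    with pytest.raises(ValueError, match="0.75"):
        distances({"a": "AAAA", "b": "CCCC"}, model="jc")


def test_pairwise_deletion_ignores_gapped_sites():
    rows = {"a": "AC-TAC", "b": "ACG-AC", "c": "ACGTAC"}
    dm = distances(rows, model="p")
    assert dm.get("a", "b") == 0.0  # only 4 mutually ungapped, all equal
    assert dm.get("a", "c") == 0.0
    sym = dm.matrix
    assert (sym == sym.T).all() and (np.diag(sym) == 0).all()


def test_supermatrix_distance_is_block_weighted_combination():
    rng = np.random.default_rng(29)
    blocks = []
    human = {}
    per_block = []
    for k in range(4):
        n = int(rng.integers(20, 40))
        rows = {
            sp: "".join(rng.choice(list("ACGT-"), size=n, p=[0.23] * 4 + [0.08]))
            for sp in SIX
        }
        rows["human"] = rows["human"].replace("-", "A")
        hid = f"h{k}"
        seq = rows["human"].replace("-", "")
        human[hid] = make_cds(seq, cds_id=hid, exons=((1 + 1000 * k, 1000 * k + len(seq)),))
        blocks.append(_block(hid, rows))
        arr = {sp: np.frombuffer(rows[sp].encode(), np.uint8) for sp in SIX}
        both = (arr["mouse"] != ord("-")) & (arr["rat"] != ord("-"))
        per_block.append(
            (int((arr["mouse"][both] != arr["rat"][both]).sum()), int(both.sum()))
        )
    sm = concatenate(blocks, human)
    dm = distances(sm, model="p")
    mism = sum(m for m, _ in per_block)
    valid = sum(v for _, v in per_block)
    assert dm.get("mouse", "rat") == pytest.approx(mism / valid)


# ------------------------------------------------------------------ NJ / RF


def test_three_taxa_three_point_formulas():
    labels = ("A", "B", "C")
    mat = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
    nwk = neighbor_joining(DistanceMatrix(labels, mat, "p"))
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    ns = {t.label: t for t in tree.taxon_namespace}
    pdm = tree.phylogenetic_distance_matrix()
    assert pdm.patristic_distance(ns["A"], ns["B"]) == pytest.approx(4)
    assert pdm.patristic_distance(ns["A"], ns["C"]) == pytest.approx(6)
    assert pdm.patristic_distance(ns["B"], ns["C"]) == pytest.approx(8)


def test_four_taxon_additive_matrix_recovers_tree_exactly():
    truth = "((A:1,B:2):1,(C:3,D:4));"
    labels = ("A", "B", "C", "D")
    mat = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )
    nwk = neighbor_joining(DistanceMatrix(labels, mat, "p"))
    assert rf_distance(nwk, truth) == 0
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    ns = {t.label: t for t in tree.taxon_namespace}
    pdm = tree.phylogenetic_distance_matrix()
    for (a, b), d in {("A", "B"): 3, ("A", "C"): 5, ("C", "D"): 7}.items():
        assert pdm.patristic_distance(ns[a], ns[b]) == pytest.approx(d)


def test_nj_recovers_random_additive_trees():
    rng = np.random.default_rng(31)
    for _ in range(10):
        n = int(rng.integers(4, 9))
        truth, dm = random_additive_tree(rng, n)
        assert rf_distance(neighbor_joining(dm), truth) == 0


def test_nj_matches_scikit_bio_on_noisy_matrix():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(37)
    _, dm = random_additive_tree(rng, 7)
    noisy = dm.matrix + rng.uniform(0, 0.05, dm.matrix.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0)
    ours = neighbor_joining(DistanceMatrix(dm.labels, noisy, "p"))
    theirs = str(
        skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=list(dm.labels)))
    )
    assert rf_distance(ours, theirs) == 0


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(("A", "B"), np.zeros((2, 2)), "p"))


def test_rf_distance_basics_and_oracle():
    assert rf_distance("((A,B),(C,D));", "((A,B),(C,D));") == 0
    assert rf_distance("((A,B),(C,D));", "((A,C),(B,D));") == 2
    with pytest.raises(ValueError, match="leaf sets"):
        rf_distance("((A,B),(C,D));", "((A,B),(C,E));")
    # cross-check against dendropy's bipartition-based implementation
    rng = np.random.default_rng(41)
    for _ in range(5):
        t1, _ = random_additive_tree(rng, 8)
        t2, _ = random_additive_tree(rng, 8)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1, schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2, schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert rf_distance(t1, t2) == expected


def test_human_nearest_neighbor_is_macaque_on_default_tree():
    cfg = SimulationConfig(n_cds=20, seed=43, n_snps=0)
    ds = evolve_orthologs(cfg)
    rows = {sp: "".join(c.sequence for c in ds.cds_sets[sp]) for sp in SIX}
    dm = distances(rows, model="jc")
    others = [sp for sp in SIX if sp != "human"]
    nearest = min(others, key=lambda sp: dm.get("human", sp))
    assert nearest == "macaque"
    # and the full ordering matches the designed divergence ranking
    ordered = sorted(others, key=lambda sp: dm.get("human", sp))
    assert ordered == ["macaque", "marmoset", "pig", "mouse", "rat"]


# ----------------------------------------------------------------- synteny


def _ortho_frame(rows):
    import pandas as pd

    return pd.DataFrame(rows, columns=["human_cds_id", "species", "species_cds_id"])


def test_synteny_intact_and_fragmented():
    human = {
        f"h{i}": make_cds("AAA", cds_id=f"h{i}", chromosome="17", exons=((i * 10 + 1, i * 10 + 3),))
        for i in range(4)
    }
    species = {}
    rows = []
    for i in range(4):
        chrom = "16" if i < 3 else "5"  # mouse: 3 CDSs on chr16, 1 on chr5
        species[f"m{i}"] = make_cds(
            "AAA", cds_id=f"m{i}", species="mouse", chromosome=chrom
        )
        rows.append((f"h{i}", "mouse", f"m{i}"))
        species[f"q{i}"] = make_cds(
            "AAA", cds_id=f"q{i}", species="macaque", chromosome="16"
        )
        rows.append((f"h{i}", "macaque", f"q{i}"))
    table = synteny_map(_ortho_frame(rows), human, species, list(human))
    mac = table[table.species == "macaque"].iloc[0]
    assert mac["intact"] and mac["source_chroms"] == "16"
    mouse = table[table.species == "mouse"].iloc[0]
    assert not mouse["intact"]
    assert mouse["source_chroms"] == "16,5" and mouse["source_counts"] == "3,1"


def test_synteny_ordering_matches_bruteforce():
    from orthosnp.core import chrom_sort_key

    from .oracles import synteny_ordering_bruteforce

    rng = np.random.default_rng(47)
    human = {}
    species = {}
    rows = []
    chroms = ["1", "2", "3", "X"]
    for i in range(60):
        hid, sid = f"h{i}", f"s{i}"
        human[hid] = make_cds(
            "AAA", cds_id=hid, chromosome="1", exons=((i * 10 + 1, i * 10 + 3),)
        )
        species[sid] = make_cds(
            "AAA", cds_id=sid, species="pig",
            chromosome=chroms[rng.integers(0, 4)],
        )
        rows.append((hid, "pig", sid))
    table = synteny_map(_ortho_frame(rows), human, species, list(human))
    cell = table.iloc[0]
    expected = synteny_ordering_bruteforce(
        [(hid, species[sid].chromosome) for hid, _, sid in rows], chrom_sort_key
    )
    assert cell["source_chroms"] == ",".join(c for c, _ in expected)
    assert cell["source_counts"] == ",".join(str(n) for _, n in expected)
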