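"""Species tree container and the default six-taxon mammalian topology.

The default tree places the two primates closest to human, the pig in the
middle, and the two rodents outermost, with branch lengths (expected
substitutions per site) ordered so that the human-to-leaf path lengths rank
macaque < marmoset < pig < mouse < rat.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

SPECIES = ("human", "macaque", "marmoset", "pig", "mouse", "rat")

_DEFAULT_NEWICK = (
    "(((human:0.02,(macaque:0.015,marmoset:0.03):0.01):0.02,pig:0.08):0.02,"
    "(mouse:0.10,rat:0.11):0.03);"
)


@dataclass
class SpeciesTree:
    """A rooted tree over six named taxa with non-negative branch lengths."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        st = cls(tree)
        st.validate()
        return st

    @classmethod
    def default(cls, total_depth: float | None = 0.3) -> "SpeciesTree":
        """The default six-species tree, optionally rescaled so that the
        maximum leaf-to-leaf path length equals ``total_depth``."""
        st = cls.from_newick(_DEFAULT_NEWICK)
        if total_depth is not None:
            st = st.scaled_to_depth(total_depth)
        return st

    def validate(self) -> None:
        names = self.taxa()
        if len(names) != len(set(names)):
            raise ValueError("duplicate taxon names")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def max_pairwise_distance(self) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        return max(
            pdm.patristic_distance(a, b)
            for a in self.tree.taxon_namespace
            for b in self.tree.taxon_namespace
        )

    def scaled_to_depth(self, total_depth: float) -> "SpeciesTree":
        current = self.max_pairwise_distance()
        if current == 0:
            raise ValueError("tree has zero depth; cannot rescale")
        factor = total_depth / current
        clone = self.tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return SpeciesTree(clone)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()
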