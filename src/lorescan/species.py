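"""The fixed species tree of the study and derived orderings.

The 13 jawed-vertebrate species sampled around the sturgeon + paddlefish
(Acipenseriformes) focal pair, with accepted relationships: two
chondrichthyans root the tree, four sarcopterygians, bichir, and four
neopterygians bracket the focal clade.  From this topology we derive the
outgroup ranking used to root gene family trees ("most distantly related
sequence relative to sturgeons and paddlefish") and the species-tree node
mapping used by strict reconciliation.
"""

from __future__ import annotations

from typing import FrozenSet, Iterable, Mapping

import dendropy

__all__ = [
    "DEFAULT_SPECIES_TREE_NEWICK",
    "STURGEON",
    "PADDLEFISH",
    "FOCAL_SPECIES",
    "TETRAPODA",
    "TELEOSTEI",
    "CHONDRICHTHYES",
    "SpeciesTree",
]

DEFAULT_SPECIES_TREE_NEWICK = (
    "((GhostShark,WhaleShark),((Coelacanth,(Frog,(Human,Chicken))),"
    "(Bichir,((Paddlefish,Sturgeon),((Zebrafish,Fugu),(SpottedGar,Bowfin))))));"
)

STURGEON = "Sturgeon"
PADDLEFISH = "Paddlefish"
FOCAL_SPECIES = frozenset({STURGEON, PADDLEFISH})

# Widely accepted clades used as positive controls for gene-tree quality.
TETRAPODA = frozenset({"Human", "Chicken", "Frog"})
TELEOSTEI = frozenset({"Zebrafish", "Fugu"})
CHONDRICHTHYES = frozenset({"GhostShark", "WhaleShark"})


class SpeciesTree:
    """A rooted species tree with LCA queries and an outgroup ranking.

    Parameters
    ----------
    newick : rooted Newick string; defaults to the 13-species study tree.
    focal : the sister-species pair whose ohnolog quartets are analysed.
    """

    def __init__(
        self,
        newick: str = DEFAULT_SPECIES_TREE_NEWICK,
        focal: Iterable[str] = FOCAL_SPECIES,
    ):
        self.tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        self.focal: FrozenSet[str] = frozenset(focal)
        self._depth: dict[int, int] = {}
        self._parent: dict[int, dendropy.Node] = {}
        self._cluster: dict[int, frozenset] = {}
        self._leaf: dict[str, dendropy.Node] = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            self._parent[id(node)] = parent
            self._depth[id(node)] = 0 if parent is None else self._depth[id(parent)] + 1
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                name = node.taxon.label
                self._leaf[name] = node
                self._cluster[id(node)] = frozenset({name})
            else:
                self._cluster[id(node)] = frozenset().union(
                    *(self._cluster[id(c)] for c in node.child_nodes())
                )
        self.species: FrozenSet[str] = frozenset(self._leaf)
        missing = self.focal - self.species
        if missing:
            raise ValueError(f"focal species {sorted(missing)} absent from species tree")
        self._focal_mrca = self.lca(self.focal)
        self._rank = {
            sp: self._depth[id(self._lca_nodes(self._leaf[sp], self._focal_mrca))]
            for sp in self.species
        }

    # -- queries ---------------------------------------------------------

    def _lca_nodes(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        da, db = self._depth[id(a)], self._depth[id(b)]
        while da > db:
            a = self._parent[id(a)]
            da -= 1
        while db > da:
            b = self._parent[id(b)]
            db -= 1
        while a is not b:
            a, b = self._parent[id(a)], self._parent[id(b)]
        return a

    def lca(self, species: Iterable[str]) -> dendropy.Node:
        """Species-tree node ancestral to all named species."""
        nodes = []
        for sp in species:
            if sp not in self._leaf:
                raise KeyError(f"unknown species {sp!r}")
            nodes.append(self._leaf[sp])
        if not nodes:
            raise ValueError("empty species set")
        node = nodes[0]
        for other in nodes[1:]:
            node = self._lca_nodes(node, other)
        return node

    def cluster(self, node: dendropy.Node) -> frozenset:
        """Species under a species-tree node."""
        return self._cluster[id(node)]

    def outgroup_rank(self, sp: str) -> int:
        """Divergence rank from the focal clade: 0 = most distantly related.

        The rank is the depth of the LCA of the species with the focal
        clade's ancestor, so chondrichthyans rank before sarcopterygians,
        bichir before neopterygians; focal species themselves rank last.
        """
        if sp not in self._rank:
            raise KeyError(f"unknown species {sp!r}")
        return self._rank[sp]

    def is_focal(self, sp: str) -> bool:
        return sp in self.focal
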