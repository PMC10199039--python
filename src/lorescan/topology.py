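"""Enumeration and classification of ohnolog quartet (and triplet) topologies.

After a whole-genome duplication (WGD) shared by two sister lineages, each
gene family retaining both duplicates ("ohnologs") in both species contains a
four-gene subtree: two sturgeon and two paddlefish sequences.  The rooted
shape of this subtree records whether the ohnolog duplication node predates
the sturgeon-paddlefish speciation (a shared duplication, ``PreSpec``) or
postdates it in each lineage independently (``PostSpec``).  A four-taxon tree
can take 15 rooted shapes: one maps to PostSpec, two to PreSpec, and the
remaining 12 ("Other") are caterpillars one branch move away from a main
topology; we subdivide those into ``PostSpecLike`` and ``PreSpecLike`` by the
species composition of their single cherry, which equals the classification
of their unrooted central split.

Trees here are nested 2-tuples of leaf labels, e.g. ``(("Sa", "Pa"), ("Sb",
"Pb"))``; leaves are plain strings.  Polytomies cannot be represented; a
helper converting from Newick/dendropy (see :mod:`lorescan.treeproc`) reports
them as ``"unresolved"`` instead of forcing a category.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RootedCategory",
    "UnrootedType",
    "QuartetLabels",
    "enumerate_rooted_topologies",
    "classify_rooted_quartet",
    "classify_unrooted_quartet",
    "classify_rooted_triplet",
    "unrooted_split",
    "unroot",
    "reroot_on_each_edge",
    "leaves",
    "canonical",
    "UNROOTED_TYPE_OF",
]

#: Leaf-label convention used across the package: ``"<SpeciesTag>|<gene_id>"``.
LABEL_SEP = "|"


class RootedCategory(str, Enum):
    """Category of a rooted 4-tip ohnolog subtree."""

    PRESPEC = "PreSpec"
    POSTSPEC = "PostSpec"
    PRESPEC_LIKE = "PreSpecLike"
    POSTSPEC_LIKE = "PostSpecLike"


class UnrootedType(str, Enum):
    """Type of an unrooted quartet (or rooted triplet)."""

    PRESPEC_TYPE = "PreSpecType"
    POSTSPEC_TYPE = "PostSpecType"


#: Each rooted category collapses onto one unrooted type when the root is lost.
UNROOTED_TYPE_OF: Mapping[RootedCategory, UnrootedType] = {
    RootedCategory.PRESPEC: UnrootedType.PRESPEC_TYPE,
    RootedCategory.PRESPEC_LIKE: UnrootedType.PRESPEC_TYPE,
    RootedCategory.POSTSPEC: UnrootedType.POSTSPEC_TYPE,
    RootedCategory.POSTSPEC_LIKE: UnrootedType.POSTSPEC_TYPE,
}


@dataclass(frozen=True)
class QuartetLabels:
    """The four gene identifiers of an ohnolog quartet.

    Two genes per species; all identifiers distinct.
    """

    sturgeon_a: str
    sturgeon_b: str
    paddlefish_a: str
    paddlefish_b: str

    def __post_init__(self) -> None:
        ids = [self.sturgeon_a, self.sturgeon_b, self.paddlefish_a, self.paddlefish_b]
        if len(set(ids)) != 4:
            raise ValueError(f"quartet gene identifiers must be distinct, got {ids}")

    @property
    def species_of(self) -> dict[str, str]:
        return {
            self.sturgeon_a: "Sturgeon",
            self.sturgeon_b: "Sturgeon",
            self.paddlefish_a: "Paddlefish",
            self.paddlefish_b: "Paddlefish",
        }


def leaves(tree) -> tuple[str, ...]:
    """All leaf labels of a nested-tuple tree, left-to-right."""
    if isinstance(tree, str):
        return (tree,)
    out: list[str] = []
    for child in tree:
        out.extend(leaves(child))
    return tuple(out)


def canonical(tree):
    """Order-normalised form of a nested-tuple tree (children sorted)."""
    if isinstance(tree, str):
        return tree
    kids = sorted((canonical(c) for c in tree), key=repr)
    return tuple(kids)


def enumerate_rooted_topologies(labels: Sequence[str]) -> list:
    """Every distinct rooted binary leaf-labelled topology on ``labels``.

    Grows trees by stepwise leaf insertion: attaching the k-th leaf onto any
    of the 2k-3 branches (including a new root branch) of each (k-1)-leaf
    tree, which yields the (2n-3)!! rooted shapes exactly once.

    Parameters
    ----------
    labels : distinct leaf names, 2 <= n <= 6.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels to build a rooted topology")
    if len(labels) > 6:
        raise ValueError("enumeration limited to 6 labels (105*9*11 trees)")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be distinct")

    trees = [labels[0]]
    for leaf in labels[1:]:
        trees = [t for tree in trees for t in _insert_everywhere(tree, leaf)]
    # stepwise insertion cannot duplicate shapes, but keep the guarantee explicit
    seen: dict = {}
    for t in trees:
        seen.setdefault(canonical(t), t)
    return list(seen.values())


def _insert_everywhere(tree, leaf: str) -> list:
    """All trees obtained by attaching ``leaf`` onto one branch of ``tree``."""
    out = [(tree, leaf)]  # new root above the old one
    if not isinstance(tree, str):
        a, b = tree
        out.extend((sub, b) for sub in _insert_everywhere(a, leaf))
        out.extend((a, sub) for sub in _insert_everywhere(b, leaf))
    return out


def _species(tree, species_of: Mapping[str, str] | None) -> dict[str, str]:
    if species_of is not None:
        return dict(species_of)
    tags = {}
    for leaf in leaves(tree):
        if LABEL_SEP not in leaf:
            raise ValueError(
                f"leaf {leaf!r} carries no species tag; pass species_of explicitly"
            )
        tags[leaf] = leaf.split(LABEL_SEP, 1)[0]
    return tags


def _check_quartet_species(tags: Mapping[str, str]) -> tuple[str, str]:
    by_species: dict[str, int] = {}
    for sp in tags.values():
        by_species[sp] = by_species.get(sp, 0) + 1
    if sorted(by_species.values()) != [2, 2]:
        raise ValueError(
            f"quartet must hold exactly two leaves of each of two species, got {by_species}"
        )
    sp_a, sp_b = sorted(by_species)
    return sp_a, sp_b


def classify_rooted_quartet(
    tree, species_of: Mapping[str, str] | None = None
) -> RootedCategory:
    """Assign one of the four rooted categories to a 4-tip ohnolog subtree.

    The three balanced shapes split into ``PostSpec`` (two same-species
    cherries) and ``PreSpec`` (two mixed cherries); the twelve caterpillars
    are ``PostSpecLike`` when their single cherry is same-species and
    ``PreSpecLike`` when it is mixed.  Every one of the 15 rooted shapes
    receives exactly one label.

    ``species_of`` maps leaf label to species tag; omitted, tags are parsed
    from ``"Species|gene"`` labels.
    """
    tips = leaves(tree)
    if len(tips) != 4 or len(set(tips)) != 4:
        raise ValueError(f"expected 4 distinct leaves, got {tips}")
    tags = _species(tree, species_of)
    _check_quartet_species({t: tags[t] for t in tips})

    cherries = _cherries(tree)
    if len(cherries) == 2:  # balanced shape
        same = [tags[a] == tags[b] for a, b in cherries]
        if all(same):
            return RootedCategory.POSTSPEC
        if not any(same):
            return RootedCategory.PRESPEC
        raise AssertionError("2+2 composition forbids one mixed + one pure cherry")
    # caterpillar: a unique cherry
    (a, b), = cherries
    if tags[a] == tags[b]:
        return RootedCategory.POSTSPEC_LIKE
    return RootedCategory.PRESPEC_LIKE


def _cherries(tree) -> list[tuple[str, str]]:
    """All internal nodes whose two children are both leaves."""
    if isinstance(tree, str):
        return []
    a, b = tree
    out = []
    if isinstance(a, str) and isinstance(b, str):
        out.append((a, b))
    out.extend(_cherries(a))
    out.extend(_cherries(b))
    return out


def unrooted_split(tree) -> frozenset:
    """Central split of the unrooted quartet underlying a 4-tip tree.

    Returns a frozenset of two frozensets of leaf labels (the 2|2
    bipartition induced by the internal edge).
    """
    tips = set(leaves(tree))
    if len(tips) != 4:
        raise ValueError("unrooted_split requires a 4-tip tree")
    # In a rooted 4-tip tree, the unrooted internal edge separates the leaf
    # pair forming a cherry (balanced: either cherry; caterpillar: the cherry)
    # from the other two.
    pair = _cherries(tree)[0]
    side = frozenset(pair)
    return frozenset({side, frozenset(tips - side)})


def unroot(tree) -> frozenset:
    """Alias for :func:`unrooted_split` (the split fully determines the
    unrooted quartet topology)."""
    return unrooted_split(tree)


def classify_unrooted_quartet(
    split_or_tree, species_of: Mapping[str, str] | None = None
) -> UnrootedType:
    """Type an unrooted quartet by its central split.

    ``Sa Sb | Pa Pb`` is ``PostSpecType``; either mixed split is
    ``PreSpecType``.  Accepts a split (as returned by :func:`unrooted_split`)
    or any rooted 4-tip tree, which is unrooted first.
    """
    if isinstance(split_or_tree, frozenset):
        split = split_or_tree
        tips = [leaf for side in split for leaf in side]
        tags = _species(tuple(tips), species_of) if species_of is None else dict(species_of)
    else:
        split = unrooted_split(split_or_tree)
        tags = _species(split_or_tree, species_of)
    sides = list(split)
    if len(sides) != 2 or any(len(s) != 2 for s in sides):
        raise ValueError("quartet split must bipartition four leaves 2|2")
    _check_quartet_species({leaf: tags[leaf] for side in sides for leaf in side})
    for side in sides:
        a, b = sorted(side)
        if tags[a] != tags[b]:
            return UnrootedType.PRESPEC_TYPE
    return UnrootedType.POSTSPEC_TYPE


def classify_rooted_triplet(
    tree, species_of: Mapping[str, str] | None = None
) -> UnrootedType:
    """Type a rooted 3-tip subtree (two sturgeon genes + one paddlefish).

    When one paddlefish ohnolog is missing (lost, or collapsed in assembly)
    only three rooted shapes exist; the one whose cherry unites the two
    sturgeon copies resembles PostSpec, the other two resemble PreSpec.
    """
    tips = leaves(tree)
    if len(tips) != 3 or len(set(tips)) != 3:
        raise ValueError(f"expected 3 distinct leaves, got {tips}")
    tags = _species(tree, species_of)
    counts: dict[str, int] = {}
    for sp in tags.values():
        counts[sp] = counts.get(sp, 0) + 1
    if sorted(counts.values()) != [1, 2]:
        raise ValueError(
            f"triplet must hold two leaves of one species and one of another, got {counts}"
        )
    (a, b), = _cherries(tree)
    if tags[a] == tags[b]:
        return UnrootedType.POSTSPEC_TYPE
    return UnrootedType.PRESPEC_TYPE


def reroot_on_each_edge(tree) -> list:
    """All rooted 4-tip trees obtained by rerooting the unrooted quartet of
    ``tree`` on each of its 5 edges (4 pendant + 1 internal)."""
    split = unrooted_split(tree)
    side_a, side_b = (sorted(s) for s in split)
    (a1, a2), (b1, b2) = side_a, side_b
    rootings = [
        ((a1, a2), (b1, b2)),  # internal edge
        (a1, (a2, (b1, b2))),  # pendant edges
        (a2, (a1, (b1, b2))),
        (b1, (b2, (a1, a2))),
        (b2, (b1, (a1, a2))),
    ]
    return rootings
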