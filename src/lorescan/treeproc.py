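"""From raw gene family trees to classified ohnolog quartets.

This module implements the tree-level plumbing around the quartet
classification: outgroup rooting, clan (unrooted monophyly) checks, strict
gene-tree/species-tree reconciliation, extraction of the ohnolog quartet
clade from larger orthogroups, family-level exclusion filters, bootstrap
support filtering, fold-deviation statistics against the uniform-topology
null, recovery of control clades, and alignment/tree diagnostics.

Gene trees are dendropy trees whose leaf labels follow the package-wide
``"Species|gene_id"`` convention; internal node labels, when present, are
integer ultrafast-bootstrap (UFBoot) percentages as written by common
maximum-likelihood tree software.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .species import FOCAL_SPECIES, PADDLEFISH, STURGEON, SpeciesTree
from .topology import (
    LABEL_SEP,
    RootedCategory,
    UNROOTED_TYPE_OF,
    classify_rooted_quartet,
    classify_rooted_triplet,
)

__all__ = [
    "GeneFamilyTree",
    "ReconciledTree",
    "FamilyFilterReport",
    "TopologyCall",
    "CategoryCounts",
    "read_gene_tree",
    "parse_leaf_label",
    "root_by_most_distant_outgroup",
    "is_clan",
    "reconcile",
    "extract_phog_quartet",
    "apply_family_filters",
    "quartet_subtree",
    "quartet_supports",
    "support_filter",
    "classify_family",
    "classify_families",
    "tally_categories",
    "fold_deviation",
    "counts_by_cutoff",
    "clade_recovery",
    "alignment_stats",
    "tree_stats",
    "compare_paired_branch_lengths",
    "RANDOM_EXPECTATION",
]

GAP_CHARS = frozenset("-.?")

#: Uniform-topology null: 1 of the 15 rooted quartets is PostSpec, 2 are
#: PreSpec and 12 are 'Other'.
RANDOM_EXPECTATION = {"PostSpec": 1 / 15, "PreSpec": 2 / 15, "Other": 12 / 15}


@dataclass
class GeneFamilyTree:
    """A gene family tree with species-tagged leaves and optional supports."""

    family_id: str
    tree: dendropy.Tree
    rooted: bool = False


@dataclass
class ReconciledTree:
    """A rooted gene tree whose internal nodes carry inferred events.

    ``events`` maps each internal node to ``"speciation"`` or
    ``"duplication"`` (strict rule: duplication iff the two child leaf
    species sets intersect); ``sp_node`` maps it to the species-tree node its
    leaf species coalesce in.
    """

    tree: dendropy.Tree
    events: dict
    sp_node: dict

    def duplication_nodes(self) -> list:
        return [n for n, ev in self.events.items() if ev == "duplication"]


@dataclass
class FamilyFilterReport:
    family_id: str
    reasons: frozenset = frozenset()

    @property
    def passed(self) -> bool:
        return not self.reasons


@dataclass
class TopologyCall:
    """Classification of one family's ohnolog subtree."""

    family_id: str
    rooted_category: str  # RootedCategory value or "unresolved"
    unrooted_type: str | None
    supports: tuple
    missing_support: bool = False

    @property
    def support_min(self) -> int:
        return min((0 if s is None else s) for s in self.supports) if self.supports else 0


@dataclass
class CategoryCounts:
    """Per-category tree counts at one UFBoot cutoff."""

    post_spec: int = 0
    pre_spec: int = 0
    post_spec_like: int = 0
    pre_spec_like: int = 0
    unresolved: int = 0
    cutoff: int = 0

    @property
    def other(self) -> int:
        return self.post_spec_like + self.pre_spec_like

    @property
    def total(self) -> int:
        """Classified trees (the 'unresolved' residue is reported separately)."""
        return self.post_spec + self.pre_spec + self.other


# ---------------------------------------------------------------------------
# parsing / rooting


def parse_leaf_label(label: str) -> tuple[str, str]:
    """Split ``"Species|gene_id"`` into its parts."""
    if LABEL_SEP not in label:
        raise ValueError(f"leaf label {label!r} lacks the 'Species|gene' tag")
    sp, gid = label.split(LABEL_SEP, 1)
    return sp, gid


def read_gene_tree(newick: str, family_id: str = "", rooted: bool = False) -> GeneFamilyTree:
    """Parse a Newick gene tree (supports as internal-node labels)."""
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    # the seed node is treated as the root throughout (even pre-rooting)
    tree.is_rooted = True
    return GeneFamilyTree(family_id=family_id, tree=tree, rooted=rooted)


def _leaf_species(leaf: dendropy.Node) -> str:
    return parse_leaf_label(leaf.taxon.label)[0]


def _support_value(node: dendropy.Node) -> int | None:
    """Integer support from an internal-node label (IQ-TREE dialect);
    ``"95/0.99"``-style joint labels use the first field."""
    if node.label is None or node.label == "":
        return None
    try:
        return int(round(float(str(node.label).split("/")[0])))
    except ValueError:
        return None


def root_by_most_distant_outgroup(
    gft: GeneFamilyTree, sp_tree: SpeciesTree
) -> GeneFamilyTree:
    """Root on the branch of the single most distantly related outgroup leaf.

    The outgroup ranking derives from the species tree
    (:meth:`SpeciesTree.outgroup_rank`); ties among equally ranked species
    are broken by the lexicographically smallest gene identifier.
    """
    tree = gft.tree.clone(depth=1)
    candidates = []
    for leaf in tree.leaf_node_iter():
        sp, gid = parse_leaf_label(leaf.taxon.label)
        if sp_tree.is_focal(sp):
            continue
        candidates.append((sp_tree.outgroup_rank(sp), gid, leaf))
    if not candidates:
        raise ValueError(f"family {gft.family_id!r}: no outgroup leaf to root on")
    _, _, out_leaf = min(candidates, key=lambda t: (t[0], t[1]))
    root = tree.seed_node
    if out_leaf.parent_node is root and len(root.child_nodes()) == 2:
        return GeneFamilyTree(gft.family_id, tree, rooted=True)
    edge = out_leaf.edge
    if edge.length is not None:
        tree.reroot_at_edge(edge, length1=edge.length / 2.0, length2=edge.length / 2.0,
                            suppress_unifurcations=True)
    else:
        tree.reroot_at_edge(edge, suppress_unifurcations=True)
    return GeneFamilyTree(gft.family_id, tree, rooted=True)


# ---------------------------------------------------------------------------
# clans and reconciliation


def _clusters(tree: dendropy.Tree) -> set[frozenset]:
    out = set()
    memo: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            memo[id(node)] = frozenset({node.taxon.label})
        else:
            memo[id(node)] = frozenset().union(*(memo[id(c)] for c in node.child_nodes()))
        out.add(memo[id(node)])
    return out


def is_clan(tree: dendropy.Tree | GeneFamilyTree, leaf_set: Iterable[str]) -> bool:
    """True iff some edge bipartition isolates exactly ``leaf_set``.

    This is monophyly in the unrooted sense ("clan"): the set or its
    complement must appear as the cluster of some node.
    """
    if isinstance(tree, GeneFamilyTree):
        tree = tree.tree
    wanted = frozenset(leaf_set)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    if not wanted or wanted == all_leaves:
        raise ValueError("leaf_set must be a proper non-empty subset of the leaves")
    if not wanted <= all_leaves:
        raise ValueError(f"unknown leaves in leaf_set: {sorted(wanted - all_leaves)}")
    clusters = _clusters(tree)
    return wanted in clusters or (all_leaves - wanted) in clusters


def reconcile(gft: GeneFamilyTree | dendropy.Tree, sp_tree: SpeciesTree) -> ReconciledTree:
    """Strict gene-tree/species-tree reconciliation.

    Each internal node maps to the species-tree LCA of its leaves' species
    and is labelled a duplication iff its two child leaf-species sets
    intersect, otherwise a speciation.
    """
    tree = gft.tree if isinstance(gft, GeneFamilyTree) else gft
    events: dict = {}
    sp_node: dict = {}
    species_below: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sp = _leaf_species(node)
            if sp not in sp_tree.species:
                raise KeyError(f"species {sp!r} missing from the species tree")
            species_below[id(node)] = frozenset({sp})
        else:
            kids = node.child_nodes()
            species_below[id(node)] = frozenset().union(
                *(species_below[id(c)] for c in kids)
            )
            overlap = False
            for a, b in itertools.combinations(kids, 2):
                if species_below[id(a)] & species_below[id(b)]:
                    overlap = True
                    break
            events[node] = "duplication" if overlap else "speciation"
            sp_node[node] = sp_tree.lca(species_below[id(node)])
    return ReconciledTree(tree=tree, events=events, sp_node=sp_node)


def extract_phog_quartet(rt: ReconciledTree | dendropy.Tree | GeneFamilyTree) -> list[frozenset]:
    """Leaf sets of the maximal clades holding exactly one ohnolog quartet.

    For each group of two sturgeon + two paddlefish sequences, walk to the
    highest ancestor whose subtree contains no additional sturgeon or
    paddlefish sequence, maximising retained outgroup species.  An ancient
    duplication retaining a full quartet in both copies yields two disjoint
    sets.  If no ancestor holds exactly a 2+2 complement (e.g. interleaved
    extra paralogs), the MRCA leaf set of all focal sequences is returned.
    """
    if isinstance(rt, ReconciledTree):
        tree = rt.tree
    elif isinstance(rt, GeneFamilyTree):
        tree = rt.tree
    else:
        tree = rt
    n_s: dict[int, int] = {}
    n_p: dict[int, int] = {}
    labels: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sp = _leaf_species(node)
            n_s[id(node)] = int(sp == STURGEON)
            n_p[id(node)] = int(sp == PADDLEFISH)
            labels[id(node)] = frozenset({node.taxon.label})
        else:
            kids = node.child_nodes()
            n_s[id(node)] = sum(n_s[id(c)] for c in kids)
            n_p[id(node)] = sum(n_p[id(c)] for c in kids)
            labels[id(node)] = frozenset().union(*(labels[id(c)] for c in kids))
    root = tree.seed_node
    if n_s[id(root)] < 2 or n_p[id(root)] < 2:
        raise ValueError("tree holds fewer than two sturgeon or paddlefish sequences")
    sets = []
    for node in tree.preorder_node_iter():
        if n_s[id(node)] == 2 and n_p[id(node)] == 2:
            parent = node.parent_node
            if parent is None or n_s[id(parent)] != 2 or n_p[id(parent)] != 2:
                sets.append(labels[id(node)])
    if sets:
        return sets
    # no clean 2+2 clade: fall back to the focal MRCA
    focal = [
        l.taxon.label for l in tree.leaf_node_iter() if _leaf_species(l) in FOCAL_SPECIES
    ]
    mrca = tree.mrca(taxon_labels=focal)
    return [labels[id(mrca)]]


# ---------------------------------------------------------------------------
# family filters


def apply_family_filters(
    quartet,
    coords: pd.DataFrame,
    gft: GeneFamilyTree,
    sp_tree: SpeciesTree,
    placed_chromosomes: Mapping[str, Iterable[str]],
) -> FamilyFilterReport:
    """Exclusion filters applied to each candidate ohnolog-pair family.

    Reason codes: ``same_chromosome`` (both ohnologs of either species on one
    chromosome), ``unplaced_scaffold`` (any focal gene on a scaffold outside
    the configured placed-chromosome list), ``no_outgroup`` (nothing to root
    on), ``not_clan`` (the four focal sequences are not separable by a single
    edge), ``wrong_copy_number`` (not exactly 2+2 focal sequences in the
    tree).  ``coords`` needs columns gene_id, species, chrom.
    """
    reasons = set()
    table = coords.set_index("gene_id")
    genes = {
        STURGEON: [quartet.sturgeon_a, quartet.sturgeon_b],
        PADDLEFISH: [quartet.paddlefish_a, quartet.paddlefish_b],
    }
    for sp, (g1, g2) in genes.items():
        for g in (g1, g2):
            if g not in table.index:
                raise KeyError(f"no coordinate record for gene {g!r}")
        c1, c2 = table.loc[g1, "chrom"], table.loc[g2, "chrom"]
        if c1 == c2:
            reasons.add("same_chromosome")
        placed = set(placed_chromosomes.get(sp, ()))
        if placed and not {c1, c2} <= placed:
            reasons.add("unplaced_scaffold")

    species_in_tree = [_leaf_species(l) for l in gft.tree.leaf_node_iter()]
    if not any(sp not in FOCAL_SPECIES for sp in species_in_tree):
        reasons.add("no_outgroup")
    if (
        species_in_tree.count(STURGEON) != 2
        or species_in_tree.count(PADDLEFISH) != 2
    ):
        reasons.add("wrong_copy_number")
    else:
        focal_leaves = [
            l.taxon.label
            for l in gft.tree.leaf_node_iter()
            if _leaf_species(l) in FOCAL_SPECIES
        ]
        if "no_outgroup" not in reasons and not is_clan(gft.tree, focal_leaves):
            reasons.add("not_clan")
    return FamilyFilterReport(family_id=gft.family_id, reasons=frozenset(reasons))


# ---------------------------------------------------------------------------
# quartet subtree classification


def _nested(node: dendropy.Node):
    """dendropy subtree -> nested tuple; ``None`` marks a polytomy."""
    if node.is_leaf():
        return node.taxon.label
    kids = node.child_nodes()
    if len(kids) != 2:
        return None
    a, b = (_nested(k) for k in kids)
    if a is None or b is None:
        return None
    return (a, b)


def quartet_subtree(gft: GeneFamilyTree | dendropy.Tree) -> dendropy.Node:
    """MRCA node of the focal (sturgeon + paddlefish) leaves."""
    tree = gft.tree if isinstance(gft, GeneFamilyTree) else gft
    focal = [
        l.taxon.label for l in tree.leaf_node_iter() if _leaf_species(l) in FOCAL_SPECIES
    ]
    if not focal:
        raise ValueError("no focal leaves present")
    return tree.mrca(taxon_labels=focal)


def quartet_supports(subtree_root: dendropy.Node) -> tuple:
    """Supports of the two non-root internal edges of a 4-tip subtree.

    A rooted binary quartet has exactly two internal nodes besides its root;
    their incoming edges carry the two UFBoot values checked by the support
    filter.  Missing labels yield ``None`` entries.
    """
    internals = [
        n
        for n in subtree_root.preorder_iter()
        if n is not subtree_root and not n.is_leaf()
    ]
    return tuple(_support_value(n) for n in internals)


def support_filter(subtree_root: dendropy.Node, cutoff: int, *, strict: bool = False) -> bool:
    """True iff both quartet-internal UFBoot values are >= ``cutoff``.

    Missing supports are treated as 0 (conservative) unless ``strict``.
    """
    sups = quartet_supports(subtree_root)
    if strict and any(s is None for s in sups):
        raise ValueError("missing support on a quartet-internal edge")
    vals = [0 if s is None else s for s in sups]
    return bool(vals) and min(vals) >= cutoff


def classify_family(
    gft: GeneFamilyTree, sp_tree: SpeciesTree | None = None
) -> TopologyCall:
    """Classify a family's ohnolog subtree into a rooted category.

    The tree must already be rooted (or a species tree is given and rooting
    is performed here).  The subtree of the four focal leaves is located,
    checked for resolution, and classified; triplet families (3 focal
    leaves) are typed by the 3-tip rule and reported through
    ``unrooted_type`` with ``rooted_category`` set to the type as well.
    """
    if not gft.rooted:
        if sp_tree is None:
            raise ValueError("tree unrooted and no species tree supplied for rooting")
        gft = root_by_most_distant_outgroup(gft, sp_tree)
    mrca = quartet_subtree(gft)
    shape = _nested(mrca)
    sups = quartet_supports(mrca)
    missing = any(s is None for s in sups)
    if shape is None:
        return TopologyCall(gft.family_id, "unresolved", None, sups, missing)
    n_focal = sum(
        1 for l in mrca.leaf_iter() if _leaf_species(l) in FOCAL_SPECIES
    )
    n_total = sum(1 for _ in mrca.leaf_iter())
    if n_total != n_focal:
        # outgroup sequences interleave the focal clade: not a clan
        return TopologyCall(gft.family_id, "unresolved", None, sups, missing)
    if n_total == 3:
        t = classify_rooted_triplet(shape)
        return TopologyCall(gft.family_id, t.value, t.value, sups, missing)
    if n_total != 4:
        raise ValueError(f"family {gft.family_id!r}: {n_total} focal leaves")
    cat = classify_rooted_quartet(shape)
    return TopologyCall(
        gft.family_id, cat.value, UNROOTED_TYPE_OF[cat].value, sups, missing
    )


def classify_families(
    families: Iterable[GeneFamilyTree], sp_tree: SpeciesTree | None = None
) -> pd.DataFrame:
    """Classification table (family_id, rooted_category, unrooted_type,
    support_min) over many families, in input order."""
    rows = []
    for gft in families:
        call = classify_family(gft, sp_tree)
        rows.append(
            {
                "family_id": call.family_id,
                "rooted_category": call.rooted_category,
                "unrooted_type": call.unrooted_type if call.unrooted_type else "NA",
                "support_min": call.support_min,
            }
        )
    return pd.DataFrame(rows, columns=["family_id", "rooted_category", "unrooted_type", "support_min"])


# ---------------------------------------------------------------------------
# counts, fold deviation, cutoff sweeps


def tally_categories(calls: Iterable[TopologyCall], cutoff: int = 0) -> CategoryCounts:
    """Count rooted categories among families whose both quartet supports
    pass ``cutoff``; unresolved quartets are tallied separately."""
    counts = CategoryCounts(cutoff=cutoff)
    for call in calls:
        if call.support_min < cutoff:
            continue
        if call.rooted_category == RootedCategory.POSTSPEC.value:
            counts.post_spec += 1
        elif call.rooted_category == RootedCategory.PRESPEC.value:
            counts.pre_spec += 1
        elif call.rooted_category == RootedCategory.POSTSPEC_LIKE.value:
            counts.post_spec_like += 1
        elif call.rooted_category == RootedCategory.PRESPEC_LIKE.value:
            counts.pre_spec_like += 1
        else:
            counts.unresolved += 1
    return counts


def fold_deviation(counts: CategoryCounts | Mapping[str, int]) -> dict[str, float]:
    """Observed/expected frequency ratio per main category.

    The null expectation is the uniform-topology lottery over the 15 rooted
    quartets: PostSpec 1/15, PreSpec 2/15, Other 12/15.  A ratio of 1 means
    the category is recovered exactly as often as by chance.
    """
    if isinstance(counts, CategoryCounts):
        obs = {
            "PostSpec": counts.post_spec,
            "PreSpec": counts.pre_spec,
            "Other": counts.other,
        }
    else:
        obs = dict(counts)
    total = sum(obs.values())
    if total <= 0:
        raise ValueError("fold deviation undefined for zero classified trees")
    return {
        cat: (obs[cat] / total) / RANDOM_EXPECTATION[cat] for cat in RANDOM_EXPECTATION
    }


def counts_by_cutoff(
    calls: Sequence[TopologyCall], cutoffs: Sequence[int] = (0, 50, 75, 90, 95, 100)
) -> pd.DataFrame:
    """Category counts, percentages and fold deviations per UFBoot cutoff."""
    rows = []
    for cutoff in cutoffs:
        c = tally_categories(calls, cutoff)
        row = {
            "cutoff": cutoff,
            "PostSpec": c.post_spec,
            "PreSpec": c.pre_spec,
            "Other": c.other,
            "unresolved": c.unresolved,
            "total": c.total,
        }
        if c.total:
            fd = fold_deviation(c)
            for cat in ("PostSpec", "PreSpec", "Other"):
                row[f"pct_{cat}"] = 100.0 * row[cat] / c.total
                row[f"fold_{cat}"] = fd[cat]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# control clades


def clade_recovery(
    tree: dendropy.Tree | GeneFamilyTree, clade_species: Iterable[str]
) -> bool | None:
    """Does the tree recover a control clade (Tetrapoda, Teleostei, ...)?

    Requires at least one sequence per clade species; returns ``None``
    (not evaluable) if any species is absent, otherwise whether all the
    clade's sequences form a clan.
    """
    if isinstance(tree, GeneFamilyTree):
        tree = tree.tree
    wanted = set(clade_species)
    members = []
    present = set()
    for leaf in tree.leaf_node_iter():
        sp = _leaf_species(leaf)
        if sp in wanted:
            present.add(sp)
            members.append(leaf.taxon.label)
    if present != wanted:
        return None
    return is_clan(tree, members)


# ---------------------------------------------------------------------------
# alignment and tree diagnostics


def _char_matrix(alignment) -> tuple[list[str], np.ndarray]:
    """Accepts a Bio.Align.MultipleSeqAlignment or an iterable of
    (name, sequence) pairs; returns names and an upper-cased char matrix."""
    names, seqs = [], []
    for rec in alignment:
        if hasattr(rec, "seq"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
        else:
            name, seq = rec
            names.append(name)
            seqs.append(str(seq))
    if len(seqs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    mat = np.array([list(s.upper()) for s in seqs])
    return names, mat


def alignment_stats(alignment) -> dict:
    """Length, average pairwise % identity, variable and
    parsimony-informative site counts.

    Identity is averaged over all unordered sequence pairs; columns where
    both members of a pair are gaps are excluded for that pair, and a
    residue-vs-gap column counts as a mismatch.  A variable site has >= 2
    distinct non-gap residues; a parsimony-informative site has >= 2
    residues each occurring >= 2 times.
    """
    _, mat = _char_matrix(alignment)
    n, length = mat.shape
    gap = np.isin(mat, list(GAP_CHARS))

    idents = []
    for i, j in itertools.combinations(range(n), 2):
        both_gap = gap[i] & gap[j]
        compared = (~both_gap).sum()
        if compared == 0:
            continue
        matches = ((mat[i] == mat[j]) & ~gap[i] & ~gap[j]).sum()
        idents.append(100.0 * matches / compared)
    avg_ident = float(np.mean(idents)) if idents else float("nan")

    n_var = 0
    n_pi = 0
    for col in range(length):
        residues = mat[~gap[:, col], col]
        if residues.size == 0:
            continue
        vals, cnts = np.unique(residues, return_counts=True)
        if vals.size >= 2:
            n_var += 1
            if (cnts >= 2).sum() >= 2:
                n_pi += 1
    return {
        "length": length,
        "avg_pairwise_identity": avg_ident,
        "n_variable_sites": n_var,
        "n_parsimony_informative": n_pi,
    }


def tree_stats(tree: dendropy.Tree | GeneFamilyTree, alignment) -> dict:
    """Rate/treeness/RCV/saturation diagnostics for one family.

    evolutionary_rate = total tree length / leaf count; treeness = internal
    branch length share of total; RCV = mean absolute deviation of per-taxon
    residue counts from the column-mean composition, normalised by taxa x
    alignment length; saturation = through-origin slope of uncorrected
    pairwise distance on patristic distance (1 means unsaturated, values
    below 1 indicate multiple hits).
    """
    if isinstance(tree, GeneFamilyTree):
        tree = tree.tree
    names, mat = _char_matrix(alignment)
    gap = np.isin(mat, list(GAP_CHARS))
    n_taxa, length = mat.shape

    total = 0.0
    internal = 0.0
    n_leaves = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length or 0.0
        total += bl
        if not node.is_leaf():
            internal += bl
    for _ in tree.leaf_node_iter():
        n_leaves += 1
    if total <= 0:
        raise ValueError("treeness undefined: zero total tree length")

    states = sorted(set(np.unique(mat)) - GAP_CHARS)
    counts = np.array(
        [[(mat[t] == s).sum() for s in states] for t in range(n_taxa)], float
    )
    mean_per_state = counts.mean(axis=0)
    rcv = float(np.abs(counts - mean_per_state).sum() / (n_taxa * length))

    # saturation: uncorrected vs patristic distance, slope through origin
    idx = {name: i for i, name in enumerate(names)}
    pdm = tree.phylogenetic_distance_matrix()
    xs, ys = [], []
    taxa = list(tree.taxon_namespace)
    for t1, t2 in itertools.combinations(taxa, 2):
        i, j = idx[t1.label], idx[t2.label]
        ok = ~gap[i] & ~gap[j]
        if ok.sum() == 0:
            continue
        p_dist = (mat[i][ok] != mat[j][ok]).sum() / ok.sum()
        xs.append(pdm.patristic_distance(t1, t2))
        ys.append(p_dist)
    xs_a, ys_a = np.asarray(xs), np.asarray(ys)
    denom = float((xs_a**2).sum())
    slope = float((xs_a * ys_a).sum() / denom) if denom > 0 else float("nan")

    treeness = internal / total
    return {
        "evolutionary_rate": total / n_leaves,
        "treeness": treeness,
        "rcv": rcv,
        "treeness_over_rcv": treeness / rcv if rcv > 0 else float("inf"),
        "saturation": slope,
    }


def compare_paired_branch_lengths(
    pairs: Sequence[tuple[float, float]], max_len: float = 0.15
) -> dict:
    """Two-sided paired Wilcoxon signed-rank test of sturgeon vs paddlefish
    ortholog branch lengths, after removing extreme pairs.

    Pairs where either branch length is >= ``max_len`` are excluded before
    testing (outlier rule of the rate comparison).
    """
    kept = [(a, b) for a, b in pairs if a < max_len and b < max_len]
    if not kept:
        raise ValueError("no pairs remain after the branch-length filter")
    a = np.array([p[0] for p in kept])
    b = np.array([p[1] for p in kept])
    if np.all(a == b):
        statistic, p_value = 0.0, 1.0
    else:
        res = stats.wilcoxon(a, b, alternative="two-sided")
        statistic, p_value = float(res.statistic), float(res.pvalue)
    return {
        "statistic": statistic,
        "p_value": p_value,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_used": len(kept),
        "n_removed": len(pairs) - len(kept),
    }
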