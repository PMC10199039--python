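"""Rooting, clans, reconciliation, filters, supports, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import lorescan as ls
from lorescan.treeproc import (
    CategoryCounts,
    extract_phog_quartet,
    quartet_subtree,
    quartet_supports,
)
from lorescan.topology import QuartetLabels


def gt(newick, fid="fam1", rooted=False):
    return ls.read_gene_tree(newick, fid, rooted=rooted)


# ---------------------------------------------------------------------------
# rooting


def test_rooting_picks_most_distant_outgroup(species_tree):
    nwk = "((Sturgeon|s1,Paddlefish|p1),(Zebrafish|z1,GhostShark|g1));"
    rooted = ls.root_by_most_distant_outgroup(gt(nwk), species_tree)
    kids = rooted.tree.seed_node.child_nodes()
    leaf_kids = [k.taxon.label for k in kids if k.is_leaf()]
    assert "GhostShark|g1" in leaf_kids


def test_rooting_idempotent_when_already_rooted(species_tree):
    nwk = "(GhostShark|g1,((Sturgeon|s1,Paddlefish|p1),Zebrafish|z1));"
    once = ls.root_by_most_distant_outgroup(gt(nwk), species_tree)
    twice = ls.root_by_most_distant_outgroup(once, species_tree)
    b1 = {frozenset(l.taxon.label for l in n.leaf_iter())
          for n in once.tree.preorder_node_iter()}
    b2 = {frozenset(l.taxon.label for l in n.leaf_iter())
          for n in twice.tree.preorder_node_iter()}
    assert b1 == b2


def test_rooting_tie_break_by_gene_id(species_tree):
    nwk = "((Sturgeon|s1,Paddlefish|p1),(GhostShark|g2,GhostShark|g1));"
    rooted = ls.root_by_most_distant_outgroup(gt(nwk), species_tree)
    kids = [k.taxon.label for k in rooted.tree.seed_node.child_nodes() if k.is_leaf()]
    assert kids == ["GhostShark|g1"]
    # swapping the gene ids swaps the chosen root leaf
    nwk2 = "((Sturgeon|s1,Paddlefish|p1),(GhostShark|g1,GhostShark|g2));"
    rooted2 = ls.root_by_most_distant_outgroup(gt(nwk2), species_tree)
    kids2 = [k.taxon.label for k in rooted2.tree.seed_node.child_nodes() if k.is_leaf()]
    assert kids2 == ["GhostShark|g1"]


def test_rooting_requires_an_outgroup(species_tree):
    with pytest.raises(ValueError):
        ls.root_by_most_distant_outgroup(
            gt("((Sturgeon|a,Sturgeon|b),(Paddlefish|c,Paddlefish|d));"), species_tree
        )


# ---------------------------------------------------------------------------
# clans


def _random_nested(labels, rng):
    trees = [labels[0]]
    tree = labels[0]
    for leaf in labels[1:]:
        positions = []

        def collect(node, path):
            positions.append(path)
            if not isinstance(node, str):
                collect(node[0], path + (0,))
                collect(node[1], path + (1,))

        collect(tree, ())
        choice = positions[rng.integers(0, len(positions))]

        def insert(node, path):
            if not path:
                return (node, leaf)
            a, b = node
            if path[0] == 0:
                return (insert(a, path[1:]), b)
            return (a, insert(b, path[1:]))

        tree = insert(tree, choice)
    return tree


def _nested_to_newick(t):
    if isinstance(t, str):
        return t
    return "(" + ",".join(_nested_to_newick(c) for c in t) + ")"


def _all_bipartitions(t):
    """Independent oracle: leaf set under every subtree."""
    out = []

    def walk(node):
        if isinstance(node, str):
            out.append(frozenset({node}))
            return frozenset({node})
        s = frozenset().union(*(walk(c) for c in node))
        out.append(s)
        return s

    walk(t)
    return out


def test_is_clan_matches_bipartition_oracle(rng):
    labels = [f"Sturgeon|g{i}" for i in range(8)]
    for _ in range(20):
        nested = _random_nested(labels, rng)
        tree = gt(_nested_to_newick(nested) + ";")
        sides = _all_bipartitions(nested)
        full = frozenset(labels)
        clan_sets = {s for s in sides} | {full - s for s in sides}
        for size in (1, 2, 3, 4):
            for _ in range(5):
                subset = frozenset(rng.choice(labels, size=size, replace=False))
                if subset == full:
                    continue
                assert ls.is_clan(tree, subset) == (subset in clan_sets)


def test_is_clan_rejects_trivial_sets():
    tree = gt("((Sturgeon|a,Sturgeon|b),(Paddlefish|c,GhostShark|d));")
    with pytest.raises(ValueError):
        ls.is_clan(tree, [])
    with pytest.raises(ValueError):
        ls.is_clan(tree, ["Sturgeon|a", "Sturgeon|b", "Paddlefish|c", "GhostShark|d"])


# ---------------------------------------------------------------------------
# reconciliation


def test_reconcile_prespec_quartet_shares_duplication(species_tree):
    nwk = "(GhostShark|g,((Sturgeon|a,Paddlefish|c),(Sturgeon|b,Paddlefish|d)));"
    rec = ls.reconcile(gt(nwk, rooted=True), species_tree)
    dups = rec.duplication_nodes()
    assert len(dups) == 1
    cluster = {l.taxon.label.split("|")[0] for l in dups[0].leaf_iter()}
    assert cluster == {"Sturgeon", "Paddlefish"}
    assert species_tree.cluster(rec.sp_node[dups[0]]) == frozenset(
        {"Sturgeon", "Paddlefish"}
    )


def test_reconcile_postspec_quartet_two_duplications(species_tree):
    nwk = "(GhostShark|g,((Sturgeon|a,Sturgeon|b),(Paddlefish|c,Paddlefish|d)));"
    rec = ls.reconcile(gt(nwk, rooted=True), species_tree)
    dups = rec.duplication_nodes()
    assert len(dups) == 2
    clusters = sorted(
        {l.taxon.label.split("|")[0] for l in d.leaf_iter()} == {"Sturgeon"}
        for d in dups
    )
    assert clusters == [False, True]  # one sturgeon-only, one paddlefish-only


def test_reconcile_species_tree_as_gene_tree_is_all_speciations(species_tree):
    from lorescan.species import DEFAULT_SPECIES_TREE_NEWICK

    nwk = DEFAULT_SPECIES_TREE_NEWICK
    for sp in species_tree.species:
        nwk = nwk.replace(sp, f"{sp}|{sp.lower()}1")
    rec = ls.reconcile(gt(nwk, rooted=True), species_tree)
    assert rec.duplication_nodes() == []


def test_reconcile_unknown_species_raises(species_tree):
    with pytest.raises(KeyError):
        ls.reconcile(gt("(Martian|x,(Sturgeon|a,Paddlefish|b));", rooted=True), species_tree)


# ---------------------------------------------------------------------------
# PHOG extraction


def test_phog_extraction_trivial_family_returns_all_leaves():
    nwk = "(GhostShark|g,((Sturgeon|a,Paddlefish|c),(Sturgeon|b,Paddlefish|d)));"
    sets = extract_phog_quartet(gt(nwk, rooted=True))
    assert sets == [frozenset({"GhostShark|g", "Sturgeon|a", "Sturgeon|b",
                               "Paddlefish|c", "Paddlefish|d"})]


def test_phog_extraction_stops_below_extra_paralog():
    nwk = ("(GhostShark|g,(Sturgeon|extra,(Human|h,((Sturgeon|a,Paddlefish|c),"
           "(Sturgeon|b,Paddlefish|d)))));")
    sets = extract_phog_quartet(gt(nwk, rooted=True))
    assert len(sets) == 1
    assert "Sturgeon|extra" not in sets[0]
    assert "Human|h" in sets[0]  # outgroup retention is maximised


def test_phog_extraction_ancient_duplication_yields_two_sets():
    sub1 = "((Sturgeon|a1,Paddlefish|c1),(Sturgeon|b1,Paddlefish|d1))"
    sub2 = "((Sturgeon|a2,Paddlefish|c2),(Sturgeon|b2,Paddlefish|d2))"
    nwk = f"(GhostShark|g,((Zebrafish|z1,{sub1}),(Zebrafish|z2,{sub2})));"
    sets = extract_phog_quartet(gt(nwk, rooted=True))
    assert len(sets) == 2
    assert not sets[0] & sets[1]


# ---------------------------------------------------------------------------
# family filters


@pytest.fixture()
def coords_table():
    return pd.DataFrame(
        {
            "gene_id": ["sa", "sb", "pa", "pb"],
            "species": ["Sturgeon", "Sturgeon", "Paddlefish", "Paddlefish"],
            "chrom": ["stu_chr1", "stu_chr2", "pad_chr1", "pad_chr2"],
            "start": [0, 0, 0, 0],
            "end": [10, 10, 10, 10],
        }
    )


PLACED = {
    "Sturgeon": ["stu_chr1", "stu_chr2", "stu_chr5"],
    "Paddlefish": ["pad_chr1", "pad_chr2"],
}
GOOD_NWK = "(GhostShark|g,((Sturgeon|sa,Paddlefish|pa),(Sturgeon|sb,Paddlefish|pb)));"


def test_family_filters_pass(coords_table, species_tree):
    q = QuartetLabels("sa", "sb", "pa", "pb")
    rep = ls.apply_family_filters(q, coords_table, gt(GOOD_NWK), species_tree, PLACED)
    assert rep.passed and rep.reasons == frozenset()


def test_family_filters_same_chromosome(coords_table, species_tree):
    coords_table.loc[coords_table.gene_id == "sb", "chrom"] = "stu_chr1"
    q = QuartetLabels("sa", "sb", "pa", "pb")
    rep = ls.apply_family_filters(q, coords_table, gt(GOOD_NWK), species_tree, PLACED)
    assert "same_chromosome" in rep.reasons and not rep.passed


def test_family_filters_unplaced_scaffold(coords_table, species_tree):
    coords_table.loc[coords_table.gene_id == "pb", "chrom"] = "pad_scaffold99"
    q = QuartetLabels("sa", "sb", "pa", "pb")
    rep = ls.apply_family_filters(q, coords_table, gt(GOOD_NWK), species_tree, PLACED)
    assert rep.reasons == {"unplaced_scaffold"}


def test_family_filters_no_outgroup_and_not_clan(coords_table, species_tree):
    q = QuartetLabels("sa", "sb", "pa", "pb")
    no_out = "((Sturgeon|sa,Paddlefish|pa),(Sturgeon|sb,Paddlefish|pb));"
    rep = ls.apply_family_filters(q, coords_table, gt(no_out), species_tree, PLACED)
    assert "no_outgroup" in rep.reasons
    interleaved = ("((Sturgeon|sa,GhostShark|g),"
                   "((Sturgeon|sb,Paddlefish|pa),(Paddlefish|pb,Human|h)));")
    rep2 = ls.apply_family_filters(q, coords_table, gt(interleaved), species_tree, PLACED)
    assert "not_clan" in rep2.reasons


def test_family_filters_missing_coordinate(coords_table, species_tree):
    q = QuartetLabels("sa", "sb", "pa", "zz")
    with pytest.raises(KeyError):
        ls.apply_family_filters(q, coords_table, gt(GOOD_NWK), species_tree, PLACED)


# ---------------------------------------------------------------------------
# support filtering


def quartet_with_supports(s1, s2):
    nwk = (f"(GhostShark|g,((Sturgeon|sa,Paddlefish|pa){s1},"
           f"(Sturgeon|sb,Paddlefish|pb){s2}));")
    tree = gt(nwk, rooted=True)
    return quartet_subtree(tree)


def test_support_filter_min_rule():
    assert ls.support_filter(quartet_with_supports(100, 100), 100)
    assert not ls.support_filter(quartet_with_supports(94, 100), 95)
    assert ls.support_filter(quartet_with_supports(94, 100), 94)


def test_support_filter_missing_supports():
    node = quartet_with_supports("", "")
    assert quartet_supports(node) == (None, None)
    assert not ls.support_filter(node, 1)  # treated as 0
    with pytest.raises(ValueError):
        ls.support_filter(node, 50, strict=True)


def test_support_filter_retention_monotone(small_dataset, species_tree):
    calls = [
        ls.classify_family(t, species_tree) for t in small_dataset["trees"].values()
    ]
    retained = [
        sum(c.support_min >= cutoff for c in calls) for cutoff in range(0, 101, 5)
    ]
    assert all(a >= b for a, b in zip(retained, retained[1:]))


# ---------------------------------------------------------------------------
# fold deviation


def test_fold_deviation_uniform_expectation_is_one():
    fd = ls.fold_deviation({"PostSpec": 1, "PreSpec": 2, "Other": 12})
    assert all(abs(v - 1.0) < 1e-12 for v in fd.values())


def test_fold_deviation_zero_total_is_an_error():
    with pytest.raises(ValueError):
        ls.fold_deviation({"PostSpec": 0, "PreSpec": 0, "Other": 0})


def test_fold_deviation_converges_under_uniform_null(rng):
    """Law of large numbers: equal topology frequencies give ratios -> 1."""
    draws = rng.choice(15, size=10000)
    counts = {
        "PostSpec": int((draws == 0).sum()),
        "PreSpec": int((draws < 3).sum() - (draws == 0).sum()),
    }
    counts["Other"] = 10000 - counts["PostSpec"] - counts["PreSpec"]
    fd = ls.fold_deviation(counts)
    # 3 multinomial SEs on each ratio
    for cat, e in (("PostSpec", 1 / 15), ("PreSpec", 2 / 15), ("Other", 12 / 15)):
        se = np.sqrt(e * (1 - e) / 10000) / e
        assert abs(fd[cat] - 1.0) <= 3 * se


# ---------------------------------------------------------------------------
# clade recovery


def test_clade_recovery_cases(species_tree):
    good = ("(GhostShark|g,((Frog|f,(Human|h,Chicken|c)),"
            "((Sturgeon|sa,Paddlefish|pa),(Sturgeon|sb,Paddlefish|pb))));")
    assert ls.clade_recovery(gt(good), {"Human", "Chicken", "Frog"}) is True
    no_frog = ("(GhostShark|g,((Human|h,Chicken|c),"
               "((Sturgeon|sa,Paddlefish|pa),(Sturgeon|sb,Paddlefish|pb))));")
    assert ls.clade_recovery(gt(no_frog), {"Human", "Chicken", "Frog"}) is None
    broken = ("(GhostShark|g,((Fugu|f,(WhaleShark|w,Zebrafish|z)),"
              "((Sturgeon|sa,Paddlefish|pa),(Sturgeon|sb,Paddlefish|pb))));")
    assert ls.clade_recovery(broken and gt(broken), {"Fugu", "Zebrafish"}) is False


# ---------------------------------------------------------------------------
# alignment / tree statistics


def test_alignment_stats_identical_sequences():
    stats = ls.alignment_stats([("a", "ACDEFG"), ("b", "ACDEFG")])
    assert stats["avg_pairwise_identity"] == 100.0
    assert stats["n_variable_sites"] == 0
    assert stats["length"] == 6


def test_alignment_stats_parsimony_informative_column():
    aln = [("a", "AAAAAA"), ("b", "AAAAAA"), ("c", "ABAAAA"), ("d", "ABAAAA")]
    stats = ls.alignment_stats(aln)
    assert stats["n_variable_sites"] == 1
    assert stats["n_parsimony_informative"] == 1


def test_alignment_stats_matches_columnwise_oracle(rng):
    chars = np.array(list("ACDE-"))
    for _ in range(10):
        mat = chars[rng.integers(0, 5, size=(5, 40))]
        aln = [(f"t{i}", "".join(row)) for i, row in enumerate(mat)]
        stats = ls.alignment_stats(aln)
        n_var = n_pi = 0
        for col in mat.T:
            residues = [c for c in col if c != "-"]
            uniq = set(residues)
            if len(uniq) >= 2:
                n_var += 1
                if sum(residues.count(u) >= 2 for u in uniq) >= 2:
                    n_pi += 1
        assert stats["n_variable_sites"] == n_var
        assert stats["n_parsimony_informative"] == n_pi


def test_alignment_stats_rejects_ragged():
    with pytest.raises(ValueError):
        ls.alignment_stats([("a", "ACD"), ("b", "AC")])


def test_tree_stats_star_tree_treeness_zero():
    tree = gt("(Sturgeon|a:0.1,Sturgeon|b:0.1,Sturgeon|c:0.1);", rooted=True)
    aln = [("Sturgeon|a", "ACDE"), ("Sturgeon|b", "ACDE"), ("Sturgeon|c", "ACDE")]
    stats = ls.tree_stats(tree, aln)
    assert stats["treeness"] == 0.0
    assert stats["rcv"] == 0.0
    assert stats["evolutionary_rate"] == pytest.approx(0.3 / 3)


def test_tree_stats_saturation_slope_declines_with_depth():
    rates = {"shallow": 0.02, "deep": 1.5}
    slopes = {}
    for name, scale in rates.items():
        nwk = (f"((Sturgeon|a:{scale},Sturgeon|b:{scale}):{scale},"
               f"(Sturgeon|c:{scale},Sturgeon|d:{scale}):{scale});")
        tree = gt(nwk, rooted=True)
        seqs = ls.simulate_sequences(tree, 2000, seed=7)
        stats = ls.tree_stats(gt(nwk, rooted=True), sorted(seqs.items()))
        slopes[name] = stats["saturation"]
    assert slopes["shallow"] > 0.85
    assert slopes["deep"] < slopes["shallow"] - 0.2


def test_paired_branch_length_comparison():
    same = [(0.05, 0.05)] * 20
    res = ls.compare_paired_branch_lengths(same)
    assert res["p_value"] == 1.0
    rng = np.random.default_rng(0)
    a = rng.uniform(0.02, 0.1, size=50)
    shifted = list(zip(a, a + 0.02))
    res2 = ls.compare_paired_branch_lengths(shifted)
    assert res2["p_value"] < 0.001
    assert res2["median_b"] > res2["median_a"]
    res3 = ls.compare_paired_branch_lengths([(0.2, 0.01), (0.05, 0.06)])
    assert res3["n_used"] == 1 and res3["n_removed"] == 1
    with pytest.raises(ValueError):
        ls.compare_paired_branch_lengths([(0.2, 0.01)])
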