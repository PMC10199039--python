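"""The WGD/rediploidization simulator: truth, trees, sequences, observables."""

import numpy as np
import pytest

import lorescan as ls
from lorescan.io import write_dataset, read_gene_trees, read_coords, read_depth
from lorescan.ks import ks_ng86
from lorescan.simulate import family_time_tree


def test_config_validation():
    with pytest.raises(ValueError):
        ls.SimConfig(t_wgd=2.0, t_root=1.0)
    with pytest.raises(ValueError):
        ls.SimConfig(t_spec=1.5)  # above t_wgd
    with pytest.raises(ValueError):
        ls.SimConfig(p_loss=1.5)


def test_point_mass_rediploidization_forces_scenarios():
    all_pre = ls.simulate_blocks(
        ls.SimConfig(redip_low=1.0, redip_high=1.0, n_blocks=20, seed=1)
    )
    assert {f.category for f in all_pre.families} == {"PreSpec"}
    all_post = ls.simulate_blocks(
        ls.SimConfig(redip_low=1e-6, redip_high=1e-6, n_blocks=20, seed=1)
    )
    assert {f.category for f in all_post.families} == {"PostSpec"}


def test_uniform_law_gives_expected_prespec_fraction():
    cfg = ls.SimConfig(t_wgd=1.0, t_spec=0.4, n_blocks=500, genes_per_block=1, seed=8)
    truth = ls.simulate_blocks(cfg)
    frac = np.mean([f.category == "PreSpec" for f in truth.families])
    expect = (cfg.t_wgd - cfg.t_spec) / cfg.t_wgd
    se = np.sqrt(expect * (1 - expect) / 500)
    assert abs(frac - expect) <= 3 * se


def test_truth_time_invariants():
    truth = ls.simulate_blocks(ls.SimConfig(n_blocks=100, genes_per_block=1, seed=2))
    cfg = truth.config
    for fam in truth.families:
        if fam.category == "PreSpec":
            assert fam.r_shared > cfg.t_spec
        else:
            assert fam.r_sturgeon < cfg.t_spec and fam.r_paddlefish < cfg.t_spec


def test_simulator_is_deterministic(tmp_path):
    cfg = ls.SimConfig(n_blocks=10, genes_per_block=3, p_nni=0.2, p_loss=0.1,
                       p_collapse=0.3, seed=77)
    d1 = ls.simulate_dataset(cfg)
    d2 = ls.simulate_dataset(cfg)
    n1 = {f: t.tree.as_string("newick") for f, t in d1["trees"].items()}
    n2 = {f: t.tree.as_string("newick") for f, t in d2["trees"].items()}
    assert n1 == n2
    assert d1["coords"].equals(d2["coords"])
    assert d1["depth"].equals(d2["depth"])


def test_dataset_roundtrips_through_text_formats(tmp_path, small_dataset):
    write_dataset(small_dataset, tmp_path)
    trees = read_gene_trees(tmp_path / "gene_trees.tsv")
    assert len(trees) == len(small_dataset["trees"])
    coords = read_coords(tmp_path / "coords.tsv")
    assert len(coords) == len(small_dataset["coords"])
    depth = read_depth(tmp_path / "depth.tsv")
    assert len(depth) == len(small_dataset["depth"])


def test_zero_length_branches_give_identical_sequences():
    tree = ls.read_gene_tree(
        "((A|a:0.0,B|b:0.0):0.0,(C|c:0.0,D|d:0.0):0.0);", "t", rooted=True
    )
    seqs = ls.simulate_sequences(tree, 50, seed=0)
    assert len(set(seqs.values())) == 1
    codons = ls.simulate_sequences(tree, 30, seed=0, mode="codon")
    assert len(set(codons.values())) == 1


def test_pairwise_distance_grows_with_path_length(rng):
    dists = []
    for depth in (0.02, 0.1, 0.4):
        tree = ls.read_gene_tree(
            f"(A|a:{depth},B|b:{depth});", "t", rooted=True
        )
        seqs = ls.simulate_sequences(tree, 3000, seed=int(depth * 1000))
        a, b = seqs["A|a"], seqs["B|b"]
        dists.append(np.mean([x != y for x, y in zip(a, b)]))
    assert dists[0] < dists[1] < dists[2]


def test_codon_mode_ks_tracks_divergence_time():
    """Median NG86 Ks over simulated pairs approximates 2 * syn_rate * t."""
    t, syn_rate = 0.6, 0.12
    tree = ls.read_gene_tree(f"(A|a:{t},B|b:{t});", "t", rooted=True)
    ks_vals = []
    for seed in range(120):
        seqs = ls.simulate_sequences(tree, 200, seed=seed, mode="codon",
                                     syn_rate=syn_rate, nonsyn_rate=0.024)
        res = ks_ng86(seqs["A|a"], seqs["B|b"])
        if res.ks is not None:
            ks_vals.append(res.ks)
    med = float(np.median(ks_vals))
    assert med == pytest.approx(2 * syn_rate * t, rel=0.15)


def test_median_ks_monotone_in_divergence_time():
    meds = []
    for t in (0.2, 0.5, 0.9):
        tree = ls.read_gene_tree(f"(A|a:{t},B|b:{t});", "t", rooted=True)
        vals = []
        for seed in range(40):
            seqs = ls.simulate_sequences(tree, 150, seed=seed, mode="codon")
            res = ks_ng86(seqs["A|a"], seqs["B|b"])
            if res.ks is not None:
                vals.append(res.ks)
        meds.append(np.median(vals))
    assert meds[0] < meds[1] < meds[2]


def test_observables_without_loss_or_collapse(small_dataset):
    truth = small_dataset["truth"]
    assert all(f.is_quartet for f in truth.families)
    depth = small_dataset["depth"]
    assert set(depth["label"]) == {"two_copy_pair"}
    # depth clusters tightly around the single-copy mean
    assert ls.modal_depth(depth["depth"]) == pytest.approx(30.0, abs=2.0)


def test_loss_and_collapse_edit_families():
    cfg = ls.SimConfig(n_blocks=120, genes_per_block=2, p_loss=0.1, p_collapse=0.5,
                       redip_low=0.0, redip_high=0.3, seed=13)  # all PostSpec
    truth = ls.simulate_blocks(cfg)
    obs = ls.simulate_observables(truth)
    assert obs["n_lost"] > 0 and obs["n_collapsed"] > 0
    depth = obs["depth"]
    collapsed = depth[depth["label"] == "single_copy_PostSpecType"]
    lost_or_collapsed = obs["n_lost"] + obs["n_collapsed"]
    # every edited family removed one paddlefish gene from the coordinates
    assert len(obs["coords"]) == len(truth.coords) - lost_or_collapsed
    # collapsed genes sit near twice the reference depth
    doubles = collapsed["depth"][collapsed["depth"] > 45]
    assert len(doubles) >= obs["n_collapsed"] * 0.9


def test_gene_tree_shapes_match_truth(species_tree):
    cfg = ls.SimConfig(n_blocks=30, genes_per_block=1, seed=21)
    truth = ls.simulate_blocks(cfg)
    for fam in truth.families[:10]:
        gft = ls.simulate_gene_tree(fam, cfg)
        call = ls.classify_family(gft, species_tree)
        assert call.rooted_category == fam.category
        # time tree: tips are ultrametric at the quartet scale
        tt = family_time_tree(fam, cfg)
        depths = {
            l.taxon.label: sum(
                n.edge.length or 0.0 for n in _ancestors(l)
            )
            for l in tt.tree.leaf_node_iter()
        }
        vals = list(depths.values())
        assert max(vals) - min(vals) < 1e-9


def test_edited_families_classify_as_triplets(species_tree):
    """Collapsed families present PostSpec-type triplets; lost families
    present the triplet type matching their true category."""
    cfg = ls.SimConfig(n_blocks=150, genes_per_block=1, p_loss=0.15, p_collapse=0.8,
                       collapse_recency=0.25, seed=29)
    truth = ls.simulate_blocks(cfg)
    ls.simulate_observables(truth)
    seen_collapsed = seen_lost = 0
    for fam in truth.families:
        if fam.is_quartet:
            continue
        call = ls.classify_family(ls.simulate_gene_tree(fam, cfg), species_tree)
        if fam.collapsed:
            seen_collapsed += 1
            assert call.rooted_category == "PostSpecType"
        else:
            seen_lost += 1
            expected = "PreSpecType" if fam.category == "PreSpec" else "PostSpecType"
            assert call.rooted_category == expected
    assert seen_collapsed > 0 and seen_lost > 0


def _ancestors(leaf):
    node = leaf
    while node is not None:
        yield node
        node = node.parent_node
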