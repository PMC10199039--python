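"""Simulation of WGD + asynchronous rediploidization datasets.

The generator realises the three competing scenarios for the sturgeon +
paddlefish genomes: independent lineage-specific WGDs (all families show
independent duplication nodes), a shared WGD with completed
rediploidization (all families show a shared duplication node), and the
intermediate — a shared WGD at ``t_wgd`` followed by block-wise
rediploidization at times straddling the speciation ``t_spec``, so that
early-rediploidizing blocks yield PreSpec gene trees and late ones yield
PostSpec trees in each lineage independently.

Each block draws one candidate rediploidization time from a configurable
distribution (uniform over the post-WGD interval by default).  Families
inherit their block's category, a gene tree with branch lengths (lineage
rate x time span), heuristic bootstrap supports (logistic in the internal
branch length — a stand-in for real bootstrapping, chosen for speed), and
optional topology noise: with a probability that decays with the shortest
internal branch, one nearest-neighbour interchange inside the quartet
produces an 'Other'-topology tree with depressed supports.  Ohnolog loss
and assembly collapse edit the paddlefish complement and the simulated
read depths.  All times are in arbitrary units before present with
``t_root > t_wgd > t_spec > 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ks import GENETIC_CODE, NUCLEOTIDES
from .models import AminoAcidModel, discrete_gamma_rates, jtt_model
from .treeproc import GeneFamilyTree, read_gene_tree

__all__ = [
    "SimConfig",
    "FamilyTruth",
    "BlockTruth",
    "SimTruth",
    "simulate_blocks",
    "simulate_gene_tree",
    "simulate_sequences",
    "simulate_observables",
    "simulate_dataset",
    "family_time_tree",
]

#: Node depths (time before present) of the 13-species tree used to hang
#: outgroup lineages off the focal quartet.
DEFAULT_OUTGROUP_DEPTHS = {
    "root": 3.0,          # crown gnathostomes
    "chondrichthyes": 1.8,
    "osteichthyes": 2.8,
    "sarcopterygii": 2.2,
    "tetrapoda": 1.9,
    "amniota": 1.6,
    "actinopterygii": 2.4,
    "actinopteri": 2.0,   # Acipenseriformes vs Neopterygii
    "neopterygii": 1.5,
    "teleostei": 1.0,
    "holostei": 1.2,
}


@dataclass
class SimConfig:
    """Full parameterisation of the WGD/rediploidization simulator."""

    t_root: float = 3.0
    t_wgd: float = 1.0
    t_spec: float = 0.5
    n_blocks: int = 50
    genes_per_block: int | tuple = 10
    #: rediploidization-time law: uniform over (redip_low, redip_high);
    #: None bounds default to (0, t_wgd).
    redip_low: float | None = None
    redip_high: float | None = None
    rate_sturgeon: float = 0.15          # substitutions/site/time
    rate_paddlefish_factor: float = 1.2  # paddlefish evolves faster
    rate_outgroup: float = 0.15
    syn_rate: float = 0.12               # synonymous subs / syn site / time
    nonsyn_rate: float = 0.024
    p_loss: float = 0.0                  # paddlefish ohnolog loss
    p_collapse: float = 0.0              # assembly collapse of recent PostSpec pairs
    collapse_recency: float | None = None  # r_bP below this may collapse (default t_spec/2)
    p_nni: float = 0.0                   # topology-noise ceiling
    nni_branch_scale: float = 0.005      # subst/site decay scale of NNI probability
    support_b50: float = 0.0005          # branch length of 50% support
    support_scale: float = 0.0002
    support_noise_sd: float = 2.0
    outgroup_support: int = 100
    depth_mean: float = 30.0
    depth_sd: float = 3.0
    n_chrom_pairs: int = 3
    gene_length: int = 1000
    gene_spacing: int = 10000
    alignment_length: int = 300          # amino acids
    gamma_alpha: float = 1.0
    outgroup_depths: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTGROUP_DEPTHS)
    )
    seed: int = 0

    def __post_init__(self):
        if not (self.t_root > self.t_wgd > self.t_spec > 0):
            raise ValueError("times must satisfy t_root > t_wgd > t_spec > 0")
        for p in (self.p_loss, self.p_collapse, self.p_nni):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for r in (self.rate_sturgeon, self.rate_outgroup, self.syn_rate):
            if r <= 0:
                raise ValueError("rates must be positive")

    @property
    def rate_paddlefish(self) -> float:
        return self.rate_sturgeon * self.rate_paddlefish_factor

    @property
    def rate_ancestral(self) -> float:
        return (self.rate_sturgeon + self.rate_paddlefish) / 2.0


@dataclass
class BlockTruth:
    block_id: int
    category: str                 # "PreSpec" | "PostSpec"
    r_shared: float | None        # rediploidization time if PreSpec
    r_sturgeon: float | None      # lineage times if PostSpec
    r_paddlefish: float | None
    chrom_pair: int


@dataclass
class FamilyTruth:
    family_id: str
    block_id: int
    category: str
    r_shared: float | None
    r_sturgeon: float | None
    r_paddlefish: float | None
    lost: bool = False
    collapsed: bool = False

    @property
    def genes(self) -> dict:
        f = self.family_id
        return {
            "Sturgeon": (f"{f}_sa", f"{f}_sb"),
            "Paddlefish": (f"{f}_pa", f"{f}_pb"),
        }

    @property
    def ortholog_pairs(self) -> tuple:
        """True cross-species ortholog pairing (A copies, B copies)."""
        f = self.family_id
        return ((f"{f}_sa", f"{f}_pa"), (f"{f}_sb", f"{f}_pb"))

    @property
    def is_quartet(self) -> bool:
        return not (self.lost or self.collapsed)


@dataclass
class SimTruth:
    config: SimConfig
    blocks: list
    families: list
    coords: pd.DataFrame
    chrom_lengths: dict


def _rng(seed_parts) -> np.random.Generator:
    return np.random.default_rng(list(seed_parts))


# ---------------------------------------------------------------------------
# block / truth simulation


def simulate_blocks(cfg: SimConfig) -> SimTruth:
    """Draw block-wise rediploidization times and lay genes on chromosomes.

    Per block one ancestral candidate time ``u`` is drawn; ``u > t_spec``
    makes the block PreSpec with shared time ``u``, otherwise the two
    lineages rediploidize independently at Uniform(0, t_spec) times and the
    block is PostSpec.  Genes are placed contiguously in block order on
    WGD-derived chromosome pairs (copy A on one member, copy B on the
    other), mirrored across the two species.
    """
    rng = _rng((cfg.seed, 1))
    lo = 0.0 if cfg.redip_low is None else cfg.redip_low
    hi = cfg.t_wgd if cfg.redip_high is None else cfg.redip_high
    if not (0.0 <= lo <= hi <= cfg.t_wgd):
        raise ValueError("rediploidization bounds must satisfy 0 <= low <= high <= t_wgd")

    blocks: list[BlockTruth] = []
    families: list[FamilyTruth] = []
    fam_counter = 0
    for b in range(cfg.n_blocks):
        u = float(rng.uniform(lo, hi)) if hi > lo else lo
        if u > cfg.t_spec:
            block = BlockTruth(b, "PreSpec", u, None, None, b % cfg.n_chrom_pairs)
        else:
            r_s = float(rng.uniform(0.0, cfg.t_spec))
            r_p = float(rng.uniform(0.0, cfg.t_spec))
            block = BlockTruth(b, "PostSpec", None, r_s, r_p, b % cfg.n_chrom_pairs)
        blocks.append(block)
        if isinstance(cfg.genes_per_block, tuple):
            n_genes = int(rng.integers(cfg.genes_per_block[0], cfg.genes_per_block[1] + 1))
        else:
            n_genes = int(cfg.genes_per_block)
        for _ in range(n_genes):
            fid = f"fam{fam_counter:05d}"
            fam_counter += 1
            families.append(
                FamilyTruth(
                    fid, b, block.category, block.r_shared,
                    block.r_sturgeon, block.r_paddlefish,
                )
            )
    coords, chrom_lengths = _layout_coords(cfg, blocks, families)
    return SimTruth(cfg, blocks, families, coords, chrom_lengths)


def _layout_coords(cfg: SimConfig, blocks, families) -> tuple[pd.DataFrame, dict]:
    cursors: dict[str, int] = {}
    rows = []
    by_block: dict[int, list] = {}
    for fam in families:
        by_block.setdefault(fam.block_id, []).append(fam)
    for block in blocks:
        for sp, prefix in (("Sturgeon", "stu"), ("Paddlefish", "pad")):
            chrom_a = f"{prefix}_chr{2 * block.chrom_pair + 1}"
            chrom_b = f"{prefix}_chr{2 * block.chrom_pair + 2}"
            for fam in by_block.get(block.block_id, ()):
                ga, gb = fam.genes[sp]
                for gene, chrom in ((ga, chrom_a), (gb, chrom_b)):
                    start = cursors.get(chrom, 0)
                    rows.append(
                        {
                            "gene_id": gene,
                            "species": sp,
                            "chrom": chrom,
                            "start": start,
                            "end": start + cfg.gene_length,
                        }
                    )
                    cursors[chrom] = start + cfg.gene_length + cfg.gene_spacing
    coords = pd.DataFrame(rows, columns=["gene_id", "species", "chrom", "start", "end"])
    return coords, dict(cursors)


# ---------------------------------------------------------------------------
# gene trees


class _N:
    """Minimal mutable tree node for Newick assembly."""

    __slots__ = ("children", "length", "label", "name")

    def __init__(self, name=None, length=0.0, label=None, children=None):
        self.name = name
        self.length = length
        self.label = label
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        lab = "" if self.label is None else str(self.label)
        return f"({inner}){lab}:{self.length:.6f}"


def _support(cfg: SimConfig, branch_length: float, rng) -> int:
    """Heuristic UFBoot stand-in: logistic in internal branch length."""
    x = (branch_length - cfg.support_b50) / cfg.support_scale
    base = 100.0 / (1.0 + math.exp(-min(max(x, -60.0), 60.0)))
    return int(round(min(100.0, max(0.0, base + rng.normal(0.0, cfg.support_noise_sd)))))


def _quartet_nodes(fam: FamilyTruth, cfg: SimConfig, rng) -> tuple[_N, float]:
    """Rooted quartet subtree with branch lengths (subst/site) and supports."""
    f = fam.family_id
    r_s, r_p, r_anc = cfg.rate_sturgeon, cfg.rate_paddlefish, cfg.rate_ancestral
    sa = _N(f"Sturgeon|{f}_sa")
    sb = _N(f"Sturgeon|{f}_sb")
    pa = _N(f"Paddlefish|{f}_pa")
    pb = _N(f"Paddlefish|{f}_pb")
    if fam.category == "PreSpec":
        internal = r_anc * (fam.r_shared - cfg.t_spec)
        for leaf, rate in ((sa, r_s), (sb, r_s), (pa, r_p), (pb, r_p)):
            leaf.length = rate * cfg.t_spec
        left = _N(children=[sa, pa], length=internal, label=_support(cfg, internal, rng))
        right = _N(children=[sb, pb], length=internal, label=_support(cfg, internal, rng))
        root = _N(children=[left, right])
        root_time = fam.r_shared
    else:
        int_s = r_s * (cfg.t_spec - fam.r_sturgeon)
        int_p = r_p * (cfg.t_spec - fam.r_paddlefish)
        sa.length = sb.length = r_s * fam.r_sturgeon
        pa.length = pb.length = r_p * fam.r_paddlefish
        left = _N(children=[sa, sb], length=int_s, label=_support(cfg, int_s, rng))
        right = _N(children=[pa, pb], length=int_p, label=_support(cfg, int_p, rng))
        root = _N(children=[left, right])
        root_time = cfg.t_spec
    return root, root_time


def _maybe_nni(root: _N, cfg: SimConfig, rng) -> bool:
    """With probability decaying in the shortest internal branch, apply one
    NNI inside the quartet, turning the balanced shape into a caterpillar."""
    if cfg.p_nni <= 0:
        return False
    left, right = root.children
    b_min = min(left.length, right.length)
    p = cfg.p_nni * math.exp(-b_min / cfg.nni_branch_scale)
    if rng.random() >= p:
        return False
    # swap one child of one internal node with the sibling subtree
    u, v = (left, right) if rng.random() < 0.5 else (right, left)
    x = u.children[int(rng.integers(0, 2))]
    u.children[u.children.index(x)] = v
    root.children = [u, x]
    # lengths keep their magnitudes; supports drop on the rearranged nodes
    for node in (u, v):
        if node.children:
            node.label = int(rng.integers(20, 81))
    return True


def simulate_gene_tree(fam: FamilyTruth, cfg: SimConfig) -> GeneFamilyTree:
    """Observed gene family tree: quartet (or triplet after loss/collapse)
    plus the outgroup scaffold of the species tree, with branch lengths and
    heuristic supports; optional NNI topology noise inside the quartet."""
    rng = _rng((cfg.seed, 2, int(fam.family_id[3:])))
    root, root_time = _quartet_nodes(fam, cfg, rng)
    _maybe_nni(root, cfg, rng)
    if not fam.is_quartet:
        root = _drop_paddlefish_copy(root, drop=f"Paddlefish|{fam.family_id}_pb")
    d = cfg.outgroup_depths
    r_o = cfg.rate_outgroup
    f = fam.family_id

    def leaf(sp, depth):
        return _N(f"{sp}|{sp.lower()}_{f}", r_o * depth)

    def inner(children, parent_depth, depth):
        return _N(children=children, length=r_o * (parent_depth - depth),
                  label=cfg.outgroup_support)

    root.length = cfg.rate_ancestral * (d["actinopteri"] - root_time)
    root.label = cfg.outgroup_support
    tele = inner([leaf("Zebrafish", d["teleostei"]), leaf("Fugu", d["teleostei"])],
                 d["neopterygii"], d["teleostei"])
    holo = inner([leaf("SpottedGar", d["holostei"]), leaf("Bowfin", d["holostei"])],
                 d["neopterygii"], d["holostei"])
    neo = inner([tele, holo], d["actinopteri"], d["neopterygii"])
    actinopteri = inner([root, neo], d["actinopterygii"], d["actinopteri"])
    actino = inner([leaf("Bichir", d["actinopterygii"]), actinopteri],
                   d["osteichthyes"], d["actinopterygii"])
    amniote = inner([leaf("Human", d["amniota"]), leaf("Chicken", d["amniota"])],
                    d["tetrapoda"], d["amniota"])
    tetra = inner([leaf("Frog", d["tetrapoda"]), amniote],
                  d["sarcopterygii"], d["tetrapoda"])
    sarc = inner([leaf("Coelacanth", d["sarcopterygii"]), tetra],
                 d["osteichthyes"], d["sarcopterygii"])
    osteich = inner([sarc, actino], d["root"], d["osteichthyes"])
    chond = inner([leaf("GhostShark", d["chondrichthyes"]),
                   leaf("WhaleShark", d["chondrichthyes"])],
                  d["root"], d["chondrichthyes"])
    top = _N(children=[chond, osteich])
    newick = f"({chond.newick()},{osteich.newick()});"
    return read_gene_tree(newick, family_id=f, rooted=False)


def _drop_paddlefish_copy(root: _N, drop: str) -> _N:
    """Remove one paddlefish leaf, suppressing the resulting unifurcation."""

    def prune(node: _N) -> _N | None:
        if not node.children:
            return None if node.name == drop else node
        kids = [prune(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if len(kids) == len(node.children):
            node.children = kids
            return node
        if len(kids) == 1:
            child = kids[0]
            child.length += node.length
            return child
        node.children = kids
        return node

    out = prune(root)
    assert out is not None
    return out


def family_time_tree(fam: FamilyTruth, cfg: SimConfig) -> GeneFamilyTree:
    """True quartet subtree with branch lengths in TIME units (for codon
    simulation; no topology noise, no outgroups)."""
    f = fam.family_id
    sa = _N(f"Sturgeon|{f}_sa")
    sb = _N(f"Sturgeon|{f}_sb")
    pa = _N(f"Paddlefish|{f}_pa")
    pb = _N(f"Paddlefish|{f}_pb")
    if fam.category == "PreSpec":
        span = fam.r_shared - cfg.t_spec
        for leaf in (sa, sb, pa, pb):
            leaf.length = cfg.t_spec
        left = _N(children=[sa, pa], length=span)
        right = _N(children=[sb, pb], length=span)
    else:
        sa.length = sb.length = fam.r_sturgeon
        pa.length = pb.length = fam.r_paddlefish
        left = _N(children=[sa, sb], length=cfg.t_spec - fam.r_sturgeon)
        right = _N(children=[pa, pb], length=cfg.t_spec - fam.r_paddlefish)
    newick = f"({left.newick()},{right.newick()});"
    return read_gene_tree(newick, family_id=f, rooted=True)


# ---------------------------------------------------------------------------
# sequences


SENSE_CODONS = tuple(c for c, aa in GENETIC_CODE.items() if aa != "*")


def simulate_sequences(
    tree: GeneFamilyTree,
    length: int,
    model: AminoAcidModel | None = None,
    seed: int = 0,
    mode: str = "aa",
    alpha: float | None = None,
    syn_rate: float | None = None,
    nonsyn_rate: float | None = None,
) -> dict[str, str]:
    """Evolve sequences down a gene tree; returns ``{leaf label: sequence}``.

    ``aa`` mode: branch lengths are substitutions/site; the root sequence is
    drawn from the model's stationary frequencies and evolved with the
    model's transition matrices, optionally with discrete-gamma rate
    variation across sites (``alpha``).

    ``codon`` mode: branch lengths are TIME spans; each codon evolves by a
    jump process in which every single-nucleotide change to a sense codon
    carries rate ``syn_rate/3`` if synonymous and ``nonsyn_rate/3``
    otherwise, so the realised pairwise Ks of two tips tracks
    ``syn_rate x (time to their common ancestor) x 2``.
    """
    if length < 1:
        raise ValueError("sequence length must be positive")
    rng = np.random.default_rng(seed)
    if mode == "aa":
        return _simulate_aa(tree, length, model or jtt_model(), alpha, rng)
    if mode == "codon":
        sr = syn_rate if syn_rate is not None else 0.12
        nr = nonsyn_rate if nonsyn_rate is not None else 0.024
        return _simulate_codon(tree, length, sr, nr, rng)
    raise ValueError(f"unknown mode {mode!r}")


def _simulate_aa(tree, length, model, alpha, rng) -> dict[str, str]:
    dtree = tree.tree if isinstance(tree, GeneFamilyTree) else tree
    if alpha is None:
        rates = np.ones(length)
    else:
        cats = discrete_gamma_rates(alpha, 4)
        rates = cats[rng.integers(0, 4, size=length)]
    aa = "ARNDCQEGHILKMFPSTWYV"
    seqs: dict[int, np.ndarray] = {}
    out: dict[str, str] = {}
    root = dtree.seed_node
    seqs[id(root)] = rng.choice(20, size=length, p=model.freqs)
    for node in dtree.preorder_node_iter():
        if node is root:
            pass
        else:
            parent_seq = seqs[id(node.parent_node)]
            bl = node.edge.length or 0.0
            child = parent_seq.copy()
            if bl > 0:
                # group sites by rate for vectorised transition sampling
                for r in np.unique(rates):
                    P = model.transition_matrix(bl * r)
                    cum = np.cumsum(P, axis=1)
                    idx = np.nonzero(rates == r)[0]
                    u = rng.random(idx.size)
                    child[idx] = (
                        cum[parent_seq[idx]] < u[:, None]
                    ).sum(axis=1)
            seqs[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = "".join(aa[s] for s in seqs[id(node)])
    return out


from functools import lru_cache


@lru_cache(maxsize=None)
def _codon_neighbor_rates(codon: str, syn_rate: float, nonsyn_rate: float):
    aa = GENETIC_CODE[codon]
    neigh, rates = [], []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            alt_aa = GENETIC_CODE[alt]
            if alt_aa == "*":
                continue
            neigh.append(alt)
            rates.append(syn_rate / 3.0 if alt_aa == aa else nonsyn_rate / 3.0)
    return neigh, np.asarray(rates)


def _evolve_codon(codon: str, t: float, syn_rate, nonsyn_rate, rng) -> str:
    clock = 0.0
    while True:
        neigh, rates = _codon_neighbor_rates(codon, syn_rate, nonsyn_rate)
        total = rates.sum()
        clock += rng.exponential(1.0 / total)
        if clock >= t:
            return codon
        codon = neigh[int(rng.choice(len(neigh), p=rates / total))]


def _simulate_codon(tree, n_codons, syn_rate, nonsyn_rate, rng) -> dict[str, str]:
    dtree = tree.tree if isinstance(tree, GeneFamilyTree) else tree
    root = dtree.seed_node
    seqs: dict[int, list] = {
        id(root): [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    }
    out: dict[str, str] = {}
    for node in dtree.preorder_node_iter():
        if node is not root:
            parent = seqs[id(node.parent_node)]
            t = node.edge.length or 0.0
            if t > 0:
                seqs[id(node)] = [
                    _evolve_codon(c, t, syn_rate, nonsyn_rate, rng) for c in parent
                ]
            else:
                seqs[id(node)] = list(parent)
        if node.is_leaf():
            out[node.taxon.label] = "".join(seqs[id(node)])
    return out


# ---------------------------------------------------------------------------
# observables: loss, collapse, depth, coordinates


def simulate_observables(truth: SimTruth) -> dict:
    """Apply ohnolog loss and assembly collapse, fabricate per-gene depths.

    Loss removes one paddlefish copy (the family becomes a triplet at 1x
    depth); collapse — possible only for PostSpec families whose paddlefish
    rediploidization is more recent than ``collapse_recency`` — merges the
    two paddlefish copies into one gene observed at 2x depth.  All other
    genes sit on the 1x peak with Gaussian noise.  Returns the updated
    coordinate table, the depth table (gene_id, label, depth) and the
    per-family edits (also recorded on the FamilyTruth entries).
    """
    cfg = truth.config
    rng = _rng((cfg.seed, 3))
    recency = cfg.collapse_recency if cfg.collapse_recency is not None else cfg.t_spec / 2.0
    drop_genes: set[str] = set()
    depth_rows = []
    for fam in truth.families:
        fam.lost = False
        fam.collapsed = False
        if cfg.p_loss > 0 and rng.random() < cfg.p_loss:
            fam.lost = True
        elif (
            cfg.p_collapse > 0
            and fam.category == "PostSpec"
            and fam.r_paddlefish is not None
            and fam.r_paddlefish < recency
            and rng.random() < cfg.p_collapse
        ):
            fam.collapsed = True
        pa, pb = fam.genes["Paddlefish"]
        if fam.lost:
            drop_genes.add(pb)
            label = (
                "single_copy_PreSpecType"
                if fam.category == "PreSpec"
                else "single_copy_PostSpecType"
            )
            depth_rows.append((pa, label, rng.normal(cfg.depth_mean, cfg.depth_sd)))
        elif fam.collapsed:
            drop_genes.add(pb)
            depth_rows.append(
                (
                    pa,
                    "single_copy_PostSpecType",
                    rng.normal(2.0 * cfg.depth_mean, cfg.depth_sd * math.sqrt(2.0)),
                )
            )
        else:
            for g in (pa, pb):
                depth_rows.append((g, "two_copy_pair", rng.normal(cfg.depth_mean, cfg.depth_sd)))
    coords = truth.coords[~truth.coords["gene_id"].isin(drop_genes)].reset_index(drop=True)
    depth = pd.DataFrame(depth_rows, columns=["gene_id", "label", "depth"])
    depth["depth"] = depth["depth"].clip(lower=0.0)
    return {"coords": coords, "depth": depth, "n_lost": sum(f.lost for f in truth.families),
            "n_collapsed": sum(f.collapsed for f in truth.families)}


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(cfg: SimConfig) -> dict:
    """Simulate truth, observables and all gene trees in one call."""
    truth = simulate_blocks(cfg)
    obs = simulate_observables(truth)
    trees = {fam.family_id: simulate_gene_tree(fam, cfg) for fam in truth.families}
    return {"truth": truth, "trees": trees, **obs}
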