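"""End-to-end orchestration: simulate (or load) -> classify -> validate ->
Ks -> synteny -> coverage -> supermatrix, with one structured report.

Every stage is a pure function of (inputs, config, seed); all randomness
derives from the master seed via fixed per-stage substreams, so a rerun
with the same configuration reproduces the report exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import autest, coverage, ks, supermatrix, synteny
from .simulate import SimConfig, family_time_tree, simulate_dataset, simulate_sequences
from .species import CHONDRICHTHYES, SpeciesTree, TELEOSTEI, TETRAPODA
from .treeproc import (
    GeneFamilyTree,
    TopologyCall,
    clade_recovery,
    classify_family,
    counts_by_cutoff,
)

__all__ = ["PipelineConfig", "RunReport", "run"]


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run (simulation + analysis stages)."""

    sim: SimConfig = field(default_factory=SimConfig)
    cutoffs: Sequence[int] = (0, 50, 75, 95, 100)
    au_alpha: float = 0.05
    au_scales: Sequence[float] = autest.DEFAULT_SCALES
    au_replicates: int = 1000
    n_au_families: int = 8        # AU likelihoods are the expensive stage
    n_ks_families: int = 120
    ks_codons: int = 200
    max_ks: float = 0.3
    min_block_genes: int = 3
    max_block_gap: int = 1
    n_synteny_perm: int = 1000
    depth_threshold_factor: float = 1.5
    n_concat_replicates: int = 5
    max_dating_families: int = 30
    seed: int = 0


@dataclass
class RunReport:
    config: PipelineConfig
    classification: pd.DataFrame
    counts: pd.DataFrame
    clade_recovery: pd.DataFrame
    au_rejections: dict
    ks_summary: dict
    ks_records: pd.DataFrame
    blocks: list
    clustering: pd.DataFrame
    coverage: dict
    dating: dict

    def to_dict(self) -> dict:
        """JSON-ready digest (tables flattened to records)."""
        return {
            "counts": self.counts.to_dict(orient="records"),
            "clade_recovery": self.clade_recovery.to_dict(orient="records"),
            "au_rejections": self.au_rejections,
            "ks_summary": {
                str(k): {kk: vv for kk, vv in v.items() if kk not in ("density", "grid")}
                for k, v in self.ks_summary.items()
            },
            "n_blocks": len(self.blocks),
            "clustering": self.clustering.to_dict(orient="records"),
            "coverage": self.coverage,
            "dating": self.dating,
            "seed": self.config.seed,
        }


def _sub_seed(seed: int, stage: int, item: int = 0) -> int:
    return int(np.random.SeedSequence([seed, stage, item]).generate_state(1)[0] % (2**31))


def run(config: PipelineConfig, out_dir: str | None = None) -> RunReport:
    """Execute every stage on a freshly simulated dataset."""
    cfg = dataclasses.replace(config.sim, seed=config.seed)
    dataset = simulate_dataset(cfg)
    truth = dataset["truth"]
    trees: Mapping[str, GeneFamilyTree] = dataset["trees"]
    sp_tree = SpeciesTree()

    # --- classification ------------------------------------------------
    calls: list[TopologyCall] = []
    truth_by_id = {f.family_id: f for f in truth.families}
    for fid in sorted(trees):
        calls.append(classify_family(trees[fid], sp_tree))
    quartet_calls = [c for c in calls if truth_by_id[c.family_id].is_quartet]
    classification = pd.DataFrame(
        {
            "family_id": c.family_id,
            "rooted_category": c.rooted_category,
            "unrooted_type": c.unrooted_type or "NA",
            "support_min": c.support_min,
            "true_category": truth_by_id[c.family_id].category,
            "otherwise_single_copy": True,  # the simulator keeps outgroups single copy
        }
        for c in calls
    )
    counts = counts_by_cutoff(quartet_calls, config.cutoffs)

    # --- control clades -------------------------------------------------
    clade_rows = []
    for c in quartet_calls:
        gft = trees[c.family_id]
        for name, members in (
            ("Tetrapoda", TETRAPODA),
            ("Teleostei", TELEOSTEI),
            ("Chondrichthyes", CHONDRICHTHYES),
        ):
            res = clade_recovery(gft, members)
            clade_rows.append(
                {
                    "family_id": c.family_id,
                    "rooted_category": c.rooted_category,
                    "clade": name,
                    "recovered": res,
                }
            )
    clade_df = pd.DataFrame(clade_rows)

    # --- AU tests on a seeded subsample ---------------------------------
    rng = np.random.default_rng(_sub_seed(config.seed, 10))
    main = [c for c in quartet_calls if c.rooted_category in ("PreSpec", "PostSpec")]
    chosen = list(rng.permutation([c.family_id for c in main]))[: config.n_au_families]
    grouped: dict[str, list] = {}
    for i, fid in enumerate(sorted(chosen)):
        call = next(c for c in calls if c.family_id == fid)
        seqs = simulate_sequences(
            trees[fid],
            config.sim.alignment_length,
            seed=_sub_seed(config.seed, 11, i),
            alpha=config.sim.gamma_alpha,
        )
        focal = {k: v for k, v in seqs.items() if k.split("|")[0] in ("Sturgeon", "Paddlefish")}
        aln = sorted(focal.items())
        sll = autest.quartet_site_likelihoods(aln)
        res = autest.au_test(
            sll, config.au_scales, config.au_replicates, seed=_sub_seed(config.seed, 12, i)
        )
        names = [n for n, _ in aln]
        species_of = {n: n.split("|")[0] for n in names}
        type_of = {
            autest.split_id(names, s): autest.split_unrooted_type(names, s, species_of)
            for s in autest.QUARTET_SPLITS
        }
        grouped.setdefault(call.rooted_category, []).append((res, type_of))
    au_rej = autest.summarize_rejections(grouped, config.au_alpha) if grouped else {}

    # --- Ks --------------------------------------------------------------
    rng = np.random.default_rng(_sub_seed(config.seed, 20))
    quartet_fams = [f for f in truth.families if f.is_quartet]
    ks_pick = list(rng.permutation([f.family_id for f in quartet_fams]))[: config.n_ks_families]
    call_by_id = {c.family_id: c for c in calls}
    ks_families = []
    for i, fid in enumerate(sorted(ks_pick)):
        fam = truth_by_id[fid]
        cds = simulate_sequences(
            family_time_tree(fam, cfg),
            config.ks_codons,
            seed=_sub_seed(config.seed, 21, i),
            mode="codon",
            syn_rate=cfg.syn_rate,
            nonsyn_rate=cfg.nonsyn_rate,
        )
        label = lambda sp, g: f"{sp}|{g}"
        (sa, sb), (pa, pb) = fam.genes["Sturgeon"], fam.genes["Paddlefish"]
        ortho = tuple(
            ((sg, cds[label("Sturgeon", sg)]), (pg, cds[label("Paddlefish", pg)]))
            for sg, pg in fam.ortholog_pairs
        )
        ks_families.append(
            ks.KsFamily(
                family_id=fid,
                rooted_category=call_by_id[fid].rooted_category,
                sturgeon_pair=((sa, cds[label("Sturgeon", sa)]), (sb, cds[label("Sturgeon", sb)])),
                paddlefish_pair=((pa, cds[label("Paddlefish", pa)]), (pb, cds[label("Paddlefish", pb)])),
                ortholog_pairs=ortho if call_by_id[fid].rooted_category == "PreSpec" else (),
            )
        )
    ks_records = ks.build_ks_datasets(ks_families, max_ks=config.max_ks)
    ks_sum = ks.ks_summary(ks_records) if not ks_records.empty else {}

    # --- synteny ---------------------------------------------------------
    main_df = classification[
        classification["rooted_category"].isin(["PreSpec", "PostSpec"])
        & classification["family_id"].isin([f.family_id for f in quartet_fams])
    ]
    quartets = {
        f.family_id: {
            "Sturgeon": list(f.genes["Sturgeon"]),
            "Paddlefish": list(f.genes["Paddlefish"]),
            "orthologs": list(f.ortholog_pairs),
        }
        for f in quartet_fams
    }
    links = synteny.build_links(main_df, dataset["coords"], mode="intra", quartets=quartets)
    blocks = synteny.detect_blocks(links, config.min_block_genes, config.max_block_gap)
    clus_rows = []
    stu_links = links[links["species_a"] == "Sturgeon"].sort_values(["chrom_a", "pos_a"])
    for i, (chrom, grp) in enumerate(stu_links.groupby("chrom_a", sort=True)):
        res = synteny.clustering_permutation_test(
            grp["rooted_category"].tolist(),
            config.n_synteny_perm,
            seed=_sub_seed(config.seed, 30, i),
        )
        clus_rows.append({"chrom": chrom, **res})
    clustering = pd.DataFrame(clus_rows)

    # --- coverage --------------------------------------------------------
    depth = dataset["depth"]
    two_copy = depth[depth["label"] == "two_copy_pair"]["depth"]
    cov: dict = {}
    if len(two_copy) >= 10:
        ref = coverage.modal_depth(two_copy)
        cov["reference_mode"] = ref
        for lab in ("two_copy_pair", "single_copy_PostSpecType", "single_copy_PreSpecType"):
            sub = depth[depth["label"] == lab]
            if sub.empty:
                cov[f"double_fraction_{lab}"] = None
                continue
            _, frac = coverage.classify_collapsed(
                pd.Series(sub["depth"].to_numpy(), index=sub["gene_id"]),
                ref,
                config.depth_threshold_factor,
            )
            cov[f"double_fraction_{lab}"] = frac

    # --- supermatrix -----------------------------------------------------
    dating_df = supermatrix.select_dating_families(classification)
    dating_ids = sorted(
        fid for fid in dating_df["family_id"] if truth_by_id[fid].is_quartet
    )[: config.max_dating_families]
    dating_families = []
    for i, fid in enumerate(dating_ids):
        seqs = simulate_sequences(
            trees[fid],
            config.sim.alignment_length,
            seed=_sub_seed(config.seed, 40, i),
            alpha=config.sim.gamma_alpha,
        )
        fam = truth_by_id[fid]
        (sa, sb), (pa, pb) = fam.genes["Sturgeon"], fam.genes["Paddlefish"]
        outgroups = {
            k.split("|")[0]: v
            for k, v in seqs.items()
            if k.split("|")[0] not in ("Sturgeon", "Paddlefish")
        }
        dating_families.append(
            supermatrix.DatingFamily(
                family_id=fid,
                pair_1={"Sturgeon": seqs[f"Sturgeon|{sa}"], "Paddlefish": seqs[f"Paddlefish|{pa}"]},
                pair_2={"Sturgeon": seqs[f"Sturgeon|{sb}"], "Paddlefish": seqs[f"Paddlefish|{pb}"]},
                outgroups=outgroups,
            )
        )
    dating: dict = {"n_selected": int(len(dating_df)), "n_used": len(dating_families)}
    if dating_families:
        mats = supermatrix.shuffle_concat(
            dating_families, config.n_concat_replicates, seed=_sub_seed(config.seed, 41)
        )
        trimmed0 = supermatrix.trim_gapped_columns(mats[0][0], mats[0][1])
        dating.update(
            {
                "n_replicates": len(mats),
                "columns_before": mats[0][1].columns_before,
                "columns_after": mats[0][1].columns_after,
                "taxa": sorted(trimmed0),
            }
        )

    report = RunReport(
        config=config,
        classification=classification,
        counts=counts,
        clade_recovery=clade_df,
        au_rejections=au_rej,
        ks_summary=ks_sum,
        ks_records=ks_records,
        blocks=blocks,
        clustering=clustering,
        coverage=cov,
        dating=dating,
    )
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _write_report(report: RunReport, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    report.classification.to_csv(os.path.join(out_dir, "classification.tsv"), sep="\t", index=False)
    report.counts.to_csv(os.path.join(out_dir, "category_counts.tsv"), sep="\t", index=False)
    report.clade_recovery.to_csv(os.path.join(out_dir, "clade_recovery.tsv"), sep="\t", index=False)
    report.ks_records.to_csv(os.path.join(out_dir, "ks_records.tsv"), sep="\t", index=False)
    report.clustering.to_csv(os.path.join(out_dir, "synteny_clustering.tsv"), sep="\t", index=False)
    block_rows = [dataclasses.asdict(b) for b in report.blocks]
    pd.DataFrame(block_rows).to_csv(os.path.join(out_dir, "synteny_blocks.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=str)
    with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
        fh.write(_summary_text(report))


def _summary_text(report: RunReport) -> str:
    lines = ["ohnolog quartet classification by UFBoot cutoff", ""]
    lines.append(report.counts.to_string(index=False))
    lines.append("")
    if report.coverage:
        lines.append("read-depth double fractions:")
        for k, v in report.coverage.items():
            lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append(f"dating families: {report.dating}")
    return "\n".join(lines) + "\n"
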