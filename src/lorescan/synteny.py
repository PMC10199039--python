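"""Chromosomal layout of classified ohnolog pairs: links, blocks, clustering.

Rediploidization proceeds block-wise, so neighbouring genes share a
rediploidization history and gene-tree category.  This module lays
classified ohnolog pairs onto chromosomes as circos-style links, detects
contiguous same-category runs ("synteny blocks"), and tests whether
categories cluster along chromosomes more than a random shuffle would
allow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntenyBlock",
    "build_links",
    "detect_blocks",
    "clustering_permutation_test",
    "write_circos_links",
    "write_karyotype",
]


@dataclass
class SyntenyBlock:
    species: str
    chrom_a: str
    chrom_b: str
    category: str
    n_genes: int
    start_a: float
    end_a: float
    start_b: float
    end_b: float
    family_ids: tuple


def _midpoint(row) -> float:
    return (row["start"] + row["end"]) / 2.0


def build_links(
    classified: pd.DataFrame,
    coords: pd.DataFrame,
    mode: str = "intra",
    quartets: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
) -> pd.DataFrame:
    """Link table of classified families on chromosome coordinates.

    ``classified`` needs family_id and rooted_category; ``coords`` needs
    gene_id, species, chrom, start, end; ``quartets`` maps family_id to
    ``{"Sturgeon": [geneA, geneB], "Paddlefish": [geneA, geneB],
    "orthologs": [(s_gene, p_gene), (s_gene, p_gene)]}`` (ortholog pairing
    from the gene-tree cherries, present for PreSpec families).

    Modes: ``intra`` — one within-species ohnolog link per species per
    family; ``inter`` — the two cross-species ortholog links of each PreSpec
    family; ``combined`` — PostSpec families contribute intra links and
    PreSpec families inter links (the mixed view used to contrast shared vs
    independent duplications).
    """
    if mode not in {"intra", "inter", "combined"}:
        raise ValueError(f"unknown mode {mode!r}")
    table = coords.set_index("gene_id")
    rows = []

    def link(fid, cat, scope, species, ga, gb):
        ra, rb = table.loc[ga], table.loc[gb]
        rows.append(
            {
                "family_id": fid,
                "rooted_category": cat,
                "scope": scope,
                "species_a": ra["species"],
                "chrom_a": ra["chrom"],
                "pos_a": _midpoint(ra),
                "gene_a": ga,
                "species_b": rb["species"],
                "chrom_b": rb["chrom"],
                "pos_b": _midpoint(rb),
                "gene_b": gb,
            }
        )

    for _, fam in classified.iterrows():
        fid, cat = fam["family_id"], fam["rooted_category"]
        info = quartets[fid]
        want_intra = mode == "intra" or (mode == "combined" and cat != "PreSpec")
        want_inter = (mode == "inter" or (mode == "combined" and cat == "PreSpec")) and cat == "PreSpec"
        if want_intra:
            for sp in ("Sturgeon", "Paddlefish"):
                ga, gb = info[sp]
                link(fid, cat, "intra", sp, ga, gb)
        if want_inter:
            for ga, gb in info["orthologs"]:
                link(fid, cat, "inter", "both", ga, gb)
    return pd.DataFrame(
        rows,
        columns=[
            "family_id", "rooted_category", "scope",
            "species_a", "chrom_a", "pos_a", "gene_a",
            "species_b", "chrom_b", "pos_b", "gene_b",
        ],
    )


def detect_blocks(
    links: pd.DataFrame, min_genes: int = 3, max_gap: int = 1
) -> list[SyntenyBlock]:
    """Maximal same-category runs of links on each chromosome pair.

    Links are grouped by (species_a, chrom_a, chrom_b), ordered along
    ``pos_a``, and scanned for runs of one category tolerating up to
    ``max_gap`` interleaved links of other categories; runs of at least
    ``min_genes`` become blocks.  Input order is irrelevant (sorted
    internally); output is deterministic.
    """
    blocks: list[SyntenyBlock] = []
    if links.empty:
        return blocks
    ordered = links.sort_values(["species_a", "chrom_a", "chrom_b", "pos_a", "family_id"])
    for (sp, ca, cb), grp in ordered.groupby(["species_a", "chrom_a", "chrom_b"], sort=True):
        cats = grp["rooted_category"].tolist()
        idx = grp.index.tolist()
        i = 0
        n = len(cats)
        while i < n:
            cat = cats[i]
            members = [i]
            gap = 0
            j = i + 1
            while j < n:
                if cats[j] == cat:
                    members.append(j)
                    gap = 0
                else:
                    gap += 1
                    if gap > max_gap:
                        break
                j += 1
            if len(members) >= min_genes:
                sel = grp.loc[[idx[m] for m in members]]
                blocks.append(
                    SyntenyBlock(
                        species=sp,
                        chrom_a=ca,
                        chrom_b=cb,
                        category=cat,
                        n_genes=len(members),
                        start_a=float(sel["pos_a"].min()),
                        end_a=float(sel["pos_a"].max()),
                        start_b=float(sel["pos_b"].min()),
                        end_b=float(sel["pos_b"].max()),
                        family_ids=tuple(sel["family_id"]),
                    )
                )
                i = members[-1] + 1
            else:
                i += 1
    return blocks


def clustering_permutation_test(
    labels: Sequence[str], n_perm: int = 1000, seed: int = 0
) -> dict:
    """Are same-category genes adjacent more often than a random shuffle?

    Statistic: number of adjacent same-label pairs in chromosome gene
    order.  Null: uniformly random label permutations.  One-sided
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    labels = list(labels)
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    if len(set(labels)) < 2 or len(labels) < 2:
        return {"observed_statistic": _adjacent_same(labels), "p_value": 1.0}
    obs = _adjacent_same(labels)
    rng = np.random.default_rng(seed)
    arr = np.array(labels)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(arr)
        if _adjacent_same(perm) >= obs:
            hits += 1
    return {"observed_statistic": obs, "p_value": (1 + hits) / (1 + n_perm)}


def _adjacent_same(labels) -> int:
    arr = np.asarray(labels)
    return int((arr[:-1] == arr[1:]).sum())


# ---------------------------------------------------------------------------
# circos-format writers


def write_circos_links(links: pd.DataFrame, path, half_width: float = 500.0) -> None:
    """Circos link file: ``chrom start end chrom start end`` per line, link
    anchors centred on gene midpoints."""
    with open(path, "w") as fh:
        for _, row in links.iterrows():
            a0 = max(0, int(row["pos_a"] - half_width))
            a1 = int(row["pos_a"] + half_width)
            b0 = max(0, int(row["pos_b"] - half_width))
            b1 = int(row["pos_b"] + half_width)
            fh.write(
                f"{row['chrom_a']} {a0} {a1} {row['chrom_b']} {b0} {b1} "
                f"category={row['rooted_category']}\n"
            )


def write_karyotype(
    chrom_lengths: Mapping[str, int], path, species: str = "", min_label_mb: float = 20.0
) -> None:
    """Circos karyotype file; chromosomes under ``min_label_mb`` megabases
    get no label (microchromosome convention of the circos figures)."""
    with open(path, "w") as fh:
        for chrom, length in sorted(chrom_lengths.items()):
            label = chrom if length >= min_label_mb * 1e6 else "-"
            fh.write(f"chr - {chrom} {label} 0 {int(length)} grey\n")
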