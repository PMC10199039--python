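"""Readers/writers for the plain-text formats the pipeline consumes.

Gene trees travel as Newick with integer supports on internal-node labels;
alignments and coding sequences as FASTA; coordinates as a BED-like TSV
(gene_id, species, chrom, start, end); per-gene depth as a TSV (gene_id,
label, depth) shaped like a reduced mosdepth regions summary.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .treeproc import GeneFamilyTree, read_gene_tree

__all__ = [
    "read_gene_trees",
    "write_gene_trees",
    "read_coords",
    "write_coords",
    "read_depth",
    "write_depth",
    "read_fasta",
    "write_fasta",
    "write_dataset",
]


def read_gene_trees(path) -> list[GeneFamilyTree]:
    """One family per line: ``family_id<TAB>newick``."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            fid, newick = line.split("\t", 1)
            out.append(read_gene_tree(newick, family_id=fid))
    return out


def write_gene_trees(trees: Mapping[str, GeneFamilyTree] | Iterable[GeneFamilyTree], path) -> None:
    items = trees.values() if isinstance(trees, Mapping) else trees
    with open(path, "w") as fh:
        for gft in items:
            newick = gft.tree.as_string(schema="newick", unquoted_underscores=True).strip()
            if newick.startswith("[&R] ") or newick.startswith("[&U] "):
                newick = newick[5:]
            fh.write(f"{gft.family_id}\t{newick}\n")


def read_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "species", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table lacks columns {sorted(missing)}")
    return df


def write_coords(coords: pd.DataFrame, path) -> None:
    coords.to_csv(path, sep="\t", index=False)


def read_depth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "depth"} <= set(df.columns):
        raise ValueError("depth table needs gene_id and depth columns")
    return df


def write_depth(depth: pd.DataFrame, path) -> None:
    depth.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_dataset(dataset: dict, out_dir) -> None:
    """Write a simulated dataset (trees, coordinates, depths, truth)."""
    os.makedirs(out_dir, exist_ok=True)
    write_gene_trees(dataset["trees"], os.path.join(out_dir, "gene_trees.tsv"))
    write_coords(dataset["coords"], os.path.join(out_dir, "coords.tsv"))
    write_depth(dataset["depth"], os.path.join(out_dir, "depth.tsv"))
    truth = dataset["truth"]
    rows = [
        {
            "family_id": f.family_id,
            "block_id": f.block_id,
            "category": f.category,
            "r_shared": f.r_shared,
            "r_sturgeon": f.r_sturgeon,
            "r_paddlefish": f.r_paddlefish,
            "lost": f.lost,
            "collapsed": f.collapsed,
        }
        for f in truth.families
    ]
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
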