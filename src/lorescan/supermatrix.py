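"""Phylogenomic dating input preparation: A/B shuffling, concatenation,
no-gaps trimming.

A lower bound on the WGD date comes from the families that rediploidized
before speciation: PreSpec families at maximal support.  Each such family
holds two ohnolog pairs; which pair is called "A" and which "B" is
arbitrary, so several supermatrices are built with independent random A/B
assignments and the dating (performed externally) is checked for robustness
across them.  Concatenated matrices are trimmed to gap-free columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DatingFamily",
    "ConcatenationRecord",
    "select_dating_families",
    "shuffle_concat",
    "trim_gapped_columns",
    "write_phylip",
    "write_fasta",
]

GAP_CHARS = set("-.?Xx")


@dataclass
class DatingFamily:
    """Aligned sequences of one maximal-support PreSpec family.

    ``pair_1`` and ``pair_2`` are the two ohnolog pairs (each a mapping
    ``{"Sturgeon": seq, "Paddlefish": seq}``) as read off the two
    mixed-species cherries of the gene tree; ``outgroups`` maps single-copy
    outgroup species to their aligned sequences.
    """

    family_id: str
    pair_1: Mapping[str, str]
    pair_2: Mapping[str, str]
    outgroups: Mapping[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(next(iter(self.pair_1.values())))


@dataclass
class ConcatenationRecord:
    replicate: int
    seed: int
    assignment: dict            # family_id -> "12" (pair_1 is A) or "21"
    partitions: dict            # family_id -> (start, end), 0-based half-open
    columns_before: int
    columns_after: int
    dropped_families: tuple = ()


def select_dating_families(classified: pd.DataFrame) -> pd.DataFrame:
    """PreSpec families with both quartet supports at 100 and no duplicate
    genes in any other species.

    ``classified`` needs columns rooted_category, support_min and
    ``otherwise_single_copy`` (no second copy in any non-focal species).
    """
    mask = (
        (classified["rooted_category"] == "PreSpec")
        & (classified["support_min"] >= 100)
        & classified["otherwise_single_copy"].astype(bool)
    )
    return classified[mask].reset_index(drop=True)


def shuffle_concat(
    families: Sequence[DatingFamily],
    n_replicates: int = 5,
    seed: int = 0,
    outgroup_species: Sequence[str] | None = None,
) -> list[tuple[dict, ConcatenationRecord]]:
    """Concatenated supermatrices with random per-family A/B assignment.

    Per replicate and family a fair coin (seeded) decides which ohnolog
    pair becomes the "A" copy; rows are SturgeonA/PaddlefishA/SturgeonB/
    PaddlefishB plus the requested single-copy outgroups.  Families missing
    a required sequence are dropped (recorded on the replicate record).
    Returns ``(supermatrix, record)`` per replicate, the supermatrix as an
    ordered ``{taxon: sequence}`` mapping; replicates differ only in the
    assignments.
    """
    if outgroup_species is None:
        outgroup_species = sorted(
            set().union(*(set(f.outgroups) for f in families)) if families else ()
        )
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_replicates):
        taxa = ["SturgeonA", "PaddlefishA", "SturgeonB", "PaddlefishB"] + list(outgroup_species)
        chunks: dict[str, list[str]] = {t: [] for t in taxa}
        assignment: dict[str, str] = {}
        partitions: dict[str, tuple[int, int]] = {}
        dropped = []
        col = 0
        for fam in families:
            missing = [sp for sp in outgroup_species if sp not in fam.outgroups]
            if missing or not all(
                sp in pair for pair in (fam.pair_1, fam.pair_2)
                for sp in ("Sturgeon", "Paddlefish")
            ):
                dropped.append(fam.family_id)
                rng.integers(0, 2)  # keep the coin stream aligned across reruns
                continue
            flip = bool(rng.integers(0, 2))
            a_pair, b_pair = (fam.pair_2, fam.pair_1) if flip else (fam.pair_1, fam.pair_2)
            assignment[fam.family_id] = "21" if flip else "12"
            chunks["SturgeonA"].append(a_pair["Sturgeon"])
            chunks["PaddlefishA"].append(a_pair["Paddlefish"])
            chunks["SturgeonB"].append(b_pair["Sturgeon"])
            chunks["PaddlefishB"].append(b_pair["Paddlefish"])
            for sp in outgroup_species:
                chunks[sp].append(fam.outgroups[sp])
            partitions[fam.family_id] = (col, col + fam.length)
            col += fam.length
        matrix = {t: "".join(parts) for t, parts in chunks.items()}
        record = ConcatenationRecord(
            replicate=rep,
            seed=seed,
            assignment=assignment,
            partitions=partitions,
            columns_before=col,
            columns_after=col,
            dropped_families=tuple(dropped),
        )
        out.append((matrix, record))
    return out


def trim_gapped_columns(
    alignment: Mapping[str, str], record: ConcatenationRecord | None = None
) -> dict:
    """Remove every column containing a gap or missing character.

    The no-gaps trimming applied to dating supermatrices; idempotent.  When
    a :class:`ConcatenationRecord` is given its ``columns_after`` is
    updated.
    """
    taxa = list(alignment)
    if not taxa:
        raise ValueError("empty alignment")
    mat = np.array([list(alignment[t]) for t in taxa])
    if mat.ndim != 2:
        raise ValueError("alignment must be rectangular")
    keep = ~np.isin(mat, list(GAP_CHARS)).any(axis=0)
    trimmed = {t: "".join(mat[i, keep]) for i, t in enumerate(taxa)}
    if record is not None:
        record.columns_after = int(keep.sum())
    if keep.sum() == 0:
        import warnings

        warnings.warn("no columns remain after no-gaps trimming")
    return trimmed


def write_phylip(alignment: Mapping[str, str], path) -> None:
    """Relaxed PHYLIP (taxon name, two spaces, full sequence)."""
    taxa = list(alignment)
    length = len(alignment[taxa[0]]) if taxa else 0
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)} {length}\n")
        for t in taxa:
            fh.write(f"{t}  {alignment[t]}\n")


def write_fasta(alignment: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for t, seq in alignment.items():
            fh.write(f">{t}\n{seq}\n")
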