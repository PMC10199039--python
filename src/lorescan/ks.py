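"""Synonymous-distance (Ks) estimation and category-stratified summaries.

Ks — synonymous substitutions per synonymous site — proxies divergence time
for a gene pair.  Ohnolog pairs that rediploidized before speciation
(PreSpec) should show higher Ks than orthologs, and pairs that
rediploidized after speciation (PostSpec) lower Ks, so the ordering of the
category-wise Ks distributions corroborates the gene-tree signal.

The estimator is the Nei–Gojobori (1986) counting method with Jukes–Cantor
multiple-hit correction: synonymous/nonsynonymous site counts per codon
(changes to stop codons excluded from the counting), observed differences
averaged over all minimal substitution pathways between differing codons
(pathways through stop codons discarded), and the proportions corrected by
``d = -3/4 ln(1 - 4p/3)``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

__all__ = [
    "NUCLEOTIDES",
    "GENETIC_CODE",
    "NG86Result",
    "KsFamily",
    "ks_ng86",
    "build_ks_datasets",
    "ks_summary",
    "bimodality_check",
]

log = logging.getLogger(__name__)

NUCLEOTIDES = "TCAG"

#: The universal genetic code, codon -> one-letter amino acid ('*' = stop).
GENETIC_CODE = {
    f"{a}{b}{c}": aa
    for (a, b, c), aa in zip(
        itertools.product(NUCLEOTIDES, repeat=3),
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
}


@dataclass
class NG86Result:
    ks: float | None
    ka: float | None
    s_sites: float
    n_sites: float
    n_codons: int
    flag: str | None = None  # "saturated_s", "saturated_n", "no_codons"


@dataclass
class KsFamily:
    """Coding-sequence bundle of one classified ohnolog family.

    ``sturgeon_pair`` / ``paddlefish_pair`` are ``((gene_id, cds), (gene_id,
    cds))``; ``ortholog_pairs`` (PreSpec families) holds the two
    cross-species pairs defined by the gene-tree cherries, each as
    ``((sturgeon_gene, cds), (paddlefish_gene, cds))``.
    """

    family_id: str
    rooted_category: str
    sturgeon_pair: tuple
    paddlefish_pair: tuple
    ortholog_pairs: tuple = ()


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if GENETIC_CODE[alt] == "*":
                continue
            n_valid += 1
            if GENETIC_CODE[alt] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitutions between two sense codons,
    averaged over minimal pathways; pathways through stops are discarded
    (all-stop pathway sets fall back to including them)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        syn = nsyn = 0.0
        cur = c1
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                hits_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        return syn, nsyn, hits_stop

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [(s, n) for s, n, stop in paths if not stop]
    if not valid:
        valid = [(s, n) for s, n, _ in paths]
    syn = sum(s for s, _ in valid) / len(valid)
    nsyn = sum(n for _, n in valid) / len(valid)
    return syn, nsyn


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))


def ks_ng86(seq_a: str, seq_b: str) -> NG86Result:
    """NG86 Ks/Ka between two aligned coding sequences.

    Sequences must be equal length, divisible by 3, in frame.  Codon pairs
    where either codon has a gap/ambiguity or is a stop are skipped.  Site
    counts are averaged over the two sequences; the Jukes–Cantor correction
    is applied; proportions >= 3/4 are flagged non-computable.
    """
    a, b = seq_a.upper().replace("U", "T"), seq_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("coding sequences must be aligned to equal length")
    if len(a) % 3:
        raise ValueError("aligned coding length must be divisible by 3")
    s_a = s_b = 0.0
    n_a = n_b = 0.0
    sd = nd = 0.0
    used = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca not in GENETIC_CODE or cb not in GENETIC_CODE:
            continue
        if GENETIC_CODE[ca] == "*" or GENETIC_CODE[cb] == "*":
            continue
        used += 1
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        s_a += sa
        s_b += sb
        n_a += na
        n_b += nb
        ds, dn = _codon_differences(ca, cb)
        sd += ds
        nd += dn
    if used == 0:
        return NG86Result(None, None, 0.0, 0.0, 0, flag="no_codons")
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    flag = None
    if ks is None:
        flag = "saturated_s"
    elif ka is None:
        flag = "saturated_n"
    return NG86Result(ks, ka, S, N, used, flag)


# ---------------------------------------------------------------------------
# datasets


def build_ks_datasets(
    families: Iterable[KsFamily],
    single_copy_pairs: Iterable[tuple] = (),
    max_ks: float = 0.3,
) -> pd.DataFrame:
    """Ks record table across the category-stratified pair datasets.

    Per classified family: one intra-sturgeon and one intra-paddlefish
    ohnolog pair labelled by the family's rooted category; PreSpec families
    additionally contribute exactly two cross-species ortholog pairs
    ("PreSpecOrtholog").  ``single_copy_pairs`` (each ``((sturgeon_gene,
    cds), (paddlefish_gene, cds))``) form the "SingleCopyOrtholog" set.
    Pairs flagged by the estimator are dropped; remaining records with
    Ks >= ``max_ks`` carry ``excluded=True``.
    """
    rows = []

    def emit(dataset, context, species, pair, family_id=""):
        (ga, sa), (gb, sb) = pair
        if sa is None or sb is None:
            log.warning("skipping pair %s-%s: missing coding sequence", ga, gb)
            return
        res = ks_ng86(sa, sb)
        if res.flag is not None:
            log.warning("skipping pair %s-%s: %s", ga, gb, res.flag)
            return
        rows.append(
            {
                "family_id": family_id,
                "dataset": dataset,
                "species_context": context,
                "species": species,
                "gene_a": ga,
                "gene_b": gb,
                "ks": res.ks,
                "ka": res.ka,
                "excluded": res.ks >= max_ks,
            }
        )

    for fam in families:
        emit(fam.rooted_category, "intra", "Sturgeon", fam.sturgeon_pair, fam.family_id)
        emit(fam.rooted_category, "intra", "Paddlefish", fam.paddlefish_pair, fam.family_id)
        if fam.rooted_category == "PreSpec":
            if len(fam.ortholog_pairs) != 2:
                log.warning(
                    "PreSpec family %s lacks its two ortholog pairs", fam.family_id
                )
            for pair in fam.ortholog_pairs:
                emit("PreSpecOrtholog", "inter", "both", pair, fam.family_id)
    for pair in single_copy_pairs:
        emit("SingleCopyOrtholog", "inter", "both", pair)
    return pd.DataFrame(
        rows,
        columns=[
            "family_id", "dataset", "species_context", "species",
            "gene_a", "gene_b", "ks", "ka", "excluded",
        ],
    )


# ---------------------------------------------------------------------------
# summaries


def _density(values: np.ndarray, grid: np.ndarray) -> np.ndarray | None:
    if values.size < 2 or np.allclose(values, values[0]):
        return None
    kde = gaussian_kde(values, bw_method="silverman")
    return kde(grid)


def ks_summary(
    records: pd.DataFrame,
    by: Sequence[str] = ("dataset",),
    grid: np.ndarray | None = None,
    include_excluded: bool = False,
) -> dict:
    """Per-group n, quartiles, kernel density and mode of the Ks values.

    Quartiles use linear interpolation; the density is a Gaussian kernel
    with Silverman bandwidth evaluated on a fixed grid (default 512 points
    over [0, 0.3]) and the mode is its argmax.
    """
    if grid is None:
        grid = np.linspace(0.0, 0.3, 512)
    data = records if include_excluded else records[~records["excluded"]]
    out = {}
    for key, group in data.groupby(list(by)):
        key = key if len(by) > 1 else key[0] if isinstance(key, tuple) else key
        vals = group["ks"].to_numpy(float)
        if vals.size == 0:
            out[key] = {"n": 0}
            continue
        q = np.quantile(vals, [0.25, 0.5, 0.75])
        dens = _density(vals, grid)
        mode = float(grid[int(np.argmax(dens))]) if dens is not None else float(vals[0])
        out[key] = {
            "n": int(vals.size),
            "quartiles": tuple(float(x) for x in q),
            "density": dens,
            "grid": grid,
            "mode": mode,
        }
    return out


def bimodality_check(
    values: Sequence[float],
    grid: np.ndarray | None = None,
    prominence_frac: float = 0.1,
) -> dict:
    """Count kernel-density modes of a Ks sample.

    Local density maxima with prominence above ``prominence_frac`` times the
    density peak count as modes.  With strict support filtering the pooled
    ohnolog Ks distribution is expected to turn bimodal (an older PreSpec
    and a younger PostSpec component).
    """
    vals = np.asarray(values, float)
    if vals.size < 20:
        raise ValueError("need at least 20 values for a mode count")
    if grid is None:
        lo, hi = vals.min(), vals.max()
        pad = 0.05 * (hi - lo + 1e-9)
        grid = np.linspace(lo - pad, hi + pad, 512)
    dens = _density(vals, grid)
    if dens is None:
        return {"n_modes": 1, "mode_positions": (float(vals[0]),)}
    peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    return {
        "n_modes": int(peaks.size),
        "mode_positions": tuple(float(grid[p]) for p in peaks),
    }
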