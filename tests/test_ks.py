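"""NG86 synonymous distances and Ks dataset bookkeeping."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lorescan as ls
from lorescan.ks import GENETIC_CODE, KsFamily, NUCLEOTIDES, ks_ng86

SENSE = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


# ---------------------------------------------------------------------------
# independent oracle: a from-scratch NG86 written against the definitions,
# sharing no code with the implementation


def oracle_codon_sites(codon):
    syn = 0.0
    for pos in range(3):
        neighbours = []
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if GENETIC_CODE[alt] != "*":
                neighbours.append(GENETIC_CODE[alt] == GENETIC_CODE[codon])
        if neighbours:
            syn += sum(neighbours) / len(neighbours)
    return syn, 3.0 - syn


def oracle_codon_diffs(c1, c2):
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(positions):
        cur, syn, nsyn, through_stop = c1, 0, 0, False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if GENETIC_CODE[nxt] == "*":
                through_stop = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        results.append((syn, nsyn, through_stop))
    ok = [(s, n) for s, n, stop in results if not stop]
    if not ok:
        ok = [(s, n) for s, n, _ in results]
    return (sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok))


def oracle_ks(seq_a, seq_b):
    S = N = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if ca not in GENETIC_CODE or cb not in GENETIC_CODE:
            continue
        if GENETIC_CODE[ca] == "*" or GENETIC_CODE[cb] == "*":
            continue
        sa, na = oracle_codon_sites(ca)
        sb, nb = oracle_codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = oracle_codon_diffs(ca, cb)
        sd += ds
        nd += dn
    ps = sd / S if S else 0.0
    if ps >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * ps / 3)


def test_identical_sequences_have_zero_distances():
    seq = "".join(SENSE[:50])
    res = ks_ng86(seq, seq)
    assert res.ks == 0.0 and res.ka == 0.0
    assert res.n_codons == 50


def test_single_synonymous_change_matches_oracle():
    a = "GGT" * 100                      # glycine, fourfold degenerate
    b = "GGC" + "GGT" * 99               # one third-position synonymous change
    res = ks_ng86(a, b)
    assert res.ka == 0.0
    assert res.ks == pytest.approx(oracle_ks(a, b), rel=1e-12)


def test_ng86_matches_pathway_oracle_on_random_pairs(rng):
    for _ in range(300):
        n = int(rng.integers(5, 30))
        a = "".join(rng.choice(SENSE, n))
        b = "".join(rng.choice(SENSE, n))
        mine = ks_ng86(a, b)
        theirs = oracle_ks(a, b)
        if mine.flag == "saturated_s":
            assert theirs is None
        else:
            assert mine.ks == pytest.approx(theirs, rel=1e-10)


def test_ks_is_symmetric(rng):
    for _ in range(50):
        a = "".join(rng.choice(SENSE, 20))
        b = "".join(rng.choice(SENSE, 20))
        ra, rb = ks_ng86(a, b), ks_ng86(b, a)
        assert (ra.ks is None) == (rb.ks is None)
        if ra.ks is not None:
            assert ra.ks == pytest.approx(rb.ks, abs=1e-12)


@settings(max_examples=80, derandomize=True)
@given(st.lists(st.sampled_from(SENSE), min_size=3, max_size=12),
       st.lists(st.sampled_from(SENSE), min_size=3, max_size=12))
def test_ks_symmetry_property(codons_a, codons_b):
    n = min(len(codons_a), len(codons_b))
    a, b = "".join(codons_a[:n]), "".join(codons_b[:n])
    ra, rb = ks_ng86(a, b), ks_ng86(b, a)
    assert (ra.ks is None) == (rb.ks is None)
    assert ra.s_sites == pytest.approx(rb.s_sites)
    if ra.ks is not None:
        assert ra.ks == pytest.approx(rb.ks, abs=1e-12)


def test_ks_invariant_to_synonymous_relabeling():
    """Relabelling fourfold codons while keeping the difference pattern
    (third position T->C in both) leaves Ks unchanged."""
    a1, b1 = "GGT" * 30, ("GGC" + "GGT" * 29)
    a2, b2 = "CCT" * 30, ("CCC" + "CCT" * 29)  # proline, also fourfold
    assert ks_ng86(a1, b1).ks == pytest.approx(ks_ng86(a2, b2).ks, abs=1e-12)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        ks_ng86("ATGC", "ATGC")  # not divisible by 3
    with pytest.raises(ValueError):
        ks_ng86("ATG", "ATGATG")


def test_ambiguous_and_stop_codons_skipped():
    res = ks_ng86("ATGTAAANN", "ATGTAAAAA")  # stop + ambiguity: only ATG usable
    assert res.n_codons == 1


# ---------------------------------------------------------------------------
# dataset bookkeeping


def _fam(fid, category, ks_scale=0.0):
    """A family whose paddlefish pair carries one synonymous difference."""
    base = "GGT" * 60
    variant = "GGC" * 10 + "GGT" * 50
    ortho = (
        (("s_a", base), ("p_a", base)),
        (("s_b", base), ("p_b", variant)),
    )
    return KsFamily(
        family_id=fid,
        rooted_category=category,
        sturgeon_pair=(("s_a", base), ("s_b", base)),
        paddlefish_pair=(("p_a", base), ("p_b", variant)),
        ortholog_pairs=ortho if category == "PreSpec" else (),
    )


def test_prespec_family_contributes_two_ortholog_pairs():
    table = ls.build_ks_datasets([_fam("f1", "PreSpec")])
    assert len(table) == 4  # sturgeon + paddlefish + 2 ortholog pairs
    assert (table["dataset"] == "PreSpecOrtholog").sum() == 2
    post = ls.build_ks_datasets([_fam("f2", "PostSpec")])
    assert len(post) == 2 and set(post["dataset"]) == {"PostSpec"}


def test_flagged_pair_dropped_and_high_ks_marked_excluded():
    bad = KsFamily(
        "f3",
        "PostSpec",
        sturgeon_pair=(("s_a", "GGT" * 5), ("s_b", None)),  # missing sequence
        paddlefish_pair=(("p_a", "TTT" * 5), ("p_b", "CCG" * 5)),  # saturated
    )
    table = ls.build_ks_datasets([bad])
    assert table.empty
    # Ks just above the cutoff is kept but flagged excluded: 26% of the
    # fourfold third positions changed gives Ks ~ 0.319
    a = "GGT" * 100
    b = "GGC" * 26 + "GGT" * 74
    res = ks_ng86(a, b)
    assert res.flag is None and res.ks >= 0.3
    fam = KsFamily("f4", "PostSpec", (("x", a), ("y", b)), (("u", a), ("v", a)))
    table = ls.build_ks_datasets([fam])
    assert bool(table.loc[table.gene_a == "x", "excluded"].iloc[0]) is True
    assert bool(table.loc[table.gene_a == "u", "excluded"].iloc[0]) is False


def test_summary_quartiles_match_order_statistics(rng):
    vals = rng.uniform(0.0, 0.29, 200)
    table = pd.DataFrame(
        {
            "family_id": "",
            "dataset": "D",
            "species_context": "intra",
            "species": "Sturgeon",
            "gene_a": "a",
            "gene_b": "b",
            "ks": vals,
            "ka": 0.0,
            "excluded": False,
        }
    )
    out = ls.ks_summary(table)["D"]
    # independent order-statistics interpolation
    srt = np.sort(vals)
    for q, got in zip((0.25, 0.5, 0.75), out["quartiles"]):
        h = q * (len(srt) - 1)
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        expect = srt[lo] + (h - lo) * (srt[hi] - srt[lo])
        assert got == pytest.approx(expect, abs=1e-12)
    assert out["n"] == 200


def test_summary_single_value_group():
    table = pd.DataFrame(
        [{"family_id": "", "dataset": "D", "species_context": "intra",
          "species": "s", "gene_a": "a", "gene_b": "b",
          "ks": 0.1, "ka": 0.0, "excluded": False}]
    )
    out = ls.ks_summary(table)["D"]
    assert out["quartiles"] == (0.1, 0.1, 0.1)
    assert out["mode"] == pytest.approx(0.1)


def test_bimodality_detection(rng):
    two = np.concatenate([rng.normal(0.05, 0.008, 300), rng.normal(0.2, 0.012, 300)])
    res = ls.bimodality_check(two)
    assert res["n_modes"] == 2
    one = rng.normal(0.1, 0.01, 400)
    assert ls.bimodality_check(one)["n_modes"] == 1
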