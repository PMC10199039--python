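"""Quartet site likelihoods and the Approximately Unbiased (AU) topology test.

For each ohnolog quartet we extract the four-sequence amino-acid
subalignment, compute per-site log-likelihoods of the three possible
unrooted quartet topologies under an empirical substitution model with
discrete-gamma rate variation (Felsenstein pruning, branch lengths
optimised per topology), and ask whether the data can decisively reject a
topology with the AU test of the multiscale RELL bootstrap: site
log-likelihoods are resampled at several scaled alignment lengths, the
proportion of resamples in which each topology wins is probit-transformed
and regressed on sqrt(r) and 1/sqrt(r), and the AU p-value is
``1 - Phi(d - c)`` from the fitted signed distance and curvature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .models import AminoAcidModel, discrete_gamma_rates, jtt_model
from .topology import UnrootedType

__all__ = [
    "QUARTET_SPLITS",
    "SiteLikelihoodMatrix",
    "AUResult",
    "split_id",
    "split_unrooted_type",
    "site_log_likelihoods",
    "quartet_site_likelihoods",
    "au_test",
    "summarize_rejections",
]

#: The three unrooted topologies on four sequences, as index pairs of the
#: cherry containing sequence 0.
QUARTET_SPLITS = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2))

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))

_MISSING = 20  # state code for gaps/ambiguity (conditional likelihood of 1)


@dataclass
class SiteLikelihoodMatrix:
    """Per-topology, per-site log-likelihoods for one quartet."""

    log_likelihoods: np.ndarray  # (n_topologies, L_used)
    topology_ids: tuple
    skipped_columns: tuple = ()
    alpha: float = 1.0

    @property
    def totals(self) -> np.ndarray:
        return self.log_likelihoods.sum(axis=1)

    @property
    def best(self) -> str:
        return self.topology_ids[int(np.argmax(self.totals))]


@dataclass
class AUResult:
    """AU p-values for the candidate topologies of one quartet."""

    p_values: dict
    best: str
    scales: tuple
    replicates: int
    seed: int


def _encode(seqs: Sequence[str], alphabet: str) -> np.ndarray:
    lut = np.full(128, _MISSING, dtype=np.int8)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
        lut[ord(ch.lower())] = i
    arrs = [lut[np.frombuffer(s.encode(), dtype=np.uint8)] for s in seqs]
    return np.vstack(arrs)


def split_id(names: Sequence[str], split=QUARTET_SPLITS[0]) -> str:
    """Readable topology id, e.g. ``"(a,b)|(c,d)"``."""
    i, j, k, l = split
    return f"({names[i]},{names[j]})|({names[k]},{names[l]})"


def split_unrooted_type(
    names: Sequence[str], split, species_of: Mapping[str, str]
) -> UnrootedType:
    """Unrooted type (PreSpec/PostSpec) of one of the three quartet splits."""
    i, j, _, _ = split
    if species_of[names[i]] == species_of[names[j]]:
        return UnrootedType.POSTSPEC_TYPE
    return UnrootedType.PRESPEC_TYPE


def _conditional(P: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Leaf conditional likelihoods, (L, 20); missing states give ones."""
    Px = np.vstack([P.T, np.ones((1, P.shape[0]))])  # row 20 = missing
    return Px[states]


def _site_likelihoods_fixed(
    coded: np.ndarray,
    split,
    branch_lengths: np.ndarray,
    model: AminoAcidModel,
    rates: np.ndarray,
) -> np.ndarray:
    """Per-site likelihoods (not logs) for one topology at fixed branch
    lengths, averaged over gamma categories.

    ``branch_lengths`` holds the four pendant branches (in sequence order)
    followed by the internal branch.
    """
    i, j, k, l = split
    L = coded.shape[1]
    site_lik = np.zeros(L)
    for r in rates:
        Pi = model.transition_matrix(branch_lengths[i] * r)
        Pj = model.transition_matrix(branch_lengths[j] * r)
        Pk = model.transition_matrix(branch_lengths[k] * r)
        Pl = model.transition_matrix(branch_lengths[l] * r)
        P5 = model.transition_matrix(branch_lengths[4] * r)
        left = _conditional(Pi, coded[i]) * _conditional(Pj, coded[j])   # (L,20)
        right = _conditional(Pk, coded[k]) * _conditional(Pl, coded[l])  # (L,20)
        site_lik += (left * (right @ P5.T)) @ model.freqs
    return site_lik / len(rates)


def _optimize_branches(
    coded, split, model, rates, x0=None, n_sweeps: int = 2
) -> tuple[np.ndarray, float]:
    """Coordinate-wise bounded optimisation of the five branch lengths."""
    x = np.full(5, 0.1) if x0 is None else np.asarray(x0, float).copy()
    lo, hi = 1e-6, 10.0

    def neg_lnl(bl):
        lik = _site_likelihoods_fixed(coded, split, bl, model, rates)
        return -np.log(np.maximum(lik, 1e-300)).sum()

    best = neg_lnl(x)
    for _ in range(n_sweeps):
        for b in range(5):
            def f(v, b=b):
                trial = x.copy()
                trial[b] = v
                return neg_lnl(trial)

            res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-4})
            if res.fun <= best:
                x[b] = float(res.x)
                best = float(res.fun)
    return x, -best


def site_log_likelihoods(
    alignment,
    topology=QUARTET_SPLITS[0],
    model: AminoAcidModel | None = None,
    alpha: float = 1.0,
    n_gamma: int = 4,
    x0=None,
) -> tuple[np.ndarray, dict]:
    """Per-site log-likelihood vector of one unrooted quartet topology.

    ``alignment`` is four (name, sequence) pairs (or SeqRecords) of equal
    length; ``topology`` is one of :data:`QUARTET_SPLITS`.  All-gap columns
    are skipped and reported in the info dict.  The five branch lengths are
    optimised numerically (two coordinate sweeps, bounded).
    """
    model = model or jtt_model()
    names, seqs = _unpack(alignment)
    coded = _encode(seqs, "ARNDCQEGHILKMFPSTWYV")
    keep = ~(coded == _MISSING).all(axis=0)
    skipped = tuple(int(c) for c in np.nonzero(~keep)[0])
    coded = coded[:, keep]
    if coded.shape[1] < 1:
        raise ValueError("no informative (non-all-gap) columns in subalignment")
    rates = discrete_gamma_rates(alpha, n_gamma)
    bl, _ = _optimize_branches(coded, topology, model, rates, x0=x0)
    lik = _site_likelihoods_fixed(coded, topology, bl, model, rates)
    return np.log(np.maximum(lik, 1e-300)), {
        "branch_lengths": bl,
        "skipped_columns": skipped,
        "names": names,
        "alpha": alpha,
    }


def _unpack(alignment) -> tuple[list[str], list[str]]:
    names, seqs = [], []
    for rec in alignment:
        if hasattr(rec, "seq"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
        else:
            names.append(rec[0])
            seqs.append(str(rec[1]))
    if len(seqs) != 4:
        raise ValueError("quartet likelihoods need exactly 4 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    return names, seqs


def quartet_site_likelihoods(
    alignment,
    model: AminoAcidModel | None = None,
    n_gamma: int = 4,
    estimate_alpha: bool = True,
) -> SiteLikelihoodMatrix:
    """Site log-likelihoods of all three quartet topologies.

    The gamma shape is estimated once by 1-D optimisation on the topology
    that fits best at alpha = 1, then reused for all three topologies
    (branch lengths are re-optimised per topology).
    """
    model = model or jtt_model()
    names, _ = _unpack(alignment)
    alpha = 1.0
    if estimate_alpha:
        quick = [
            site_log_likelihoods(alignment, split, model, alpha=1.0, n_gamma=n_gamma)
            for split in QUARTET_SPLITS
        ]
        best_split = QUARTET_SPLITS[int(np.argmax([v.sum() for v, _ in quick]))]

        def neg(a):
            v, _ = site_log_likelihoods(alignment, best_split, model, alpha=a, n_gamma=n_gamma)
            return -v.sum()

        res = minimize_scalar(neg, bounds=(0.1, 20.0), method="bounded",
                              options={"xatol": 1e-2})
        alpha = float(res.x)

    vectors = []
    skipped: tuple = ()
    for split in QUARTET_SPLITS:
        v, info = site_log_likelihoods(alignment, split, model, alpha=alpha, n_gamma=n_gamma)
        vectors.append(v)
        skipped = info["skipped_columns"]
    ids = tuple(split_id(names, s) for s in QUARTET_SPLITS)
    return SiteLikelihoodMatrix(
        log_likelihoods=np.vstack(vectors),
        topology_ids=ids,
        skipped_columns=skipped,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# AU test


def au_test(
    sll: SiteLikelihoodMatrix,
    scales: Sequence[float] = DEFAULT_SCALES,
    replicates: int = 1000,
    seed: int = 0,
) -> AUResult:
    """Approximately Unbiased test from multiscale RELL bootstrap.

    For each scale ``r`` the per-site log-likelihoods are resampled with
    replacement to ``ceil(r * L)`` sites ``replicates`` times; the bootstrap
    proportion with which each topology attains the maximal resampled
    likelihood is recorded.  Weighted least squares fits
    ``z(r) = d*sqrt(r) + c/sqrt(r)`` to the probit-transformed proportions
    (scales with proportions of exactly 0 or 1 carry no information and are
    dropped); the AU p-value is ``1 - Phi(d - c)``.  Proportions degenerate
    at every scale map to p = 0 or 1 directly.
    """
    M = sll.log_likelihoods
    n_topo, L = M.shape
    if n_topo < 2:
        raise ValueError("AU test needs at least two topologies")
    if L < 10:
        raise ValueError("alignment too short for multiscale bootstrap (L < 10)")
    totals = M.sum(axis=1)
    if np.ptp(totals) < 1e-10 and np.allclose(M, M[0], atol=1e-12):
        # nothing distinguishes the topologies
        return AUResult(
            {tid: 1.0 for tid in sll.topology_ids},
            sll.topology_ids[0],
            tuple(scales),
            replicates,
            seed,
        )

    rng = np.random.default_rng(seed)
    bp = np.zeros((len(scales), n_topo))
    for si, r in enumerate(scales):
        n_sites = int(np.ceil(r * L))
        counts = rng.multinomial(n_sites, np.full(L, 1.0 / L), size=replicates)
        res = counts @ M.T  # (replicates, n_topo)
        # a topology is "best" whenever it attains the maximum, so exactly
        # tied topologies (identical site vectors) receive identical BP
        best = res >= res.max(axis=1, keepdims=True) - 1e-9
        bp[si] = best.mean(axis=0)

    p_values = {}
    sqrt_r = np.sqrt(np.asarray(scales, float))
    for t in range(n_topo):
        props = bp[:, t]
        usable = (props > 0.0) & (props < 1.0)
        if usable.sum() < 2:
            p = 1.0 if props.mean() > 0.5 else 0.0
        else:
            z = norm.ppf(1.0 - props[usable])
            X = np.column_stack([sqrt_r[usable], 1.0 / sqrt_r[usable]])
            phi = norm.pdf(z)
            w = replicates * phi**2 / (props[usable] * (1.0 - props[usable]))
            WX = X * w[:, None]
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
            d, c = beta
            p = float(1.0 - norm.cdf(d - c))
        p_values[sll.topology_ids[t]] = min(max(p, 0.0), 1.0)
    return AUResult(p_values, sll.best, tuple(scales), replicates, seed)


def summarize_rejections(
    grouped_results: Mapping[str, Iterable[tuple[AUResult, Mapping[str, UnrootedType]]]],
    alpha: float = 0.05,
) -> dict:
    """Per-category frequencies of decisive unrooted-type rejection.

    ``grouped_results`` maps a rooted-category label to an iterable of
    ``(AUResult, type_of_topology)`` pairs, where ``type_of_topology`` maps
    each topology id to its unrooted type.  A type is rejected when every
    topology of that type has AU p < ``alpha``.  Reported per group: the
    fraction of families rejecting the type matching the group's category,
    and the fraction rejecting the alternative type.
    """
    out = {}
    for category, results in grouped_results.items():
        match_type = (
            UnrootedType.POSTSPEC_TYPE
            if "PostSpec" in category
            else UnrootedType.PRESPEC_TYPE
        )
        alt_type = (
            UnrootedType.PRESPEC_TYPE
            if match_type is UnrootedType.POSTSPEC_TYPE
            else UnrootedType.POSTSPEC_TYPE
        )
        n = 0
        rej_match = 0
        rej_alt = 0
        for au, type_of in results:
            n += 1
            for utype, bucket in ((match_type, "match"), ((alt_type), "alt")):
                ps = [p for tid, p in au.p_values.items() if type_of[tid] is utype]
                if ps and all(p < alpha for p in ps):
                    if bucket == "match":
                        rej_match += 1
                    else:
                        rej_alt += 1
        if n == 0:
            raise ValueError(f"no AU results in group {category!r}")
        out[category] = {
            "n": n,
            "reject_matching_type": rej_match / n,
            "reject_alternative_type": rej_alt / n,
        }
    return out
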