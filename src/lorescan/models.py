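"""Amino-acid substitution model: rate matrix, gamma rates, transition
probabilities.

A general time-reversible amino-acid model is built from an exchangeability
table ``s`` and stationary frequencies ``pi`` as ``Q_ij = s_ij * pi_j``
(i != j), with the diagonal set so rows sum to zero and the whole matrix
scaled to one expected substitution per site per unit branch length.
Transition probabilities ``P(t) = exp(Qt)`` are computed through the
symmetric eigendecomposition that time reversibility affords.  Rate
variation across sites uses the standard discrete-gamma approximation with
equal-probability categories represented by their conditional means.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._jtt import AA_ORDER, JTT_EXCH, JTT_FREQS

__all__ = ["AA_ORDER", "AminoAcidModel", "jtt_model", "discrete_gamma_rates"]


class AminoAcidModel:
    """Time-reversible 20-state substitution model.

    Parameters
    ----------
    exchangeabilities :
        Lower triangle of the symmetric exchangeability matrix, column-wise
        (190 values, the conventional distribution format), or a full
        symmetric (20, 20) array.
    freqs :
        Stationary amino-acid frequencies (sum to 1), order ARNDCQEGHILKMFPSTWYV.
    """

    n_states = 20

    def __init__(self, exchangeabilities, freqs, name: str = "custom"):
        self.name = name
        self.freqs = np.asarray(freqs, float)
        if self.freqs.shape != (20,) or not np.isclose(self.freqs.sum(), 1.0, atol=1e-6):
            raise ValueError("freqs must be 20 values summing to 1")
        ex = np.asarray(exchangeabilities, float)
        if ex.shape == (190,):
            S = np.zeros((20, 20))
            k = 0
            for j in range(20):  # column-wise lower triangle
                for i in range(j + 1, 20):
                    S[i, j] = S[j, i] = ex[k]
                    k += 1
        elif ex.shape == (20, 20):
            S = ex.copy()
        else:
            raise ValueError("exchangeabilities must be 190 values or a 20x20 matrix")
        Q = S * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalise: one expected substitution per unit time
        mu = -(self.freqs * np.diag(Q)).sum()
        Q /= mu
        self.rate_matrix = Q

        # symmetric form B = D^1/2 Q D^-1/2 for a stable eigendecomposition
        d = np.sqrt(self.freqs)
        B = (Q * d[:, None]) / d[None, :]
        B = (B + B.T) / 2.0
        eigval, eigvec = np.linalg.eigh(B)
        self._eigval = eigval
        self._left = eigvec / d[:, None]          # D^-1/2 V
        self._right = (eigvec * d[:, None]).T     # V^T D^1/2

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows index the ancestral state."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


@lru_cache(maxsize=1)
def jtt_model() -> AminoAcidModel:
    """The JTT empirical model with its published frequencies."""
    return AminoAcidModel(JTT_EXCH, JTT_FREQS, name="JTT")


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of ``k`` equal-probability discrete-gamma categories.

    The continuous rate is Gamma(shape=alpha, mean=1); each category is
    represented by its conditional mean, so the discretised rates average
    exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    bounds = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    partial = gammainc(alpha + 1.0, alpha * bounds)  # cumulative category means
    rates = k * np.diff(partial)
    return rates / rates.mean() * 1.0
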