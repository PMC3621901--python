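"""GTR+I+Gamma substitution model.

The general time-reversible (GTR) rate matrix has off-diagonal entries
``q_ij = s_ij * pi_j`` with six exchangeabilities ``s_ij`` (AC, AG, AT, CG, CT,
GT) and stationary base frequencies ``pi``.  Q is normalised to unit mean rate
(``-sum_i pi_i q_ii = 1``) so branch lengths are expected substitutions per
site.  Rate variation across sites uses the discrete-gamma approximation
(equal-probability slices, category rate = slice mean, overall mean 1) plus a
separate proportion of invariable sites which enters only in the final
root-likelihood mixture, never in the category rates.

Transition probabilities ``P(r_k * t) = expm(Q r_k t)`` are computed through
the eigendecomposition of the symmetrised reversible matrix
``diag(sqrt(pi)) Q diag(1/sqrt(pi))``.  A branch carries one 4x4 matrix per
rate category ("tip" block): 64 values at the default 4 categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "GTRParams",
    "RateMatrix",
    "ModelParameterError",
    "build_rate_matrix",
    "discrete_gamma_rates",
    "transition_block",
    "jc_params",
]

EXCH_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT
EXCH_NAMES = ("AC", "AG", "AT", "CG", "CT", "GT")
STATE_NAMES = "ACGT"


class ModelParameterError(ValueError):
    """Raised for invalid substitution-model parameters."""


@dataclass(frozen=True)
class GTRParams:
    """Free parameters of the GTR+I+Gamma model.

    exch : six positive exchangeabilities in order AC, AG, AT, CG, CT, GT
    freqs : stationary base frequencies (A, C, G, T), on the simplex
    pinvar : proportion of invariable sites, in [0, 1)
    alpha : gamma shape for among-site rate variation, > 0
    n_cat : number of discrete gamma categories (default 4)
    """

    exch: tuple[float, ...]
    freqs: tuple[float, ...]
    pinvar: float = 0.0
    alpha: float = 1.0
    n_cat: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "exch", tuple(float(x) for x in self.exch))
        object.__setattr__(self, "freqs", tuple(float(x) for x in self.freqs))
        if len(self.exch) != 6 or any(x <= 0 for x in self.exch):
            raise ModelParameterError("exch must be 6 positive rates")
        if len(self.freqs) != 4 or any(x <= 0 for x in self.freqs):
            raise ModelParameterError("freqs must be 4 positive frequencies")
        if abs(sum(self.freqs) - 1.0) > 1e-12:
            raise ModelParameterError("freqs must sum to 1 within 1e-12")
        if not (0.0 <= self.pinvar < 1.0):
            raise ModelParameterError("pinvar must lie in [0, 1)")
        if self.alpha <= 0:
            raise ModelParameterError("alpha must be positive")
        if self.n_cat < 1:
            raise ModelParameterError("n_cat must be >= 1")

    def replace(self, **kw) -> "GTRParams":
        from dataclasses import replace

        return replace(self, **kw)


def jc_params(pinvar: float = 0.0, alpha: float = 1.0, n_cat: int = 4) -> GTRParams:
    """Jukes-Cantor special case: equal exchangeabilities, uniform frequencies."""
    return GTRParams((1.0,) * 6, (0.25,) * 4, pinvar=pinvar, alpha=alpha, n_cat=n_cat)


@dataclass
class RateMatrix:
    """Normalised reversible instantaneous rate matrix with cached spectrum."""

    Q: np.ndarray
    freqs: np.ndarray
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (eigenvalues, right_transform, left_transform) with
        P(t) = right @ diag(exp(lam t)) @ left."""
        if self._eig is None:
            sq = np.sqrt(self.freqs)
            B = (sq[:, None] * self.Q) / sq[None, :]
            B = 0.5 * (B + B.T)  # symmetric up to round-off by reversibility
            lam, V = np.linalg.eigh(B)
            right = V / sq[:, None]
            left = V.T * sq[None, :]
            self._eig = (lam, right, left)
        return self._eig


def build_rate_matrix(params: GTRParams) -> RateMatrix:
    """Construct the unit-mean-rate GTR matrix from exchangeabilities and freqs."""
    pi = np.asarray(params.freqs, dtype=float)
    Q = np.zeros((4, 4))
    for s, (i, j) in zip(params.exch, EXCH_PAIRS):
        Q[i, j] = s * pi[j]
        Q[j, i] = s * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(np.dot(pi, np.diag(Q)))
    if mean_rate <= 0:
        raise ModelParameterError("degenerate rate matrix")
    Q /= mean_rate
    return RateMatrix(Q, pi)


def discrete_gamma_rates(alpha: float, n_cat: int) -> np.ndarray:
    """Mean rates of ``n_cat`` equal-probability slices of Gamma(alpha, alpha).

    The returned rates have mean exactly 1 (the slice means of a unit-mean
    gamma, computed from the incomplete-gamma identity
    E[X; X<b] = F_{alpha+1}(b) for X ~ Gamma(alpha, scale=1/alpha)).
    """
    if alpha <= 0:
        raise ModelParameterError("alpha must be positive")
    if n_cat < 1:
        raise ModelParameterError("n_cat must be >= 1")
    return _discrete_gamma_rates_cached(float(alpha), int(n_cat))


from functools import lru_cache as _lru_cache


@_lru_cache(maxsize=64)
def _discrete_gamma_rates_cached(alpha: float, n_cat: int) -> np.ndarray:
    if n_cat == 1:
        rates = np.ones(1)
    else:
        probs = np.arange(1, n_cat) / n_cat
        bounds = _gamma_dist.ppf(probs, alpha, scale=1.0 / alpha)
        upper_cdf = _gamma_dist.cdf(bounds, alpha + 1.0, scale=1.0 / alpha)
        slice_mass = np.diff(np.concatenate([[0.0], upper_cdf, [1.0]]))
        rates = n_cat * slice_mass
    rates.flags.writeable = False  # shared across callers
    return rates


def transition_block(rate_matrix: RateMatrix, t: float, rates: np.ndarray) -> np.ndarray:
    """Stacked transition matrices P(r_k * t), one 4x4 per rate category.

    Tiny negative entries from the eigendecomposition are clipped to zero; the
    rows remain stochastic to ~1e-12.
    """
    if t < 0:
        raise ModelParameterError(f"negative branch length {t}")
    rates = np.asarray(rates, dtype=float)
    if t == 0.0:
        return np.broadcast_to(np.eye(4), (rates.shape[0], 4, 4)).copy()
    lam, right, left = rate_matrix.eigensystem()
    # (n_cat, 4, 4): right @ diag(exp(lam r t)) @ left for each category rate
    elam = np.exp(np.outer(rates * t, lam))  # (n_cat, 4)
    block = np.einsum("ij,kj,jl->kil", right, elam, left)
    np.clip(block, 0.0, None, out=block)
    return block
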