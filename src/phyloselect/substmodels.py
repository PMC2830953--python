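"""Amino-acid substitution models (JTT with optional +I, +G, +F).

The JTT exchangeabilities and stationary frequencies are the published
Jones-Taylor-Thornton (1992) empirical values, in the conventional
ARNDCQEGHILKMFPSTWYV state order.  Rate heterogeneity follows the standard
equal-probability discrete-gamma construction (category rate = conditional
mean of its gamma slice), optionally mixed with an invariant class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gencode import AMINO_ACIDS

# Lower triangle (row i, col j<i) of the symmetric JTT exchangeability matrix.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

JTT_FREQS = np.array([
    0.0767479233, 0.0516909483, 0.0426449574, 0.0515439485, 0.0198029802,
    0.0407519592, 0.0618299382, 0.0731519268, 0.0229439771, 0.0537609462,
    0.0919039081, 0.0586759413, 0.0238259762, 0.0401259599, 0.0509009491,
    0.0687649312, 0.0585649414, 0.0142609857, 0.0321019679, 0.0660049340,
])


def jtt_exchangeabilities() -> np.ndarray:
    """Symmetric 20x20 exchangeability matrix S (zero diagonal)."""
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = _JTT_LOWER[k]
            k += 1
    return s


def discrete_gamma_rates(alpha: float, k: int = 8) -> np.ndarray:
    """Equal-probability discrete gamma rates with unit mean.

    Each category's rate is the mean of its gamma(alpha, mean 1) quantile
    slice, computed with the standard incomplete-gamma identity, then the
    vector is renormalized so the categories average exactly to 1.
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError(f"gamma shape alpha must be finite and > 0, got {alpha}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(1)
    bounds = stats.gamma.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    # mean of slice [b0,b1) of Gamma(alpha, scale 1/alpha) is
    # [F(b1; alpha+1) - F(b0; alpha+1)] * k  (mean-1 parameterization)
    upper = stats.gamma.cdf(np.concatenate([bounds, [np.inf]]), a=alpha + 1,
                            scale=1.0 / alpha)
    lower = stats.gamma.cdf(np.concatenate([[0.0], bounds]), a=alpha + 1,
                            scale=1.0 / alpha)
    rates = (upper - lower) * k
    return rates / rates.mean()


@dataclass
class SubstitutionModelSpec:
    """JTT-family amino-acid model: JTT [+I][+G][+F].

    plus_G uses `k_rates` equal-weight gamma categories with shape `alpha`;
    plus_I mixes in an invariant class with proportion `p_inv` (the variable
    rates are rescaled so the overall mean rate stays 1); plus_F replaces the
    JTT frequencies with frequencies estimated from the data.
    """

    matrix: str = "JTT"
    plus_I: bool = False
    p_inv: float = 0.0
    plus_G: bool = False
    alpha: float = 1.0
    k_rates: int = 8
    plus_F: bool = False
    frequencies: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.matrix != "JTT":
            raise ValueError("only the JTT exchangeability matrix is supported")
        if self.plus_I and not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")

    @property
    def name(self) -> str:
        return "JTT" + ("+I" if self.plus_I else "") + \
            ("+G" if self.plus_G else "") + ("+F" if self.plus_F else "")

    def freqs(self) -> np.ndarray:
        if self.plus_F:
            if self.frequencies is None:
                raise ValueError("+F model without data frequencies attached")
            return self.frequencies
        return JTT_FREQS

    def with_frequencies_from(self, counts: np.ndarray) -> "SubstitutionModelSpec":
        total = counts.sum()
        if total == 0:
            raise ValueError("no residues to estimate +F frequencies from")
        f = (counts + 0.5) / (total + 10.0)  # light smoothing; no zero states
        return SubstitutionModelSpec(
            matrix=self.matrix, plus_I=self.plus_I, p_inv=self.p_inv,
            plus_G=self.plus_G, alpha=self.alpha, k_rates=self.k_rates,
            plus_F=True, frequencies=f / f.sum(),
        )

    def rate_mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the site-rate mixture, overall mean rate 1."""
        if self.plus_G:
            rates = discrete_gamma_rates(self.alpha, self.k_rates)
            weights = np.full(self.k_rates, 1.0 / self.k_rates)
        else:
            rates, weights = np.ones(1), np.ones(1)
        if self.plus_I and self.p_inv > 0:
            rates = np.concatenate([[0.0], rates / (1.0 - self.p_inv)])
            weights = np.concatenate([[self.p_inv], weights * (1.0 - self.p_inv)])
        return rates, weights

    def n_free_params(self) -> int:
        n = 0
        if self.plus_I:
            n += 1
        if self.plus_G:
            n += 1
        if self.plus_F:
            n += 19
        return n


def build_rate_matrix(freqs: np.ndarray) -> np.ndarray:
    """JTT rate matrix Q with given stationary frequencies, mean rate 1."""
    s = jtt_exchangeabilities()
    q = s * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(freqs * np.diag(q)).sum()
    return q / mu


class TransitionMatrices:
    """Eigendecomposition cache: P(t) for a reversible Q at arbitrary t."""

    def __init__(self, q: np.ndarray, freqs: np.ndarray) -> None:
        self.freqs = freqs
        root = np.sqrt(freqs)
        b = q * root[:, None] / root[None, :]
        w, u = np.linalg.eigh((b + b.T) / 2.0)
        self._w = w
        self._left = u / root[None, :].T  # D^{-1/2} U
        self._right = u.T * root[None, :]  # U^T D^{1/2}

    def probability(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        p = (self._left * np.exp(self._w * t)) @ self._right
        np.clip(p, 1e-300, None, out=p)
        return p


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def aa_index(aa: str) -> int | None:
    """State index for a residue; None for gap/ambiguity (missing data)."""
    return _AA_INDEX.get(aa)
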