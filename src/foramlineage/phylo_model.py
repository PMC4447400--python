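"""GTR+I+G substitution model and tree likelihood.

The general time-reversible (GTR) rate matrix is Q_ij = r_ij * pi_j for
i != j, with six symmetric exchangeabilities r (order AC, AG, AT, CG, CT,
GT) and stationary base frequencies pi (order A, C, G, T).  Q is scaled
so the expected substitution rate at stationarity is one, which makes
branch lengths expected substitutions per site.

Rate heterogeneity follows the standard discrete-gamma treatment: k
equal-probability categories, each represented by its category mean, plus
a separate class of invariant sites with proportion p_inv.  The site
likelihood is the two-component mixture

    L_site = p_inv * [site constant] * pi_base
           + (1 - p_inv) * (1/k) * sum_c L_pruning(rate_c)

computed by Felsenstein pruning with per-node rescaling to avoid
underflow on long alignments.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .io_formats import Alignment
from .tree import PhyloTree

BASES = "ACGT"
EXCHANGE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")

#: IUPAC code -> indicator vector over (A, C, G, T); gaps behave like N.
AMBIGUITY_VECTORS: dict[str, np.ndarray] = {
    code: np.array([1.0 if b in bases else 0.0 for b in BASES])
    for code, bases in {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
        "N": "ACGT", "-": "ACGT",
    }.items()
}


@dataclass
class GTRIGParams:
    """Parameters of the GTR+I+G model."""

    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6)
    )
    gamma_shape: float = 1.0
    p_inv: float = 0.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.base_freqs.shape != (4,) or np.any(self.base_freqs <= 0):
            raise ValueError("base_freqs must be 4 positive values")
        total = self.base_freqs.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"base_freqs must sum to 1, got {total}")
        self.base_freqs = self.base_freqs / total
        if self.exchangeabilities.shape != (6,) or np.any(
            self.exchangeabilities <= 0
        ):
            raise ValueError("exchangeabilities must be 6 positive values")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must lie in [0, 1)")
        if int(self.n_categories) < 1:
            raise ValueError("n_categories must be >= 1")
        self.n_categories = int(self.n_categories)

    def with_(self, **kwargs) -> "GTRIGParams":
        return replace(self, **kwargs)

    def rates(self) -> np.ndarray:
        return discretize_gamma(self.gamma_shape, self.n_categories)


def build_gtr_rate_matrix(params: GTRIGParams) -> np.ndarray:
    """GTR rate matrix, rows summing to zero, unit expected rate."""
    pi = params.base_freqs
    r = params.exchangeabilities
    pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    q = np.zeros((4, 4))
    for rate, (i, j) in zip(r, pairs):
        q[i, j] = rate * pi[j]
        q[j, i] = rate * pi[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(pi @ np.diag(q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix")
    return q / mu


def discretize_gamma(shape: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability gamma categories (mean 1).

    The gamma has shape and rate both equal to ``shape`` (so mean 1);
    each category is represented by its conditional mean between the
    (i/k)-quantile boundaries.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be > 0")
    if int(k) < 1:
        raise ValueError("number of categories must be >= 1")
    k = int(k)
    if k == 1:
        return np.ones(1)
    bounds = _gamma_dist.ppf(np.arange(1, k) / k, shape, scale=1.0 / shape)
    edges = np.concatenate([[0.0], bounds * shape, [np.inf]])
    # E[X; a < X < b] for Gamma(shape, rate=shape) = P(shape+1 upper inc.)
    cum = gammainc(shape + 1.0, edges)
    rates = k * np.diff(cum)
    return rates / rates.mean()


def _stationary(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a rate matrix (left null vector)."""
    a = np.vstack([q.T[:-1], np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    pi = np.linalg.solve(a, b)
    if np.any(pi <= 0):
        raise ValueError("rate matrix has no positive stationary distribution")
    return pi


class _Eigen:
    """Spectral decomposition of a reversible Q for fast exp(Q t)."""

    def __init__(self, q: np.ndarray, pi: np.ndarray) -> None:
        d = np.sqrt(pi)
        sym = (q * d[:, None]) / d[None, :]
        sym = (sym + sym.T) / 2.0
        lam, vec = np.linalg.eigh(sym)
        self.lam = lam
        self.left = vec / d[:, None]      # D^-1/2 V
        self.right = vec.T * d[None, :]   # V^T D^1/2

    def pmat(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.lam * t)) @ self.right
        if p.min() < -1e-9:
            raise FloatingPointError("transition matrix lost positivity")
        return np.clip(p, 0.0, None)

    def pmats(self, ts: np.ndarray) -> np.ndarray:
        """Stack of transition matrices for several scaled times."""
        expd = np.exp(np.outer(ts, self.lam))          # (k, 4)
        p = np.einsum("il,kl,lj->kij", self.left, expd, self.right)
        return np.clip(p, 0.0, None)


def transition_matrix(q: np.ndarray, t: float, rate: float = 1.0) -> np.ndarray:
    """P = exp(Q t rate) via spectral decomposition of the reversible Q."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if rate < 0:
        raise ValueError("rate multiplier must be >= 0")
    pi = _stationary(q)
    return _Eigen(q, pi).pmat(t * rate)


@dataclass
class SitePatternSet:
    """Distinct alignment columns with multiplicities."""

    taxon_ids: list[str]
    codes: np.ndarray      # (n_taxa, n_patterns) uint8 indices into _CODE_KEYS
    counts: np.ndarray     # (n_patterns,) multiplicities

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


_CODE_KEYS = list(AMBIGUITY_VECTORS)
_CODE_INDEX = {c: i for i, c in enumerate(_CODE_KEYS)}
_CODE_MATRIX = np.vstack([AMBIGUITY_VECTORS[c] for c in _CODE_KEYS])


def compress_patterns(aln: Alignment) -> SitePatternSet:
    """Collapse an alignment to its distinct site patterns."""
    codes = np.empty((len(aln.records), aln.n_sites), dtype=np.uint8)
    for row, rec in enumerate(aln.records):
        codes[row] = [_CODE_INDEX[c] for c in rec.sequence]
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    return SitePatternSet(aln.taxon_ids, patterns, counts)


def tree_log_likelihood(
    tree: PhyloTree, aln: Alignment, params: GTRIGParams
) -> float:
    """Log-likelihood of an alignment on a tree under GTR+I+G."""
    from ._likelihood import TreeLikelihood

    return TreeLikelihood(tree, aln, params).loglik()
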