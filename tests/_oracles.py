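"""Independent oracle implementations used only by the tests.

These deliberately avoid the package's likelihood engine: transition
probabilities come from scipy's expm, the rate matrix and discrete-gamma
rates are rebuilt long-hand, and the tree likelihood is an exhaustive
sum over internal-state assignments.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from foramlineage.tree import Node, PhyloTree

AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT",
}
BASES = "ACGT"


def oracle_rate_matrix(freqs, exch):
    """Hand-built scaled GTR matrix (pair loops, no vectorization)."""
    q = [[0.0] * 4 for _ in range(4)]
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for rate, (i, j) in zip(exch, pairs):
        q[i][j] = rate * freqs[j]
        q[j][i] = rate * freqs[i]
    for i in range(4):
        q[i][i] = -sum(q[i][j] for j in range(4) if j != i)
    mu = -sum(freqs[i] * q[i][i] for i in range(4))
    return np.array(q) / mu


def oracle_gamma_rates(shape, k):
    """Equal-probability category means, recomputed from quantiles."""
    if k == 1:
        return np.ones(1)
    qs = gamma_dist.ppf(np.arange(1, k) / k, shape, scale=1.0 / shape)
    edges = [0.0] + [q * shape for q in qs] + [np.inf]
    means = [
        k * (gammainc(shape + 1, edges[i + 1]) - gammainc(shape + 1, edges[i]))
        for i in range(k)
    ]
    return np.array(means)


def brute_force_loglik(tree: PhyloTree, aln, params) -> float:
    """Exhaustive enumeration over internal-node states, per category."""
    pi = np.asarray(params.base_freqs, dtype=float)
    q = oracle_rate_matrix(pi, params.exchangeabilities)
    rates = oracle_gamma_rates(params.gamma_shape, params.n_categories)
    seqs = {r.taxon_id: r.sequence for r in aln.records}
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]

    total = 0.0
    for site in range(aln.n_sites):
        leaf_vec = {}
        comp = np.ones(4)
        for leaf in leaves:
            vec = np.array(
                [1.0 if b in AMBIG[seqs[leaf.name][site]] else 0.0 for b in BASES]
            )
            leaf_vec[id(leaf)] = vec
            comp = comp * vec
        site_var = 0.0
        for rate in rates:
            pmat = {
                id(n): expm(q * (n.length or 0.0) * rate)
                for n in nodes
                if n.parent is not None
            }
            cat = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                amap = {id(n): s for n, s in zip(internal, assign)}
                prob = pi[amap[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    ps = amap[id(n.parent)]
                    if n.is_leaf:
                        prob *= float(pmat[id(n)][ps] @ leaf_vec[id(n)])
                    else:
                        prob *= pmat[id(n)][ps, amap[id(n)]]
                cat += prob
            site_var += cat / len(rates)
        site_l = (1.0 - params.p_inv) * site_var + params.p_inv * float(comp @ pi)
        total += math.log(site_l)
    return total


def jc_pairwise_loglik(n_sites_same: int, n_sites_diff: int, t: float) -> float:
    """Closed-form two-taxon Jukes-Cantor log-likelihood."""
    p_same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
    p_diff = (1.0 - p_same) / 3.0
    return n_sites_same * math.log(0.25 * p_same) + n_sites_diff * math.log(
        0.25 * p_diff
    )


def jc_special_case_loglik(tree: PhyloTree, aln) -> float:
    """Independent Jukes-Cantor pruning (dicts and loops, no engine)."""

    def pmat(t):
        same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
        diff = (1.0 - same) / 3.0
        return [[same if i == j else diff for j in range(4)] for i in range(4)]

    seqs = {r.taxon_id: r.sequence for r in aln.records}

    def partial(node, site):
        if node.is_leaf:
            return [
                1.0 if BASES[i] in AMBIG[seqs[node.name][site]] else 0.0
                for i in range(4)
            ]
        vec = [1.0] * 4
        for child in node.children:
            p = pmat(child.length or 0.0)
            cv = partial(child, site)
            vec = [
                vec[i] * sum(p[i][j] * cv[j] for j in range(4)) for i in range(4)
            ]
        return vec

    total = 0.0
    for site in range(aln.n_sites):
        vec = partial(tree.root, site)
        total += math.log(sum(0.25 * v for v in vec))
    return total


# ---------------------------------------------------------------------------
# LDA oracles
# ---------------------------------------------------------------------------

def lda_closed_form(x1: np.ndarray, x2: np.ndarray):
    """Long-hand LDA: pooled covariance and 2x2 adjugate inverse."""
    n1, n2 = len(x1), len(x2)
    m1 = [sum(x1[:, 0]) / n1, sum(x1[:, 1]) / n1]
    m2 = [sum(x2[:, 0]) / n2, sum(x2[:, 1]) / n2]
    s = [[0.0, 0.0], [0.0, 0.0]]
    for data, m in ((x1, m1), (x2, m2)):
        for row in data:
            d0, d1 = row[0] - m[0], row[1] - m[1]
            s[0][0] += d0 * d0
            s[0][1] += d0 * d1
            s[1][0] += d1 * d0
            s[1][1] += d1 * d1
    denom = n1 + n2 - 2
    s = [[v / denom for v in row] for row in s]
    det = s[0][0] * s[1][1] - s[0][1] * s[1][0]
    inv = [[s[1][1] / det, -s[0][1] / det], [-s[1][0] / det, s[0][0] / det]]
    diff = [m2[0] - m1[0], m2[1] - m1[1]]
    w = [
        inv[0][0] * diff[0] + inv[0][1] * diff[1],
        inv[1][0] * diff[0] + inv[1][1] * diff[1],
    ]
    mid = [(m1[0] + m2[0]) / 2.0, (m1[1] + m2[1]) / 2.0]
    c = -(w[0] * mid[0] + w[1] * mid[1])
    return np.array(w), c


def fisher_grid_direction(x1: np.ndarray, x2: np.ndarray, n_angles: int = 20000):
    """Dense angular grid search maximizing the Fisher criterion."""
    best_j, best_w = -1.0, None
    for theta in np.linspace(0.0, np.pi, n_angles, endpoint=False):
        w = np.array([np.cos(theta), np.sin(theta)])
        p1, p2 = x1 @ w, x2 @ w
        between = (p1.mean() - p2.mean()) ** 2
        within = ((p1 - p1.mean()) ** 2).sum() + ((p2 - p2.mean()) ** 2).sum()
        j = between / within
        if j > best_j:
            best_j, best_w = j, w
    return best_w


# ---------------------------------------------------------------------------
# Random trees
# ---------------------------------------------------------------------------

def random_tree(
    names,
    rng,
    internal_range=(0.03, 0.2),
    terminal_range=(0.02, 0.3),
) -> PhyloTree:
    """Random unrooted binary topology by sequential random attachment."""
    names = list(names)
    if len(names) < 3:
        raise ValueError("need at least 3 names")
    root = Node()
    for name in names[:3]:
        root.add_child(Node(name=name))
    for name in names[3:]:
        candidates = [n for n in root.postorder() if n is not root]
        target = candidates[rng.integers(0, len(candidates))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(Node(name=name))
    tree = PhyloTree(root)
    for node in tree.postorder():
        if node is tree.root:
            continue
        lo, hi = terminal_range if node.is_leaf else internal_range
        node.length = float(rng.uniform(lo, hi))
    return tree
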