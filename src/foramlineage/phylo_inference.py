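"""Maximum-likelihood tree inference under GTR+I+G.

The search strategy: a neighbor-joining starting tree on Jukes-Cantor
distances, cyclic per-edge branch-length optimization, and repeated
nearest-neighbor-interchange (NNI) rounds accepting the best strictly
improving rearrangement until the tree is NNI-locally optimal.  Clade
support comes from the nonparametric bootstrap (column resampling), with
supports mapped onto the best ML tree.  Rooting is by outgroup: the root
is placed on the edge separating the outgroup from the ingroup, which the
reference analysis repeats with three alternative outgroup sets to test
topology stability.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ._likelihood import TreeLikelihood
from .io_formats import Alignment
from .phylo_model import GTRIGParams, compress_patterns
from .tree import Node, PhyloTree

#: cap for Jukes-Cantor distances of saturated pairs
MAX_DISTANCE = 5.0


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # (n, n) symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")


def pairwise_distances(
    aln: Alignment, max_distance: float = MAX_DISTANCE
) -> DistanceMatrix:
    """Jukes-Cantor corrected distances on pairwise-complete sites.

    d = -(3/4) ln(1 - (4/3) p) with p the mismatch proportion over sites
    where both sequences carry an unambiguous base; saturated pairs
    (p >= 3/4) are capped at ``max_distance``.
    """
    if len(aln.records) < 2:
        raise ValueError("need at least 2 sequences")
    pats = compress_patterns(aln)
    codes = pats.codes
    counts = pats.counts.astype(float)
    plain = codes < 4  # A, C, G, T occupy code indices 0-3
    n = codes.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = plain[i] & plain[j]
            total = counts[both].sum()
            if total == 0:
                raise ValueError(
                    f"no comparable sites between {pats.taxon_ids[i]!r} "
                    f"and {pats.taxon_ids[j]!r}"
                )
            mism = counts[both & (codes[i] != codes[j])].sum()
            p_hat = mism / total
            if p_hat >= 0.75 - 1e-12:
                dist = max_distance
            else:
                dist = min(-0.75 * np.log1p(-4.0 * p_hat / 3.0), max_distance)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(pats.taxon_ids), d)


def nj_tree(distances: DistanceMatrix) -> PhyloTree:
    """Neighbor joining; additive matrices are recovered exactly.

    Ties in the Q criterion break deterministically on the lowest index
    pair.  Negative branch-length estimates are clamped at zero.
    """
    n = len(distances.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[Node] = [Node(name=t) for t in distances.ids]
    d = distances.values.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        return max(0.0, float(x))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = Node()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    root = Node()
    nodes[i].length = clamp((d[i, j] + d[i, k] - d[j, k]) / 2.0)
    nodes[j].length = clamp((d[i, j] + d[j, k] - d[i, k]) / 2.0)
    nodes[k].length = clamp((d[i, k] + d[j, k] - d[i, j]) / 2.0)
    for idx in (i, j, k):
        root.add_child(nodes[idx])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Branch lengths and model parameters
# ---------------------------------------------------------------------------

def optimize_branch_lengths(
    tree: PhyloTree,
    aln: Alignment,
    params: GTRIGParams,
    tol: float = 1e-6,
    max_rounds: int = 20,
) -> PhyloTree:
    """Iterative per-edge ML branch lengths (modifies and returns tree)."""
    TreeLikelihood(tree, aln, params).optimize_branch_lengths(tol, max_rounds)
    return tree


def observed_base_freqs(aln: Alignment) -> np.ndarray:
    """Observed A, C, G, T proportions (with a +1 pseudocount)."""
    counts = np.ones(4)
    index = {b: i for i, b in enumerate("ACGT")}
    for rec in aln.records:
        for ch in rec.sequence:
            if ch in index:
                counts[index[ch]] += 1
    return counts / counts.sum()


def estimate_model_params(
    tree: PhyloTree,
    aln: Alignment,
    params_init: GTRIGParams,
    tol: float = 1e-5,
    max_iter: int = 50,
    optimize_branches: bool = True,
) -> GTRIGParams:
    """Fit exchangeabilities, gamma shape and p_inv on a fixed topology.

    Base frequencies are fixed at observed proportions; the GT
    exchangeability is the reference rate (fixed at 1).  Optimization is
    cyclic coordinate ascent with bounded 1-D searches, interleaved with
    branch-length re-optimization.
    """
    params = params_init.with_(base_freqs=observed_base_freqs(aln))
    eng = TreeLikelihood(tree, aln, params)
    if optimize_branches:
        eng.optimize_branch_lengths(tol=1e-4, max_rounds=5)
    ll = eng.loglik()

    def try_params(candidate: GTRIGParams) -> float:
        eng.set_params(candidate)
        return eng.loglik()

    converged = False
    for _ in range(max_iter):
        # exchangeabilities, one bounded 1-D search each (GT fixed at 1)
        for which in range(5):
            current = params.exchangeabilities[which]

            def make(v: float, idx: int = which) -> GTRIGParams:
                ex = params.exchangeabilities.copy()
                ex[idx] = v
                return params.with_(exchangeabilities=ex)

            def neg(x: float) -> float:
                return -try_params(make(np.exp(x)))

            res = minimize_scalar(
                neg, bounds=(-7.0, 7.0), method="bounded",
                options={"xatol": 1e-5},
            )
            x0 = np.log(current)
            best_x = res.x if -res.fun >= -neg(x0) else x0
            params = make(np.exp(best_x))
            eng.set_params(params)

        # gamma shape and p_inv trade off along a ridge that is coupled
        # to total tree length (more invariant sites need longer branches
        # on the variable ones), so optimize (shape, p_inv) jointly with
        # a global branch-scale factor
        edges = [n for n in tree.preorder() if n is not tree.root]
        base_lengths = [n.length if n.length is not None else 0.0 for n in edges]

        def rate_het(xyz: np.ndarray) -> tuple[GTRIGParams, float]:
            shape = float(np.clip(np.exp(xyz[0]), 0.02, 100.0))
            pv = 0.99 / (1.0 + np.exp(-xyz[1]))
            c = float(np.clip(np.exp(xyz[2]), 0.02, 50.0))
            return params.with_(gamma_shape=shape, p_inv=pv), c

        def neg_joint(xyz: np.ndarray) -> float:
            cand, c = rate_het(xyz)
            for node, length in zip(edges, base_lengths):
                node.length = length * c
            return -try_params(cand)

        pv0 = min(max(params.p_inv, 1e-3), 0.985)
        x0 = np.array(
            [np.log(params.gamma_shape), np.log(pv0 / (0.99 - pv0)), 0.0]
        )
        res2 = minimize(
            neg_joint, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
        )
        best_x = res2.x if -res2.fun >= -neg_joint(x0) else x0
        params, c_best = rate_het(best_x)
        for node, length in zip(edges, base_lengths):
            node.length = length * c_best
        eng.set_params(params)
        if optimize_branches:
            eng.optimize_branch_lengths(tol=1e-4, max_rounds=2)
        new_ll = eng.loglik()
        if new_ll < ll - 1e-6:  # pragma: no cover - ascent safety net
            warnings.warn("model-parameter ascent step decreased likelihood")
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged:
        warnings.warn(
            "model-parameter estimation hit the iteration cap; "
            "returning best-found parameters"
        )
    eng.set_params(params)
    return params


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------

def _internal_edges(tree: PhyloTree) -> list[Node]:
    return [
        n for n in tree.preorder()
        if n is not tree.root and not n.is_leaf and len(n.children) == 2
    ]


def nni_search(
    tree: PhyloTree,
    aln: Alignment,
    params: GTRIGParams,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> PhyloTree:
    """Nearest-neighbor-interchange hill climbing (modifies the tree).

    Every internal edge contributes two alternative topologies; each is
    scored with the central branch re-optimized (outer branches keep
    their lengths during scoring).  The best strictly improving move is
    applied, followed by a full branch-length re-optimization, until no
    edge improves.  Edge enumeration is preorder, so equal gains break
    toward the earlier edge.
    """
    tree.unroot()
    eng = TreeLikelihood(tree, aln, params)
    eng.optimize_branch_lengths(tol=tol)
    current_ll = eng.loglik()

    for _ in range(max_iter):
        arrs = eng.flows()
        msg, mscale = arrs["msg"], arrs["msg_scale"]
        down, dscale = arrs["down"], arrs["down_scale"]
        best = None  # (gain, v, moved, s, t_opt)
        for v in _internal_edges(tree):
            u = v.parent
            a, b = v.children
            sibs = [c for c in u.children if c is not v]
            s = sibs[0]
            outer = np.array(down[id(u)])
            oscale = dscale[id(u)].copy()
            for c in u.children:
                if c is v or c is s:
                    continue
                outer = outer * msg[id(c)]
                oscale = oscale + mscale[id(c)]
            for moved, kept in ((a, b), (b, a)):
                upper = outer * msg[id(moved)]
                upper_scale = oscale + mscale[id(moved)]
                lower = msg[id(s)] * msg[id(kept)]
                lower_scale = mscale[id(s)] + mscale[id(kept)]
                value, value_grad = eng.edge_objective(
                    upper, upper_scale, lower, lower_scale
                )
                t_opt, ll_alt = eng._optimize_edge(
                    value, value_grad, v.length if v.length is not None else 0.0
                )
                gain = ll_alt - current_ll
                if gain > tol and (best is None or gain > best[0]):
                    best = (gain, v, moved, s, t_opt)
        if best is None:
            break
        _, v, moved, s, t_opt = best
        u = v.parent
        u.children[u.children.index(s)] = moved
        v.children[v.children.index(moved)] = s
        moved.parent = u
        s.parent = v
        v.length = t_opt
        v.support = None
        current_ll = eng.optimize_branch_lengths(tol=tol, max_rounds=2)
    # final polish of branch lengths on the NNI-optimal topology
    eng.optimize_branch_lengths(tol=tol)
    return tree


def infer_ml_tree(
    aln: Alignment, params: GTRIGParams, tol: float = 1e-6
) -> PhyloTree:
    """NJ start + branch-length optimization + NNI, in one call."""
    tree = nj_tree(pairwise_distances(aln))
    for node in tree.postorder():
        if node is not tree.root and (node.length is None or node.length <= 0):
            node.length = 1e-6
    return nni_search(tree, aln, params, tol=tol)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSummary:
    """Bipartition supports from B column-resampling replicates."""

    n_replicates: int
    seed: int
    support: dict[frozenset, float]
    best_tree: PhyloTree
    replicate_counts: dict[frozenset, int] = field(default_factory=dict)


def _resample_alignment(aln: Alignment, rng: np.random.Generator) -> Alignment:
    idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
    from .io_formats import SequenceRecord

    return Alignment(
        [
            SequenceRecord(
                r.taxon_id, "".join(r.sequence[i] for i in idx), r.description
            )
            for r in aln.records
        ]
    )


def bootstrap_support(
    aln: Alignment,
    params: GTRIGParams,
    n_replicates: int,
    seed: int,
    best_tree: Optional[PhyloTree] = None,
) -> BootstrapSummary:
    """Nonparametric bootstrap clade support.

    Each replicate resamples alignment columns with replacement
    (replicate r uses RNG seed ``seed + r``), reruns the NJ + branch
    optimization + NNI pipeline, and contributes its bipartitions.
    Supports are the fraction of replicates containing each bipartition
    of the best ML tree, attached to that tree as percentages.
    """
    if n_replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    if best_tree is None:
        best_tree = infer_ml_tree(aln, params)
    else:
        best_tree = best_tree.copy()
        best_tree.unroot()

    tally: dict[frozenset, int] = {}
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        rep = _resample_alignment(aln, rng)
        rep_tree = infer_ml_tree(rep, params)
        for split in rep_tree.bipartitions():
            tally[split] = tally.get(split, 0) + 1

    support = {
        split: tally.get(split, 0) / n_replicates
        for split in best_tree.bipartitions()
    }
    all_leaves = frozenset(best_tree.leaf_names())
    ref = min(all_leaves)
    for node in best_tree.postorder():
        if node is best_tree.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        canon = side if ref not in side else all_leaves - side
        if canon in support:
            node.support = float(round(100.0 * support[canon]))
    return BootstrapSummary(
        n_replicates=n_replicates,
        seed=seed,
        support=support,
        best_tree=best_tree,
        replicate_counts=tally,
    )


def clade_support(
    summary: BootstrapSummary, taxa: Sequence[str]
) -> Union[float, str]:
    """Support for a taxon set, or "absent" if it is not an edge of the
    best tree.  Trivial clades (single taxa, the full leaf set and their
    complements) are reported as 1.0 by convention."""
    all_leaves = frozenset(summary.best_tree.leaf_names())
    taxa = frozenset(taxa)
    unknown = taxa - all_leaves
    if unknown:
        raise KeyError(f"unknown taxa: {sorted(unknown)}")
    n = len(all_leaves)
    if len(taxa) <= 1 or len(taxa) >= n - 1:
        return 1.0
    ref = min(all_leaves)
    canon = taxa if ref not in taxa else all_leaves - taxa
    if canon in summary.support:
        return summary.support[canon]
    return "absent"


# ---------------------------------------------------------------------------
# Outgroup rooting
# ---------------------------------------------------------------------------

@dataclass
class OutgroupScheme:
    """A named outgroup/ingroup split of the alignment taxa."""

    name: str
    outgroup: list[str]
    ingroup: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.outgroup) & set(self.ingroup)
        if overlap:
            raise ValueError(f"outgroup and ingroup overlap: {sorted(overlap)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.ingroup) + list(self.outgroup)


def _root_on_edge(tree: PhyloTree, target_side: frozenset) -> PhyloTree:
    """Root a copy of the tree on the edge above the node whose leaf set
    is ``target_side``, splitting that edge at its midpoint."""
    tree = tree.copy()
    v = None
    for node in tree.postorder():
        if node is tree.root:
            continue
        if frozenset(node.leaf_names()) == target_side:
            v = node
            break
    if v is None:
        raise ValueError("no edge subtends the requested leaf set")
    t_len = v.length if v.length is not None else 0.0
    u = v.parent
    u.remove_child(v)
    new_root = Node()
    new_root.add_child(v)
    v.length = t_len / 2.0

    prev_attach: Node = new_root
    prev_length: Optional[float] = t_len / 2.0
    prev_support = v.support
    cur: Optional[Node] = u
    while cur is not None:
        parent = cur.parent
        if parent is not None:
            parent.remove_child(cur)
        carry_length = cur.length
        carry_support = cur.support
        prev_attach.add_child(cur)
        cur.length = prev_length
        cur.support = prev_support
        prev_length = carry_length
        prev_support = carry_support
        prev_attach = cur
        cur = parent
    rooted = PhyloTree(new_root)
    rooted.suppress_unifurcations()
    return rooted


def root_with_outgroup(tree: PhyloTree, scheme: OutgroupScheme) -> PhyloTree:
    """Root on the edge separating the outgroup clade from the ingroup.

    If the outgroup is not monophyletic in the tree, a warning is issued
    and the root goes on the edge whose outgroup side contains the most
    outgroup taxa (fewest ingroup taxa breaking ties).
    """
    leaves = set(tree.leaf_names())
    og = set(scheme.outgroup)
    missing = og - leaves
    if missing:
        raise ValueError(f"outgroup taxa absent from tree: {sorted(missing)}")
    if not og or og == leaves:
        raise ValueError("outgroup must be a proper non-empty subset of taxa")

    sides = []
    for node in tree.postorder():
        if node is tree.root:
            continue
        sides.append(frozenset(node.leaf_names()))
    for side in sides:
        if side == og or leaves - side == og:
            target = side if side == og else side
            return _root_on_edge(tree, side)

    warnings.warn(
        f"outgroup {scheme.name!r} is not monophyletic; rooting on the "
        "edge best separating it",
        stacklevel=2,
    )
    def score(side: frozenset) -> tuple:
        inside = len(side & og)
        outside = len(side - og)
        comp_inside = len(og) - inside
        comp_outside = len(leaves) - len(side) - comp_inside
        # pick the orientation with more outgroup taxa on the outgroup side
        best_local = max(
            (inside, -outside),
            (comp_inside, -comp_outside),
        )
        return best_local

    best_side = max(sides, key=score)
    return _root_on_edge(tree, best_side)
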