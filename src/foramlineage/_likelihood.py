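"""Felsenstein-pruning likelihood engine.

Internal module: holds the per-pattern conditional likelihood machinery
shared by `tree_log_likelihood`, branch-length optimization and the NNI
search.  Arrays are shaped (k categories, p patterns, 4 states) and are
rescaled per node, with the log scaling factors accumulated per pattern.
"""
from __future__ import annotations

import warnings
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .io_formats import Alignment
from .phylo_model import (
    GTRIGParams,
    _CODE_MATRIX,
    _Eigen,
    build_gtr_rate_matrix,
    compress_patterns,
)
from .tree import Node, PhyloTree

#: branch-length search window (expected substitutions per site)
MIN_BRANCH = 1e-9
MAX_BRANCH = 50.0


class TreeLikelihood:
    """Likelihood of one alignment on one (mutable) tree."""

    def __init__(
        self, tree: PhyloTree, aln: Alignment, params: GTRIGParams
    ) -> None:
        tree_taxa = set(tree.leaf_names())
        aln_taxa = set(aln.taxon_ids)
        if tree_taxa != aln_taxa:
            only_tree = sorted(tree_taxa - aln_taxa)
            only_aln = sorted(aln_taxa - tree_taxa)
            raise ValueError(
                "tree and alignment taxa differ; "
                f"only in tree: {only_tree}, only in alignment: {only_aln}"
            )
        self.tree = tree
        self.patterns = compress_patterns(aln)
        self.counts = self.patterns.counts.astype(float)
        # per-leaf partials: (p, 4) indicator/ambiguity vectors
        self._leaf_partials = {
            taxon: _CODE_MATRIX[self.patterns.codes[row]]
            for row, taxon in enumerate(self.patterns.taxon_ids)
        }
        # bases compatible with every leaf simultaneously, per pattern
        comp = np.ones((len(self.counts), 4))
        for part in self._leaf_partials.values():
            comp = comp * part
        self._constant_mask = comp
        self.set_params(params)

    # -- model -------------------------------------------------------------
    def set_params(self, params: GTRIGParams) -> None:
        self.params = params
        q = build_gtr_rate_matrix(params)
        self.pi = params.base_freqs
        self._eigen = _Eigen(q, self.pi)
        self.rates = params.rates()
        self.k = params.n_categories
        self._inv_pi = self._constant_mask @ self.pi
        with np.errstate(divide="ignore"):
            self._log1p_pinv = np.log1p(-params.p_inv)
            self._log_inv = np.log(params.p_inv * self._inv_pi)

    def _pmats(self, t: float) -> np.ndarray:
        """Transition matrices for all rate categories, (k, 4, 4)."""
        return self._eigen.pmats(self.rates * t)

    # -- pruning -----------------------------------------------------------
    def _edge_length(self, node: Node) -> float:
        return node.length if node.length is not None else 0.0

    def _postorder_partials(self):
        """Conditional likelihoods of each subtree, with log scalers."""
        below: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        p = len(self.counts)
        for node in self.tree.postorder():
            key = id(node)
            if node.is_leaf:
                part = np.broadcast_to(
                    self._leaf_partials[node.name], (self.k, p, 4)
                )
                below[key] = part
                scale[key] = np.zeros(p)
                continue
            arr = np.ones((self.k, p, 4))
            sc = np.zeros(p)
            for child in node.children:
                pm = self._pmats(self._edge_length(child))
                arr = arr * (below[id(child)] @ pm.transpose(0, 2, 1))
                sc = sc + scale[id(child)]
            m = arr.max(axis=(0, 2))
            nz = m > 0
            arr[:, nz, :] /= m[None, nz, None]
            with np.errstate(divide="ignore"):
                sc = sc + np.where(nz, np.log(np.where(nz, m, 1.0)), 0.0)
            below[key] = arr
            scale[key] = sc
        return below, scale

    def _combine(self, g: np.ndarray, sc: np.ndarray) -> float:
        """Mixture of the gamma part with the invariant class; sums sites."""
        with np.errstate(divide="ignore"):
            log_var = np.log(g) + sc
            if self.params.p_inv > 0:
                log_site = np.logaddexp(
                    log_var + self._log1p_pinv, self._log_inv
                )
            else:
                log_site = log_var
        total = float(self.counts @ log_site)
        if not np.isfinite(total):
            warnings.warn("zero site likelihood; returning -inf", stacklevel=2)
            return -np.inf
        return total

    def loglik(self) -> float:
        below, scale = self._postorder_partials()
        root = below[id(self.tree.root)]
        g = (root @ self.pi).mean(axis=0)
        return self._combine(g, scale[id(self.tree.root)])

    # -- directional messages (for branch and NNI work) ---------------------
    def flows(self):
        """Rootward messages, down messages and per-edge upper arrays.

        Returns a dict with, keyed by ``id(node)``:
          below  - subtree conditionals at the node
          msg    - below propagated through the node's own edge
          edge_up- everything outside the node's subtree, at the parent,
                   including the stationary prior (so that the total
                   likelihood is  sum_ij edge_up_i P_ij(t) below_j)
        plus matching ``*_scale`` log-scaler arrays.
        """
        below, bscale = self._postorder_partials()
        p = len(self.counts)
        msg: dict[int, np.ndarray] = {}
        mscale: dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            if node is self.tree.root:
                continue
            pm = self._pmats(self._edge_length(node))
            msg[id(node)] = below[id(node)] @ pm.transpose(0, 2, 1)
            mscale[id(node)] = bscale[id(node)]

        down: dict[int, np.ndarray] = {}
        dscale: dict[int, np.ndarray] = {}
        edge_up: dict[int, np.ndarray] = {}
        escale: dict[int, np.ndarray] = {}
        root = self.tree.root
        down[id(root)] = np.broadcast_to(self.pi, (self.k, p, 4))
        dscale[id(root)] = np.zeros(p)
        for node in self.tree.preorder():
            if node.is_leaf:
                continue
            for child in node.children:
                arr = np.array(down[id(node)])
                sc = dscale[id(node)].copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    arr = arr * msg[id(sib)]
                    sc = sc + mscale[id(sib)]
                m = arr.max(axis=(0, 2))
                nz = m > 0
                arr[:, nz, :] /= m[None, nz, None]
                with np.errstate(divide="ignore"):
                    sc = sc + np.where(nz, np.log(np.where(nz, m, 1.0)), 0.0)
                edge_up[id(child)] = arr
                escale[id(child)] = sc
                pm = self._pmats(self._edge_length(child))
                down[id(child)] = arr @ pm
                dscale[id(child)] = sc
        return {
            "below": below, "below_scale": bscale,
            "msg": msg, "msg_scale": mscale,
            "edge_up": edge_up, "edge_up_scale": escale,
            "down": down, "down_scale": dscale,
        }

    def edge_objective(
        self,
        upper: np.ndarray,
        upper_scale: np.ndarray,
        lower: np.ndarray,
        lower_scale: np.ndarray,
    ) -> tuple[Callable[[float], float], Callable[[float], tuple]]:
        """Log-likelihood (and derivatives) as a function of one edge length.

        Precomputes the spectral contraction C_l = (U V')_l (B V'')_l so
        each evaluation only weights four eigenvalue terms per category;
        derivatives in t just multiply those terms by (lambda_l rate_c)^n.
        """
        sc = upper_scale + lower_scale
        contraction = (upper @ self._eigen.left) * (lower @ self._eigen.right.T)
        lamr = np.outer(self.rates, self._eigen.lam)  # (k, 4)
        k = float(self.k)
        counts = self.counts
        p_inv = self.params.p_inv

        def value(t: float) -> float:
            expd = np.exp(lamr * t)
            g = np.einsum("kpl,kl->p", contraction, expd) / k
            np.maximum(g, 1e-300, out=g)  # guard spectral round-off
            return self._combine(g, sc)

        def value_grad(t: float) -> tuple[float, float, float]:
            expd = np.exp(lamr * t)
            g0 = np.einsum("kpl,kl->p", contraction, expd) / k
            g1 = np.einsum("kpl,kl->p", contraction, expd * lamr) / k
            g2 = np.einsum("kpl,kl->p", contraction, expd * lamr * lamr) / k
            np.maximum(g0, 1e-300, out=g0)
            with np.errstate(divide="ignore"):
                log_var = np.log(g0) + sc + self._log1p_pinv
            if p_inv > 0:
                log_site = np.logaddexp(log_var, self._log_inv)
                sigma = np.exp(log_var - log_site)
            else:
                log_site = log_var
                sigma = 1.0
            f = float(counts @ log_site)
            r1 = sigma * (g1 / g0)
            r2 = sigma * (g2 / g0)
            d1 = float(counts @ r1)
            d2 = float(counts @ (r2 - r1 * r1))
            return f, d1, d2

        return value, value_grad

    def _optimize_edge(
        self,
        value: Callable[[float], float],
        value_grad: Callable[[float], tuple],
        current: float,
    ) -> tuple[float, float]:
        """Maximize over one branch length; never worse than ``current``.

        Safeguarded Newton iterations on the analytic derivatives, with a
        bounded golden-section fallback when Newton stalls.
        """
        lo, hi = MIN_BRANCH, MAX_BRANCH
        t = min(max(current, lo), hi)
        f, d1, d2 = value_grad(t)
        f_start, t_start = f, t
        ok = np.isfinite(f)
        if ok:
            for _ in range(25):
                # predicted gain below tolerance -> converged
                if d2 < 0 and d1 * d1 / (-2.0 * d2) < 1e-10:
                    return t, f
                if d2 < 0:
                    step = -d1 / d2
                else:
                    step = (0.5 if d1 > 0 else -0.5) * max(t, 0.01)
                t_new = min(max(t + step, lo), hi)
                if t_new == t:  # pinned at a bound, gradient points out
                    return t, f
                f_new = value(t_new)
                halvings = 0
                while f_new < f and halvings < 12:
                    t_new = 0.5 * (t + t_new)
                    f_new = value(t_new)
                    halvings += 1
                if f_new < f:
                    ok = False
                    break
                if f_new - f < 1e-12 and abs(t_new - t) < 1e-9:
                    return t_new, f_new
                t = t_new
                f, d1, d2 = value_grad(t)
            else:
                ok = False
        if ok:
            return t, f
        # fallback: robust bounded search
        res = minimize_scalar(
            lambda x: -value(x),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        candidates = [(f_start, t_start), (float(-res.fun), float(res.x))]
        if np.isfinite(f):
            candidates.append((f, t))
        best_f, best_t = max(candidates)
        return best_t, best_f

    def _edges(self) -> list[Node]:
        return [n for n in self.tree.preorder() if n is not self.tree.root]

    def optimize_branch_lengths(
        self, tol: float = 1e-6, max_rounds: int = 20
    ) -> float:
        """Cyclic per-edge optimization; the log-likelihood never decreases.

        Each round updates every edge against messages computed at the
        start of the round (fast path).  If that simultaneous update ever
        lowers the likelihood, the round is redone sequentially with
        fresh messages per edge, which is guaranteed monotone.
        """
        ll = self.loglik()
        for _ in range(max_rounds):
            saved = [(n, n.length) for n in self._edges()]
            arrs = self.flows()
            for node in self._edges():
                value, value_grad = self.edge_objective(
                    arrs["edge_up"][id(node)],
                    arrs["edge_up_scale"][id(node)],
                    arrs["below"][id(node)],
                    arrs["below_scale"][id(node)],
                )
                t, _ = self._optimize_edge(
                    value, value_grad, self._edge_length(node)
                )
                node.length = t
            new_ll = self.loglik()
            if new_ll < ll - 1e-9:
                for node, length in saved:
                    node.length = length
                for node in self._edges():
                    arrs = self.flows()
                    value, value_grad = self.edge_objective(
                        arrs["edge_up"][id(node)],
                        arrs["edge_up_scale"][id(node)],
                        arrs["below"][id(node)],
                        arrs["below_scale"][id(node)],
                    )
                    t, _ = self._optimize_edge(
                        value, value_grad, self._edge_length(node)
                    )
                    node.length = t
                new_ll = self.loglik()
            improvement = new_ll - ll
            ll = max(new_ll, ll)
            if improvement < tol:
                break
        if not np.isfinite(ll):
            raise ValueError("non-finite likelihood during branch optimization")
        return ll
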