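"""Felsenstein pruning over a fixed tree, shared by all likelihood code.

The engine evaluates mixture likelihoods of the form

    L_site = sum_c w_c * pi_c' D_root(c, site)

where class c has its own transition matrix on every edge, and provides

* analytic branch-length gradients via an outside (preorder) pass using
  dP(t)/dt = Q P(t), and
* per-node marginal posteriors (inside x outside), the basis of marginal
  ancestral reconstruction.

States are generic integers (20 amino acids or 61 sense codons); a leaf
code of -1 (gap/ambiguous) contributes a vector of ones.  No per-node
rescaling is applied: with the tree sizes used here (<= ~20 taxa) per-site
likelihoods stay comfortably within double range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import PhyloTree


def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse identical site columns.  Returns (patterns, counts, inverse).

    ``codes``: (n_taxa, n_sites) integer states.  ``patterns`` is
    (n_taxa, n_patterns); ``inverse`` maps original sites to patterns.
    """
    cols, inverse, counts = np.unique(codes, axis=1, return_inverse=True,
                                      return_counts=True)
    return cols, counts.astype(float), inverse


@dataclass
class LikResult:
    lnl: float
    site_lnl: np.ndarray                    # per pattern
    class_site_lik: np.ndarray              # (C, n_patterns)
    grad_bl: np.ndarray | None = None       # per node index (root entry 0)
    node_posteriors: np.ndarray | None = None  # (n_nodes, n_patterns, K)


class PruningEngine:
    """Pruning likelihoods on one tree topology for one leaf data matrix."""

    def __init__(self, tree: PhyloTree, leaf_codes: dict[str, np.ndarray],
                 n_states: int):
        self.tree = tree
        self.n_states = n_states
        self.nodes = tree.postorder                  # root last
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.n_nodes = len(self.nodes)
        self.root_idx = self.n_nodes - 1
        first = next(iter(leaf_codes.values()))
        self.n_patterns = len(first)
        self.leaf_onehot: dict[int, np.ndarray] = {}
        for node in tree.leaves:
            codes = np.asarray(leaf_codes[node.name])
            oh = np.ones((self.n_patterns, n_states))
            obs = codes >= 0
            oh[obs] = 0.0
            oh[np.arange(self.n_patterns)[obs], codes[obs]] = 1.0
            self.leaf_onehot[self.index[id(node)]] = oh

    def compute(self, P: np.ndarray, weights: np.ndarray,
                root_freqs: np.ndarray, counts: np.ndarray | None = None,
                Q: np.ndarray | None = None,
                node_posteriors: bool = False) -> LikResult:
        """Evaluate the mixture likelihood.

        P: (C, n_nodes, K, K) transition matrix for the edge above each
        node (root entry ignored).  weights: (C,) class proportions.
        root_freqs: (K,) or (C, K).  Q: optional (C, n_nodes, K, K) rate
        matrices per edge; when given, analytic d lnL / d t per edge is
        returned.
        """
        C = P.shape[0]
        S, K = self.n_patterns, self.n_states
        pf = np.asarray(root_freqs, dtype=float)
        if pf.ndim == 1:
            pf = np.broadcast_to(pf, (C, K))
        if counts is None:
            counts = np.ones(S)
        down = [None] * self.n_nodes                 # inside partials (C,S,K)
        emarg = [None] * self.n_nodes                # P_v @ down_v at parent end
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                d = np.broadcast_to(self.leaf_onehot[i], (C, S, K))
            else:
                d = np.ones((C, S, K))
                for child in node.children:
                    d = d * emarg[self.index[id(child)]]
            down[i] = d
            if node.parent is not None:
                emarg[i] = np.matmul(d, P[:, i].transpose(0, 2, 1))
        class_lik = np.einsum("ck,csk->cs", pf, down[self.root_idx])
        site_lik = np.maximum(weights @ class_lik.reshape(C, S), 1e-300)
        site_lnl = np.log(site_lik)
        lnl = float(counts @ site_lnl)
        result = LikResult(lnl=lnl, site_lnl=site_lnl, class_site_lik=class_lik)

        if Q is None and not node_posteriors:
            return result

        # outside pass: o_v(i) = P(rest of data | parent-of-v = i) * prior
        outside = [None] * self.n_nodes
        for i in range(self.n_nodes - 1, -1, -1):
            node = self.nodes[i]
            if node.is_leaf:
                continue
            if node.parent is None:
                u = np.broadcast_to(pf[:, None, :], (C, S, K))
            else:
                u = np.matmul(outside[i], P[:, i])
            for child in node.children:
                ci = self.index[id(child)]
                o = u
                for sib in node.children:
                    if sib is child:
                        continue
                    o = o * emarg[self.index[id(sib)]]
                outside[ci] = o

        if Q is not None:
            grad = np.zeros(self.n_nodes)
            w = np.asarray(weights, dtype=float)
            inv_site = counts / site_lik
            for i, node in enumerate(self.nodes):
                if node.parent is None:
                    continue
                oq = np.matmul(outside[i], Q[:, i])       # (C,S,K)
                dL = np.einsum("csk,csk->cs", oq, emarg[i])
                grad[i] = float(((w @ dL.reshape(C, S)) * inv_site).sum())
            result.grad_bl = grad

        if node_posteriors:
            post = np.zeros((self.n_nodes, S, K))
            w = np.asarray(weights, dtype=float)
            for i, node in enumerate(self.nodes):
                if node.is_leaf:
                    continue
                if node.parent is None:
                    out_here = np.broadcast_to(pf[:, None, :], (C, S, K))
                else:
                    out_here = np.matmul(outside[i], P[:, i])
                joint = np.einsum("c,csk->sk", w, out_here * down[i])
                tot = joint.sum(axis=1, keepdims=True)
                post[i] = joint / np.maximum(tot, 1e-300)
            result.node_posteriors = post
        return result
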