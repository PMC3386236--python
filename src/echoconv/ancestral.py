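"""Distance-based Bayesian ancestral amino-acid reconstruction.

The procedure fixes the species topology, estimates branch lengths by
ordinary least squares from pairwise protein distances (Poisson-corrected
p-distances by default, keeping lengths on the substitutions-per-site
scale), and then computes, for every internal node and site, the marginal
posterior distribution over the 20 residues under the JTT model with
observed frequencies ("+F"), via the pruning recursion.  Substitutions are
mapped onto branches by comparing MAP states at the two ends of each edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, encode_protein
from .distances import DistanceMatrix
from .likelihood import PruningEngine, compress_patterns
from .models import AA_ORDER, ReversibleModel, aa_rate_matrix
from .tree import Node, PhyloTree


def poisson_corrected_matrix(D: DistanceMatrix) -> DistanceMatrix:
    """Poisson correction d = -ln(1 - p) of a p-distance matrix."""
    with np.errstate(invalid="ignore", divide="ignore"):
        v = -np.log(1.0 - D.values)
    v[D.values >= 1.0] = np.nan
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(list(D.names), v)


def least_squares_branch_lengths(topology: PhyloTree,
                                 D: DistanceMatrix) -> PhyloTree:
    """Fit branch lengths minimizing sum (d_ij - path_ij)^2.

    Negative estimates are fixed at zero and the remaining lengths refit.
    When the root is a bifurcation the two root-adjacent edges are only
    identifiable as a sum; they are fit as one variable and the estimate is
    split equally between them.
    """
    tree = topology.copy()
    if set(tree.leaf_names) != set(D.names):
        raise ValueError("tree leaves do not match distance-matrix names")
    if np.isnan(D.values).any():
        raise ValueError("distance matrix contains undefined entries")
    nodes = [n for n in tree.postorder if n.parent is not None]
    node_pos = {id(n): k for k, n in enumerate(nodes)}
    # map each edge to a free variable; merge the two root edges if binary
    var_of_edge = list(range(len(nodes)))
    if len(tree.root.children) == 2:
        a, b = tree.root.children
        var_of_edge[node_pos[id(b)]] = node_pos[id(a)]
    var_ids = sorted(set(var_of_edge))
    var_index = {v: k for k, v in enumerate(var_ids)}
    n_vars = len(var_ids)

    leaf_nodes = {n.name: n for n in tree.leaves}
    names = D.names
    rows, y = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            path = np.zeros(n_vars)
            # edges on the path = symmetric difference of root-paths
            seen: dict[int, Node] = {}
            for start in (leaf_nodes[names[i]], leaf_nodes[names[j]]):
                n = start
                while n.parent is not None:
                    if id(n) in seen:
                        del seen[id(n)]
                    else:
                        seen[id(n)] = n
                    n = n.parent
            for n in seen.values():
                path[var_index[var_of_edge[node_pos[id(n)]]]] += 1.0
            rows.append(path)
            y.append(D.values[i, j])
    X = np.array(rows)
    y = np.array(y)
    if np.allclose(y, 0):
        raise ValueError("singular design: all distances zero")

    free = np.ones(n_vars, dtype=bool)
    beta = np.zeros(n_vars)
    for _ in range(n_vars + 1):
        sol, *_ = np.linalg.lstsq(X[:, free], y, rcond=None)
        beta[:] = 0.0
        beta[free] = sol
        neg = beta < 0
        if not neg.any():
            break
        free &= ~neg
        if not free.any():
            beta[:] = 0.0
            break
    # a merged variable carries a +1 coefficient per root edge on the path,
    # so its estimate already is the common per-edge length (the equal split)
    for k, n in enumerate(nodes):
        n.length = max(float(beta[var_index[var_of_edge[k]]]), 0.0)
    return tree


@dataclass
class AncestralReconstruction:
    """Marginal posteriors and MAP residues at every internal node."""

    tree: PhyloTree
    posteriors: dict[str, np.ndarray]       # edge_id -> (n_sites, 20)
    map_states: dict[str, np.ndarray]       # edge_id -> residue index
    map_posterior: dict[str, np.ndarray]
    frequencies: np.ndarray
    model: str = "JTT+F"
    all_gap_sites: list[int] = field(default_factory=list)   # 1-based

    @property
    def n_sites(self) -> int:
        return next(iter(self.posteriors.values())).shape[0]

    def map_residue(self, edge_id: str, site: int) -> str:
        """MAP residue at a 1-based protein site."""
        return AA_ORDER[self.map_states[edge_id][site - 1]]


def _map_with_tiebreak(post: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Argmax with ties broken by higher equilibrium frequency, then
    alphabetically."""
    order = sorted(range(20), key=lambda i: (-pi[i], AA_ORDER[i]))
    ranked = post[:, order]
    best = np.argmax(np.round(ranked, 12), axis=1)
    return np.array(order)[best]


def marginal_ancestral_states(protein_aln: Alignment, tree: PhyloTree,
                              frequencies: str | np.ndarray = "observed"
                              ) -> AncestralReconstruction:
    """Marginal posterior ancestral residues under JTT(+F).

    ``frequencies``: "observed" (alignment-wide counts), "jtt" (published
    equilibrium), or an explicit 20-vector.  Branch lengths of ``tree`` are
    used as-is and must be set (>= 0).
    """
    if protein_aln.kind != "protein":
        raise ValueError("marginal_ancestral_states requires a protein alignment")
    if set(protein_aln.names) != set(tree.leaf_names):
        raise ValueError("alignment names do not match tree leaves")
    for n in tree.postorder:
        if n.parent is not None and (n.length is None or n.length < 0):
            raise ValueError("tree must carry non-negative branch lengths")
    codes = encode_protein(protein_aln)
    if isinstance(frequencies, str):
        if frequencies == "observed":
            obs = codes[codes >= 0]
            freqs = (np.bincount(obs, minlength=20) + 1.0)
            freqs = freqs / freqs.sum()
        elif frequencies == "jtt":
            freqs = None
        else:
            raise ValueError(f"unknown frequency mode {frequencies!r}")
    else:
        freqs = np.asarray(frequencies, dtype=float)
    Q, pi = aa_rate_matrix(freqs)
    model = ReversibleModel(Q, pi)

    patterns, counts, inverse = compress_patterns(codes)
    leaf_codes = {name: patterns[i] for i, name in enumerate(protein_aln.names)}
    engine = PruningEngine(tree, leaf_codes, 20)
    lengths = np.array([n.length if n.parent is not None else 0.0
                        for n in tree.postorder])
    P = model.transition_matrices(lengths)[None, :, :, :]
    res = engine.compute(P, np.ones(1), pi, counts=counts,
                         node_posteriors=True)

    all_gap = [int(s) + 1 for s in range(protein_aln.length)
               if (patterns[:, inverse[s]] < 0).all()]
    posteriors, map_states, map_post = {}, {}, {}
    for i, node in enumerate(tree.postorder):
        if node.is_leaf:
            continue
        eid = tree.edge_id(node)
        post = res.node_posteriors[i][inverse]        # (n_sites, 20)
        posteriors[eid] = post
        ms = _map_with_tiebreak(post, pi)
        map_states[eid] = ms
        map_post[eid] = post[np.arange(len(ms)), ms]
    return AncestralReconstruction(
        tree=tree, posteriors=posteriors, map_states=map_states,
        map_posterior=map_post, frequencies=pi, all_gap_sites=all_gap)


@dataclass
class SubstitutionEvent:
    """One inferred replacement on one branch, e.g. R204Q at site 204."""

    branch: str
    site: int                               # 1-based protein site
    parent_aa: str
    child_aa: str
    parent_posterior: float
    child_posterior: float

    def __post_init__(self):
        if self.parent_aa == self.child_aa:
            raise ValueError("event with identical parent and child residue")

    def __str__(self) -> str:
        return f"{self.parent_aa}{self.site}{self.child_aa}"


def map_substitutions(rec: AncestralReconstruction, aln: Alignment
                      ) -> dict[str, list[SubstitutionEvent]]:
    """Per-branch replacement events from MAP states.

    For each edge, an event is emitted at a site iff the MAP residue at the
    parent node differs from the child state (the observed leaf residue for
    terminal branches, the child's MAP residue otherwise).  Leaf gaps or 'X'
    yield no event.
    """
    tree = rec.tree
    codes = encode_protein(aln)
    row = {name: codes[i] for i, name in enumerate(aln.names)}
    events: dict[str, list[SubstitutionEvent]] = {}
    for node in tree.postorder:
        if node.parent is None:
            continue
        eid = tree.edge_id(node)
        pid = tree.edge_id(node.parent)
        pstate = rec.map_states[pid]
        ppost = rec.map_posterior[pid]
        if node.is_leaf:
            cstate = row[node.name]
            cpost = np.ones(len(cstate))
        else:
            cstate = rec.map_states[eid]
            cpost = rec.map_posterior[eid]
        evs = []
        for s in np.nonzero((cstate >= 0) & (pstate != cstate))[0]:
            evs.append(SubstitutionEvent(
                branch=eid, site=int(s) + 1,
                parent_aa=AA_ORDER[pstate[s]], child_aa=AA_ORDER[cstate[s]],
                parent_posterior=float(ppost[s]),
                child_posterior=float(cpost[s])))
        events[eid] = evs
    return events
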