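"""Detection and significance testing of parallel/convergent substitutions.

A site is *parallel* for a set of focal branches when every branch carries a
replacement at that site with the same parent residue and the same derived
residue; it is *convergent* when the derived residues agree but the parent
residues do not all agree.  The expected numbers of such events under the
null of independent substitution along each branch are computed from the
amino-acid model's per-branch replacement probabilities, conditioning on the
(posterior-weighted) parent states — the classic test of whether observed
sharing exceeds chance — and the observed count is referred to a Poisson
tail probability with that expectation as the mean.

Reports distinguish parallel from convergent sites, but the headline count
and test combine them, matching how shared replacements are conventionally
tallied in the echolocation literature.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .alignment import Alignment
from .ancestral import AncestralReconstruction, SubstitutionEvent
from .distances import aa_p_matrix, neighbor_joining
from .models import ReversibleModel, aa_rate_matrix
from .tree import PhyloTree


@dataclass
class ConvergenceReport:
    """Observed and expected shared replacements for a branch pair/triple."""

    branches: tuple[str, ...]
    parallel_sites: list[str] = field(default_factory=list)    # "R204Q"
    convergent_sites: list[str] = field(default_factory=list)  # "{K|T}10R"
    e_parallel: float | None = None
    e_convergent: float | None = None
    p_parallel: float | None = None
    p_convergent: float | None = None
    p_total: float | None = None

    @property
    def o_parallel(self) -> int:
        return len(self.parallel_sites)

    @property
    def o_convergent(self) -> int:
        return len(self.convergent_sites)

    @property
    def o_total(self) -> int:
        """Headline count: parallel + convergent."""
        return self.o_parallel + self.o_convergent

    @property
    def e_total(self) -> float | None:
        if self.e_parallel is None or self.e_convergent is None:
            return None
        return self.e_parallel + self.e_convergent

    def summary(self) -> str:
        lines = [f"branches {'^'.join(self.branches)}: "
                 f"O_par={self.o_parallel} O_conv={self.o_convergent}"]
        if self.e_parallel is not None:
            lines.append(f"  E_par={self.e_parallel:.4f} "
                         f"E_conv={self.e_convergent:.4f} "
                         f"p_total={self.p_total:.3g}")
        if self.parallel_sites:
            lines.append("  parallel: " + ", ".join(self.parallel_sites))
        if self.convergent_sites:
            lines.append("  convergent: " + ", ".join(self.convergent_sites))
        return "\n".join(lines)


def find_shared_changes(events_by_branch: dict[str, list[SubstitutionEvent]],
                        branches: set[str] | list[str],
                        tree: PhyloTree | None = None) -> ConvergenceReport:
    """Observed parallel/convergent sites shared by 2-3 focal branches.

    ``tree`` (optional) enables the non-nestedness check: focal branches
    must not be ancestral to one another.
    """
    branches = tuple(sorted(branches))
    if not 2 <= len(branches) <= 3:
        raise ValueError("need 2 or 3 focal branches")
    if tree is not None:
        nodes = {b: tree.node_by_edge_id(b) for b in branches}
        for a in branches:
            for b in branches:
                if a != b and tree.is_ancestor(nodes[a], nodes[b]):
                    raise ValueError(
                        f"focal branches nested: {a} is ancestral to {b}")
    by_site = []
    for b in branches:
        by_site.append({e.site: e for e in events_by_branch.get(b, [])})
    shared = set(by_site[0])
    for d in by_site[1:]:
        shared &= set(d)
    report = ConvergenceReport(branches=branches)
    for site in sorted(shared):
        evs = [d[site] for d in by_site]
        derived = {e.child_aa for e in evs}
        if len(derived) != 1:
            continue
        parents = [e.parent_aa for e in evs]
        to = evs[0].child_aa
        if len(set(parents)) == 1:
            report.parallel_sites.append(f"{parents[0]}{site}{to}")
        else:
            report.convergent_sites.append(
                "{" + "|".join(parents) + "}" + f"{site}{to}")
    return report


def zhang_kumar_expectation(rec: AncestralReconstruction,
                            branches: set[str] | list[str],
                            mode: str = "posterior"
                            ) -> tuple[float, float]:
    """Expected parallel and convergent counts for the focal branches.

    Per site, the probability that every focal branch experiences a
    replacement ending in the same residue is accumulated from the
    amino-acid model transition probabilities P(t) on each branch,
    conditioned on the parent-node state — the full posterior distribution
    by default (``mode="posterior"``) or the MAP point estimate
    (``mode="map"``, for sensitivity analysis).  Returns (E_par, E_conv).
    """
    branches = tuple(sorted(branches))
    tree = rec.tree
    Q, pi = aa_rate_matrix(rec.frequencies)
    model = ReversibleModel(Q, pi)
    n_sites = rec.n_sites
    weights, Ps = [], []
    for b in branches:
        node = tree.node_by_edge_id(b)
        if node.parent is None:
            raise ValueError(f"focal branch {b!r} is the root")
        t = node.length or 0.0
        if t <= 0:
            warnings.warn(f"focal branch {b!r} has zero length; "
                          "its expected contribution is zero")
        pid = tree.edge_id(node.parent)
        w = rec.posteriors[pid]
        if mode == "map":
            onehot = np.zeros_like(w)
            ms = rec.map_states[pid]
            onehot[np.arange(n_sites), ms] = 1.0
            w = onehot
        elif mode != "posterior":
            raise ValueError(f"unknown mode {mode!r}")
        weights.append(w)
        Ps.append(model.transition_matrix(t))

    # prob. of a replacement ending at residue r, per branch and site
    subst = []
    for w, P in zip(weights, Ps):
        subst.append(w @ P - w * np.diag(P)[None, :])
    prod = np.ones_like(subst[0])
    for v in subst:
        prod = prod * v
    e_same_end = float(prod.sum())

    # parallel part: identical parent residue a on every branch, same b != a
    Pprod = np.ones_like(Ps[0])
    for P in Ps:
        Pprod = Pprod * P
    m = Pprod.sum(axis=1) - np.diag(Pprod)        # sum_{b != a} prod_i P_i[a,b]
    wprod = np.ones_like(weights[0])
    for w in weights:
        wprod = wprod * w
    e_par = float((wprod * m[None, :]).sum())
    e_conv = max(e_same_end - e_par, 0.0)
    return e_par, e_conv


def poisson_tail_test(O: int, E: float) -> float:
    """Upper-tail Poisson probability P(X >= O) with mean E.

    O = 0 returns 1.  A non-positive expectation with O > 0 is reported as
    machine epsilon (with a warning): any observation is then "impossible"
    under the null.
    """
    if O < 0 or O != int(O):
        raise ValueError("O must be a non-negative integer")
    if O == 0:
        return 1.0
    if E <= 0:
        warnings.warn("non-positive expectation with positive observed count")
        return sys.float_info.epsilon
    return float(poisson.sf(O - 1, E))


def convergence_test(rec: AncestralReconstruction,
                     events_by_branch: dict[str, list[SubstitutionEvent]],
                     branches: set[str] | list[str],
                     mode: str = "posterior") -> ConvergenceReport:
    """Full report: observed sites, expectations, and Poisson p-values."""
    report = find_shared_changes(events_by_branch, branches, tree=rec.tree)
    e_par, e_conv = zhang_kumar_expectation(rec, branches, mode=mode)
    report.e_parallel = e_par
    report.e_convergent = e_conv
    report.p_parallel = poisson_tail_test(report.o_parallel, e_par)
    report.p_convergent = poisson_tail_test(report.o_convergent, e_conv)
    report.p_total = poisson_tail_test(report.o_total, e_par + e_conv)
    return report


def exclude_sites_and_rebuild(protein_aln: Alignment,
                              sites: list[int]) -> PhyloTree:
    """NJ (p-distance) tree on the protein alignment minus the given
    1-based sites.  Excluding every column raises ValueError."""
    reduced = protein_aln.drop_protein_sites(sites) if sites else protein_aln
    return neighbor_joining(aa_p_matrix(reduced))
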