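"""Pairwise distances and neighbor-joining.

Implements the distance machinery behind the gene-tree incongruence
analysis: uncorrected p-distances for proteins, Kimura two-parameter (K2P)
corrected distances for nucleotides, and Li-Wu-Luo (LWL) synonymous (Ks)
and nonsynonymous (Ka) distances for in-frame codon sequences, plus
neighbor-joining and nonparametric bootstrap supports.

Gap handling is pairwise deletion throughout: a column (codon) is compared
for a pair only when both sequences have an unambiguous state there.

The LWL method classifies each codon position as nondegenerate (0-fold),
two-fold or four-fold degenerate under the standard genetic code, counts
transitional and transversional differences per class, applies the K2P
correction within each class, and composes

    Ks = (L2*A2 + L4*(A4+B4)) / (L2/3 + L4)
    Ka = (L2*B2 + L0*(A0+B0)) / (2*L2/3 + L0)

where A_i and B_i are the corrected transitional and transversional rates
in class i and L_i the (pair-averaged) site counts.  A position whose class
differs between the two codons is apportioned half to each class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, encode_codons, encode_nucleotides, encode_protein
from .models import CODON_INDEX, SENSE_CODONS, standard_dna_table
from .tree import Node, PhyloTree

# ---------------------------------------------------------------------------
# Elementary pairwise distances


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Proportion of differing columns under pairwise deletion.

    Returns (p, number of compared columns); (nan, 0) when no column is
    comparable.  Columns with '-', 'X' or '?' in either sequence are skipped
    ('N' counts as a residue here: this function sees protein alignments;
    nucleotide ambiguity is handled by the nucleotide-specific distances).
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    skip = set("-X?")
    n = diff = 0
    for x, y in zip(a, b):
        if x in skip or y in skip:
            continue
        n += 1
        diff += x != y
    if n == 0:
        return float("nan"), 0
    return diff / n, n


def k2p_from_proportions(P: float, Q: float) -> float:
    """K2P distance from transition (P) and transversion (Q) proportions.

    Returns nan when either logarithm argument is non-positive (saturation).
    """
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return float("nan")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(a: str, b: str) -> float:
    """K2P corrected distance between two aligned nucleotide sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    valid = set("ACGT")
    purines = set("AG")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in valid or y not in valid:
            continue
        n += 1
        if x != y:
            if (x in purines) == (y in purines):
                ts += 1
            else:
                tv += 1
    if n == 0:
        return float("nan")
    return k2p_from_proportions(ts / n, tv / n)


# ---------------------------------------------------------------------------
# Li-Wu-Luo codon distances via precomputed per-codon-pair tables


def _position_fold(codon: str, pos: int) -> int:
    """Degeneracy class (0, 2 or 4) of one codon position."""
    aa = standard_dna_table.forward_table[codon]
    syn = 0
    for nt in "TCAG":
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1:]
        if standard_dna_table.forward_table.get(alt) == aa:
            syn += 1
    if syn == 3:
        return 4
    return 2 if syn > 0 else 0


_FOLD_CLASS = {0: 0, 2: 1, 4: 2}


def _build_lwl_tables() -> dict[str, np.ndarray]:
    """Per ordered sense-codon pair (61*61): site and difference counts.

    L[k]: pair-averaged site count in class k; S[k]/V[k]: transitional /
    transversional differences attributed to class k (half-and-half when the
    two codons disagree on the class).
    """
    n = len(SENSE_CODONS)
    L = np.zeros((3, n * n))
    S = np.zeros((3, n * n))
    V = np.zeros((3, n * n))
    folds = [[_FOLD_CLASS[_position_fold(c, p)] for p in range(3)]
             for c in SENSE_CODONS]
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            idx = i * n + j
            for p in range(3):
                ki, kj = folds[i][p], folds[j][p]
                L[ki, idx] += 0.5
                L[kj, idx] += 0.5
                if ci[p] != cj[p]:
                    is_ts = {ci[p], cj[p]} in ({"A", "G"}, {"C", "T"})
                    tgt = S if is_ts else V
                    tgt[ki, idx] += 0.5
                    tgt[kj, idx] += 0.5
    return {"L": L, "S": S, "V": V}


_LWL = _build_lwl_tables()


@dataclass
class KaKsPair:
    """LWL nonsynonymous (Ka) and synonymous (Ks) distances for one pair."""

    ka: float
    ks: float
    sites: dict[str, float]                 # L0, L2, L4 compared
    failed_classes: list[str] = field(default_factory=list)

    @property
    def ka_defined(self) -> bool:
        return math.isfinite(self.ka)

    @property
    def ks_defined(self) -> bool:
        return math.isfinite(self.ks)


def _lwl_from_counts(L: np.ndarray, S: np.ndarray, V: np.ndarray) -> KaKsPair:
    A = np.zeros(3)
    B = np.zeros(3)
    failed = []
    for k, name in enumerate(("0-fold", "2-fold", "4-fold")):
        if L[k] <= 0:
            continue
        P, Q = S[k] / L[k], V[k] / L[k]
        w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if w1 <= 0 or w2 <= 0:
            A[k] = B[k] = float("nan")
            failed.append(name)
            continue
        A[k] = -0.5 * math.log(w1) + 0.25 * math.log(w2)
        B[k] = -0.5 * math.log(w2)
    syn_sites = L[1] / 3.0 + L[2]
    nonsyn_sites = 2.0 * L[1] / 3.0 + L[0]
    ks = (L[1] * A[1] + L[2] * (A[2] + B[2])) / syn_sites if syn_sites > 0 \
        else float("nan")
    ka = (L[1] * B[1] + L[0] * (A[0] + B[0])) / nonsyn_sites if nonsyn_sites > 0 \
        else float("nan")
    return KaKsPair(ka=float(ka), ks=float(ks),
                    sites={"L0": float(L[0]), "L2": float(L[1]),
                           "L4": float(L[2])},
                    failed_classes=failed)


def lwl_ka_ks(a: str, b: str) -> KaKsPair:
    """LWL Ka/Ks between two in-frame, stop-free codon sequences.

    Codons containing gaps or ambiguity in either sequence are skipped.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("sequence length not divisible by 3")
    n61 = len(SENSE_CODONS)
    L = np.zeros(3)
    S = np.zeros(3)
    V = np.zeros(3)
    for k in range(0, len(a), 3):
        ca, cb = a[k:k + 3], b[k:k + 3]
        ia, ib = CODON_INDEX.get(ca, -1), CODON_INDEX.get(cb, -1)
        if ia < 0 or ib < 0:
            continue
        idx = ia * n61 + ib
        L += _LWL["L"][:, idx]
        S += _LWL["S"][:, idx]
        V += _LWL["V"][:, idx]
    return _lwl_from_counts(L, S, V)


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray                      # symmetric, zero diagonal

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match names")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(v - v.T)) > 1e-9:
                raise ValueError("matrix not symmetric")
            if np.nanmin(v) < -1e-12:
                raise ValueError("negative distances")
        self.values = v

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.names)]
        for name, row in zip(self.names, self.values):
            lines.append(name + "\t" + "\t".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def nt_k2p_matrix(aln: Alignment) -> DistanceMatrix:
    """K2P distance matrix for a nucleotide/codon alignment."""
    codes = encode_nucleotides(aln)
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = codes[i], codes[j]
            m = (xi >= 0) & (xj >= 0)
            tot = int(m.sum())
            if tot == 0:
                D[i, j] = D[j, i] = np.nan
                continue
            d = xi[m] != xj[m]
            # with T=0 C=1 A=2 G=3, a substitution is a transition iff the
            # two codes share the same pyrimidine/purine half (code // 2)
            ts = int((d & ((xi[m] // 2) == (xj[m] // 2))).sum())
            tv = int(d.sum()) - ts
            D[i, j] = D[j, i] = k2p_from_proportions(ts / tot, tv / tot)
    return DistanceMatrix(list(aln.names), D)


def aa_p_matrix(aln: Alignment) -> DistanceMatrix:
    """Uncorrected p-distance matrix for a protein alignment."""
    codes = encode_protein(aln)
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = (codes[i] >= 0) & (codes[j] >= 0)
            tot = int(m.sum())
            D[i, j] = D[j, i] = (np.nan if tot == 0
                                 else float((codes[i][m] != codes[j][m]).mean()))
    return DistanceMatrix(list(aln.names), D)


def lwl_matrices(aln: Alignment) -> tuple[DistanceMatrix, DistanceMatrix]:
    """(Ka matrix, Ks matrix) for a codon alignment, via the LWL tables."""
    codes = encode_codons(aln)
    n = aln.n_taxa
    n61 = len(SENSE_CODONS)
    Ka = np.zeros((n, n))
    Ks = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = (codes[i] >= 0) & (codes[j] >= 0)
            idx = codes[i][m].astype(np.int64) * n61 + codes[j][m]
            L = _LWL["L"][:, idx].sum(axis=1)
            S = _LWL["S"][:, idx].sum(axis=1)
            V = _LWL["V"][:, idx].sum(axis=1)
            pair = _lwl_from_counts(L, S, V)
            Ka[i, j] = Ka[j, i] = pair.ka
            Ks[i, j] = Ks[j, i] = pair.ks
    return (DistanceMatrix(list(aln.names), Ka),
            DistanceMatrix(list(aln.names), Ks))


# ---------------------------------------------------------------------------
# Neighbor-joining


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining.

    Returns an unrooted tree represented with a trifurcating root (the final
    three-way join).  Negative branch-length estimates are clamped to zero.
    Exactly recovers the generating tree on additive matrices.
    """
    n = len(D.names)
    if n < 3:
        raise ValueError("neighbor-joining requires at least 3 taxa")
    if D.has_undefined:
        raise ValueError("distance matrix contains undefined entries")
    d = D.values.astype(float).copy()
    nodes = [Node(name=name) for name in D.names]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        di = 0.5 * sub[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        dj = sub[i, j] - di
        ai, aj = active[i], active[j]
        left, right = nodes[ai], nodes[aj]
        left.length = max(di, 0.0)
        right.length = max(dj, 0.0)
        parent = Node(children=[left, right])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[ai] + d[aj] - d[ai, aj])
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]
    a, b, c = active
    # closed-form star resolution for the last three lineages
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = max(ln, 0.0)
    return PhyloTree(Node(children=[nodes[a], nodes[b], nodes[c]]))


def bootstrap_supports(aln: Alignment, distance_fn, n_reps: int,
                       seed: int) -> PhyloTree:
    """NJ tree with per-edge bootstrap support percentages.

    ``distance_fn`` maps an Alignment to a DistanceMatrix.  Resampling is by
    alignment column, or by codon for codon alignments.  Supports (0-100)
    are attached to internal nodes as ``node.support`` and as the node name,
    by bipartition matching against the full-data tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(distance_fn(aln))
    rng = np.random.default_rng(seed)
    unit = 3 if aln.kind == "codon" else 1
    n_units = aln.length // unit
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        pick = rng.integers(0, n_units, size=n_units)
        if unit == 1:
            cols = pick
        else:
            cols = (pick[:, None] * 3 + np.arange(3)).ravel()
        rep_tree = neighbor_joining(distance_fn(aln.take_columns(cols)))
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    for node in tree.internal:
        if node is tree.root:
            continue
        all_leaves = frozenset(tree.leaf_names)
        ref = min(all_leaves)
        side = frozenset(tree.subtree_leaves(node))
        if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
            continue
        if ref in side:
            side = all_leaves - side
        pct = 100.0 * counts.get(side, 0) / n_reps
        node.support = pct
        node.name = f"{pct:.0f}"
    return tree
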