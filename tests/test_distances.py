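"""Distances (p, K2P, Li-Wu-Luo) and neighbor-joining."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import echoconv as ec
from echoconv.distances import (DistanceMatrix, k2p_from_proportions,
                                lwl_ka_ks, neighbor_joining, p_distance)
from echoconv.models import SENSE_CODONS


class TestPDistance:
    def test_identical(self):
        assert p_distance("MKVMKV", "MKVMKV") == (0.0, 6)

    def test_one_third(self):
        p, n = p_distance("MKV", "MRV")
        assert p == pytest.approx(1 / 3) and n == 3

    def test_no_comparable_columns_flagged(self):
        p, n = p_distance("M-", "-K")
        assert math.isnan(p) and n == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.tuples(st.text("ARNDC-X", min_size=20, max_size=20),
                     st.text("ARNDC-X", min_size=20, max_size=20)))
    def test_matches_brute_force_column_scan(self, pair):
        a, b = pair
        p, n = p_distance(a, b)
        cols = [(x, y) for x, y in zip(a, b)
                if x not in "-X" and y not in "-X"]
        if not cols:
            assert math.isnan(p)
        else:
            assert n == len(cols)
            assert p == pytest.approx(
                sum(x != y for x, y in cols) / len(cols))


class TestK2P:
    def test_zero(self):
        assert k2p_from_proportions(0.0, 0.0) == 0.0

    def test_closed_form(self):
        # d = -0.5 ln(0.75) - 0.25 ln(0.9) at P=0.1, Q=0.05
        expect = -0.5 * math.log(0.75) - 0.25 * math.log(0.9)
        assert k2p_from_proportions(0.1, 0.05) == pytest.approx(expect)

    def test_saturation_flag(self):
        assert math.isnan(k2p_from_proportions(0.45, 0.2))

    def test_k2p_at_least_p_distance(self, null_alignment):
        aln, _ = null_alignment
        a, b = aln.sequences[0], aln.sequences[5]
        p, _ = p_distance(a, b)
        assert ec.k2p_distance(a, b) >= p


class TestLWL:
    def test_identical_zero(self):
        s = "ATGAAACCTGGG" * 5
        pair = lwl_ka_ks(s, s)
        assert pair.ka == 0.0 and pair.ks == 0.0

    def test_single_fourfold_synonymous_change(self):
        a = "GGA" + "GGT" * 100
        b = "GGG" + "GGT" * 100
        pair = lwl_ka_ks(a, b)
        assert pair.ka == 0.0
        assert pair.ks > 0.0

    def test_saturated_class_flagged(self):
        # the only 4-fold site is 100% diverged: K2P log-domain failure
        pair = lwl_ka_ks("GGA" + "ATG" * 100, "GGG" + "ATG" * 100)
        assert "4-fold" in pair.failed_classes
        assert not pair.ks_defined

    def test_matches_independent_reimplementation(self):
        # second implementation of the same equations, structured around
        # explicit per-codon dictionaries rather than lookup tables
        rng = np.random.default_rng(7)
        a_codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=50)]
        b_codons = list(a_codons)
        # moderate divergence: random single-nucleotide (non-stop) changes
        for k in rng.choice(50, size=15, replace=False):
            cands = [c for c in SENSE_CODONS
                     if sum(x != y for x, y in zip(c, b_codons[k])) == 1]
            b_codons[k] = cands[rng.integers(len(cands))]
        a = "".join(a_codons)
        b = "".join(b_codons)
        pair = lwl_ka_ks(a, b)
        ka, ks = _lwl_reference(a, b)
        assert pair.ka == pytest.approx(ka, abs=1e-10)
        assert pair.ks == pytest.approx(ks, abs=1e-10)


def _lwl_reference(a, b):
    from Bio.Data.CodonTable import standard_dna_table
    code = standard_dna_table.forward_table

    def fold(codon, pos):
        syn = sum(code.get(codon[:pos] + n + codon[pos + 1:]) == code[codon]
                  for n in "TCAG" if n != codon[pos])
        return 2 if syn == 3 else (1 if syn > 0 else 0)

    L = [0.0, 0.0, 0.0]
    S = [0.0, 0.0, 0.0]
    V = [0.0, 0.0, 0.0]
    for k in range(0, len(a), 3):
        ca, cb = a[k:k + 3], b[k:k + 3]
        for pos in range(3):
            fa, fb = fold(ca, pos), fold(cb, pos)
            L[fa] += 0.5
            L[fb] += 0.5
            if ca[pos] != cb[pos]:
                ts = {ca[pos], cb[pos]} in ({"A", "G"}, {"C", "T"})
                tgt = S if ts else V
                tgt[fa] += 0.5
                tgt[fb] += 0.5
    A = [0.0] * 3
    B = [0.0] * 3
    for i in range(3):
        if L[i] == 0:
            continue
        P, Q = S[i] / L[i], V[i] / L[i]
        A[i] = 0.5 * math.log(1 / (1 - 2 * P - Q)) - 0.25 * math.log(1 / (1 - 2 * Q))
        B[i] = 0.5 * math.log(1 / (1 - 2 * Q))
    ks = (L[1] * A[1] + L[2] * (A[2] + B[2])) / (L[1] / 3 + L[2])
    ka = (L[1] * B[1] + L[0] * (A[0] + B[0])) / (2 * L[1] / 3 + L[0])
    return ka, ks


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # tree ((A:1,B:2):1,(C:1,D:1)) -> additive distances
        names = list("ABCD")
        D = DistanceMatrix(names, np.array(
            [[0, 3, 3, 3],
             [3, 0, 4, 4],
             [3, 4, 0, 2],
             [3, 4, 2, 0]], dtype=float))
        tree = neighbor_joining(D)
        assert tree.has_clade({"A", "B"}) and tree.has_clade({"C", "D"})
        # brute force over the 3 unrooted topologies with least squares
        best = _best_topology_by_ls(names, D.values)
        assert best == frozenset([frozenset("AB")])
        lengths = {n.name: n.length for n in tree.leaves}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(list("ABC"), np.array(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float))
        tree = neighbor_joining(D)
        lengths = {n.name: n.length for n in tree.leaves}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_permutation_invariance(self, seed, species_tree):
        aln, _ = ec.simulate_codon_alignment(
            species_tree, 2.0, {"model": "m0", "omega": 0.3}, 200, seed=seed)
        D = ec.nt_k2p_matrix(aln)
        t1 = neighbor_joining(D)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(D.names))
        D2 = DistanceMatrix([D.names[i] for i in perm],
                            D.values[np.ix_(perm, perm)])
        t2 = neighbor_joining(D2)
        assert t1.same_unrooted_topology(t2)

    def test_nj_additive_recovery_vs_enumeration(self):
        # random additive matrices from random 6-taxon trees
        rng = np.random.default_rng(3)
        for _ in range(5):
            tree = _random_caterpillar(rng, 6)
            D = _tree_distance_matrix(tree)
            rec = neighbor_joining(D)
            assert rec.same_unrooted_topology(tree)

    def test_agrees_with_dendropy_nj(self, null_alignment):
        import dendropy
        aln, _ = null_alignment
        D = ec.nt_k2p_matrix(aln)
        mine = neighbor_joining(D)
        csv = "," + ",".join(D.names) + "\n" + "\n".join(
            name + "," + ",".join(str(x) for x in row)
            for name, row in zip(D.names, D.values))
        import io
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=",")
        theirs = pdm.nj_tree()
        theirs_newick = theirs.as_string(schema="newick").replace("'", "")
        other = ec.read_newick(theirs_newick)
        assert mine.same_unrooted_topology(other)


def _random_caterpillar(rng, n):
    nodes = [ec.tree.Node(name=f"t{i}", length=float(rng.uniform(0.5, 2)))
             for i in range(n)]
    spine = nodes[0]
    for node in nodes[1:-1]:
        spine = ec.tree.Node(children=[spine, node],
                             length=float(rng.uniform(0.5, 2)))
    root = ec.tree.Node(children=[spine, nodes[-1]])
    return ec.PhyloTree(root)


def _tree_distance_matrix(tree):
    names = tree.leaf_names
    leaf = {n.name: n for n in tree.leaves}
    D = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                d = _path_length(leaf[a], leaf[b])
                D[i, j] = D[j, i] = d
    return DistanceMatrix(names, D)


def _path_length(a, b):
    anc = {}
    n, d = a, 0.0
    while n is not None:
        anc[id(n)] = d
        d += n.length or 0.0
        n = n.parent
    n, d = b, 0.0
    while id(n) not in anc:
        d += n.length or 0.0
        n = n.parent
    return d + anc[id(n)]


def _best_topology_by_ls(names, D):
    """Exhaustive least-squares over the 3 unrooted 4-taxon topologies."""
    a, b, c, d = names
    best, best_rss = None, np.inf
    for pair in (frozenset((a, b)), frozenset((a, c)), frozenset((a, d))):
        other = frozenset(names) - pair
        # path design for ((p1,p2),(q1,q2)) with internal edge
        p1, p2 = sorted(pair)
        q1, q2 = sorted(other)
        order = [p1, p2, q1, q2]
        idx = {n: names.index(n) for n in names}
        rows, y = [], []
        for i, j in itertools.combinations(range(4), 2):
            row = [0.0] * 5            # e1..e4 terminal, e5 internal
            row[i] = 1.0
            row[j] = 1.0
            crosses = (i < 2) != (j < 2)
            row[4] = 1.0 if crosses else 0.0
            rows.append(row)
            y.append(D[idx[order[i]], idx[order[j]]])
        beta, rss, *_ = np.linalg.lstsq(np.array(rows), np.array(y),
                                        rcond=None)
        resid = np.array(y) - np.array(rows) @ beta
        rss = float(resid @ resid)
        if rss < best_rss - 1e-12:
            best_rss, best = rss, frozenset([pair])
    return best


class TestBootstrap:
    def test_single_replicate_supports_binary(self, species_tree):
        aln, _ = ec.simulate_codon_alignment(
            species_tree, 2.0, {"model": "m0", "omega": 0.3}, 200, seed=4)
        tree = ec.bootstrap_supports(aln, ec.nt_k2p_matrix, n_reps=1, seed=0)
        sup = [n.support for n in tree.internal if hasattr(n, "support")]
        assert sup and all(s in (0.0, 100.0) for s in sup)

    def test_fixed_seed_reproducible(self, species_tree):
        aln, _ = ec.simulate_codon_alignment(
            species_tree, 2.0, {"model": "m0", "omega": 0.3}, 200, seed=4)
        t1 = ec.bootstrap_supports(aln, ec.nt_k2p_matrix, n_reps=25, seed=9)
        t2 = ec.bootstrap_supports(aln, ec.nt_k2p_matrix, n_reps=25, seed=9)
        s1 = sorted(n.support for n in t1.internal if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.internal if hasattr(n, "support"))
        assert s1 == s2

    def test_strong_signal_high_support(self, species_tree):
        aln, _ = ec.simulate_codon_alignment(
            species_tree, 2.0, {"model": "m0", "omega": 0.5}, 4000, seed=8)
        tree = ec.bootstrap_supports(aln, ec.nt_k2p_matrix, n_reps=50, seed=1)
        sup = [n.support for n in tree.internal if hasattr(n, "support")]
        assert np.mean(sup) > 85.0
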