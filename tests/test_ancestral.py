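"""Least-squares branch lengths and marginal ancestral reconstruction."""

import numpy as np
import pytest

import echoconv as ec
from echoconv.alignment import Alignment
from echoconv.distances import DistanceMatrix
from echoconv.models import AA_INDEX, ReversibleModel, aa_rate_matrix


class TestLeastSquares:
    def test_additive_exact(self):
        t = ec.read_newick("((A:1,B:2):1,(C:1,D:1):1);")
        D = _path_matrix(t)
        fitted = ec.least_squares_branch_lengths(t, D)
        resid = np.abs(_path_matrix(fitted).values - D.values).max()
        assert resid < 1e-9

    def test_matches_normal_equations(self):
        t = ec.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rng = np.random.default_rng(0)
        base = _path_matrix(t).values
        noisy = base + rng.normal(0, 0.05, base.shape)
        noisy = np.triu(noisy, 1)
        noisy = noisy + noisy.T
        D = DistanceMatrix(t.leaf_names, np.abs(noisy))
        fitted = ec.least_squares_branch_lengths(t, D)
        # explicit normal-equations oracle on the same design
        X, y, edges = _design(t, D)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        if (beta >= 0).all():
            got = np.array([fitted.node_by_edge_id(e).length for e in edges])
            assert np.allclose(got, beta, atol=1e-8)

    def test_scaling_linearity(self):
        t = ec.read_newick("((A:1,B:2):1,(C:1,D:1):1);")
        D = _path_matrix(t)
        D2 = DistanceMatrix(D.names, 2.0 * D.values)
        f1 = ec.least_squares_branch_lengths(t, D)
        f2 = ec.least_squares_branch_lengths(t, D2)
        for n1, n2 in zip(f1.postorder, f2.postorder):
            if n1.parent is not None:
                assert n2.length == pytest.approx(2 * n1.length, abs=1e-9)

    def test_all_zero_distances_rejected(self):
        t = ec.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError, match="singular"):
            ec.least_squares_branch_lengths(
                t, DistanceMatrix(t.leaf_names, np.zeros((4, 4))))


def _path_matrix(tree):
    names = tree.leaf_names
    leaf = {n.name: n for n in tree.leaves}
    D = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                D[i, j] = D[j, i] = _path(leaf[a], leaf[b])
    return DistanceMatrix(names, D)


def _path(a, b):
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


def _design(tree, D):
    """Pair x edge indicator design with the two root edges merged."""
    nodes = [n for n in tree.postorder if n.parent is not None]
    root_kids = tree.root.children
    edges = []
    col = {}
    for n in nodes:
        if len(root_kids) == 2 and n is root_kids[1]:
            col[id(n)] = col[id(root_kids[0])]
            continue
        col[id(n)] = len(edges)
        edges.append(tree.edge_id(n))
    leaf = {n.name: n for n in tree.leaves}
    rows, y = [], []
    names = D.names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            row = np.zeros(len(edges))
            seen = {}
            for start in (leaf[names[i]], leaf[names[j]]):
                n = start
                while n.parent is not None:
                    seen[id(n)] = seen.get(id(n), 0) + 1
                    n = n.parent
            for n in nodes:
                if seen.get(id(n), 0) == 1:
                    row[col[id(n)]] += 1
            rows.append(row)
            y.append(D.values[i, j])
    return np.array(rows), np.array(y), edges


class TestMarginalAncestral:
    def test_star_consistency(self):
        t = ec.read_newick("(A:1e-6,B:1e-6,C:1e-6,D:1e-6,E:1e-6);")
        aln = Alignment(list("ABCDE"), ["K"] * 5, "protein")
        rec = ec.marginal_ancestral_states(aln, t, frequencies="jtt")
        root_id = t.edge_id(t.root)
        assert rec.map_residue(root_id, 1) == "K"
        assert rec.map_posterior[root_id][0] > 0.999

    def test_matches_exhaustive_enumeration(self):
        t = ec.read_newick("((A:0.12,B:0.3):0.08,(C:0.2,D:0.15):0.1);")
        seqs = {"A": "KR", "B": "KK", "C": "QR", "D": "KR"}
        aln = Alignment(list(seqs), list(seqs.values()), "protein")
        rec = ec.marginal_ancestral_states(aln, t, frequencies="jtt")
        Q, pi = aa_rate_matrix(None)
        M = ReversibleModel(Q, pi)
        P = {id(n): M.transition_matrix(n.length)
             for n in t.postorder if n.parent is not None}
        U = next(n for n in t.internal
                 if set(t.subtree_leaves(n)) == {"A", "B"})
        V = next(n for n in t.internal
                 if set(t.subtree_leaves(n)) == {"C", "D"})
        R = t.root
        leafmap = {n.name: n for n in t.leaves}
        for site in range(2):
            codes = {x: AA_INDEX[seqs[x][site]] for x in seqs}
            joint = np.zeros((20, 20, 20))
            for r in range(20):
                for u in range(20):
                    for v in range(20):
                        joint[r, u, v] = (
                            pi[r] * P[id(U)][r, u] * P[id(V)][r, v]
                            * P[id(leafmap["A"])][u, codes["A"]]
                            * P[id(leafmap["B"])][u, codes["B"]]
                            * P[id(leafmap["C"])][v, codes["C"]]
                            * P[id(leafmap["D"])][v, codes["D"]])
            joint /= joint.sum()
            for node, axes in ((R, (1, 2)), (U, (0, 2)), (V, (0, 1))):
                marg = joint.sum(axis=axes)
                got = rec.posteriors[t.edge_id(node)][site]
                assert np.abs(marg - got).max() < 1e-9

    def test_posteriors_normalized_and_invariant_site(self, species_tree,
                                                     null_alignment):
        aln, _ = null_alignment
        prot = ec.translate(aln)
        fitted = ec.least_squares_branch_lengths(
            species_tree,
            ec.poisson_corrected_matrix(ec.aa_p_matrix(prot)))
        rec = ec.marginal_ancestral_states(prot, fitted)
        for eid, post in rec.posteriors.items():
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        # invariant columns must be reconstructed with high confidence
        from echoconv.alignment import encode_protein
        codes = encode_protein(prot)
        invariant = [(s, codes[0, s]) for s in range(prot.length)
                     if (codes[:, s] == codes[0, s]).all() and codes[0, s] >= 0]
        s, aa = invariant[0]
        for eid in rec.map_states:
            assert rec.map_states[eid][s] == aa
            assert rec.map_posterior[eid][s] > 0.99

    def test_reroot_invariance(self):
        aln = Alignment(list("ABCD"), ["KR", "KK", "QR", "KR"], "protein")
        t1 = ec.read_newick("((A:0.1,B:0.3):0.08,(C:0.2,D:0.15):0.1);")
        # same unrooted tree, rooted on the other side
        t2 = ec.read_newick("((C:0.2,D:0.15):0.09,(A:0.1,B:0.3):0.09);")
        r1 = ec.marginal_ancestral_states(aln, t1, frequencies="jtt")
        r2 = ec.marginal_ancestral_states(aln, t2, frequencies="jtt")
        u1 = next(t1.edge_id(n) for n in t1.internal
                  if set(t1.subtree_leaves(n)) == {"A", "B"})
        u2 = next(t2.edge_id(n) for n in t2.internal
                  if set(t2.subtree_leaves(n)) == {"A", "B"})
        assert np.abs(r1.posteriors[u1] - r2.posteriors[u2]).max() < 1e-9

    def test_all_gap_site_flagged(self):
        t = ec.read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = Alignment(list("ABCD"), ["-K", "-K", "-K", "-K"], "protein")
        rec = ec.marginal_ancestral_states(aln, t, frequencies="jtt")
        assert rec.all_gap_sites == [1]
        root_post = rec.posteriors[t.edge_id(t.root)][0]
        np.testing.assert_allclose(root_post, rec.frequencies, atol=1e-9)


class TestMapSubstitutions:
    def test_leaf_event_named_like_paper_notation(self, small_tree):
        # parent MAP R, dolphin leaf Q at some site -> event "R<site>Q"
        seqs = {name: "R" * 5 for name in small_tree.leaf_names}
        seqs["Tursiops_truncatus"] = "R" * 3 + "Q" + "R"
        aln = Alignment(list(seqs), list(seqs.values()), "protein")
        t = small_tree.copy()
        rec = ec.marginal_ancestral_states(aln, t, frequencies="jtt")
        events = ec.map_substitutions(rec, aln)
        assert [str(e) for e in events["g"]] == ["R4Q"]
        assert events["g"][0].parent_posterior > 0.9
        assert events["g"][0].child_posterior == 1.0

    def test_no_change_no_events(self, small_tree):
        seqs = {name: "MKVR" for name in small_tree.leaf_names}
        aln = Alignment(list(seqs), list(seqs.values()), "protein")
        rec = ec.marginal_ancestral_states(aln, small_tree.copy(),
                                           frequencies="jtt")
        events = ec.map_substitutions(rec, aln)
        assert all(not evs for evs in events.values())

    def test_recovers_true_history_on_long_branches(self):
        """>=90% of single-hit substitutions on long branches recovered."""
        nwk = ("((A:0.08,X:0.35):0.06,((B:0.08,Y:0.35):0.06,C:0.10):0.04);")
        t = ec.read_newick(nwk)
        from echoconv.models import CODON_AA
        hits = total = 0
        for seed in range(3):
            aln, truth = ec.simulate_codon_alignment(
                t, 2.0, {"model": "m0", "omega": 0.5}, 400, seed=seed)
            prot = ec.translate(aln)
            fitted = ec.least_squares_branch_lengths(
                t, ec.poisson_corrected_matrix(ec.aa_p_matrix(prot)))
            rec = ec.marginal_ancestral_states(prot, fitted)
            events = ec.map_substitutions(rec, prot)
            for branch in ("X", "Y"):
                by_site = {}
                for _, site, frm, to in truth.events_on(branch):
                    by_site.setdefault(site, []).append((frm, to))
                singles = {s: v[0] for s, v in by_site.items()
                           if len(v) == 1 and CODON_AA[v[0][0]] != CODON_AA[v[0][1]]}
                found = {e.site - 1 for e in events[branch]}
                total += len(singles)
                hits += sum(s in found for s in singles)
        assert total > 50
        assert hits / total >= 0.90
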