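import numpy as np
import pytest

import echoconv as ec


@pytest.fixture(scope="session")
def species_tree():
    return ec.fixture_species_tree()


@pytest.fixture(scope="session")
def small_tree():
    """6-taxon tree with foreground edges b (internal) and g (terminal)."""
    return ec.read_newick(
        "((Bos_taurus:0.06,Tursiops_truncatus#g:0.05):0.03,"
        "((Rousettus_leschenaultii:0.05,"
        "(Rhinolophus_ferrumequinum:0.04,Hipposideros_armiger:0.04)#b:0.03):0.03,"
        "Myotis_ricketti:0.06):0.02);")


@pytest.fixture(scope="session")
def power_tree():
    """Like small_tree but with long foreground branches (selection power)."""
    return ec.read_newick(
        "((Bos_taurus:0.06,Tursiops_truncatus#g:0.30):0.03,"
        "((Rousettus_leschenaultii:0.05,"
        "(Rhinolophus_ferrumequinum:0.04,Hipposideros_armiger:0.04)#b:0.20):0.03,"
        "Myotis_ricketti:0.06):0.02);")


@pytest.fixture(scope="session")
def null_alignment(species_tree):
    """One M0 alignment on the species tree (no convergence, no selection)."""
    aln, truth = ec.simulate_codon_alignment(
        species_tree, kappa=2.0, omega_spec={"model": "m0", "omega": 0.05},
        n_codons=1500, seed=101)
    return aln, truth


@pytest.fixture(scope="session")
def convergent_alignment(species_tree):
    """Alignment with 21 parallel sites injected on branches b and g."""
    aln, truth = ec.simulate_codon_alignment(
        species_tree, kappa=2.0, omega_spec={"model": "m0", "omega": 0.05},
        n_codons=3000, seed=204)
    return ec.inject_parallel_substitutions(aln, truth, ["b", "g"],
                                            n_sites=21, seed=205)


@pytest.fixture(scope="session")
def foreground_taxa(species_tree):
    t = species_tree
    taxa = set(t.subtree_leaves(t.node_by_edge_id("b")))
    taxa |= set(t.subtree_leaves(t.node_by_edge_id("g")))
    return taxa
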