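"""Detect parallel replacements and test their excess against chance.

Reconstructs ancestral amino acids on the species tree (least-squares
branch lengths + JTT+F marginal posteriors), maps replacements onto every
branch, collects the sites shared by the Rhinolophoidea stem (b) and the
dolphin (g), and compares the observed count with the Poisson expectation
under independent evolution.
"""

import echoconv as ec

tree = ec.fixture_species_tree()
aln, truth = ec.simulate_codon_alignment(
    tree, kappa=2.0, omega_spec={"model": "m0", "omega": 0.05},
    n_codons=3000, seed=1)
aln, truth = ec.inject_parallel_substitutions(aln, truth, ["b", "g"],
                                              n_sites=21, seed=2)
prot = ec.translate(aln)
fitted = ec.least_squares_branch_lengths(
    tree, ec.poisson_corrected_matrix(ec.aa_p_matrix(prot)))
rec = ec.marginal_ancestral_states(prot, fitted)
events = ec.map_substitutions(rec, prot)

print("replacements mapped per focal branch:",
      {b: len(events[b]) for b in ("b", "d", "g")})
report = ec.convergence_test(rec, events, ["b", "g"])
print(report.summary())
injected = {d["site"] for d in truth.injected_sites}
detected = {int("".join(c for c in s if c.isdigit()))
            for s in report.parallel_sites}
print(f"\ninjected sites recovered: {len(injected & detected)}/21")
print("O far above E with a vanishing Poisson tail probability is the "
      "signature of genuine parallel evolution.")
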