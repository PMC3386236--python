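# Methods

`echoconv` implements the molecular side of a classic convergent-evolution
study design: three independent mammalian lineages — two bat clades
(Rhinolophoidea, stem branch conventionally labeled *b*; Yangochiroptera,
stem *d*) and the dolphin (terminal branch *g*) — acquired laryngeal/nasal
echolocation independently, and hearing genes in these lineages show an
excess of identical amino-acid replacements.  The package provides every
analysis stage needed to detect and test that excess, plus a generator of
synthetic data with known truth on which all of it is validated.

## Distances and trees

Gene trees are built by neighbor-joining on four kinds of pairwise
distance:

* **Nucleotide** — Kimura two-parameter (K2P),
  `d = -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q)` with transition proportion `P`
  and transversion proportion `Q`.  A non-positive logarithm argument marks
  saturation and the entry is flagged undefined.
* **Protein** — uncorrected p-distance.
* **Synonymous / nonsynonymous** — the Li-Wu-Luo (LWL) composite: each
  codon position is classified as nondegenerate, two-fold or four-fold
  degenerate under the standard genetic code (three-fold sites count as
  two-fold); transitional and transversional differences are counted per
  class (a position whose class differs between the two codons contributes
  half to each class), K2P-corrected within class, and composed into
  `Ks = (L2 A2 + L4 K4) / (L2/3 + L4)` and
  `Ka = (L2 B2 + L0 K0) / (2 L2/3 + L0)`.  Differences are counted
  position-by-position; no pathway averaging over multi-hit codons is
  applied (at the divergences this package targets, multi-hit codons are
  rare and the simplification is immaterial; it is exercised against an
  independently coded implementation of the same equations in the tests).

Gap handling is pairwise deletion throughout.  Neighbor-joining clamps
negative branch-length estimates to zero and resolves the final three
lineages in closed form; bootstrap supports (resampling columns, or whole
codons for codon alignments) are mapped onto the full-data tree by
bipartition matching.

## Ancestral reconstruction

The species topology is fixed.  Branch lengths are estimated by ordinary
least squares from Poisson-corrected protein p-distances
(`d = -ln(1-p)`, keeping lengths on the substitutions-per-site scale);
negative estimates are pinned at zero and the remainder refit.  With a
bifurcating root the two root-adjacent edges are only identifiable as a
sum from leaf-leaf distances; they are fit as one variable, which amounts
to an equal split.

Marginal posterior amino acids at every internal node are then computed by
the pruning recursion under the JTT replacement matrix with alignment-wide
observed frequencies ("+F"); JTT is the era-standard empirical model for
mammalian nuclear proteins, and no rate-across-sites heterogeneity is
applied.  Gapped leaves contribute ones; a site gapped in every taxon gets
the equilibrium distribution and is flagged.  MAP ties (numerically within
1e-12) break toward the higher-frequency residue, then alphabetically.
Replacements are mapped onto a branch wherever the parent-node MAP residue
differs from the child state (observed residue for terminal branches,
child MAP otherwise).

## Parallel/convergent excess test

For a set of 2–3 non-nested focal branches, a site is *parallel* when all
branches carry a replacement with identical parent and identical derived
residue, *convergent* when only the derived residues agree.  The headline
count sums both, which is how shared replacements are conventionally
tallied in this literature.

The null expectation treats branches as independent: per site and branch,
the probability of a replacement ending in residue `r` is
`sum_{a != r} w(a) P_ar(t)`, with `w` the posterior distribution of the
parent node's state (a MAP point-mass variant is available for sensitivity
analysis) and `P(t)` the JTT+F transition matrix at the fitted branch
length.  Summing the product over branches and destinations across sites
gives the expected number of shared-derived events, split into parallel
(identical parent) and convergent components.  The observed count is
referred to `P(X >= O)` for `X ~ Poisson(E)`.  Monte-Carlo validation
(tests) shows `E` matches the mean observed count over null replicates
within a few percent at moderate divergence; at the very low divergences
of the packaged fixture both `O` and `E` are near zero and the test is
conservative.

## Codon models

The substitution process is the Goldman–Yang-style codon model on the 61
sense codons: single-nucleotide exchanges with rate multipliers `kappa`
(transitions) and `omega` (nonsynonymous), target frequencies F3x4
computed from the data (lightly smoothed, never optimized).  Implemented
models: one-ratio M0; two-ratio branch models with the designated
echolocator edges as foreground (the significance test compares against
the same model with foreground omega fixed at 1, df = 1); and branch-site
Model A with classes 0 (omega0 <= 1), 1 (omega1 = 1), 2a/2b (foreground
omega2 >= 1), whose "test 2" compares against the null fixing omega2 = 1.

**Rate scaling.**  All site classes share one time scale: every class
matrix is divided by the proportion-weighted mean rate of the *background*
process, so branch lengths read as expected background substitutions per
codon and a foreground class with omega2 > 1 genuinely substitutes faster.
The simulator uses the identical convention, which is what makes
simulation-estimation consistency exact.  (Normalizing each class to unit
rate separately — an alternative convention — silently removes the rate
elevation that carries most of the branch-site signal.)

**Optimization.**  Likelihoods are evaluated by pruning over 61 states
with site-pattern compression; the reversible rate matrices are
eigendecomposed once per (kappa, omega) via the symmetric similarity
transform, so `P(t)` is cheap for all branches at once.  Fitting uses
bounded L-BFGS-B with analytic branch-length gradients (outside/inside
pass, `dP/dt = QP`) and analytic mixture-proportion gradients (weight and
time-scale channels); `kappa` and the omegas use forward finite
differences.  A multi-start stage (default 3 random starts, branch lengths
held at distance-based initial values from least squares on K2P distances)
precedes one joint refinement of all parameters.  A nested alternative can
be warm-started from its null fit; the extra parameter then starts exactly
at the boundary (omega2 = 1), so the alternative begins at the null
optimum and can only climb — this guarantees a non-negative
likelihood-ratio statistic up to optimizer tolerance.

**BEB.**  Positively selected sites are scored by Bayes empirical Bayes:
a uniform 10-point grid on each of (p0+p1, p0/(p0+p1), omega0 in (0,1),
omega2 in (1,11)) with equal prior mass, integrating the per-site
posterior of classes 2a+2b over the grid posterior.  `kappa`, branch
lengths and the MLE's time scale are held fixed while the grid varies —
proportion uncertainty enters through the prior weights, not the clock —
which keeps the grid evaluation to ~121 pruning passes.  Sites above 0.90
are flagged, and a plug-in NEB mode (MLE weights) is provided and labeled
as the faster, anticonservative variant.

## Expression (comparative Ct)

Technical replicates are averaged on the Ct scale per individual and gene;
`dCt = Ct_target - Ct_reference`; `ddCt` subtracts the calibrator cell's
mean `dCt`; folds are `2^-ddCt` (100% amplification efficiency, no Pfaffl
correction).  Individuals are summarized on the fold scale and everything
is rescaled so the calibrator cell's mean is exactly 1 — the calibrator
mean defines the baseline unit.  Fold changes are invariant to any
constant added to all Ct values of both genes.

## The synthetic-data generator

`simulate_codon_alignment` evolves each site along the fixed species tree
by exact stochastic simulation (exponential waiting times under the same
rate matrices the likelihood code builds), recording every substitution
event; `inject_parallel_substitutions` then forces a common derived
residue, realized by minimal codon changes, onto all leaves below each
designated branch at randomly chosen conserved sites.  `simulate_qpcr`
inverts the ddCt formula exactly, so a noiseless table reproduces the
requested fold profile to machine precision.  All randomness flows from
one integer seed through a single generator.

**Fixture and default conditions.**  The packaged 18-leaf laurasiatherian
tree places Yinpterochiroptera (Old World fruit bats + Rhinolophoidea,
stem *b*), Yangochiroptera (stem *d*) and the dolphin (terminal *g*) among
standard background mammals.  Its branch lengths are deliberately in the
short-internode regime (internodes 0.012 expected substitutions per codon,
foreground stems 0.024, terminals 0.024–0.078): convergence can only
mislead protein trees when the true internal signal of a conserved gene is
comparable to the convergent pull, which is precisely the empirical regime
of the echolocation genes (one-ratio omega around 0.05, ~3000 codons,
~21 shared sites).  Default study conditions follow that regime:
`kappa = 2`, `omega = 0.05` for incongruence experiments, 3000 codons,
21 injected sites on *b* and *g*; `omega = 0.2`, 500 codons for parameter
recovery; branch-site experiments use a 6-taxon subtree (300 codons for
null calibration; 800 codons with foreground lengths 0.2/0.3 for power,
sized so the test 2 statistic is decisively above the chi-square critical
value when omega2 = 4 acts on ~10% of sites).

**What the generator does not emulate.**  No indels beyond whole-codon
gaps, no rate heterogeneity across sites beyond the discrete omega
classes, no alignment error, no sequencing error, and foreground
convergence is injected (deterministic derived states) rather than arising
from an explicit selective process.  Passing tests therefore demonstrate
that the analysis machinery is correct and calibrated under its own model
assumptions — not that those assumptions hold for any particular real
alignment.

## Numerical notes and limitations

* Pruning is unscaled double precision; fine to ~20 taxa and the
  divergences used here.  Larger trees would need per-node rescaling.
* Site-exclusion rebuilds the protein NJ tree after dropping the detected
  columns.  On the conserved fixture this always removes the artifactual
  echolocator clade, but the exact species topology is recovered in only
  ~85–90% of replicates — short internodes can be left with no remaining
  signal, the same behavior seen in the original study's supplementary
  trees for one of its three genes.
* Distance-based NJ and LS-branch-length stages flag (as NaN / errors)
  saturated distances rather than guessing.
* LRT p-values use chi-square df = 1; under the null the branch-site
  statistic is stochastically smaller (about half the replicates are at
  the boundary), so the test is conservative, which the acceptance suite
  checks by a one-sided Kolmogorov–Smirnov comparison.
* Multiple branch pairs are tested without multiplicity correction, as is
  conventional for this design; a Bonferroni option exists in the pipeline
  and is off by default.
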