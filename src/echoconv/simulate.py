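"""Synthetic data with known truth.

Generates the inputs every analysis stage is tested against: in-frame codon
alignments evolved along a fixed laurasiatherian species tree under the same
GY94-style rate matrices the likelihood code uses (simulator/inference
consistency is the module's central guarantee), optional injection of
parallel amino-acid replacements on designated echolocator branches, and
triplicate qPCR Ct tables realizing a specified relative-expression profile.

All randomness flows from a single integer seed through one numpy
Generator, so every artifact is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment
from .models import (AA_ORDER, CODON_AA, CODON_INDEX, SENSE_CODONS,
                     codon_rate_matrix_raw, mixture_rate_scale, uniform_f3x4)
from .tree import PhyloTree, read_newick

# 18-leaf laurasiatherian fixture: Yinpterochiroptera = Old World fruit bats
# + Rhinolophoidea (stem = b); Yangochiroptera (stem = d); dolphin terminal
# = g; outgroups Homo and Mus.  Branch lengths are plausible mammalian
# values (expected substitutions per codon) with short internodes relative
# to terminal branches — the regime in which convergent replacements are
# known to distort amino-acid trees.
_FIXTURE_NEWICK = (
    "((Homo_sapiens:0.060,Mus_musculus:0.078):0.024,"
    "((Canis_familiaris:0.042,Felis_catus:0.042):0.012,"
    "(Equus_caballus:0.048,"
    "((Sus_scrofa:0.048,"
    "(Bos_taurus:0.042,Tursiops_truncatus#g:0.036):0.012):0.012,"
    "(((Cynopterus_sphinx:0.030,"
    "(Rousettus_leschenaultii:0.024,Pteropus_vampyrus:0.024):0.012):0.012,"
    "((Rhinolophus_ferrumequinum:0.024,Hipposideros_armiger:0.024):0.012,"
    "Megaderma_lyra:0.030)#b:0.024):0.012,"
    "((Taphozous_melanopogon:0.030,Chaerephon_plicata:0.030):0.012,"
    "(Miniopterus_schreibersii:0.024,Myotis_ricketti:0.024):0.012)#d:0.024"
    "):0.012):0.012):0.012):0.012);"
)


def fixture_species_tree() -> PhyloTree:
    """The packaged 18-leaf species tree with foreground edges b, d, g."""
    return read_newick(_FIXTURE_NEWICK)


@dataclass
class SimulationTruth:
    """Everything the generator knows that an analysis must recover."""

    tree: PhyloTree
    root_codons: np.ndarray                     # sense-codon indices
    site_classes: np.ndarray | None             # 0/1/2/3 for modelA, else None
    events: list[tuple[str, int, int, int]]     # (branch, site0, from, to)
    injected_sites: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def events_on(self, branch: str) -> list[tuple[str, int, int, int]]:
        return [e for e in self.events if e[0] == branch]

    def counted_dn_ds(self) -> tuple[int, int]:
        """(nonsynonymous, synonymous) event counts over the whole history."""
        dn = ds = 0
        for _, _, a, b in self.events:
            if CODON_AA[a] != CODON_AA[b]:
                dn += 1
            else:
                ds += 1
        return dn, ds


def _omega_for(spec: dict, site_classes: np.ndarray | None,
               is_foreground: bool, n_sites: int) -> np.ndarray:
    """Per-site omega on one branch."""
    if spec["model"] == "m0":
        return np.full(n_sites, float(spec["omega"]))
    w0, w2 = float(spec["omega0"]), float(spec["omega2"])
    bg = np.array([w0, 1.0, w0, 1.0])
    fg = np.array([w0, 1.0, w2, w2])
    table = fg if is_foreground else bg
    return table[site_classes]


def simulate_codon_alignment(tree: PhyloTree, kappa: float, omega_spec: dict,
                             n_codons: int, seed: int,
                             pi: np.ndarray | None = None
                             ) -> tuple[Alignment, SimulationTruth]:
    """Evolve a codon alignment along ``tree`` by exact stochastic simulation.

    ``omega_spec`` is ``{"model": "m0", "omega": w}`` or
    ``{"model": "modelA", "omega0": w0, "omega2": w2, "p0": p0, "p1": p1}``
    (foreground = the tree's labeled edges).  Root codons are drawn from the
    F3x4-compatible stationary frequencies; each site then evolves by
    exponential waiting times under the same rate matrices the likelihood
    module builds, and every substitution event is recorded in the truth.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    if pi is None:
        pi = uniform_f3x4()
    if omega_spec["model"] == "modelA":
        p0, p1 = float(omega_spec["p0"]), float(omega_spec["p1"])
        if p0 < 0 or p1 < 0 or p0 + p1 > 1 + 1e-9:
            raise ValueError("modelA proportions must be >= 0 with p0+p1 <= 1")
        rest = max(1.0 - p0 - p1, 0.0)
        props = np.array([p0, p1, rest * p0 / (p0 + p1),
                          rest * p1 / (p0 + p1)])
        site_classes = rng.choice(4, size=n_codons, p=props / props.sum())
    elif omega_spec["model"] == "m0":
        site_classes = None
    else:
        raise ValueError(f"unknown omega spec model {omega_spec['model']!r}")

    # one common time scale across classes (weighted mean background rate),
    # matching the likelihood module's convention exactly
    if site_classes is None:
        classes = [(1.0, float(omega_spec["omega"]), float(omega_spec["omega"]))]
    else:
        w0, w2 = float(omega_spec["omega0"]), float(omega_spec["omega2"])
        classes = [(props[0], w0, w0), (props[1], 1.0, 1.0),
                   (props[2], w0, w2), (props[3], 1.0, w2)]
    scale = mixture_rate_scale(classes, kappa, pi)
    omegas = sorted({float(w) for w in
                     ([omega_spec["omega"]] if site_classes is None else
                      [omega_spec["omega0"], 1.0, omega_spec["omega2"]])})
    rates, cum_jump = {}, {}
    for w in omegas:
        Q, _ = codon_rate_matrix_raw(kappa, w, pi)
        r = -np.diag(Q) / scale
        J = Q / (-np.diag(Q))[:, None]
        np.fill_diagonal(J, 0.0)
        rates[w] = r
        cum_jump[w] = np.cumsum(J, axis=1)

    fg_ids = set()
    for node in tree.foreground_edges.values():
        fg_ids.add(id(node))

    root_states = rng.choice(len(SENSE_CODONS), size=n_codons, p=pi)
    states_at = {id(tree.root): root_states}
    events: list[tuple[str, int, int, int]] = []
    for node in reversed(tree.postorder):             # preorder
        if node.parent is None:
            continue
        t = float(node.length or 0.0)
        eid = tree.edge_id(node)
        parent_states = states_at[id(node.parent)]
        states = parent_states.copy()
        site_omega = _omega_for(omega_spec, site_classes, id(node) in fg_ids,
                                n_codons)
        for w in omegas:
            sites = np.nonzero(site_omega == w)[0]
            if sites.size == 0:
                continue
            remaining = np.full(sites.size, t)
            active = np.arange(sites.size)
            while active.size:
                s = states[sites[active]]
                wait = rng.exponential(size=active.size) / rates[w][s]
                jump = wait < remaining[active]
                hit = active[jump]
                if hit.size:
                    u = rng.random(hit.size)
                    rows = cum_jump[w][states[sites[hit]]]
                    nxt = (rows < u[:, None]).sum(axis=1)
                    for k, site_idx in enumerate(sites[hit]):
                        events.append((eid, int(site_idx),
                                       int(states[site_idx]), int(nxt[k])))
                    states[sites[hit]] = nxt
                remaining[active] -= wait
                active = hit
        states_at[id(node)] = states

    names, seqs = [], []
    for leaf in tree.leaves:
        st = states_at[id(leaf)]
        names.append(leaf.name)
        seqs.append("".join(SENSE_CODONS[c] for c in st))
    aln = Alignment(names, seqs, "codon")
    truth = SimulationTruth(tree=tree, root_codons=root_states,
                            site_classes=site_classes, events=events,
                            params={"kappa": kappa, "omega_spec": omega_spec,
                                    "n_codons": n_codons, "seed": seed})
    return aln, truth


def conserved_protein_sites(aln: Alignment) -> np.ndarray:
    """0-based codon sites where all taxa share one residue (no gaps)."""
    cols = []
    for s in range(aln.length // 3):
        aas = {int(CODON_AA[CODON_INDEX[cod]])
               if (cod := seq[3 * s:3 * s + 3]) in CODON_INDEX else -1
               for seq in aln.sequences}
        if len(aas) == 1 and -1 not in aas:
            cols.append(s)
    return np.array(cols, dtype=int)


def inject_parallel_substitutions(aln: Alignment, truth: SimulationTruth,
                                  branch_ids: list[str], n_sites: int,
                                  seed: int
                                  ) -> tuple[Alignment, SimulationTruth]:
    """Force identical derived residues on the subtrees of listed branches.

    At each of ``n_sites`` randomly chosen conserved codon sites, one target
    residue distinct from the ancestral residue is realized on every leaf
    below each listed branch by the minimal codon change.  The truth records
    the injected sites.
    """
    tree = truth.tree
    rng = np.random.default_rng(seed)
    if n_sites == 0:
        return aln, truth
    candidates = conserved_protein_sites(aln)
    candidates = np.array([s for s in candidates
                           if all(d["site"] != s + 1
                                  for d in truth.injected_sites)])
    if len(candidates) < n_sites:
        raise ValueError(
            f"only {len(candidates)} conserved sites available, "
            f"{n_sites} requested")
    chosen = rng.choice(candidates, size=n_sites, replace=False)
    target_leaves: set[str] = set()
    for b in branch_ids:
        node = tree.node_by_edge_id(b)
        target_leaves.update(tree.subtree_leaves(node))

    seqs = {n: list(s) for n, s in zip(aln.names, aln.sequences)}
    new_truth = SimulationTruth(
        tree=tree, root_codons=truth.root_codons,
        site_classes=truth.site_classes, events=list(truth.events),
        injected_sites=list(truth.injected_sites), params=dict(truth.params))
    for s in sorted(int(x) for x in chosen):
        anc_codon = aln.sequences[0][3 * s:3 * s + 3]
        anc_aa = CODON_AA[CODON_INDEX[anc_codon]]
        # prefer residues one nucleotide away from the ancestral codon
        near = sorted({int(CODON_AA[j]) for j, cj in enumerate(SENSE_CODONS)
                       if CODON_AA[j] != anc_aa
                       and sum(a != b for a, b in zip(anc_codon, cj)) == 1})
        pool = near if near else [a for a in range(20) if a != anc_aa]
        target = int(rng.choice(pool))
        for name in target_leaves:
            cur = "".join(seqs[name][3 * s:3 * s + 3])
            best = min((c for j, c in enumerate(SENSE_CODONS)
                        if CODON_AA[j] == target),
                       key=lambda c: sum(a != b for a, b in zip(c, cur)))
            seqs[name][3 * s:3 * s + 3] = list(best)
        new_truth.injected_sites.append(
            {"site": s + 1, "branches": tuple(branch_ids),
             "residue": AA_ORDER[target],
             "ancestral": AA_ORDER[anc_aa]})
    new_aln = Alignment(list(aln.names),
                        ["".join(seqs[n]) for n in aln.names], "codon")
    return new_aln, new_truth


# ---------------------------------------------------------------------------
# qPCR synthesis

GROUPS = ("adult_echolocator", "embryo_echolocator", "adult_non_echolocator")
REGIONS = ("auditory", "visual", "motor_sensory", "olfactory_bulb",
           "cerebellum")


def default_fold_profile() -> dict[tuple[str, str], float]:
    """Relative-expression truth emulating the published pattern.

    Adult echolocating bats: ~70x in auditory cortex, ~40x visual, ~30x
    motor+sensory, ~17x olfactory bulb, baseline cerebellum; embryos ~13x /
    ~3x and otherwise near baseline; adult non-echolocators ~3x in the three
    cortices and below baseline elsewhere.
    """
    return {
        ("adult_echolocator", "auditory"): 70.0,
        ("adult_echolocator", "visual"): 40.0,
        ("adult_echolocator", "motor_sensory"): 30.0,
        ("adult_echolocator", "olfactory_bulb"): 17.0,
        ("adult_echolocator", "cerebellum"): 1.0,
        ("embryo_echolocator", "auditory"): 13.0,
        ("embryo_echolocator", "visual"): 3.2,
        ("embryo_echolocator", "motor_sensory"): 1.0,
        ("embryo_echolocator", "olfactory_bulb"): 1.0,
        ("embryo_echolocator", "cerebellum"): 1.0,
        ("adult_non_echolocator", "auditory"): 3.0,
        ("adult_non_echolocator", "visual"): 3.0,
        ("adult_non_echolocator", "motor_sensory"): 3.0,
        ("adult_non_echolocator", "olfactory_bulb"): 0.8,
        ("adult_non_echolocator", "cerebellum"): 0.8,
    }


def simulate_qpcr(true_folds: dict[tuple[str, str], float],
                  n_individuals: int = 3, n_replicates: int = 3,
                  ct_sd: float = 0.3, seed: int = 0,
                  calibrator: tuple[str, str] = ("adult_echolocator",
                                                 "cerebellum"),
                  base_reference_ct: float = 20.0,
                  base_delta_ct: float = 5.0) -> pd.DataFrame:
    """Triplicate Ct table realizing ``true_folds`` exactly (up to noise).

    The reference gene has constant Ct per individual (plus replicate
    noise); the target gene's Ct is offset so that 2^-ddCt relative to the
    calibrator cell reproduces the requested fold.  ``ct_sd`` is the
    replicate-level Gaussian noise on every well, in cycles.
    """
    if ct_sd < 0:
        raise ValueError("ct_sd must be >= 0")
    for fold in true_folds.values():
        if fold <= 0:
            raise ValueError("fold values must be positive")
    if calibrator not in true_folds:
        raise ValueError(f"calibrator cell {calibrator} missing from profile")
    rng = np.random.default_rng(seed)
    cal_fold = true_folds[calibrator]
    rows = []
    for (group, region), fold in true_folds.items():
        for ind in range(1, n_individuals + 1):
            ind_shift = rng.normal(0.0, ct_sd)
            ref_ct = base_reference_ct + ind_shift
            delta = base_delta_ct - np.log2(fold / cal_fold)
            for rep in range(1, n_replicates + 1):
                rows.append((group, region, f"ind{ind}", rep, "reference",
                             ref_ct + rng.normal(0.0, ct_sd)))
                rows.append((group, region, f"ind{ind}", rep, "target",
                             ref_ct + delta + rng.normal(0.0, ct_sd)))
    return pd.DataFrame(rows, columns=["group", "region", "individual",
                                       "replicate", "gene", "ct"])
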