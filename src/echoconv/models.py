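"""Substitution models: JTT amino-acid model and GY94-style codon model.

Both models are continuous-time reversible Markov chains.  The amino-acid
chain uses the JTT empirical exchangeabilities (Jones, Taylor & Thornton
1992; the integer exchangeability values and equilibrium frequencies as
conventionally distributed with phylogenetics software) combined with either
the published equilibrium frequencies or frequencies observed in the data
("+F").  The codon chain is the Goldman-Yang style model over the 61 sense
codons of the standard genetic code: single-nucleotide changes only, with a
transition/transversion ratio ``kappa`` and a nonsynonymous/synonymous rate
ratio ``omega``; target-codon frequencies ``pi`` multiply every rate.

Every rate matrix is scaled to one expected event per unit branch length so
branch lengths are expected substitutions per site (per codon for the codon
chain).
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# JTT exchangeabilities, lower triangle, row-major in AA_ORDER (190 values).
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

JTT_FREQS = np.array([
    0.076747923252076758, 0.051690948309051694, 0.042644957355042652,
    0.051543948456051550, 0.019802980197019805, 0.040751959248040752,
    0.061829938170061841, 0.073151926848073159, 0.022943977056022944,
    0.053760946239053767, 0.091903908096091905, 0.058675941324058678,
    0.023825976174023829, 0.040125959874040135, 0.050900949099050907,
    0.068764931235068771, 0.058564941435058568, 0.014260985739014262,
    0.032101967898032102, 0.066004933995066004,
])


def _jtt_exchangeabilities() -> np.ndarray:
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = _JTT_LOWER[k]
            k += 1
    return S


JTT_EXCH = _jtt_exchangeabilities()


def normalize_rate_matrix(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Scale Q (off-diagonals set, diagonal ignored) to unit mean rate."""
    Q = Q.copy()
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / mu


def aa_rate_matrix(freqs: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """JTT(+F) rate matrix, unit mean rate.  Returns (Q, pi)."""
    pi = JTT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if pi.shape != (20,) or np.any(pi < 0):
        raise ValueError("frequencies must be a non-negative 20-vector")
    pi = pi / pi.sum()
    Q = JTT_EXCH * pi[None, :]
    return normalize_rate_matrix(Q, pi), pi


class ReversibleModel:
    """Eigendecomposition of a reversible rate matrix for fast P(t).

    The similarity transform B = D^{1/2} Q D^{-1/2} (D = diag(pi)) is
    symmetric, so a single `eigh` yields P(t) = A exp(L t) Ainv for any t.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self.pi = np.asarray(pi, dtype=float)
        d = np.sqrt(np.maximum(self.pi, 1e-300))
        B = (d[:, None] * self.Q) / d[None, :]
        B = 0.5 * (B + B.T)
        lam, V = np.linalg.eigh(B)
        self.lam = lam
        self.A = V / d[:, None]
        self.Ainv = V.T * d[None, :]

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self.A * np.exp(self.lam * t)) @ self.Ainv
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Batched P(t) for an array of branch lengths -> (n, k, k)."""
        ts = np.asarray(ts, dtype=float)
        E = np.exp(self.lam[None, :] * ts[:, None])      # (n, k)
        P = np.einsum("ik,nk,kj->nij", self.A, E, self.Ainv, optimize=True)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# Standard genetic code tables for the codon chain.

NUC_ORDER = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUC_ORDER)}

_ALL_CODONS = [a + b + c for a in NUC_ORDER for b in NUC_ORDER for c in NUC_ORDER]
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}          # 61 states
CODON_AA = np.array([AA_INDEX[standard_dna_table.forward_table[c]]
                     for c in SENSE_CODONS])
N_CODONS = len(SENSE_CODONS)

_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


def _codon_change_type() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per ordered sense-codon pair: single-nt change flags.

    Returns boolean (61,61) arrays: single nucleotide difference, is a
    transition, is nonsynonymous.
    """
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            single[i, j] = True
            transition[i, j] = frozenset((ci[p], cj[p])) in _TRANSITION_PAIRS
            nonsyn[i, j] = CODON_AA[i] != CODON_AA[j]
    return single, transition, nonsyn


CODON_SINGLE_NT, CODON_TRANSITION, CODON_NONSYN = _codon_change_type()


def codon_rate_matrix_raw(kappa: float, omega: float,
                          pi: np.ndarray) -> tuple[np.ndarray, float]:
    """Unscaled GY94-style rate matrix.  Returns (Q, mean rate under pi).

    Mixture models share one time scale across site classes: every class
    matrix is divided by the same factor (the proportion-weighted mean rate
    of the background classes), so a class or branch with elevated omega
    genuinely substitutes faster — the relative rates among classes carry
    the selection signal.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError("pi must have one entry per sense codon")
    pi = pi / pi.sum()
    Q = np.where(CODON_SINGLE_NT, pi[None, :], 0.0)
    Q = np.where(CODON_TRANSITION, kappa * Q, Q)
    Q = np.where(CODON_NONSYN, omega * Q, Q)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q, float(mu)


def codon_rate_matrix(kappa: float, omega: float,
                      pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GY94-style codon rate matrix, unit mean rate (single-class models)."""
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    Q, mu = codon_rate_matrix_raw(kappa, omega, pi)
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / mu, pi


def mixture_rate_scale(classes, kappa: float, pi: np.ndarray) -> float:
    """Common time scale for a set of (weight, omega_bg, omega_fg) classes.

    The scale is the weighted mean substitution rate of the *background*
    process, so branch lengths read as expected substitutions per codon on
    a background branch.
    """
    s = 0.0
    for w, om_bg, _ in classes:
        _, mu = codon_rate_matrix_raw(kappa, om_bg, pi)
        s += w * mu
    if s <= 0:
        raise ValueError("degenerate mixture: zero mean rate")
    return s


def f3x4_frequencies(codon_columns: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from integer-coded codon data.

    ``codon_columns``: any-shape array of sense-codon indices (negative =
    missing).  Position-specific nucleotide frequencies are multiplied and
    renormalized over sense codons.
    """
    codes = np.asarray(codon_columns).ravel()
    codes = codes[codes >= 0]
    if codes.size == 0:
        raise ValueError("no codons observed")
    pos_freq = np.zeros((3, 4))
    for p in range(3):
        nts = np.array([NUC_INDEX[SENSE_CODONS[c][p]] for c in codes])
        pos_freq[p] = np.bincount(nts, minlength=4) + 0.5   # light smoothing
        pos_freq[p] /= pos_freq[p].sum()
    pi = np.array([pos_freq[0][NUC_INDEX[c[0]]]
                   * pos_freq[1][NUC_INDEX[c[1]]]
                   * pos_freq[2][NUC_INDEX[c[2]]] for c in SENSE_CODONS])
    return pi / pi.sum()


def uniform_f3x4(base_freqs: np.ndarray | None = None) -> np.ndarray:
    """F3x4 frequencies from one shared nucleotide composition."""
    if base_freqs is None:
        base_freqs = np.array([0.22, 0.26, 0.28, 0.24])   # T C A G
    f = np.asarray(base_freqs, dtype=float)
    f = f / f.sum()
    pi = np.array([f[NUC_INDEX[c[0]]] * f[NUC_INDEX[c[1]]] * f[NUC_INDEX[c[2]]]
                   for c in SENSE_CODONS])
    return pi / pi.sum()
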