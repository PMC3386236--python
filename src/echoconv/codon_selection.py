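"""Codon-model likelihoods, branch and branch-site tests, and BEB sites.

The substitution process is the Goldman-Yang style codon model (61 sense
codons, single-nucleotide exchanges, transition/transversion ratio kappa,
nonsynonymous/synonymous ratio omega, F3x4 codon frequencies computed from
the data).  Models:

* ``m0``           one ratio for all branches and sites;
* ``branch2``      two ratios: background omega0, foreground omega_fg on the
                   designated echolocator edges; ``branch2_null`` fixes
                   omega_fg = 1 (the branch-model significance test);
* ``modelA``       the branch-site mixture with classes 0 (omega0 <= 1),
                   1 (omega1 = 1), 2a and 2b (foreground omega2 >= 1, the
                   background keeping omega0 / 1); ``modelA_null`` fixes
                   omega2 = 1 ("test 2").

Fits maximize the likelihood by bounded quasi-Newton (L-BFGS-B) with
analytic branch-length gradients and a multi-start stage for the model
parameters; branch lengths are refined jointly in the final stage.
Positively selected sites are identified by the Bayes empirical Bayes
scheme, integrating over a discrete grid on (p0, p1, omega0, omega2) with
equal prior weight; a plug-in NEB mode is available for quick looks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import Alignment, encode_codons
from .ancestral import least_squares_branch_lengths
from .distances import nt_k2p_matrix
from .likelihood import PruningEngine, compress_patterns
from .models import (N_CODONS, ReversibleModel, codon_rate_matrix_raw,
                     f3x4_frequencies, mixture_rate_scale)
from .tree import PhyloTree

MODEL_IDS = ("m0", "branch2", "branch2_null", "modelA", "modelA_null")


@dataclass
class CodonModel:
    """Parameter set for one codon model."""

    model_id: str
    kappa: float
    pi: np.ndarray                            # 61 codon frequencies (F3x4)
    branch_lengths: dict[str, float]          # edge_id -> expected events/codon
    foreground: tuple[str, ...] = ()
    omega: float | None = None                # m0
    omega0: float | None = None               # branch2 background / class 0
    omega_fg: float | None = None             # branch2 foreground
    omega2: float | None = None               # modelA classes 2a/2b (fg)
    p0: float | None = None
    p1: float | None = None

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.model_id.startswith(("branch2", "modelA")) and not self.foreground:
            raise ValueError(f"{self.model_id} requires foreground edges")

    @property
    def proportions(self) -> tuple[float, float, float, float] | None:
        """Site-class proportions (p0, p1, p2a, p2b) for modelA."""
        if not self.model_id.startswith("modelA"):
            return None
        p0, p1 = self.p0, self.p1
        rest = max(1.0 - p0 - p1, 0.0)
        tot = p0 + p1
        return (p0, p1, rest * p0 / tot, rest * p1 / tot)

    def site_classes(self) -> list[tuple[float, float, float]]:
        """List of (weight, background omega, foreground omega)."""
        mid = self.model_id
        if mid == "m0":
            return [(1.0, self.omega, self.omega)]
        if mid == "branch2":
            return [(1.0, self.omega0, self.omega_fg)]
        if mid == "branch2_null":
            return [(1.0, self.omega0, 1.0)]
        w2 = 1.0 if mid == "modelA_null" else self.omega2
        p0, p1, p2a, p2b = self.proportions
        return [(p0, self.omega0, self.omega0), (p1, 1.0, 1.0),
                (p2a, self.omega0, w2), (p2b, 1.0, w2)]


@dataclass
class CodonModelFit:
    model: CodonModel
    lnl: float
    site_class_posteriors: np.ndarray | None = None     # (n_sites, 4)
    converged: bool = True
    grad_norm: float = float("nan")
    n_restarts: int = 0
    _fitter: "object | None" = field(default=None, repr=False)


class _CodonLik:
    """Cached pruning machinery for one alignment x tree."""

    def __init__(self, aln: Alignment, tree: PhyloTree,
                 foreground: tuple[str, ...], pi: np.ndarray):
        if set(aln.names) != set(tree.leaf_names):
            raise ValueError("alignment names do not match tree leaves")
        self.tree = tree
        self.pi = pi
        codes = encode_codons(aln)
        self.n_sites = codes.shape[1]
        patterns, counts, inverse = compress_patterns(codes)
        self.counts, self.inverse = counts, inverse
        leaf_codes = {name: patterns[i] for i, name in enumerate(aln.names)}
        self.engine = PruningEngine(tree, leaf_codes, N_CODONS)
        self.edge_order = [tree.edge_id(n) for n in tree.postorder]
        fg_nodes = set()
        for label in foreground:
            node = tree.node_by_edge_id(label)
            fg_nodes.add(id(node))
        self.fg_mask = np.array([id(n) in fg_nodes for n in tree.postorder])
        self.free_edges = [i for i, n in enumerate(tree.postorder)
                           if n.parent is not None]
        self._model_cache: dict[tuple[float, float], ReversibleModel] = {}

    def _model_for(self, kappa: float, omega: float) -> ReversibleModel:
        key = (float(kappa), float(omega))
        if key not in self._model_cache:
            if len(self._model_cache) > 64:
                self._model_cache.clear()
            Q, _ = codon_rate_matrix_raw(kappa, omega, self.pi)
            self._model_cache[key] = ReversibleModel(Q, self.pi)
        return self._model_cache[key]

    def matrices(self, kappa: float, classes, lengths: np.ndarray,
                 want_q: bool, scale: float | None = None):
        """(C, n_nodes, K, K) transition (and rate) matrices per class.

        All classes share one time scale (weighted mean background rate),
        so relative rates among classes and between foreground/background
        are preserved.
        """
        if scale is None:
            scale = mixture_rate_scale(classes, kappa, self.pi)
        C = len(classes)
        N = len(self.edge_order)
        eff = np.asarray(lengths, dtype=float) / scale
        models = {om: self._model_for(kappa, om)
                  for _, wb, wf in classes for om in (wb, wf)}
        P = np.empty((C, N, N_CODONS, N_CODONS))
        Qa = np.empty_like(P) if want_q else None
        cache: dict[float, np.ndarray] = {}
        for c, (_, wb, wf) in enumerate(classes):
            for om, mask in ((wb, ~self.fg_mask), (wf, self.fg_mask)):
                idx = np.nonzero(mask)[0]
                if idx.size == 0:
                    continue
                if om not in cache:
                    cache[om] = models[om].transition_matrices(eff)
                P[c, idx] = cache[om][idx]
                if want_q:
                    Qa[c, idx] = models[om].Q / scale
        return P, Qa

    def _mu(self, kappa: float, omega: float) -> float:
        """Mean rate of the unscaled matrix (for the common time scale)."""
        Q = self._model_for(kappa, omega).Q
        return float(-(self.pi * np.diag(Q)).sum())

    def loglik(self, model: CodonModel, want_grad: bool = False,
               want_classes: bool = False):
        classes = model.site_classes()
        lengths = np.array([model.branch_lengths.get(eid, 0.0)
                            for eid in self.edge_order])
        weights = np.array([w for w, _, _ in classes])
        mus_bg = np.array([self._mu(model.kappa, wb) for _, wb, _ in classes])
        scale = float(weights @ mus_bg)
        P, Qa = self.matrices(model.kappa, classes, lengths, want_grad,
                              scale=scale)
        res = self.engine.compute(P, weights, self.pi, counts=self.counts,
                                  Q=Qa)
        if not np.isfinite(res.lnl):
            bad = np.nonzero(~np.isfinite(res.site_lnl))[0]
            site = int(self.inverse.tolist().index(bad[0])) if bad.size else -1
            raise FloatingPointError(
                f"non-finite likelihood (first bad site {site + 1})")
        out = [res.lnl]
        if want_grad:
            out.append(res.grad_bl)
            out.append({"class_site_lik": res.class_site_lik,
                        "weights": weights, "mus_bg": mus_bg,
                        "scale": scale, "lengths": lengths})
        if want_classes:
            post = (weights[:, None] * res.class_site_lik)
            post = post / np.maximum(post.sum(axis=0, keepdims=True), 1e-300)
            out.append(post.T[self.inverse])             # (n_sites, C)
        return out[0] if len(out) == 1 else tuple(out)

    def class_site_likelihoods(self, kappa: float, lengths: np.ndarray,
                               omega_bg: float, omega_fg: float,
                               scale: float) -> np.ndarray:
        """Per-pattern likelihood of a single (bg, fg) omega class, on the
        fitted model's time scale."""
        P, _ = self.matrices(kappa, [(1.0, omega_bg, omega_fg)], lengths,
                             False, scale=scale)
        res = self.engine.compute(P, np.ones(1), self.pi, counts=self.counts)
        return np.maximum(res.class_site_lik[0], 1e-300)


def codon_loglik(aln: Alignment, tree: PhyloTree, model: CodonModel) -> float:
    """Log-likelihood of a codon alignment under one model.

    Branch lengths are taken from ``model.branch_lengths`` (keyed by edge
    id); gap codons contribute ones in the pruning recursion.
    """
    lik = _CodonLik(aln, tree, model.foreground, model.pi)
    return float(lik.loglik(model))


# ---------------------------------------------------------------------------
# Fitting


_PARAM_SPECS = {
    # name -> (bounds, default init)
    "kappa": ((0.2, 30.0), 2.0),
    "omega": ((1e-4, 30.0), 0.3),
    "omega0": ((1e-4, 1.0), 0.2),
    "omega_fg": ((1e-4, 30.0), 0.5),
    "omega2": ((1.0, 50.0), 2.0),
    "pA": ((1e-3, 1.0 - 1e-6), 0.9),       # p0 + p1
    "pB": ((1e-6, 1.0 - 1e-6), 0.8),       # p0 / (p0 + p1)
}

_MODEL_PARAMS = {
    "m0": ["kappa", "omega"],
    "branch2": ["kappa", "omega0", "omega_fg"],
    "branch2_null": ["kappa", "omega0"],
    "modelA": ["kappa", "omega0", "omega2", "pA", "pB"],
    "modelA_null": ["kappa", "omega0", "pA", "pB"],
}

_BL_BOUNDS = (1e-7, 8.0)


def initial_codon_branch_lengths(aln: Alignment, tree: PhyloTree
                                 ) -> dict[str, float]:
    """Distance-based starting branch lengths (events per codon).

    Least-squares fit of K2P nucleotide distances on the fixed topology,
    converted to a per-codon scale (x3) and floored away from zero.
    """
    fitted = least_squares_branch_lengths(tree, nt_k2p_matrix(aln))
    return {fitted.edge_id(n): max(3.0 * (n.length or 0.0), 1e-4)
            for n in fitted.postorder if n.parent is not None}


def fit_model(aln: Alignment, tree: PhyloTree, model_id: str,
              foreground: tuple[str, ...] | list[str] = (),
              pi: np.ndarray | None = None, seed: int = 0,
              restarts: int = 3, maxiter: int = 150,
              init: CodonModel | None = None) -> CodonModelFit:
    """Maximum-likelihood fit of one codon model.

    F3x4 codon frequencies are computed from the data (not optimized).
    ``restarts`` random starts of the model parameters (branch lengths held
    at distance-based initial values) are refined, then the best start is
    polished jointly over model parameters and all branch lengths.
    ``init`` (e.g. a null fit) seeds one additional warm start.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    if model_id != "m0" and not foreground:
        foreground = tuple(tree.foreground_edges)
        if not foreground:
            raise ValueError(f"{model_id} requires foreground edges")
    foreground = tuple(foreground)
    if pi is None:
        pi = f3x4_frequencies(encode_codons(aln))
    fitter = _CodonLik(aln, tree, foreground, pi)
    names = _MODEL_PARAMS[model_id]
    rng = np.random.default_rng(seed)

    bl0 = initial_codon_branch_lengths(aln, tree)
    if init is not None:
        bl0 = dict(init.branch_lengths)
    t0 = np.array([bl0[fitter.edge_order[i]] for i in fitter.free_edges])

    def neg_lnl_params(x):
        m = _vector_to_model(model_id, names, x, fitter, foreground, pi,
                             dict(zip((fitter.edge_order[i] for i in
                                       fitter.free_edges), t0)))
        return -fitter.loglik(m)

    def starts():
        draws = []
        if init is not None:
            draws.append(_init_from_model(names, init))
        draws.append(np.array([_PARAM_SPECS[n][1] for n in names]))
        while len(draws) < max(restarts, 1) + (init is not None):
            x = []
            for n in names:
                if n == "kappa":
                    x.append(rng.uniform(1.0, 5.0))
                elif n in ("omega", "omega_fg"):
                    x.append(rng.uniform(0.05, 2.0))
                elif n == "omega0":
                    x.append(rng.uniform(0.02, 0.9))
                elif n == "omega2":
                    x.append(rng.uniform(1.0, 6.0))
                else:
                    x.append(rng.uniform(0.3, 0.98))
            draws.append(np.array(x))
        return draws

    pbounds = [_PARAM_SPECS[n][0] for n in names]
    best_x, best_f = None, np.inf
    for x0 in starts():
        r = minimize(neg_lnl_params, x0, method="L-BFGS-B", bounds=pbounds,
                     options={"maxiter": 60, "ftol": 1e-9})
        if r.fun < best_f:
            best_f, best_x = r.fun, r.x

    # joint refinement over model parameters and branch lengths
    x0 = np.concatenate([best_x, t0])
    bounds = pbounds + [_BL_BOUNDS] * len(t0)

    def neg_lnl_and_grad(x):
        m = _vector_to_model(model_id, names, x[:len(names)], fitter,
                             foreground, pi,
                             dict(zip((fitter.edge_order[i] for i in
                                       fitter.free_edges),
                                      x[len(names):])))
        lnl, grad_bl, aux = fitter.loglik(m, want_grad=True)
        g = np.empty_like(x)
        g[len(names):] = -grad_bl[fitter.free_edges]
        analytic: dict[str, float] = {}
        if model_id.startswith("modelA"):
            # mixture-proportion gradients: weight channel plus the common
            # time-scale channel (scale = sum_c w_c mu_bg_c)
            w = aux["weights"]
            cls_lik = aux["class_site_lik"]
            site_lik = np.maximum(w @ cls_lik, 1e-300)
            dl_dw = ((fitter.counts[None, :] * cls_lik)
                     / site_lik[None, :]).sum(axis=1)
            dl_ds = -float((aux["lengths"] * grad_bl).sum()) / aux["scale"]
            total = dl_dw + dl_ds * aux["mus_bg"]
            pA, pB = (float(x[names.index("pA")]),
                      float(x[names.index("pB")]))
            dwdpA = np.array([pB, 1 - pB, -pB, -(1 - pB)])
            dwdpB = np.array([pA, -pA, 1 - pA, -(1 - pA)])
            analytic["pA"] = float(total @ dwdpA)
            analytic["pB"] = float(total @ dwdpB)
        for k, name in enumerate(names):
            if name in analytic:
                g[k] = -analytic[name]
                continue
            h = 1e-5 * max(1.0, abs(x[k]))
            xp = x.copy()
            lo, hi = bounds[k]
            if x[k] + h > hi:
                h = -h
            xp[k] = x[k] + h
            mp = _vector_to_model(model_id, names, xp[:len(names)], fitter,
                                  foreground, pi,
                                  dict(zip((fitter.edge_order[i] for i in
                                            fitter.free_edges),
                                           xp[len(names):])))
            g[k] = -(fitter.loglik(mp) - lnl) / h
        return -lnl, g

    r = minimize(neg_lnl_and_grad, x0, jac=True, method="L-BFGS-B",
                 bounds=bounds, options={"maxiter": maxiter, "ftol": 1e-10})
    converged = bool(r.success) or abs(r.fun - best_f) < 0.5
    if not r.success and r.fun > best_f:
        # joint stage failed to improve; keep the multi-start optimum
        r.x = x0
        r.fun = best_f
    model = _vector_to_model(model_id, names, r.x[:len(names)], fitter,
                             foreground, pi,
                             dict(zip((fitter.edge_order[i] for i in
                                       fitter.free_edges),
                                      r.x[len(names):])))
    want_classes = model_id.startswith("modelA")
    if want_classes:
        lnl, post = fitter.loglik(model, want_classes=True)
    else:
        lnl = fitter.loglik(model)
        post = None
    if not converged:
        warnings.warn(f"{model_id} fit did not converge cleanly")
    return CodonModelFit(model=model, lnl=float(lnl),
                         site_class_posteriors=post, converged=converged,
                         grad_norm=float(np.linalg.norm(
                             getattr(r, "jac", np.nan))),
                         n_restarts=max(restarts, 1), _fitter=fitter)


def _init_from_model(names, model: CodonModel) -> np.ndarray:
    # missing nested parameters start exactly at the null boundary, so a
    # warm-started alternative begins at the null optimum and can only climb
    vals = {"kappa": model.kappa, "omega": model.omega,
            "omega0": model.omega0, "omega_fg": model.omega_fg or 1.0,
            "omega2": model.omega2 or 1.0}
    if model.p0 is not None:
        pA = model.p0 + model.p1
        vals["pA"] = pA
        vals["pB"] = model.p0 / pA if pA > 0 else 0.5
    out = []
    for n in names:
        lo, hi = _PARAM_SPECS[n][0]
        v = vals.get(n)
        out.append(np.clip(v if v is not None else _PARAM_SPECS[n][1],
                           lo, hi))
    return np.array(out)


def _vector_to_model(model_id, names, x, fitter, foreground, pi,
                     branch_lengths) -> CodonModel:
    kw = dict(zip(names, (float(v) for v in x)))
    params: dict = {}
    if model_id == "m0":
        params = {"omega": kw["omega"]}
    elif model_id == "branch2":
        params = {"omega0": kw["omega0"], "omega_fg": kw["omega_fg"]}
    elif model_id == "branch2_null":
        params = {"omega0": kw["omega0"], "omega_fg": 1.0}
    else:
        pA, pB = kw["pA"], kw["pB"]
        params = {"omega0": kw["omega0"], "p0": pA * pB,
                  "p1": pA * (1.0 - pB)}
        if model_id == "modelA":
            params["omega2"] = kw["omega2"]
    return CodonModel(model_id=model_id, kappa=kw["kappa"], pi=pi,
                      branch_lengths=branch_lengths, foreground=foreground,
                      **params)


def lrt(fit_alt: CodonModelFit, fit_null: CodonModelFit,
        df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio test of nested fits: (2*delta_lnL, p from chi2_df).

    The statistic is clamped at zero; a markedly negative value before
    clamping indicates optimizer failure and raises.
    """
    two_delta = 2.0 * (fit_alt.lnl - fit_null.lnl)
    if two_delta < -1e-4:
        raise RuntimeError(
            f"alternative lnL below null lnL (2dl = {two_delta:.6f}): "
            "optimizer failure")
    two_delta = max(two_delta, 0.0)
    return two_delta, float(chi2.sf(two_delta, df))


# ---------------------------------------------------------------------------
# Empirical Bayes identification of positively selected sites


@dataclass
class SelectedSite:
    site: int                # 1-based protein/codon site
    residue: str             # residue of the first taxon at that site
    posterior: float


def beb_site_posteriors(fit: CodonModelFit, n_grid: int = 10,
                        threshold: float = 0.90, method: str = "beb"
                        ) -> tuple[np.ndarray, list[SelectedSite]]:
    """Posterior probability per site of the positive-selection classes.

    ``method="beb"`` integrates over a uniform discrete grid on
    (p0+p1, p0/(p0+p1), omega0, omega2) with equal prior weight, holding
    kappa and branch lengths at their MLEs (the Bayes empirical Bayes
    scheme).  ``method="neb"`` plugs in the MLEs directly (faster,
    anticonservative).  Returns (per-site posterior, sites above
    ``threshold``).
    """
    model = fit.model
    if model.model_id != "modelA":
        raise ValueError("site posteriors require a modelA alternative fit")
    fitter: _CodonLik = fit._fitter
    if fitter is None:
        raise ValueError("fit carries no likelihood context")

    if method == "neb":
        post = fit.site_class_posteriors
        p_sel = post[:, 2] + post[:, 3]
        return p_sel, _flag_sites(fitter, p_sel, threshold)
    if method != "beb":
        raise ValueError(f"unknown method {method!r}")

    lengths = np.array([model.branch_lengths.get(eid, 0.0)
                        for eid in fitter.edge_order])
    scale = mixture_rate_scale(model.site_classes(), model.kappa, fitter.pi)
    mid = (2.0 * np.arange(1, n_grid + 1) - 1.0) / (2.0 * n_grid)
    w0_grid = mid                                  # omega0 in (0,1)
    w2_grid = 1.0 + 10.0 * mid                     # omega2 in (1,11)
    pa_grid, pb_grid = mid, mid

    f1 = fitter.class_site_likelihoods(model.kappa, lengths, 1.0, 1.0, scale)
    f0 = np.array([fitter.class_site_likelihoods(model.kappa, lengths, w, w,
                                                 scale)
                   for w in w0_grid])
    f2b = np.array([fitter.class_site_likelihoods(model.kappa, lengths,
                                                  1.0, w2, scale)
                    for w2 in w2_grid])
    f2a = np.array([[fitter.class_site_likelihoods(model.kappa, lengths,
                                                   w0, w2, scale)
                     for w2 in w2_grid] for w0 in w0_grid])

    pa = pa_grid[:, None]
    pb = pb_grid[None, :]
    W = np.stack([pa * pb, pa * (1 - pb),
                  (1 - pa) * pb, (1 - pa) * (1 - pb)])    # (4, n, n)
    W = W.reshape(4, -1).T                                # grid x class

    counts = fitter.counts
    logms = []
    terms = []
    for i in range(n_grid):
        for j in range(n_grid):
            F = np.stack([f0[i], f1, f2a[i, j], f2b[j]])  # (4, S)
            L = W @ F                                     # (grid_pq, S)
            logm = (counts[None, :] * np.log(L)).sum(axis=1)
            sel = (W[:, 2:4] @ F[2:4]) / L                # P(sel | theta)
            logms.append(logm)
            terms.append(sel)
    logms = np.concatenate(logms)
    terms = np.vstack(terms)
    logms -= logms.max()
    gw = np.exp(logms)
    gw /= gw.sum()
    p_sel_patterns = gw @ terms
    p_sel = p_sel_patterns[fitter.inverse]
    return p_sel, _flag_sites(fitter, p_sel, threshold)


def _flag_sites(fitter: _CodonLik, p_sel: np.ndarray,
                threshold: float) -> list[SelectedSite]:
    from .models import AA_ORDER, CODON_AA
    first_leaf = fitter.tree.leaves[0]
    idx = fitter.engine.index[id(first_leaf)]
    onehot = fitter.engine.leaf_onehot[idx]
    codes = np.where(onehot.sum(axis=1) == 1, np.argmax(onehot, axis=1), -1)
    codes = codes[fitter.inverse]
    out = []
    for s in np.nonzero(p_sel > threshold)[0]:
        res = AA_ORDER[CODON_AA[codes[s]]] if codes[s] >= 0 else "?"
        out.append(SelectedSite(site=int(s) + 1, residue=res,
                                posterior=float(p_sel[s])))
    return out
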