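"""Codon substitution models and the positive-selection screen.

GY94-style models over the 61 sense codons of the universal code:

* M0 — a single dN/dS ratio (omega) for all sites and branches;
* M1a — nearly-neutral site mixture (omega0 < 1, omega = 1);
* M2a — M1a plus a positively selected class (omega2 > 1);
* branch-site model A — site classes whose omega switches to omega2 on a
  pre-specified foreground branch set only, and its null with omega2 = 1.

Likelihood-ratio tests use chi-square thresholds of 3.84 (1 df, branch-site)
and 5.99 (2 df, M1a vs M2a).  Site-wise positive selection on the foreground
is scored with a Bayes empirical Bayes (BEB) posterior that integrates the
site-class probabilities over a uniform prior grid on the mixture and omega
parameters, with kappa and branch lengths plugged in at their MLEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .phylik import EigSystem, LikelihoodEngine, SiteClass, TreeData
from .seqdata import GeneAlignment
from .stats import chisq_critical
from .treekit import PhyloTree

NT = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT)}
STOPS = {"TAA", "TAG", "TGA"}

CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in NT
    for b in NT
    for c in NT
    if a + b + c not in STOPS
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

from Bio.Data.CodonTable import standard_dna_table as _std

CODON_AA = tuple(_std.forward_table[c] for c in CODONS)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _pair_tables():
    n = len(CODONS)
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    synonymous = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = diffs[0] in _TRANSITIONS
            synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return single, transition, synonymous


_SINGLE, _TRANSITION, _SYNONYMOUS = _pair_tables()


def f3x4_frequencies(codon_seqs: dict[str, str]) -> np.ndarray:
    """F3x4 codon frequencies from positional nucleotide counts."""
    counts = np.full((3, 4), 0.1)
    for seq in codon_seqs.values():
        for i, ch in enumerate(seq):
            j = NT_INDEX.get(ch)
            if j is not None:
                counts[i % 3, j] += 1
    pos = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            pos[0, NT_INDEX[c[0]]] * pos[1, NT_INDEX[c[1]]] * pos[2, NT_INDEX[c[2]]]
            for c in CODONS
        ]
    )
    return freqs / freqs.sum()


def codon_generator(
    kappa: float, omega: float, freqs: np.ndarray
) -> np.ndarray:
    """Unscaled GY94 rate matrix; reversible w.r.t. ``freqs``.

    q_ij is zero for multi-nucleotide changes and proportional to pi_j,
    with factor kappa for transitions and omega for non-synonymous changes.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size != len(CODONS) or abs(freqs.sum() - 1) > 1e-8 or freqs.min() < 0:
        raise ValueError("invalid codon frequency vector")
    Q = np.where(_SINGLE, freqs[None, :], 0.0)
    Q = np.where(_TRANSITION, kappa * Q, Q)
    Q = np.where(_SINGLE & ~_SYNONYMOUS, omega * Q, Q)
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
    return Q


def mean_rate(Q: np.ndarray, freqs: np.ndarray) -> float:
    return float(-(freqs * np.diag(Q)).sum())


@dataclass
class CodonFit:
    """One fitted codon model for one gene."""

    model: str
    lnl: float
    kappa: float
    params: dict
    lengths: np.ndarray
    freqs: np.ndarray
    converged: bool
    foreground: frozenset[str] | None = None


@dataclass
class LrtResult:
    """Likelihood-ratio verdict; the statistic is clamped at zero."""

    stat: float
    df: int
    critical: float
    significant: bool
    clamped: bool = False
    lnl_alt: float = float("nan")
    lnl_null: float = float("nan")

    @classmethod
    def from_fits(cls, alt: CodonFit, null: CodonFit, df: int) -> "LrtResult":
        raw = 2.0 * (alt.lnl - null.lnl)
        clamped = raw < 0
        stat = max(raw, 0.0)
        crit = round(chisq_critical(df), 2)  # 3.84 / 5.99
        return cls(stat, df, crit, stat > crit, clamped, alt.lnl, null.lnl)


@dataclass
class SiteSelectionPosterior:
    site: int           # codon index, 0-based
    pp_positive: float

    @property
    def flagged(self) -> bool:
        return self.pp_positive > 0.95


# ---------------------------------------------------------------------------
# model internals
# ---------------------------------------------------------------------------

def _codon_states(aln: GeneAlignment) -> dict[str, np.ndarray]:
    states = {}
    for taxon in aln.taxa:
        seq = aln.codon_seqs[taxon]
        states[taxon] = np.array(
            [
                CODON_INDEX.get(seq[i : i + 3], -1)
                for i in range(0, len(seq), 3)
            ],
            dtype=int,
        )
    return states


class _CodonProblem:
    """Shared state for fitting one gene: patterns, tree index, eig cache."""

    def __init__(self, aln: GeneAlignment, tree: PhyloTree, default_length=0.1):
        self.aln = aln
        self.freqs = f3x4_frequencies(aln.codon_seqs)
        states = _codon_states(aln)
        leaf_names = set(tree.leaf_names())
        mat = np.array([states[t] for t in aln.taxa if t in leaf_names])
        taxa = [t for t in aln.taxa if t in leaf_names]
        cols, counts = np.unique(mat, axis=1, return_counts=True)
        self.site_to_pattern = self._pattern_index(mat, cols)
        self.tip_states = {t: cols[i] for i, t in enumerate(taxa)}
        self.weights = counts.astype(float)
        self.td = TreeData.from_tree(tree, default_length=default_length)
        self._eig_cache: dict[tuple, EigSystem] = {}

    @staticmethod
    def _pattern_index(mat, cols):
        key = {tuple(cols[:, j]): j for j in range(cols.shape[1])}
        return np.array([key[tuple(mat[:, s])] for s in range(mat.shape[1])])

    def eig(self, kappa: float, omega: float) -> EigSystem:
        key = (round(kappa, 12), round(omega, 12))
        if key not in self._eig_cache:
            if len(self._eig_cache) > 400:
                self._eig_cache.clear()
            self._eig_cache[key] = EigSystem(
                codon_generator(kappa, omega, self.freqs), self.freqs
            )
        return self._eig_cache[key]

    def engine(self, classes) -> LikelihoodEngine:
        return LikelihoodEngine(
            self.td, self.tip_states, self.weights, classes, len(CODONS)
        )

    def fg_mask(self, foreground: frozenset[str]) -> np.ndarray:
        mask = np.zeros(self.td.n_nodes, dtype=bool)
        for node, taxon in self.td.leaf_taxon.items():
            if taxon in foreground:
                mask[node] = True
        return mask


def _scaled_classes(problem, kappa, class_defs, fg_mask=None):
    """Build SiteClasses scaled so one unit of branch length is one expected
    substitution per codon site under the omega-mixture on the background."""
    mu = 0.0
    for w, w_bg, _ in class_defs:
        mu += w * mean_rate(
            codon_generator(kappa, w_bg, problem.freqs), problem.freqs
        )
    classes = []
    for w, w_bg, w_fg in class_defs:
        eig_bg = problem.eig(kappa, w_bg)
        eig_fg = problem.eig(kappa, w_fg) if w_fg is not None else None
        classes.append(
            SiteClass(
                weight=w,
                eig_bg=eig_bg,
                eig_fg=eig_fg,
                fg_edges=fg_mask if w_fg is not None else None,
                rate=1.0 / mu,
            )
        )
    return classes


def _class_defs(model, kappa, params, for_scaling_only=False):
    """(weight, omega_background, omega_foreground|None) triples."""
    if model == "M0":
        return [(1.0, params["omega"], None)]
    if model == "M1a":
        p0, w0 = params["p0"], params["omega0"]
        return [(p0, w0, None), (1 - p0, 1.0, None)]
    if model == "M2a":
        p0, p1, w0, w2 = (
            params["p0"], params["p1"], params["omega0"], params["omega2"],
        )
        return [(p0, w0, None), (p1, 1.0, None), (1 - p0 - p1, w2, None)]
    if model in ("BS_A", "BS_A_null"):
        p0, p1, w0 = params["p0"], params["p1"], params["omega0"]
        w2 = 1.0 if model == "BS_A_null" else params["omega2"]
        p01 = p0 + p1
        p2 = 1 - p01
        return [
            (p0, w0, w0),
            (p1, 1.0, 1.0),
            (p2 * p0 / p01, w0, w2),
            (p2 * p1 / p01, 1.0, w2),
        ]
    raise ValueError(f"unknown model {model}")


# parameter packing: rates on log scale, probabilities via logistic maps
def _pack(model, params):
    x = [np.log(params["kappa"])]
    if model == "M0":
        x.append(np.log(params["omega"]))
    elif model == "M1a":
        x += [_logit(params["p0"]), _logit(params["omega0"])]
    elif model == "M2a":
        x += list(_simplex_to_z(params["p0"], params["p1"]))
        x += [_logit(params["omega0"]), np.log(params["omega2"] - 1.0)]
    elif model == "BS_A":
        x += list(_simplex_to_z(params["p0"], params["p1"]))
        x += [_logit(params["omega0"]), np.log(max(params["omega2"] - 1.0, 1e-6))]
    elif model == "BS_A_null":
        x += list(_simplex_to_z(params["p0"], params["p1"]))
        x += [_logit(params["omega0"])]
    return np.array(x)


def _unpack(model, x):
    params = {"kappa": float(np.exp(np.clip(x[0], -5, 5)))}
    if model == "M0":
        params["omega"] = float(np.exp(np.clip(x[1], -12, 5)))
    elif model == "M1a":
        params["p0"] = _expit(x[1])
        params["omega0"] = _expit(x[2])
    elif model in ("M2a", "BS_A"):
        params["p0"], params["p1"] = _z_to_simplex(x[1], x[2])
        params["omega0"] = _expit(x[3])
        params["omega2"] = 1.0 + float(np.exp(np.clip(x[4], -12, 5)))
    elif model == "BS_A_null":
        params["p0"], params["p1"] = _z_to_simplex(x[1], x[2])
        params["omega0"] = _expit(x[3])
        params["omega2"] = 1.0
    return params


def _logit(p):
    p = min(max(p, 1e-6), 1 - 1e-6)
    return np.log(p / (1 - p))


def _expit(z):
    z = np.clip(z, -30, 30)
    return float(1.0 / (1.0 + np.exp(-z)))


def _simplex_to_z(p0, p1):
    p2 = max(1.0 - p0 - p1, 1e-6)
    return np.log(max(p0, 1e-6) / p2), np.log(max(p1, 1e-6) / p2)


def _z_to_simplex(z0, z1):
    e0, e1 = np.exp(np.clip(z0, -30, 30)), np.exp(np.clip(z1, -30, 30))
    denom = 1.0 + e0 + e1
    return float(e0 / denom), float(e1 / denom)


_START = {
    "M0": {"kappa": 2.0, "omega": 0.3},
    "M1a": {"kappa": 2.0, "p0": 0.7, "omega0": 0.2},
    "M2a": {"kappa": 2.0, "p0": 0.6, "p1": 0.3, "omega0": 0.2, "omega2": 2.5},
    "BS_A": {"kappa": 2.0, "p0": 0.6, "p1": 0.3, "omega0": 0.2, "omega2": 2.5},
    "BS_A_null": {"kappa": 2.0, "p0": 0.6, "p1": 0.3, "omega0": 0.2},
}


def fit_codon_model(
    aln: GeneAlignment,
    tree: PhyloTree,
    model: str = "M0",
    foreground: frozenset[str] | set[str] | None = None,
    fixed_lengths: np.ndarray | None = None,
    problem: _CodonProblem | None = None,
    start: dict | None = None,
    maxiter: int = 200,
) -> CodonFit:
    """ML fit of one codon model.

    M0 alternates parameter and branch-length optimisation; the mixture
    models keep branch lengths fixed (normally at the M0 estimates, the
    standard two-stage practice) and maximise over their own parameters.
    """
    if model not in _START:
        raise ValueError(f"unknown model {model}")
    if model in ("BS_A", "BS_A_null") and not foreground:
        raise ValueError("branch-site models need a foreground taxon set")
    problem = problem or _CodonProblem(aln, tree)
    fg_mask = problem.fg_mask(frozenset(foreground)) if foreground else None
    params = dict(_START[model])
    if start:
        params.update(start)

    lengths = (
        np.asarray(fixed_lengths, dtype=float).copy()
        if fixed_lengths is not None
        else problem.td.lengths.copy()
    )

    def make_engine(p):
        classes = _scaled_classes(
            problem, p["kappa"], _class_defs(model, p["kappa"], p), fg_mask
        )
        return problem.engine(classes)

    def neg_loglik(x):
        p = _unpack(model, x)
        try:
            return -make_engine(p).loglik(lengths)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    x0 = _pack(model, params)
    converged = True
    if model == "M0" and fixed_lengths is None:
        lnl_prev = -np.inf
        for _round in range(4):
            res = minimize(
                neg_loglik, x0, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-10},
            )
            x0 = res.x
            p = _unpack(model, x0)
            engine = make_engine(p)
            lengths, lnl, conv = engine.optimize_lengths(lengths, max_sweeps=15)
            converged = conv
            if lnl - lnl_prev < 1e-4 * max(1.0, abs(lnl)):
                break
            lnl_prev = lnl
        final = minimize(
            neg_loglik, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        x0, lnl = final.x, -final.fun
        converged = converged and (final.success or final.status == 1)
    else:
        res = minimize(
            neg_loglik, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        x0, lnl = res.x, -res.fun
        converged = bool(res.success or res.status == 1)
    p = _unpack(model, x0)
    if model in ("M2a", "BS_A", "BS_A_null"):
        p["p2"] = 1.0 - p["p0"] - p["p1"]
    return CodonFit(
        model=model,
        lnl=float(lnl),
        kappa=p["kappa"],
        params=p,
        lengths=lengths,
        freqs=problem.freqs,
        converged=converged,
        foreground=frozenset(foreground) if foreground else None,
    )


def fit_gene_branch_lengths(
    aln: GeneAlignment, tree: PhyloTree
) -> tuple[CodonFit, _CodonProblem]:
    """Stage-one M0 fit providing branch lengths for the mixture models."""
    problem = _CodonProblem(aln, tree)
    fit = fit_codon_model(aln, tree, "M0", problem=problem)
    return fit, problem


def branch_site_test(
    aln: GeneAlignment,
    species_tree: PhyloTree,
    foreground: frozenset[str] | set[str],
    m0: CodonFit | None = None,
    problem: _CodonProblem | None = None,
) -> tuple[LrtResult, CodonFit, CodonFit]:
    """Branch-site model A vs its omega2=1 null on the species tree.

    The foreground is the set of terminal branches of the focal taxa (they
    are not monophyletic on the species tree, so no stem branch exists).
    """
    if problem is None:
        m0, problem = fit_gene_branch_lengths(aln, species_tree)
    elif m0 is None:
        m0 = fit_codon_model(aln, species_tree, "M0", problem=problem)
    alt = fit_codon_model(
        aln, species_tree, "BS_A", foreground=foreground,
        fixed_lengths=m0.lengths, problem=problem,
        start={"kappa": m0.kappa, "omega0": min(m0.params["omega"], 0.9)},
    )
    null = fit_codon_model(
        aln, species_tree, "BS_A_null", foreground=foreground,
        fixed_lengths=m0.lengths, problem=problem,
        start={"kappa": m0.kappa, "omega0": min(m0.params["omega"], 0.9)},
    )
    if null.lnl > alt.lnl + 1e-6:
        # the null is nested in the alternative: refit from the null's optimum
        alt = fit_codon_model(
            aln, species_tree, "BS_A", foreground=foreground,
            fixed_lengths=m0.lengths, problem=problem,
            start={**null.params, "omega2": 1.0 + 1e-4},
        )
    return LrtResult.from_fits(alt, null, df=1), alt, null


def background_site_test(
    aln: GeneAlignment, tree_without_focal: PhyloTree
) -> tuple[LrtResult, CodonFit, CodonFit]:
    """M1a vs M2a screen on the focal-excluded tree (2 df, 5.99)."""
    keep = set(tree_without_focal.leaf_names())
    sub = aln.subset_taxa(keep)
    m0, problem = fit_gene_branch_lengths(sub, tree_without_focal)
    null = fit_codon_model(
        sub, tree_without_focal, "M1a",
        fixed_lengths=m0.lengths, problem=problem,
        start={"kappa": m0.kappa, "omega0": min(m0.params["omega"], 0.9)},
    )
    alt = fit_codon_model(
        sub, tree_without_focal, "M2a",
        fixed_lengths=m0.lengths, problem=problem,
        start={
            "kappa": m0.kappa,
            "p0": min(max(null.params["p0"], 0.05), 0.9),
            "p1": min(max(1 - null.params["p0"] - 0.05, 0.05), 0.9),
            "omega0": null.params["omega0"],
        },
    )
    if null.lnl > alt.lnl + 1e-6:
        alt = fit_codon_model(
            sub, tree_without_focal, "M2a",
            fixed_lengths=m0.lengths, problem=problem,
            start={
                "kappa": null.kappa,
                "p0": null.params["p0"] * (1 - 1e-3),
                "p1": (1 - null.params["p0"]) * (1 - 1e-3),
                "omega0": null.params["omega0"],
                "omega2": 1.0 + 1e-4,
            },
        )
    return LrtResult.from_fits(alt, null, df=2), alt, null


# ---------------------------------------------------------------------------
# Bayes empirical Bayes site posteriors
# ---------------------------------------------------------------------------

def beb_site_posteriors(
    fit: CodonFit,
    aln: GeneAlignment,
    tree: PhyloTree,
    grid: int = 10,
    problem: _CodonProblem | None = None,
) -> list[SiteSelectionPosterior]:
    """Posterior probability per codon site that omega > 1 on the foreground.

    Integrates the branch-site class posteriors over a uniform prior grid:
    omega0 on (0,1), omega2 on (1,11), (p0, p1) on the probability triangle
    (``grid`` points per dimension); kappa and branch lengths are fixed at
    their MLEs.
    """
    if fit.model != "BS_A":
        raise ValueError("BEB requires a branch-site model A fit")
    if not fit.converged:
        raise ValueError("refusing BEB on an unconverged fit")
    problem = problem or _CodonProblem(aln, tree)
    fg_mask = problem.fg_mask(fit.foreground)
    kappa = fit.kappa
    lengths = fit.lengths

    mids = (np.arange(grid) + 0.5) / grid
    w0_grid = mids                      # omega0 in (0, 1)
    w2_grid = 1.0 + 10.0 * mids         # omega2 in (1, 11)

    # per-site log-likelihoods for every distinct conditional site class
    def class_loglik(w_bg, w_fg):
        defs = [(1.0, w_bg, w_fg)]
        classes = _scaled_classes(problem, kappa, defs, fg_mask)
        engine = problem.engine(classes)
        return engine.class_site_logliks(lengths, classes[0])

    f0 = {w0: class_loglik(w0, w0) for w0 in w0_grid}          # class 0
    f1 = class_loglik(1.0, 1.0)                                # class 1
    f2a = {
        (w0, w2): class_loglik(w0, w2)
        for w0 in w0_grid
        for w2 in w2_grid
    }
    f2b = {w2: class_loglik(1.0, w2) for w2 in w2_grid}

    n_pat = len(problem.weights)
    post_pos = np.zeros(n_pat)
    log_marg = []
    contribs = []
    # triangle grid on (p0, p1): p0 = u, p1 = (1-u) v, Jacobian (1-u)
    for u in mids:
        for v in mids:
            p0, p1 = u, (1.0 - u) * v
            p01 = p0 + p1
            p2 = max(1.0 - p01, 1e-12)
            prior_w = (1.0 - u)  # Jacobian for uniformity on the triangle
            for w0 in w0_grid:
                for w2 in w2_grid:
                    mix = np.stack(
                        [f0[w0], f1, f2a[(w0, w2)], f2b[w2]]
                    )
                    wts = np.array(
                        [p0, p1, p2 * p0 / p01, p2 * p1 / p01]
                    )
                    mx = mix.max(axis=0)
                    site_lik = (wts[:, None] * np.exp(mix - mx)).sum(axis=0)
                    site_log = mx + np.log(np.maximum(site_lik, 1e-300))
                    pos_frac = (
                        wts[2] * np.exp(mix[2] - mx)
                        + wts[3] * np.exp(mix[3] - mx)
                    ) / np.maximum(site_lik, 1e-300)
                    data_loglik = float(site_log @ problem.weights)
                    log_marg.append(np.log(prior_w + 1e-300) + data_loglik)
                    contribs.append(pos_frac)
    log_marg = np.array(log_marg)
    wpost = np.exp(log_marg - log_marg.max())
    wpost /= wpost.sum()
    for w, frac in zip(wpost, contribs):
        post_pos += w * frac
    per_site = post_pos[problem.site_to_pattern]
    return [
        SiteSelectionPosterior(site=i, pp_positive=float(pp))
        for i, pp in enumerate(per_site)
    ]
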