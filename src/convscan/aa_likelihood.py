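"""Amino-acid likelihood engine for gene-specific log-likelihood support.

GSLS is the maximised log-likelihood of one gene's protein alignment under a
fixed tree topology, with branch lengths free.  The convergence statistic is

    dGSLS(H_n) = GSLS(H_0) - GSLS(H_n)

so strongly negative values mean the gene's signal fits the convergence
hypothesis H_n better than the species tree H_0.

The default model is WAG with observed (+F) frequencies and no rate
heterogeneity; all likelihood contrasts use the same model throughout, which
is what the dGSLS difference requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from . import aa_matrices
from .phylik import EigSystem, LikelihoodEngine, SiteClass, TreeData
from .treekit import PhyloTree

AA_ORDER = aa_matrices.AA_ORDER
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

_MODEL_DATA = {
    "WAG": (aa_matrices.WAG_LOWER_TRIANGLE, aa_matrices.WAG_FREQS),
    "LG": (aa_matrices.LG_LOWER_TRIANGLE, aa_matrices.LG_FREQS),
    "JTT": (aa_matrices.JTT_LOWER_TRIANGLE, aa_matrices.JTT_FREQS),
}


@dataclass(frozen=True)
class AAModelSpec:
    """Amino-acid substitution model settings.

    ``frequency_mode``: "model" uses the matrix's published frequencies,
    "observed" (+F) the alignment's residue frequencies.  ``gamma_categories``
    0 disables rate heterogeneity; k >= 2 uses the discrete-gamma (mean)
    approximation with shape ``gamma_shape``.
    """

    matrix_name: str = "WAG"
    frequency_mode: str = "observed"
    gamma_categories: int = 0
    gamma_shape: float | None = None

    def __post_init__(self):
        if self.matrix_name not in set(_MODEL_DATA) | {"POISSON"}:
            raise ValueError(f"unknown matrix {self.matrix_name}")
        if self.frequency_mode not in {"model", "observed"}:
            raise ValueError(f"unknown frequency mode {self.frequency_mode}")
        if self.gamma_categories == 1 or self.gamma_categories < 0:
            raise ValueError("gamma_categories must be 0 or >= 2")
        if self.gamma_categories and not self.gamma_shape:
            raise ValueError("gamma_shape required when gamma is on")


def exchangeabilities(matrix_name: str) -> np.ndarray:
    """Symmetric 20x20 exchangeability matrix (zero diagonal)."""
    S = np.zeros((20, 20))
    if matrix_name == "POISSON":
        S[:] = 1.0
        np.fill_diagonal(S, 0.0)
        return S
    lower, _ = _MODEL_DATA[matrix_name]
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = lower[k]
            k += 1
    return S


def model_frequencies(matrix_name: str) -> np.ndarray:
    if matrix_name == "POISSON":
        return np.full(20, 0.05)
    _, bf = _MODEL_DATA[matrix_name]
    f = np.asarray(bf, dtype=float)
    return f / f.sum()


def observed_frequencies(aa_seqs: dict[str, str]) -> np.ndarray:
    """+F frequencies with a small pseudocount so no residue has rate 0."""
    counts = np.full(20, 0.5)
    for seq in aa_seqs.values():
        for ch in seq:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def rate_matrix(model: AAModelSpec, freqs: np.ndarray) -> np.ndarray:
    """Reversible generator Q, normalised to 1 substitution per unit time."""
    S = exchangeabilities(model.matrix_name)
    Q = S * freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(20)] = -Q.sum(axis=1)
    mu = -(freqs * np.diag(Q)).sum()
    return Q / mu


def aa_transition_matrix(
    model: AAModelSpec, t: float, freqs: np.ndarray | None = None
) -> np.ndarray:
    """P(t) for the model; rows sum to 1, P(0) = I."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if freqs is None:
        freqs = model_frequencies(model.matrix_name)
    return EigSystem(rate_matrix(model, freqs), freqs).pmat(t)


def discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean rates of k equiprobable discrete-gamma categories (mean 1)."""
    edges = gamma_dist.ppf(np.arange(1, k) / k, shape, scale=1.0 / shape)
    # category means via the incomplete-gamma identity
    full = np.concatenate([[0.0], edges, [np.inf]])
    upper = gammainc(shape + 1, np.where(np.isinf(full[1:]), 1e12, full[1:]) * shape)
    lower = gammainc(shape + 1, full[:-1] * shape)
    rates = (upper - lower) * k
    return rates / rates.mean()


def _site_classes(
    model: AAModelSpec, freqs: np.ndarray
) -> list[SiteClass]:
    eig = EigSystem(rate_matrix(model, freqs), freqs)
    if not model.gamma_categories:
        return [SiteClass(weight=1.0, eig_bg=eig)]
    rates = discrete_gamma_rates(model.gamma_shape, model.gamma_categories)
    w = 1.0 / model.gamma_categories
    return [SiteClass(weight=w, eig_bg=eig, rate=r) for r in rates]


def build_engine(
    tree: PhyloTree,
    aa_seqs: dict[str, str],
    model: AAModelSpec,
    default_length: float = 0.1,
) -> LikelihoodEngine:
    leaf_names = set(tree.leaf_names())
    seqs = {t: s for t, s in aa_seqs.items() if t in leaf_names}
    missing = leaf_names - set(seqs)
    if missing:
        raise ValueError(f"alignment lacks taxa: {sorted(missing)}")
    freqs = (
        observed_frequencies(seqs)
        if model.frequency_mode == "observed"
        else model_frequencies(model.matrix_name)
    )
    mat = np.array(
        [[AA_INDEX.get(ch, -1) for ch in seqs[t]] for t in seqs], dtype=int
    )
    cols, weights = np.unique(mat, axis=1, return_counts=True)
    tip_states = {t: cols[i] for i, t in enumerate(seqs)}
    td = TreeData.from_tree(tree, default_length=default_length)
    return LikelihoodEngine(
        td, tip_states, weights.astype(float), _site_classes(model, freqs), 20
    )


def pruning_loglik(
    tree: PhyloTree, aa_seqs: dict[str, str], model: AAModelSpec
) -> float:
    """Log-likelihood at the tree's own branch lengths."""
    engine = build_engine(tree, aa_seqs, model)
    lnl = engine.loglik()
    if not np.isfinite(lnl):
        raise ArithmeticError("non-finite log-likelihood")
    return lnl


def optimize_branch_lengths(
    topology: PhyloTree,
    aa_seqs: dict[str, str],
    model: AAModelSpec,
    start: float = 0.1,
    max_sweeps: int = 30,
    tol: float = 1e-6,
):
    """ML branch lengths on a fixed topology; returns (tree, lnL, converged)."""
    engine = build_engine(topology, aa_seqs, model, default_length=start)
    lengths0 = np.full(engine.td.n_nodes, start)
    lengths0[engine.td.root] = 0.0
    lengths, lnl, converged = engine.optimize_lengths(
        lengths0, max_sweeps=max_sweeps, tol=tol
    )
    fitted = topology.copy()
    # node order in TreeData matches PhyloTree.nodes() preorder
    for node, ln in zip(fitted.nodes(), lengths):
        if node.parent is not None:
            node.length = float(ln)
    return fitted, lnl, converged


@dataclass
class GslsResult:
    """Per-gene, per-hypothesis log-likelihood supports and their contrast."""

    gene_id: str
    hypothesis: str
    gsls_h0: float
    gsls_hn: float
    converged: bool = True

    @property
    def delta_gsls(self) -> float:
        return self.gsls_h0 - self.gsls_hn


def gsls(
    tree: PhyloTree,
    aa_seqs: dict[str, str],
    model: AAModelSpec,
    max_sweeps: int = 30,
    tol: float = 1e-6,
) -> tuple[float, bool]:
    """Maximised log-likelihood of the alignment under a fixed topology."""
    _, lnl, converged = optimize_branch_lengths(
        tree, aa_seqs, model, max_sweeps=max_sweeps, tol=tol
    )
    return lnl, converged


def delta_gsls(
    gene_id: str,
    aa_seqs: dict[str, str],
    h0: PhyloTree,
    hn: PhyloTree,
    model: AAModelSpec | None = None,
    hypothesis: str | None = None,
    max_sweeps: int = 30,
) -> GslsResult:
    """Branch-length-optimised support contrast between H_0 and H_n."""
    model = model or AAModelSpec()
    l0, c0 = gsls(h0, aa_seqs, model, max_sweeps=max_sweeps)
    ln, cn = gsls(hn, aa_seqs, model, max_sweeps=max_sweeps)
    return GslsResult(
        gene_id,
        hypothesis or (hn.name or "H_n"),
        gsls_h0=l0,
        gsls_hn=ln,
        converged=c0 and cn,
    )
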