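"""Shared phylogenetic likelihood machinery.

Felsenstein pruning over compressed site patterns for time-reversible
substitution models on rooted binary trees, with:

* eigendecomposition-based transition matrices ``P(t) = A exp(Lambda t) B``
  computed once per rate matrix and reused across branches;
* site-class mixtures (rate categories, omega classes) including classes
  whose rate matrix differs between foreground and background branches;
* per-node likelihood rescaling for numerical stability;
* fast branch-length optimisation using the standard edge decomposition:
  with all other branches fixed, the log-likelihood along one branch is
  ``sum_s log sum_k c_k(s) exp(lambda_k t)``, which makes each univariate
  optimisation essentially free once inside/outside partials are known.

Both the amino-acid (20-state) and codon (61-state) engines are thin
wrappers over this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .treekit import PhyloTree

MIN_BRANCH = 1e-8
MAX_BRANCH = 50.0


class EigSystem:
    """Spectral form of a reversible rate matrix.

    For Q reversible w.r.t. pi, ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` is
    symmetric; its eigendecomposition gives
    ``P(t) = A @ diag(exp(lam * t)) @ B`` with real ``lam``.
    """

    __slots__ = ("pi", "lam", "A", "B", "n_states")

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        sq = np.sqrt(pi)
        S = (sq[:, None] * Q) / sq[None, :]
        S = 0.5 * (S + S.T)  # symmetrise away rounding noise
        lam, U = np.linalg.eigh(S)
        self.pi = pi
        self.lam = lam
        self.A = U / sq[:, None]
        self.B = U.T * sq[None, :]
        self.n_states = pi.size

    def pmat(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self.A * np.exp(self.lam * t)) @ self.B
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


@dataclass
class SiteClass:
    """One mixture component: weight, rate matrix, optional foreground one.

    ``fg_edges`` is a boolean mask over edges (indexed by child node id);
    edges in the mask use ``eig_fg``, all others ``eig_bg``.  ``rate``
    multiplies every branch length (gamma rate categories).
    """

    weight: float
    eig_bg: EigSystem
    eig_fg: EigSystem | None = None
    fg_edges: np.ndarray | None = None
    rate: float = 1.0

    def eig_for_edge(self, edge: int) -> EigSystem:
        if self.eig_fg is not None and self.fg_edges is not None and self.fg_edges[edge]:
            return self.eig_fg
        return self.eig_bg


@dataclass
class TreeData:
    """Indexed form of a rooted binary tree for vectorised pruning."""

    n_nodes: int
    root: int
    postorder: np.ndarray          # internal nodes only, children first
    children: np.ndarray           # (n_nodes, 2), -1 for leaves
    parent: np.ndarray             # -1 at root
    leaf_taxon: dict[int, str]     # node id -> taxon code
    lengths: np.ndarray            # branch length above each node (0 at root)

    @classmethod
    def from_tree(cls, tree: PhyloTree, default_length: float = 0.1) -> "TreeData":
        nodes = tree.nodes()
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        children = np.full((n, 2), -1, dtype=int)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        leaf_taxon: dict[int, str] = {}
        for node in nodes:
            i = index[id(node)]
            if node.children:
                if len(node.children) != 2:
                    raise ValueError("tree must be binary")
                children[i] = [index[id(c)] for c in node.children]
            else:
                leaf_taxon[i] = node.name
            if node.parent is not None:
                parent[i] = index[id(node.parent)]
                lengths[i] = (
                    node.length if node.length is not None else default_length
                )
        post = [index[id(x)] for x in tree.postorder() if x.children]
        return cls(
            n_nodes=n,
            root=index[id(tree.root)],
            postorder=np.array(post, dtype=int),
            children=children,
            parent=parent,
            leaf_taxon=leaf_taxon,
            lengths=lengths,
        )

    def edge_ids(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if i != self.root])


def compress_patterns(
    seqs: dict[str, str], encode: dict[str, int]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Column-compress an alignment; unknown symbols encode to -1.

    Returns (taxa order, state matrix (n_taxa, n_patterns), pattern weights).
    For codon data pass 3-mer "columns" pre-split by the caller.
    """
    taxa = list(seqs)
    mat = np.array(
        [[encode.get(ch, -1) for ch in seqs[t]] for t in taxa], dtype=int
    )
    cols, weights = np.unique(mat, axis=1, return_counts=True)
    return taxa, cols, weights.astype(float)


def leaf_partials(
    states: np.ndarray, n_states: int
) -> np.ndarray:
    """Indicator partials (n_taxa, n_states, n_patterns); -1 = missing."""
    n_taxa, n_pat = states.shape
    out = np.zeros((n_taxa, n_states, n_pat))
    for i in range(n_taxa):
        s = states[i]
        known = s >= 0
        out[i, s[known], np.nonzero(known)[0]] = 1.0
        out[i, :, ~known] = 1.0
    return out


class LikelihoodEngine:
    """Pruning likelihood for one alignment on one tree topology."""

    def __init__(
        self,
        td: TreeData,
        tip_states: dict[str, np.ndarray],
        weights: np.ndarray,
        classes: list[SiteClass],
        n_states: int,
    ):
        self.td = td
        self.weights = weights
        self.classes = classes
        self.n_states = n_states
        self.n_pat = len(weights)
        self.tips = {}
        for node, taxon in td.leaf_taxon.items():
            if taxon not in tip_states:
                raise ValueError(f"taxon {taxon} missing from alignment")
            s = tip_states[taxon]
            part = np.zeros((n_states, self.n_pat))
            known = s >= 0
            part[s[known], np.nonzero(known)[0]] = 1.0
            part[:, ~known] = 1.0
            self.tips[node] = part

    # -- core pruning -----------------------------------------------------
    def _below(self, lengths, cls: SiteClass):
        """Below partials with per-node cumulative log-scales."""
        td = self.td
        L = {}
        s = {}
        for node in td.postorder:
            part = np.ones((self.n_states, self.n_pat))
            acc = np.zeros(self.n_pat)
            for child in td.children[node]:
                child_part = (
                    self.tips[child] if child in self.tips else L[child]
                )
                eig = cls.eig_for_edge(child)
                part *= eig.pmat(lengths[child] * cls.rate) @ child_part
                acc += s.get(child, 0.0)
            mx = part.max(axis=0)
            mx[mx == 0] = 1.0
            part /= mx
            acc = acc + np.log(mx)
            L[node] = part
            s[node] = acc
        return L, s

    def class_site_logliks(self, lengths, cls: SiteClass) -> np.ndarray:
        if self.td.root in self.tips:  # degenerate single-leaf tree
            lik = cls.eig_bg.pi @ self.tips[self.td.root]
            return np.log(np.maximum(lik, 1e-300))
        L, s = self._below(lengths, cls)
        lik = cls.eig_bg.pi @ L[self.td.root]
        return np.log(np.maximum(lik, 1e-300)) + s[self.td.root]

    def site_logliks(self, lengths=None) -> np.ndarray:
        """Mixture per-pattern log-likelihoods."""
        if lengths is None:
            lengths = self.td.lengths
        per_class = np.array(
            [self.class_site_logliks(lengths, c) for c in self.classes]
        )
        w = np.array([c.weight for c in self.classes])
        mx = per_class.max(axis=0)
        return mx + np.log(
            np.maximum((w[:, None] * np.exp(per_class - mx)).sum(axis=0), 1e-300)
        )

    def loglik(self, lengths=None) -> float:
        return float(self.site_logliks(lengths) @ self.weights)

    # -- branch-length optimisation ---------------------------------------
    def _edge_coefficients(self, lengths):
        """Inside/outside decomposition for every edge and class.

        For edge e (above node v) in class c the site likelihood is
        ``exp(logscale) * sum_k u_k v_k exp(lam_k rate t)`` with u, v from
        the outside/inside partials; returns those spectra per (class, edge).
        """
        td = self.td
        out = []
        for cls in self.classes:
            L, sL = self._below(lengths, cls)
            # outside partials O_v: data outside subtree(v) as a function of
            # the state at parent(v); recursion O_v = Ahat_u * (P_w @ L_w)
            # with Ahat_root = pi and Ahat_u = P_u^T @ O_u otherwise
            Oout: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            coeffs: dict[int, list] = {}
            stack = [td.root]
            while stack:
                u = stack.pop()
                kids = td.children[u]
                if kids[0] == -1:
                    continue
                if u == td.root:
                    Ahat = np.tile(cls.eig_bg.pi[:, None], (1, self.n_pat))
                    sAhat = np.zeros(self.n_pat)
                else:
                    Ou, sOu = Oout[u]
                    eig_u = cls.eig_for_edge(u)
                    Ahat = eig_u.pmat(lengths[u] * cls.rate).T @ Ou
                    sAhat = sOu
                for v, w in (kids, kids[::-1]):
                    eig_w = cls.eig_for_edge(w)
                    part_w = self.tips[w] if w in self.tips else L[w]
                    Ov = Ahat * (eig_w.pmat(lengths[w] * cls.rate) @ part_w)
                    sOv = sAhat + sL.get(w, 0.0)
                    mx = Ov.max(axis=0)
                    mx[mx == 0] = 1.0
                    Ov = Ov / mx
                    sOv = sOv + np.log(mx)
                    Oout[v] = (Ov, sOv)
                    stack.append(v)
            for v in range(td.n_nodes):
                if v == td.root:
                    continue
                Ov, sOv = Oout[v]
                part_v = self.tips[v] if v in self.tips else L[v]
                eig = cls.eig_for_edge(v)
                u_spec = eig.A.T @ Ov        # (n_states, n_pat)
                v_spec = eig.B @ part_v
                coeffs[v] = [
                    (u_spec * v_spec, eig.lam * cls.rate, sOv + sL.get(v, 0.0))
                ]
            out.append(coeffs)
        return out

    def _optimize_edge(self, edge_coeffs, t0: float) -> float:
        """Maximise the one-branch log-likelihood by safeguarded Newton.

        The edge decomposition makes the site likelihood a positive sum of
        exponentials in t, so first and second derivatives are closed-form;
        Newton from the current length almost always converges in a few
        steps, with a golden-section fallback when it misbehaves.
        """
        w = np.array([c.weight for c in self.classes])
        scales = []
        for ci, (spec, lam, logscale) in enumerate(edge_coeffs):
            scales.append(logscale)
        # per-site numeric anchor so exp(logscale) stays in range
        anchor = np.max(np.stack(scales), axis=0) if scales else 0.0

        def derivatives(t):
            g = np.zeros(self.n_pat)
            g1 = np.zeros(self.n_pat)
            g2 = np.zeros(self.n_pat)
            for ci, (spec, lam, logscale) in enumerate(edge_coeffs):
                e = spec * np.exp(lam[:, None] * t)
                W = w[ci] * np.exp(logscale - anchor)
                g += W * e.sum(axis=0)
                g1 += W * (lam[:, None] * e).sum(axis=0)
                g2 += W * ((lam**2)[:, None] * e).sum(axis=0)
            g = np.maximum(g, 1e-300)
            r1 = g1 / g
            f = float((np.log(g) + anchor) @ self.weights)
            f1 = float(r1 @ self.weights)
            f2 = float((g2 / g - r1**2) @ self.weights)
            return f, f1, f2

        t = min(max(t0, MIN_BRANCH), MAX_BRANCH)
        f, f1, f2 = derivatives(t)
        best_t, best_f = t, f
        for _ in range(20):
            if abs(f1) < 1e-8 * max(1.0, abs(f)):
                break
            if f2 < 0:
                step = -f1 / f2
            else:  # wrong curvature: move along the gradient
                step = np.sign(f1) * max(0.1 * t, 1e-4)
            t_new = min(max(t + step, MIN_BRANCH), MAX_BRANCH)
            if t_new == t:
                break
            f_new, f1_new, f2_new = derivatives(t_new)
            if f_new < f - 1e-12:
                # backtrack halving until improvement or giving up
                ok = False
                for _half in range(8):
                    t_new = 0.5 * (t + t_new)
                    f_new, f1_new, f2_new = derivatives(t_new)
                    if f_new >= f:
                        ok = True
                        break
                if not ok:
                    break
            t, f, f1, f2 = t_new, f_new, f1_new, f2_new
            if f > best_f:
                best_t, best_f = t, f
        if best_f < f:
            best_t, best_f = t, f
        return best_t

    def _edge_loglik_fn(self, edge_coeffs):
        """Log-likelihood of the data as a function of one branch length."""
        w = np.array([c.weight for c in self.classes])

        def fn(t: float) -> float:
            per_class = []
            for (spec, lam, logscale) in edge_coeffs:
                f = (spec * np.exp(lam[:, None] * t)).sum(axis=0)
                per_class.append(np.log(np.maximum(f, 1e-300)) + logscale)
            per_class = np.array(per_class)
            mx = per_class.max(axis=0)
            site = mx + np.log(
                np.maximum(
                    (w[:, None] * np.exp(per_class - mx)).sum(axis=0), 1e-300
                )
            )
            return float(site @ self.weights)

        return fn

    def optimize_lengths(
        self,
        lengths0: np.ndarray | None = None,
        max_sweeps: int = 30,
        tol: float = 1e-6,
    ) -> tuple[np.ndarray, float, bool]:
        """Coordinate-wise branch-length maximisation.

        Each sweep refreshes inside/outside partials once and optimises
        every branch against them (a Jacobi-style sweep); sweeps repeat to
        convergence of the full log-likelihood.  Returns (lengths, lnL,
        converged).
        """
        td = self.td
        lengths = (
            td.lengths.copy() if lengths0 is None else np.asarray(lengths0, float).copy()
        )
        edges = td.edge_ids()
        best = self.loglik(lengths)
        best_lengths = lengths.copy()
        converged = False
        for _ in range(max_sweeps):
            all_coeffs = self._edge_coefficients(lengths)
            new_lengths = lengths.copy()
            for e in edges:
                per_edge = [all_coeffs[ci][e][0] for ci in range(len(self.classes))]
                new_lengths[e] = self._optimize_edge(per_edge, lengths[e])
            cur = self.loglik(new_lengths)
            if cur < best:
                # Jacobi sweep overshot: fall back to sequential refresh
                cur, new_lengths = self._safe_sweep(lengths)
            if cur > best:
                improvement = cur - best
                best, best_lengths, lengths = cur, new_lengths.copy(), new_lengths
                if improvement < tol * max(1.0, abs(best)):
                    converged = True
                    break
            else:
                converged = True
                break
        return best_lengths, best, converged

    def _safe_sweep(self, lengths):
        """One monotone sweep: refresh partials before every edge."""
        lengths = lengths.copy()
        for e in self.td.edge_ids():
            all_coeffs = self._edge_coefficients(lengths)
            per_edge = [all_coeffs[ci][e][0] for ci in range(len(self.classes))]
            fn = self._edge_loglik_fn(per_edge)
            res = minimize_scalar(
                lambda t: -fn(t),
                bounds=(MIN_BRANCH, MAX_BRANCH),
                method="bounded",
                options={"xatol": 1e-7},
            )
            if fn(res.x) > fn(lengths[e]):
                lengths[e] = res.x
        return self.loglik(lengths), lengths
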