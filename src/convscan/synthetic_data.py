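"""Seeded simulator of 16-taxon codon alignments with known truth.

Genes evolve along the species tree (or a convergence-hypothesis topology)
under GY94-family codon models:

* NEUTRAL — single omega < 1 everywhere (M0);
* SELECTED — branch-site structure: a fraction of sites switches to
  omega2 > 1 on the focal (foreground) terminal branches;
* CONVERGENT — simulated on the hypothesis topology (topology-level
  convergence), optionally with shared derived residues injected at chosen
  sites in the focal taxa (site-level convergence);
* CONVERGENT_SELECTED — hypothesis topology plus foreground selection.

Evolution uses exact transition probabilities of the 61-state chain, so no
stop codons ever arise and alignments are born clean.  Everything is
deterministic under the configured seed.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import codon_selection as cs
from .phylik import EigSystem, TreeData
from .seqdata import GeneAlignment
from .treekit import HYPOTHESES, PhyloTree, parse_newick

GENE_CLASSES = ("NEUTRAL", "SELECTED", "CONVERGENT", "CONVERGENT_SELECTED")

#: Fig.-1-style species topology for the 16-taxon panel.
SPECIES_TREE_NEWICK = (
    "(STRCA,(GALGA,((PHORU,PODCR),((CALAN,CAPCA),((GAVST,(PHACA,EGRGA)),"
    "(((CATAU,(HALAL,HALLE)),(TYTAL,PICPU)),(FALPE,TAEGU)))))));"
)


def fixture_species_tree(
    internal_length: float = 0.05, terminal_length: float = 0.1
) -> PhyloTree:
    """The packaged 16-taxon species tree with default branch lengths."""
    try:
        text = (
            importlib.resources.files("convscan")
            .joinpath("data/species_tree_16.nwk")
            .read_text()
        )
    except FileNotFoundError:
        text = SPECIES_TREE_NEWICK
    tree = parse_newick(text, name="H_0")
    for node in tree.nodes():
        if node.parent is None:
            continue
        node.length = terminal_length if node.is_leaf else internal_length
    return tree


@dataclass
class SimulationConfig:
    """Study-level simulation settings.

    ``class_mix`` maps gene classes to proportions (summing to 1);
    ``length_range`` is in codons.  ``omega_neutral`` is the background
    purifying ratio; SELECTED genes add a fraction ``p_selected`` of sites
    with foreground ratio ``omega2`` on the focal terminals.  Site-level
    convergence injects ``n_inject`` shared derived residues.
    """

    tree: PhyloTree = field(default_factory=fixture_species_tree)
    n_genes: int = 50
    length_range: tuple[int, int] = (100, 500)
    kappa: float = 2.0
    codon_freqs: np.ndarray | None = None
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"NEUTRAL": 1.0}
    )
    hypothesis: str = "H_noc"
    omega_neutral: float = 0.2
    omega2: float = 4.0
    p_selected: float = 0.1
    n_inject: int = 0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class mix proportions must sum to 1")
        unknown = set(self.class_mix) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis}")


@dataclass
class TruthLabels:
    gene_id: str
    gene_class: str
    length: int
    injected_sites: tuple[int, ...]
    params: dict


def _gene_seed(seed: int, index: int) -> int:
    digest = hashlib.sha256(f"{seed}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _default_freqs() -> np.ndarray:
    # mildly uneven frequencies, F3x4-like rather than flat
    rng = np.random.default_rng(20201107)
    pos = rng.dirichlet(np.full(4, 20.0), size=3)
    freqs = np.array(
        [
            pos[0][cs.NT_INDEX[c[0]]]
            * pos[1][cs.NT_INDEX[c[1]]]
            * pos[2][cs.NT_INDEX[c[2]]]
            for c in cs.CODONS
        ]
    )
    return freqs / freqs.sum()


def _simulate_states(
    td: TreeData,
    eigs_per_class: list[tuple[EigSystem, EigSystem | None]],
    site_class: np.ndarray,
    fg_mask: np.ndarray,
    freqs: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve codon states site-by-site down the tree, vectorised per branch."""
    n_sites = site_class.size
    root_states = rng.choice(len(cs.CODONS), size=n_sites, p=freqs)
    states = {td.root: root_states}
    pending = [td.root]  # preorder: parent states always known
    while pending:
        node = pending.pop()
        for child in td.children[node]:
            if child == -1:
                continue
            t = td.lengths[child]
            child_states = np.empty(n_sites, dtype=int)
            for ci, (eig_bg, eig_fg) in enumerate(eigs_per_class):
                sites = np.nonzero(site_class == ci)[0]
                if sites.size == 0:
                    continue
                eig = (
                    eig_fg
                    if (eig_fg is not None and fg_mask[child])
                    else eig_bg
                )
                P = eig.pmat(t)
                cum = np.cumsum(P, axis=1)
                u = rng.random(sites.size)
                rows = cum[states[node][sites]]
                child_states[sites] = (u[:, None] < rows).argmax(axis=1)
            states[child] = child_states
            pending.append(child)
    return {
        taxon: states[node] for node, taxon in td.leaf_taxon.items()
    }


def simulate_gene(
    config: SimulationConfig, index: int, gene_class: str | None = None
) -> tuple[GeneAlignment, TruthLabels]:
    """Simulate one gene; fully determined by (config.seed, index)."""
    rng = np.random.default_rng(_gene_seed(config.seed, index))
    if gene_class is None:
        classes = sorted(config.class_mix)
        probs = np.array([config.class_mix[c] for c in classes])
        gene_class = classes[rng.choice(len(classes), p=probs)]
    lo, hi = config.length_range
    length = int(rng.integers(lo, hi + 1))
    freqs = (
        config.codon_freqs
        if config.codon_freqs is not None
        else _default_freqs()
    )
    hyp = HYPOTHESES[config.hypothesis]
    focal = set(hyp.focal_taxa)

    if gene_class in ("CONVERGENT", "CONVERGENT_SELECTED"):
        topo = hyp.constrained_tree(config.tree)
        # topology-only output: restore the study's default branch lengths
        for node in topo.nodes():
            if node.parent is not None:
                node.length = 0.1 if node.is_leaf else 0.05
        tree = topo
    else:
        tree = config.tree
    td = TreeData.from_tree(tree)
    fg_mask = np.zeros(td.n_nodes, dtype=bool)
    for node, taxon in td.leaf_taxon.items():
        if taxon in focal:
            fg_mask[node] = True

    def eig(omega):
        Q = cs.codon_generator(config.kappa, omega, freqs)
        Q = Q / cs.mean_rate(
            cs.codon_generator(config.kappa, config.omega_neutral, freqs),
            freqs,
        )
        return EigSystem(Q, freqs)

    selected = gene_class in ("SELECTED", "CONVERGENT_SELECTED")
    if selected:
        site_class = (rng.random(length) < config.p_selected).astype(int)
        eigs = [(eig(config.omega_neutral), None), (eig(config.omega_neutral), eig(config.omega2))]
    else:
        site_class = np.zeros(length, dtype=int)
        eigs = [(eig(config.omega_neutral), None)]

    leaf_states = _simulate_states(td, eigs, site_class, fg_mask, freqs, rng)

    injected: list[int] = []
    if config.n_inject and gene_class in ("CONVERGENT", "CONVERGENT_SELECTED"):
        injected = _inject_convergent_sites(
            leaf_states, focal, length, config.n_inject, rng
        )

    seqs = {
        taxon: "".join(cs.CODONS[s] for s in leaf_states[taxon])
        for taxon in sorted(leaf_states, key=list(config.tree.leaf_names()).index)
    }
    aln = GeneAlignment(
        f"gene{index:04d}",
        tuple(config.tree.leaf_names()),
        {t: seqs[t] for t in config.tree.leaf_names()},
        cleaned=True,
    )
    truth = TruthLabels(
        gene_id=aln.gene_id,
        gene_class=gene_class,
        length=length,
        injected_sites=tuple(injected),
        params={
            "kappa": config.kappa,
            "omega_neutral": config.omega_neutral,
            "omega2": config.omega2 if selected else None,
            "hypothesis": config.hypothesis,
        },
    )
    return aln, truth


def _inject_convergent_sites(leaf_states, focal, length, n_inject, rng):
    """Overwrite focal codons with a shared residue absent elsewhere.

    The residue is the alphabetically first amino acid missing from the
    non-focal taxa at the site; its lexicographically first codon is used,
    making the injection deterministic given the site choice.
    """
    aa_of = np.array([cs.CODON_AA[i] for i in range(len(cs.CODONS))])
    non_focal = [t for t in leaf_states if t not in focal]
    candidates = rng.permutation(length)
    injected = []
    attempts = 0
    for site in candidates:
        if len(injected) == n_inject:
            break
        attempts += 1
        present = {aa_of[leaf_states[t][site]] for t in non_focal}
        free = sorted(set("ACDEFGHIKLMNPQRSTVWY") - present)
        if not free:
            if attempts > 100 + n_inject:
                raise RuntimeError("no injectable site found in 100 attempts")
            continue
        residue = free[0]
        codon_idx = min(
            i for i in range(len(cs.CODONS)) if cs.CODON_AA[i] == residue
        )
        for taxon in focal:
            leaf_states[taxon][site] = codon_idx
        injected.append(int(site))
    if len(injected) < n_inject:
        raise RuntimeError("could not inject the requested number of sites")
    return sorted(injected)


def simulate_study(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[GeneAlignment], list[TruthLabels]]:
    """Simulate a whole gene set; optionally write FASTA files + truth TSV."""
    alignments, truths = [], []
    for i in range(config.n_genes):
        aln, truth = simulate_gene(config, i)
        alignments.append(aln)
        truths.append(truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for aln in alignments:
            aln.write_fasta(out_dir / f"{aln.gene_id}.fasta")
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("gene_id\tclass\tlength\tinjected_sites\thypothesis\n")
            for tr in truths:
                sites = ",".join(map(str, tr.injected_sites)) or "-"
                fh.write(
                    f"{tr.gene_id}\t{tr.gene_class}\t{tr.length}\t{sites}\t"
                    f"{tr.params['hypothesis']}\n"
                )
    return alignments, truths
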