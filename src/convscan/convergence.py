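"""Core inference: null calibration of dGSLS and the two-step ACG caller.

Step one compares each gene's dGSLS for a convergence hypothesis with a
null distribution of dGSLS values computed over branch-moved topologies
(all one-move topologies, or a seeded sample of two-move topologies for the
three-lineage hypothesis).  A gene is sequence-convergent when its empirical
dGSLS lies strictly below the null's 5th percentile (direct for the
enumerated one-move null; the mean of 1000 bootstrap 5th percentiles for
the sampled two-move null).

Step two requires a significant branch-site positive-selection signal on
the focal terminal branches, and discards genes whose focal-excluded
background also shows a site-model signal.  Survivors are adaptively
convergent genes (ACGs).

Below the gene level, ACGs are scanned for adaptively convergent site
mutations (ACSMs: BEB-flagged sites whose residue is shared by all focal
taxa and absent elsewhere), and compared against the expected number of
neutrally convergent multiple-substitution sites
M = (D - P)/20 * L (two lineages) or ((D - P)/20)^2 * L (three lineages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .aa_likelihood import AAModelSpec, gsls
from .codon_selection import LrtResult, SiteSelectionPosterior
from .seqdata import GeneAlignment
from .stats import bh_adjust
from .treekit import (
    HYPOTHESES,
    ConvergenceHypothesis,
    PhyloTree,
    TopologySet,
    one_move_neighbors,
    sample_topologies,
    tree_from_key,
    two_move_neighbors,
)


def percentile_5(values) -> float:
    """5th percentile by linear interpolation between order statistics."""
    return float(np.percentile(np.asarray(values, float), 5.0, method="linear"))


@dataclass
class NullDistribution:
    """Simulated dGSLS null for one gene and move order, with threshold."""

    gene_id: str
    move_order: int
    values: np.ndarray
    threshold: float
    bootstrap_reps: int = 0
    seed: int | None = None
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def __post_init__(self):
        if not np.isfinite(self.threshold):
            raise ValueError("non-finite threshold")


def bootstrap_threshold(
    values, B: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Mean of B bootstrap 5th percentiles, with the bootstrap 95% CI.

    Resamples with replacement at the original sample size; the returned
    threshold is the mean of the B resample percentiles and the CI is the
    (2.5, 97.5) percentile interval of those B values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 20:
        raise ValueError("need at least 20 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    boots = np.percentile(values[idx], 5.0, axis=1, method="linear")
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(boots.mean()), (float(lo), float(hi))


def null_distribution(
    gene: GeneAlignment,
    species_tree: PhyloTree,
    move_order: int,
    model: AAModelSpec | None = None,
    n_sample: int = 1000,
    seed: int = 0,
    bootstrap_reps: int = 1000,
    topology_set: TopologySet | None = None,
    gsls_h0: float | None = None,
    max_sweeps: int = 30,
) -> NullDistribution:
    """dGSLS null for one gene over the branch-moved topology set.

    For move order 1 the set is enumerated exhaustively and the threshold is
    the direct 5th percentile; for order 2 a seeded sample of ``n_sample``
    topologies is scored and the threshold is the bootstrap estimate.
    ``topology_set`` lets callers reuse a precomputed (possibly reduced)
    set; ``gsls_h0`` a precomputed species-tree support.
    """
    if move_order not in (1, 2):
        raise ValueError("move_order must be 1 or 2")
    model = model or AAModelSpec()
    if topology_set is None:
        one = one_move_neighbors(species_tree)
        if move_order == 1:
            topology_set = one
        else:
            topology_set = sample_topologies(
                two_move_neighbors(species_tree, one), n_sample, seed
            )
    aa = gene.aa_seqs
    if gsls_h0 is None:
        gsls_h0, _ = gsls(species_tree, aa, model, max_sweeps=max_sweeps)
    values = np.empty(len(topology_set.keys))
    for i, key in enumerate(topology_set.keys):
        lnl, _ = gsls(tree_from_key(key), aa, model, max_sweeps=max_sweeps)
        values[i] = gsls_h0 - lnl
    if move_order == 1:
        threshold = percentile_5(values)
        ci = (float("nan"), float("nan"))
        reps = 0
    else:
        threshold, ci = bootstrap_threshold(
            values, B=bootstrap_reps, seed=seed
        )
        reps = bootstrap_reps
    return NullDistribution(
        gene_id=gene.gene_id,
        move_order=move_order,
        values=values,
        threshold=threshold,
        bootstrap_reps=reps,
        seed=seed,
        ci_low=ci[0],
        ci_high=ci[1],
    )


@dataclass
class ConvergenceCall:
    """Final two-step verdict for one gene under one hypothesis."""

    gene_id: str
    hypothesis: str
    delta_gsls: float
    threshold: float
    sequence_convergent: bool
    foreground_selected: bool
    background_selected: bool

    @property
    def excluded_both_models(self) -> bool:
        return self.foreground_selected and self.background_selected

    @property
    def is_acg(self) -> bool:
        return (
            self.sequence_convergent
            and self.foreground_selected
            and not self.excluded_both_models
        )

    @property
    def neutrally_convergent(self) -> bool:
        """Sequence-convergent but not adaptively so."""
        return self.sequence_convergent and not self.is_acg


def call_acg(
    gene_id: str,
    hypothesis: str,
    delta: float,
    null: NullDistribution,
    foreground_lrt: LrtResult | None,
    background_lrt: LrtResult | None,
) -> ConvergenceCall:
    """Two-step call; sequence convergence requires dGSLS strictly below
    the threshold (ties are not significant)."""
    if null.gene_id != gene_id:
        raise ValueError(
            f"null distribution for {null.gene_id}, gene is {gene_id}"
        )
    seq_conv = delta < null.threshold
    fg = bool(foreground_lrt.significant) if foreground_lrt else False
    bg = bool(background_lrt.significant) if background_lrt else False
    return ConvergenceCall(
        gene_id=gene_id,
        hypothesis=hypothesis,
        delta_gsls=delta,
        threshold=null.threshold,
        sequence_convergent=seq_conv,
        foreground_selected=fg,
        background_selected=bg,
    )


@dataclass
class DerivedHypothesisTest:
    gene_id: str
    hypothesis: str
    X: float         # percentile rank of dGSLS in the one-move null, 0-100
    X_adj: float     # BH-adjusted within the gene across the derived set

    @property
    def significant(self) -> bool:
        return self.X_adj < 5.0


DERIVED_SETS = {
    "H_foot": ("H_foot_a", "H_foot_b", "H_foot_c"),
    "H_rap": ("H_rap_a", "H_rap_b"),
}


def percentile_rank(value: float, null_values) -> float:
    """Percent of null values <= the empirical value."""
    null_values = np.asarray(null_values, float)
    return float(100.0 * (null_values <= value).mean())


def derived_hypothesis_tests(
    gene_id: str,
    deltas: dict[str, float],
    null_values,
) -> list[DerivedHypothesisTest]:
    """Percentile ranks in the one-move null, BH-adjusted within the gene.

    ``deltas`` maps each derived hypothesis of ONE convergence case to the
    gene's empirical dGSLS; all share the same one-move null values.
    """
    null_values = np.asarray(null_values, float)
    if null_values.size == 0:
        raise ValueError("empty null distribution")
    names = list(deltas)
    X = [percentile_rank(deltas[h], null_values) for h in names]
    X_adj = bh_adjust(X)
    return [
        DerivedHypothesisTest(gene_id, h, x, xa)
        for h, x, xa in zip(names, X, X_adj)
    ]


@dataclass
class AcsmCall:
    """An adaptively convergent site mutation."""

    gene_id: str
    hypothesis: str
    site: int          # codon/residue index, 0-based
    residue: str
    pp_positive: float


def find_acsm(
    gene: GeneAlignment,
    hypothesis: ConvergenceHypothesis | str,
    beb: list[SiteSelectionPosterior],
) -> list[AcsmCall]:
    """Sites with BEB pp > 0.95 whose residue is identical in every focal
    taxon and absent from every non-focal taxon (gap-free columns only)."""
    hyp = HYPOTHESES[hypothesis] if isinstance(hypothesis, str) else hypothesis
    aa = gene.aa_seqs
    focal = sorted(hyp.focal_taxa)
    others = [t for t in gene.taxa if t not in hyp.focal_taxa]
    out = []
    for post in beb:
        if not post.flagged:
            continue
        s = post.site
        residues = {aa[t][s] for t in focal}
        if len(residues) != 1:
            continue
        (residue,) = residues
        if residue == "-" or any(aa[t][s] == "-" for t in others):
            continue
        if any(aa[t][s] == residue for t in others):
            continue
        out.append(
            AcsmCall(
                gene_id=gene.gene_id,
                hypothesis=hyp.name,
                site=s,
                residue=residue,
                pp_positive=post.pp_positive,
            )
        )
    return out


def pairwise_distances(
    gene: GeneAlignment, taxa: list[str]
) -> tuple[float, float]:
    """Mean pairwise Poisson-correction (D) and p (P) amino-acid distances.

    Pairwise deletion: positions where either sequence has a non-residue
    symbol are skipped for that pair.  Distances are means over all pairs of
    the given (non-convergent) taxa.
    """
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    aa = gene.aa_seqs
    ps, ds = [], []
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            s1, s2 = aa[t1], aa[t2]
            pairs = [
                (a, b)
                for a, b in zip(s1, s2)
                if a.isalpha() and b.isalpha()
            ]
            if not pairs:
                raise ValueError(f"no comparable sites for {t1}/{t2}")
            p = sum(a != b for a, b in pairs) / len(pairs)
            if p >= 1.0:
                raise ValueError(
                    f"p-distance {p} for {t1}/{t2}: Poisson correction undefined"
                )
            ps.append(p)
            ds.append(-math.log(1.0 - p))
    return float(np.mean(ds)), float(np.mean(ps))


@dataclass
class NeutralExpectation:
    """Expected neutrally convergent multiple-substitution sites for a gene."""

    gene_id: str
    hypothesis: str
    D: float
    P: float
    L: int
    M: float


def neutral_expectation(
    gene: GeneAlignment,
    hypothesis: ConvergenceHypothesis | str,
    D: float | None = None,
    P: float | None = None,
) -> NeutralExpectation:
    """M = (D-P)/20 * L for two focal lineages, ((D-P)/20)^2 * L for three.

    D and P are computed between the non-focal taxa (the whole panel minus
    the hypothesis' focal set) unless supplied.
    """
    hyp = HYPOTHESES[hypothesis] if isinstance(hypothesis, str) else hypothesis
    if D is None or P is None:
        others = [t for t in gene.taxa if t not in hyp.focal_taxa]
        D, P = pairwise_distances(gene, others)
    if D < P:
        raise ValueError("D < P violates the multiple-hit construction")
    per_site = (D - P) / 20.0
    # three independently moved lineages only for the three-taxon diving case
    exponent = 2 if hyp.name == "H_foot" else 1
    M = (per_site**exponent) * gene.L
    return NeutralExpectation(gene.gene_id, hyp.name, D, P, gene.L, float(M))
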