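# Methods

`convscan` implements a two-step scan for adaptively convergent genes
(ACGs) across phenotypically convergent avian lineages, together with the
downstream constraint analyses that interpret the calls, and a seeded
simulator that generates study data with known truth.  This note records
the models, the tunable parameters and their defaults, the numerical
choices, and the places where the design was genuinely open.

## The two-step model

**Step one — sequence convergence.**  For each gene the protein alignment
is scored under a fixed tree topology by maximising the phylogenetic
log-likelihood over branch lengths; this maximised value is the
gene-specific log-likelihood support, GSLS(T).  The convergence statistic
for hypothesis H_n is

    dGSLS(H_n) = GSLS(H_0) − GSLS(H_n),

where H_0 is the species tree and H_n forces the focal taxa into a
monophyletic clade.  Strongly negative values mean the gene's signal fits
the convergence topology better.  Significance is calibrated per gene
against a null distribution of dGSLS values computed over branch-moved
topologies (below); a gene is *sequence-convergent* when its empirical
dGSLS falls strictly below the null's 5th percentile.  Ties are not
significant.

**Step two — adaptive signal.**  Sequence-convergent genes are tested for
positive selection with codon models: branch-site model A against its
ω2 = 1 null on the species tree (foreground = the focal taxa's terminal
branches; χ², 1 df, threshold 3.84), and, for genes passing that test, an
M1a-vs-M2a site-model screen on the tree with the focal taxa pruned
(2 df, threshold 5.99).  A gene significant in both the foreground and the
background screen is discarded; the survivors are ACGs.  Sequence-
convergent genes that are not ACGs are "neutrally sequence-convergent" and
serve as the baseline in overlap comparisons.

## Convergence hypotheses

Eight hypotheses are built by forcing focal sets monophyletic on the
16-taxon species tree (nocturnal: TYTAL+CAPCA; foot-propelled diving:
GAVST+PHACA+PODCR; raptorial: FALPE+CATAU+HALAL+HALLE; plus the five
derived pairings used in the constraint analyses).  The constrained tree
is built by anchoring on the focal lineage most distant (in node depth)
from the basal ostrich split and regrafting the other focal lineages onto
its branch, which keeps the forced clade away from the root and preserves
all non-focal relationships.  Constrained trees are topology-only; branch
lengths are always re-optimised per gene, because a constrained topology
has no meaningful inherited lengths.

## Branch-moved null topology sets

A single branch move is a rooted subtree-prune-and-regraft: any non-root
branch is detached, the vacated node suppressed, and the subtree regrafted
onto any remaining branch or above the root.  Topologies are deduplicated
by a canonical key (sorted child order, lengths ignored).  The one-move
set of the species tree (650 topologies) is the null for the two-lineage
hypotheses; it is enumerated exhaustively and the threshold is the direct
5th percentile (linear interpolation between order statistics, position
1 + 0.05(n−1)).

The two-move set contains every topology in which two disjoint pruned
lineages are rebuilt, together with an anchor lineage of the remaining
tree, into a single three-lineage clade (any of the three rooted shapes,
at any anchor position), excluding the source topology and the one-move
set — i.e. restricted monophylies of three lineages at branch-move
distance exactly two (17,380 topologies).  A free second prune-and-regraft
was considered and rejected: it produces a 174k-topology shell dominated
by tree pairs that no longer describe a single forced monophyly, which is
not what the three-lineage diving hypothesis distorts.  Because scoring
the full two-move set per gene is wasteful, a seeded uniform sample of
1000 topologies is scored and the threshold is estimated by bootstrap:
resample the 1000 dGSLS values with replacement 1000 times, take each
resample's 5th percentile, and use the mean; the (2.5, 97.5) percentile
interval of the bootstrap values gives a 95% CI.  Applying the same
bootstrap to the fully enumerated one-move null shows the estimator sits
well within 5% of the value range of the direct percentile, with the
direct value covered by the CI (this validation is an acceptance test).

Every hypothesis tree is a member of the null set of its own move order,
which is the property that makes the percentile calibration meaningful.

## Likelihood engines

Both engines share one pruning core: Felsenstein's algorithm over
column-compressed site patterns, per-node rescaling for stability, and
transition matrices from the spectral form of the reversible generator
(P(t) = A·exp(Λt)·B computed once per rate matrix).  Branch lengths are
maximised coordinate-wise: each sweep refreshes inside/outside partials
once, and each branch is then optimised by safeguarded Newton on the
closed-form one-branch likelihood Σ_s log Σ_k c_k(s)·exp(λ_k t).  Sweeps
repeat until the full log-likelihood improves by less than a relative
1e−6 (30-sweep cap; non-convergence is flagged, never silently dropped).
Branch lengths start at 0.1; bounds are [1e−8, 50].  Optimisation of the
two root-child branches is redundant under reversibility (only their sum
is identifiable); both are still optimised, and tests compare their sum.

**Amino-acid model.**  Default WAG with observed (+F) frequencies
(0.5 pseudocount per residue) and no rate heterogeneity; POISSON, LG and
JTT, model frequencies, and discrete-gamma rates (mean-category method)
are configurable.  The published engine settings for the GSLS step are
unknown; what matters for dGSLS is that every topology for a gene is
scored under the same model, which the implementation guarantees.  The
discrete-gamma approximation converges to the homogeneous model as the
shape grows like 1/√shape (category spread), so exact agreement is only
reached around shape 1e8.

**Codon models.**  GY94-style over the 61 sense codons (universal code),
F3x4 frequencies with a 0.1 pseudocount per positional nucleotide count,
transition/transversion ratio κ and dN/dS ratio ω; generators are scaled
so one unit of branch length is one expected substitution per codon site
under the ω-mixture on the background.  M0 alternates L-BFGS over
(log κ, log ω) with branch-length sweeps; the mixture models (M1a, M2a,
branch-site A and its null) keep branch lengths fixed at the M0 estimates
(standard two-stage practice) and maximise their own parameters on
transformed scales (log for rates, logistic/additive-logistic for
proportions and ω0, 1 + exp for ω2 ≥ 1).  Nested fits that land below
their null are restarted from the null's optimum; the LRT statistic is
clamped at zero and the clamp recorded.

**BEB site posteriors.**  Site-wise evidence of foreground positive
selection integrates the branch-site class posteriors over a uniform
prior grid: ω0 midpoints on (0,1), ω2 midpoints on (1,11), and (p0, p1)
on the probability triangle via a 10×10 product grid with the triangle
Jacobian as prior weight; κ and branch lengths are plugged in at their
MLEs.  Sites with posterior P(ω > 1) > 0.95 are flagged.  The grid
resolution is configurable; 10 points per dimension is the default.

## Sites, distances and the neutral expectation

An adaptively convergent site mutation (ACSM) is a flagged site whose
residue is identical in all focal taxa and absent from every non-focal
taxon (columns with any gap are ineligible).  The neutral expectation of
convergent multiple-substitution sites per gene is M = (D − P)/20 · L for
two-lineage hypotheses and ((D − P)/20)² · L for the three-lineage diving
hypothesis, where P is the mean pairwise amino-acid p-distance, D the mean
pairwise Poisson-correction distance −ln(1 − p), and L the locus length in
codons.  D and P are computed with pairwise deletion between the non-focal
taxa — here taken to be the whole panel minus the focal set, outgroups
included, since the analysis only requires taxa free of the focal
adaptation.

Derived hypotheses are scored by the percentile rank X of the gene's
dGSLS within the one-move null (percent of null values at or below it),
Benjamini-Hochberg-adjusted within the gene across the derived hypotheses
of the same convergence case (the grouping that matches "multiple derived
hypotheses about one phenotype"; across-gene adjustment is available via
`stats.bh_adjust` on any collection).  Significance requires adjusted
X < 5.  Overlap between two hypotheses' gene sets uses union-based 2×2
tables — (overlap, union minus overlap) for ACGs and for neutrally
sequence-convergent genes — tested with the two-sided Fisher's exact test
under the minimum-likelihood tail rule, which reproduces the published
raptorial overlap p = 0.7055 exactly; chi-square goodness of fit (no
continuity correction) compares ACG counts between pairs.

## Synthetic data

The generator evolves codon states down the species tree by exact
transition probabilities of the 61-state chain, so alignments are born
clean (no stops, gaps or ambiguity).  Defaults: branch lengths 0.05
(internal) / 0.1 (terminal) on the fixed 16-taxon topology, κ = 2,
background ω = 0.2, F3x4-like frequencies from a fixed Dirichlet draw,
gene lengths uniform on 100-500 codons.  SELECTED genes give a fraction
p2 = 0.1 of sites foreground ω2 = 4 on the focal terminals (branch-site
structure).  CONVERGENT genes are simulated on the hypothesis topology
(topology-level convergence); site-level convergence additionally
overwrites chosen sites in the focal taxa with the alphabetically first
residue absent elsewhere, encoded by its lexicographically first codon —
fully deterministic given the seed.  Per-gene seeds derive from the study
seed and gene index by hashing, so results do not depend on scheduling.

What the simulator does not emulate: indels and alignment error, among-
gene rate variation beyond length, non-stationary composition,
recombination/ILS-style gene-tree discordance, and genome-scale gene
counts.  Passing calibration tests therefore demonstrates correct
behaviour of the inference machinery under the generating model, not
robustness to real-data artefacts.

## Study sizes used by the checks

Single CPU sizes, chosen once: branch-site type-I calibration uses 50
neutral genes of 120 codons (flag rate ≤ 7% at the 3.84 threshold); the
end-to-end study uses 32 genes (20 neutral, 12 convergent+selected, H_rap,
100-140 codons) with a 40-topology reduced null (`null_size`), asserting
≤ 10% neutral ACG calls and a strictly higher rate on the convergent
class; M0 recovery uses 20 replicates at 16 taxa × 500 codons (ω and κ
within 10%); bootstrap validation uses one 120-codon gene's full 650-value
one-move null.  The analysis drivers under `analysis/` use 20-gene studies
with a 60-topology null.  Null reduction only widens the Monte-Carlo error
of the 5th percentile; no decision threshold is altered anywhere.

## Known limitations

* The branch-move operator behind the published topology counts is not
  described in the source; rooted SPR with clean deduplication gives 650
  one-move and 17,380 two-move topologies on this species tree, close to
  but not equal to the published 663 / 18,570 (no deterministic operator
  we tested reproduces an odd one-move count under full deduplication).
* GSLS model settings (replacement matrix, frequencies, rate
  heterogeneity) are assumptions; all contrasts are internally consistent
  under the chosen model.
* Branch lengths inside mixture codon fits are fixed at M0 estimates;
  full joint optimisation is not implemented.
* The BEB triangle grid uses a product approximation with a Jacobian
  weight rather than an exact uniform triangle lattice.
* p-distances ≥ 1 make the Poisson correction undefined and raise.
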