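# convscan

Detection of **adaptively convergent genes (ACGs)** across phenotypically
convergent avian lineages, as a reusable, tested pipeline.

Phenotypic convergence — nocturnality, raptorial behaviour, foot-propelled
diving — has evolved repeatedly across bird orders.  Whether unrelated
lineages reach the same phenotype through the *same genes* is a question
about the genetic constraint on evolution.  `convscan` implements a
two-step scan over per-gene codon alignments of a fixed 16-taxon avian
panel that asks exactly that:

1. **Sequence convergence.**  For each gene, the protein alignment's
   support for the species tree H₀ versus a convergence topology Hₙ (the
   focal taxa forced monophyletic) is measured by the gene-specific
   log-likelihood support contrast ΔGSLS(Hₙ) = GSLS(H₀) − GSLS(Hₙ), where
   GSLS is the branch-length-maximised log-likelihood under a fixed
   topology.  Significance is calibrated per gene against the ΔGSLS
   distribution over *branch-moved* null topologies (all 650 one-move
   rearrangements of the species tree, or a seeded 1000-topology sample of
   the 17,380 two-move set for the three-lineage diving hypothesis, with a
   bootstrap 5th-percentile threshold).  A gene is sequence-convergent when
   its ΔGSLS falls below the null's 5th percentile.
2. **Adaptive signal.**  Sequence-convergent genes must also show positive
   selection on the focal (foreground) terminal branches — branch-site
   model A versus its ω₂ = 1 null (χ², 1 df, 3.84) — and must *not* show a
   site-model signal (M1a vs M2a, 2 df, 5.99) on the tree with the focal
   taxa removed.  Survivors are ACGs.

Below the gene level, Bayes-empirical-Bayes site posteriors identify
adaptively convergent site mutations (ACSMs: P(ω > 1) > 0.95, residue
shared by all focal taxa and absent elsewhere), which are compared against
the neutral expectation M = (D − P)/20·L (two lineages) or
((D − P)/20)²·L (three), with D and P the mean pairwise Poisson-correction
and p amino-acid distances among non-focal taxa.  Above single
hypotheses, derived-hypothesis percentile tests with Benjamini–Hochberg
correction and union-based Fisher overlap tests quantify whether different
convergent pairs reuse the same genes.

Everything runs on synthetic data from the built-in seeded simulator
(`convscan.synthetic_data`), which evolves 16-taxon codon alignments along
the species tree under GY94-family models with optional injected
convergence and selection, plus truth labels.

## Worked example

Simulate two 20-gene studies and scan them (about 15 minutes on one CPU):

```bash
python analysis/01_simulate_study.py
python analysis/02_scan_acgs.py
python analysis/03_constraint_stats.py
```

`02_scan_acgs.py` prints, for the nocturnal study:

```
H_noc: ACG calls by simulation truth
                     mean  sum  count
class
CONVERGENT_SELECTED   1.0    6      6
NEUTRAL               0.0    0     14
ACSMs found: 7 (observed convergent site mutations in called ACGs)
summed neutral expectation M over ACGs: 0.4314
```

All six genes simulated with convergence + foreground selection are called
ACGs and no neutral gene is, and the seven observed convergent site
mutations far exceed the 0.43 sites expected from neutral multiple
substitution — the pattern the scan is designed to expose.  The raptor
study behaves the same way (6 of 9 convergent genes called, 0 of 11
neutral).  `03_constraint_stats.py` then tests the derived raptor pairs on
the same genes:

```
            sum  count
hypothesis
H_rap_a       9     20
H_rap_b       9     20
overlap H_rap_a|H_rap_b: table=[[3, 4], [2, 4]] p=1.0000

published raptorial ACG overlap: p = 0.7055 (two-tailed Fisher)
published ACG-count comparison (12 vs 10): chi2 = 0.1818, p = 0.67
```

Nine genes support each derived raptor hypothesis; their overlap is no
larger than that of the neutral baseline (Fisher p = 1), i.e. no evidence
that the two raptor pairs reuse the same genes.  The last two lines
recompute published worked-example statistics from their printed inputs.

A `convscan` command-line tool exposes the same stages
(`simulate`, `clean`, `gsls`, `acg`, `overlap`); see `convscan --help`.

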