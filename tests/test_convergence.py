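"""Null calibration, ACG calling, derived tests, ACSMs and neutral M."""

import math

import numpy as np
import pytest

from convscan.codon_selection import SiteSelectionPosterior
from convscan.convergence import (
    NullDistribution,
    bootstrap_threshold,
    call_acg,
    derived_hypothesis_tests,
    find_acsm,
    neutral_expectation,
    pairwise_distances,
    percentile_5,
    percentile_rank,
)
from convscan.seqdata import GeneAlignment
from convscan.treekit import TAXA_16


class _Lrt:
    def __init__(self, significant):
        self.significant = significant


def make_null(threshold, gene_id="g1"):
    return NullDistribution(
        gene_id=gene_id, move_order=1,
        values=np.array([threshold] * 30), threshold=threshold,
    )


class TestPercentile:
    def test_linear_interpolation_rule(self):
        assert percentile_5(np.arange(1, 101)) == pytest.approx(5.95)

    def test_constant_values(self):
        assert percentile_5(np.full(50, 3.3)) == pytest.approx(3.3)


class TestBootstrapThreshold:
    def test_constant_values_give_degenerate_interval(self):
        thr, (lo, hi) = bootstrap_threshold(np.full(100, 2.5), seed=0)
        assert thr == pytest.approx(2.5)
        assert hi - lo == pytest.approx(0.0)

    def test_deterministic_under_seed(self):
        vals = np.random.default_rng(1).normal(size=200)
        assert bootstrap_threshold(vals, seed=7) == bootstrap_threshold(
            vals, seed=7
        )

    def test_tracks_true_normal_quantile_with_ci_coverage(self):
        # the bootstrap mean-5th-percentile should sit near the true -1.645
        # and its 95% CI should cover the truth in most meta-replicates
        rng = np.random.default_rng(42)
        hits = 0
        n_meta = 30
        for i in range(n_meta):
            vals = rng.normal(size=1000)
            thr, (lo, hi) = bootstrap_threshold(vals, B=500, seed=i)
            assert abs(thr - (-1.645)) < 0.15
            hits += lo <= -1.645 <= hi
        assert hits >= 0.9 * n_meta

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_threshold(np.ones(5))


class TestCallAcg:
    def test_tie_with_threshold_is_not_convergent(self):
        call = call_acg("g1", "H_noc", -4.0, make_null(-4.0), _Lrt(True), _Lrt(False))
        assert not call.sequence_convergent and not call.is_acg

    def test_full_positive_call(self):
        call = call_acg("g1", "H_noc", -9.0, make_null(-4.0), _Lrt(True), _Lrt(False))
        assert call.sequence_convergent and call.is_acg

    def test_background_selection_excludes_gene(self):
        call = call_acg("g1", "H_noc", -9.0, make_null(-4.0), _Lrt(True), _Lrt(True))
        assert call.excluded_both_models
        assert not call.is_acg
        assert call.neutrally_convergent

    def test_monotone_in_delta(self):
        null = make_null(-4.0)
        weaker = call_acg("g1", "H", -4.5, null, _Lrt(True), _Lrt(False))
        stronger = call_acg("g1", "H", -20.0, null, _Lrt(True), _Lrt(False))
        assert weaker.sequence_convergent
        assert stronger.sequence_convergent

    def test_gene_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_acg("g2", "H", -9.0, make_null(-4.0, "g1"), None, None)


class TestDerivedHypothesisTests:
    def test_single_hypothesis_is_unadjusted(self):
        null = np.arange(100.0)
        out = derived_hypothesis_tests("g", {"H_rap_a": 1.5}, null)
        assert len(out) == 1
        assert out[0].X == out[0].X_adj == pytest.approx(2.0)
        assert out[0].significant

    def test_step_up_adjustment_matches_hand_computation(self):
        null = np.arange(100.0)  # value v -> percentile floor(v)+1
        deltas = {"a": 0.5, "b": 1.5, "c": 89.5}
        out = {t.hypothesis: t.X_adj for t in derived_hypothesis_tests("g", deltas, null)}
        assert out["a"] == pytest.approx(3.0)
        assert out["b"] == pytest.approx(3.0)
        assert out["c"] == pytest.approx(90.0)

    def test_mid_ranks_are_never_significant(self):
        null = np.arange(100.0)
        out = derived_hypothesis_tests(
            "g", {"a": 49.5, "b": 49.5, "c": 49.5}, null
        )
        assert not any(t.significant for t in out)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            derived_hypothesis_tests("g", {"a": 0.0}, [])


def panel_alignment(focal_codon="AGC", other_codon="GCA", special=None):
    """Three-codon gene; site 1 carries the pattern under test."""
    seqs = {}
    for t in TAXA_16:
        codon = focal_codon if t in {"TYTAL", "CAPCA"} else other_codon
        if special and t in special:
            codon = special[t]
        seqs[t] = "ATG" + codon + "AAA"
    return GeneAlignment("g1", tuple(TAXA_16), seqs, cleaned=True)


class TestFindAcsm:
    def post(self, pp, site=1):
        return [SiteSelectionPosterior(site=site, pp_positive=pp)]

    def test_focal_exclusive_shared_residue_is_acsm(self):
        aln = panel_alignment()  # focal serine, others alanine
        calls = find_acsm(aln, "H_noc", self.post(0.99))
        assert len(calls) == 1
        assert calls[0].residue == "S" and calls[0].site == 1

    def test_residue_shared_with_background_is_rejected(self):
        aln = panel_alignment(special={"GALGA": "AGC"})
        assert find_acsm(aln, "H_noc", self.post(0.99)) == []

    def test_weak_posterior_is_rejected(self):
        aln = panel_alignment()
        assert find_acsm(aln, "H_noc", self.post(0.90)) == []

    def test_non_identical_focal_residues_rejected(self):
        aln = panel_alignment(special={"TYTAL": "TCA", "CAPCA": "ACA"})
        assert find_acsm(aln, "H_noc", self.post(0.99)) == []


class TestPairwiseDistances:
    def test_identical_sequences_have_zero_distance(self):
        aln = panel_alignment()
        D, P = pairwise_distances(aln, ["GALGA", "STRCA"])
        assert D == P == 0.0

    def test_half_different_sites_match_poisson_formula(self):
        seqs = {t: "ATG" * 100 for t in TAXA_16}
        half = "ATG" * 50 + "TGG" * 50
        seqs["GALGA"] = half
        aln = GeneAlignment("g", tuple(TAXA_16), seqs, cleaned=True)
        D, P = pairwise_distances(aln, ["GALGA", "STRCA"])
        assert P == pytest.approx(0.5)
        assert D == pytest.approx(-math.log(0.5), abs=1e-4)

    def test_three_taxa_average_over_pairs(self):
        seqs = {t: "ATG" * 10 for t in TAXA_16}
        seqs["GALGA"] = "TGG" + "ATG" * 9       # differs at site 0
        aln = GeneAlignment("g", tuple(TAXA_16), seqs, cleaned=True)
        D, P = pairwise_distances(aln, ["GALGA", "STRCA", "PHORU"])
        # pairs: (GALGA,STRCA)=0.1, (GALGA,PHORU)=0.1, (STRCA,PHORU)=0
        assert P == pytest.approx((0.1 + 0.1 + 0.0) / 3)

    def test_too_few_taxa_rejected(self):
        aln = panel_alignment()
        with pytest.raises(ValueError):
            pairwise_distances(aln, ["GALGA"])


class TestNeutralExpectation:
    def gene(self, L=1000):
        seqs = {t: "ATG" * L for t in TAXA_16}
        return GeneAlignment("g", tuple(TAXA_16), seqs, cleaned=True)

    def test_equal_distances_give_zero_expectation(self):
        ne = neutral_expectation(self.gene(), "H_noc", D=0.3, P=0.3)
        assert ne.M == 0.0

    def test_two_lineage_formula(self):
        p = 0.1
        d = -math.log(1 - p)
        ne = neutral_expectation(self.gene(1000), "H_noc", D=d, P=p)
        assert ne.M == pytest.approx((d - p) / 20 * 1000)
        assert ne.M == pytest.approx(0.268, abs=5e-4)

    def test_three_lineage_formula_is_squared(self):
        p = 0.1
        d = -math.log(1 - p)
        ne = neutral_expectation(self.gene(1000), "H_foot", D=d, P=p)
        assert ne.M == pytest.approx(((d - p) / 20) ** 2 * 1000)
        assert ne.M == pytest.approx(7.18e-5, rel=5e-3)

    def test_three_lineage_never_exceeds_two_lineage(self):
        p, L = 0.2, 500
        d = -math.log(1 - p)
        two = neutral_expectation(self.gene(L), "H_noc", D=d, P=p).M
        three = neutral_expectation(self.gene(L), "H_foot", D=d, P=p).M
        assert three <= two

    def test_inverted_distances_rejected(self):
        with pytest.raises(ValueError):
            neutral_expectation(self.gene(), "H_noc", D=0.1, P=0.2)


class TestPercentileRank:
    def test_rank_is_fraction_of_null_at_or_below(self):
        null = np.array([1.0, 2.0, 3.0, 4.0])
        assert percentile_rank(2.5, null) == pytest.approx(50.0)
        assert percentile_rank(0.0, null) == 0.0
        assert percentile_rank(9.0, null) == 100.0
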