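import math

import numpy as np
import pytest

from strobehap import (
    AlleleCounts,
    DesignParams,
    filter_sites,
    greedy_phase,
    haplotype_error_rate,
    inject_errors,
    likelihood_ratio,
    site_allele_counts,
    simulate_experiment,
    switch_error_rate,
    synthesize_powerlaw_track,
)
from strobehap.calling import ReadObservation
from strobehap import SNPGraph


class TestLikelihoodRatio:
    @pytest.mark.parametrize("n1,n2", [(10, 0), (5, 5), (7, 3), (1, 0)])
    def test_identically_zero_at_half(self, n1, n2):
        assert likelihood_ratio(AlleleCounts(0, n1, n2), 0.5) == pytest.approx(0.0)

    def test_pure_dominant_counts(self):
        # 10*ln(0.95) + 10*ln(2), evaluated independently
        expected = 10 * math.log(0.95) + 10 * math.log(2)
        lam = likelihood_ratio(AlleleCounts(0, 10, 0), 0.05)
        assert lam == pytest.approx(expected)
        assert lam == pytest.approx(6.4183, abs=1e-3)

    def test_balanced_counts(self):
        expected = 5 * math.log(0.95) + 5 * math.log(0.05) + 10 * math.log(2)
        lam = likelihood_ratio(AlleleCounts(0, 5, 5), 0.05)
        assert lam == pytest.approx(expected)
        assert lam == pytest.approx(-8.3037, abs=1e-3)

    @pytest.mark.parametrize("eps", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_epsilon_rejected(self, eps):
        with pytest.raises(ValueError):
            likelihood_ratio(AlleleCounts(0, 5, 5), eps)

    def test_decreasing_in_minor_count(self):
        """At fixed n and eps < 0.5, more minor-allele evidence always
        drives Lambda down (toward the heterozygous call)."""
        for eps in (0.01, 0.05, 0.2, 0.49):
            for n in range(2, 21):
                lams = [
                    likelihood_ratio(AlleleCounts(0, n - n2, n2), eps)
                    for n2 in range(n // 2 + 1)
                ]
                assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            AlleleCounts(0, 2, 3)  # n1 < n2
        with pytest.raises(ValueError):
            AlleleCounts(0, 0, 0)  # uncovered


class TestFilterSites:
    def test_balanced_called_heterozygous(self):
        calls = filter_sites([AlleleCounts(0, 5, 5)], 0.05)
        assert calls[0].called_heterozygous

    def test_dominant_filtered_out(self):
        calls = filter_sites([AlleleCounts(0, 10, 0)], 0.05)
        assert not calls[0].called_heterozygous

    def test_boundary_is_inclusive(self):
        counts = AlleleCounts(0, 6, 2)
        lam = likelihood_ratio(counts, 0.05)
        calls = filter_sites([counts], 0.05, cutoff=lam)
        assert calls[0].called_heterozygous

    def test_decision_boundary_at_n10(self):
        """At n=10, eps=0.05, cutoff -1, the filter keeps a site exactly
        when the minor count is >= 3 (Lambda(8,2)=+0.53, Lambda(7,3)=-2.42)."""
        for n2 in range(6):
            calls = filter_sites([AlleleCounts(0, 10 - n2, n2)], 0.05)
            assert calls[0].called_heterozygous == (n2 >= 3)

    def test_loss_rate_on_binomial_heterozygous_sites(self):
        """Monte-Carlo loss of true het sites matches the closed-form
        binomial tail P(minor <= 2 | Bin(10, 1/2)) = 112/1024."""
        rng = np.random.default_rng(10)
        ones = rng.binomial(10, 0.5, size=10_000)
        counts = [
            AlleleCounts(i, max(o, 10 - o), min(o, 10 - o))
            for i, o in enumerate(ones)
        ]
        calls = filter_sites(counts, 0.05)
        lost = sum(not c.called_heterozygous for c in calls) / 10_000
        expected = 112 / 1024  # 2 * (C(10,0)+C(10,1)+C(10,2)) / 2^10
        assert abs(lost - expected) < 0.01

    def test_survival_rate_on_homozygous_decoys(self):
        """Monte-Carlo decoy survival matches P(errors >= 3 | Bin(10, 0.05))."""
        from scipy import stats
        rng = np.random.default_rng(11)
        errors = rng.binomial(10, 0.05, size=10_000)
        counts = [
            AlleleCounts(i, max(e, 10 - e), min(e, 10 - e))
            for i, e in enumerate(errors)
        ]
        calls = filter_sites(counts, 0.05)
        survived = sum(c.called_heterozygous for c in calls) / 10_000
        expected = float(stats.binom.sf(2, 10, 0.05))  # ~= 0.0115
        assert abs(survived - expected) < 0.005


class TestInjectErrors:
    @pytest.fixture
    def small_setup(self):
        track = synthesize_powerlaw_track(200_000, mean_gap=500, seed=20)
        params = DesignParams(L=900, c=5, A=2000, k=2,
                              beta_params=((1, 1),), seed=21)
        graph, reads = simulate_experiment(track, params)
        return track, graph, reads

    def test_error_free_observations_match_source_haplotype(self, small_setup):
        track, _, reads = small_setup
        rng = np.random.default_rng(0)
        obs = inject_errors(reads, track, 0.0, 0.0, rng)
        for read, o in zip(reads, obs):
            assert set(o.alleles) == set(read.covered_sites)
            hap = track.truth[o.haplotype]
            assert all(hap[s] == a for s, a in o.alleles.items())

    def test_full_dropout_leaves_nothing(self, small_setup):
        track, _, reads = small_setup
        obs = inject_errors(reads, track, 0.0, 1.0, np.random.default_rng(0))
        assert all(not o.alleles for o in obs)

    def test_flip_fraction_concentrates_at_epsilon(self, small_setup):
        track, _, reads = small_setup
        rng = np.random.default_rng(1)
        # replicate the read set until we exceed 1e5 observations
        pool = reads * (100_000 // max(sum(len(r.covered_sites) for r in reads), 1) + 1)
        obs = inject_errors(pool, track, 0.05, 0.0, rng)
        flips = total = 0
        for o in obs:
            hap = track.truth[o.haplotype]
            for s, a in o.alleles.items():
                total += 1
                flips += a != hap[s]
        assert total >= 100_000
        assert abs(flips / total - 0.05) < 0.005

    def test_missing_truth_rejected(self):
        from strobehap import VariantTrack
        track = VariantTrack(np.array([10, 20]), 100)
        with pytest.raises(ValueError):
            inject_errors([], track, 0.05, 0.0, np.random.default_rng(0))

    def test_homozygous_decoys_emit_single_allele(self, small_setup):
        track, _, reads = small_setup
        mask = np.zeros(track.n_sites, dtype=bool)
        mask[::2] = True
        obs = inject_errors(reads, track, 0.0, 0.0,
                            np.random.default_rng(2), homozygous_sites=mask)
        for o in obs:
            for s, a in o.alleles.items():
                if mask[s]:
                    assert a == 0


class TestGreedyPhase:
    def test_error_free_phasing_is_perfect(self):
        track = synthesize_powerlaw_track(300_000, mean_gap=800, seed=30)
        params = DesignParams(L=900, c=8, A=3000, k=2,
                              beta_params=((1, 1),), seed=31)
        graph, reads = simulate_experiment(track, params)
        obs = inject_errors(reads, track, 0.0, 0.0, np.random.default_rng(0))
        result = greedy_phase(graph, obs)
        assert haplotype_error_rate(track.truth, result) == 0.0
        assert switch_error_rate(track.truth, result) == 0.0

    def test_tie_between_opposite_votes_keeps_phase_zero(self):
        graph = SNPGraph.from_edge_list(2, [(0, 1), (0, 1)])
        obs = [
            ReadObservation(0, {0: 0, 1: 0}),  # votes phase 0
            ReadObservation(1, {0: 0, 1: 1}),  # votes phase 1
        ]
        result = greedy_phase(graph, obs)
        assert result.alleles[0] == result.alleles[1]  # phase 0 kept

    def test_majority_overrides_single_bad_read(self):
        graph = SNPGraph.from_edge_list(2, [(0, 1)] * 3)
        obs = [
            ReadObservation(0, {0: 0, 1: 0}),
            ReadObservation(0, {0: 0, 1: 0}),
            ReadObservation(0, {0: 0, 1: 1}),  # miscalled
        ]
        result = greedy_phase(graph, obs)
        assert result.alleles[0] == result.alleles[1]

    def test_low_error_rate_yields_accurate_haplotypes(self):
        """HER stays under 5% in nearly all seeded noisy runs at c=10."""
        track = synthesize_powerlaw_track(500_000, mean_gap=1000, seed=40)
        good = 0
        for seed in range(20):
            params = DesignParams(L=900, c=10, A=1500, k=2,
                                  beta_params=((1, 1),), seed=seed)
            graph, reads = simulate_experiment(track, params)
            obs = inject_errors(reads, track, 0.05, 0.05,
                                np.random.default_rng(500 + seed))
            result = greedy_phase(graph, obs)
            good += haplotype_error_rate(track.truth, result) < 0.05
        assert good >= 18


class TestCountsAggregation:
    def test_counts_are_dominant_minor_ordered(self):
        obs = [
            ReadObservation(0, {0: 1, 1: 0}),
            ReadObservation(1, {0: 1, 1: 1}),
            ReadObservation(0, {0: 0}),
        ]
        counts = {c.site: c for c in site_allele_counts(obs, 3)}
        assert (counts[0].n1, counts[0].n2) == (2, 1)
        assert (counts[1].n1, counts[1].n2) == (1, 1)
        assert 2 not in counts  # uncovered site omitted
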