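"""HMM inference against closed forms and exhaustive path enumeration."""

import math

import numpy as np
import pytest

from fshd_nipd.core import InferenceError, Locus, PaternalHaplotypes, SNPPanel, SNPSite
from fshd_nipd.hmm import (
    HMMParams,
    ObservationSequence,
    build_observations,
    call_fetal_inheritance,
    call_segments,
    emission_loglik,
    forward_backward,
    transition_matrix,
    transition_prob,
    viterbi,
    _emission_matrix,
)
from fshd_nipd.phasing import phase_paternal, select_informative_snps
from fshd_nipd.simulate import (
    SimConfig,
    simulate_family,
    simulate_plasma_counts,
    simulate_population_sites,
)

from conftest import enumerate_all_paths, random_observation_sequence


def _seq(pos, hap0_carries_b, depth, b_count, b_is_alt=None):
    pos = np.asarray(pos)
    if b_is_alt is None:
        b_is_alt = np.ones(len(pos), dtype=bool)
    return ObservationSequence(
        chrom="chr4", pos=pos, b_is_alt=b_is_alt,
        hap0_carries_b=np.asarray(hap0_carries_b, dtype=bool),
        depth=np.asarray(depth), b_count=np.asarray(b_count),
    )


class TestEmission:
    def test_noncarry_zero_error_zero_reads_is_certain(self):
        params = HMMParams(f=0.2, epsilon=0.0)
        ll = emission_loglik(np.array([0]), np.array([50]), np.array([False]), params)
        assert ll[0] == pytest.approx(0.0)

    def test_closed_form_binomial(self):
        # f=0.3, eps=0: mu_carry = 0.15; P(k=2 | n=10) from first principles
        params = HMMParams(f=0.3, epsilon=0.0)
        expected = math.comb(10, 2) * 0.15**2 * 0.85**8
        ll = emission_loglik(np.array([2]), np.array([10]), np.array([True]), params)
        assert ll[0] == pytest.approx(math.log(expected), abs=1e-12)

    def test_mixture_rate_at_reported_parameters(self):
        # f=0.1558, eps=6e-4: mu_carry = 0.0779*0.9994 + 0.9221*0.0006
        params = HMMParams(f=0.1558, epsilon=6e-4)
        assert params.mu_carry == pytest.approx(0.0779 * 0.9994 + 0.9221 * 6e-4, abs=1e-12)
        assert params.mu_carry == pytest.approx(0.0784065, abs=1e-6)
        assert params.mu_noncarry == 6e-4

    def test_impossible_observation_floored_not_inf(self):
        params = HMMParams(f=0.2, epsilon=0.0)
        ll = emission_loglik(np.array([3]), np.array([50]), np.array([False]), params)
        assert np.isfinite(ll[0]) and ll[0] < -500


class TestTransitions:
    def test_zero_rate_never_switches(self):
        assert transition_prob(123456, 0.0) == 0.0

    def test_large_distance_asymptote(self):
        assert transition_prob(1e12, 1e-8) == pytest.approx(0.5)

    def test_haldane_closed_form(self):
        r = transition_prob(1_000_000, 1e-8)
        assert r == pytest.approx((1 - math.exp(-0.02)) / 2, abs=1e-15)
        assert r == pytest.approx(0.009901, abs=5e-7)
        m = transition_matrix(1_000_000, 1e-8)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert m[0, 1] == pytest.approx(r)


class TestForwardBackward:
    def test_single_uninformative_site_is_fifty_fifty(self):
        seq = _seq([100], [True], [0], [0])  # zero depth: emissions equal
        track = forward_backward(seq, HMMParams(f=0.15, epsilon=1e-3))
        assert track.p_hap0[0] == pytest.approx(0.5)
        assert track.log10_odds[0] == pytest.approx(0.0)

    def test_matches_exhaustive_enumeration(self):
        params = HMMParams(f=0.12, epsilon=1e-3, c=1e-7)
        rng = np.random.default_rng(2024)
        for _ in range(60):
            seq = random_observation_sequence(rng, n_max=8)
            oracle = enumerate_all_paths(
                _emission_matrix(seq, params), seq.gaps, params.c, params.prior
            )
            track = forward_backward(seq, params)
            assert track.loglik == pytest.approx(oracle["loglik"], abs=1e-9)
            np.testing.assert_allclose(track.p_hap0, oracle["posterior_state0"], atol=1e-9)

    def test_posteriors_normalized_and_reversal_invariant(self):
        params = HMMParams(f=0.15, epsilon=6e-4)
        rng = np.random.default_rng(5)
        seq = random_observation_sequence(rng, n_max=12)
        track = forward_backward(seq, params)
        assert np.all(np.abs(track.p_hap0 + (1 - track.p_hap0) - 1.0) < 1e-12)
        # running the chain backwards (same symmetric transitions) must give
        # the same total likelihood and mirrored posteriors
        rev = ObservationSequence(
            chrom=seq.chrom,
            pos=np.sort(seq.pos.max() - seq.pos + 1),
            b_is_alt=seq.b_is_alt[::-1],
            hap0_carries_b=seq.hap0_carries_b[::-1],
            depth=seq.depth[::-1],
            b_count=seq.b_count[::-1],
        )
        rtrack = forward_backward(rev, params)
        assert rtrack.loglik == pytest.approx(track.loglik, abs=1e-9)
        np.testing.assert_allclose(rtrack.p_hap0, track.p_hap0[::-1], atol=1e-9)

    def test_label_swap_symmetry_is_exact(self):
        params = HMMParams(f=0.15, epsilon=6e-4)
        rng = np.random.default_rng(11)
        seq = random_observation_sequence(rng, n_max=12)
        flipped = ObservationSequence(
            chrom=seq.chrom, pos=seq.pos, b_is_alt=seq.b_is_alt,
            hap0_carries_b=~seq.hap0_carries_b, depth=seq.depth, b_count=seq.b_count,
        )
        t1 = forward_backward(seq, params)
        t2 = forward_backward(flipped, params)
        np.testing.assert_array_equal(t2.p_hap0, 1.0 - t1.p_hap0)

    def test_no_underflow_on_long_sequences(self):
        rng = np.random.default_rng(3)
        n = 10_000
        pos = np.sort(rng.choice(np.arange(1, 10**8), size=n, replace=False))
        depth = np.full(n, 300)
        params = HMMParams(f=0.15, epsilon=6e-4)
        b = rng.binomial(depth, params.mu_carry)
        seq = _seq(pos, np.ones(n, dtype=bool), depth, b)
        track = forward_backward(seq, params)
        assert np.isfinite(track.loglik)
        assert np.all(np.isfinite(track.p_hap0))

    def test_empty_sequence_errors(self):
        seq = _seq([], [], [], [])
        with pytest.raises(InferenceError):
            forward_backward(seq, HMMParams(f=0.15, epsilon=6e-4))


class TestViterbi:
    def test_constant_signal_gives_constant_path(self):
        params = HMMParams(f=0.15, epsilon=6e-4)
        n = 50
        pos = np.arange(1, n + 1) * 40_000
        depth = np.full(n, 300)
        b = np.round(depth * params.mu_carry).astype(int)  # k/n ~ f/2 everywhere
        path, _ = viterbi(_seq(pos, np.ones(n, bool), depth, b), params)
        assert np.all(path == 0)

    def test_matches_exhaustive_enumeration(self):
        params = HMMParams(f=0.12, epsilon=1e-3, c=1e-7)
        rng = np.random.default_rng(99)
        for _ in range(60):
            seq = random_observation_sequence(rng, n_max=8)
            oracle = enumerate_all_paths(
                _emission_matrix(seq, params), seq.gaps, params.c, params.prior
            )
            path, score = viterbi(seq, params)
            assert score == pytest.approx(oracle["viterbi_score"], abs=1e-9)

    def test_posterior_concentrates_with_depth(self):
        # consistency: at very high depth the posterior pins the truth
        params = HMMParams(f=0.1558, epsilon=6e-4)
        rng = np.random.default_rng(8)
        n = 40
        pos = np.arange(1, n + 1) * 40_000
        truth = (np.arange(n) >= n // 2).astype(int)  # hap0 then hap1
        carries = np.ones(n, bool)
        depth = np.full(n, 10_000)
        mu = np.where(truth == 0, params.mu_carry, params.mu_noncarry)
        b = rng.binomial(depth, mu)
        track = forward_backward(_seq(pos, carries, depth, b), params)
        called = (track.p_hap0 < 0.5).astype(int)
        assert np.array_equal(called, truth)
        assert np.all(np.maximum(track.p_hap0, 1 - track.p_hap0) > 0.999)


class TestSegmentsAndCall:
    def test_breakpoint_convention(self):
        segs = call_segments(np.array([1, 1, 0, 0]), np.array([100, 200, 300, 400]), chrom="chr4")
        assert [(s.start, s.end, s.state) for s in segs.segments] == [
            (100, 200, "hap1"), (300, 400, "hap0"),
        ]
        bp = segs.breakpoints[0]
        assert (bp.left, bp.right, bp.coord) == (200, 300, 300)
        assert (bp.from_state, bp.to_state) == ("hap1", "hap0")

    def test_constant_path_single_segment(self):
        segs = call_segments(np.zeros(5, int), np.arange(5) * 10 + 1)
        assert len(segs.segments) == 1 and segs.breakpoints == []

    def test_call_is_state_of_nearest_snp(self):
        locus = Locus("chr4", 1_000_000, 1_040_000)
        pos = np.array([900_000, 920_000, 990_000])
        path = np.array([1, 1, 0])
        params = HMMParams(f=0.15, epsilon=6e-4)
        depth = np.full(3, 300)
        b = np.array([0, 0, 22])
        track = forward_backward(_seq(pos, np.ones(3, bool), depth, b), params)
        segs = call_segments(path, pos, chrom="chr4")
        call = call_fetal_inheritance(segs, track, locus)
        assert call.call == "hap0"
        assert call.nearest_pos == 990_000
        assert call.distance_bp == 10_000
        assert not call.low_confidence

    def test_switch_spanning_locus_is_low_confidence(self):
        locus = Locus("chr4", 1_000_000, 1_040_000)
        pos = np.array([980_000, 990_000, 1_060_000])  # gap straddles the locus
        path = np.array([1, 1, 0])
        params = HMMParams(f=0.15, epsilon=6e-4)
        track = forward_backward(
            _seq(pos, np.ones(3, bool), np.full(3, 300), np.array([0, 0, 22])), params
        )
        segs = call_segments(path, pos, chrom="chr4")
        call = call_fetal_inheritance(segs, track, locus)
        assert call.low_confidence
        assert "spans" in call.reason


class TestBuildObservations:
    def test_b_allele_is_the_one_mother_lacks(self, small_config):
        from conftest import make_genotype_table

        gt = make_genotype_table(
            [
                ("chr4", 190_200_000, "A", "G", "0/1", "1/1", "0/1", "0/0"),  # hap0 alt
                ("chr4", 190_300_000, "A", "G", "0/1", "0/0", "0/1", "1/1"),  # hap0 ref... depends
            ]
        )
        res = phase_paternal(gt, affected_source="grandmother")
        counts = np.array([[280, 20], [15, 285]])
        import pandas as pd

        plasma = pd.DataFrame(
            {
                "chrom": "chr4",
                "pos": [190_200_000, 190_300_000],
                "ref": "A",
                "alt": "G",
                "ref_count": counts[:, 0],
                "alt_count": counts[:, 1],
                "sample_id": "s1",
            }
        )
        obs = build_observations(gt, res.haplotypes, plasma)
        # site 1: mother 0/0 -> B = alt; hap0 allele is 1 -> hap0 carries B
        assert obs.b_is_alt[0] and obs.hap0_carries_b[0]
        assert obs.b_count[0] == 20
        # site 2: mother 1/1 -> B = ref; hap0 allele is 0 (gm passed ref? no:
        # gm hom ref pins father's gm-allele to ref) -> hap0 carries B
        assert not obs.b_is_alt[1]
        assert obs.b_count[1] == 15
        assert obs.hap0_carries_b[1] == (res.haplotypes.hap0[1] == 0)

    def test_roundtrip_b_counts_match_simulated_reads(self, small_config):
        sites = simulate_population_sites(small_config)
        genotypes, truth = simulate_family(sites, small_config)
        plasma = simulate_plasma_counts(genotypes, truth, small_config)
        locus = small_config.locus
        panel = SNPPanel(
            locus,
            [s for s in sites if s.chrom == locus.chrom],
            [s for s in sites if s.chrom != locus.chrom],
            small_config.window_bp,
        )
        selection = select_informative_snps(genotypes, panel)
        res = phase_paternal(selection.table, small_config.affected_grandparent)
        obs = build_observations(selection.table, res.haplotypes, plasma)
        merged = plasma.set_index(["chrom", "pos"])
        for i, p in enumerate(obs.pos):
            row = merged.loc[("chr4", p)]
            expected = row["alt_count"] if obs.b_is_alt[i] else row["ref_count"]
            assert obs.b_count[i] == expected
            assert obs.depth[i] == row["ref_count"] + row["alt_count"]

    def test_zero_depth_sites_dropped_but_inference_survives(self):
        from conftest import make_genotype_table
        import pandas as pd

        gt = make_genotype_table(
            [("chr4", 100 + i * 50_000, "A", "G", "0/1", "1/1", "0/1", "0/0") for i in range(4)]
        )
        res = phase_paternal(gt)
        plasma = pd.DataFrame(
            {
                "chrom": "chr4",
                "pos": [100, 50_100, 100_100, 150_100],
                "ref": "A",
                "alt": "G",
                "ref_count": [280, 0, 280, 290],
                "alt_count": [20, 0, 25, 18],
                "sample_id": "s1",
            }
        )
        obs = build_observations(gt, res.haplotypes, plasma)
        assert len(obs) == 3 and obs.n_dropped_zero_depth == 1
        track = forward_backward(obs, HMMParams(f=0.15, epsilon=6e-4))
        assert np.all(np.isfinite(track.log10_odds))
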