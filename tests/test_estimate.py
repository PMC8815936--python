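import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldne.estimate import (LDBin, NeTrajectory, bin_pairs, critical_sweep_c,
                           historical_trajectory, log_bins, mean_ne_in_c_window,
                           ne_from_bin, ne_from_pi, ne_vk_analytic,
                           ne_vk_from_pedigree, pairwise_r2, regional_ne)
from ldne.maps import haldane_c

from conftest import sample_from_haplotype_counts


def brute_force_r2(n_ab, n_aB, n_Ab, n_AB):
    """r2 from first principles on the 2x2 haplotype table."""
    n = n_ab + n_aB + n_Ab + n_AB
    p_a = (n_Ab + n_AB) / n          # freq of allele 1 at site 1
    p_b = (n_aB + n_AB) / n          # freq of allele 1 at site 2
    d = n_AB / n - p_a * p_b
    return d ** 2 / (p_a * (1 - p_a) * p_b * (1 - p_b))


class TestPairwiseR2:
    @pytest.mark.parametrize("counts,expected", [
        ((5, 0, 0, 5), 1.0),          # complete association
        ((25, 25, 25, 25), 0.0),      # independence
        ((4, 1, 1, 4), 0.36),         # D = 0.15, r2 = 0.0225/0.0625
    ])
    def test_known_tables(self, counts, expected):
        sample = sample_from_haplotype_counts(*counts)
        pairs = pairwise_r2(sample, c_min=1e-6)
        assert len(pairs) == 1
        assert pairs.r2[0] == pytest.approx(expected, abs=1e-12)

    @given(st.tuples(*[st.integers(0, 20)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_on_small_tables(self, counts):
        n_ab, n_aB, n_Ab, n_AB = counts
        n = sum(counts)
        # both sites must segregate
        if n < 2 or n_Ab + n_AB in (0, n) or n_aB + n_AB in (0, n):
            return
        sample = sample_from_haplotype_counts(*counts)
        pairs = pairwise_r2(sample, c_min=1e-6)
        assert pairs.r2[0] == pytest.approx(brute_force_r2(*counts), abs=1e-10)

    def test_c_comes_from_haldane_of_map_distance(self):
        sample = sample_from_haplotype_counts(4, 1, 1, 4, d_morgans=0.3)
        pairs = pairwise_r2(sample)
        assert pairs.c[0] == pytest.approx(haldane_c(0.3))

    def test_monomorphic_site_rejected(self):
        sample = sample_from_haplotype_counts(5, 0, 0, 5)
        sample.matrix[:, 0] = 0   # invariant violation introduced in place
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_r2(sample)

    def test_subsampling_cap_is_respected_and_seeded(self, rng):
        mat = (np.random.default_rng(0).random((30, 40)) < 0.5).astype(np.uint8)
        from ldne.simulate import HaplotypeSample
        pos = np.arange(40) * 1000
        sample = HaplotypeSample(mat, pos, pos * 1e-6, 40_000)
        p1 = pairwise_r2(sample, max_pairs=50, rng=np.random.default_rng(3))
        p2 = pairwise_r2(sample, max_pairs=50, rng=np.random.default_rng(3))
        assert len(p1) == 50
        np.testing.assert_array_equal(p1.c, p2.c)


class TestNeFromBin:
    def test_exact_inversion_of_forward_expectation(self):
        # E(r2) = 1/(1 + 4 Ne c) + 1/n_h at Ne = 1000, c = 0.0025, n_h = 200
        b = LDBin(0.002, 0.003, 1000, 0.0025, 1 / 11 + 1 / 200)
        assert ne_from_bin(b, 200, phased=True) == pytest.approx(1000.0)

    @given(st.floats(10, 1e5), st.floats(1e-3, 0.5), st.integers(10, 500))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_property(self, ne, c, n_h):
        expected_r2 = 1.0 / (1.0 + 4.0 * ne * c) + 1.0 / n_h
        b = LDBin(c * 0.9, c * 1.1, 500, c, expected_r2)
        assert ne_from_bin(b, n_h, phased=True) == pytest.approx(ne, rel=1e-9)

    def test_unphased_round_trip_uses_alpha_two_and_diploid_correction(self):
        ne, c, n = 500.0, 0.01, 50
        expected_r2 = 1.0 / (2.0 + 4.0 * ne * c) + 1.0 / n
        b = LDBin(c * 0.9, c * 1.1, 500, c, expected_r2)
        assert ne_from_bin(b, 2 * n, phased=False) == pytest.approx(ne)

    def test_boundary_r2_of_one_gives_zero(self):
        b = LDBin(0.01, 0.02, 500, 0.015, 1.0 + 1.0 / 100)
        assert ne_from_bin(b, 100, phased=True) == pytest.approx(0.0)

    def test_r2_below_sampling_floor_is_flagged_invalid(self):
        b = LDBin(0.01, 0.02, 500, 0.015, 0.005)   # below 1/n_h = 0.01
        assert np.isnan(ne_from_bin(b, 100, phased=True))

    def test_monotone_decreasing_in_c(self):
        r2 = 0.05
        nes = [ne_from_bin(LDBin(c * 0.9, c * 1.1, 500, c, r2), 1000, True)
               for c in (0.005, 0.01, 0.05, 0.2)]
        assert np.all(np.diff(nes) < 0)


class TestTrajectory:
    def test_hayes_time_mapping(self):
        bins = [LDBin(0.4, 0.5, 200, 0.5, 0.3),
                LDBin(0.002, 0.003, 200, 0.0025, 0.1)]
        traj = historical_trajectory(bins, 100)
        np.testing.assert_allclose(traj.t, [1.0, 200.0])
        assert np.all(np.diff(traj.t) > 0)

    def test_empty_bins_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            historical_trajectory([], 100)

    def test_window_mean_skips_invalid_bins(self):
        bins = [LDBin(0.002, 0.003, 200, 0.0025, 0.2),
                LDBin(0.01, 0.02, 200, 0.015, 0.001)]   # second is invalid
        traj = historical_trajectory(bins, 100)
        assert np.isnan(traj.ne_hat[0])  # sorted by t: invalid bin is t=33
        m = mean_ne_in_c_window(traj, 0.002, 0.02)
        assert m == pytest.approx(traj.ne_hat[1])

    def test_default_bins_span_configured_range(self):
        edges = log_bins()
        assert edges[0] == pytest.approx(0.001)
        assert edges[-1] == pytest.approx(0.5)
        assert len(edges) == 31


class TestRegionalNe:
    def _window_sample(self, seed=0, n_sites=60):
        rng = np.random.default_rng(seed)
        from ldne.simulate import HaplotypeSample
        mat = (rng.random((100, n_sites)) < rng.uniform(0.1, 0.9, n_sites)).astype(np.uint8)
        keep = (mat.sum(0) > 0) & (mat.sum(0) < 100)
        mat = mat[:, keep]
        pos = np.arange(mat.shape[1]) * 1000
        return HaplotypeSample(mat, pos, pos * 2e-8 * 25, 10_000_000)

    def test_insufficient_pairs_flagged_not_raised(self):
        sample = self._window_sample()
        reg = regional_ne(sample, min_pairs=10 ** 9)
        assert not reg.sufficient
        assert np.isnan(reg.ne_hat)

    def test_pooled_estimate_uses_configured_c_range(self):
        sample = self._window_sample()
        reg = regional_ne(sample, min_pairs=1)
        assert reg.sufficient
        assert 1 / 100 <= reg.mean_c <= 1 / 50


class TestScalarEstimators:
    @pytest.mark.parametrize("pi,mu,expected", [
        (4e-5, 1e-8, 1000.0), (0.0, 1e-8, 0.0), (3e-5, 1e-8, 750.0)])
    def test_ne_from_pi(self, pi, mu, expected):
        assert ne_from_pi(pi, mu) == pytest.approx(expected)

    def test_ne_from_pi_requires_positive_mu(self):
        with pytest.raises(ValueError):
            ne_from_pi(1e-5, 0.0)

    @pytest.mark.parametrize("n,beta,expected", [
        (1000, 0.5, 750.0),    # alpha = 1/3
        (1000, 0.0, 1000.0),
        (1000, 1.0, 500.0),    # alpha = 1
    ])
    def test_selfing_analytic_value(self, n, beta, expected):
        assert ne_vk_analytic(n, beta) == pytest.approx(expected)

    def test_pedigree_estimator_boundaries(self):
        assert ne_vk_from_pedigree(np.full(100, 2), 100) == pytest.approx(199.0)
        assert ne_vk_from_pedigree(np.array([2]), 1) <= 1.0

    def test_pedigree_estimator_recovers_census_under_multinomial(self, rng):
        # oracle: multinomial reproduction has Vk ~ 2, so ne ~ N
        n = 100
        nes = [ne_vk_from_pedigree(rng.multinomial(2 * n, np.full(n, 1 / n)), n)
               for _ in range(500)]
        assert np.mean(nes) == pytest.approx(n, rel=0.05)

    def test_pedigree_counts_must_conserve_gametes(self):
        with pytest.raises(ValueError):
            ne_vk_from_pedigree(np.full(100, 2), 99)

    def test_sweep_critical_recombination_distance(self):
        assert critical_sweep_c(0.02) == pytest.approx(0.002, abs=0.0)
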