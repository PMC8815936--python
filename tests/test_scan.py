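import numpy as np
import pandas as pd
import pytest

from ldne.maps import GenomeMap, RecombinationMap
from ldne.scan import (aggregate_track, correlate, correlation_matrix,
                       filter_windows, partition_windows, scan_windows,
                       window_stats)
from ldne.simulate import HaplotypeSample


def uniform_genome(length=10_000_000, rate=1.0):
    return GenomeMap({"1": RecombinationMap.uniform(length, rate)})


class TestPartition:
    def test_uniform_map_gives_equal_bp_windows(self):
        windows = partition_windows(uniform_genome(10_000_000, 1.0))
        assert len(windows) == 5
        widths = {w.end_bp - w.start_bp for w in windows}
        assert widths == {2_000_000}
        assert all(w.map_end - w.map_start == pytest.approx(0.02) for w in windows)

    def test_telomeric_remainder_dropped(self):
        windows = partition_windows(uniform_genome(11_000_000, 1.0))
        assert len(windows) == 5
        assert windows[-1].end_bp == 10_000_000

    def test_short_chromosome_yields_no_windows(self):
        windows = partition_windows(uniform_genome(1_000_000, 1.0))  # 1 cM total
        assert windows == []

    def test_window_bp_width_inverse_to_local_rate(self):
        # first half at 2 cM/Mb, second half at 0.5 cM/Mb
        rmap = RecombinationMap(np.array([0, 5_000_000]), np.array([2.0, 0.5]),
                                10_000_000)
        windows = partition_windows(GenomeMap({"1": rmap}))
        widths = np.array([w.end_bp - w.start_bp for w in windows])
        assert widths[0] == pytest.approx(1_000_000, rel=0.01)   # high RR: narrow
        assert widths[-1] == pytest.approx(4_000_000, rel=0.01)  # low RR: wide

    def test_windows_are_ordered_and_non_overlapping(self):
        windows = partition_windows(uniform_genome())
        for a, b in zip(windows, windows[1:]):
            assert a.end_bp <= b.start_bp


class TestWindowStats:
    def test_hand_computed_diversity(self):
        # 4 haplotypes, one SNP at p = 0.5, window of 100 bp:
        # pi = 2 * 0.25 * (4/3) / 100 = 1/150
        mat = np.array([[1, 0], [1, 1], [0, 0], [0, 1]], dtype=np.uint8)
        # column 0: p = 0.5; column 1 also segregates (needed by invariants)
        sample = HaplotypeSample(mat, np.array([10, 500]), np.array([0.0, 1e-4]), 1000)
        # 20,000 cM/Mb: each 100 bp spans one 2 cM window
        windows = partition_windows(GenomeMap({"1": RecombinationMap.uniform(1000, 20_000.0)}))
        w = [x for x in windows if x.start_bp <= 10 < x.end_bp][0]
        stats = window_stats(sample, w, min_pairs=10 ** 9)
        assert w.end_bp - w.start_bp == 100
        contrib = 2 * 0.25 * (4 / 3) / 100
        assert stats["pi"] == pytest.approx(contrib)
        assert stats["P"] == pytest.approx(1 / 100)
        assert stats["maf_mean"] == pytest.approx(0.5)

    def test_rr_mean_of_uniform_window(self):
        mat = np.array([[1, 0], [0, 1], [0, 0], [1, 1]], dtype=np.uint8)
        sample = HaplotypeSample(mat, np.array([100, 1_500_000]),
                                 np.array([1e-6, 0.015]), 2_000_000)
        windows = partition_windows(GenomeMap({"1": RecombinationMap.uniform(2_000_000, 1.0)}))
        stats = window_stats(sample, windows[0], min_pairs=10 ** 9)
        assert stats["rr_mean"] == pytest.approx(1.0)

    def test_empty_window_has_zero_diversity(self):
        mat = np.array([[1, 0], [0, 1], [0, 0], [1, 1]], dtype=np.uint8)
        sample = HaplotypeSample(mat, np.array([100, 200]), np.array([0.0, 1e-5]),
                                 4_000_000)
        windows = partition_windows(GenomeMap({"1": RecombinationMap.uniform(4_000_000, 1.0)}))
        stats = window_stats(sample, windows[1], min_pairs=10 ** 9)
        assert stats["pi"] == 0.0
        assert stats["P"] == 0.0


class TestFilter:
    def _stats(self):
        return pd.DataFrame({
            "ne_ld": [500.0, -12.0, 100_001.0, 99_999.0, np.nan, 2000.0],
            "n_pairs_in_c_range": [300_000, 300_000, 300_000, 300_000, 300_000, 249_999],
        })

    def test_exclusion_rules(self):
        kept, counts = filter_windows(self._stats())
        assert counts["total"] == 6
        assert counts["kept"] == 2
        assert set(kept["ne_ld"]) == {500.0, 99_999.0}
        # negative, > 100,000 and NaN fall under the Ne rule; the
        # 249,999-pair window under the pair rule
        assert counts["excluded_ne_out_of_range"] == 3
        assert counts["excluded_insufficient_pairs"] == 1

    def test_filter_conserves_window_count(self):
        kept, counts = filter_windows(self._stats())
        assert (counts["kept"] + counts["excluded_ne_out_of_range"]
                + counts["excluded_insufficient_pairs"]) == counts["total"]

    def test_boundary_pair_count_is_strict(self):
        stats = pd.DataFrame({"ne_ld": [100.0, 100.0],
                              "n_pairs_in_c_range": [250_000, 250_001]})
        kept, _ = filter_windows(stats)
        assert len(kept) == 1

    def test_all_windows_failing_yields_clean_empty_result(self):
        stats = pd.DataFrame({"ne_ld": [-1.0], "n_pairs_in_c_range": [0]})
        kept, counts = filter_windows(stats)
        assert kept.empty
        results = correlate(kept.assign(pi=[], rr_mean=[]) if kept.empty else kept,
                            [("pi", "rr_mean")])
        assert results[0].reason is not None


class TestCorrelate:
    def _frame(self, x, y):
        return pd.DataFrame({"pi": x, "rr_mean": y})

    def test_perfect_monotone_association(self):
        x = np.arange(10.0)
        res = correlate(self._frame(x, 2 * x), [("pi", "rr_mean")])[0]
        assert res.rho == pytest.approx(1.0)
        res = correlate(self._frame(x, -x), [("pi", "rr_mean")])[0]
        assert res.rho == pytest.approx(-1.0)

    def test_textbook_rank_example(self):
        # ranks (1..5) vs (2,1,4,3,5): rho = 1 - 6*4/120 = 0.8
        res = correlate(self._frame([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]),
                        [("pi", "rr_mean")])[0]
        assert res.rho == pytest.approx(0.8)

    def test_invariance_under_monotone_transform(self, rng):
        x = rng.random(50)
        y = rng.random(50)
        base = correlate(self._frame(x, y), [("pi", "rr_mean")])[0].rho
        trans = correlate(self._frame(np.exp(3 * x), y ** 3 + y),
                          [("pi", "rr_mean")])[0].rho
        assert trans == pytest.approx(base)

    def test_constant_variable_reported_not_raised(self):
        res = correlate(self._frame(np.ones(10), np.arange(10.0)),
                        [("pi", "rr_mean")])[0]
        assert np.isnan(res.rho)
        assert res.reason == "constant variable"

    def test_p_value_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(200), rng.random(200)
        res = correlate(self._frame(x, y), [("pi", "rr_mean")])[0]
        rho, n = res.rho, res.n_windows
        from scipy import stats as sps
        t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), n - 2))

    def test_matrix_is_symmetric_with_unit_diagonal(self, rng):
        stats = pd.DataFrame({"pi": rng.random(30), "ne_ld": rng.random(30),
                              "rr_mean": rng.random(30)})
        mat = correlation_matrix(stats, ["pi", "ne_ld", "rr_mean"])
        np.testing.assert_allclose(mat.values, mat.values.T)
        np.testing.assert_allclose(np.diag(mat.values), 1.0)


class TestTracks:
    def _windows(self):
        return partition_windows(uniform_genome(6_000_000, 1.0))  # 3 windows of 2 Mb

    def test_gene_spanning_windows_assigned_by_midpoint(self):
        windows = self._windows()
        # interval straddles the first boundary; midpoint in window 1
        track = pd.DataFrame({"chrom": ["1"], "start": [1_900_000],
                              "end": [2_300_000], "value": [1.0]})
        counts = aggregate_track(windows, track, mode="midpoint_sum")
        np.testing.assert_allclose(counts, [0.0, 1.0, 0.0])

    def test_value_track_overlap_weighted_mean(self):
        windows = self._windows()
        track = pd.DataFrame({"chrom": ["1", "1"],
                              "start": [0, 1_000_000],
                              "end": [1_000_000, 2_000_000],
                              "value": [0.4, 0.8]})
        means = aggregate_track(windows, track, mode="mean")
        assert means[0] == pytest.approx(0.6)
        assert np.isnan(means[1]) and np.isnan(means[2])  # no coverage
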