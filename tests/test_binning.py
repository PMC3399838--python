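"""Bin partitioning, bin-average covariates and the F2 bin-variance theory."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binsel import (
    GenotypeMatrix,
    MarkerMap,
    bin_average,
    make_bins,
    simulate_f2,
    theoretical_bin_variance,
)
from binsel.simulate import evenly_spaced_map


class TestMakeBins:
    @pytest.mark.parametrize(
        "size, n_bins", [(1, 2400), (2, 1200), (5, 480), (10, 240),
                         (20, 120), (40, 60), (100, 24)]
    )
    def test_2400_cM_chromosome_bin_counts(self, size, n_bins):
        mm = evenly_spaced_map(2400.0, 1.0)  # marker-per-cM grid suffices
        part = make_bins(mm, size, "cM")
        assert part.m == n_bins

    def test_single_bin_when_size_spans_genome(self, small_map):
        part = make_bins(small_map, 200.0, "cM")
        assert part.m == 1 and part.p_k[0] == small_map.n_markers

    def test_truncated_final_bin(self):
        mm = evenly_spaced_map(100.0, 10.0)
        part = make_bins(mm, 30.0, "cM")
        widths = part.end - part.start
        np.testing.assert_allclose(widths, [30, 30, 30, 10])

    def test_boundary_marker_goes_to_right_bin(self):
        mm = MarkerMap(["a", "b", "c"], ["1"] * 3, genetic_pos=[0.0, 10.0, 15.0])
        part = make_bins(mm, 10.0, "cM")
        # marker exactly at 10.0 starts the second (half-open) bin
        assert list(part.marker_bin) == [0, 1, 1]

    def test_chromosome_end_marker_included_in_last_bin(self):
        mm = evenly_spaced_map(100.0, 10.0)
        part = make_bins(mm, 10.0, "cM")
        assert part.m == 10
        assert part.p_k[-1] == 2  # markers at 90 and at the 100 cM end

    def test_empty_bins_flagged_not_dropped(self):
        mm = MarkerMap(["a", "b"], ["1", "1"], genetic_pos=[0.0, 95.0])
        part = make_bins(mm, 10.0, "cM")
        assert part.m == 10
        assert part.empty.sum() == 8
        assert part.p_k.sum() == 2

    def test_log10_bp_unit(self):
        mm = MarkerMap(
            ["a", "b", "c"], ["1"] * 3, physical_pos=[0.0, 5e5, 2.5e6]
        )
        part = make_bins(mm, 6.0, "log10_bp")  # 10^6 bp bins
        assert part.m == 3
        assert list(part.p_k) == [2, 0, 1]

    def test_markers_unit(self, small_map):
        part = make_bins(small_map, 5, "markers")
        assert part.m == 5  # 21 markers -> 5,5,5,5,1
        assert list(part.p_k) == [5, 5, 5, 5, 1]

    def test_missing_unit_in_map_is_error(self, small_map):
        with pytest.raises(ValueError, match="physical"):
            make_bins(small_map, 1e6, "bp")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        size=st.floats(min_value=0.5, max_value=500.0),
        n_markers=st.integers(min_value=1, max_value=60),
    )
    def test_tiling_invariant(self, size, n_markers):
        """Every marker lands in exactly one bin; counts sum to p."""
        rng = np.random.default_rng(7)
        pos = np.sort(rng.uniform(0, 400, size=n_markers))
        pos[0] = 0.0
        pos = np.unique(pos)
        mm = MarkerMap(
            [f"m{i}" for i in range(len(pos))], ["1"] * len(pos),
            genetic_pos=pos,
        )
        part = make_bins(mm, size, "cM")
        assert part.p_k.sum() == len(pos)
        counts = np.bincount(part.marker_bin, minlength=part.m)
        np.testing.assert_array_equal(counts, part.p_k)

    def test_refining_partition_preserves_marker_set(self, small_map):
        coarse = make_bins(small_map, 40.0, "cM")
        fine = make_bins(small_map, 20.0, "cM")
        assert coarse.p_k.sum() == fine.p_k.sum() == small_map.n_markers
        # each fine bin maps inside exactly one coarse bin
        for k in range(fine.m):
            members = np.flatnonzero(fine.marker_bin == k)
            if members.size:
                assert len(set(coarse.marker_bin[members])) == 1


class TestBinAverage:
    def test_single_marker_bins_reproduce_genotypes(self, f2_small, small_map):
        part = make_bins(small_map, 1, "markers")
        B = bin_average(f2_small, part)
        np.testing.assert_array_equal(B.values, f2_small.values)

    def test_forced_arithmetic(self):
        mm = evenly_spaced_map(2.0, 1.0)
        G = GenotypeMatrix([[1.0, 1.0, 0.0], [-1.0, 0.0, 0.0]], ["i1", "i2"])
        part = make_bins(mm, 3.0, "cM")
        B = bin_average(G, part)
        np.testing.assert_allclose(B.values[:, 0], [2 / 3, -1 / 3])

    def test_dense_grid_full_bins_have_fifty_markers(self):
        # 0.02 cM spacing with 1 cM bins: 50 markers per full bin
        mm = evenly_spaced_map(20.0, 0.02)
        part = make_bins(mm, 1.0, "cM")
        assert set(part.p_k[:-1]) == {50}

    def test_empty_bin_columns_zero_and_excluded(self):
        mm = MarkerMap(["a", "b"], ["1", "1"], genetic_pos=[0.0, 95.0])
        part = make_bins(mm, 10.0, "cM")
        G = GenotypeMatrix([[1.0, -1.0], [0.0, 1.0]], ["i1", "i2"])
        B = bin_average(G, part)
        assert np.all(B.values[:, part.empty] == 0.0)
        X, cols = B.design_columns()
        assert X.shape[1] == 2 and list(cols) == [0, 9]

    def test_values_bounded_by_unit_interval(self, f2_small, small_map):
        B = bin_average(f2_small, make_bins(small_map, 50.0, "cM"))
        assert np.all(np.abs(B.values) <= 1.0)


class TestTheoreticalBinVariance:
    def test_complete_linkage_is_half(self):
        assert theoretical_bin_variance([7.0] * 10) == pytest.approx(0.5)

    def test_single_marker_is_half(self):
        assert theoretical_bin_variance([3.0]) == pytest.approx(0.5)

    def test_unlinked_markers_give_one_over_2p(self):
        pos = [0.0, 1e5, 2e5, 3e5, 4e5]  # pairwise r = 1/2
        assert theoretical_bin_variance(pos) == pytest.approx(0.1)

    def test_monotone_under_appending_unlinked_marker(self):
        pos = [0.0, 5.0, 12.0]
        v1 = theoretical_bin_variance(pos)
        v2 = theoretical_bin_variance(pos + [1e6])
        assert v2 < v1

    def test_matches_monte_carlo_bin_average_variance(self):
        """Empirical Var(Zbar) from simulation within 3 MC standard errors."""
        rng = np.random.default_rng(99)
        n = 20000
        for _ in range(4):
            p = rng.integers(2, 7)
            pos = np.sort(rng.uniform(0.0, 40.0, size=p))
            pos = np.unique(pos)
            mm = MarkerMap(
                [f"m{i}" for i in range(len(pos))], ["1"] * len(pos),
                genetic_pos=pos,
            )
            G = simulate_f2(n, mm, seed=int(rng.integers(2**31)))
            zbar = G.values.mean(axis=1)
            emp = zbar.var(ddof=1)
            m4 = np.mean((zbar - zbar.mean()) ** 4)
            se = np.sqrt(max(m4 - emp**2, 0.0) / n)
            assert abs(emp - theoretical_bin_variance(pos)) < 3 * se
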