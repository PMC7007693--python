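"""Decay weight, chrom-RP / peak-RP, normalization, percentiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromisd import (
    GenomeGrid,
    RPParams,
    chrom_rp,
    decay_weight,
    normalize_rp,
    peak_rp,
    rp_percentile,
)
from chromisd.grid import GeneAnnotation
from chromisd.store import Cistrome
from conftest import oracle_chrom_rp

PARAMS = RPParams()


class TestDecayWeight:
    def test_closed_forms(self):
        assert decay_weight(0, PARAMS) == pytest.approx(1.0, abs=1e-15)
        assert decay_weight(PARAMS.delta, PARAMS) == pytest.approx(0.5, abs=1e-12)
        expected_at_L = 2 * 3.0**-10 / (1 + 3.0**-10)
        assert decay_weight(PARAMS.L, PARAMS) == pytest.approx(
            expected_at_L, rel=1e-12
        )

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 500_000), st.integers(1, 500_000))
    def test_strictly_decreasing_and_bounded(self, d, step):
        w1, w2 = decay_weight(d, PARAMS), decay_weight(d + step, PARAMS)
        assert 0 < w2 < w1 <= 1.0

    def test_vectorized_matches_scalar(self):
        d = np.array([0, 5_000, 10_000, 50_000])
        vec = decay_weight(d, PARAMS)
        assert vec == pytest.approx([decay_weight(int(x), PARAMS) for x in d])

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            decay_weight(-1, PARAMS)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            RPParams(L=100, delta=100)


class TestChromRP:
    def _grid(self, length=1_000_000):
        return GenomeGrid(("chr1",), (length,))

    def test_zero_track_gives_zero(self):
        grid = self._grid()
        gene = GeneAnnotation("G", "chr1", 500_000)
        assert chrom_rp(np.zeros(grid.window_count), gene, grid, PARAMS) == 0.0

    def test_uniform_signal_equals_weight_sum(self):
        grid = self._grid()
        gene = GeneAnnotation("G", "chr1", 500_000)
        ones = np.ones(grid.window_count)
        expected = oracle_chrom_rp(ones, gene, grid, PARAMS)
        assert chrom_rp(ones, gene, grid, PARAMS) == pytest.approx(
            expected, rel=1e-12
        )

    def test_single_window_at_tss(self):
        grid = self._grid()
        gene = GeneAnnotation("G", "chr1", 500_500)  # window midpoint
        values = np.zeros(grid.window_count)
        values[500] = 2.0
        assert chrom_rp(values, gene, grid, PARAMS) == pytest.approx(2.0)

    def test_linearity_in_signal(self):
        grid = self._grid(300_000)
        gene = GeneAnnotation("G", "chr1", 150_000)
        rng = np.random.default_rng(0)
        s1, s2 = rng.random(grid.window_count), rng.random(grid.window_count)
        combo = chrom_rp(3.0 * s1 + 0.5 * s2, gene, grid, PARAMS)
        assert combo == pytest.approx(
            3.0 * chrom_rp(s1, gene, grid, PARAMS)
            + 0.5 * chrom_rp(s2, gene, grid, PARAMS),
            rel=1e-12,
        )

    def test_matches_bruteforce_oracle_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n_windows = int(rng.integers(50, 400))
            grid = GenomeGrid(("chr1",), (n_windows * 1000 - 137,))
            values = rng.random(grid.window_count)
            tss = int(rng.integers(0, grid.chrom_length("chr1")))
            gene = GeneAnnotation("G", "chr1", tss)
            assert chrom_rp(values, gene, grid, PARAMS) == pytest.approx(
                oracle_chrom_rp(values, gene, grid, PARAMS), rel=1e-12, abs=1e-12
            )

    def test_interval_truncated_at_chromosome_ends(self):
        grid = self._grid(150_000)
        gene = GeneAnnotation("G", "chr1", 10_000)  # -L reaches past the start
        values = np.ones(grid.window_count)
        assert chrom_rp(values, gene, grid, PARAMS) == pytest.approx(
            oracle_chrom_rp(values, gene, grid, PARAMS), rel=1e-12
        )


class TestPeakRP:
    def _setup(self):
        grid = GenomeGrid(("chr1",), (1_000_000,))
        gene = GeneAnnotation("G", "chr1", 500_500)
        return grid, gene

    def _cistrome(self, windows):
        return Cistrome("c", "TR", "chipseq_peaks", np.array(windows))

    def test_no_occupied_window_in_range(self):
        grid, gene = self._setup()
        c = self._cistrome([900])  # ~400 kb away
        assert peak_rp(c, gene, grid, PARAMS) == 0.0

    def test_window_at_half_decay_distance_scores_half(self):
        grid, gene = self._setup()
        # window 510 midpoint 510500 is exactly delta = 10 kb from the TSS
        c = self._cistrome([510])
        assert peak_rp(c, gene, grid, PARAMS) == pytest.approx(0.5, abs=1e-12)

    def test_additive_over_disjoint_union(self):
        grid, gene = self._setup()
        a, b = self._cistrome([495, 500]), self._cistrome([505, 540])
        union = self._cistrome([495, 500, 505, 540])
        assert peak_rp(union, gene, grid, PARAMS) == pytest.approx(
            peak_rp(a, gene, grid, PARAMS) + peak_rp(b, gene, grid, PARAMS),
            rel=1e-12,
        )


class TestNormalizeRP:
    def test_constant_column_maps_to_zero(self):
        rp = normalize_rp(np.full((4, 1), 7.0), list("abcd"), ["p"])
        assert rp.normalized == pytest.approx(np.zeros((4, 1)), abs=1e-12)

    def test_hand_computed_offsets(self):
        raw = np.array([[0.0], [np.e - 1.0]])
        rp = normalize_rp(raw, ["a", "b"], ["p"])
        assert rp.norm_offset[0] == pytest.approx(0.5)
        assert rp.normalized[:, 0] == pytest.approx([-0.5, 0.5])

    def test_column_means_are_zero(self):
        rng = np.random.default_rng(1)
        raw = rng.random((30, 4)) * 100
        rp = normalize_rp(raw, [f"g{i}" for i in range(30)], list("wxyz"))
        assert np.abs(rp.normalized.mean(axis=0)).max() < 1e-9

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        raw = rng.random((10, 2))
        perm = rng.permutation(10)
        a = normalize_rp(raw, [f"g{i}" for i in range(10)], ["p", "q"])
        b = normalize_rp(raw[perm], [f"g{i}" for i in perm], ["p", "q"])
        assert a.norm_offset == pytest.approx(b.norm_offset)

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(ValueError):
            normalize_rp(np.empty((0, 1)), [], ["p"])
        with pytest.raises(ValueError):
            normalize_rp(np.array([[-1.0]]), ["g"], ["p"])


class TestRPPercentile:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3], [1 / 3, 2 / 3, 1.0]),
            ([5, 5, 5, 5], [0.625] * 4),  # (n+1)/(2n) with n = 4
            ([42], [1.0]),
            ([3, 1, 2], [1.0, 1 / 3, 2 / 3]),
        ],
    )
    def test_average_rank_convention(self, values, expected):
        assert rp_percentile(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rp_percentile([])
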