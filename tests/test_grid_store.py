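"""Genome grid, signal binning, peak loading and HDF5 store round-trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromisd import (
    CompendiumStore,
    GenomeGrid,
    StoreIntegrityError,
    bin_signal,
    load_peaks,
    load_store,
    save_store,
)
from chromisd.grid import GeneAnnotation, validate_genes
from chromisd.rp import build_rp_cache
from chromisd.store import BinnedSignalTrack, Cistrome


class TestGenomeGrid:
    def test_window_count_is_sum_of_ceils(self, small_grid):
        expected = math.ceil(10_000 / 1000) + math.ceil(5_500 / 1000)
        assert small_grid.window_count == expected == 16

    def test_global_index_bijection(self, small_grid):
        seen = set()
        for gidx in range(small_grid.window_count):
            chrom, start, end = small_grid.window_bounds(gidx)
            assert start < end <= small_grid.chrom_length(chrom)
            assert small_grid.window_of(chrom, start) == gidx
            seen.add((chrom, start))
        assert len(seen) == small_grid.window_count

    def test_partial_last_window_kept(self, small_grid):
        chrom, start, end = small_grid.window_bounds(small_grid.window_count - 1)
        assert (chrom, start, end) == ("chr2", 5000, 5500)
        assert small_grid.midpoints("chr2")[-1] == 5250.0

    def test_invalid_construction(self):
        with pytest.raises(ValueError):
            GenomeGrid(("chr1", "chr1"), (100, 100))
        with pytest.raises(ValueError):
            GenomeGrid(("chr1",), (0,))


class TestBinSignal:
    def test_constant_coverage_reproduced(self, small_grid):
        track = bin_signal([("chr1", 0, 1000, 2.0)], small_grid)
        assert track.values[0] == pytest.approx(2.0)

    def test_half_covered_window_is_length_weighted(self, small_grid):
        track = bin_signal([("chr1", 0, 500, 4.0)], small_grid)
        assert track.values[0] == pytest.approx(2.0)

    def test_empty_input_gives_zero_track(self, small_grid):
        track = bin_signal([], small_grid)
        assert np.all(track.values == 0)

    def test_unknown_chromosome_rejected_with_record_named(self, small_grid):
        with pytest.raises(ValueError, match="chrX:0-100"):
            bin_signal([("chrX", 0, 100, 1.0)], small_grid)

    def test_negative_value_rejected(self, small_grid):
        with pytest.raises(ValueError, match="invalid signal"):
            bin_signal([("chr1", 0, 100, -1.0)], small_grid)

    def test_partial_final_window_averages_over_actual_span(self, small_grid):
        track = bin_signal([("chr2", 5000, 5500, 3.0)], small_grid)
        assert track.values[-1] == pytest.approx(3.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 9_900),
                st.integers(1, 800),
                st.floats(0.0, 10.0, allow_nan=False),
            ),
            min_size=1,
            max_size=15,
        )
    )
    def test_mass_conservation(self, raw):
        grid = GenomeGrid(("chr1",), (10_000,), window_size=1000)
        intervals = [
            ("chr1", s, min(s + l, 10_000), v) for s, l, v in raw if s + 1 <= 10_000
        ]
        track = bin_signal(intervals, grid)
        in_mass = sum(v * (e - s) for _, s, e, v in intervals)
        out_mass = float(np.sum(track.values * grid.window_lengths("chr1")))
        assert out_mass == pytest.approx(in_mass, rel=1e-9, abs=1e-9)


class TestLoadPeaks:
    def test_midpoint_summit_maps_to_window(self, small_grid):
        c = load_peaks([("chr1", 1500, 1700)], small_grid)
        assert list(c.occupied_windows) == [1]

    def test_same_window_summits_collapse(self, small_grid):
        c = load_peaks([("chr1", 1100, 1200), ("chr1", 1700, 1800)], small_grid)
        assert list(c.occupied_windows) == [1]

    def test_summit_rule_not_span_rule(self, small_grid):
        # peak spans windows 0 and 1 but its summit is in window 1
        c = load_peaks([("chr1", 800, 1600)], small_grid)
        assert list(c.occupied_windows) == [1]

    def test_explicit_summit_offset(self, small_grid):
        c = load_peaks([("chr1", 0, 3000, 2500)], small_grid)
        assert list(c.occupied_windows) == [2]

    def test_malformed_record_names_line(self, small_grid):
        with pytest.raises(ValueError, match="line 2"):
            load_peaks([("chr1", 100, 200), ("chr1", 300, 250)], small_grid)
        with pytest.raises(ValueError, match="line 1"):
            load_peaks([("chr1", 100, 200, 150)], small_grid)

    def test_idempotent_under_duplication(self, small_grid):
        recs = [("chr1", 1500, 1700), ("chr2", 100, 300)]
        once = load_peaks(recs, small_grid)
        twice = load_peaks(recs + recs, small_grid)
        assert np.array_equal(once.occupied_windows, twice.occupied_windows)


class TestStoreRoundTrip:
    def _make_store(self):
        grid = GenomeGrid(("chr1", "chr2"), (10_000, 5_500))
        genes = [
            GeneAnnotation("GA", "chr1", 4000, "+"),
            GeneAnnotation("GB", "chr2", 2000, "-"),
        ]
        rng = np.random.default_rng(5)
        tracks = [
            BinnedSignalTrack("d0", "dnase", rng.random(grid.window_count)),
            BinnedSignalTrack("k0", "h3k27ac", rng.random(grid.window_count)),
        ]
        cistromes = [
            Cistrome("c0", "TRX", "chipseq_peaks", np.array([1, 5, 12]),
                     summits={"chr1": np.array([1500, 5100])}),
        ]
        import pandas as pd

        store = CompendiumStore(
            grid=grid, genes=genes, tracks=tracks, cistromes=cistromes,
            covariates=pd.Series([1.0, 2.0], index=["GA", "GB"]),
        )
        build_rp_cache(store)
        return store

    def test_lossless_round_trip(self, tmp_path):
        store = self._make_store()
        path = tmp_path / "store.h5"
        save_store(store, path)
        loaded = load_store(path)
        assert loaded.grid == store.grid
        assert loaded.genes == store.genes
        for a, b in zip(loaded.tracks, store.tracks):
            assert a.profile_id == b.profile_id and a.assay_kind == b.assay_kind
            assert np.array_equal(a.values, b.values)
        for a, b in zip(loaded.cistromes, store.cistromes):
            assert np.array_equal(a.occupied_windows, b.occupied_windows)
            assert a.summits.keys() == b.summits.keys()
        # RP values preserved bitwise
        assert np.array_equal(loaded.rp_cache.raw, store.rp_cache.raw)
        assert np.array_equal(loaded.rp_cache.norm_offset, store.rp_cache.norm_offset)

    def test_missing_path_errors(self, tmp_path):
        with pytest.raises(OSError):
            load_store(tmp_path / "nope.h5")

    def test_corrupted_array_reported(self, tmp_path):
        store = self._make_store()
        path = tmp_path / "store.h5"
        save_store(store, path)
        blob = bytearray(path.read_bytes())
        # flip a bit inside a known stored array value
        needle = np.ascontiguousarray(store.tracks[0].values).tobytes()[:32]
        at = bytes(blob).find(needle)
        assert at > 0, "array bytes not located in file"
        blob[at + 3] ^= 0xFF
        path.write_bytes(bytes(blob))
        with pytest.raises(StoreIntegrityError, match="checksum"):
            load_store(path)

    def test_annotation_invariants_enforced(self, small_grid):
        with pytest.raises(ValueError, match="duplicate gene_id"):
            validate_genes(
                [GeneAnnotation("G", "chr1", 1), GeneAnnotation("G", "chr1", 2)],
                small_grid,
            )
        with pytest.raises(ValueError, match="outside"):
            validate_genes([GeneAnnotation("G", "chr1", 10_000)], small_grid)
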