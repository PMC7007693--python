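"""Rank-sum tests, Cauchy combination, baseline and direct/indirect split."""

import itertools

import numpy as np
import pytest
from scipy.stats import kstest

from chromisd import (
    GeneSetPair,
    GenomeGrid,
    baseline_promoter_count,
    cauchy_combine,
    combine_channels,
    split_direct_indirect,
    wilcoxon_one_sided,
)
from chromisd.grid import GeneAnnotation
from chromisd.motifs import MotifHitSet
from chromisd.store import Cistrome


def enumeration_p(query, background):
    """Exact one-sided rank-sum p by enumerating all label assignments.

    Average ranks handle ties, so the oracle also covers tied data (where
    the implementation switches to the corrected normal approximation)."""
    from scipy.stats import rankdata

    allv = list(query) + list(background)
    ranks = rankdata(allv, method="average")
    n = len(query)
    obs = ranks[:n].sum()
    count = total = 0
    for combo in itertools.combinations(range(len(allv)), n):
        total += 1
        if ranks[list(combo)].sum() >= obs - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_exact_textbook_case(self):
        assert wilcoxon_one_sided([3, 4, 5], [0, 1, 2]) == pytest.approx(1 / 20)

    def test_constant_samples_no_evidence(self):
        assert wilcoxon_one_sided([2.0, 2.0], [2.0, 2.0, 2.0]) >= 0.5

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n, m = int(rng.integers(3, 7)), int(rng.integers(3, 8))
            vals = rng.permutation(100)[: n + m].astype(float).tolist()
            q, b = vals[:n], vals[n:]
            assert wilcoxon_one_sided(q, b) == pytest.approx(enumeration_p(q, b))

    def test_swap_symmetry_no_ties(self):
        q, b = [9.0, 4.0, 7.0], [1.0, 6.0, 3.0, 2.0]
        p_fwd = wilcoxon_one_sided(q, b)
        p_rev = wilcoxon_one_sided(b, q)
        assert p_fwd == pytest.approx(enumeration_p(q, b))
        assert p_rev == pytest.approx(enumeration_p(b, q))
        # the two one-sided tails overlap exactly on the observed statistic
        assert p_fwd + p_rev > 1.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(2000):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            ps.append(wilcoxon_one_sided(x, y))
        stat = kstest(ps, "uniform").statistic
        assert stat < 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sided([], [1.0])


class TestCauchyCombine:
    def test_neutral_inputs(self):
        assert cauchy_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    @pytest.mark.parametrize("p", [0.001, 0.05, 0.3, 0.7, 0.999])
    def test_identity_on_repeated_p(self, p):
        assert cauchy_combine([p, p]) == pytest.approx(p, abs=1e-12)
        assert cauchy_combine([p] * 5) == pytest.approx(p, abs=1e-12)

    def test_numeric_check_against_direct_evaluation(self):
        p = np.array([0.01, 0.5, 0.5])
        t = np.mean(np.tan((0.5 - p) * np.pi))
        direct = 0.5 - np.arctan(t) / np.pi
        combined = cauchy_combine(p)
        assert combined == pytest.approx(direct, rel=1e-12)
        assert combined == pytest.approx(0.0299, abs=5e-4)

    def test_extreme_values_clamped_finite(self):
        assert 0 < cauchy_combine([0.0, 0.5]) < 1
        assert 0 < cauchy_combine([1.0, 1.0]) < 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([])


class TestCombineChannels:
    META = {
        "c1": ("TRA", "chipseq_peaks"),
        "c2": ("TRB", "chipseq_peaks"),
        "c3": ("TRB", "chipseq_peaks"),
    }

    def _channels(self, **over):
        base = {
            "c1": {"peak_rp": 0.5, "isd_dnase": 0.5, "isd_h3k27ac": 0.5},
            "c2": {"peak_rp": 0.5, "isd_dnase": 0.5, "isd_h3k27ac": 0.5},
            "c3": {"peak_rp": 0.5, "isd_dnase": 0.5, "isd_h3k27ac": 0.5},
        }
        for cid, chans in over.items():
            base[cid].update(chans)
        return base

    def test_neutral_channels_combine_to_half(self):
        table = combine_channels(self._channels(), self.META).table
        assert table["p_combined"].to_numpy() == pytest.approx([0.5] * 3)

    def test_strong_cistrome_ranks_first(self):
        chans = self._channels(
            c2={"peak_rp": 0.001, "isd_dnase": 0.001, "isd_h3k27ac": 0.001}
        )
        result = combine_channels(chans, self.META)
        assert result.rank_of("c2") == 1
        assert result.tr_rank_of("TRB") == 1

    def test_motif_mode_ignores_peak_channel(self):
        chans = self._channels(c1={"peak_rp": 1e-9})
        result = combine_channels(chans, self.META, mode="motif")
        assert result.table["p_combined"].to_numpy() == pytest.approx([0.5] * 3)
        assert result.table["p_peak_rp"].isna().all()

    def test_missing_channel_skipped_with_warning(self):
        chans = self._channels()
        del chans["c3"]["isd_dnase"]
        with pytest.warns(UserWarning, match="c3"):
            result = combine_channels(chans, self.META)
        assert "c3" not in set(result.table["cistrome_id"])

    def test_order_invariance_up_to_tiebreak(self):
        chans = self._channels(
            c1={"peak_rp": 0.01}, c3={"isd_dnase": 0.2}
        )
        a = combine_channels(chans, self.META).table
        reordered = {k: chans[k] for k in reversed(list(chans))}
        b = combine_channels(reordered, self.META).table
        assert list(a["cistrome_id"]) == list(b["cistrome_id"])

    def test_per_tr_summary_takes_best_cistrome(self):
        chans = self._channels(c3={"peak_rp": 0.001})
        result = combine_channels(chans, self.META)
        row = result.tr_summary[result.tr_summary["tr_name"] == "TRB"]
        assert row["best_cistrome"].iloc[0] == "c3"


class TestBaseline:
    def _setup(self):
        grid = GenomeGrid(("chr1",), (100_000,))
        genes = [
            GeneAnnotation(f"g{i}", "chr1", 10_000 + 20_000 * i) for i in range(5)
        ]
        sets = GeneSetPair(("g0", "g1"), ("g2", "g3", "g4"))
        return grid, genes, sets

    def test_no_summits_gives_no_evidence(self):
        grid, genes, sets = self._setup()
        c = Cistrome("c", "TR", "chipseq_peaks", np.array([], dtype=np.int64),
                     summits={"chr1": np.array([], dtype=np.int64)})
        assert baseline_promoter_count(c, genes, sets, grid) == 1.0

    def test_query_only_summits_match_enumeration(self):
        grid, genes, sets = self._setup()
        c = Cistrome("c", "TR", "chipseq_peaks", np.array([10, 30]),
                     summits={"chr1": np.array([10_000, 30_000])})
        p = baseline_promoter_count(c, genes, sets, grid)
        # counting must yield query (1, 1) vs background (0, 0, 0); the
        # heavy zero ties route through the corrected normal approximation
        assert p == pytest.approx(wilcoxon_one_sided([1.0, 1.0], [0.0, 0.0, 0.0]))
        assert p < 0.05

    def test_boundary_summit_included(self):
        grid, genes, sets = self._setup()
        # summit exactly at tss + 5000 for g0 (closed interval)
        c = Cistrome("c", "TR", "chipseq_peaks", np.array([15]),
                     summits={"chr1": np.array([15_000])})
        p_with = baseline_promoter_count(c, genes, sets, grid)
        c_out = Cistrome("c", "TR", "chipseq_peaks", np.array([15]),
                         summits={"chr1": np.array([15_001])})
        p_without = baseline_promoter_count(c_out, genes, sets, grid)
        assert p_with < p_without


class TestDirectIndirect:
    def _cistrome(self, windows):
        return Cistrome("c", "TR", "chipseq_peaks", np.array(windows))

    def _hits(self, windows):
        return MotifHitSet(motif_id="m", scores={},
                           hits=np.array(windows, dtype=np.int64))

    def test_hits_cover_peaks_means_no_indirect(self):
        direct, indirect = split_direct_indirect(
            self._cistrome([1, 2, 3]), self._hits([1, 2, 3, 4])
        )
        assert list(direct.occupied_windows) == [1, 2, 3]
        assert indirect.occupied_windows.size == 0

    def test_disjoint_hits_means_no_direct(self):
        direct, indirect = split_direct_indirect(
            self._cistrome([1, 2]), self._hits([5, 6])
        )
        assert direct.occupied_windows.size == 0
        assert list(indirect.occupied_windows) == [1, 2]

    def test_partition_is_exact_and_disjoint(self):
        occ = [1, 4, 7, 9, 12]
        direct, indirect = split_direct_indirect(
            self._cistrome(occ), self._hits([4, 9, 20])
        )
        got = np.union1d(direct.occupied_windows, indirect.occupied_windows)
        assert list(got) == occ
        assert not set(direct.occupied_windows) & set(indirect.occupied_windows)

    def test_empty_hits_warns_all_indirect(self):
        with pytest.warns(UserWarning, match="indirect"):
            direct, indirect = split_direct_indirect(
                self._cistrome([1, 2]), self._hits([])
            )
        assert direct.occupied_windows.size == 0
        assert list(indirect.occupied_windows) == [1, 2]
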