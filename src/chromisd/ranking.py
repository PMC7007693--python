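"""Rank-sum testing, Cauchy p-value combination, and final TR ranking.

Each candidate cistrome accumulates up to three evidence channels — peak-RP,
DNase-seq ISD and H3K27ac ISD — each tested one-sided (query stochastically
greater than background) with the Wilcoxon rank-sum test.  Channel p-values
are combined with the Cauchy combination test,

    t = sum_i w_i tan((0.5 - p_i) pi),    p_combined = 1/2 - arctan(t)/pi,

with uniform weights 1/d (d = 3 for ChIP-seq-based ranking, 2 for
motif-based), which is robust to dependence among channels.  Cistromes are
ranked ascending by combined p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .grid import GeneAnnotation, GenomeGrid
from .landscape import GeneSetPair
from .motifs import MotifHitSet
from .rp import rp_percentile
from .store import Cistrome

P_CLAMP = 1e-15

CHIPSEQ_CHANNELS = ("peak_rp", "isd_dnase", "isd_h3k27ac")
MOTIF_CHANNELS = ("isd_dnase", "isd_h3k27ac")


def wilcoxon_one_sided(
    query_values: np.ndarray, background_values: np.ndarray
) -> float:
    """One-sided Wilcoxon rank-sum p: are query values stochastically greater?

    Exact enumeration when min(n, m) <= 8 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.  Samples
    that are entirely one constant carry no evidence and return 1.
    """
    q = np.asarray(query_values, dtype=np.float64)
    b = np.asarray(background_values, dtype=np.float64)
    if q.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([q, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(q.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(q, b, alternative="greater", method=method)
    return float(min(res.pvalue, 1.0))


def cauchy_combine(
    p_values: Sequence[float], weights: Optional[Sequence[float]] = None
) -> float:
    """Cauchy combination of p-values (uniform weights 1/d by default).

    Inputs are clamped to [1e-15, 1 - 1e-15] before the tangent transform,
    which diverges at 0 and 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("need at least one p-value to combine")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != p.shape:
            raise ValueError("weights must match p-values")
    p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    t = float(np.sum(w * np.tan((0.5 - p) * np.pi)))
    combined = 0.5 - np.arctan(t) / np.pi
    return float(np.clip(combined, P_CLAMP, 1.0 - P_CLAMP))


def cauchy_statistic(p_values: Sequence[float]) -> float:
    """The combination statistic t itself (uniform weights)."""
    p = np.clip(np.asarray(p_values, dtype=np.float64), P_CLAMP, 1.0 - P_CLAMP)
    return float(np.mean(np.tan((0.5 - p) * np.pi)))


@dataclass
class TRRankTable:
    """Ranked cistrome table plus a best-p-per-TR summary."""

    table: pd.DataFrame
    tr_summary: pd.DataFrame
    mode: str

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def rank_of(self, cistrome_id: str) -> int:
        row = self.table[self.table["cistrome_id"] == cistrome_id]
        if row.empty:
            raise KeyError(f"cistrome {cistrome_id!r} not in table")
        return int(row["rank"].iloc[0])

    def tr_rank_of(self, tr_name: str) -> int:
        row = self.tr_summary[self.tr_summary["tr_name"] == tr_name]
        if row.empty:
            raise KeyError(f"TR {tr_name!r} not in summary")
        return int(row["rank"].iloc[0])


def combine_channels(
    channel_pvalues: Mapping[str, Mapping[str, float]],
    cistrome_meta: Mapping[str, Tuple[str, str]],
    mode: str = "chipseq",
) -> TRRankTable:
    """Cauchy-combine per-cistrome channel p-values into the final ranking.

    Parameters
    ----------
    channel_pvalues : cistrome_id -> {channel: p}.  ChIP-seq mode requires
        peak_rp + both ISD channels; motif mode requires the two ISD channels
        (a peak_rp entry, if present, is ignored).  Cistromes missing a
        required channel are skipped with a warning.
    cistrome_meta : cistrome_id -> (tr_name, source).

    Ties on combined p break by smaller mean ISD-channel p, then cistrome_id.
    """
    if mode not in ("chipseq", "motif"):
        raise ValueError("mode must be 'chipseq' or 'motif'")
    required = CHIPSEQ_CHANNELS if mode == "chipseq" else MOTIF_CHANNELS
    rows = []
    for cid in sorted(channel_pvalues):
        chans = channel_pvalues[cid]
        missing = [c for c in required if c not in chans]
        if missing:
            warnings.warn(f"cistrome {cid}: missing channel(s) {missing}; skipped")
            continue
        ps = [float(chans[c]) for c in required]
        tr_name, source = cistrome_meta.get(cid, (cid, "chipseq_peaks"))
        isd_mean = float(np.mean([chans[c] for c in MOTIF_CHANNELS]))
        rows.append(
            {
                "cistrome_id": cid,
                "tr_name": tr_name,
                "source": source,
                "p_peak_rp": float(chans.get("peak_rp", np.nan))
                if mode == "chipseq"
                else np.nan,
                "p_isd_dnase": float(chans["isd_dnase"]),
                "p_isd_h3k27ac": float(chans["isd_h3k27ac"]),
                "t_cauchy": cauchy_statistic(ps),
                "p_combined": cauchy_combine(ps),
                "_isd_mean": isd_mean,
            }
        )
    if not rows:
        raise ValueError("no cistrome had all required channels")
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["p_combined", "_isd_mean", "cistrome_id"], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table = table.drop(columns=["_isd_mean"])

    summary = (
        table.groupby("tr_name", as_index=False)
        .agg(p_combined=("p_combined", "min"), best_cistrome=("cistrome_id", "first"))
        .sort_values("p_combined", kind="stable")
        .reset_index(drop=True)
    )
    summary["rank"] = np.arange(1, len(summary) + 1)
    return TRRankTable(table=table, tr_summary=summary, mode=mode)


def baseline_promoter_count(
    cistrome: Cistrome | MotifHitSet,
    genes: Sequence[GeneAnnotation],
    sets: GeneSetPair,
    grid: Optional[GenomeGrid] = None,
    half_width: int = 5000,
) -> float:
    """Promoter-count baseline: summits within +/-5 kb of the TSS (closed
    interval), one-sided Wilcoxon query vs background on the counts."""
    if isinstance(cistrome, MotifHitSet):
        positions = cistrome.hit_positions
    elif cistrome.summits is not None:
        positions = cistrome.summits
    else:
        if grid is None:
            raise ValueError("grid required to fall back to window midpoints")
        warnings.warn(
            f"cistrome {cistrome.cistrome_id}: no summit positions stored; "
            "using occupied-window midpoints"
        )
        positions = {}
        for gidx in cistrome.occupied_windows:
            chrom, start, end = grid.window_bounds(int(gidx))
            positions.setdefault(chrom, []).append((start + end) // 2)
        positions = {c: np.sort(np.array(v)) for c, v in positions.items()}

    by_id = {g.gene_id: g for g in genes}
    counts = {}
    for gid in sets.all_genes:
        g = by_id[gid]
        pos = positions.get(g.chrom)
        if pos is None or len(pos) == 0:
            counts[gid] = 0
            continue
        lo = np.searchsorted(pos, g.tss - half_width, side="left")
        hi = np.searchsorted(pos, g.tss + half_width, side="right")  # closed end
        counts[gid] = int(hi - lo)
    q = np.array([counts[g] for g in sets.query], dtype=float)
    b = np.array([counts[g] for g in sets.background], dtype=float)
    return wilcoxon_one_sided(q, b)


def split_direct_indirect(
    cistrome: Cistrome, motif_hits: MotifHitSet
) -> Tuple[Cistrome, Cistrome]:
    """Partition a cistrome by cognate-motif support.

    Direct = occupied windows that intersect the TR's motif-hit windows;
    indirect = the set difference.  Together they partition the original
    occupancy.  Summits are carried along by window membership.
    """
    hits = set(motif_hits.hits.tolist())
    if not hits:
        warnings.warn(
            f"cistrome {cistrome.cistrome_id}: empty motif hit set; "
            "all peaks classified indirect"
        )
    occ = cistrome.occupied_windows
    mask = np.array([int(w) in hits for w in occ], dtype=bool)

    def _sub(name: str, windows: np.ndarray) -> Cistrome:
        return Cistrome(
            cistrome_id=f"{cistrome.cistrome_id}.{name}",
            tr_name=cistrome.tr_name,
            source=cistrome.source,
            occupied_windows=windows,
            summits=None,
        )

    return _sub("direct", occ[mask]), _sub("indirect", occ[~mask])
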