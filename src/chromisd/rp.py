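"""Regulatory potential (RP) models.

A gene's RP summarizes genomic signal within +/-L of its TSS, weighted by a
sigmoidal exponential decay in TSS distance:

    w(d) = 2 exp(-mu d/L) / (1 + exp(-mu d/L)),    mu = ln(3) L / Delta

so w(0) = 1 and w(Delta) = 1/2 exactly: Delta is the half-decay distance.
The chrom-RP sums continuous window-mean signal (DNase-seq / H3K27ac); the
peak-RP is the same sum over binary summit occupancy.  Both are evaluated on
the 1-kb binned grid using window-midpoint distances, which makes in silico
deletion exactly consistent (deleting every window drives the RP to zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
from scipy.stats import rankdata

from .grid import GeneAnnotation, GenomeGrid
from .store import BinnedSignalTrack, Cistrome, CompendiumStore, RPMatrixData


@dataclass(frozen=True)
class RPParams:
    """Decay-model parameters.

    L : half-interval around the TSS, bp (default 100 kb)
    delta : half-decay distance, bp (default 10 kb); w(delta) = 1/2
    window_size : grid window width, bp
    """

    L: int = 100_000
    delta: int = 10_000
    window_size: int = 1000

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if not 0 < self.delta < self.L:
            raise ValueError("delta must satisfy 0 < delta < L")

    @property
    def mu(self) -> float:
        """Decay rate on the distance/L scale: exp(-mu*delta/L) = 1/3."""
        return np.log(3.0) * self.L / self.delta


def decay_weight(
    distance_bp: Union[float, np.ndarray], params: RPParams = RPParams()
) -> Union[float, np.ndarray]:
    """Regulatory-influence weight at a genomic distance from the TSS.

    Strictly decreasing, bounded in (0, 1]; w(0) = 1, w(delta) = 1/2.
    Accepts scalars or arrays of non-negative distances in bp.
    """
    d = np.asarray(distance_bp, dtype=np.float64) / params.L
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    x = np.exp(-params.mu * d)
    w = 2.0 * x / (1.0 + x)
    return float(w) if np.isscalar(distance_bp) else w


def gene_window_span(
    gene: GeneAnnotation, grid: GenomeGrid, params: RPParams
) -> Tuple[int, int, np.ndarray]:
    """Global window slice [g0, g1) around the gene's TSS plus decay weights.

    A window belongs to the span iff its midpoint lies within
    [tss - L, tss + L]; the span never crosses a chromosome boundary.
    """
    mids = grid.midpoints(gene.chrom)
    lo = int(np.searchsorted(mids, gene.tss - params.L, side="left"))
    hi = int(np.searchsorted(mids, gene.tss + params.L, side="right"))
    off = grid.offset_index[gene.chrom]
    weights = decay_weight(np.abs(mids[lo:hi] - gene.tss), params)
    return off + lo, off + hi, weights


def chrom_rp(
    track: Union[BinnedSignalTrack, np.ndarray],
    gene: GeneAnnotation,
    grid: GenomeGrid,
    params: RPParams = RPParams(),
) -> float:
    """Continuous-signal RP: sum of decay-weighted window-mean signal."""
    values = track.values if isinstance(track, BinnedSignalTrack) else track
    g0, g1, w = gene_window_span(gene, grid, params)
    return float(np.dot(w, values[g0:g1]))


def peak_rp(
    cistrome: Cistrome,
    gene: GeneAnnotation,
    grid: GenomeGrid,
    params: RPParams = RPParams(),
) -> float:
    """Binary-occupancy RP: sum of decay weights over occupied windows in span."""
    g0, g1, w = gene_window_span(gene, grid, params)
    occ = cistrome.occupied_windows
    lo = np.searchsorted(occ, g0, side="left")
    hi = np.searchsorted(occ, g1, side="left")
    if lo == hi:
        return 0.0
    return float(np.sum(w[occ[lo:hi] - g0]))


def compute_raw_rp_matrix(
    tracks: Sequence[BinnedSignalTrack],
    genes: Sequence[GeneAnnotation],
    grid: GenomeGrid,
    params: RPParams = RPParams(),
) -> np.ndarray:
    """Raw chrom-RP matrix, genes x profiles, evaluated on the binned grid."""
    if not tracks:
        return np.zeros((len(genes), 0))
    stacked = np.vstack([t.values for t in tracks])  # profiles x windows
    raw = np.empty((len(genes), len(tracks)), dtype=np.float64)
    for k, gene in enumerate(genes):
        g0, g1, w = gene_window_span(gene, grid, params)
        raw[k, :] = stacked[:, g0:g1] @ w
    return raw


def normalize_rp(
    raw: np.ndarray,
    gene_ids: Sequence[str],
    profile_ids: Sequence[str],
) -> RPMatrixData:
    """Per-profile log-shift normalization.

    Offset c_j = mean over genes of log(R_jk + 1); the normalized value is
    log(R_jk + 1) - c_j, giving each profile column zero mean.  Natural log.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2 or raw.shape[0] == 0:
        raise ValueError("raw RP matrix must be 2-D with at least one gene")
    if raw.shape != (len(gene_ids), len(profile_ids)):
        raise ValueError("raw shape does not match gene/profile labels")
    if not np.all(np.isfinite(raw)) or np.any(raw < 0):
        raise ValueError("raw RP values must be finite and non-negative")
    offsets = np.log1p(raw).mean(axis=0)
    return RPMatrixData(
        gene_ids=list(gene_ids),
        profile_ids=list(profile_ids),
        raw=raw,
        norm_offset=offsets,
    )


def build_rp_cache(store: CompendiumStore, params: RPParams = RPParams()) -> RPMatrixData:
    """Compute and attach the store's genes x profiles RP matrix."""
    raw = compute_raw_rp_matrix(store.tracks, store.genes, store.grid, params)
    cache = normalize_rp(raw, store.gene_ids, [t.profile_id for t in store.tracks])
    store.rp_cache = cache
    return cache


@dataclass
class PeakRPVector:
    """Peak-RP of one cistrome across a gene list."""

    cistrome_id: str
    gene_ids: List[str]
    values: np.ndarray

    @property
    def percentile(self) -> np.ndarray:
        return rp_percentile(self.values)


def compute_peak_rp(
    cistrome: Cistrome,
    genes: Sequence[GeneAnnotation],
    grid: GenomeGrid,
    params: RPParams = RPParams(),
) -> PeakRPVector:
    values = np.array([peak_rp(cistrome, g, grid, params) for g in genes])
    return PeakRPVector(
        cistrome_id=cistrome.cistrome_id,
        gene_ids=[g.gene_id for g in genes],
        values=values,
    )


def rp_percentile(values: Iterable[float]) -> np.ndarray:
    """Average-rank percentiles in (0, 1]; ties share the mean rank."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    if arr.size == 0:
        raise ValueError("need at least one value")
    return rankdata(arr, method="average") / arr.size
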