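"""In silico deletion (ISD) of TR cistromes from chromatin landscape models.

Deleting a cistrome zeroes the chromatin signal in every 1-kb window the
cistrome occupies.  Because the chrom-RP is a weighted sum over windows, the
deleted RP is an exact subtraction:

    R~ = R - sum over occupied windows m in the gene's +/-L span of w_m s_jm

The deleted RP is renormalized with the ORIGINAL per-profile offset (not
recomputed), and the per-gene effect of the deletion on the landscape model
is the coefficient-weighted drop Delta R' = sum_j alpha_j (R'_jk - R~'_jk),
evaluated with frozen coefficients (no refitting).  Genes with no occupied
window in range get an exact zero without any recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Union

import numpy as np

from .grid import GeneAnnotation, GenomeGrid
from .landscape import ChromModel
from .rp import RPParams, chrom_rp, gene_window_span
from .store import BinnedSignalTrack, Cistrome, RPMatrixData


@dataclass
class DeltaRPResult:
    """Per-gene RP drop caused by deleting one cistrome from one landscape."""

    cistrome_id: str
    assay_kind: str
    gene_ids: List[str]
    delta_rp: np.ndarray
    deleted_window_count: int

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"gene_id": self.gene_ids, "delta_rp": self.delta_rp}
        ).set_index("gene_id")


def _deletion_term(
    values: np.ndarray,
    occupied: np.ndarray,
    gene: GeneAnnotation,
    grid: GenomeGrid,
    params: RPParams,
) -> float:
    """Sum of w_m * s_jm over occupied windows within the gene's span."""
    g0, g1, w = gene_window_span(gene, grid, params)
    lo = np.searchsorted(occupied, g0, side="left")
    hi = np.searchsorted(occupied, g1, side="left")
    if lo == hi:
        return 0.0
    idx = occupied[lo:hi]
    return float(np.dot(w[idx - g0], values[idx]))


def deleted_rp(
    track: Union[BinnedSignalTrack, np.ndarray],
    cistrome: Cistrome,
    gene: GeneAnnotation,
    grid: GenomeGrid,
    params: RPParams = RPParams(),
) -> float:
    """Raw RP after zeroing the cistrome's windows; clamped at 0.

    On the binned grid the subtraction is exact, so the clamp only guards
    floating-point rounding.
    """
    values = track.values if isinstance(track, BinnedSignalTrack) else track
    r = chrom_rp(values, gene, grid, params)
    d = _deletion_term(values, cistrome.occupied_windows, gene, grid, params)
    return max(r - d, 0.0)


def renormalize_deleted(
    r_tilde: Union[float, np.ndarray], norm_offset: float
) -> Union[float, np.ndarray]:
    """log(R~ + 1) - c_j with the pre-deletion offset c_j."""
    return np.log1p(r_tilde) - norm_offset


def delta_rp(
    model: ChromModel,
    rp: RPMatrixData,
    tracks: Mapping[str, np.ndarray],
    cistrome: Cistrome,
    genes: Sequence[GeneAnnotation],
    grid: GenomeGrid,
    params: RPParams = RPParams(),
) -> DeltaRPResult:
    """Per-gene landscape drop for one cistrome, with frozen coefficients.

    Parameters
    ----------
    model : fitted ChromModel whose ``selected_profiles`` index into ``rp``.
    rp : RP matrix covering at least the genes in ``genes`` (raw + offsets).
    tracks : profile_id -> window signal vector for the selected profiles.
    cistrome : the cistrome whose windows are deleted.
    genes : the genes to evaluate (query union background).

    Notes
    -----
    The per-profile offsets cancel in R' - R~', leaving
    log(R+1) - log(R~+1); they are kept in the formulas for clarity of the
    contract but do not need recomputation here.
    """
    occupied = cistrome.occupied_windows
    row_of = {g: i for i, g in enumerate(rp.gene_ids)}
    try:
        rows = np.array([row_of[g.gene_id] for g in genes])
    except KeyError as exc:
        raise KeyError(f"gene {exc} missing from RP matrix") from exc
    cols = []
    for pid in model.selected_profiles:
        if pid not in tracks:
            raise KeyError(f"selected profile {pid!r} missing from tracks")
        cols.append(rp.column(pid))

    delta = np.zeros(len(genes), dtype=np.float64)
    touched_windows: set = set()
    if occupied.size:
        for k, gene in enumerate(genes):
            g0, g1, w = gene_window_span(gene, grid, params)
            lo = np.searchsorted(occupied, g0, side="left")
            hi = np.searchsorted(occupied, g1, side="left")
            if lo == hi:
                continue  # sparse path: exact zero
            idx = occupied[lo:hi]
            touched_windows.update(idx.tolist())
            wsel = w[idx - g0]
            acc = 0.0
            for j, pid in enumerate(model.selected_profiles):
                values = tracks[pid]
                raw = rp.raw[rows[k], cols[j]]
                d = float(np.dot(wsel, values[idx]))
                r_tilde = max(raw - d, 0.0)
                acc += model.alpha[j] * (np.log1p(raw) - np.log1p(r_tilde))
            delta[k] = acc
    return DeltaRPResult(
        cistrome_id=cistrome.cistrome_id,
        assay_kind=model.assay_kind,
        gene_ids=[g.gene_id for g in genes],
        delta_rp=delta,
        deleted_window_count=len(touched_windows),
    )
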