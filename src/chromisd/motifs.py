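"""Genome-wide PWM scanning at 100-bp resolution.

The genome is tiled with non-overlapping 100-bp windows.  A window's score
is the best log-odds placement (both strands, stride 1) starting inside it;
hits are windows whose score strictly exceeds the per-motif 99th-percentile
threshold, mapped onto the 1-kb grid to form a motif-imputed cistrome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np

from .grid import GenomeGrid
from .store import Cistrome

_CODE = np.full(256, 4, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i

DEFAULT_SCAN_WINDOW = 100
DEFAULT_THRESHOLD_PERCENTILE = 99.0


@dataclass
class PWM:
    """Position probability matrix with background and pseudocount.

    ``matrix`` is positions x 4 (A, C, G, T) base probabilities; rows must
    sum to 1.  Log-odds use a background-proportional pseudocount so zero
    probabilities stay finite:

        lo[k, b] = log( (p[k, b] + pc * bg[b]) / (1 + pc) / bg[b] )
    """

    motif_id: str
    tr_name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25, dtype=np.float64)
    )
    pseudocount: float = 0.001

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.motif_id}: matrix must be positions x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1")
        if self.background.shape != (4,) or np.any(self.background <= 0):
            raise ValueError(f"PWM {self.motif_id}: invalid background")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError(f"PWM {self.motif_id}: background must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """positions x 5 log-odds; column 4 (N) is -inf."""
        p = (self.matrix + self.pseudocount * self.background) / (1 + self.pseudocount)
        lo = np.log(p / self.background)
        out = np.full((len(self), 5), -np.inf)
        out[:, :4] = lo
        return out

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            tr_name=self.tr_name,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


def read_jaspar(path) -> List[PWM]:
    """Parse a JASPAR-format PWM text file (counts or frequencies)."""
    from Bio import motifs as bio_motifs

    out: List[PWM] = []
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:  # re-raise with the file named
            raise ValueError(f"{path}: failed to parse JASPAR PWMs: {exc}") from exc
        for m in parsed:
            counts = np.array(
                [[m.counts[b][i] for b in "ACGT"] for i in range(m.length)],
                dtype=np.float64,
            )
            totals = counts.sum(axis=1, keepdims=True)
            if np.any(totals <= 0):
                raise ValueError(f"{path}: motif {m.matrix_id} has empty columns")
            motif_id = m.matrix_id or m.name
            tr_name = m.name or motif_id
            out.append(PWM(motif_id=motif_id, tr_name=tr_name, matrix=counts / totals))
    return out


@dataclass
class MotifHitSet:
    """Scan result for one PWM: per-100-bp-window scores and called hits."""

    motif_id: str
    scores: Dict[str, np.ndarray]  # chrom -> per-tile max log-odds
    scan_window: int = DEFAULT_SCAN_WINDOW
    threshold_percentile: float = DEFAULT_THRESHOLD_PERCENTILE
    threshold: float = np.nan
    hits: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    hit_positions: Dict[str, np.ndarray] = field(default_factory=dict)

    def to_cistrome(self, tr_name: Optional[str] = None) -> Cistrome:
        return Cistrome(
            cistrome_id=f"{self.motif_id}.motif",
            tr_name=tr_name or self.motif_id,
            source="motif_hits",
            occupied_windows=self.hits,
            summits={c: p.copy() for c, p in self.hit_positions.items()},
        )


def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _placement_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every stride-1 placement of the motif along an encoded sequence."""
    m = lo.shape[0]
    n = codes.size - m + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n, dtype=np.float64)
    for k in range(m):
        scores += lo[k, codes[k : k + n]]
    return scores


def score_windows(
    sequences: Mapping[str, str],
    pwm: PWM,
    grid: GenomeGrid,
    scan_window: int = DEFAULT_SCAN_WINDOW,
) -> Dict[str, np.ndarray]:
    """Per-100-bp-tile max log-odds over both strands and all offsets.

    A placement containing N scores -inf; a tile with no finite placement
    (all N, or too close to the chromosome end to fit the motif) is -inf.
    """
    if len(pwm) > scan_window:
        raise ValueError(
            f"PWM {pwm.motif_id} length {len(pwm)} exceeds scan window {scan_window}"
        )
    lo_fwd = pwm.log_odds()
    lo_rev = pwm.reverse_complement().log_odds()
    out: Dict[str, np.ndarray] = {}
    for chrom in grid.chrom_names:
        seq = sequences[chrom]
        if len(seq) != grid.chrom_length(chrom):
            raise ValueError(
                f"sequence for {chrom} has length {len(seq)}, "
                f"grid expects {grid.chrom_length(chrom)}"
            )
        codes = _encode(seq)
        fwd = _placement_scores(codes, lo_fwd)
        rev = _placement_scores(codes, lo_rev)
        best = np.maximum(fwd, rev)
        n_tiles = math.ceil(len(seq) / scan_window)
        tiles = np.full(n_tiles, -np.inf)
        # max over placements starting inside each tile
        n_pad = n_tiles * scan_window
        padded = np.full(n_pad, -np.inf)
        padded[: best.size] = best
        tiles = padded.reshape(n_tiles, scan_window).max(axis=1)
        out[chrom] = tiles
    return out


def call_hits(
    scores: Dict[str, np.ndarray],
    grid: GenomeGrid,
    threshold_percentile: float = DEFAULT_THRESHOLD_PERCENTILE,
    scan_window: int = DEFAULT_SCAN_WINDOW,
    motif_id: str = "motif",
) -> MotifHitSet:
    """Call hits strictly above the per-motif score percentile.

    The threshold is the linear-interpolation percentile of all finite tile
    scores genome-wide; strict inequality keeps the hit fraction at or below
    (100 - percentile)% under ties.  Hit tiles are mapped to the 1-kb window
    containing the tile's midpoint.
    """
    flat = np.concatenate([v for v in scores.values()]) if scores else np.empty(0)
    finite = flat[np.isfinite(flat)]
    result = MotifHitSet(
        motif_id=motif_id,
        scores=scores,
        scan_window=scan_window,
        threshold_percentile=threshold_percentile,
    )
    if finite.size == 0:
        warnings.warn(f"motif {motif_id}: no finite scores; empty hit set")
        return result
    threshold = float(np.percentile(finite, threshold_percentile))
    result.threshold = threshold
    hit_windows: List[int] = []
    hit_positions: Dict[str, np.ndarray] = {}
    for chrom, tile_scores in scores.items():
        idx = np.nonzero(tile_scores > threshold)[0]
        if idx.size == 0:
            continue
        length = grid.chrom_length(chrom)
        starts = idx * scan_window
        ends = np.minimum(starts + scan_window, length)
        mids = (starts + ends) // 2
        hit_positions[chrom] = mids.astype(np.int64)
        off = grid.offset_index[chrom]
        hit_windows.extend(off + mids // grid.window_size)
    result.hits = np.unique(np.array(hit_windows, dtype=np.int64))
    result.hit_positions = hit_positions
    return result


def scan_genome(
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    grid: GenomeGrid,
    scan_window: int = DEFAULT_SCAN_WINDOW,
    threshold_percentile: float = DEFAULT_THRESHOLD_PERCENTILE,
) -> List[MotifHitSet]:
    """Scan every PWM and call hits; convenience wrapper for the CLI."""
    out = []
    for pwm in pwms:
        scores = score_windows(sequences, pwm, grid, scan_window=scan_window)
        out.append(
            call_hits(
                scores,
                grid,
                threshold_percentile=threshold_percentile,
                scan_window=scan_window,
                motif_id=pwm.motif_id,
            )
        )
    return out


def load_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into chrom -> sequence strings (pyfaidx-backed)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}
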