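"""Genome-wide fixed-width window grid.

Chromatin signal, cistrome occupancy and motif hits are all expressed on one
shared coordinate system: non-overlapping windows (default 1 kb) tiling each
chromosome, indexed globally so a single integer addresses any window in the
genome.  All base-pair coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, NamedTuple, Sequence, Tuple

import numpy as np


class GeneAnnotation(NamedTuple):
    """A gene reduced to its single representative TSS."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"


@dataclass
class GenomeGrid:
    """Chromosome sizes plus the genome-wide window index.

    Parameters
    ----------
    chrom_names : sequence of str
        Ordered chromosome identifiers.
    chrom_lengths : sequence of int
        Chromosome lengths in base pairs, parallel to ``chrom_names``.
    window_size : int, default 1000
        Window width in base pairs.  The last window of a chromosome may be
        shorter than this; it is kept and treated with its actual span.
    """

    chrom_names: Tuple[str, ...]
    chrom_lengths: Tuple[int, ...]
    window_size: int = 1000
    _midpoint_cache: Dict[str, np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.chrom_names = tuple(self.chrom_names)
        self.chrom_lengths = tuple(int(x) for x in self.chrom_lengths)
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        self._windows_per_chrom = tuple(
            math.ceil(l / self.window_size) for l in self.chrom_lengths
        )
        offsets = np.concatenate([[0], np.cumsum(self._windows_per_chrom)])
        self._offsets = offsets
        self.offset_index: Dict[str, int] = {
            name: int(offsets[i]) for i, name in enumerate(self.chrom_names)
        }
        self._chrom_index = {name: i for i, name in enumerate(self.chrom_names)}
        self._length_of = dict(zip(self.chrom_names, self.chrom_lengths))

    # ------------------------------------------------------------------ info
    @property
    def window_count(self) -> int:
        return int(self._offsets[-1])

    def windows_in(self, chrom: str) -> int:
        return self._windows_per_chrom[self._chrom_index[chrom]]

    def chrom_length(self, chrom: str) -> int:
        try:
            return self._length_of[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._chrom_index

    # ------------------------------------------------------------ addressing
    def window_of(self, chrom: str, pos: int) -> int:
        """Global index of the window containing base-pair position ``pos``."""
        length = self.chrom_length(chrom)
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom} (length {length})")
        return self.offset_index[chrom] + pos // self.window_size

    def window_bounds(self, gidx: int) -> Tuple[str, int, int]:
        """(chrom, start, end) of a global window; end clipped to the chromosome."""
        if not 0 <= gidx < self.window_count:
            raise IndexError(f"window index {gidx} out of range")
        ci = int(np.searchsorted(self._offsets, gidx, side="right")) - 1
        local = gidx - int(self._offsets[ci])
        chrom = self.chrom_names[ci]
        start = local * self.window_size
        end = min(start + self.window_size, self.chrom_lengths[ci])
        return chrom, start, end

    def midpoints(self, chrom: str) -> np.ndarray:
        """Base-pair midpoints of every window on ``chrom`` (float array).

        The final partial window's midpoint is the midpoint of its actual span.
        """
        cached = self._midpoint_cache.get(chrom)
        if cached is not None:
            return cached
        n = self.windows_in(chrom)
        length = self.chrom_length(chrom)
        starts = np.arange(n, dtype=np.float64) * self.window_size
        ends = np.minimum(starts + self.window_size, length)
        mids = (starts + ends) / 2.0
        mids.setflags(write=False)
        self._midpoint_cache[chrom] = mids
        return mids

    def window_lengths(self, chrom: str) -> np.ndarray:
        n = self.windows_in(chrom)
        length = self.chrom_length(chrom)
        starts = np.arange(n, dtype=np.int64) * self.window_size
        return np.minimum(starts + self.window_size, length) - starts

    def describe(self) -> str:
        return (
            f"GenomeGrid({len(self.chrom_names)} chromosomes, "
            f"{sum(self.chrom_lengths):,} bp, "
            f"{self.window_count:,} x {self.window_size} bp windows)"
        )


def validate_genes(genes: Sequence[GeneAnnotation], grid: GenomeGrid) -> None:
    """Check annotation invariants: unique ids, TSS within chromosome bounds."""
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in annotation")
        seen.add(g.gene_id)
        if not grid.has_chrom(g.chrom):
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        if not 0 <= g.tss < grid.chrom_length(g.chrom):
            raise ValueError(
                f"gene {g.gene_id}: TSS {g.tss} outside {g.chrom} "
                f"(length {grid.chrom_length(g.chrom)})"
            )
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.gene_id}: bad strand {g.strand!r}")
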