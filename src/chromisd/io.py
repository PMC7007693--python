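"""Readers and writers for the standard text formats the pipeline consumes.

chrom.sizes, gene annotation (TSV or BED6), bedGraph / bigWig signal, BED
peak files (optional summit column), plain gene lists, and TSV exports.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .grid import GeneAnnotation, GenomeGrid
from .store import BinnedSignalTrack, bin_signal


def read_chrom_sizes(path, window_size: int = 1000) -> GenomeGrid:
    """Two-column ``chrom<TAB>length`` file -> GenomeGrid."""
    names: List[str] = []
    lengths: List[int] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{line_no}: expected 'chrom length'")
            names.append(fields[0])
            lengths.append(int(fields[1]))
    if not names:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return GenomeGrid(tuple(names), tuple(lengths), window_size=window_size)


def read_gene_annotation(path) -> List[GeneAnnotation]:
    """Gene annotation as TSV (gene_id, chrom, tss, strand) or BED6.

    BED6 rows are detected by column order (chrom first, score column 5); the
    TSS is start for + strand, end-1 for - strand.  Duplicate gene ids are an
    error: one representative TSS per gene is the contract.
    """
    genes: List[GeneAnnotation] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) >= 6 and f[1].isdigit() and f[2].isdigit() and f[5] in "+-":
                chrom, start, end, name, _, strand = f[:6]
                tss = int(start) if strand == "+" else int(end) - 1
                genes.append(GeneAnnotation(name, chrom, tss, strand))
            elif len(f) >= 4 and f[2].isdigit():
                gene_id, chrom, tss, strand = f[0], f[1], int(f[2]), f[3]
                genes.append(GeneAnnotation(gene_id, chrom, tss, strand))
            else:
                raise ValueError(f"{path}:{line_no}: unrecognized annotation row")
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def iter_bedgraph(path) -> Iterator[Tuple[str, int, int, float]]:
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"{path}:{line_no}: expected 4 bedGraph fields")
            yield f[0], int(f[1]), int(f[2]), float(f[3])


def read_signal_track(
    path,
    grid: GenomeGrid,
    profile_id: Optional[str] = None,
    assay_kind: str = "dnase",
) -> BinnedSignalTrack:
    """Bin a bedGraph (.bedgraph/.bdg) or bigWig (.bw/.bigwig) file."""
    path = Path(path)
    if profile_id is None:
        profile_id = path.stem
    if path.suffix.lower() in (".bw", ".bigwig"):
        intervals = _iter_bigwig(path, grid)
    else:
        intervals = iter_bedgraph(path)
    return bin_signal(intervals, grid, profile_id=profile_id, assay_kind=assay_kind)


def _iter_bigwig(path, grid: GenomeGrid) -> Iterator[Tuple[str, int, int, float]]:
    import pyBigWig  # deferred: only needed for bigWig input

    bw = pyBigWig.open(str(path))
    try:
        for chrom in grid.chrom_names:
            if chrom not in bw.chroms():
                continue
            entries = bw.intervals(chrom)
            if entries is None:
                continue
            for start, end, value in entries:
                yield chrom, start, end, float(value)
    finally:
        bw.close()


def read_peak_bed(path) -> List[Tuple[str, int, int, Optional[int]]]:
    """BED3+ peak records; a 10th (narrowPeak) or 4th integer column, when
    present and a valid offset, is taken as the summit offset."""
    records: List[Tuple[str, int, int, Optional[int]]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{line_no}: expected at least BED3")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            summit: Optional[int] = None
            for idx in (9, 3):  # narrowPeak summit column, else BED4 numeric
                if len(f) > idx and _is_int(f[idx]):
                    cand = int(f[idx])
                    if 0 <= cand < end - start:
                        summit = cand
                        break
            records.append((chrom, start, end, summit))
    return records


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def read_gene_list(path) -> List[str]:
    """Plain-text query gene list, one identifier per line."""
    out: List[str] = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.append(token)
    return out


def read_covariates(path) -> pd.Series:
    """Two-column TSV ``gene_id<TAB>promoter_activity``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_id", "promoter_activity"])
    series = pd.Series(
        df["promoter_activity"].to_numpy(dtype=float),
        index=df["gene_id"].astype(str),
        name="promoter_activity",
    )
    if not np.all(np.isfinite(series.to_numpy())):
        raise ValueError(f"{path}: non-finite covariate values")
    return series


def write_rp_matrix_tsv(rp, path) -> None:
    """Export a genes x profiles RP matrix (normalized scale) as TSV."""
    pd.DataFrame(
        rp.normalized, index=rp.gene_ids, columns=rp.profile_ids
    ).rename_axis("gene_id").to_csv(path, sep="\t")
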