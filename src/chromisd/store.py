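"""Compendium data model: binned signal tracks, cistromes, persistent store.

The store mirrors the layout of a precomputed epigenome compendium: one
genome grid, a gene annotation, continuous chromatin profiles (DNase-seq /
H3K27ac-like) binned into the grid's windows, binarized TR cistromes
(peak-summit or motif-hit windows), a per-gene promoter-activity covariate
used for background stratification, and an optional cached RP matrix.
Persistence is HDF5 with per-dataset CRC32 integrity checks.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .grid import GeneAnnotation, GenomeGrid, validate_genes

FORMAT_VERSION = 1

ASSAY_KINDS = ("dnase", "h3k27ac")
CISTROME_SOURCES = ("chipseq_peaks", "motif_hits")


class StoreIntegrityError(RuntimeError):
    """Raised when a stored dataset fails its checksum on load."""


@dataclass
class BinnedSignalTrack:
    """One chromatin profile as mean per-base signal per genome window."""

    profile_id: str
    assay_kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.assay_kind not in ASSAY_KINDS:
            raise ValueError(f"assay_kind must be one of {ASSAY_KINDS}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"track {self.profile_id}: non-finite signal values")
        if np.any(self.values < 0):
            raise ValueError(f"track {self.profile_id}: negative signal values")


@dataclass
class Cistrome:
    """Binarized genome-wide binding of one TR sample.

    ``occupied_windows`` is the sorted set of global 1-kb window indices that
    contain at least one peak summit (or motif hit).  ``summits`` optionally
    retains base-pair summit positions per chromosome; the promoter-count
    baseline uses them when available.
    """

    cistrome_id: str
    tr_name: str
    source: str
    occupied_windows: np.ndarray
    summits: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.source not in CISTROME_SOURCES:
            raise ValueError(f"source must be one of {CISTROME_SOURCES}")
        occ = np.unique(np.asarray(self.occupied_windows, dtype=np.int64))
        self.occupied_windows = occ
        if self.summits is not None:
            self.summits = {
                c: np.sort(np.asarray(p, dtype=np.int64))
                for c, p in self.summits.items()
            }

    def check_against(self, grid: GenomeGrid) -> None:
        occ = self.occupied_windows
        if occ.size and (occ[0] < 0 or occ[-1] >= grid.window_count):
            raise ValueError(
                f"cistrome {self.cistrome_id}: window index outside grid"
            )


@dataclass
class RPMatrixData:
    """Genes x profiles raw RP values plus per-profile normalization offsets.

    ``normalized`` is ``log(raw + 1) - offset`` with the offset chosen so each
    profile's normalized column has zero mean across genes.
    """

    gene_ids: List[str]
    profile_ids: List[str]
    raw: np.ndarray
    norm_offset: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        return np.log1p(self.raw) - self.norm_offset[np.newaxis, :]

    def column(self, profile_id: str) -> int:
        return self.profile_ids.index(profile_id)


@dataclass
class CompendiumStore:
    grid: GenomeGrid
    genes: List[GeneAnnotation]
    tracks: List[BinnedSignalTrack] = field(default_factory=list)
    cistromes: List[Cistrome] = field(default_factory=list)
    covariates: Optional[pd.Series] = None  # promoter activity per gene_id
    rp_cache: Optional[RPMatrixData] = None

    def __post_init__(self) -> None:
        validate_genes(self.genes, self.grid)
        for t in self.tracks:
            if t.values.shape != (self.grid.window_count,):
                raise ValueError(
                    f"track {t.profile_id}: length {t.values.shape} does not "
                    f"match grid window_count {self.grid.window_count}"
                )
        for c in self.cistromes:
            c.check_against(self.grid)

    # ------------------------------------------------------------- accessors
    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.chrom, g.tss, g.strand) for g in self.genes],
            columns=["gene_id", "chrom", "tss", "strand"],
        )

    def track(self, profile_id: str) -> BinnedSignalTrack:
        for t in self.tracks:
            if t.profile_id == profile_id:
                return t
        raise KeyError(f"no track {profile_id!r} in store")

    def cistrome(self, cistrome_id: str) -> Cistrome:
        for c in self.cistromes:
            if c.cistrome_id == cistrome_id:
                return c
        raise KeyError(f"no cistrome {cistrome_id!r} in store")

    def tracks_of(self, assay_kind: str) -> List[BinnedSignalTrack]:
        return [t for t in self.tracks if t.assay_kind == assay_kind]

    def cistromes_of(self, source: str) -> List[Cistrome]:
        return [c for c in self.cistromes if c.source == source]

    def add_cistrome(self, cistrome: Cistrome, replace: bool = True) -> None:
        cistrome.check_against(self.grid)
        existing = [c.cistrome_id for c in self.cistromes]
        if cistrome.cistrome_id in existing:
            if not replace:
                raise ValueError(f"cistrome {cistrome.cistrome_id!r} already present")
            self.cistromes[existing.index(cistrome.cistrome_id)] = cistrome
        else:
            self.cistromes.append(cistrome)


# ---------------------------------------------------------------------------
# signal binning and peak loading
# ---------------------------------------------------------------------------

def bin_signal(
    track_intervals: Iterable[Tuple[str, int, int, float]],
    grid: GenomeGrid,
    profile_id: str = "track",
    assay_kind: str = "dnase",
) -> BinnedSignalTrack:
    """Summarize interval-valued signal into the grid's windows.

    Each window's value is the length-weighted mean of the interval values
    covering it, counting uncovered bases as zero, so a constant track is
    reproduced exactly and total signal mass (value x covered length) is
    conserved.  The last partial window of each chromosome is averaged over
    its actual span.
    """
    acc = np.zeros(grid.window_count, dtype=np.float64)
    ws = grid.window_size
    for rec_no, (chrom, start, end, value) in enumerate(track_intervals, start=1):
        if not grid.has_chrom(chrom):
            raise ValueError(
                f"record {rec_no} ({chrom}:{start}-{end}): unknown chromosome"
            )
        value = float(value)
        if not np.isfinite(value) or value < 0:
            raise ValueError(
                f"record {rec_no} ({chrom}:{start}-{end}): "
                f"invalid signal value {value}"
            )
        length = grid.chrom_length(chrom)
        start = max(int(start), 0)
        end = min(int(end), length)
        if start >= end:
            continue
        off = grid.offset_index[chrom]
        w0, w1 = start // ws, (end - 1) // ws
        if w0 == w1:
            acc[off + w0] += value * (end - start)
        else:
            acc[off + w0] += value * ((w0 + 1) * ws - start)
            acc[off + w1] += value * (end - w1 * ws)
            if w1 > w0 + 1:
                acc[off + w0 + 1 : off + w1] += value * ws
    # divide by actual window spans
    values = np.empty_like(acc)
    for chrom in grid.chrom_names:
        off = grid.offset_index[chrom]
        n = grid.windows_in(chrom)
        values[off : off + n] = acc[off : off + n] / grid.window_lengths(chrom)
    return BinnedSignalTrack(profile_id=profile_id, assay_kind=assay_kind, values=values)


def load_peaks(
    bed_records: Iterable[Tuple],
    grid: GenomeGrid,
    cistrome_id: str = "cistrome",
    tr_name: str = "TR",
    source: str = "chipseq_peaks",
) -> Cistrome:
    """Binarize peak records into occupied summit windows.

    A record is ``(chrom, start, end)`` or ``(chrom, start, end, summit_offset)``;
    the summit defaults to the interval midpoint when no offset is given.
    Occupancy is set semantics: multiple summits in one window count once.
    """
    occupied: List[int] = []
    summits: Dict[str, List[int]] = {}
    for line_no, rec in enumerate(bed_records, start=1):
        if len(rec) not in (3, 4):
            raise ValueError(f"line {line_no}: expected 3 or 4 fields, got {len(rec)}")
        chrom, start, end = rec[0], int(rec[1]), int(rec[2])
        if not grid.has_chrom(chrom):
            raise ValueError(f"line {line_no}: unknown chromosome {chrom!r}")
        if start >= end:
            raise ValueError(f"line {line_no}: start {start} >= end {end}")
        if len(rec) == 4 and rec[3] is not None:
            offset = int(rec[3])
            if not 0 <= offset < end - start:
                raise ValueError(
                    f"line {line_no}: summit offset {offset} outside peak"
                )
            summit = start + offset
        else:
            summit = (start + end) // 2
        summit = min(summit, grid.chrom_length(chrom) - 1)
        occupied.append(grid.window_of(chrom, summit))
        summits.setdefault(chrom, []).append(summit)
    return Cistrome(
        cistrome_id=cistrome_id,
        tr_name=tr_name,
        source=source,
        occupied_windows=np.array(occupied, dtype=np.int64),
        summits={c: np.array(p, dtype=np.int64) for c, p in summits.items()},
    )


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def _write_checked(group: h5py.Group, name: str, data: np.ndarray) -> None:
    data = np.ascontiguousarray(data)
    ds = group.create_dataset(name, data=data, track_times=False)
    if data.dtype.kind in "fiu":
        ds.attrs["crc32"] = zlib.crc32(data.tobytes())


def _read_checked(group: h5py.Group, name: str) -> np.ndarray:
    ds = group[name]
    data = ds[()]
    expected = ds.attrs.get("crc32")
    if expected is not None:
        actual = zlib.crc32(np.ascontiguousarray(data).tobytes())
        if int(expected) != actual:
            raise StoreIntegrityError(
                f"dataset {ds.name!r} failed checksum: file is corrupt or truncated"
            )
    return data


def save_store(store: CompendiumStore, path) -> None:
    """Write the compendium to HDF5 (little-endian arrays, checksummed)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        g = f.create_group("grid")
        g.attrs["window_size"] = store.grid.window_size
        g.create_dataset("chrom_names", track_times=False,
                         data=np.array(store.grid.chrom_names, dtype="S"))
        _write_checked(g, "chrom_lengths", np.array(store.grid.chrom_lengths, "<i8"))

        gg = f.create_group("genes")
        gg.create_dataset("gene_id", track_times=False,
                          data=np.array(store.gene_ids, dtype="S"))
        gg.create_dataset("chrom", track_times=False,
                          data=np.array([x.chrom for x in store.genes], dtype="S"))
        _write_checked(gg, "tss", np.array([x.tss for x in store.genes], "<i8"))
        gg.create_dataset("strand", track_times=False,
                          data=np.array([x.strand for x in store.genes], dtype="S"))

        gt = f.create_group("tracks")
        for t in store.tracks:
            tg = gt.create_group(t.profile_id)
            tg.attrs["assay_kind"] = t.assay_kind
            _write_checked(tg, "values", t.values.astype("<f8"))

        gc = f.create_group("cistromes")
        for c in store.cistromes:
            cg = gc.create_group(c.cistrome_id)
            cg.attrs["tr_name"] = c.tr_name
            cg.attrs["source"] = c.source
            _write_checked(cg, "occupied_windows", c.occupied_windows.astype("<i8"))
            if c.summits is not None:
                sg = cg.create_group("summits")
                for chrom, pos in c.summits.items():
                    _write_checked(sg, chrom, pos.astype("<i8"))

        if store.covariates is not None:
            cv = f.create_group("covariates")
            cov = store.covariates.reindex(store.gene_ids)
            _write_checked(cv, "promoter_activity", cov.to_numpy(dtype="<f8"))

        if store.rp_cache is not None:
            rc = f.create_group("rp_cache")
            rc.create_dataset("gene_ids", track_times=False,
                              data=np.array(store.rp_cache.gene_ids, dtype="S"))
            rc.create_dataset("profile_ids", track_times=False,
                              data=np.array(store.rp_cache.profile_ids, dtype="S"))
            _write_checked(rc, "raw", store.rp_cache.raw.astype("<f8"))
            _write_checked(rc, "norm_offset", store.rp_cache.norm_offset.astype("<f8"))


def _decode(arr) -> List[str]:
    return [x.decode() if isinstance(x, bytes) else str(x) for x in arr]


def load_store(path) -> CompendiumStore:
    """Load an HDF5 compendium, verifying format version and checksums."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"unsupported store format version {version!r} "
                f"(expected {FORMAT_VERSION})"
            )
        g = f["grid"]
        grid = GenomeGrid(
            chrom_names=tuple(_decode(g["chrom_names"][()])),
            chrom_lengths=tuple(_read_checked(g, "chrom_lengths")),
            window_size=int(g.attrs["window_size"]),
        )
        gg = f["genes"]
        genes = [
            GeneAnnotation(gid, chrom, int(tss), strand)
            for gid, chrom, tss, strand in zip(
                _decode(gg["gene_id"][()]),
                _decode(gg["chrom"][()]),
                _read_checked(gg, "tss"),
                _decode(gg["strand"][()]),
            )
        ]
        tracks = []
        for pid in f["tracks"]:
            tg = f["tracks"][pid]
            tracks.append(
                BinnedSignalTrack(
                    profile_id=pid,
                    assay_kind=tg.attrs["assay_kind"],
                    values=_read_checked(tg, "values"),
                )
            )
        cistromes = []
        for cid in f["cistromes"]:
            cg = f["cistromes"][cid]
            summits = None
            if "summits" in cg:
                summits = {
                    chrom: _read_checked(cg["summits"], chrom)
                    for chrom in cg["summits"]
                }
            cistromes.append(
                Cistrome(
                    cistrome_id=cid,
                    tr_name=cg.attrs["tr_name"],
                    source=cg.attrs["source"],
                    occupied_windows=_read_checked(cg, "occupied_windows"),
                    summits=summits,
                )
            )
        covariates = None
        if "covariates" in f:
            covariates = pd.Series(
                _read_checked(f["covariates"], "promoter_activity"),
                index=[g.gene_id for g in genes],
                name="promoter_activity",
            )
        rp_cache = None
        if "rp_cache" in f:
            rc = f["rp_cache"]
            rp_cache = RPMatrixData(
                gene_ids=_decode(rc["gene_ids"][()]),
                profile_ids=_decode(rc["profile_ids"][()]),
                raw=_read_checked(rc, "raw"),
                norm_offset=_read_checked(rc, "norm_offset"),
            )
    store = CompendiumStore(
        grid=grid,
        genes=genes,
        tracks=tracks,
        cistromes=cistromes,
        covariates=covariates,
        rp_cache=rp_cache,
    )
    if rp_cache is not None and rp_cache.gene_ids != store.gene_ids:
        raise StoreIntegrityError("rp_cache gene rows are not aligned with genes")
    return store
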