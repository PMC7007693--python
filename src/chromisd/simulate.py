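"""Synthetic chromatin compendium with a planted true regulator.

The generator emulates the statistical structure the inference assumes: a
regulator's peaks co-localize with elevated chromatin signal near the genes
it regulates.  Concretely, one planted cistrome places a peak within the
half-decay distance of each query gene's TSS; a subset of "informative"
chromatin profiles carry a multiplicative signal enrichment (boxcar around
each planted summit) on top of log-normal background noise; decoy cistromes
scatter peaks uniformly and decoy profiles are pure noise.  A per-gene
promoter-activity covariate is derived from the generated tracks for
background stratification, and a truth record names the planted cistrome and
informative profiles so the regulator-recovery benchmark (rank of the true
TR) can be scored.

With ``effect_size == 1`` the generator produces a full null: peaks are
placed uniformly and the query set is drawn at random, so the planted
cistrome is statistically indistinguishable from the decoys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .grid import GeneAnnotation, GenomeGrid
from .rp import RPParams
from .store import BinnedSignalTrack, Cistrome, CompendiumStore

ASSAYS = ("dnase", "h3k27ac")


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry and effect sizes of the synthetic compendium.

    Defaults are desk-scale: the full pipeline runs in seconds while every
    sparsity path is still exercised.
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 400
    n_profiles: int = 12          # per assay
    n_informative: int = 3        # per assay, carry the enrichment
    n_cistromes: int = 30         # total, including the planted one
    n_query: int = 60
    effect_size: float = 5.0      # multiplicative signal enrichment at peaks
    noise_sd: float = 1.0         # sigma of log-normal background signal
    peak_rate: float = 0.02       # expected fraction of windows with a peak
    enrich_halfwidth: int = 2     # windows on each side of a planted summit
    window_size: int = 1000
    delta: int = 10_000           # planted summits fall within +/-delta of TSS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_profiles",
                     "n_cistromes", "n_query", "window_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_query >= self.n_genes:
            raise ValueError("n_query must be smaller than n_genes")
        if not 0 < self.n_informative <= self.n_profiles:
            raise ValueError("n_informative must be in (0, n_profiles]")
        if not 0 < self.peak_rate < 1:
            raise ValueError("peak_rate must be in (0, 1)")
        total_windows = self.n_chroms * math.ceil(self.chrom_length / self.window_size)
        if self.n_genes > total_windows:
            raise ValueError("infeasible geometry: more genes than windows")


@dataclass
class FixtureTruth:
    """What was planted: enough to score rank-of-true-regulator."""

    planted_cistrome: str
    planted_tr: str
    informative_profiles: List[str]
    planted_summits: Dict[str, np.ndarray]
    query_genes: List[str]
    is_null: bool


def _make_grid(spec: FixtureSpec) -> GenomeGrid:
    names = tuple(f"chr{i + 1}" for i in range(spec.n_chroms))
    return GenomeGrid(names, (spec.chrom_length,) * spec.n_chroms,
                      window_size=spec.window_size)


def _layout(
    spec: FixtureSpec, rng: np.random.Generator
) -> Tuple[GenomeGrid, List[GeneAnnotation], List[str], Dict[str, np.ndarray]]:
    """Genes, query choice and planted summit positions (shared by the
    signal generator and the sequence generator, keyed off one rng stream)."""
    grid = _make_grid(spec)
    genes: List[GeneAnnotation] = []
    per_chrom = [spec.n_genes // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_genes % spec.n_chroms):
        per_chrom[i] += 1
    gid = 0
    for ci, chrom in enumerate(grid.chrom_names):
        n = per_chrom[ci]
        spacing = spec.chrom_length / (n + 1)
        for k in range(n):
            base = (k + 1) * spacing
            jitter = rng.uniform(-spacing / 4, spacing / 4)
            tss = int(np.clip(base + jitter, 0, spec.chrom_length - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneAnnotation(f"G{gid:04d}", chrom, tss, strand))
            gid += 1

    query_idx = rng.choice(spec.n_genes, size=spec.n_query, replace=False)
    query = sorted(genes[i].gene_id for i in query_idx)

    planted: Dict[str, List[int]] = {c: [] for c in grid.chrom_names}
    if spec.effect_size > 1:
        by_id = {g.gene_id: g for g in genes}
        for qid in query:
            g = by_id[qid]
            offset = int(rng.integers(-spec.delta, spec.delta + 1))
            pos = int(np.clip(g.tss + offset, 0, spec.chrom_length - 1))
            planted[g.chrom].append(pos)
    summits = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in planted.items()
               if v}
    return grid, genes, query, summits


def _uniform_summits(
    spec: FixtureSpec, grid: GenomeGrid, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    n_peaks = max(1, round(spec.peak_rate * grid.window_count))
    out: Dict[str, List[int]] = {}
    for _ in range(n_peaks):
        chrom = grid.chrom_names[int(rng.integers(len(grid.chrom_names)))]
        out.setdefault(chrom, []).append(int(rng.integers(grid.chrom_length(chrom))))
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in out.items()}


def _summits_to_cistrome(
    summits: Dict[str, np.ndarray],
    grid: GenomeGrid,
    cistrome_id: str,
    tr_name: str,
) -> Cistrome:
    windows = []
    for chrom, pos in summits.items():
        off = grid.offset_index[chrom]
        windows.extend((off + pos // grid.window_size).tolist())
    return Cistrome(
        cistrome_id=cistrome_id,
        tr_name=tr_name,
        source="chipseq_peaks",
        occupied_windows=np.array(windows, dtype=np.int64),
        summits=summits,
    )


def generate(spec: FixtureSpec) -> Tuple[CompendiumStore, List[str], FixtureTruth]:
    """Build the synthetic store, the query gene list and the truth record.

    Deterministic given ``spec.seed``: the same spec yields a byte-identical
    store.
    """
    rng = np.random.default_rng(spec.seed)
    grid, genes, query, planted_summits = _layout(spec, rng)
    is_null = spec.effect_size <= 1

    # --- cistromes: planted first, then uniform decoys -----------------
    cistromes: List[Cistrome] = []
    base_summits = _uniform_summits(spec, grid, rng)
    if is_null:
        summits0 = base_summits
    else:
        summits0 = {
            c: np.sort(
                np.concatenate(
                    [base_summits.get(c, np.empty(0, np.int64)),
                     planted_summits.get(c, np.empty(0, np.int64))]
                )
            )
            for c in grid.chrom_names
        }
        summits0 = {c: v for c, v in summits0.items() if v.size}
    cistromes.append(_summits_to_cistrome(summits0, grid, "TR00_rep1", "TR00"))
    for i in range(1, spec.n_cistromes):
        cistromes.append(
            _summits_to_cistrome(
                _uniform_summits(spec, grid, rng), grid, f"TR{i:02d}_rep1", f"TR{i:02d}"
            )
        )

    # --- windows carrying the enrichment boxcar -------------------------
    enriched = np.zeros(grid.window_count, dtype=bool)
    if not is_null:
        for chrom, pos in planted_summits.items():
            off = grid.offset_index[chrom]
            n = grid.windows_in(chrom)
            centers = pos // grid.window_size
            for c in centers:
                lo = max(0, int(c) - spec.enrich_halfwidth)
                hi = min(n, int(c) + spec.enrich_halfwidth + 1)
                enriched[off + lo : off + hi] = True

    # --- chromatin profiles --------------------------------------------
    tracks: List[BinnedSignalTrack] = []
    truth_profiles: List[str] = []
    for assay in ASSAYS:
        for j in range(spec.n_profiles):
            pid = f"{assay}_{j:02d}"
            values = np.exp(spec.noise_sd * rng.standard_normal(grid.window_count))
            informative = j < spec.n_informative
            if informative and not is_null:
                values = values.copy()
                values[enriched] *= spec.effect_size
            if informative:
                truth_profiles.append(pid)
            tracks.append(
                BinnedSignalTrack(profile_id=pid, assay_kind=assay, values=values)
            )

    # --- covariate: promoter activity from the generated tracks --------
    import pandas as pd

    stacked = np.vstack([t.values for t in tracks])
    cov = np.empty(len(genes))
    for i, g in enumerate(genes):
        off = grid.offset_index[g.chrom]
        w = off + g.tss // grid.window_size
        lo = max(off, w - 2)
        hi = min(off + grid.windows_in(g.chrom), w + 3)
        cov[i] = np.log1p(stacked[:, lo:hi].mean())
    covariates = pd.Series(cov, index=[g.gene_id for g in genes],
                           name="promoter_activity")

    store = CompendiumStore(
        grid=grid,
        genes=genes,
        tracks=tracks,
        cistromes=cistromes,
        covariates=covariates,
    )
    truth = FixtureTruth(
        planted_cistrome="TR00_rep1",
        planted_tr="TR00",
        informative_profiles=truth_profiles,
        planted_summits=planted_summits,
        query_genes=query,
        is_null=is_null,
    )
    return store, query, truth


# ---------------------------------------------------------------------------
# sequence generation for motif-scan testing
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGT", "TGCA")


def generate_sequences(
    spec: FixtureSpec, consensus: str
) -> Tuple[Dict[str, str], Dict[str, np.ndarray]]:
    """Random genome with the consensus embedded at planted peak summits.

    Returns (sequences, planted positions).  Embeddings are centered on each
    summit; roughly half are reverse-complemented.  The gene/peak layout is
    re-derived from the spec's seed, so sequences line up with ``generate``.
    """
    consensus = consensus.upper()
    if not 0 < len(consensus) <= 100:
        raise ValueError("consensus length must be in 1..100")
    if set(consensus) - set("ACGT"):
        raise ValueError("consensus must be ACGT only")
    rng = np.random.default_rng(spec.seed)
    grid, _genes, _query, planted = _layout(spec, rng)
    seq_rng = np.random.default_rng(spec.seed + 777)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    sequences: Dict[str, str] = {}
    m = len(consensus)
    for chrom in grid.chrom_names:
        arr = bases[seq_rng.integers(0, 4, size=grid.chrom_length(chrom))]
        seq = bytearray(arr.tobytes())
        for pos in planted.get(chrom, ()):  # center the motif on the summit
            start = int(np.clip(pos - m // 2, 0, len(seq) - m))
            insert = consensus if seq_rng.random() < 0.5 else consensus.translate(_RC)[::-1]
            seq[start : start + m] = insert.encode()
        sequences[chrom] = seq.decode()
    return sequences, planted


# ---------------------------------------------------------------------------
# bundle writer: fixtures as standard text formats
# ---------------------------------------------------------------------------

def write_bundle(
    spec: FixtureSpec,
    out_dir,
    consensus: Optional[str] = None,
) -> Dict[str, Path]:
    """Emit the fixture as standard files (chrom.sizes, TSV annotation,
    bedGraph tracks, BED peak files, covariates, gene list, truth TSV and
    optionally FASTA), so the bundle doubles as a format-parsing test and as
    input to the build/scan/rank commands."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    store, query, truth = generate(spec)
    grid = store.grid
    paths: Dict[str, Path] = {}

    p = out / "genome.chrom.sizes"
    with open(p, "w") as fh:
        for name, length in zip(grid.chrom_names, grid.chrom_lengths):
            fh.write(f"{name}\t{length}\n")
    paths["chrom_sizes"] = p

    p = out / "genes.tsv"
    with open(p, "w") as fh:
        for g in store.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")
    paths["annotation"] = p

    track_dir = out / "tracks"
    track_dir.mkdir(exist_ok=True)
    for t in store.tracks:
        tp = track_dir / f"{t.profile_id}.bedgraph"
        with open(tp, "w") as fh:
            for chrom in grid.chrom_names:
                off = grid.offset_index[chrom]
                n = grid.windows_in(chrom)
                length = grid.chrom_length(chrom)
                for w in range(n):
                    start = w * grid.window_size
                    end = min(start + grid.window_size, length)
                    fh.write(f"{chrom}\t{start}\t{end}\t{t.values[off + w]:.6g}\n")
        paths[f"track:{t.profile_id}"] = tp

    peak_dir = out / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for c in store.cistromes:
        cp = peak_dir / f"{c.cistrome_id}.bed"
        with open(cp, "w") as fh:
            for chrom, positions in sorted((c.summits or {}).items()):
                for pos in positions:
                    start = max(0, int(pos) - 150)
                    end = min(grid.chrom_length(chrom), int(pos) + 150)
                    fh.write(f"{chrom}\t{start}\t{end}\t{int(pos) - start}\n")
        paths[f"peaks:{c.cistrome_id}"] = cp

    p = out / "covariates.tsv"
    store.covariates.to_csv(p, sep="\t", header=False)
    paths["covariates"] = p

    p = out / "query_genes.txt"
    p.write_text("\n".join(query) + "\n")
    paths["query"] = p

    p = out / "truth.tsv"
    with open(p, "w") as fh:
        fh.write(f"planted_cistrome\t{truth.planted_cistrome}\n")
        fh.write(f"planted_tr\t{truth.planted_tr}\n")
        fh.write(f"informative_profiles\t{','.join(truth.informative_profiles)}\n")
        fh.write(f"is_null\t{int(truth.is_null)}\n")
    paths["truth"] = p

    if consensus is not None:
        sequences, _ = generate_sequences(spec, consensus)
        fp = out / "genome.fa"
        with open(fp, "w") as fh:
            for chrom in grid.chrom_names:
                fh.write(f">{chrom}\n")
                seq = sequences[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        paths["fasta"] = fp
    return paths
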