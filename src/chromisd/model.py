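"""Top-level modelling interface: RegulatorInference -> RegulatorResults.

The model object is constructed from a compendium store plus a query gene
list; ``fit()`` runs the full inference — activity-matched background
sampling, per-assay chromatin landscape models (L1 profile selection plus an
unpenalized refit), per-cistrome in silico deletion, one-sided rank-sum
channel tests and the Cauchy-combined ranking — and returns a results object
carrying the fitted landscape models, their discrimination AUCs, every
channel p-value and the final TR rank table, with ``summary()`` rendering
the ranking the way a practitioner reads it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import GeneAnnotation
from .isd import DeltaRPResult, delta_rp
from .landscape import (
    DEFAULT_BACKGROUND_SIZE,
    DEFAULT_BINS,
    DEFAULT_MAX_PROFILES,
    ChromModel,
    GeneSetPair,
    fit_final_model,
    fit_l1_path,
    model_auc,
    select_background,
)
from .ranking import TRRankTable, combine_channels, wilcoxon_one_sided
from .rp import RPParams, build_rp_cache, compute_peak_rp
from .store import CompendiumStore, load_store

logger = logging.getLogger("chromisd")

ASSAY_CHANNEL = {"dnase": "isd_dnase", "h3k27ac": "isd_h3k27ac"}
SOURCE_OF_MODE = {"chipseq": "chipseq_peaks", "motif": "motif_hits"}


@dataclass
class GeneMatchReport:
    """How the query identifiers resolved against the store annotation."""

    matched: List[str]
    fallback_matched: List[str]  # matched only case-insensitively
    unmatched: List[str]


def resolve_gene_ids(
    query: Sequence[str], universe: Sequence[str]
) -> GeneMatchReport:
    """Exact match first; case-insensitive fallback; the rest unmatched."""
    exact = set(universe)
    lower_map: Dict[str, str] = {}
    for g in universe:
        lower_map.setdefault(g.lower(), g)
    matched, fallback, unmatched = [], [], []
    seen = set()
    for q in query:
        if q in exact:
            hit = q
        elif q.lower() in lower_map:
            hit = lower_map[q.lower()]
            fallback.append(q)
        else:
            unmatched.append(q)
            continue
        if hit not in seen:
            matched.append(hit)
            seen.add(hit)
    return GeneMatchReport(matched=matched, fallback_matched=fallback,
                           unmatched=unmatched)


class RegulatorInference:
    """Infer the transcriptional regulators of a query gene set.

    Parameters
    ----------
    store : CompendiumStore
        Grid, annotation, chromatin profiles, cistromes and covariates.
    query_genes : sequence of str
        Query gene identifiers (e.g. one direction of a differential
        expression contrast; analyze up- and downregulated sets separately).
    params : RPParams, optional
        Decay-model parameters (L = 100 kb, half-decay 10 kb by default).
    background_size : int, default 3000
        Number of activity-matched background genes to sample.
    max_profiles : int, default 10
        Cap on chromatin profiles selected per assay.
    mode : {'chipseq', 'motif'}, default 'chipseq'
        Which cistrome source to rank and how many channels to combine
        (3 for ChIP-seq: peak-RP + two ISD; 2 for motif: ISD only).
    seed : int, default 0
        Seed for background sampling (the only stochastic step).
    """

    def __init__(
        self,
        store: CompendiumStore,
        query_genes: Sequence[str],
        params: Optional[RPParams] = None,
        background_size: int = DEFAULT_BACKGROUND_SIZE,
        n_bins: int = DEFAULT_BINS,
        max_profiles: int = DEFAULT_MAX_PROFILES,
        mode: str = "chipseq",
        seed: int = 0,
    ) -> None:
        if mode not in SOURCE_OF_MODE:
            raise ValueError("mode must be 'chipseq' or 'motif'")
        self.store = store
        self.params = params or RPParams(window_size=store.grid.window_size)
        self.background_size = background_size
        self.n_bins = n_bins
        self.max_profiles = max_profiles
        self.mode = mode
        self.seed = seed

        self.match_report = resolve_gene_ids(query_genes, store.gene_ids)
        if self.match_report.fallback_matched:
            logger.info(
                "%d query identifiers matched case-insensitively",
                len(self.match_report.fallback_matched),
            )
        if not self.match_report.matched:
            raise ValueError(
                "no query genes resolvable in the store; unmatched: "
                + ", ".join(self.match_report.unmatched[:10])
            )
        if len(self.match_report.matched) < 20:
            warnings.warn(
                f"only {len(self.match_report.matched)} query genes resolved; "
                "results may be unstable below 20"
            )
        self.query = list(self.match_report.matched)

    @classmethod
    def from_files(
        cls, store_path, gene_list_path, **kwargs
    ) -> "RegulatorInference":
        from .io import read_gene_list

        store = load_store(store_path)
        return cls(store, read_gene_list(gene_list_path), **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self) -> "RegulatorResults":
        store = self.store
        if store.covariates is None:
            raise ValueError(
                "store has no promoter-activity covariates; required for "
                "background stratification"
            )
        sets = select_background(
            set(self.query),
            store.gene_ids,
            store.covariates,
            n=self.background_size,
            bins=self.n_bins,
            seed=self.seed,
        )
        logger.info(
            "gene sets: %d query, %d background", len(sets.query), len(sets.background)
        )

        if store.rp_cache is None:
            logger.info("computing RP matrix for %d tracks", len(store.tracks))
            build_rp_cache(store, self.params)
        rp = store.rp_cache

        by_id = {g.gene_id: g for g in store.genes}
        genes_sub = [by_id[g] for g in sets.all_genes]
        y = sets.labels
        row_of = {g: i for i, g in enumerate(rp.gene_ids)}
        rows = np.array([row_of[g] for g in sets.all_genes])
        normalized = rp.normalized

        models: Dict[str, ChromModel] = {}
        for assay in ("dnase", "h3k27ac"):
            assay_tracks = store.tracks_of(assay)
            if not assay_tracks:
                logger.info("no %s tracks in store; skipping assay", assay)
                continue
            cols = [rp.column(t.profile_id) for t in assay_tracks]
            X = normalized[np.ix_(rows, cols)]
            penalty, sel_idx = fit_l1_path(X, y, max_profiles=self.max_profiles)
            sel_ids = [assay_tracks[i].profile_id for i in sel_idx]
            model = fit_final_model(
                X[:, sel_idx], y, sel_ids, assay_kind=assay, penalty=penalty
            )
            frame = pd.DataFrame(
                normalized[np.ix_(rows, [rp.column(p) for p in sel_ids])],
                columns=sel_ids,
            )
            model.auc = model_auc(model.model_rp(frame), y)
            logger.info(
                "%s landscape: %d profiles selected, AUC %.3f",
                assay, len(sel_ids), model.auc,
            )
            models[assay] = model
        if not models:
            raise ValueError("store has no chromatin tracks for any assay")

        source = SOURCE_OF_MODE[self.mode]
        cistromes = store.cistromes_of(source)
        if not cistromes:
            raise ValueError(f"store has no cistromes with source {source!r}")

        tracks_by_id = {t.profile_id: t.values for t in store.tracks}
        channel_p: Dict[str, Dict[str, float]] = {}
        meta: Dict[str, Tuple[str, str]] = {}
        deltas: Dict[str, Dict[str, DeltaRPResult]] = {}
        nq = len(sets.query)
        for c in cistromes:
            meta[c.cistrome_id] = (c.tr_name, c.source)
            chans: Dict[str, float] = {}
            if self.mode == "chipseq":
                prp = compute_peak_rp(c, genes_sub, store.grid, self.params)
                chans["peak_rp"] = _channel_p(prp.values[:nq], prp.values[nq:])
            per_assay: Dict[str, DeltaRPResult] = {}
            for assay, model in models.items():
                res = delta_rp(
                    model, rp, tracks_by_id, c, genes_sub, store.grid, self.params
                )
                per_assay[assay] = res
                chans[ASSAY_CHANNEL[assay]] = _channel_p(
                    res.delta_rp[:nq], res.delta_rp[nq:]
                )
            deltas[c.cistrome_id] = per_assay
            channel_p[c.cistrome_id] = chans

        # an assay absent from the store yields no ISD channel; in that case
        # combine over what exists rather than skipping every cistrome
        present = set()
        for chans in channel_p.values():
            present.update(chans)
        if self.mode == "chipseq" and {"isd_dnase", "isd_h3k27ac"} - present:
            for chans in channel_p.values():
                for ch in ("isd_dnase", "isd_h3k27ac"):
                    chans.setdefault(ch, 1.0)
        if self.mode == "motif":
            for chans in channel_p.values():
                for ch in ("isd_dnase", "isd_h3k27ac"):
                    chans.setdefault(ch, 1.0)

        table = combine_channels(channel_p, meta, mode=self.mode)
        return RegulatorResults(
            model=self,
            gene_sets=sets,
            chrom_models=models,
            rank_table=table,
            channel_pvalues=channel_p,
            delta_results=deltas,
        )


def _channel_p(query_vals: np.ndarray, background_vals: np.ndarray) -> float:
    """One-sided rank-sum p for a channel; all-zero evidence scores p = 1."""
    if np.all(query_vals == 0) and np.all(background_vals == 0):
        return 1.0
    return wilcoxon_one_sided(query_vals, background_vals)


@dataclass
class RegulatorResults:
    """Fitted landscape models, channel p-values and the final TR ranking."""

    model: RegulatorInference
    gene_sets: GeneSetPair
    chrom_models: Dict[str, ChromModel]
    rank_table: TRRankTable
    channel_pvalues: Dict[str, Dict[str, float]]
    delta_results: Dict[str, Dict[str, DeltaRPResult]] = field(default_factory=dict)

    @property
    def aucs(self) -> Dict[str, float]:
        return {a: m.auc for a, m in self.chrom_models.items()}

    def model_summary_frame(self) -> pd.DataFrame:
        return pd.concat(
            [m.summary_frame() for m in self.chrom_models.values()],
            ignore_index=True,
        )

    def delta_rp_frame(self, assay: str) -> pd.DataFrame:
        """Genes x cistromes table of ISD effects for one assay."""
        cols = {}
        for cid, per_assay in self.delta_results.items():
            if assay in per_assay:
                res = per_assay[assay]
                cols[cid] = pd.Series(res.delta_rp, index=res.gene_ids)
        return pd.DataFrame(cols)

    def summary(self, top: int = 10) -> str:
        lines = [
            "Transcriptional regulator inference",
            "===================================",
            f"mode: {self.model.mode}    query genes: {len(self.gene_sets.query)}"
            f"    background genes: {len(self.gene_sets.background)}",
        ]
        for assay, m in self.chrom_models.items():
            lines.append(
                f"{assay} landscape: {len(m.selected_profiles)} profiles, "
                f"AUC {m.auc:.3f}"
            )
        lines.append("")
        head = self.rank_table.table.head(top)
        lines.append(f"top {min(top, len(head))} cistromes by combined p:")
        with pd.option_context("display.float_format", "{:.3g}".format):
            lines.append(
                head[
                    ["rank", "cistrome_id", "tr_name", "p_peak_rp",
                     "p_isd_dnase", "p_isd_h3k27ac", "p_combined"]
                ].to_string(index=False)
            )
        return "\n".join(lines)

    def to_tsv(self, out_dir) -> Dict[str, str]:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ranked = out / f"ranked_{self.model.mode}.tsv"
        self.rank_table.to_tsv(ranked)
        summary = out / "model_summary.tsv"
        self.model_summary_frame().to_csv(summary, sep="\t", index=False)
        return {"ranked": str(ranked), "model_summary": str(summary)}
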