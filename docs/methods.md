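# Methods

## Model overview

`chromisd` ranks candidate transcriptional regulators (TRs) of a query gene
set by asking how much each TR's binding sites matter to a chromatin model
of that gene set. The chain of reasoning is: (1) a gene's regulation is
summarized by regulatory potentials (RPs), decaying sums of nearby genomic
signal; (2) a small panel of chromatin profiles whose RPs separate query
from background genes defines a landscape model of the gene set; (3)
deleting a cistrome's windows from the signal and propagating the loss
through the frozen model measures that TR's predicted impact per gene; (4)
one-sided rank tests contrast the impact on query versus background genes,
and the Cauchy combination aggregates the evidence channels into one p per
cistrome.

Key assumptions: regulatory influence decays with TSS distance and is
additive across sites; chromatin signal is a proxy for regulatory activity
(correlation, not causation, is claimed); a true regulator's peaks
co-localize with the signal that discriminates the query set; deleting
signal can only remove evidence, hence one-sided tests.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| L | 100 000 | bp | half-interval of the RP sum around the TSS |
| Δ | 10 000 | bp | half-decay distance: w(Δ) = 1/2 exactly |
| μ | ln(3)·L/Δ | — | decay rate on the d = distance/L scale |
| window_size | 1000 | bp | grid resolution for signal, deletion, occupancy |
| background_size | 3000 | genes | activity-matched background sample |
| n_bins | 10 | — | covariate quantile strata for background sampling |
| max_profiles | 10 | profiles | cap on L1-selected profiles per assay |
| scan_window | 100 | bp | motif-scan tile width |
| threshold_percentile | 99 | % | per-motif hit threshold |
| promoter half-width | 5000 | bp | baseline peaks/hits-in-promoter interval |

The weight parameterization fixes exp(−μΔ/L) = 1/3, which makes
w(0) = 1, w(Δ) = 1/2 and w(L) = 2·3⁻¹⁰/(1+3⁻¹⁰) ≈ 3.39·10⁻⁵; Δ is the only
interpretable decay knob. μ is derived, never set directly.

## Numerical and design choices

- **Binned evaluation.** RPs are computed on the 1-kb grid from
  window-midpoint distances, not per-nucleotide. This makes in silico
  deletion an exact algebraic subtraction — deleting every window drives the
  RP to exactly zero — and the per-window deletion term w_m·s_jm needs no
  separate length factor because s is the window-mean signal and the sum is
  in window units. Sub-kilobase positional error in the weight is the
  accepted cost.
- A window contributes to a gene iff its midpoint lies in [t_k−L, t_k+L];
  the interval truncates at chromosome ends. The last partial window of a
  chromosome is kept, with signal averaged over its actual span (mass
  conserving). Strand places the TSS but does not flip the (symmetric)
  weight.
- All logs are natural. Normalization offsets are per profile, over all
  genes in the store's annotation, and are reused unchanged after deletion.
- Deleted RPs are clamped at zero before the log; on the binned grid
  negative values can only arise from rounding.
- ΔRP is evaluated sparsely: a gene with no occupied window within ±L gets
  an exact zero without recomputation, and only query ∪ background genes are
  touched.
- **Background sampling** stratifies the gene universe into promoter-activity
  deciles and draws without replacement so each stratum contributes its
  universe share (largest-remainder rounding, deficits refilled from the
  remaining pool). The spec's alternative — matching the query's covariate
  profile instead of the universe's — was considered and not used: sampling
  "a range of activities" reads as representative sampling, and a
  universe-matched background keeps the null hypothesis interpretable when
  the query is activity-biased. With fewer non-query genes than requested,
  all of them are used (with a warning), which is the desk-scale regime.
- **L1 profile selection** standardizes features, then binary-searches the
  penalty (liblinear, ≤ 50 fits, bounds auto-expanded over C ∈ [1e-8, 1e6])
  for the weakest penalty whose nonzero count stays within the cap; ties
  resolve toward fewer profiles. The final model is an unpenalized logistic
  refit stabilized by a 1e-6 ridge; its coefficients are mapped back to the
  unstandardized RP scale so the same α apply directly to deletion
  differences. On exactly collinear profiles the L1 optimum is non-unique
  and the solver may retain both copies; only the cap is guaranteed.
- **Rank tests** use exact enumeration when min(n, m) ≤ 8 with no ties,
  otherwise the normal approximation with tie and continuity corrections.
  Samples that are a single constant (e.g. a cistrome whose deletion touches
  nothing) carry no evidence and score p = 1 rather than being dropped.
  Before the Cauchy transform p-values are clamped to [1e-15, 1−1e-15]
  because tan((0.5−p)π) diverges at the endpoints. Rank ties break by
  smaller mean ISD-channel p, then lexicographic cistrome id, so output is
  deterministic.
- **Motif scanning** tiles the genome with non-overlapping 100-bp windows;
  within a tile every stride-1 placement on both strands is scored
  (log-odds with a 0.001-background pseudocount) and the tile takes the
  maximum. Placements containing N score −∞. The hit threshold is the
  per-motif linear-interpolation percentile of all finite tile scores, with
  strict inequality so ties cannot push the hit fraction above 1%. Hit tiles
  map to the 1-kb window containing the tile midpoint. Overlapping tiling
  was considered and rejected as a resolution/compute trade-off; plants are
  recovered regardless because placements are dense within tiles.
- The promoter-count baseline uses a closed interval [tss−5000, tss+5000]
  on base-pair summit positions (an explicit boundary contract).
- Peaks are reduced to summits (given summit offset, else the interval
  midpoint); occupancy is set-valued per window. A 100-bp binarized peak
  representation appears in upstream tooling but feeds no formula here and
  is not stored.
- Up- and downregulated gene sets are separate runs by design; no automatic
  direction calling.

## The synthetic compendium

The generator (`chromisd.simulate`) emulates the statistical structure the
method assumes rather than the mechanics of sequencing:

- log-normal per-window background signal (positive, heavy-tailed, like
  real coverage), σ = `noise_sd` (default 1.0);
- one planted cistrome with a peak within ±Δ of each query gene's TSS plus
  uniform background peaks; decoy cistromes purely uniform at
  `peak_rate` = 0.02 occupied-window fraction (a few peaks per ±L interval,
  so peak-RPs are mostly nonzero and rank tests are well behaved);
- `n_informative` profiles per assay carry an `effect_size`-fold (default 5)
  multiplicative enrichment in a ±2-window boxcar around each planted
  summit; remaining profiles are pure noise;
- the promoter-activity covariate is derived from the generated tracks
  (log mean signal in the TSS ± 2 windows);
- default geometry: 2 chromosomes × 5 Mb, 400 genes, 12 profiles/assay,
  30 cistromes, 60 query genes — chosen so the full pipeline runs in
  seconds while exercising every sparsity path.

`effect_size = 1` is the null condition: peaks are placed uniformly and the
query set is drawn at random, so the "planted" cistrome is exchangeable
with the decoys. (Merely removing the signal enrichment would not be a
null: peaks near query TSSs are detectable by the peak-RP channel alone.)

`generate_sequences` embeds a consensus motif at the planted summits
(about half reverse-complemented) in an otherwise uniform-random genome,
for testing the scanner's recall against known plants.

What the generator does **not** emulate: mappability and GC biases,
fragment-level read noise, peak-width variation, TAD structure, correlated
profiles from shared cell types, or indirect (tethered) binding. Passing
tests therefore demonstrate correctness of the algebra and calibration of
the statistics under the assumed structure, not performance on real
compendia, where signal-to-noise and confounding are far less favorable.

## Degenerate inputs and edge behavior

Empty interval lists bin to a zero track; cistromes with no occupied
windows get ΔRP ≡ 0 and p = 1 in every channel; an empty motif hit set
classifies every peak as indirect (with a warning); gene sets smaller than
20 resolvable identifiers warn; duplicate gene ids in an annotation are an
error (one representative TSS per gene is the contract, collapsing isoforms
is the caller's job). Store files carry per-dataset CRC32 checksums; a
corrupted array fails loading with an explicit integrity error.

## Known limitations

- Landscape discrimination (AUC ≈ 0.98 on the defaults) is easier on
  synthetic data than the ~0.8 typical of real compendia; the acceptance
  bound (> 0.9) is meaningful only under the generator's conditions.
- The Cauchy combination assumes channels are individually valid p-values;
  heavy discreteness (tiny gene sets, near-empty cistromes) makes the
  combination conservative.
- Motif-imputed cistromes inherit every limitation of PWM scanning; no
  machine-learned binding imputation is attempted.
- One TSS per gene: alternative promoters are invisible to the RP.
- No multiple-testing correction across cistromes: output is a ranking,
  not a significance call.
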