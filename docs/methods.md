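# Methods

This note documents the statistical procedures implemented by `sigscore`,
the parameters that matter, the synthetic data used to validate them, and
the design choices made where published descriptions leave room.

## Input contract

All scoring functions take a normalized expression matrix with genes as rows
(official HUGO symbols, matched case-sensitively after whitespace trimming)
and samples as columns. Both microarray log-intensities and log-scale
normalized RNA-seq values satisfy the contract; no normalization, batch
correction or identifier conversion is performed. `validate_expression`
enforces it:

- rows containing any missing or non-finite value are dropped (count
  logged); imputation is out of scope;
- duplicate gene symbols are collapsed to the row with the highest mean
  expression — the common probe-collapse convention — rather than averaged,
  which would blur rank-based statistics; ties keep the first row;
- duplicate sample identifiers are an error;
- validation is idempotent and preserves row/column order.

Genes listed in a signature but absent from the matrix are intersected out
silently at scoring time; quantifying that loss is the explicit job of
`check_sig`, which reports counts, fractions and missing symbols per
signature and treats zero coverage as a reportable fact, not an error.

## Enrichment engines

All three engines score each signature independently per sample and return
a tidy table (`sample_id` column plus one column per signature). Signatures
with no genes in the matrix yield an explicit NA column with a warning —
never silent zeros.

### Combined z-score

Each gene is standardized across the cohort with the sample standard
deviation (divisor n−1). Zero-variance genes get z = 0 with a warning so a
constant housekeeping row cannot abort a run. The signature score is
`Σ z / √k` over the k present set genes; up- and down-gene lists are pooled,
as the classic combined z-score is undirected. The score is shift- and
scale-invariant in expression units but cohort-dependent through the z step.

### ssGSEA

Within each sample, genes are ranked 1..N ascending in expression (tie rule
below) and walked in order of decreasing rank, ties broken by matrix row
order (stable sort) for determinism. The running sum accumulates the
normalized in-set weight `rank^α` against the out-set empirical CDF; the
enrichment score is the sum of the differences over all N positions. The
exponent α defaults to 0.25; α = 0 weights all in-set genes equally.
Normalization modes:

- `raw` (default): the plain enrichment score;
- `separate`: each signature column divided by its own max−min across
  samples;
- `all`: every score divided by the single global max−min across all
  requested signatures — note this makes scores depend on the cohort *and*
  on which signatures were requested together; use it only when that
  coupling is intended.

A zero normalization range (e.g. a cohort of identical samples) is an error
naming the degenerate signature. A set covering every gene of the matrix is
an error (the out-set CDF is undefined).

### singscore

The directional score is the normalized mean rank
`(meanRank − r_min)/(r_max − r_min)` with `r_min = (k+1)/2` and
`r_max = (2N−k+1)/2`, exactly 0 when the set occupies the bottom k ranks
and 1 at the top. Down-regulated lists are scored on reversed ranks
(N+1−rank) and added to the up component. Centering (default on) subtracts
0.5 per direction, giving symmetric ranges [−0.5, 0.5] (undirected) and
[−1, 1] (bidirectional). Undirected sets are treated as up-sets on plain
ranks by default; an `abs_median_centered` mode ranks |x − sample median|
instead, for sets whose genes deviate in both directions. A declared down
list whose genes are all absent degrades to up-only scoring with a warning.

### Ties

Tied expression values receive average ranks by default, which preserves the
rank-sum invariant Σranks = N(N+1)/2; `min` and `max` rules are available
for compatibility studies. On continuous expression data ties are rare and
the choice is immaterial.

### Original-publication archetypes

`score_original` evaluates the two recipes that cover most published
signatures: the arithmetic mean of the present signature genes, and the
weighted sum `Σ coeff_g · x_g` (a fitted-model linear predictor). For the
weighted sum every listed gene must carry a coefficient; genes absent from
the matrix drop their term with a warning. Signatures whose original
procedure *is* an enrichment method (`ssgsea_like`) are dispatched to raw
ssGSEA by `hack_sig`.

## Dedicated scorers

### ESTIMATE-style

Immune and stromal scores are raw ssGSEA scores (α = 0.25) of the two gene
sets; the ESTIMATE score is their exact sum. Tumor purity is
`cos(a + b·ESTIMATE)` with the published calibration a = 0.6049872018,
b = 0.0001467884, valid on the monotone-decreasing branch `[0, π]` of the
cosine; samples leaving that branch get NA with a warning, and the cosine
is clamped to [0, 1]. The calibration was fit on Affymetrix-scale scores
(order 10³–10⁴); on other platforms the purity mapping should be treated as
indicative. Gene lists and coefficients live in an editable YAML config.

### CINSARC-style

Present signature genes are standardized across the cohort (mean 0, sd 1,
divisor n−1; constant genes contribute 0). For each sample, the per-gene
mean centroids of the no-metastasis (label 0) and metastasis (label 1)
groups are recomputed with that sample held out, and the sample is called
C1 (low risk) when strictly closer — Euclidean distance by default — to the
no-metastasis centroid, C2 otherwise; exact ties are C2, the conservative
call. Standardization is computed once on the full cohort by default
(simpler and stabler for small cohorts); `restandardize=True` re-derives it
within each leave-one-out fold. `metric="correlation"` (1 − Pearson) is
available as an alternative distance. Both label classes must have at least
two samples so leave-one-out centroids always exist.

### Immunophenoscore

Per-gene z-scores (same z step as the combined z-score) are averaged into
marker scores; each category score (MHC, EC, SC, CP) is the
weight-normalized sum `Σ w·s / Σ|w|` of its markers, so with unit-magnitude
weights it is the mean of the signed marker scores; `az` is the sum of the
four category scores, and the discrete score is IPS = 0 for az ≤ 0, else
`min(10, round(az·10/3))`, rounding half away from zero (the published
procedure does not state its rounding convention; half-away-from-zero is
documented and tested here). Markers with no genes in the matrix are
dropped with a warning; a category losing all markers is an error. The
z step makes the IPS invariant to adding a constant to all expression
values.

### Bundled configuration data

The three dedicated scorers read editable YAML configs carrying a
`method_doi` provenance field. The purity coefficients are transcribed from
the published calibration. The gene lists, however, are demonstration
stand-ins — short panels of canonical marker genes, *not* the published
141-gene ESTIMATE lists, 67-gene CINSARC list, or supplementary IPS
cell-type lists — and the files are named and annotated `synthetic`
accordingly. Users analysing real data should drop in the published lists;
everything downstream treats the configs as data.

## Registry and dispatch

The bundled registry is a small demonstration catalog (one YAML per
signature: id, keywords, DOI, description, gene lists, optional
coefficients, original-method descriptor), including two mean-scored
published signatures and two clearly-labelled synthetic demos exercising
the weighted-sum and directional paths; the dedicated scorers appear as
registry entries so `get_sig_info`/`get_sig_genes` discover everything
through one interface. Curating a large signature collection is a non-goal:
the GMT path and the signature schema make user curation first-class.

Keyword selection is case-insensitive substring matching against ids and
keywords (an exact mode exists); several keywords select the union of their
matches. `hack_sig` dispatch rules:

- registry signatures, no method → each signature's original procedure;
  dedicated signatures are skipped with a pointer to their functions (an
  error if the selection contains nothing else);
- registry signatures + `zscore`/`ssgsea`/`singscore` → that engine for all
  matches, dedicated ones included (scored as plain gene sets);
- custom gene sets, no method → raw ssGSEA;
- custom gene sets + `original` → usage error (no publication procedure is
  attached to a custom set).

Dispatch adds nothing numerically: scores equal the direct engine calls.

## Parallelism

`parallel_score` partitions per-sample methods (ssGSEA, singscore) by
sample and reassembles in order; cohort-level coupling (the z step;
`separate`/`all` ssGSEA normalization) is computed once on the full data,
so results are bit-identical for any worker count. The combined z-score is
computed whole — its cost is a single vectorized pass and parallelizing it
would only add transport overhead.

## Synthetic data

`make_cohort` draws i.i.d. Gaussian baseline expression (mean 6, sd 1, a
log2-like scale) and up-shifts the genes of one set by `effect_size` sd in
a designated sample fraction; `make_separable_classes` builds two Gaussian
clusters `delta` sd apart per gene for the nearest-centroid harness.
Defaults (1000 genes × 50 samples, 25-gene set, 2 sd shift in half the
cohort) describe a mid-sized expression study. All randomness flows from
the explicit seed; equal seeds give bit-identical cohorts.

What the generators deliberately do not emulate: count-scale RNA-seq noise,
gene–gene correlation structure, batch effects, and heavy-tailed platform
artefacts. Passing tests therefore demonstrate correctness of the scoring
arithmetic and the planted-signal behaviour of the methods, not robustness
to real-data pathologies — on real cohorts the usual normalization and QC
obligations stand.

## Validation strategy and problem sizes

The test suite checks every engine against an independent brute-force
implementation sharing no code with it: an explicit P_in/P_out running-sum
walk for ssGSEA (200 random instances, N ≤ 50, |S| ≤ 10, α ∈ {0, 0.25, 1},
agreement to 1e−9), direct mean-rank enumeration for singscore, closed
forms for the combined z-score, and a literal leave-one-out centroid loop
for the classifier. Invariance properties (monotone-transform, permutation,
shift) and round-trip identities (GMT, wide/long score layouts) are
asserted exactly. Parallel determinism is verified on a 2000-gene ×
50-sample cohort. Classifier calibration uses 20 replicates of
delta = 4 (perfect recovery expected) and delta = 0 cohorts (pooled
accuracy inside the binomial 99% band around 0.5); these sizes make the
whole suite run in well under a minute while leaving the binomial band
tight enough to detect systematic bias.

## Known limitations

- The cosine purity calibration is platform-sensitive; outside
  Affymetrix-scale scores it should be read qualitatively.
- Bundled dedicated gene lists are demo stand-ins (see above).
- Empirical p-values for enrichment scores and the GSVA kernel method are
  out of scope; the package implements three single-sample alternatives.
- `ssgsea_norm="all"` couples scores across requested signatures by design.
- Leave-one-out nearest-centroid classification carries a small negative
  bias at the null (the held-out sample's own class centroid is estimated
  from one fewer sample); it vanishes as class sizes grow.
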