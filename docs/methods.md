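# Methods

This note documents the models, statistics, parameter choices and known
limitations of `agingaccel`. It is the package's own account of what it
computes; every number quoted here is produced by the test suite, the
example scripts, or `scripts/acceptance.py` at run time.

## The analysis in one paragraph

Given a genes × samples brain-expression matrix with per-sample age,
diagnosis (AD / normal) and tissue, the package (i) selects *aging
biomarkers* (genes separating young from old normals) and *AD biomarkers*
(genes separating AD from normal) with ReliefF ranking and a
nearest-neighbour classifier tuned by cross-validation; (ii) assigns every
sample a *transcriptomic aging score* from its distances to young and old
reference profiles; (iii) builds an *aging-acceleration network* whose
edges are gene pairs whose expression product tracks the aging score with
opposite correlation signs in AD versus normal samples; (iv) connects the
two biomarker panels through shortest paths in that network (the aging–AD
*bipartite graph*); and (v) tests gene lists arising at each step for
gene-set over-representation with the hypergeometric test and
Benjamini–Hochberg FDR.

## Preprocessing (`preprocess`)

Fixed order: probe collapsing → missingness filter and imputation → log
transform → per-tissue SVD diagnostic → z-scoring.

- **Probe collapsing.** Probes mapping to one symbol are averaged per
  sample; a cell's mean is over the probes that are non-missing in that
  sample. The mean is the common convention for array summarisation;
  median or max would also be defensible and the rule is isolated in
  `collapse_probes` if a user needs to swap it.
- **Missingness.** Genes with a missing fraction ≥ 0.30 (inclusive) are
  removed. Remaining gaps are filled with the gene's mean within the same
  tissue (falling back to the gene's global mean if a tissue is entirely
  missing). Mean imputation is the minimal-assumption filler and is
  neutral under the later z-scoring.
- **Log transform.** `log2(x + 1)`. Matrices already containing negative
  values are assumed to be on a log-like scale and pass through unchanged
  (`force=True` overrides). This matters for the synthetic cohorts, whose
  baseline is Gaussian around zero.
- **SVD.** Per tissue with ≥ 2 samples, the row-centred submatrix's
  squared singular values are reported as variance fractions. This is a
  *diagnostic* of inter-sample variation; no components are removed and no
  correction is applied.
- **z-score.** Per gene across all samples of the cohort, population SD.
  Zero-variance genes become all-zero rows and are reported via a warning.
  Scoping the z-score per cohort rather than per tissue is a choice; the
  per-tissue alternative would erase cross-tissue level differences that
  the predictors may legitimately use.

## Biomarker predictors (`predictor`)

Two binary tasks: **aging** (normal samples; label 1 iff age > 50 years)
and **disease** (all samples; label 1 iff AD). Data are split 2:1 into
train/test, stratified by label, so class proportions agree between the
parts to within rounding.

- **ReliefF.** Every training sample is visited once (m = n). Features
  are range-normalised; neighbourhoods are the k = 10 nearest hits and
  k = 10 nearest misses under Manhattan distance on the normalised
  features; a gene's weight is the average (miss difference − hit
  difference). These are the standard ReliefF defaults in the feature-
  selection literature. Constant genes get weight exactly 0. Determinism:
  weight ties in the output ranking break lexicographically by symbol.
- **Nearest-neighbour classifier.** 1-NN with distance
  `1 − cos(u, v)`. The predicted label is 1 iff the nearest label-1
  reference is strictly closer than the nearest label-0 reference; ties go
  to label 0. The ROC score is the margin `d0 − d1`; a 1-NN classifier has
  no native probability, and the margin is the minimal continuous
  statistic consistent with the distance.
- **Model selection.** The nested models "top-1 … top-`top_models` (100)
  genes" of the ranking are scored by stratified 5-fold CV accuracy
  (pooled over folds); `best_k` is the smallest maximiser. The scan is
  incremental — one rank-1 update of the cosine Gram matrix per added
  gene — so it costs O(K · n²) rather than O(K² · n²). If `folds ≥ n`
  the scheme degrades to leave-one-out.
- **Evaluation.** AUC is the trapezoid area under the score-thresholded
  ROC, which equals Mann–Whitney concordance with ties counting ½ (an
  equivalence the tests assert to 1e-12). Single-class test sets raise.

## Aging score (`aging_score`)

Normal samples are split into **young** (age ≤ 50) and **old** (> 50)
reference pools over the aging-marker panel. A sample's raw score is
`min_y ||x − y||₂ − min_o ||x − o||₂`; the reported score is
`arctan(raw)`, bounded in (−π/2, π/2). Higher = transcriptomically older.
A sample that is itself a pool member is scored leave-one-out (otherwise
its own term would be 0 by self-matching); if exclusion empties a pool the
sample is not scorable and the call fails loudly. Distances are computed
on the z-scored matrix, and pools are drawn from all normal samples by
default (`build_reference_pools` accepts any sample subset, so train-only
pools are a one-line variant).

Group comparisons use the Kruskal–Wallis rank test (tie-corrected,
chi-squared reference) on the atan scale, within nested age strata
(floors 58, 60, 65, 70, 75, 80, 85 by default). The test is rank-based,
so it is invariant to the atan transform; the transform only stabilises
the reported means/medians.

## Aging-acceleration network (`network`)

For each unordered gene pair (canonical lexicographic order), the Pearson
correlation between the per-sample product `x_i · x_j` and the samples'
atan aging scores is computed separately in AD and in normal samples,
with two-sided p-values from the t reference with n − 2 df. An edge is
retained iff p < 0.05 in both conditions, BH FDR < 0.2 in both
conditions, and the two correlation signs differ. The BH family is all
tested pairs within one condition — the only family that is well defined
without further assumptions. Zero-variance products are excluded (never
passed through as p = 0); a pair must survive in both conditions to be
tested.

Products are formed in gene-row blocks, so peak memory scales with
`chunk_rows × n_genes × n_samples`, independent of the ~G²/2 pair count;
the tests verify block-size invariance against a dense per-pair
computation to 1e-10. At the full 11,333-gene scale (~64M pairs per
condition) the same code path applies; the shipped tests run at ≤ 500
genes to stay desk-sized.

Validation mirrors the intended use:

- **Fisher overlap** of two networks (e.g. train- and test-derived): 2×2
  table over the all-unordered-pairs universe of the shared profiled
  genes (isolated genes included), one-sided exact p.
- **Scale-free diagnostic**: Pearson r between log₁₀(degree) and
  log₁₀(degree probability) over distinct degrees of connected nodes;
  an exact `P(d) ∝ d⁻²` fixture yields r = −1 and 1,000-node
  preferential-attachment graphs yield r ≈ −0.93. This is the
  log-log-linearity check, deliberately not a maximum-likelihood
  power-law fit.
- **Hub predictor**: genes ranked by network degree (ties lexicographic)
  replace the ReliefF ranking, and the same CV/top-k/evaluation machinery
  runs downstream — a check that the network's hubs carry disease signal.

## Bipartite graph (`bipartite`)

Shortest paths between every (aging marker, AD marker) pair inside the
acceleration network. The network is unweighted, so Dijkstra coincides
with breadth-first search; among tied shortest paths the lexicographically
smallest node sequence is returned, making results order-independent.
Unreachable and same-gene pairs are omitted. The summary reports both the
number of connected pairs and the per-panel connected-marker counts, plus
per-marker connection degrees (the "links the most" ranking). The
cross-panel Pearson correlation matrix is computed in AD samples, and the
largest-|r| (aging, AD) pair is reported, excluding self-pairs.

## Enrichment (`enrichment`)

Hypergeometric upper tail `P(X ≥ x)` with background N = the number of
profiled genes (not the union of set members), set size M counted after
intersecting the set with the background, query size n after intersecting
the query. Evaluated through the hypergeometric survival function, stable
at N ~ 10⁴. BH FDR per call (one collection × one query), so path-level
enrichments each form their own family. Significance requires strictly
p < 0.05 and FDR < 0.2.

## Synthetic cohorts (`synthetic`)

The generator emulates the structure the analysis assumes, not any
particular dataset: ages uniform on [20, 100]; i.i.d. Gaussian baseline
(`noise_sd` = 1); a few hundred samples per diagnosis arm; three tissues;
optional MCAR missingness.

Planted signals, on disjoint gene blocks:

- **aging markers** (default 30): `+ aging_effect × a` in every sample,
  with `a` the standardised age (effect 1.0 ≈ r ≈ 0.7 with age at unit
  noise);
- **AD markers** (default 30): `+ ad_effect` in AD samples;
- **planted edges** (default 20): `x_j = ± b·a·x_i + ε`, `+` in normal,
  `−` in AD, so `x_i·x_j` has conditional mean `± b·a·σ²` — exactly the
  opposite-sign product-correlation structure the network criterion
  retains; `b = edge_strength` (default 1);
- **acceleration** (`ad_acceleration`, default 0): an extra shift of AD
  samples along the aging-marker axis, making them transcriptomically
  older than their chronological age.

Default cohort size is 500 genes and 300 samples per arm — large enough
for the planted effects to be comfortably detectable at the stated effect
sizes, small enough that the full analysis runs in seconds. Chronological
age is used as the planting surrogate for the aging score because the
pipeline's score is constructed to increase with age; the planted
structure therefore transfers to the pipeline-derived score, which the
tests confirm empirically (Spearman ρ ≈ 0.87 between score and age).

One consequence worth knowing: with both aging markers and mean-shifted
AD markers present, *every* (aging marker × AD marker) pair genuinely
satisfies the edge criterion — within AD samples the product is
`≈ +c · x_aging`, within normals `≈ −c · x_aging`, giving significant
opposite-sign correlations. Recovered networks therefore contain this
dense cross-marker block in addition to the explicitly planted edges. It
is planted structure, not a false-positive artefact; specificity is
measured on pairs in which neither gene carries any planted signal, where
the edge rate is ~10⁻⁵.

What the generator does **not** emulate: platform/batch effects across
array platforms, tissue-specific co-expression, realistic (heavy-tailed,
count-derived) expression distributions, age-dependent missingness, or
correlated marker blocks. Passing tests show the machinery is correct and
powered under the planted model; they do not certify performance on real
compendia, where effect sizes are smaller and confounding is real.

## Pipeline (`pipeline`)

`run_all` executes the stages in order, writes every artifact as plain
TSV/JSON, and records SHA-256 digests in `manifest.json`. One global seed
is fanned out to stage seeds by fixed offsets, so any stage can be rerun
independently and reproduce its output byte-for-byte (TSV floats are
written in shortest-round-trip form and parsed back with round-trip
precision precisely so that resume-from-disk is bit-exact). With
`resume=True`, stages whose outputs exist are loaded instead of
recomputed. When no GMT file is supplied, a seeded synthetic gene-set
collection (the planted marker panels plus random sets) keeps the
enrichment stage exercised.

## Numerical conventions and degenerate inputs

- Ties: prediction ties → label 0; `best_k` ties → smallest k; degree and
  ReliefF-weight ties → lexicographic by symbol; tied shortest paths →
  lexicographically smallest sequence.
- |r| = 1 correlations are assigned p = 0 rather than propagating a
  division overflow.
- Kruskal–Wallis on identical values returns H = 0, p = 1 with a warning
  instead of failing.
- Constant genes: weight 0 in ReliefF, all-zero rows after z-scoring,
  excluded pairs in the network, flagged rows/columns in correlation
  matrices — never silent NaNs.
- All stochastic components (generator, splits, CV folds) take explicit
  seeds; there is no hidden global RNG state.

## Known limitations

- ReliefF is O(n² · G) per task; fine for hundreds of samples, slow for
  tens of thousands (the intended cohort sizes are hundreds).
- The full-scale all-pairs network (11,333 genes) is supported by the
  chunked path but takes hours on one core at two conditions × 64M pairs;
  the package does not parallelise it.
- The aging score depends on reference-pool density; with very few young
  or old normals the nearest-reference distances are noisy, and the
  leave-one-out rule can make a pool of size 1 unusable by design.
- Probe collapsing assumes a probe→symbol map is supplied; no annotation
  lookup is performed.
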