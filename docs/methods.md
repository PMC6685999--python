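# Methods

This note documents the models, statistics, numerical choices and known
limitations of `noarewire`. Everything stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from
external runs.

## CNA burden and stress stratification

A sample's genomic-stress proxy is the fraction of the autosomal genome
covered by copy-number-altered segments:
`burden = (n_gain + n_loss) / n_autosome`, with 1-based inclusive
segment coordinates (length = end − start + 1). Segments whose segment
mean (log2 tumour/normal copy ratio) lies in the **open** interval
(−0.2, 0.2) are copy-neutral and ignored; values of exactly ±0.2 count
as altered. Overlapping segments are summed as given — no merging — and
a diagnostic warns when the summed altered length exceeds the genome
size, which is the signature of overlapping calls.

Stress cuts come from the pooled burden distribution: low ≤ first
quartile, high > median, computed with linear-interpolation percentiles
so the thresholds are exactly reproducible. Fixed cuts (e.g. the
published 7.0% / 19.2% pair) can be supplied through the config instead
of deriving them; deriving them on a strongly bimodal synthetic cohort
is legal but shifts group sizes, so the bundled fixtures use the fixed
pair. A cohort enters the comparative analysis only when both groups
have ≥ 20 samples (`min_group`).

## Preprocessing

* Gene filters: zero variance across samples, and raw count < 10 in
  *strictly more than* 90% of samples (exactly 90% low is kept).
  Filtering is idempotent.
* Normalization: median-of-ratios size factors against the
  geometric-mean reference sample; when fewer than 100 genes are
  positive everywhere, upper-quartile scaling is used instead. Values
  are `log2(count / size_factor + 0.5)`. The pseudocount of 0.5 keeps
  zeros finite while distorting the upper expression range negligibly.
* Covariate correction: per-gene least-squares residualization on
  intercept + covariates (categoricals dummy-coded). The projection is
  idempotent and leaves residuals exactly uncorrelated with continuous
  covariates; rank-deficient designs are rejected by name.
* CNA-correlated genes (dosage effects rather than stress rewiring) are
  removed by per-gene Pearson correlation between expression and
  gene-level CNA (length-weighted mean segment mean over the gene locus
  — a convention, since no aggregation rule is canonical), two-sided t
  p-values, Benjamini–Hochberg correction, and removal at q ≤ 0.05.

## Differential expression

An ordinary linear model per gene on the normalized log2 scale —
`expr ~ intercept + stress_group (+ covariates)` — so the group
coefficient is directly the log2 fold change (positive = up in high
stress), with two-sided t tests and BH correction across genes. This is
a deliberate simplification of a count-based negative-binomial GLM: on
variance-stabilized values the two agree in direction and
approximately in magnitude, the linear model is exactly reproducible
and fast, and the package's accuracy claims (planted-effect recovery,
null calibration) are verified against it directly. When the input has
already been residualized on covariates, the DE model omits them to
avoid double adjustment.

## Differential coexpression

* Change adjacency
  `d_ij = (½ |sign(c1_ij) c1_ij² − sign(c2_ij) c2_ij²|)^(β/2)` from
  per-condition Pearson matrices; zero-variance genes within a condition
  get zero correlations with a warning.
* Soft threshold β: `pick_soft_threshold` returns the smallest candidate
  whose change-connectivity distribution fits a scale-free line with
  signed R² ≥ 0.85 (log-binned frequency regression; the sign penalizes
  increasing fits), falling back to the best-fitting candidate with a
  warning. On the synthetic study conditions no candidate reaches the
  target and the fallback prefers β = 1, which over-densifies the
  network, so the pipeline default is the config value **β = 2**;
  moderate exponents (2–3) gave robust module recovery across seeds
  while high exponents compress the TOM scale until weakly separated
  modules sink into the background. Automatic selection remains
  available (`beta: null`).
* Topological overlap:
  `TOM_ij = (Σ_u d_iu d_uj + d_ij) / (min(k_i, k_j) + 1 − d_ij)` with
  unit diagonal, denominator floored at 1e−12. Verified against a
  triple-loop oracle at 1e−12 on random instances.
* Module detection: average-linkage hierarchical clustering of
  `1 − TOM`, then **iterated gap-cut peeling**. Each round cuts the
  dendrogram at the largest gap in its merge-height distribution —
  restricted to ranks where a min-size module could have fully merged
  below the cut, and only when the gap exceeds `gap_factor` (10) times
  the median inter-merge gap; otherwise the cut falls back to the
  0.99-quantile of merge heights. A cluster is accepted as a module only
  if it has ≥ 30 genes and its mean within-cluster TOM is at least
  `coherence_ratio` (2.0) times its mean TOM to the remaining genes;
  accepted modules are removed and the remainder re-clustered until a
  round finds nothing. Rationale: average-linkage heights on TOM
  dissimilarities compress toward 1, so a single static cut either
  leaves distinct modules merged or carves selection-biased noise
  clusters; the decisive-gap rule finds the empty height band that tight
  modules leave beneath the background, peeling makes detection
  multi-scale (a weak module becomes visible once stronger ones are
  removed), and the coherence screen is what keeps the downstream
  dispersion test honest — measured on the synthetic conditions, noise
  clusters reach within/between ratios of at most ≈ 1.1 while planted
  modules sit at ≥ 3.7, and 20 null replicate runs produce zero modules.
  Labels are assigned in decreasing size order with ties broken by the
  smallest member gene, so the partition is invariant to gene order.
* Dispersion test: module dispersion is
  `sqrt(mean_{i<j} (c1_ij − c2_ij)² / 2)`; sample labels are shuffled
  between the two conditions preserving group sizes (unassigned samples
  never enter), one shuffle set shared by all modules, and
  `p = (1 + #{perm ≥ obs}) / (n_perm + 1)` with ties counting against
  significance — permutation p-values can therefore never be 0.

## Interactome mapping and rewiring hubs

Edges are kept at score strictly greater than 0.156 (duplicates keep the
maximum score; self-loops dropped). A significant module is mapped as
its induced subgraph and retained when ≥ 5 members carry an induced
edge. The rewiring degree of a gene counts its subgraph neighbours with
DE q < 0.05 *in either direction*; the hub rule additionally requires
the gene itself upregulated with log2FC ≥ 0.5 (inclusive) and q < 0.05
(strict). Rewiring neighbours are counted within the gene's module
subgraph by default; counting against the whole interactome is the
`rewiring_degree` call on the full graph. Modules are ranked by the
fraction of members that are both significantly upregulated and
connected in the subgraph.

## Overlap statistics and the network null

Hub and neighbour sets are compared with the Jaccard index (defined 0
for two empty sets, logged); the overlap matrix carries set sizes on the
diagonal and the summary is the mean over unordered distinct pairs. The
null model shuffles node labels uniformly within exact-degree classes,
leaving edge structure untouched, so every label keeps its degree;
`p = (1 + #{null ≥ obs}) / (n + 1)`. On small graphs the high-degree
classes are singletons and the null cannot move hub labels at all — for
that regime an optional log2 degree binning pools degrees into
powers-of-two classes (preserving degrees only up to bin resolution);
it is off by default.

## Validation

* Stability: "fivefold" is implemented as five independent subsampling
  repeats per fraction (a literal disjoint fold partition is undefined
  for 90% subsampling). Both stress groups are subsampled without
  replacement, module detection re-run, and the union of module genes
  compared with the full run's union
  (`overlap % = 100·|∩|/|full set|`), with a hypergeometric upper-tail
  test against the tested-gene universe. Per-module best-match Jaccard
  is available from the same machinery.
* Dependency test: per-gene mean score across cell lines; one-sided
  lower-tail permutation p over random same-size gene subsets (lower
  score = stronger dependency; +1 correction; null subset indices sorted
  before averaging so ties are exact), plus a two-sided
  normal-approximation rank-sum test with tie correction of set vs
  non-set per-gene means. The statistic is invariant to adding a
  constant to every score.

## Synthetic data

The generators define the study conditions and are pure functions of
(parameters, seed); sub-seeds derive deterministically from one root
seed (a multiplicative hash of the generator name, kept below 2³¹).

* Segments: one altered segment per chromosome covering the target
  fraction at a random offset, |segment mean| drawn in [0.3, 1.5] with
  random sign; flanks are neutral with mean in (−0.19, 0.19). The
  realized burden equals the target up to base-pair rounding (error
  beyond 0.01 raises).
* Expression: negative-binomial counts (variance μ + αμ², default
  α = 0.1; fixtures use 0.05) around a log2-scale latent signal with
  per-gene sd 1.0 and base means 2⁶–2⁹. Planted modules share a
  per-condition latent factor whose loading is tuned so the *observable*
  log2-count correlation matches the target r after the counting noise
  (delta-method variance (1/μ + α)/ln²2) dilutes the latent signal; when
  the noise ceiling makes a target unreachable the loading saturates
  with a warning. The factor is mean-centered within each condition so
  planted coexpression cannot leak a coherent module-wide offset into
  the planted fold changes — without centering, the factor's sample mean
  biases every member gene's log2FC together. Hub and neighbour genes
  gain the target log2FC additively in the high group; optional age
  slope and sex offset act on the latent scale and are recorded in the
  metadata.
* Interactome: configuration model on a discrete power-law degree
  sequence (min degree 1, capped at 2√n; self-loops and collapsed
  multi-edges dropped), background scores uniform on [0, 1] and filtered
  at the cutoff like real data; planted hub–neighbour edges score above
  the cutoff so they always survive loading.
* Dependency: i.i.d. standard-normal scores with an additive mean shift
  on the planted set.

What the generators do **not** emulate: tumour purity, batch structure,
library-size extremes, gene-length effects, correlated CNA–expression
dosage coupling (the CNA filter is exercised on separately constructed
inputs), or realistic gene annotations. Passing tests therefore show
that the pipeline recovers the structures it models under controlled
noise — not that it is robust to every artefact of real cohorts.

## Problem sizes and defaults

The standard fixture is 500 genes × (60 low + 60 high) samples, three
planted 40-gene modules (r_low 0.7, r_high 0), two hubs at log2FC 1.0
with five neighbours each, 1000-permutation dispersion and network
nulls, and a 10,000 gene × 50 cell-line dependency screen with a −0.5
shift on 128 genes. These sizes make every stage's statistical behaviour
measurable while a full pipeline run stays in the low seconds.

## Known limitations

* The linear DE model is not an edgeR/DESeq2 replacement at low counts
  or small n.
* A single β is used for the change matrix per run; per-condition
  thresholds are not supported.
* The gap-cut peeling assumes modules are denser than the background at
  a common scale per round; heavily nested module hierarchies would need
  the hybrid dynamic-tree-cut behaviour, which is not implemented.
* Module p-values are reported raw (optionally BH-adjustable across
  modules by the caller); the selection step before testing means null
  calibration holds because incoherent clusters are never promoted to
  modules, not because selection bias is impossible in principle.
* The within-degree network null loses resolution on toy-scale graphs;
  the log2-binned variant trades exactness for mobility and is explicit
  about it.
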