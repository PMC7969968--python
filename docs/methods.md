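# Methods

## Scope and model

The package treats a bacterial transcriptome experiment as three layers:

1. a **count layer** — gene × sample integer counts from a multi-condition,
   replicated design, modeled as negative binomial (NB) with gene-wise
   dispersion: `K ~ NB(mean = s_j μ_gc, var = m + α_g m²)`, where `s_j` is a
   sample-specific library-size factor and `μ_gc` a gene-and-condition mean;
2. a **regulatory layer** — a curated directed graph of sigma factors and
   transcription factors (TFs) to their target genes, each edge typed
   activator / repressor / dual / unknown;
3. an **annotation layer** — gene → COG one-letter functional categories.

The analysis asks which regulators plausibly account for the expression
changes between populations, by counting sign-consistent direct edges into
the significant genes and testing whether those per-regulon counts differ
between populations. It makes no attempt to infer *new* edges, to resolve
indirect cascades, or to model derepression (a repressor losing activity);
attribution is to known direct interactions only, and a gene reached by
several qualifying regulators is deliberately attributed to all of them.

## Differential expression

* **Normalization.** Median-of-ratios size factors over genes with nonzero
  counts in every sample. Only factor *ratios* are identified: scaling one
  column by c scales its factor relative to the others by exactly c, while
  the geometric-mean denominator absorbs a common `c^(1/n)`. All downstream
  quantities depend on the factors only through normalized counts, so the
  free overall scale is harmless.
* **Statistic.** For B vs A, `log2fc = log2((q̄_B + ½)/(q̄_A + ½))` on
  normalized group means (the ½ pseudocount stabilizes low counts), divided
  by its delta-method standard error with per-group variance
  `(m̄ z̄ + α m̄²)/n`, `z̄` the group mean of `1/s_j`. Two-sided normal
  p-values; genes with all-zero counts in both groups get missing p, and
  missing entries are excluded from the BH denominator.
* **Dispersion.** Per-gene method of moments on group-centered normalized
  counts gives `α̂_g = (v_g − μ̂_g z̄)/μ̂_g²` with `n_A + n_B − 2` degrees of
  freedom. At 3 replicates this estimate is far too noisy to plug into a
  Wald test directly — simulation shows a per-gene Wald-normal test rejects
  a true null at ~0.11 instead of 0.05 and floods the FDR layer, while a
  t(4) reference fixes calibration but destroys power (planted four-fold
  detection drops below 0.3). The default therefore moderates dispersion
  through a parametric trend `α(μ) = a₀ + a₁/μ` fitted across all genes by
  least squares on the positive moment estimates with one 3σ trimming pass
  (so a planted minority of truly differential genes cannot drag the fit).
  Measured on the simulated design: null fraction p<0.05 ≈ 0.053, mean
  false `padj<0.1` calls ≈ 0.2 per 2000 genes, four-fold detection ≈ 0.96.
  `dispersion_mode` selects `trend` (default), `gene` (raw per-gene
  moments, the uncalibrated estimator above), or `max` (elementwise max of
  both — conservative, at some cost in sensitivity). The floor 1e−8 keeps
  the NB variance from degenerating below Poisson.
* **Thresholds.** `padj < 0.1` and strictly `|log2fc| > log2(2)`, both
  configurable. The 0.1/twofold pair is the convention for this kind of
  tolerance study; both inequalities are strict, so an exactly-twofold gene
  is excluded. "Adjusted p" means Benjamini–Hochberg; Bonferroni users can
  post-process the raw p column.
* **Unique sets** remove, from a treated contrast, every gene id that was
  differential in the untreated contrast against the same reference —
  regardless of direction. The gene-id (not per-direction) reading is the
  stricter one and avoids calling a gene "treatment-specific" when it
  merely flipped sign.

## Regulator mapping and comparison

* **Strict sign rule** (default): sigma edges and activator TF edges
  explain up-genes; repressor TF edges explain down-genes; dual edges
  either; unknown-mode edges are treated as dual with a warning rather than
  dropped (dropping would silently shrink regulons). A **permissive** rule
  (any edge, any direction) is provided for sensitivity analysis; its
  record set is a superset of the strict one, which the dedup rule
  preserves by preferring a sign-consistent edge's mode when a regulator
  has several edges to one gene.
* **Fisher comparison.** Per regulator, the 2×2 table conditions on regulon
  size: rows are populations, columns (mapped, regulon − mapped). This
  keeps rows comparable across populations whose total DEG counts differ
  wildly. The alternative construction (columns: mapped to this regulator
  vs mapped to any other) is available as `table_mode="mapped"`. Up and
  down counts are pooled by default ("genes that changed expression");
  per-direction testing is a flag. The two-sided p sums hypergeometric
  probabilities ≤ observed × (1 + 1e−7) over the margin-preserving tables,
  computed via `logsumexp` of exact log-pmfs; the tie tolerance matches
  common exact-test practice and guards against float-tie undercounting.
  Selection mirrors the raw p < 0.05 convention; BH across the compared
  regulators is always reported, and the pipeline compares sigma factors
  and TFs separately (they are different analyses with different
  background structure — sigma regulons are genome-scale, TF regulons are
  not).

## The synthetic study

The generator emulates the study design the analysis is meant for: six
populations (stationary reference, untreated outgrowth, ampicillin 3 h /
6 h, proteolytic queueing, queueing + ampicillin) × 3 biological
replicates. Defaults: 2000 genes; 5 sigma factors (every gene gets one,
20% a second — overlapping sigma regulons are the norm); 30 TFs with
regulon sizes uniform in 5–100 and edge modes 0.6/0.3/0.1
activator/repressor/dual; baseline means log10-uniform in 0.5–3.5 (a
realistic four-decade expression range); dispersions log-uniform in
0.05–0.3 (typical for bacterial bulk RNA-seq replicates); library-size
factors uniform in 0.7–1.3 to exercise normalization. Planted activity
multiplies sign-consistent targets of an active regulator by
`effect_fold = 4` (activator/dual targets up, repressor targets down;
up-shifts win if both apply; `dual_direction` flips the dual convention).

What it does **not** emulate: count correlation between co-regulated genes
beyond the mean shift, operon structure, rRNA depletion artifacts, batch
effects, condition-dependent dispersion, or any kill-curve/growth
dynamics. Passing recovery tests therefore shows the pipeline's inference
is sound under its own error model, not that real tolerance data will be
as clean.

Randomness is one integer seed; network, annotation and counts each
consume an independent substream derived from it (`default_rng([seed,
stage])`), so a stage can be regenerated alone and is unaffected by
reconfiguring the others.

## Validation benchmarks and problem sizes

The test suite and `scripts/acceptance.py` measure, at these sizes:

* Fisher p vs an exact-`Fraction` enumeration oracle — 500 random tables,
  margins ≤ 30, agreement to 1e−12 (plus the closed-form table
  [[3,1],[1,3]] → 34/70).
* BH vs a brute-force step-up oracle — 1000 random vectors, 1e−12;
  statsmodels' `fdr_bh` as an additional cross-check in unit tests.
* Null calibration and sensitivity — 50 simulated 2000-gene studies each
  (α = 0.1, 3 vs 3; planted genes: 200 four-fold at μ ≥ 100 in a null
  background — planting a majority would be absorbed by normalization).
* End-to-end regulator recovery — 100 studies at generator defaults, three
  active TFs planted per study, drawn from TFs with regulon size ≥ 20.
  The floor is benchmark design, not tuning: with a 5-gene regulon the
  best attainable Fisher p is 2/252 ≈ 0.008 (5/5 vs 0/5 mapped), which
  background spillover through overlapping regulons routinely beats, so a
  recovery benchmark on uniformly drawn regulons would measure regulon
  size, not inference quality. Success = the three smallest TF padj are
  exactly the planted set; recovery is judged among TFs because the sigma
  and TF comparisons are separate analyses.

## Known limitations

* The DE test is a deliberately small NB Wald test: no shrinkage of fold
  changes, no outlier refitting, no independent filtering. An externally
  computed DE table can be substituted (`read_de_table` /
  CLI `map --de-table`).
* Dispersion-trend moderation assumes most genes are null for the fitted
  trend to be meaningful; designs where most of the transcriptome moves
  need the `gene` or `max` modes and external calibration.
* Gene identifiers are matched by exact string equality across all inputs;
  unmatched ids are reported, never resolved.
* The Fisher comparison inherits the usual caveat of count-based regulon
  tests: overlapping regulons make neighboring regulators' counts
  correlated, so "selected" marks association, not causal attribution.
* COG category counts are annotation-release dependent; the legend is
  configurable and none is pinned.
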