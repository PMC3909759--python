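# Methods

## The model

`genesetcommittee` builds *committees* of biologically interpretable expert
classifiers for expression-based sample diagnosis. An **expert** is one
classifier trained exclusively on the member genes of one biologically
relevant gene set (a GO term, pathway, disease association, ...); a
**committee** is an ordered collection of selected experts whose unweighted
majority vote assigns a condition to each new sample. Because every expert is
tied to a named biological concept, each vote is interpretable: a diagnosis
comes with the concepts that support it, and the vote margin is a simple
confidence surrogate. No calibrated probability is produced, and experts are
never weighted.

The training pipeline has six stages:

1. **Dataset** — a genes x samples matrix with one class label per sample,
   assumed already normalized (e.g. RMA for microarrays, normalized counts
   for RNA-Seq; the same pipeline applies to both without modification).
2. **Gene ranking** — score every gene's class-discrimination by one of four
   filter methods (below) and keep the top N (default N = 50).
3. **Enrichment** — score every gene set of a local GMT collection for
   over-representation of the top-N genes and filter by p-value, coverage,
   name and source.
4. **Classifier grid** — pair every surviving gene set with every classifier
   configuration from five families (k-nearest neighbours, decision tree,
   RBF support vector machine, Gaussian naive Bayes, random forest).
5. **Evaluation** — cross-validate every pair, pool the out-of-fold
   predictions into one confusion matrix per cell, and report Cohen's kappa,
   accuracy and per-class precision/recall/specificity/F-measure. A cell
   whose learner cannot be fit (typically because the set has no usable
   genes) is an ERROR marker, never a crash.
6. **Selection and final training** — keep the top-k cells by kappa or every
   cell at or above a kappa threshold (inclusive), refit each selected
   expert on the full training data, and persist the committee.

## Ranking methods

All four are filter methods; only the induced order matters.

* **chi_squared** — the raw Pearson chi-square statistic of the
  (discretized bin x class) contingency table. The statistic, not a
  p-value, is used: a monotone transform cannot change the ranking.
* **info_gain** — `H(class) − H(class | bins)` in bits (base-2 logarithm).
* **gain_ratio** — information gain divided by `H(bins)`, defined as 0 when
  the split entropy is 0; always in [0, 1].
* **relief_f** — multiclass ReliefF: for each visited instance, the k
  nearest same-class hits pull a gene's weight down by its normalized value
  difference and the k nearest misses of each other class push it up,
  weighted by the class prior `P(C)/(1 − P(class))`; updates are divided by
  `m·k`. Distances use per-gene min-max-normalized values summed over all
  genes; a comparison against a missing value contributes 0.5, bounding the
  influence of missingness; constant genes score exactly 0. With
  `relief_iterations="all"` (the default) every sample is visited once and
  the result is seed-independent; an integer m draws a seeded subsample
  without replacement.

**Discretization** (for the first three methods): a median split into two
bins when `binarize` is set, with values equal to the median falling in the
lower bin; otherwise equal-frequency terciles. The tercile default is a
fixed, reproducible choice for the unspecified non-binary path. Missing
values either form a dedicated extra bin or, under `merge_missing`, join
the populated bin whose mean is closest to the observed mean — merging
discards the (weak) signal that missingness itself may carry, which is
exactly its purpose. Constant genes collapse to a single bin and score 0
under every method.

## Enrichment

The p-value is the hypergeometric upper tail `P(X ≥ overlap)` with

* universe = dataset genes that appear anywhere in the collection (the
  annotatable genes — the standard over-representation universe, stated
  here as normative because alternatives such as all dataset genes are
  equally defensible),
* draws = |top-N ∩ universe|,
* successes = the set's **coverage**, its members present in the dataset.

No multiple-testing correction is applied: the downstream filter operates
on raw p-values, and its cutoffs (`p < max_p` strict, `coverage ≥
min_coverage` inclusive) are part of the method's definition, not a
significance claim. Results are ordered by ascending p-value with ties
broken by set id, so every downstream step is deterministic. A set's
`usable_features` — its covered members in dataset gene order — is the
exact, ordered feature list its expert trains on.

## Evaluation

* **Scheme** — stratified 5-fold cross-validation with shuffle seed 17 by
  default; LOOCV available. The fold count must not exceed the smallest
  class count. Out-of-fold predictions are pooled into a single confusion
  matrix (well-defined for LOOCV, and it makes "the expert's kappa" one
  number); per-fold metric averaging is deliberately not used.
* **Kappa** — `κ = (p_o − p_e)/(1 − p_e)` with `p_e` from the product of
  marginals. The degenerate `p_e = 1` corner (all mass in one
  true/predicted pair) returns 1 for perfect agreement and 0 otherwise.
* **Per-class metrics** — one-vs-rest; precision is 0 when a class is never
  predicted; F is 0 when precision and recall are both 0. Accuracy equals
  the `p_o` of the kappa computation by construction.
* **Defaults per family** — kNN k = 1; decision tree with entropy splits,
  unpruned; SVM with RBF kernel, C = 1, gamma = "scale"; Gaussian naive
  Bayes; random forest with 100 trees. These are conventional defaults in
  the Weka tradition, normative here but not claimed numerically identical
  to any other implementation.
* **Missing values** — imputed per fold with training-fold feature means
  (and at refit time with full-training means, which the committee stores
  for diagnostic-time imputation). A feature with no observed training
  values is a training failure, hence an ERROR cell.
* **Determinism** — every cell is a pure function of (dataset, gene set,
  config, scheme); the worker count only parallelizes independent cells and
  can never change a value. Repeated runs are bitwise identical.

## Diagnosis

Every expert predicts exactly one condition per sample. The report has four
sections: the raw expert-by-sample matrix; modal conditions grouped by gene
set and by classifier family; and the vote tally per sample with a final
row giving the condition — or conditions — with the most votes. Ties are
reported, never silently broken, and the CLI signals them with exit status
3 so pipelines can catch ambiguous diagnoses. Genes an expert needs but the
diagnostic dataset lacks are a hard error naming the genes and experts;
imputation by stored training means is an explicit opt-in
(`--impute-missing training-mean`), because silent imputation risks wrong
diagnoses.

## Synthetic data

The generator draws `value(g, s) ~ Normal(μ0 + δ_class(s)·1[g ∈ signal
set], σ)` and masks cells as missing at a configurable rate; a matching GMT
collection mixes the planted signal sets with seeded random null sets drawn
from non-signal genes where possible. Defaults: μ0 = 8, σ = 1 (log2-like
intensity scale), no missingness. This emulates the statistical structure
that matters to the pipeline — class-conditional mean shifts confined to
known gene sets against Gaussian noise — and deliberately omits microarray
probe effects, RNA-Seq count overdispersion, and gene-gene correlation.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of clean planted signal, not performance on real cohorts.

The standard recovery scenario uses two balanced classes of 20 samples, 300
genes, one signal set of 10 genes with a 3σ shift, and 26 null sets of 10
genes — 27 candidate sets so that a five-family grid has exactly 135 cells,
the scale of the worked example. In the replicated recovery and null
studies the random-forest column uses 20 trees: at 40 samples x 10 features
the forest's ranking behaviour is stable well below the 100-tree default,
and the study stays small enough to replicate 50 times.

## Reproducibility and persistence

All randomness flows through explicit seeds (fold shuffling, tree/forest
construction, ReliefF subsampling, data generation). Committees persist as
a single versioned JSON document embedding the fitted model parameters
(base64-pickled scikit-learn estimators) plus expert metadata, recorded
metrics, class ordering, the training gene universe and training feature
means; a reloaded committee predicts bit-identically. The classifier-family
tag is validated against the known families before any payload is
deserialized, and version mismatches or truncated files are explicit load
errors. Each CLI run writes a manifest (tool version, full parameter
record, SHA-256 input digests, timestamp) sufficient to re-execute the run.

## Known limitations

* The enrichment universe choice and hypergeometric tail are one defensible
  convention among several; rankings against other universes will differ.
* Reported grid kappas depend on the validation scheme; they are comparable
  within a run, not across schemes.
* Gaussian synthetic data cannot certify behaviour under heavy-tailed or
  count-distributed expression; inputs are assumed pre-normalized.
* The committee vote is unweighted by design; no stacking, weighting or
  probability calibration is provided.
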