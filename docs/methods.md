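# Methods

`pdxorigin` implements a tissue-of-origin analysis for labeled expression
matrices.  This note records the models, the tunable parameters and their
defaults, what the synthetic generator does and does not emulate, the
numerical conventions, and the known limitations — in particular, which
behaviours of the recovery checks are intrinsic to the method rather than
implementation artifacts.

## Data model

A dataset is a gene × sample matrix of continuous log-scale expression
values plus one tissue-class label per sample (`LabeledDataset`).  Values
are taken as given: there is no normalization, no imputation (missing
values are rejected), and gene symbols are compared case-sensitively.
Matrices are genes-in-rows with a sample-id header (the GEO series-matrix
convention); a transpose flag covers samples-in-rows exports, and the
delimiter is auto-detected among tab/comma.

## Monte Carlo feature selection

For each of `t` random projections of `m` genes (drawn uniformly without
replacement), `p` CART-style trees are grown, each on an independent
stratified train split of fraction `train_fraction` of the samples, with
binary entropy-gain splits at midpoints of distinct values, no pruning, and
a minimum leaf of 2 (delegated to scikit-learn's `DecisionTreeClassifier`
with `criterion="entropy"`; node statistics are extracted from the fitted
tree).  Each tree is scored on its held-out complement by **class-balanced
accuracy** (unweighted mean of per-class recalls, classes absent from the
held-out split excluded); "weighted accuracy" is deliberately the balanced
mean because the target cohorts have ~3× class-size imbalance.  A
`resample="bootstrap"` option replaces the split with a stratified bootstrap
scored on the out-of-bag samples.

Relative importance aggregates over every internal node of every tree:
`RI(g) = Σ (wAcc)^u · IG(node) · (node_samples/root_samples)^v`.
Ranking is by descending RI with ties broken by ascending gene index.

Defaults: `m = max(ceil(0.05·N), 2)`, `t = 100`, `p = 5`,
`train_fraction = 0.66`, `u = v = 1`.  Projections are drawn against the
symbol-sorted gene order, so a given seed selects the same *genes* whatever
the row order of the input matrix (tested as a permutation-invariance
property).

**Permutation threshold.**  The full RI computation is repeated on
`n_permutations` (default 20) label-permuted copies; the threshold is the
one-sided upper (1−α) Student-t prediction bound on a new maximal RI,
`mean + t_{1−α,K−1}·sd·√(1+1/K)`.  If the permuted maxima have zero
variance the maximum itself is used (logged).  Genes with observed RI above
the threshold are "informative".

## Incremental feature selection and the SVM

Prefixes of the ranking are scored by stratified k-fold CV (default 10
folds, reduced with a warning when the smallest class is smaller; repeats
pool confusion counts).  Per fold, features are z-scored with training-fold
statistics and a one-vs-rest SVM is fit (RBF kernel, `C = 1`,
`gamma = 1/(d·Var)` — scikit-learn's `"scale"`); class scores are
Platt-style fixed sigmoids of the decision values, the argmax wins, ties go
to the lower class index.  Pooled out-of-fold predictions fill one confusion
matrix from which per-class accuracy `ACC_i = M_i/N_i`, overall accuracy
`ACC = ΣM_i/ΣN_i`, and the covariance-form multi-class MCC derive.  The MCC
returns 0 by convention when a covariance term vanishes (constant
predictions).

The two-stage scan walks prefix sizes `coarse_step, 2·coarse_step, … ≤ N`
(stage 1), then every size in `[b − h·coarse_step, b + h·coarse_step]`
around the stage-1 optimum `b` (stage 2, default halfwidth `h = 10` steps).
The optimal set is the stage-2 prefix with maximal MCC; ties favour the
smallest prefix (parsimony).  The symmetric interval replaces the manual
by-inspection choice of a refinement window with a deterministic rule.

**Random-subset significance.**  `n_subsets` uniform random gene subsets of
the optimal size are scored by the same CV; the empirical p-value is the
add-one estimator `(1 + #{random ≥ observed})/(n_subsets + 1)` and the 95th
percentile of the random MCCs is the p<0.05 reference line.

## Rule branch

Candidate genes (normally the informative set) are discretized by recursive
Fayyad–Irani entropy/MDL partitioning; genes with no accepted cut fall back
to a single median cut (logged).  The **Johnson reducer** is a greedy set
cover: repeatedly pick the discretized gene that discerns the most
not-yet-covered pairs of differently labeled samples (ties: higher RI, then
earlier gene), until no remaining gene discerns an uncovered pair;
indiscernible pairs are reported, not fatal.  Pair enumeration is exact up
to 2,000 samples and seeded-subsampled above.

**RIPPER-style induction** processes classes from least to most frequent;
the most frequent class becomes the condition-free default rule (last).
Rules are grown condition-by-condition (forms `gene ≥ c` / `gene ≤ c`, `c` a
midpoint of observed values) maximizing FOIL gain on a grow split (2/3,
stratified), pruned on the remaining 1/3 by maximizing (p−n)/(p+n) over
condition prefixes, and accepted while the prune-set error stays below 1/2
and the description length (rule-theory bits plus binomial exception coding)
stays within 64 bits of the best seen.  *Deviation from the classical
optimization phase:* instead of replacement/revision on a fresh grow/prune
split, each accepted rule is re-grown on the full not-yet-covered data and
kept if it reduces training error there (ties: fewer conditions).  This
keeps thresholds at midpoints of the empirical class gap — on cleanly
separable data the recovered cut is guaranteed to lie inside the true gap —
at a small risk of extra overfit that the evaluation protocol (below) makes
visible rather than hides.

Rule sets are ordered, applied first-match with **inclusive** comparisons
(matching the published rule table's `≥`/`≤` semantics), and closed by
exactly one default rule.  Evaluation is either self-consistency (apply to
the training samples; optimistic by construction) or honest CV that
re-induces rules on each training fold (a `reinduce=False` flag scores one
fixed rule set instead, since the original protocol is ambiguous on this
point).  Class labels are compared after trim/case-fold normalization but
preserved verbatim in outputs.

The published 16-rule tissue classifier ships as a plain-text fixture
(`load_table2_rules()`): 15 condition rules over 27 genes plus the default
rule (any other condition → large intestine), thresholds exactly as printed
to three decimals.

## Synthetic cohorts

`SyntheticConfig`/`generate_dataset` draw background values i.i.d.
Normal(μ0, σ) and shift each class's `k` marker genes by δ inside that class
only.  Defaults μ0 = 4.0, σ = 1.0, δ = 3.0, k = 5 put planted thresholds in
the range of the published rule cutoffs (log2-like scale).  Markers are
disjoint across classes by default; `marker_overlap=True` draws them
independently so multi-condition rules get exercised.
`default_pdx_config(scale)` reproduces the 8-tissue cohort shape —
class sizes 79/41/121/99/52/94/46/62 (594 samples) and 20,502 genes at
`scale=1` — with proportional half-up rounding, a floor of 5 samples per
class and 200 genes at smaller scales.  One `numpy` generator seeded from
the config seed drives marker placement and then the matrix, so a seed
reproduces the dataset bit-identically.

The generator emulates class structure, imbalance, and scale only.  It does
**not** simulate probe effects, batch effects, gene–gene correlation,
heavy-tailed noise, or host-stroma contamination — so a green recovery test
establishes that the pipeline finds planted mean-shift signal at realistic
sizes, not that it is robust to those real-data complications.

## Pipeline and reproducibility

`run_pipeline(PipelineConfig)` executes data → MCFS → permutation threshold
→ rule branch → IFS/SVM branch → random-subset significance, writing plain
TSV/JSON artifacts plus a manifest.  A single master seed fans out to
per-stage seeds through `numpy.random.SeedSequence(master).generate_state`
in a fixed stage order, so any stage can be replayed in isolation from the
manifest.  The manifest is deterministic (bit-identical across reruns of
the same config); wall-clock timing goes to a separate `run.log` outside
the determinism contract.  `validate_config` returns *all* diagnostics, not
just the first.

## Known limitations and intrinsic behaviours

* **Projection coverage bounds marker recovery.**  With the default
  `t = 100` and `m = 0.05·N`, each gene enters on average only
  `t·m/N = 5` projections (Poisson); per run, a handful of true markers
  land in ≤ 2 projections and cannot accumulate competitive RI, and with
  probability ≈ 0.6% per gene a marker is never drawn at all.  Complete
  recovery of *all* planted markers in a fixed top-of-list window is
  therefore not achievable at these defaults regardless of tree quality;
  raising `t` (the reference implementations routinely use thousands of
  projections) shrinks this effect at linear cost.
* **Unpruned trees give noise genes nonzero RI.**  Trees grown to purity on
  small training sets must split ~C−1 or more times while a projection
  contains only ~`m·(kC/N)` markers, so most splits are spurious; across
  thousands of noise genes the upper tail of their RI overlaps weak (small
  class) markers.  The permutation threshold stays specific (near-zero
  false positives) but is conservative for small-class markers.
* **The IFS optimum saturates early on strong-signal data.**  One clean
  marker per class already yields CV MCC = 1, and the smallest-on-ties rule
  then selects a prefix well below the total number of planted markers.
  The optimal *size* is thus a lower bound on the signal set, not an
  estimate of it.
* **Winner's curse in the reported optimum.**  The optimal subset's MCC is
  the maximum over all scanned prefixes of the same CV; on null (δ = 0)
  data this selection maximum sits around +0.1 and can occasionally exceed
  0.15 even though every individual evaluation is unbiased (slightly
  negative, in fact — the usual CV bias for uninformative features).  This
  is selection bias, not information leakage; an honest unbiased estimate
  would need a nested or held-out evaluation of the selected subset, which
  the original protocol does not include.
* Runtime scales as `t·p` tree fits for MCFS and as (prefix count) ×
  (folds) × (classes) SVM fits for IFS; everything in the test suite is
  scaled to desk sizes (tens of samples, thousands of genes).
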