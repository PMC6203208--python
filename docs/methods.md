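# Methods

## Data model

Two experiments are integrated at gene level.  Methylation arrives as
per-sample CpG-site records (chromosome, 0-based half-open interval,
strand, gene symbol, beta value in [0, 1]); expression as per-sample
(gene, RSEM value >= 0) pairs.  Sample identity, experiment detail and
condition all live in the TCGA aliquot barcode: the first four
dash-separated fields identify the physical tissue, the remainder the
experiment performed on it, and the 2-digit sample-type code maps 01–09
to tumoral and 10–19 to normal (control codes 20–29 are rejected rather
than silently classed).

**Gene methylation quantity.**  For one sample, the value of gene *j* is
the sum of the beta values of all non-missing, gene-annotated sites of
*j*.  The sum is used exactly as defined — no normalization by site
count — so the quantity confounds site count with site level by design:
it is an intensity, bounded by the number of sites, not a mean
methylation fraction.  Sites without a gene symbol are excluded; a
composite annotation (`A;B`) credits the beta to every listed gene
(multi-gene CpG annotations are common on methylation arrays, and the
alternative — dropping or arbitrarily assigning such sites — discards
signal).  Aggregation is order-invariant and conserves the total
annotated beta mass.

**Matrices and the combined matrix.**  Per-experiment matrices hold
samples in rows (sorted aliquot ids), the sorted union of observed genes
in columns, and the class as the last CSV column; a gene unobserved in a
sample is missing (`?`), not zero, because absence of measurement is not
absence of methylation or expression (a `fill="zero"` option exists for
pipelines that want the other convention).  The combined matrix is the
full outer join of the two matrices on the truncated barcode.  Feature
names get experiment suffixes (`_dnaMeth`, `_rnaSeq`; rendering is
configurable), so the combined width is exactly the sum of the input
widths even when symbols overlap, and no value is altered by the join.
Two aliquots of the same tissue within one experiment are an error (an
averaging rule would be arbitrary), as are conflicting class labels for
a shared tissue (both derive from the same barcode field, so a conflict
means corrupt input).  A complete-cases filter can drop samples carrying
only one experiment; no imputation is offered.

## Rule induction

The learner produces an ordered list of conjunctive threshold rules
(`<=` / `>=` literals over feature values) for the minority class (ties
go to the lexicographically first class) with the majority class as
default.  Prediction is first-match; a condition on a missing value is
false, so rules never cover samples lacking their features.

Induction is IREP-style sequential covering:

* the active examples are split into grow and prune parts (stratified,
  seeded; grow fraction `1 − 1/prune_folds`, default 2/3);
* growing adds, at each step, the condition with the largest FOIL
  information gain `p1·(log2 p1/(p1+n1) − log2 p0/(p0+n0))`; candidate
  thresholds are midpoints of consecutive distinct sorted values of each
  feature among the currently covered grow examples (the scan is
  vectorized across all features at once);
* pruning keeps the condition prefix maximizing `(p − n)/(p + n)` on the
  prune part;
* the rule is kept when its prune-part precision is at least 0.5 and it
  covers at least `min_coverage` (default 1) training positives; covered
  examples are removed and the loop repeats until no positives remain
  or a grown rule fails the test.

Tie-breaks are fixed and deterministic: equal gain resolves by feature
order, then `<=` before `>=`, then the smaller midpoint; equal pruning
scores prefer the shorter prefix; a prefix covering nothing on the prune
part scores −1 (no evidence is treated as failure, which kills spurious
rules early on noise data).  Single-class input yields the degenerate
ruleless model; all-missing feature columns simply produce no
candidates.

Two deliberate departures from a textbook RIPPER: (i) reduced-error
pruning is disabled on small active sets (fewer than `min_prune_n = 16`
examples, or a class with fewer than two members) — a held-out third of
a dozen samples is pure noise, and unpruned covering lets the learner
reach every separation an exhaustive single-condition search can find on
such data; (ii) the MDL-based global optimization passes are replaced by
repeat-and-keep-best (`optimization_runs + 1` seeded runs, best training
macro-F wins, default 2 extra runs mirroring common practice).  The
pruning metric choice `(p−n)/(p+n)` is documented, not claimed identical
to any particular implementation.  The learner sits behind a minimal
contract (`fit(X, y, seed)` returning a model with `predict_frame`), so
a third-party rule learner can be substituted; all shipped tests run
against the in-repo implementation.

## Multi-model extraction

One learner run hides alternative, near-equivalent models.  The
extractor archives many: learn on all features, then iterate with
features eliminated.  Model quality per iteration is the mean macro
F-measure over stratified k-fold cross-validation (default 10 folds) on
the reduced matrix; the archived model itself is refit on all samples.
A model is archived when its CV F clears `f_threshold` (default 0.8) and
its rule-feature set was not seen before.

*Standard mode* removes the features of every archived model permanently
and stops as soon as a freshly learned model falls below threshold.
Archived models therefore use pairwise-disjoint features.

*Loose mode* removes feature subsets temporarily.  The queue of
candidate elimination subsets is chain-first: after archiving a novel
model learned with elimination set E and rule features R, the subset
E ∪ R is enqueued first, then the singletons of R; when the queue
drains, the remaining subsets of the pool of ever-used features are
enumerated size-ascending, lexicographically.  The chain-first order
matters: with redundant single-feature models, a plain size-ascending
enumeration needs on the order of 2^k iterations before the k-th
strongest feature can surface, whereas following the chain surfaces a
new feature roughly every other iteration.  The queue is deduplicated
and capped at `max_iterations` entries to bound memory.  Termination:
threshold failure (standard), iteration cap, wall-clock cap (default 30
days, i.e. effectively off), or queue exhaustion (loose).  Identical
seeds give identical runs.

The analysis step turns an archive into literal frequencies (feature ×
operator counts over all rules), conjunction lists, within-conjunction
feature-pair co-occurrence counts and the gene list (union of features
over all rules).  Combined-matrix features split into (gene symbol,
experiment) pairs by suffix; gene identity is the bare case-sensitive
symbol, with no alias resolution.  Venn-region counting supports two or
three named sets and partitions the union exactly.

## Evaluation

Precision, recall and F are the standard confusion-table quantities with
degenerate denominators mapped to 0.  Reported model quality is the
macro average of per-class F over the two classes, then the mean over
stratified folds; the support-weighted average and per-class values are
emitted alongside, because published summaries use either convention.
Grid search is exhaustive over an explicit parameter list, maximizing
mean CV macro-F with first-in-grid tie-breaking.  Permutation validation
shuffles labels without replacement (class frequencies preserved),
re-runs the full cross-validation per replicate, and reports all
replicate means plus the grand mean; on a planted-signal cohort the
permuted grand mean sits in the chance band near 0.5 while the
true-label score does not — the gap is the overfitting check.

## Synthetic cohorts

The generator emulates the data shapes the pipeline consumes: site-level
beta values drawn from Beta(2, 5) per site (right-skewed background,
mean ≈ 0.29, SD ≈ 0.16), expression from LogNormal(μ=2, σ=1), 3–8 CpG
sites per gene, syntactically valid barcodes with sample-type codes 01
(tumoral) / 11 (normal), and partially overlapping experiment
availability (default 80 % both, 10 % each single experiment).  Planted
methylation genes receive a class-dependent location shift of
`effect_size` (default 0.5, about three background SDs on the beta
scale) at *every site*, truncated to [0, 1], in tumoral samples — the
shift is applied at site level precisely so that only correct gene-level
aggregation inherits it.  Planted expression genes get `+effect_size` on
the natural-log scale (a modest half-SD shift; the methylation channel
carries the dominant signal).  The default cohort is 100 tumoral + 100
normal samples over 500 genes with the same ten genes planted in both
experiments.  Output is byte-identical for a fixed seed, and a truth
record carries planted genes and latent classes for recovery checks.

What the generator does *not* emulate — realistic CpG coordinates,
co-methylation/LD structure, batch effects, class imbalance at real
cohort ratios, heavy-tailed expression, probe-level artifacts — bounds
what passing tests show: they verify the machinery (aggregation, join,
induction, elimination, validation) end to end under known truth, not
performance on real tumor data.

## Problem sizes and numerics

The shipped tests and the acceptance script run the planted cohort at
200 samples × 500 genes (1000 combined features), loose-mode extraction
capped at 40 iterations with 10-fold internal CV, and 25 permutation
replicates — sizes chosen so the whole suite completes in about a minute
on one CPU while leaving every measured property far from its bound.
Floating-point expectations in tests use absolute tolerances of 1e-9 to
1e-12 for exact-arithmetic identities (summation order, round trips) and
the natural scale of the quantity elsewhere.  CSV serialization uses the
shortest round-tripping decimal representation, so write→read is exact.

## Known limitations

* Binary classes only; nominal features are out of scope.
* The rule learner is a faithful IREP-with-extensions, not a
  bug-for-bug RIPPER/JRip reimplementation; thresholds and rule counts
  can differ from other implementations on the same data.
* Loose-mode enumeration order is a documented deterministic choice; an
  implementation with a different queue discipline will archive a
  different (overlapping) model set.
* The gene methylation quantity depends on the annotation's site count
  per gene; comparing its values across platforms with different probe
  densities is not meaningful.
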