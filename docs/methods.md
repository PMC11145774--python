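# Methods

## Instrument model

The screening instrument has 25 ordinal items, each weighted 0–4
("Not at all" … "Extremely"), total score 0–100 binned into six severity
levels at 0–5 / 6–10 / 11–25 / 26–50 / 51–75 / 76–100. Severity labels are
encoded 0–5 in clinical order (not alphabetically) so ordinal structure is
preserved for stratification and correlation screens. Cleaning is whole-row
deletion of records with any missing item — no imputation — with the dropped
count logged and kept on the table. Category matching is case-insensitive
with whitespace stripped, and numeric columns already holding 0–4 are
accepted as-is, which lets synthetic tables round-trip exactly.

## Feature group partitioning

The four groups (10/7/5/3 items) are fixed by the instrument's structure.
Band derivation from a group of size F uses S_th = F · W_max and upper
bounds round(c·S_th), c ∈ {a=0.05, b=0.1, c=0.25, d=0.5, e=0.75}, the last
band ending at S_th; lower bounds chain as previous-upper + 1 from 0.

Numerical choices, all of which were genuinely open:

* **Rounding** is round-half-up computed on the exact decimal product
  (`Decimal`, so 0.1 × 12 = 1.2 exactly). Half-up reproduces the reference
  band tables (e.g. round(1.4) = 1 for the 7-item group's first bound);
  ceiling does not.
* **Non-empty-band clamp**: if a computed upper bound falls below its lower
  bound, the band is pinned to the single score upper = lower. This is the
  minimal rule under which all 30 reference band cells are consistent — the
  3-item group's second band is 2–2 although round(0.1 × 12) = 1.
* **Feasibility**: six non-empty integer bands need S_th ≥ 5; smaller
  thresholds raise an error rather than silently producing degenerate
  tables.
* Constants a–e and W_max are configurable (`BandConstants`), defaults
  pinned to the values above.

Because the four group scores sum to the 25-item total and the overall band
table coincides with the screening cut-points, the partitioned prediction
target PT is exactly the conventional label — an identity the test suite
asserts on random records, not an approximation. Group targets are emitted
as ordinal codes 0–5 (names recoverable via `SeverityLevel`).

## Oversampling

Both samplers raise every class to the majority count, preserving all
original rows and appending synthetic rows grouped by class in sorted class
order (deterministic given the seed).

* **SMOTE**: seed points drawn uniformly from the minority class; neighbour
  drawn uniformly from the seed's k nearest same-class neighbours
  (Euclidean; k defaults to 5, the canonical value of the original method);
  interpolation fraction R ~ U[0,1]. The default direction
  f_i + (f_near − f_i)·R keeps synthetic points on the segment between the
  pair; an alternative "as-printed" direction f_i + (f_i − f_near)·R, which
  extrapolates on the far side of the seed, is available behind a flag for
  comparison with formulations that typeset the difference reversed.
* **ADASYN**: per-point ratio r_i = (opposite-class points among the k
  nearest neighbours in the full dataset)/k, normalized; quotas are floored
  and the remainder assigned to the highest-ratio points, so the class
  deficit is met exactly (uniform allocation if all r_i = 0).
* **Degenerate classes**: a singleton class is replicated with a warning; a
  class smaller than k+1 reduces k to n−1 with a warning.
* **Grid snapping** (default on): synthetic coordinates are rounded to the
  nearest integer and clipped to the feature range (0–5 for group targets,
  0–4 for raw items), keeping categorical-likelihood models valid
  downstream. Continuous experimentation can disable it, but the pipeline
  refuses categorical naive Bayes on un-snapped features.
* **Scope**: the pipeline balances the training split only by default (a
  leakage guard); a whole-dataset scope reproduces the 654 → 2160
  accounting some study designs report.

## Classifiers

Training is delegated to scikit-learn; this package pins the
hyperparameters and seeds. DT: Gini, unpruned. RF: 100 trees,
min-samples-split 2, unlimited depth, min-samples-leaf 1. KNN: 3 neighbours,
Minkowski p=2; vote ties (possible with three neighbours over six classes)
break toward the tied class with the smallest summed neighbour distance,
then the lowest ordinal code — implemented as a thin subclass because the
backend breaks ties by class order. CNB: alpha 1, fitted priors,
`min_categories` set to the feature alphabet so prediction never meets an
unseen category index. SVM: linear kernel, degree 3, gamma "scale",
backend-default multiclass scheme. Bagging: 10 MLPs, one hidden layer of
100 units, 1000-iteration cap. Stacking: DT/RF/CNB/KNN bases with an RF
meta-learner on 5-fold cross-validated base predictions (standard practice;
the internals were open). Gini impurity (1 − ΣP_k², the standard multiclass
form) and the Minkowski distance are exposed as audited stand-alone
utilities and property-tested rather than re-implemented inside the
learners.

## Evaluation protocol

60/20/20 stratified split by per-class largest-remainder allocation
(fractional-part ties resolve train → validation → test); classes with
fewer than three members stay whole in the training split with a warning.
Validation accuracy is the mean accuracy of the train-split-fitted model
over ten stratified folds of the held-out 20% validation subset — an
unusual protocol, followed as specified rather than the more common CV on
the training split. Metrics are one-vs-rest: per-class sensitivity
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), F1
2TP/(2TP+FP+FN), support-weighted to report level; balanced accuracy is the
exact mean of weighted sensitivity and specificity. One-vs-rest weighting is
the only construction under which per-class specificity is well defined in
the multiclass setting. Macro-averaged recall is reported alongside because
the two diverge under imbalance and published "balanced accuracy" figures
are sometimes macro recall. Zero-denominator metrics (e.g. a never-predicted
class) are reported as 0 and flagged, not dropped. The Pearson screen
correlates each feature with the ordinal severity codes; constant columns
are flagged undefined rather than set to 0. Wall-clock training time is
logged per model but excluded from serialized reports so identical configs
produce byte-identical files.

## Synthetic data

The generator emulates the study conditions: per-class counts default to
14/23/180/360/67/10 (total 654, moderate prevalence 55%). For each record it
draws a target total uniformly from the class's score band, then spreads it
over the 25 items as an exactly uniform bounded composition (sequential
conditional draws weighted by an integer DP count of remaining
compositions; uniformity is validated against an enumeration oracle). The
uniform-within-band choice is a modeling convenience — the real survey's
within-band shape is unknown and irrelevant to pipeline correctness. Items
are exchangeable by default; an optional group-weights mode concentrates
score mass in chosen groups (a near-uniform sequential scheme) so the group
targets vary non-trivially.

What passing tests on this data do and do not show: structural and
algorithmic correctness (balance accounting, label identities, split
contracts, overfitting direction) transfer to real data; absolute accuracy
values do not, because real items carry correlated clinical signal the
exchangeable generator deliberately omits. The acceptance script's
per-model balanced accuracies characterize the pipeline on the synthetic
conditions only.

## Problem sizes and determinism

Tests and the acceptance script run at the study scale (654 rows, 2160
after balancing) with 10,000-record batches for the label-identity check
and 10,000 draws for the composition-uniformity check — sizes chosen so the
whole suite completes in well under a minute while keeping every assertion
at full study scale. One global seed fans out through a seed sequence to
per-stage substreams (generation, split, balancing, one per model), so any
stage reruns identically in isolation and identical configs give
byte-identical reports.

## Known limitations

* The generator's exchangeable items make group targets highly redundant
  with the overall label; it cannot (and does not claim to) reproduce
  published accuracy tables from the private survey.
* The as-printed SMOTE direction can leave the convex hull of the minority
  class (it extrapolates); it exists for comparison, not recommended use.
* Specificity under heavy imbalance is optimistic (large true-negative
  pools); balanced accuracy inherits some of that optimism, which is why
  macro recall is co-reported.
* The CV-on-validation protocol evaluates a fixed model on small folds; its
  mean equals validation accuracy in expectation and mainly adds a spread
  estimate.
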