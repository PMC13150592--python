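# Methods

`bcrpqsar` implements an interpretable QSAR regression workflow for
BCRP (ABCG2) transport inhibition: curated pIC50 values are predicted
from dictionary-defined substructure fingerprints with tree-based
models, the finalized model is explained by exact additive (Shapley)
attributions resolved back to SMARTS patterns, and an applicability
domain calibrated from Tanimoto similarity guards external screening.
This note records the model, the numerical choices, and what the
synthetic validation does and does not establish.

## Activity curation

A potency record is a positive concentration with an endpoint (IC50,
or EC50 demonstrated to measure inhibitor potency, which is then
treated as IC50), a unit, and assay tags.  Curation applies, in order:

1. an assay-condition predicate over the tags (the intended data are
   cell-based transport assays); EC50 records additionally require the
   inhibitor-potency tag;
2. exact unit standardization to μM (M ×1e6, mM ×1e3, nM ×1e-3); unit
   spellings are mapped through an explicit alias table and unknown
   tokens are errors, never guesses;
3. structure standardization: canonicalize, keep the largest organic
   fragment, neutralize charges, re-canonicalize (RDKit).  The result
   is a fixed point, so compound identity for merging is string
   equality of the standardized SMILES.  Stereochemistry is retained;
4. replicate aggregation per unique structure: the arithmetic mean of
   the μM IC50s (a geometric-mean switch exists for users who prefer
   log-scale averaging), converted to pIC50 = −log10(IC50 [M]).  The
   max/min fold range flags replicates disagreeing by more than 3-fold
   (`consistent=False`); such entries are retained and surfaced for
   manual review, because the package cannot re-read the primary
   literature;
5. dataset merging keyed by standardized SMILES, averaging overlaps on
   the concentration scale; an explicit exclusion list removes
   compounds that must not leak into an external screen (e.g. already-
   reported inhibitors).

## Fingerprint dictionaries

Features are binary substructure bits with data-file semantics: a
dictionary is an ordered TSV of (index, kind, pattern, min_count,
description), where kind is a SMARTS pattern, an element count, or a
ring count.  A bit is set iff the molecule contains at least
`min_count` instances.  Four dictionaries ship (~1050 bits):

* `maccs166` — the 166 MACCS structural keys, built at runtime from
  RDKit's SMARTS table (dense indices 0..165 = keys 1..166).  Keys
  RDKit special-cases in code are mapped: the aromatic-ring-count key
  uses our any-size aromatic ring counter; the isotope and exotic-
  element keys are placeholders that are vacuous for standardized
  organic input.  The table-driven bits are verified bit-for-bit
  against RDKit's generator in the tests.
* `counts` — PubChem-style element-count and ring-count sections,
  enumerated programmatically (68 bits).
* `funcgroups` — a curated 120-bit functional-group/heterocycle SMARTS
  dictionary (shipped as `data/funcgroups.tsv`).
* `ringsubst` — a Klekota-Roth-style systematic enumeration of ring ×
  substituent patterns (25 ring templates × 28 substituents, ~700 bits
  after deduplication; every generated SMARTS must compile).

Morgan (circular) fingerprints — radius 2, 2048 bits, recorded in every
calibration artifact — are used for similarity only, never as model
features, because hashed bits cannot be resolved to substructures.
Tanimoto similarity is |a∧b|/|a∨b|; the 0/0 case is defined as 0.0
with a warning, the conservative choice for applicability-domain use.

## Feature-reduction cascade

All fitted statistics use training rows only; leakage sentinels in the
tests corrupt everything outside the training slice and assert that no
decision changes.

1. **Variance filter** — population variance < 0.01 removed; for a
   binary bit this is p(1−p), i.e. bits present in fewer than ~1% of
   compounds.
2. **Correlation filter** — greedy pass in descending-variance order;
   a column is dropped iff |Pearson r| > 0.8 with an already-kept
   column (the higher-variance member of a pair survives,
   deterministically), and the trace records the partner responsible.
3. **Z-normalization** — mean 0, sd 1 (population sd) from the
   training table, applied to held-out tables with the stored
   statistics.  Binary fingerprint blocks bypass scaling by default;
   external descriptor columns are always scaled.  Transformed tables
   are tagged so a second application raises.
4. **Shadow-feature selection** — each round appends a shuffled copy
   of every candidate, fits a random forest, and scores a candidate a
   hit when its importance exceeds the 80th percentile of the shadow
   importances.  Hit counts are tested two-sided against Binomial(t,
   1/2) at α = 0.05, Bonferroni-corrected across the active
   candidates; significant excess confirms, significant deficit
   rejects (and removes), the rest stay tentative up to `max_iter`
   (kept by default so the subsequent RFE can adjudicate).  A
   percentile threshold below the shadow maximum admits a small
   false-confirmation rate from chance in-sample associations
   (typically ≤10% of pure-noise features in our tests); the
   downstream RFE prunes these.
5. **RFE with knee detection** — from 700 features (clipped to p) down
   to 20 in steps of 10, dropping least-important features under a
   depth-6, 200-tree random forest and recording cross-validated
   R²/RMSE at each size.  The knee is the grid point of maximum
   perpendicular distance to the chord of the normalized RMSE-vs-k
   curve (RMSE is primary; R² is asserted to agree in tests), ties
   broken toward larger k; a flat/linear curve is flagged "no knee"
   and the smallest k returned.

## Modelling protocol

The data are split 9:1 into train/test, independently 10 times
(per-split seed = base seed + split id).  Hyperparameters come from a
seeded random sampler over small per-algorithm spaces (RF, LightGBM,
Ridge, Lasso, kNN, SVR, MLP are registered; RF/LGBM/linear are the
first-class paths), scored by inner 5-fold CV RMSE on the training
partition only; the running best is monotone in the budget for a fixed
seed.  After evaluation, the model is refit on all rows using the
hyperparameters of the split with the best test R² (configurable to
best mean inner-CV) — the "finalized model".  By default the reduction
cascade re-runs inside every training partition (leakage-safe); a
`global` mode runs it once on the full table for interpretation and
replication studies, an order of magnitude cheaper.

Metrics: RMSE; R² = 1 − SSres/SStot; balanced accuracy and Matthews
correlation on confusion tables thresholded at pIC50 ∈ {5, 5.5, 6,
6.5, 7} (positive class = pIC50 ≥ threshold, boundary inclusive,
applied identically to truth and calls); rank-based AUC with ties at
1/2, using the continuous prediction as score; and the fraction of
predictions within 3-fold on the concentration scale, |ΔpIC50| ≤
log10 3, boundary inclusive.  MCC returns 0 when any denominator
factor vanishes (logged); balanced accuracy with an empty class is an
error, not a silent zero.  All metric implementations are validated
against exhaustive enumeration (all confusion tables with n ≤ 20), an
O(n²) pairwise AUC oracle, and the scikit-learn implementations.

## Attribution

Random-forest attributions use an in-package implementation of the
polynomial-time path-dependent tree-Shapley algorithm (numba-compiled
with a pure-Python fallback): the coalition game is the tree's
cover-weighted conditional expectation, and the returned values are
its exact Shapley values, satisfying local accuracy (base value + row
sum = prediction) to 1e-6 and matching brute-force coalition
enumeration at small p in the tests.  LightGBM models use the
library's native per-feature contribution output, which implements the
same algorithm.  Non-tree models fall back to a seeded
permutation-sampling estimator (backgrounds drawn from the explained
table, additivity enforced by construction, Monte-Carlo error
reported).

Feature importance for reporting is the mean |attribution| across the
full compound set; impurity-based importances are reported alongside
as a rank-overlap statistic, not asserted to agree.  Dictionary bits
resolve to their SMARTS and description; external or hashed features
raise an explicit "not resolvable" error.  Presence/absence
comparisons use Welch's t-test and the two-sample KS test on pIC50 by
bit presence, with Benjamini–Hochberg q-values reported beside the raw
p-values because the package tests every selected bit
programmatically.

## Applicability domain

On each evaluation split, test compounds are labelled at pIC50 5: TP
(observed and predicted ≥ 5), FP (predicted ≥ 5 only); predicted
negatives are excluded.  Each test compound's max Tanimoto (Morgan
r=2/2048) to its own training set is computed, and the cutoff swept
from 0.4 to 0.8 in 0.01 steps: the reported cutoff is the smallest
grid point at which FPR < 0.3 among retained (max Tanimoto > cutoff)
compounds, with FPR defined as FP/(TP+FP) — the sweep population
contains no called negatives, so the textbook FP/(FP+TN) denominator
is only meaningful outside the sweep and is available by
configuration.  An empty retained set defines FPR = 0.  The final
cutoff is the arithmetic mean of per-split cutoffs; splits missing a
class are skipped with a warning.  External compounds are in-domain
iff max Tanimoto strictly exceeds the final cutoff; in-domain
compounds predicted at or above the activity threshold are flagged as
screening candidates, training-set members are excluded and logged,
and descriptor ranges (MW, SlogP, TPSA, heavy atoms, saturated rings,
aliphatic heterocycles) of the similarity groups are profiled.

## Synthetic data generator

The generator emulates the statistical shape of the curated study set,
not its chemistry: 870 unique standardized molecules assembled from a
weighted fragment library (a core with 1–3 substituents joined at
mapped attachment points, hydrogen-capped, deduplicated), with

    pIC50 = clip(baseline + Σ effect_k · present_k + ε, [4, 8]),
    ε ~ N(0, 0.35²)

and three planted causal motifs: nitro-substituted benzene
(`O=[N+]([O-])c1ccccc1`, +0.6, prevalence ~0.10), an N-heteroaromatic
ring (`[nR]`, +0.5, ~0.94), and a saturated N/O-heterocycle
(`[N,O;R]`, +0.4, ~0.93).  The library weights make dual-motif cores
the norm so that, with baseline 4.55, the sample mean sits near 5.45
and roughly one compound in eight falls below pIC50 5 — the
class-imbalance regime of the emulated set, in which potency screens
rarely record clean non-inhibitors.  Truth presence is recomputed from
the emitted SMILES, so it is consistent with any downstream matcher by
construction.  External screening sets blend in-library molecules with
molecules from a disjoint aliphatic/carbocyclic library
(`novelty_fraction`), whose max Tanimoto to the training space is low
(median ~0.1 at full novelty).

What passing tests show: the cascade, model, attribution and
applicability-domain machinery behave correctly when the generating
process is additive over substructures with Gaussian noise.  What they
do not show: performance on real BCRP data, whose SAR is not additive,
whose assay noise is not homoscedastic, and whose chemistry is far
more diverse than a 40-fragment library; headline accuracies reported
by the original study are therefore out of the package's acceptance
surface.

**Planted-motif recovery metric.** Because the correlation filter
legitimately replaces a motif's literal bit with a correlated proxy
(duplicate columns cannot both survive a |r| > 0.8 filter), a motif
counts as recovered when any top-10 feature by mean |attribution| has
|Pearson r| ≥ 0.8 — the same level the filter uses — with the motif's
presence indicator over the dataset.

## Problem sizes and study configurations

Study-scale runs (analysis scripts, acceptance recomputation) use the
global cascade mode, an 80-tree depth-6 forest inside the selection
stages, an RFE grid from 200 to 20 (the post-filter width is ~300, so
the 700-start grid would be clipped anyway), 3-fold CV inside
selection and tuning, and a search budget of 6; unit tests scale
further down.  Recovery studies fit the finalized model as a depth-4,
200-tree forest: with an additive ground truth a shallow forest is the
correctly specified model class, and deeper trees dilute attribution
onto chance interaction structure.  The per-split cascade mode and the
5-fold/700-grid settings remain the library defaults.

## Known limitations

* The shipped PubChem-style and Klekota-Roth-style dictionaries are
  compact stand-ins with the same bit semantics, not the full 881- and
  4860-bit definitions; corrected or extended dictionaries drop in as
  TSV data files without code changes.
* Shadow-feature selection with a percentile threshold is mildly
  anti-conservative (see above); treat "confirmed" as "worth keeping
  for RFE", not as a causal claim.
* The sampling attribution fallback for non-tree models enforces
  additivity by spreading the closure gap uniformly; its Monte-Carlo
  error is reported and should be checked before interpreting small
  contributions.
* MLP and SVR registry entries are functional but not first-class
  tested paths; MLP fits are not bit-reproducible across BLAS builds.
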