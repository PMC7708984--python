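# Methods

## Problem and model

Given a 415-nt mRNA window centered on a candidate cytidine, decide
whether the central C is an N4-acetylcytidine (ac4C) site. The
classifier is a gradient-boosted tree ensemble (XGBoost,
binary-logistic objective) over fixed, formula-defined sequence
features; no feature selection is performed. The benchmark this mirrors
is 1:9 positive:negative, so all evaluation is imbalance-aware and the
precision-recall area is the primary metric.

## Sequence conventions

Sequences are normalized to uppercase DNA; U is mapped to T; ambiguity
codes (N, R, Y, …) are rejected rather than imputed because none of the
encoders defines a value for them. All user-facing coordinates are
1-based (internal indexing is 0-based numpy).

The benchmark's windows carry five consecutive CXX motifs at the
center. The published description does not fix the motif block's offset
relative to the window center, so this package adopts the convention
that the central position c = (L+1)/2 holds the C of the *third* motif:
required C positions are {c−6, c−3, c, c+3, c+6} (202, 205, 208, 211,
214 for L = 415). This places a cytidine — the candidate modified
residue — at the exact center. The check is advisory at prediction time
(a warning) and strict (`--strict`) when validating benchmark-style
input, since the motif constraint describes dataset construction, not a
property the model requires of new inputs.

## Feature encodings

Dimensions for a length-L window: one-hot 4L; NCP 3L; ND L; NCP+ND 4L;
k-mer 84; EIIP L; PseEIIP 64; EIIP+PseEIIP L+64.

Notes on choices that the formulas leave open:

- **ND**: the density at position i is the prefix frequency
  d_i = (occurrences of n_i in positions 1..i)/i. The printed
  definition sums to the full length while dividing by the prefix
  length; the prefix reading is the one used in the ND literature and
  is the only one that actually carries positional information, so it
  is adopted.
- **k-mer**: frequencies are normalized per k (counts divided by the
  L−k+1 overlapping windows), making the three blocks commensurate;
  each block sums to 1.
- **PseEIIP**: trinucleotide frequencies use the same L−2 window
  normalization. Entries are non-negative and bounded by
  max(EIIP_xyz) = 0.402 in total (a weighted mean).
- **one-hot channel order** is (A, T, G, C), following the published
  code table verbatim rather than alphabetical order.
- k-mers and trinucleotides are ordered lexicographically over
  (A, C, G, T) everywhere.
- EIIP constants are used at full printed precision in double
  arithmetic; nothing is rounded.

Feature names are stable and human-readable: positional features are
`N{i}` (with channel suffixes `_A/_T/_G/_C`, `_x/_y/_z`, `_d` where one
position yields several values), k-mer features carry their k-mer
string, PseEIIP features are `EIIP_AAA` … `EIIP_TTT`.

## Evaluation

The four-count metrics use N⁺, N⁻ (class sizes), N₋⁺ (false negatives)
and N₊⁻ (false positives). ACC, SN and SP follow the usual
complement-of-error-rate forms. MCC is computed in the four-count form
with numerator 1 − N₋⁺/N⁺ − N₊⁻/N⁻, which is algebraically identical to
the textbook TP/TN/FP/FN formula; the test suite verifies the identity
exhaustively for class sizes up to 20. AUROC uses trapezoidal
integration with threshold-grouped ties (equivalently the Mann-Whitney
statistic); AUPRC uses non-interpolated average-precision summation,
because linear PR interpolation inflates areas exactly in the
imbalanced regime this method targets.

Label metrics threshold predicted probability at 0.5 (configurable).
Undefined metrics (zero denominators, single-class inputs) raise a
typed `UndefinedMetricError` rather than returning a sentinel; inside
cross-validation, an MCC made undefined by a degenerate prediction
column (a fold where the model calls everything one class, routine for
weak models on 1:9 data) is recorded as NaN so the remaining folds and
metrics still average.

Cross-validation is stratified k-fold (default k = 5, seed 42): within
each class, indices are shuffled with the seeded generator and dealt
round-robin, so per-fold class counts deviate from n/k by at most 1.
Stratification is used because the benchmark's printed per-fold counts
(232/2171 from 1160/10855) are exactly proportional.

## Classifier and baselines

Defaults: n_estimators 1200, learning_rate 0.01, min_child_weight 5,
max_depth 5, colsample_bytree 0.8, gamma 5, subsample 0.8,
scale_pos_weight 6, `tree_method="hist"`, seeded and single-threaded by
default for reproducibility. `grid_search` scores candidate
configurations by mean cross-validated AUPRC (ties break toward the
earlier grid entry); no default search space is supplied — an explicit
grid is required, e.g.

```json
{"max_depth": [3, 5, 7], "scale_pos_weight": [1, 6, 9]}
```

Baselines (logistic regression, Gaussian naive Bayes, AdaBoost, random
forest) run with scikit-learn defaults and a pinned seed; the
comparison table records this, since tuned baselines would score
differently. Models persist as a single joblib bundle (booster bytes +
scheme + feature names + config + training class counts) and validate
scheme and width at prediction time.

## Interpretation

Global attribution uses exact TreeSHAP as implemented by xgboost
(`pred_contribs`), on the margin (log-odds) scale where the ensemble is
additive; per-sample attributions plus the base value reproduce the
margin output to numerical precision (local accuracy), and the test
suite additionally checks agreement with a brute-force
subset-enumeration Shapley computation on a small ensemble. Global
importance is the mean absolute attribution, reported with the
correlation between feature value and signed attribution (the
"high values push which way" summary).

The local explainer fits a weighted ridge surrogate on seeded
perturbations of one instance: features are discretized into quartile
bins of a user-supplied background matrix, perturbations draw bins
uniformly and replacement values empirically from the background,
sample weights decay exponentially with the number of flipped bins
(kernel width 0.75·√p), and the top-|weight| features are refit and
reported with the bin range over which each weight applies. Defaults:
5000 perturbations, quartile discretization; both configurable.
Perturbation count, discretizer and kernel are conventions of this
package.

## Synthetic benchmark generator

The generator emulates the *structure* of the real benchmark: 415-nt
windows, the central five-CXX block (forced C positions), a 1:9
imbalance, and enrichment of GGG/CGG/GGC/CCC in positives. Enrichment
is a position-independent composition tilt: positives draw G and C with
probability q = w^(1/3)/4 each (clamped at 0.45), A and T uniformly
over the remainder, so under independent sampling each target
trinucleotide's expected frequency is exactly w times the uniform
negatives' (w = `enrichment_weight`, default 4). With w = 1 the two
classes are identically distributed — the null control. All randomness
flows through one seeded numpy PCG64 generator, so output is
byte-identical across platforms.

What this does *not* emulate: real transcript context, codon
structure, positional motifs beyond the forced block, or the real
benchmark's negative-sampling procedure (which is not publicly
described). Passing tests on this generator therefore demonstrate that
the pipeline is correct and can recover a planted composition signal
of realistic strength under realistic imbalance — not that the
published performance numbers transfer; those require the external
benchmark, importable via `ac4cboost paces-import`.

Default draw: 120 positives / 1080 negatives, length 415, enrichment 4,
seed 42 — small enough that the full pipeline (CV, control, and
attribution) completes in seconds on one CPU while preserving the
benchmark's class ratio.

## Known limitations

- The tuned hyperparameters are taken as given; re-running the original
  grid search at full scale is out of scope for the bundled synthetic
  data.
- The synthetic benchmark is deliberately easy at its default
  enrichment; near-perfect scores there say nothing about real-data
  performance.
- Shapley attributions require the boosted-tree model; baseline models
  raise.
- The local surrogate's faithfulness depends on the background matrix
  supplied for discretization; a non-representative background yields
  uninformative ranges.
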