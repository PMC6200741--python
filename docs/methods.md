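# Methods

This note records the exact formulas, defaults, and numerical decisions
implemented in `pepqsar`, so results can be interpreted and reproduced
without reading the source.

## Sequences and labels

Peptides are strings over the 20 canonical residues
`ACDEFGHIKLMNPQRSTVWY`; classes are the strings `ANTI` (positive) and
`NON_ANTI`. Validation enforces the alphabet and a length range
(default 5–50 residues, matching the short-peptide regime the
descriptors are designed for; TC needs length ≥ 3). Redundancy checking
uses Needleman-Wunsch global alignment (match 1, mismatch 0, gap −1 via
Biopython's `PairwiseAligner`) with identity defined as
`identities / alignment_length`; `max_identity_check` reports pairs at
or above a threshold (default 0.70, a common curation cutoff).

## Descriptors

- **AAC** (20): residue counts divided by length `L`.
- **DC** (400): ordered dipeptide counts divided by `L − 1` (the number
  of dipeptide windows), so rows sum to exactly 1.
- **TC** (8000): ordered tripeptide counts divided by `L − 2`.
- **PC-PseAAC** (20 + λ): the 20 normalized residue frequencies plus λ
  sequence-order terms. With standardized property values
  `H1` (hydrophobicity), `H2` (hydrophilicity), `M` (side-chain mass),
  the tier-`j` correlation is
  `θ_j = (1/(L−j)) Σ_i mean_q[(P_q(r_i) − P_q(r_{i+j}))²]` over the
  three properties `q`. The vector is
  `[f_1..f_20, w·θ_1..w·θ_λ] / (Σf + w·Σθ)`.
- **SC-PseAAC** (20 + 2λ): per-property correlations
  `τ_{(j−1)·2+q} = (1/(L−j)) Σ_i P_q(r_i)·P_q(r_{i+j})` for
  hydrophobicity and hydrophilicity only, same normalization. Because
  `τ` is a product (not a squared difference) it can be negative, so
  SC-PseAAC entries are not guaranteed non-negative.

Defaults: λ = 3, w = 0.05 — small λ keeps the correlation tiers
meaningful for peptides as short as 5 residues (λ must be < L), and
w = 0.05 is the conventional weight that keeps composition dominant.
Property scales (Tanford hydrophobicity, Hopp-Woods hydrophilicity,
side-chain mass) are standardized to mean 0 and *population* variance 1
over the 20 residues before use; this is the standard convention for
pseudo-amino-acid composition and makes the three scales commensurate.

Feature names are namespaced (`AAC:S`, `DC:SP`, `TC:LSL`, `PCPSE:theta1`,
`SCPSE:tau1_hydrophobicity`), which later allows descriptor-family
bookkeeping. `remove_zero_features` drops columns that are zero for all
peptides (most TC columns, for small datasets).

## Feature selection

`rank_features_ttest` scores each feature with a two-sample t-test
between classes — Welch by default (no equal-variance assumption;
`equal_var=True` restores the pooled test). Ordering: ascending p,
then larger |t|, then feature name (for full determinism with
mergesort). Edge cases: a feature constant within both classes with
equal means has an undefined statistic (0/0) and is ranked last; a
feature with zero within-class variance but different means separates
the classes perfectly (|t| = ∞, p = 0) and ranks first. `select_top_k`
returns the chosen columns in rank order. The default subset-size
schedule explores {5,10,15} for AAC, {25,50,75,100} for DC,
{75,100,125,150} for TC, and {50,100,150,200} for merged matrices.

## Model evaluation

`run_nested_cv` runs stratified k-fold cross-validation (default 10
folds × 5 repeats; the examples and tests use 5 × 2 for speed) with an
inner stratified ⅔/⅓ holdout for hyperparameter selection by inner AUC
(first grid point wins ties, making selection deterministic). Feature
selection and z-standardization are refit on each outer training fold
(`fs_mode="fold"`); a `"global"` mode exists to quantify the optimistic
bias of selecting features on the full dataset before CV.

Learner families and full grids (`make_default_learners`):

- **RF**: `mtry` ∈ 1..⌊√p⌋, min node size 1–3, 1000 trees.
- **KNN_WEIGHTED**: inverse-distance-weighted k-NN, k ∈ 1..5.
- **SVM_RBF**: C and kernel width σ ∈ {2⁻¹²..2¹²} (σ is mapped to
  scikit-learn's `gamma`); AUC uses the decision function.
- **GLMNET**: elastic-net logistic regression over mixing α and penalty
  λ, implemented as `LogisticRegression(solver="saga", l1_ratio=α,
  C=1/(n·λ))`; λ = 0 uses C = 10¹⁰ (effectively unpenalized).

`make_fast_learners` provides reduced grids (e.g. 3×3 for SVM and
glmnet, 100 trees) for tests and examples; conclusions about the
pipeline's machinery do not depend on grid density.

Metrics: AUC by the Mann-Whitney formulation (ties count ½, via
`roc_auc_score`) with `ANTI` as the positive class, and accuracy at the
0.5 probability threshold. `aggregate` averages per-repeat means (so
repeats, not folds, are the replication unit); `performance_blocks`
pivots results into blocks × models matrices with either repeats or
folds as blocks.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning (child seeds reduced mod 2³¹),
so any (repeat, fold, learner) cell is reproducible in isolation.

## Statistical comparison

Given a blocks × models performance matrix:

1. **Shapiro-Wilk** per model column and **Bartlett** across columns
   (df = k − 1) report whether parametric ANOVA assumptions hold;
   they gate interpretation, not execution.
2. **Friedman** test on within-block ranks (rank 1 = best, average
   ranks for ties) with the standard tie correction — identical to
   `scipy.stats.friedmanchisquare`. The **Iman-Davenport** correction
   `F = (N−1)χ² / (N(k−1) − χ²)` is referred to an F(k−1, (N−1)(k−1))
   distribution; it is less conservative than the raw χ² test. Perfect
   concordance makes the denominator 0; this is reported as a
   degenerate, maximally significant result with an explicit flag.
3. **Finner step-down post-hoc** against a control (default: the model
   with the best mean rank). Raw p-values come from
   `z_i = (R̄_i − R̄_c) / √(k(k+1)/(6N))` (two-sided normal); adjusted
   p-values are `APV_(i) = max_{j≤i} min(1, 1 − (1 − p_(j))^((k−1)/j))`,
   which controls the family-wise error rate across the k−1
   comparisons.

Monte-Carlo calibration (2000 null replicates, N = 10 blocks, k = 5
models) measures an Iman-Davenport type-I error of ≈ 0.049 and a
Finner family-wise error of ≈ 0.044 at α = 0.05 with a fixed control.
Note that choosing the control as the best-ranked model *after seeing
the data* inflates the family-wise error under the null (measured
≈ 0.10), a selection effect inherent to best-vs-rest comparisons; the
calibration therefore fixes the control a priori.

## Importance

`aggregate_betas` sums glmnet coefficients over every (repeat, fold)
model: `beta_sum` (the ranking key, by absolute value), `beta_mean`
(per fitted model), and `selection_frequency` (fraction of models with
a nonzero coefficient). Since `ANTI` is encoded as 1, a positive
`beta_sum` means the feature pushes predictions toward `ANTI`
(`anti_associated=True`). Features never assigned a coefficient are
excluded from top-k reports. `descriptor_composition` compares
descriptor-family shares before and after feature selection (share
columns each sum to 100%).

## Synthetic data generator

Each class has an emission distribution: a uniform background plus an
additive per-residue bias, renormalized. Sequences draw a uniform
length in a configured range, then each configured motif is planted
with its own probability at a uniform position (overwriting residues;
one attempt per record × motif, so realized motif frequency also
includes chance occurrences). The study-like configuration
(`paper_like_config`) generates 107 `ANTI` and 105 `NON_ANTI` peptides
of length 5–50; `ANTI` is biased +0.04 toward C, S, P with motifs SP,
TC, SC, LSL planted at probability 0.8, and `NON_ANTI` is biased +0.03
toward A, V, D, I. These sizes mirror a realistic curated
anti-angiogenic benchmark while keeping full pipeline runs fast.

Scope: the generator produces compositional and short-motif signal
only. It does not model secondary structure, positional preferences
beyond uniform motif placement, or realistic residue covariance, so it
validates the machinery (recovery of planted signal, calibration under
permuted labels) rather than biological performance claims.

## Numerical conventions

- Dataset standardization (`fit_standardizer`) defaults to the sample
  standard deviation (ddof = 1), matching `scale()` conventions in
  statistical software; ddof = 0 is available. Zero-variance columns
  standardize to 0 rather than NaN.
- Derived seeds are `SeedSequence(entropy=seed, spawn_key=(...))`
  states reduced mod 2³¹, keeping them valid for every consumer.
- CSV artifacts are written with full float precision;
  pipeline reruns with identical configs are byte-identical.

## Limitations

- No external peptide benchmark ships with the package; reported
  numbers are for synthetic data and demonstrate machinery, not
  clinical utility.
- The inner model-selection loop is a single holdout, not an inner CV;
  this is cheap and deterministic but has higher selection variance.
- glmnet is emulated with saga-solver logistic regression; coefficient
  paths match coordinate-descent glmnet only approximately
  (regularization mapping C = 1/(n·λ)).
- The SVM's accuracy relies on Platt-scaled probabilities, which can
  be poorly calibrated on small folds; its AUC (decision-function
  based) is the more reliable metric.
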