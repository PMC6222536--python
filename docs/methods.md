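# Methods

This note records the models, conventions and open design choices behind
`cytofeat`, in the spirit of a package vignette: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Inputs and domain objects

Three per-protein views are consumed:

* a **sequence** over the 20 standard amino acids. Ambiguity codes
  (B, J, O, U, X, Z) are rejected outright — any remapping onto the
  standard alphabet would be arbitrary and silently distort composition
  features. Sequences shorter than 20 residues cannot enter the
  profile-correlation or PseAAC families (the lag-19 correlation and the
  λ = 10 tiers would have empty or negative-length windows).
* an **evolutionary profile**: the L×20 log-odds matrix of an iterative
  profile search, parsed from the standard ASCII output dialect. Only
  the log-odds block is used; the weighted-percentage block is ignored.
  The sigmoid squashing 1/(1+e^(−a)) is the conventional map from
  log-odds scores to (0, 1).
* a **secondary-structure prediction**: H/E/C state string plus the
  per-residue probability triple in (C, H, E) column order, as emitted
  by common three-state predictors. Rows whose probabilities sum outside
  [0.99, 1.01] are kept with a warning — trailing-digit truncation in
  printed files is not a reason to drop a residue.

Two residue orderings are frozen: profile features use the column order
of the upstream profile tool (`A R N D C Q E G H I L K M F P S T W Y V`);
composition features use plain alphabetical order. Features are consumed
positionally by the classifier, so the orders only matter for
reproducibility of persisted tables, and both are recorded in the schema
registry.

## Feature conventions

**n-gram.** The per-order prefactor 20ⁿ/Σ20ⁿ is read as a weight
multiplying each normalized count of that order, so the 20 monomer slots
sum to 20/420, the 400 dimer slots to 400/420, and the whole vector to
exactly 1. The alternative reading (a global constant) differs only by a
per-block rescaling and leaves classifier behaviour unchanged; this
reading is the one that uses the prefactor meaningfully. Dimer windows
are the L−1 overlapping adjacent pairs.

**PseAAC.** The composition terms are raw relative frequencies, not
z-scored: z-scored frequencies can drive the shared denominator
Σf + w·Σb to zero or below, destroying the vector's probability-like
structure (non-negative, sums to 1), which is also the standard type-I
definition. Z-scoring (population SD over the 20 residues) applies to
the three physicochemical property columns. The shipped property
constants are the canonical hydrophilicity (Hopp–Woods), hydrophobicity
and side-chain-mass tables of the classical pseudo-amino-acid
composition lineage; they can be overridden by a 20-row TSV. Defaults
λ = 10 and w = 0.05 give the 30-dimensional vector.

**Profile cross-correlations.** The 380 features use *population* column
standard deviations (divisor L). This is deliberate: with the population
convention, the same expression evaluated at s = t (lag 0) is exactly
Σ(A−F)²/L ÷ (sd·sd) = 1 for every non-degenerate column — the identity
that justifies dropping the diagonal — and the test suite asserts it to
1e-10 on every generated profile. Note the off-diagonal values are *not*
confined to [−1, 1]: by Cauchy–Schwarz the bound is L/(L−g), up to
≈ L/(L−19) for the largest lag, and values slightly outside ±1 do occur
for short sequences. A column with zero variance (constant scores) makes
the features undefined and raises an error naming the column.

**Secondary structure.** The transition-probability matrix between
collapsed helix (α) and sheet (β) segments uses row denominators
T(αα)+T(αβ) and T(ββ)+T(βα); a row whose denominator is zero (no H or no
E segments, or a single segment) is zero-filled rather than raising —
real predictions frequently lack one state entirely, and zero is the
conventional no-signal encoding that keeps batch extraction total.
The positional features divide by L(L−1) with L the *full* string length
including coil. The six TPM-derived features are the four entries
row-major followed by the two column averages.

## Classifier and evaluation protocol

The classifier is a soft-margin C-SVC (libsvm backend) with a linear or
Gaussian kernel. Features are not standardized by default — most
families already live in [0, 1] — but a `scale` option z-scores them on
the training portion of each split. The worked example in the README
uses it: with 380 near-zero cross-correlation features concatenated next
to small-magnitude composition features, the unscaled linear kernel is
dominated by the highest-variance block, and weak composition signal can
be buried. This is a property of the unscaled concatenation, not of any
single family, and it is why the effect-size monotonicity benchmark is
measured on the composition family that the generator's knob directly
drives.

Cross-validation partitions items into k near-equal folds (sizes differ
by at most one), stratified by class by default so that imbalanced
datasets (e.g. 1:9) keep both classes in every fold; plain random
partitioning is available. The reported aggregate is the **mean of
per-fold metrics**, not metrics of pooled confusion counts. Repeated CV
reports, per repetition, the fold mean and the within-repetition fold
SD, plus the across-repetition mean and SD of the repetition means —
both spreads, since either may be wanted.

Metric degeneracies: Mcc is defined as −1 exactly when TP = FP = 0
(nothing predicted positive — the maximally uninformative outcome for
the positive class); any other vanishing denominator yields 0 for the
affected metric together with a recorded degeneracy flag, so CV
aggregates remain computable.

Grid search sweeps C and γ over 2⁻⁵ … 2⁵ (step 2¹, 121 cells) with the
Gaussian kernel, scoring each cell by inner k-fold accuracy on a *shared*
fold assignment, so surface differences reflect hyperparameters alone.
Ties break toward smaller C, then smaller γ.

`ratio_split` performs a stratified whole-dataset split that preserves a
stated positive fraction in both halves; it refuses datasets whose own
composition cannot realize the requested fraction within integer
rounding.

Models persist in the plain-text libsvm model dialect (support vectors,
dual coefficients, rho); a parsed model reproduces the training model's
decision values to 1e-9. The scaler is not carried by that format, so
scaled models must be retrained rather than exported.

## Synthetic data generator

The generator produces consistent (sequence, profile, structure, label)
quadruples from one integer seed; identical configurations give
byte-identical fixture directories. The three signals are drawn
independently given the class — the simplest scheme making every feature
family individually informative:

* residues: negatives uniform over the 20 residues; positives tilt a
  fixed five-residue subset (L, I, V, F, M) by the factor
  exp(effect_size). The exponential tilt is calibrated so that an effect
  size of 1 makes the classes clearly separable (> 0.9 CV accuracy) on
  composition features alone, while effect 0 collapses both classes onto
  the same distribution.
* profiles: +5 on the true-residue column, −1 elsewhere, plus
  integer-rounded Gaussian noise (SD 1 by default) — a crude conserved
  profile whose sigmoid column means are a closed-form mix of σ(5) and
  σ(−1), which the tests check.
* structure: a hidden Markov chain over H/E/C with stay probability 0.8;
  positives multiply state propensities by exp(±structure_bias) toward
  helix and away from sheet. Probability rows put 0.8 on the realized
  state and 0.1 on the other two, summing to exactly 1.

Defaults (100 + 100 sequences of length 30–60, effect 1.0, structure
bias 0.5, profile noise SD 1.0) are the scale at which the end-to-end
benchmarks run: large enough for stable fold metrics, small enough for
the full suite to run in seconds.

What the generator does **not** emulate: homology within a class,
realistic cytokine motifs or domain architecture, position-dependent
conservation, correlation between composition and structure, or the
heavy-tailed length distribution of real proteins. Passing the synthetic
benchmarks therefore demonstrates that the formulas, schemas, protocol
plumbing and seeding are correct — not that the feature families attain
any particular accuracy on real cytokine data, which depends on external
sequence databases and structure predictors.

## Numerical choices and edge cases

* Internally 0-based half-open coordinates; error messages 1-based.
* Feature tables serialize floats via `repr`, so read(write(m)) is
  bit-exact.
* The chain of derived seeds (dataset seed → per-sequence child seeds)
  keeps every artifact reproducible and below 2³¹.
* Property z-scores, profile column statistics and fold-metric SDs all
  use the population convention (divisor N), matching the diagonal
  identity above and keeping conventions uniform across the package.
* Degenerate inputs are errors where a feature is mathematically
  undefined (length guards, zero-variance columns, constant property
  columns) and totals elsewhere (zero-filled TPM rows, flagged metric
  degeneracies); the split between the two is documented per operation
  in the docstrings.

## Known limitations

* The 380 profile cross-correlation features are noise-dominated when
  the profile has no genuine inter-column correlation structure; in
  unscaled concatenations they can mask weaker blocks (see above).
* The libsvm text format stores no feature scaler; `scale=True` models
  are session-local.
* Only binary classification is supported, and only the two kernels the
  evaluation protocol uses.
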