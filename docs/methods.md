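# Methods

## Model and procedure

`prednet` operationalises "potential confounder" as a variable with high
*hub centrality* in a predictive network. The network is built by
solving one supervised problem per variable: for each one-hot dummy
target `j`, a gradient boosting machine (GBM) is fitted to predict `j`
from the dummies of all other source variables, and the per-feature gain
importances of that model become the incoming edges of node `j`. The
hub score — the principal eigenvector of `A·Aᵀ`, where rows of A are
outgoing links — is high for variables whose outgoing edges point at
many strongly-predicted targets, i.e. variables that carry predictive
information about much of the questionnaire.

The approach is purely associational: a hub is a variable entangled
with many others, which is exactly the property that makes it a
candidate confounder for pairwise association analyses. No causal
direction is inferred; edge direction merely records "predictor →
target".

### Encoding

Every variable keeps **all k** of its level dummies (no reference
level). This is required because every dummy is itself a prediction
target, and it is also why the anti-leakage rule exists: within a
one-hot group the siblings determine the target exactly (row sums are
1), so all dummies of the target's source variable are removed from its
predictor set. Missing answers become an explicit `MISSING` level
rather than dropping rows: respondents may legitimately skip sensitive
questions, and row deletion would give every target a differently
biased sample. Level order is lexicographic for determinism.

Encoding is performed once on the pooled table, so the node set (and
node order) is identical in every stratum; each stratum then re-detects
its own degenerate (constant) columns, which are skipped as targets and
recorded as missing values in that stratum's hub vector.

### Boosting

The GBM is the classic Bernoulli-deviance machine: base score =
log-odds of the training base rate; each iteration fits a depth-limited
regression tree to the residuals `r_i = y_i − p_i`; leaf values are
Newton steps `Σr / Σp(1−p)`; predictions move by `learn_rate ×` tree
output. All predictors are binary, so split search is an exhaustive
scan; for a candidate feature splitting n node samples into n₀/n₁ with
residual means m₀/m₁ the gain is `(n₀n₁/n)(m₁−m₀)²`, identical to
`SSE_parent − SSE_left − SSE_right`. Gain importance is the sum of
these gains over every split on the feature in the ensemble. (Whether
this sum is additionally divided by the number of trees is a pure
rescaling that cannot change any ranking; the raw sum is used.)

Defaults: `n_trees=100`, `max_depth=4` (the published analysis
settings), `learn_rate=0.1`, `min_leaf=10` (the documented defaults of
the h2o GBM that analysis ran), no row/column subsampling. The fit is
a pure function of (X, y, config) — there is no internal randomness.

### Evaluation

One 70/30 uniform split is drawn per stratum and reused for every
target, keeping test AUCs comparable across models. AUC is the
Mann-Whitney rank statistic with midrank ties. Targets that are
degenerate or single-class in the training slice are skipped (logged
with a reason); a fitted model whose test slice is single-class keeps
its importances but reports no AUC.

### Network and hubs

With raw gains, each target's column scales with its base-rate variance
and with how predictable it happens to be, which would weight models
arbitrarily in the eigenvector; by default each non-zero column is
therefore rescaled to sum to 1 so every fitted model contributes equal
edge mass (`normalize_columns=False` restores raw gains). No edges are
thresholded. Hub scores come from power iteration on `M = A·Aᵀ`
starting at the uniform positive vector, each iterate divided by its
maximum; convergence is declared when successive normalized iterates
differ by `< tol` (default 1e−12) in max-norm, and the dominant
eigenvalue is reported as the Rayleigh quotient of the final iterate.
The zero matrix maps to the all-zero score vector. Ranking ties break
by node name for determinism.

### Replication

Per-stratum seeds derive from `blake2s(stratum_label) XOR master_seed`,
so adding a stratum never perturbs another stratum's split. Hub-score
means/SDs are taken over the strata where a node is non-degenerate, and
stratum-stratum Pearson correlations drop such nodes pairwise. One
consequence of label-keyed seeds: two strata simulated under identical
conditions replicate statistically (r ≈ 1) but not bitwise, because
their 70/30 splits differ.

## Synthetic data

The generator emulates the statistical skeleton of a large categorical
health survey: `n_confounders` uniform categorical variables that
influence `n_dependent` variables, `n_noise` independent uniform
variables, and a stratum label. Influence is an additive log-odds CPT:
a dependent variable with L levels under confounder level c has level
logits `β·c·ℓ/(L−1)`, so for binary variables `P(X=1|C=c) =
sigmoid(β·c)`, and β = 0 is exact mutual independence. CPTs are shared
across strata (mirroring the near-identical covariance structure real
regional replications show); a `divergence` knob adds stratum-specific
logit noise for sensitivity experiments. Missing labels are injected
independently per cell.

Defaults — the study conditions used throughout the tests and the
acceptance script — are 3 strata × 2,000 subjects, one binary
confounder, 12 dependent binaries at β = 2, 12 binary noise variables,
no missingness. At β = 2 the single-predictor ceiling for a dependent
target's AUC is ≈ 0.72, so observed medians slightly above 0.7 indicate
the models extract essentially all available signal.

What the generator does *not* model: questionnaire content, survey
weights, school/cluster sampling structure, ordinal scales, or
dependence among noise variables. Passing tests therefore demonstrate
that the machinery recovers a planted dependence structure of realistic
size and effect, not that any particular real-world ranking is correct.

## Numerical choices

- Split gains ≤ 1e−12 are treated as zero (indistinguishable from
  round-off on unit-scale residuals); a node with no admissible
  positive-gain split becomes a leaf.
- Exact ties in split search go to the lowest column index; identical
  partitions produce bitwise-equal gains, so the rule is deterministic.
- Newton leaf denominators are guarded at 1e−12 (saturated leaves get a
  zero step rather than an overflow).
- Boosting stops early when all residuals are below 1e−10 or a tree
  degenerates to a zero-valued stump (no further progress possible).
- `round(train_frac·n)` train rows, clamped so both sides are
  non-empty.
- Power iteration from the uniform vector returns the symmetric
  eigenvector in exactly symmetric degenerate cases — documented,
  deterministic behaviour.

## Problem sizes

The test suite and acceptance script run the full pipeline at the
default study conditions (50 dummy targets × 3 strata × 100-tree
models, ≈ 20 s per population on one CPU) over ten recovery seeds and
ten null seeds; oracle-equivalence checks (AUC pair counting,
exhaustive split enumeration, dense eigendecomposition) use fixtures up
to 500 samples, 200×10 designs and 50×50 matrices respectively.

## Known limitations

- Hub scores are max-normalized per stratum, so cross-stratum
  comparisons are of ranking shape, not absolute magnitude.
- Importance-based edges inherit the known biases of gain importance
  (preference for higher-entropy predictors); with all-binary dummies
  this bias is mild but not zero.
- The per-target models share one train/test split per stratum, so AUCs
  are correlated across targets; the replication analysis across strata,
  not the within-stratum AUC spread, is the evidence of stability.
- Variables are treated as unordered categories; ordinal structure is
  ignored by design.
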