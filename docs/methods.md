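# Methods

This note documents the generative model, the analysis procedures, the
numerical choices and the known limitations of `relmvpa`, in the order the
pipeline runs them.

## Experimental designs

Two stock profiles mirror a two-search working-memory task:

* **exp1** — 8 runs × 12 trials (96 trials), 15 TRs per trial (TR = 2 s),
  relevance conditions {current, prospective}, 3 target categories × 4
  exemplars.  Every run contains exactly 2 trials of each
  condition × category combination (16 per combination overall, 4 per
  exemplar).
* **exp2** — 9 runs × 12 trials (108 trials), 16 TRs per trial, conditions
  {current, prospective, irrelevant}, 4 trials per condition per run.
  Twelve trials per run cannot balance 9 condition × category cells, so the
  per-condition category counts within a run are a permutation of (2, 1, 1),
  rotated deterministically across runs (rotation index = run + condition
  index mod 3) so that every condition × category combination totals exactly
  12 trials.  This reproduces the property that each training fold of the
  balanced CV holds 32 trials per condition in a (10, 11, 11) category
  split.

Target-present labels are balanced within each run; trial order within a
run, exemplar placement and present/absent placement are seeded.

**Exemplar placement in exp1.**  Per combination, the 8 runs receive
exemplar *pairs* drawn from a fixed 6-row × 8-column table (seeded row
assignment, joint column permutation, and an independent exemplar
relabelling per combination).  Each row of the table holds every exemplar 4
times and contains all 6 exemplar pairs; every pair of rows jointly covers
all 16 (exemplar, exemplar) combinations in some run.  This guarantees that
the *per-run* RDM convention (below) has at least one contributing run for
every cell of the 24 × 24 matrix for any seed.  For non-stock run counts a
seeded balanced multiset is used instead and per-run RDM coverage is no
longer guaranteed.

## Generative pattern model

The voxel pattern of one trial at TR *t* in condition *c* is

```
x(trial, t) = a(c, t) * s(c, t) * P(cat, ex) + b(c, t) * P0(cat) + eps
```

* `P0(cat)`: independent unit-normalised Gaussian category prototypes;
  exemplar patterns add voxelwise jitter with relative norm
  `exemplar_jitter_sd` (default 0.3, giving within-category correlations of
  roughly 0.9 and between-category correlations near 0).
* `a(c, t) >= 0`: relevance- and phase-dependent gain (dimensionless, per
  unit-norm pattern).
* `s(c, t)` in [−1, 1]: the inversion coefficient.  `s = −1` flips the sign
  of the category pattern — the formalisation of an anti-correlated
  prospective code.  Exemplar patterns are shared across relevance
  conditions; relevance acts only through `a`, `s`, `b`, which isolates the
  inversion hypothesis in a single parameter.
* `b(c, t) >= 0`: display-evoked drive applied to the trial's own category
  prototype while a search display of that category is on screen.  Displays
  of unrelated stimuli (the constant-template and duplicate searches) carry
  no bank-category signal and are not modelled separately; their sensory
  response would be category-uninformative for the decoder by construction.
* `eps`: i.i.d. Gaussian across voxels (`noise_sd`), optionally AR(1) across
  TRs (default coefficient 0.3, unit marginal variance).

**Stock schedules.**  Defaults encode the task's relevance dynamics on the
TR grid (0-based TR slots; events lag the display timeline by the
hemodynamic delay):  the current template is at gain 1.0 from cue through
the first search (with display drive b = 1 at the search-1 TRs); the
prospective template runs at 0.8 during the delay, 0.6 with `s =
inversion_search` (default −1) during search 1, and 1.0 upright with
display drive during search 2; the irrelevant item runs at 0.6 during the
delay and is silent afterwards.  In exp1 the no-longer-relevant current
template also inverts at 0.4 gain during search 2.  These gains, together
with `n_voxels = 160` and `noise_sd = 0.5`, define the package's "moderate
SNR" reference condition: single-subject decoding sits well off both floor
and ceiling (within-condition ≈ 0.4–0.9 depending on phase), so 20-subject
cohorts resolve all the qualitative signatures.  No empirical effect sizes
exist for these quantities; they are free parameters of the generator, not
estimates.

**Analysis intervals.**  Delay = TRs 5–7, Search 1 = TRs 9–11, Search 2 =
TRs 13–15 for exp2 (one TR earlier for exp1's 15-TR trials): three TRs per
interval covering the 8-s task epochs shifted by a 4–6 s hemodynamic lag.
The exact indices are configuration, not constants.

## BOLD + GLM path

`simulate_bold_and_glm` synthesises, per trial, voxel time series = neural
schedule convolved with a double-gamma HRF (gamma shapes 6 and 16, unit
scale, undershoot ratio 1/6; configurable) plus white Gaussian noise, on the
2-s TR grid with an 8-TR post-trial tail.  A per-trial OLS GLM with one
HRF-convolved 1-TR boxcar regressor per TR (16 for exp2, 15 for exp1)
returns t = β/SE per voxel per TR.  Adjacent regressors are strongly
collinear (noise amplification on β of ~25×), so "low noise" for this path
means `noise_sd` ≲ 0.01; the per-TR correlation between the two generator
paths exceeds 0.9 only in that regime, which the tests use.  Zero residual
variance and rank-deficient design matrices raise errors rather than
returning undefined t-values.  Trials are simulated independently with
fixed inter-trial timing and no onset jitter.

## Decoding

The classifier is one-vs-rest binary logistic regression fitted by
iteratively reweighted least squares (Newton–Raphson with step halving on
the penalised deviance), iteration cap 5000, with a small L2 ridge (default
1e-4, never on the intercept) to keep separable problems well-posed.  The
predicted label is the argmax of the per-class linear scores; ties break to
the lowest category index for determinism.  Features (t-values) are used
as-is; per-fold z-scoring is available behind a flag but off by default.

* **loro** — leave-one-run-out within one condition; fold accuracies
  averaged; every trial tested exactly once.
* **balanced_loro** — the exp2 scheme: per held-out run the 32-trial
  training fold has category counts (10, 11, 11); one trial of each
  surplus category is excluded, rotating the exclusions so every surplus
  trial sits out exactly once (11 repetitions), giving 99 fits per TR on
  30-trial training sets (10 per category).  Scores are balanced accuracy
  (per-class accuracy averaged over classes), which is exactly unbiased at
  1/3 under the null even though the 4-trial test runs are unbalanced.
* **cross-relevance** — train on all trials of one condition, test on all
  trials of the other, both directions; the direction average is the
  headline number.  Train and test sets are disjoint by condition, so no
  run split is required; a leave-one-run-out variant (`run_split=True`)
  exists for sensitivity analysis and agrees closely with the default on
  the stock generator.

## Cross-temporal generalization and cluster inference

`cross_temporal_matrix` trains at each TR and tests at every TR under the
scheme's own CV, so the diagonal reproduces the per-TR timecourse exactly
and train/test trials never overlap.  Group inference vs. chance uses the
2-D cluster-based sign-flip permutation test: per-cell one-sample t, cluster
forming threshold at one-tailed p = 0.05 (configurable separately from the
family-wise α), 4-connected clusters scored by summed t (mass), null built
from subject-wise random sign flips of (accuracy − chance), p = (b + 1) /
(n_perm + 1).  When 2^n_subjects ≤ n_perm the Monte-Carlo sampling is
replaced by exhaustive enumeration (plain proportion; the identity
assignment keeps p > 0).  Two-sided testing runs the positive and negative
tails separately, each judged at α/2.  Zero-variance cells are excluded
from cluster formation with a warning.  Matrix symmetry is neither assumed
nor enforced.

## Representational dissimilarity analysis

Patterns are averaged per (condition, category, exemplar) combination
within each run; each run contributes 1 − Spearman ρ (average ranks for
ties) for every pair of combinations present in that run; cells are averaged
over contributing runs, then over the TRs of an interval.  A cell with zero
contributing runs is an error under the per-run convention;
`per_run=False` switches to the alternative of pooling each combination's
patterns across runs first (one RDM per TR), which exp2's sparse 12-trial
runs require when RDMs span two conditions.

The same-vs-different-category contrast restricts to cells pairing the two
relevance levels, averaging the 3 same-category blocks against the
off-category blocks.  On the Fisher scale each contributing cell's ρ is
atanh-transformed *before* any averaging and the dissimilarity taken as
−atanh(ρ); the transform is applied to ρ rather than to 1 − ρ because the
latter exceeds the transform's domain.  The rank transform replaces
upper-triangle cells by their average ranks scaled to [0, 1] (all-equal
input maps to 0.5).  MDS is classical/Torgerson (double-centering +
eigendecomposition, negative eigenvalues truncated): deterministic and
closed-form, sufficient for visualisation.

## Group statistics

Paired/one-sample t-tests report Cohen's d = mean(diff)/sd(diff);
comparisons of within-relevance decoding against chance are one-tailed
(within-condition accuracy has no below-chance mechanism), everything else
two-tailed.  The one-way repeated-measures ANOVA decomposes SS into
condition, subject and error; partial η² = SS_cond/(SS_cond + SS_err);
Greenhouse–Geisser ε (eigenvalue form of the double-centred condition
covariance) is applied automatically when ε < 0.75 (threshold
configurable).  Within-subject SEM uses Cousineau normalisation (subject
means removed, grand mean restored) with the Morey factor √(C/(C−1)).
No correction is applied across the three analysis intervals by default; a
Holm option exists in the stats layer.

## Reproducibility

All randomness flows through explicit integer seeds; the pipeline derives
per-subject seeds from the master seed via `numpy.random.SeedSequence`
spawning, so identical configurations yield byte-identical CSV outputs, and
each output directory carries a manifest with the configuration hash.

## Problem sizes used by the test suite and acceptance script

The chance-calibration number is computed from 100 zero-signal exp2
datasets (16 voxels, noise SD 1.0) with the balanced decoder at all 16 TRs
— 158,400 classifier fits; the voxel count is a scale choice: under the
null the expected balanced accuracy is 1/3 at any dimensionality.
Property checks run 20-subject cohorts at 80 voxels and noise SD 0.5, and
the family-wise error calibration uses 200 replicate 15-subject null
cohorts on 10 × 10 grids with 400 permutations each.

## Limitations

* No spatial voxel correlations, physiological noise, motion, or
  multi-ROI structure; the noise model is exchangeable across voxels.
* Display-evoked responses to category-unrelated search arrays are not
  modelled (they are category-uninformative by construction here, but on
  real data they contribute shared variance).
* The BOLD path fits trials independently; carry-over of the HRF tail into
  the next trial is not simulated.
* Exemplar-level inversion is not analysed (per-exemplar trial counts are
  too small by design), matching the pipeline's category-level focus.
* Passing property tests on this generator demonstrates correctness of the
  *procedures*, not that real cortical data carry an inverted prospective
  code; effect sizes in pattern space are free parameters.
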