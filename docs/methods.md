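# Methods

This note records the statistical model, estimation procedure, numerical
choices, and known limitations of `crowdrasch`. Every number quoted here is
computed by the test suite or by `scripts/acceptance.py`; nothing is taken
on faith from external sources.

## Problem setting

Items (images) carry a latent binary gold label, *normal* or *abnormal*.
Each item is graded by several workers drawn from a large, heterogeneous
pool; each worker grades a (possibly small) subset of items. The task is to
aggregate the votes on an item into a consensus label, and to do so better
than the unweighted majority vote when workers differ in skill.

Ordinal source grades (e.g. severity scales 0–3) are first dichotomized:
grades 0 and 1 map to normal, 2 and 3 to abnormal (`dichotomize`). Records
are cleaned before modeling: exact duplicate (worker, item) grades are
dropped keeping the earliest by `order_index` (`dedupe_grades`), and workers
with fewer than 10 distinct graded items within the training subset are
excluded (`filter_sparse_workers`; the threshold and the choice between
removing only the subset records or the whole worker are parameters).

## Model

On a training set with known gold labels, define the correctness indicator
x_ni = 1 if worker i's vote on item n matches gold, else 0. The dichotomous
Rasch model puts

    P(x_ni = 1) = exp(B_n − D_i) / (1 + exp(B_n − D_i))

with item measure B_n (higher = easier to grade correctly) and worker
measure D_i (lower = more able), both in logits. Conditional on the
measures, responses are independent; marginal raw scores are sufficient
statistics for the parameters.

### Identification and centering

The likelihood is invariant to a common shift of all B and D. We fix the
scale by centering (parameter `centering`): `worker_mean_zero` (default,
mean D = 0), `worker_median_zero`, or `item_mean_zero`. Under the default,
D_i is interpretable relative to the average retained worker, and the vote
weight exp(−D_i) is that worker's odds of correctly grading an item of
average difficulty.

### Estimation (JMLE)

`RaschJMLE` maximizes the joint likelihood by alternating per-parameter
Newton–Raphson updates on the score estimating equations (observed marginal
score = expected marginal score), with:

- Newton steps clipped to ±1 logit per iteration for stability.
- Initialization at the logit of each row/column proportion correct
  (clamped away from 0 and 1).
- Recentering after every sweep.
- Convergence when both the largest parameter change and the largest
  marginal-score residual fall below `tol` (default 0.005); `max_iter`
  defaults to 200. Non-convergence raises a warning and is recorded on the
  fit object, never silently ignored.
- Standard errors SE = 1 / sqrt(Σ P(1−P)) over each parameter's observed
  cells.

**Extreme scores.** Perfect or zero marginal scores have no finite MLE. We
use the conventional adjustment of pulling extreme marginal scores in by
0.3 score points (`extreme_score_adjust`), but apply it at the *cell*
level: each extreme row's pull-in is spread proportionally over its
observed cells, then the same for extreme columns, and both facets' target
scores are taken as the marginals of this single adjusted matrix. Adjusting
the row and column marginals independently (the naive reading of the
convention) makes the two sets of estimating equations disagree about the
total score, and the alternating updates then oscillate without converging
to tolerance; the cell-level form restores consistency and, in our tests,
convergence in roughly ten iterations at study scale. Affected workers and
items are flagged on the fit object.

**Connectedness.** Measures are only comparable within a connected block of
the worker–item bipartite graph. The fit computes the number of connected
components (scipy `csgraph`) and warns when it exceeds one.

Correctness of the estimator is established against two independent
oracles: a coordinate-wise brute-force grid search over the joint
likelihood (refined to a 0.001-logit lattice) and a joint BFGS minimization
of the negative log-likelihood; JMLE agrees with both within 0.01 logits on
complete matrices (see `tests/test_acceptance.py` and `tests/_oracles.py`).

## Consensus weighting

Worker weight w_i = exp(−D_i). Weights are truncated at the empirical 1st
and 99th centiles (`truncation_centiles`, linear-interpolation percentiles)
to limit the influence of poorly measured extreme workers. The consensus
score for an item is

    S = Σ_i w_i · c_i,   c_i = +1 (abnormal vote), −1 (normal vote)

and the label is abnormal iff S ≥ cutoff (default 0; ties go to abnormal,
the conservative direction for screening). `weighted_score` accumulates the
abnormal and normal sides separately before differencing so that exact
ties produce exactly 0.0 despite floating-point non-associativity. Workers
present at test time but absent from training either raise an error or
receive the neutral (median truncated) weight, per `missing_weight`.
With all weights equal, the rule provably reduces to the majority vote
(abnormal iff at least half the votes are abnormal), which is tested over
randomized vote multisets including forced ties.

## Evaluation

- **AUROC** with the empirical ROC (scikit-learn `roc_curve`), verified
  against an O(n²) pair-count oracle with half-credit for ties.
- **DeLong** variance, 95% CI, and the paired chi-square (1 df) test for
  two correlated AUROCs are implemented from midrank placements. CI
  coverage is checked by simulation (92–98% over 500 binormal replicates).
  Degenerate inputs (fewer than two members of a class, zero variance)
  return explicit not-applicable results rather than spurious p-values.
- **Calibration**: a logistic regression of gold on the consensus score
  (statsmodels), with complete separation detected up front and reported
  instead of fitted.
- **Cut-point selection** over candidate cutoffs (midpoints between
  adjacent distinct scores, plus ±∞) under three criteria: maximum percent
  correct, maximum specificity subject to sensitivity ≥ target, maximum
  sensitivity subject to specificity ≥ target; lexicographic tie-breaking
  is deterministic. Unattainable targets raise an error naming the best
  achievable value. Verified against an exhaustive sweep oracle.
- **Jackknife**: leave-one-item-out validation refits the Rasch model with
  that item's column removed (warm-started from the full fit) and scores
  the held-out item with the refitted weights. With uniform weights this is
  exactly the naive vote-margin AUROC; with estimated weights it removes
  the optimism of scoring an item with weights trained on it. The gap to
  the naive AUROC shrinks as grades per worker grow; at the geometries the
  tests use (≈25 grades per item, ≥100 workers) it is within 0.02.

## Simulator

`simulate_crowd` generates: gold ~ Bernoulli(prevalence, default 0.42);
worker measures D ~ N(0, ability_sd²); item measures B ~ N(0,
difficulty_sd²); each item receives `grades_per_item` distinct workers,
assigned either uniformly at random or with a heavy-tailed (shuffled
Zipf) worker workload; a grade is correct with probability
expit(B_n − D_i), and an incorrect grade is the flipped label. Defaults:
1200 items, 300 workers, 10 grades per item, ability_sd 1.0, difficulty_sd
1.5.

What the simulator does and does not emulate:

- It reproduces the structural features that matter for the method —
  sparse assignment, heterogeneous worker skill, heterogeneous item
  difficulty, binary votes — and is the data source for recovery,
  benchmark, and jackknife results.
- Because worker measures are drawn with mean zero, the *average simulated
  worker performs at chance* (50% correct on the average item). Real
  crowds are typically better than chance on average, so the simulated
  majority-vote baseline (AUROC near 0.5) understates real MV performance,
  and the weighted-vs-MV gap in simulation is larger than one should
  expect in practice. The directional claim — weighting helps under skill
  heterogeneity — is what the benchmark tests; the magnitude is
  generator-specific.
- The error model is symmetric: an incorrect grade is always the flipped
  label, with no class-dependent bias (no separate sensitivity/specificity
  per worker), no correlated errors between workers, and no grade
  repetition or learning over time.

`benchmark_aggregators` runs replicates of simulate → 50/50 split → fit →
score, with every replicate's seeds derived from one master seed via
`numpy.random.SeedSequence` (all sub-seeds reduced mod 2³¹).

## Numerical and design choices

- Convergence tolerance 0.005 logits and max 200 iterations balance
  accuracy (well below the ~0.1-logit standard errors at study scale)
  against runtime.
- Train/test splits use `round(fraction · n)` with an optional
  largest-remainder stratified variant; item order is sorted before
  shuffling so splits depend only on the seed and the item set.
- Estimators follow the scikit-learn protocol (`fit`, `predict`,
  `decision_function`, `get_params`/`set_params`, fitted attributes with
  trailing underscores); the module-level functions (`fit_rasch`,
  `mv_consensus`, `weighted_score`, …) are thin wrappers or primitives the
  estimators share.
- All tabular I/O is plain CSV plus a YAML run manifest; the `crowdrasch`
  CLI wraps simulate and the end-to-end run without adding logic.

## Limitations

- JMLE is known to be biased in small samples (measures are slightly too
  spread out); the package documents this rather than applying a bias
  correction, since the downstream use (relative weights, rank-based
  evaluation) is insensitive to a mild common inflation.
- Weights learned on the training half assume worker ability is stable
  across items and time; drift is not modeled.
- The Rasch model assumes a single latent ability dimension and no
  worker–item interaction beyond B − D; guessing and class-dependent error
  rates are outside the model.
- DeLong inference treats items as independent; clustered items (e.g. two
  eyes per patient) would need a clustered variance not implemented here.
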