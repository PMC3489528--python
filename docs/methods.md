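# Methods

## Target-decoy error rates

All statistics assume *separate* target and decoy searches (every spectrum
matched independently against both databases), not target-decoy
competition. For a threshold *t* over the discriminant score,

FDR(*t*) = π₀ · #{decoys ≥ *t*} / #{targets ≥ *t*}, capped at 1,

and the q-value of a target PSM scoring *s* is min{FDR(*t*) : *t* ≤ *s*},
taken over the observed target scores as candidate thresholds. Counting is
inclusive on both sides, so a decoy tied with a threshold counts against
it; ties are thus resolved conservatively. Decoy PSMs in output tables
receive the q-value of the last threshold that would accept them — a
reporting convenience, not a statistical claim.

π₀ (the fraction of incorrect matches among targets) is estimated by
converting each target score to an empirical p-value against the decoy
distribution, p = (1 + #{decoys ≥ s}) / (1 + #decoys), then applying the
fixed-cutoff estimator π̂₀ = #{p > λ} / ((1 − λ) · #targets) with λ = 0.5,
clamped to [0, 1]. Correct matches essentially never have p > 0.5, so the
density of large p-values measures the null fraction. λ is not adaptive:
a fixed cutoff keeps the estimator simple and deterministic, and λ = 0.5
is robust across the score distributions the pipeline produces. π₀ = 1 is
available (`pi0_mode="one"`) as a strictly conservative alternative.
Internal analyses that only rank or select (positive selection,
hyperparameter scoring, normalization anchoring) use π₀ = 1 throughout;
the estimate enters only the final merged q-values.

## Self-training linear SVM

Decoys are labeled negatives. The positive set is bootstrapped: score all
PSMs of the training split, run a target-decoy analysis, and take targets
at q ≤ `q_select` (default 0.01) as positives. The initial score is the
single signed feature maximizing that count (ties: lowest feature index,
then sign +1). Each of `n_iter` = 10 iterations fits the weighted
soft-margin problem

min ½‖w‖² + c_pos · Σ hinge(positives) + c_neg · Σ hinge(decoys)

and adopts the fitted decision function as the next scoring direction.
Iteration count is fixed — no convergence test — so a run is a pure
function of (data, seed, grid). Targets that fail selection are *omitted*
from the objective rather than treated as negatives: labeling ambiguous
targets negative would bias the margin against exactly the matches the
method is trying to recover. If an iteration selects no positives at
0.01, the threshold relaxes stepwise to 0.05 then 0.10 for that iteration;
if still empty the current model is returned unchanged (on pure noise this
usually means the initial single-feature direction).

Features are standardized (zero mean, unit variance) using training-split
statistics only; the returned model folds the transform into raw-space
weights, so held-out scoring is a dot product and no held-out statistics
ever enter the fit. The solver is liblinear's dual coordinate descent
(hinge loss, C = 1 with per-sample weights c_pos/c_neg, seeded). The
intercept is handled as an augmented unit feature and is therefore mildly
regularized; with standardized features the intercept is small and the
effect negligible. The solver runs to tolerance 1e-3 with a hard cap of
3000 iterations: scoring only needs the decision direction, which
stabilizes long before the dual gap closes, and the cap prevents
ill-conditioned cost combinations from stalling a run. The reference
quadratic-program check in the test suite solves the identical
(augmented-intercept) primal with an independent SLSQP solver.

Hyperparameters (c_pos, c_neg) are chosen per training set by a nested
three-fold grid search: the training split is re-split by spectrum, each
candidate is self-trained on every nested two-thirds, and candidates are
ranked by total held-out targets at q ≤ `q_select` (ties: first in grid
order). The default grid is c_pos ∈ {0.1, 1, 10} × c_neg = c_pos · {1, 3,
10}; asymmetric costs reflect the imbalance between the selected-positive
set and the full decoy set. A single-candidate grid short-circuits.

## Cross-validation and merging

Spectra (not PSMs) are permuted with a seeded generator and dealt
round-robin into k = 3 folds, so fold sizes differ by at most one and PSMs
of one spectrum never straddle folds. Fold *i* is scored by a model tuned
and trained on the other folds only; each `FoldResult` records the exact
training PSM ids, making the no-leakage property auditable after the fact.
Spectra sharing a *peptide* may still land in different folds; peptide-level
co-location is not attempted, a known caveat for strongly redundant runs.

Per fold, scores are normalized by the increasing affine map sending the
smallest target score with within-fold q ≤ α (α = 0.01, configurable
independently of `q_select`) to 0 and the decoy median (mean of the middle
two for even counts) to −1. Both anchors come from the fold's own held-out
scores; targets and decoys pass through the identical map, so within-fold
ranking is untouched. If no target reaches q ≤ α — routine in small or
uninformative folds — the top-ranked target anchors instead and a warning
is emitted; if even that anchor fails to exceed the decoy median the fold
is unnormalizable and the run aborts with a degenerate-fold error.
Normalized folds are concatenated and a single final target-decoy analysis
(with the estimated π₀) yields the reported q-values.

## The simulation and what it shows

`generate_dataset` draws n_target + n_decoy PSMs with n_features i.i.d.
Normal(feature_mean, feature_sd²) features and adds `offset` to feature 1
of exactly `n_correct` targets. Defaults — 2500 + 2500 PSMs, 50 N(0, 1)
features, offset 10.0 on 1000 targets — are the study conditions and are
not tuning knobs. Each PSM is its own spectrum (the simulation has no
spectrum structure), and the ground-truth flags live outside the dataset
object, so no learner can see them even by accident.

`run_experiment` replays the design over `n_datasets` replicates (dataset
*i* seeded with seed + *i*; 10 replicates by default, a desk-scale choice —
medians over 10 are stable well within the tolerances asserted) and
records, on a q grid of 0–0.1 in steps of 0.002, the accepted-target count
and the true false discovery proportion (FDP; 0 when nothing is accepted).
With cross-validation the median count at q ≤ 0.01 tracks the ideal rate
n_correct/(1 − q) ≈ 1010 and the FDP tracks the estimated q. With
cross-validation disabled, *everything* — hyperparameter choice,
self-training, scoring — happens on the same PSMs, representing the fully
unvalidated pipeline; on pure-noise datasets (n_correct = 0) it reports
tens to hundreds of "significant" PSMs, all incorrect, while the validated
pipeline reports essentially none. That contrast is the package's
regression test against silent overfitting.

What the simulation does *not* emulate: correlated features, confounding
variables such as charge state, multiple PSMs per spectrum, shared
peptides, or decoys that imperfectly model incorrect targets. Passing
tests show the machinery is correct and calibrated under exchangeable
noise; they do not validate the decoy-modeling assumption on real data,
which requires known-content mixtures.

## Numerical and degenerate-input choices

- Seeds: a single master seed drives fold assignment, nested splits, the
  SVM solver and the generator; derived sub-seeds stay below 2³¹.
- Equal scores share a q-value by construction (identical threshold).
- Empty positive selection, folds lacking either label, fewer spectra than
  folds, and non-finite features all raise immediately with the offending
  fold or row named; nothing is imputed.
- Input labels other than ±1 are format errors, not warnings — a misparsed
  label silently corrupts every downstream FDR.

## Known limitations

- The linear score normalization is a heuristic; it works well in practice
  but has no distributional guarantee, and none is claimed.
- Single-PSM folds aside, very small datasets can leave the q = 0.01
  anchor undefined; the top-target fallback keeps the run alive at the
  cost of a compressed score scale in that fold.
- Posterior error probabilities (PEPs) and target-decoy competition FDR
  are out of scope; so is protein-level inference.
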