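"""Self-training linear SVM for separating correct from incorrect PSMs.

The learner is semi-supervised: decoy PSMs are known negatives, but no
target PSM is a known positive.  Self-training bootstraps a positive set
from the data itself: score all PSMs with a current scoring direction,
run a target-decoy analysis on those scores, take the target PSMs that
pass a stringent q-value threshold as positives, fit a soft-margin linear
SVM of positives against all decoys, adopt the fitted decision function as
the new scoring direction, and repeat.

The SVM objective is the weighted soft-margin problem

    min_w,b  1/2 ||w||^2  +  c_pos * sum_i hinge_i  +  c_neg * sum_j hinge_j

over selected positives i and decoy negatives j.  Target PSMs that fail
the selection threshold are left out of the objective entirely (strict
self-training semantics): treating ambiguous targets as negatives would
bias the margin.

Features are standardized to zero mean and unit variance using statistics
of the training split only; the returned model folds the transform back
into raw feature space, so scoring held-out PSMs is a plain dot product
with no leakage of held-out statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .psm_io import PSMDataset
from .tdc_stats import compute_qvalues

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparams",
    "LearnerConfig",
    "SVMModel",
    "default_grid",
    "choose_initial_direction",
    "select_positives",
    "train_weighted_svm",
    "self_train",
    "grid_search",
]

# Relaxation ladder used when the stringent threshold selects no positives.
_Q_RELAXATION = (0.05, 0.10)

# liblinear handles the intercept as an augmented constant feature, so the
# regularizer includes b^2/2; with standardized features the intercept is
# small and the extra penalty is negligible.  The dual coordinate-descent
# solver is run to a loose tolerance with a hard iteration cap: PSM scoring
# only needs the decision direction, which stabilizes long before the dual
# gap closes, and the cap keeps ill-conditioned cost settings from stalling.
INTERCEPT_SCALING = 1.0
_SVM_TOL = 1e-3
_SVM_MAX_ITER = 3000


@dataclass(frozen=True)
class Hyperparams:
    """Misclassification costs of the weighted soft-margin SVM.

    ``c_pos`` weighs hinge losses of selected positives, ``c_neg`` those of
    decoy negatives.  Asymmetric costs compensate for the imbalance between
    the (small) selected-positive set and the full decoy set.
    """

    c_pos: float
    c_neg: float

    def __post_init__(self) -> None:
        if self.c_pos <= 0 or self.c_neg <= 0:
            raise ValueError("misclassification costs must be strictly positive")


def default_grid() -> list[Hyperparams]:
    """3x3 cost grid: c_pos in {0.1, 1, 10}, c_neg = c_pos * {1, 3, 10}."""
    return [
        Hyperparams(c_pos=cp, c_neg=cp * mult)
        for cp in (0.1, 1.0, 10.0)
        for mult in (1.0, 3.0, 10.0)
    ]


@dataclass(frozen=True)
class LearnerConfig:
    """Settings of the self-training loop.

    ``q_select`` is the q-value threshold under which a target PSM counts
    as a high-confidence positive (0.01 by default, the same stringency
    used later as the score-normalization anchor).  ``n_iter`` is a fixed
    iteration count — there is no convergence test, which keeps runs
    deterministic.  ``grid`` lists the hyperparameter candidates searched
    by nested cross-validation.
    """

    q_select: float = 0.01
    n_iter: int = 10
    grid: list[Hyperparams] = field(default_factory=default_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.q_select < 1.0:
            raise ValueError("q_select must be in (0, 1)")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")


@dataclass(frozen=True)
class SVMModel:
    """A linear decision function in raw feature space.

    ``score(x) = weights . x + intercept``.  Models fitted on standardized
    features are converted back to raw space before being returned, so the
    weights always align with the dataset's feature columns.
    """

    weights: np.ndarray
    intercept: float
    hyperparams: Hyperparams | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        if not np.all(np.isfinite(w)) or not np.isfinite(self.intercept):
            raise ValueError("model weights and intercept must be finite")
        object.__setattr__(self, "weights", w)

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.weights.size:
            raise ValueError(
                f"model has {self.weights.size} weights but input has "
                f"{X.shape[1]} features"
            )
        return X @ self.weights + self.intercept


def _single_feature_model(n_features: int, index: int, sign: int) -> SVMModel:
    w = np.zeros(n_features)
    w[index] = float(sign)
    return SVMModel(weights=w, intercept=0.0)


def choose_initial_direction(data: PSMDataset, q_select: float) -> tuple[int, int]:
    """Pick the single signed feature that best separates targets from decoys.

    Scans every (feature, sign) pair, scores all PSMs by that signed feature
    alone, and counts target PSMs at q <= ``q_select`` (target-decoy
    analysis with pi0 = 1).  Returns the pair with the highest count; ties
    resolve to the lowest feature index, then to sign +1.
    """
    if data.n_features < 1:
        raise ValueError("dataset has no features")
    data.require_both_labels()
    is_decoy = data.is_decoy
    best: tuple[int, int] = (0, 1)
    best_count = -1
    for j in range(data.n_features):
        col = data.features[:, j]
        for sign in (1, -1):
            scores = sign * col
            res = compute_qvalues(scores[~is_decoy], scores[is_decoy], pi0=1.0)
            count = int(np.count_nonzero(res.qvalues <= q_select))
            if count > best_count:
                best_count = count
                best = (j, sign)
    return best


def select_positives(
    scores: np.ndarray, data: PSMDataset, q_select: float, pi0: float = 1.0
) -> np.ndarray:
    """Mask of target PSMs confidently separated from the decoys.

    True exactly for targets whose q-value at the given scores is at most
    ``q_select``; decoys are never selected, whatever their score.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size != len(data):
        raise ValueError("scores must align with dataset records")
    is_decoy = data.is_decoy
    res = compute_qvalues(scores[~is_decoy], scores[is_decoy], pi0=pi0)
    mask = np.zeros(len(data), dtype=bool)
    mask[~is_decoy] = res.qvalues <= q_select
    return mask


def train_weighted_svm(
    features: np.ndarray,
    positives: np.ndarray,
    negatives: np.ndarray,
    hp: Hyperparams,
    seed: int = 0,
) -> SVMModel:
    """Fit the weighted soft-margin linear SVM on the labeled rows only.

    Rows in neither mask are excluded from the objective.  The fit is
    deterministic for a fixed ``seed``.  Raises ``ValueError`` when either
    class is empty — the caller decides the fallback.
    """
    positives = np.asarray(positives, dtype=bool)
    negatives = np.asarray(negatives, dtype=bool)
    if (positives & negatives).any():
        raise ValueError("positive and negative masks must be disjoint")
    if not positives.any() or not negatives.any():
        raise ValueError("training requires at least one positive and one negative")

    labeled = positives | negatives
    X = np.asarray(features, dtype=float)[labeled]
    y = np.where(positives[labeled], 1, -1)
    sample_weight = np.where(y == 1, hp.c_pos, hp.c_neg)

    clf = LinearSVC(
        C=1.0,
        loss="hinge",
        fit_intercept=True,
        intercept_scaling=INTERCEPT_SCALING,
        tol=_SVM_TOL,
        max_iter=_SVM_MAX_ITER,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # the iteration cap is deliberate; see _SVM_MAX_ITER
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y, sample_weight=sample_weight)
    return SVMModel(
        weights=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        hyperparams=hp,
    )


def self_train(data: PSMDataset, cfg: LearnerConfig, hp: Hyperparams) -> SVMModel:
    """Run the self-training loop on one training split.

    Each iteration scores the whole split with the current model, selects
    positives at ``cfg.q_select`` (relaxing stepwise to 0.05 then 0.10 for
    that iteration if the selection comes up empty), fits the weighted SVM
    of positives against all decoys, and adopts the new model.  If even the
    relaxed thresholds select nothing, the current model is returned
    unchanged.  ``cfg.n_iter == 0`` returns the initial single-feature
    direction.
    """
    data.require_both_labels()
    X = data.features
    j, sign = choose_initial_direction(data, cfg.q_select)
    current = _single_feature_model(data.n_features, j, sign)
    if cfg.n_iter == 0:
        return SVMModel(current.weights, current.intercept, hyperparams=hp)

    # Standardize on the training split only; the returned model maps the
    # transform back to raw feature space.
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd

    scores = current.decision_function(X)
    model_z: SVMModel | None = None
    for _ in range(cfg.n_iter):
        mask = np.zeros(len(data), dtype=bool)
        for q_thr in (cfg.q_select, *_Q_RELAXATION):
            mask = select_positives(scores, data, q_thr, pi0=1.0)
            if mask.any():
                break
        if not mask.any():
            logger.debug("self_train: empty positive set, returning current model")
            break
        model_z = train_weighted_svm(Z, mask, data.is_decoy, hp, seed=cfg.seed)
        scores = model_z.decision_function(Z)

    if model_z is None:
        return SVMModel(current.weights, current.intercept, hyperparams=hp)
    w_raw = model_z.weights / sd
    b_raw = model_z.intercept - float((model_z.weights * mu / sd).sum())
    return SVMModel(weights=w_raw, intercept=b_raw, hyperparams=hp)


def grid_search(data: PSMDataset, cfg: LearnerConfig) -> Hyperparams:
    """Choose hyperparameters by nested three-fold cross-validation.

    The training split is itself split three ways (by spectrum).  Each
    candidate is self-trained on every nested two-thirds and judged by the
    number of held-out target PSMs reaching q <= ``cfg.q_select`` on the
    remaining third, summed over the three nested folds.  The candidate
    with the largest total wins; ties go to the earliest candidate in grid
    order.
    """
    if len(cfg.grid) == 1:
        return cfg.grid[0]

    from .crossval import assign_folds  # deferred: crossval imports this module

    split = assign_folds(data, k=3, seed=_derive_seed(cfg.seed, 0x6E65))
    fold_of = np.asarray([split.assignment[sid] for sid in data.spectrum_ids])

    counts = np.zeros(len(cfg.grid), dtype=int)
    for nested_fold in range(1, 4):
        train = data.subset(fold_of != nested_fold)
        test = data.subset(fold_of == nested_fold)
        for part, name in ((train, "training"), (test, "validation")):
            if part.n_targets == 0 or part.n_decoys == 0:
                raise ValueError(
                    f"nested fold {nested_fold}: {name} part lacks targets or "
                    "decoys; use larger folds"
                )
        for gi, hp in enumerate(cfg.grid):
            model = self_train(train, cfg, hp)
            scores = model.decision_function(test.features)
            res = compute_qvalues(
                scores[~test.is_decoy], scores[test.is_decoy], pi0=1.0
            )
            counts[gi] += int(np.count_nonzero(res.qvalues <= cfg.q_select))

    best = int(np.argmax(counts))  # argmax keeps the first maximum: grid order
    logger.debug("grid_search: counts=%s chosen=%s", counts.tolist(), cfg.grid[best])
    return cfg.grid[best]


def _derive_seed(seed: int, salt: int) -> int:
    """Deterministic sub-seed, kept within 31 bits."""
    return int((seed * 1_000_003 + salt) % (2**31 - 1))
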