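"""Three-fold cross-validation orchestration.

Every PSM must be scored by a model that never saw it during training,
otherwise the final target-decoy analysis underestimates the error rates.
Spectra (not individual PSMs) are dealt into k equally sized folds, so
PSMs sharing a spectrum can never straddle the train/validation boundary.
For each fold, hyperparameters are chosen by a nested grid search on the
other k-1 folds, the self-training SVM is fitted on those folds, and the
resulting model scores only the held-out fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .psm_io import PSMDataset
from .svm_learner import LearnerConfig, SVMModel, _derive_seed, grid_search, self_train

logger = logging.getLogger(__name__)

__all__ = ["CVSplit", "FoldResult", "assign_folds", "run_cross_validation"]


@dataclass(frozen=True)
class CVSplit:
    """Assignment of every spectrum to one of k folds.

    Fold sizes (counted in spectra) differ by at most one; all PSMs of a
    spectrum share its fold.
    """

    k: int
    assignment: dict
    seed: int

    def fold_of(self, data: PSMDataset) -> np.ndarray:
        """Per-record fold tags for a dataset covered by this split."""
        try:
            return np.asarray([self.assignment[sid] for sid in data.spectrum_ids])
        except KeyError as exc:
            raise ValueError(f"spectrum {exc.args[0]!r} not covered by split") from exc


@dataclass(frozen=True)
class FoldResult:
    """One fold's fitted model and held-out scores.

    ``training_psm_ids`` records provenance: the exact PSMs the model was
    trained on, enabling a no-leakage audit of any run.
    """

    fold: int
    model: SVMModel
    heldout_scores: dict
    training_psm_ids: frozenset


def assign_folds(data: PSMDataset, k: int = 3, seed: int = 0) -> CVSplit:
    """Deal spectra into k folds, uniformly at random.

    The distinct spectrum ids are permuted with a seeded generator and
    dealt round-robin, which guarantees fold sizes within one of each
    other.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    # preserve first-appearance order before permuting, for determinism
    seen: dict = {}
    for sid in data.spectrum_ids:
        seen.setdefault(sid, None)
    spectra = list(seen)
    if len(spectra) < k:
        raise ValueError(f"need at least {k} distinct spectra, got {len(spectra)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(spectra))
    assignment = {spectra[idx]: (pos % k) + 1 for pos, idx in enumerate(order)}
    return CVSplit(k=k, assignment=assignment, seed=seed)


def run_cross_validation(
    data: PSMDataset, cfg: LearnerConfig, split: CVSplit
) -> list[FoldResult]:
    """Train on k-1 folds, score the held-out fold; repeat for every fold.

    Returns one :class:`FoldResult` per fold; their held-out score maps
    partition the dataset's PSM ids exactly.  Learner errors are re-raised
    annotated with the fold index.
    """
    fold_of = split.fold_of(data)
    results: list[FoldResult] = []
    for fold in range(1, split.k + 1):
        train = data.subset(fold_of != fold)
        test = data.subset(fold_of == fold)
        fold_cfg = LearnerConfig(
            q_select=cfg.q_select,
            n_iter=cfg.n_iter,
            grid=cfg.grid,
            seed=_derive_seed(cfg.seed, fold),
        )
        try:
            hp = grid_search(train, fold_cfg)
            model = self_train(train, fold_cfg, hp)
        except ValueError as exc:
            raise ValueError(f"fold {fold}: {exc}") from exc
        scores = model.decision_function(test.features)
        logger.info(
            "fold %d: %d train / %d held-out PSMs, hyperparams %s",
            fold, len(train), len(test), hp,
        )
        results.append(
            FoldResult(
                fold=fold,
                model=model,
                heldout_scores=dict(zip(test.psm_ids.tolist(), scores.tolist())),
                training_psm_ids=frozenset(train.psm_ids.tolist()),
            )
        )
    return results
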