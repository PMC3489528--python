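"""End-to-end rescoring pipelines.

``rescore_dataset`` is the validated path: spectrum-level three-fold
cross-validation, per-fold normalization, merging, and a final
target-decoy analysis.  ``rescore_no_cv`` deliberately trains and scores
on the same PSMs (hyperparameters included); it exists only to
demonstrate how overfitting corrupts the estimated error rates and should
never be used for real analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossval import CVSplit, FoldResult, assign_folds, run_cross_validation
from .psm_io import PSMDataset
from .score_merge import NormalizationParams, fit_normalization, merge_folds
from .svm_learner import LearnerConfig, SVMModel, compute_qvalues, self_train
from .tdc_stats import estimate_pi0, qvalues_at

logger = logging.getLogger(__name__)

__all__ = ["RescoreResult", "rescore_dataset", "rescore_no_cv"]


@dataclass
class RescoreResult:
    """Merged rescoring output plus the artifacts that produced it.

    ``table`` has one row per PSM (psm_id, is_decoy, score, qvalue,
    peptide).  ``pi0`` is the estimate used for the final q-values.
    ``fold_results``/``norm_params``/``split`` are None for the
    no-cross-validation path.
    """

    table: pd.DataFrame
    pi0: float
    split: CVSplit | None = None
    fold_results: list[FoldResult] | None = None
    norm_params: list[NormalizationParams] | None = None
    models: list[SVMModel] | None = None

    def n_significant(self, q: float = 0.01) -> int:
        t = self.table
        return int(((~t["is_decoy"]) & (t["qvalue"] <= q)).sum())


def _final_pi0(scores: np.ndarray, is_decoy: np.ndarray, pi0_mode: str) -> float:
    if pi0_mode == "one":
        return 1.0
    if pi0_mode == "fixed-lambda":
        return estimate_pi0(scores[~is_decoy], scores[is_decoy], lam=0.5)
    raise ValueError(f"unknown pi0 mode {pi0_mode!r}")


def rescore_dataset(
    data: PSMDataset,
    cfg: LearnerConfig | None = None,
    k: int = 3,
    alpha: float = 0.01,
    pi0_mode: str = "fixed-lambda",
    seed: int | None = None,
) -> RescoreResult:
    """Run the full cross-validated rescoring pipeline on one dataset.

    Folds are assigned by spectrum with ``seed`` (defaults to the learner
    seed); each fold is scored by a model trained and tuned on the other
    folds only; fold scores are normalized (q = ``alpha`` threshold -> 0,
    decoy median -> -1) and merged; pi0 is estimated on the merged
    normalized scores and the final q-values computed from them.
    """
    cfg = cfg or LearnerConfig()
    data.require_both_labels()
    split = assign_folds(data, k=k, seed=cfg.seed if seed is None else seed)
    fold_results = run_cross_validation(data, cfg, split)

    decoy_of = dict(zip(data.psm_ids.tolist(), data.is_decoy.tolist()))
    norm_params = []
    for fr in fold_results:
        ids = list(fr.heldout_scores)
        raw = np.asarray([fr.heldout_scores[i] for i in ids])
        flags = np.asarray([decoy_of[i] for i in ids], dtype=bool)
        norm_params.append(fit_normalization(raw, flags, alpha=alpha, fold=fr.fold))

    # pi0 for the final analysis comes from the merged normalized scores
    merged_raw = merge_folds(fold_results, norm_params, data, pi0=1.0)
    s = merged_raw["score"].to_numpy()
    f = merged_raw["is_decoy"].to_numpy()
    pi0 = _final_pi0(s, f, pi0_mode)
    table = merge_folds(fold_results, norm_params, data, pi0=pi0)
    logger.info(
        "rescore: pi0=%.4f, %d of %d targets significant at q<=0.01",
        pi0,
        int(((~table["is_decoy"]) & (table["qvalue"] <= 0.01)).sum()),
        int((~table["is_decoy"]).sum()),
    )
    return RescoreResult(
        table=table,
        pi0=pi0,
        split=split,
        fold_results=fold_results,
        norm_params=norm_params,
        models=[fr.model for fr in fold_results],
    )


def rescore_no_cv(
    data: PSMDataset,
    cfg: LearnerConfig | None = None,
    pi0_mode: str = "fixed-lambda",
) -> RescoreResult:
    """Train and score on the same PSMs — the overfitting condition.

    No hold-out anywhere: each hyperparameter candidate is self-trained on
    the full dataset and judged by its significant-target count on the
    very same dataset; the winner's model then scores those PSMs and the
    q-values are computed from those scores.  Error rates estimated this
    way are unreliable by construction.
    """
    cfg = cfg or LearnerConfig()
    data.require_both_labels()
    is_decoy = data.is_decoy

    best_model: SVMModel | None = None
    best_count = -1
    for hp in cfg.grid:
        model = self_train(data, cfg, hp)
        scores = model.decision_function(data.features)
        res = compute_qvalues(scores[~is_decoy], scores[is_decoy], pi0=1.0)
        count = int(np.count_nonzero(res.qvalues <= cfg.q_select))
        if count > best_count:  # strict: ties keep the earliest candidate
            best_count = count
            best_model = model
    assert best_model is not None

    scores = best_model.decision_function(data.features)
    pi0 = _final_pi0(scores, is_decoy, pi0_mode)
    res = compute_qvalues(scores[~is_decoy], scores[is_decoy], pi0=pi0)
    qvals = np.empty(len(data))
    qvals[~is_decoy] = res.qvalues
    if is_decoy.any():
        qvals[is_decoy] = qvalues_at(
            scores[is_decoy], scores[~is_decoy], scores[is_decoy], pi0=pi0
        )
    table = pd.DataFrame(
        {
            "psm_id": data.psm_ids,
            "is_decoy": is_decoy,
            "score": scores,
            "qvalue": qvals,
            "peptide": (
                data.peptides if data.peptides is not None else [""] * len(data)
            ),
        }
    )
    return RescoreResult(table=table, pi0=pi0, models=[best_model])
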