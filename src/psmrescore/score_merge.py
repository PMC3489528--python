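"""Per-fold score normalization and merging.

Cross-validation leaves each fold scored by a different classifier, and
raw decision values from different classifiers are not comparable.  Before
merging, each fold's scores are put on a common scale by an affine map
pinned by two anchors from that fold's internal target-decoy analysis:

* the smallest target score reaching q <= alpha maps to 0, and
* the median decoy score maps to -1.

Targets and decoys of a fold are transformed by the identical map, so
within-fold score order is preserved (the map has strictly positive
slope).  After normalization the folds are concatenated and a single
target-decoy analysis over the merged list yields the final q-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossval import FoldResult
from .psm_io import PSMDataset
from .tdc_stats import compute_qvalues, qvalues_at

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationParams",
    "DegenerateFoldError",
    "DegenerateFoldWarning",
    "fit_normalization",
    "merge_folds",
]


class DegenerateFoldError(ValueError):
    """The fold's anchors cannot define an increasing affine map."""


class DegenerateFoldWarning(UserWarning):
    """No target reached q <= alpha; the top-ranked target anchors instead."""


@dataclass(frozen=True)
class NormalizationParams:
    """Affine transform x -> scale * x + offset for one fold.

    ``s_star`` is the raw score anchoring normalized 0 (the q = alpha
    threshold score); ``m_decoy`` is the raw decoy median anchoring
    normalized -1.  The two anchors force scale = 1/(s_star - m_decoy)
    and offset = -s_star * scale.
    """

    fold: int
    s_star: float
    m_decoy: float
    scale: float
    offset: float

    def apply(self, scores) -> np.ndarray:
        return self.scale * np.asarray(scores, dtype=float) + self.offset


def fit_normalization(
    scores, is_decoy, alpha: float = 0.01, fold: int = 0
) -> NormalizationParams:
    """Fit one fold's normalization from its raw scores and decoy flags.

    ``s_star`` is the minimal raw score among targets with within-fold
    q-value <= ``alpha`` (pi0 = 1 for this internal analysis).  If no
    target reaches the threshold — possible in small or poorly separated
    folds — the top-ranked target's score anchors instead and a
    :class:`DegenerateFoldWarning` is emitted.  If the chosen anchor does
    not strictly exceed the decoy median the fold cannot be normalized and
    a :class:`DegenerateFoldError` is raised.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    is_decoy = np.asarray(is_decoy, dtype=bool).ravel()
    if scores.size != is_decoy.size:
        raise ValueError("scores and decoy flags must align")
    target_scores = scores[~is_decoy]
    decoy_scores = scores[is_decoy]
    if target_scores.size == 0 or decoy_scores.size == 0:
        raise ValueError(f"fold {fold}: needs both targets and decoys")

    res = compute_qvalues(target_scores, decoy_scores, pi0=1.0)
    passing = target_scores[res.qvalues <= alpha]
    if passing.size:
        s_star = float(passing.min())
    else:
        s_star = float(target_scores.max())
        warnings.warn(
            f"fold {fold}: no target reached q <= {alpha}; anchoring the "
            "normalization at the top-ranked target score",
            DegenerateFoldWarning,
            stacklevel=2,
        )
    m_decoy = float(np.median(decoy_scores))  # even count: mean of middle two
    if not s_star > m_decoy:
        raise DegenerateFoldError(
            f"fold {fold}: q-threshold score {s_star} does not exceed decoy "
            f"median {m_decoy}; fold cannot be normalized"
        )
    scale = 1.0 / (s_star - m_decoy)
    offset = -s_star * scale
    return NormalizationParams(
        fold=fold, s_star=s_star, m_decoy=m_decoy, scale=scale, offset=offset
    )


def merge_folds(
    fold_results: list[FoldResult],
    params: list[NormalizationParams],
    data: PSMDataset,
    pi0: float = 1.0,
) -> pd.DataFrame:
    """Normalize each fold's scores, concatenate, and re-analyze.

    Each PSM's raw score passes through its own fold's affine map; the
    merged list gets one final target-decoy analysis at the given ``pi0``.
    Returns a table with columns ``psm_id``, ``is_decoy``, ``score``
    (normalized), ``qvalue`` and ``peptide``, covering every input PSM
    exactly once.  Decoy PSMs receive the q-value of the last threshold
    that would accept them, for reporting only.
    """
    by_fold = {p.fold: p for p in params}
    decoy_of = dict(zip(data.psm_ids.tolist(), data.is_decoy.tolist()))
    peptide_of = (
        dict(zip(data.psm_ids.tolist(), data.peptides.tolist()))
        if data.peptides is not None
        else {}
    )

    ids: list = []
    flags: list = []
    normalized: list = []
    for fr in fold_results:
        if fr.fold not in by_fold:
            raise ValueError(f"no normalization parameters for fold {fr.fold}")
        p = by_fold[fr.fold]
        for psm_id, raw in fr.heldout_scores.items():
            ids.append(psm_id)
            flags.append(decoy_of[psm_id])
            normalized.append(p.apply(raw).item())

    flags_arr = np.asarray(flags, dtype=bool)
    scores_arr = np.asarray(normalized, dtype=float)
    res = compute_qvalues(scores_arr[~flags_arr], scores_arr[flags_arr], pi0=pi0)
    qvals = np.empty(len(ids))
    qvals[~flags_arr] = res.qvalues
    if flags_arr.any():
        qvals[flags_arr] = qvalues_at(
            scores_arr[flags_arr], scores_arr[~flags_arr], scores_arr[flags_arr], pi0=pi0
        )
    return pd.DataFrame(
        {
            "psm_id": ids,
            "is_decoy": flags_arr,
            "score": scores_arr,
            "qvalue": qvals,
            "peptide": [peptide_of.get(i, "") for i in ids],
        }
    )
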