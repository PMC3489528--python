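"""Target-decoy statistics: FDR, pi0 and q-value estimation from separate searches.

In a separate target/decoy search every spectrum is matched independently
against the target database and against the decoy database.  Decoy matches
are assumed incorrect by construction, so the decoy score distribution
models the scores of incorrect target matches.  For a score threshold ``t``
the false discovery rate among accepted targets is estimated as

    FDR(t) = pi0 * #{decoys >= t} / #{targets >= t}

where ``pi0`` is the expected proportion of incorrect matches among all
target PSMs.  The q-value of a target PSM is the minimum FDR over all
thresholds that would accept it.

Conventions used throughout:

* Counting is inclusive (``>= t``) for both targets and decoys, so a decoy
  tied with a target threshold counts against that threshold.  This is the
  conservative choice; ties otherwise create an optimistic bias.
* Estimated FDRs are capped at 1 before the running minimum is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


__all__ = [
    "QValueResult",
    "estimate_pi0",
    "compute_qvalues",
    "qvalues_at",
]


@dataclass(frozen=True)
class QValueResult:
    """Per-target-PSM scores and q-values, plus the pi0 used to compute them.

    ``qvalues[i]`` is aligned with ``scores[i]`` in the caller's input
    order.  After sorting by descending score the q-values are
    non-decreasing.
    """

    scores: np.ndarray
    qvalues: np.ndarray
    pi0: float

    def __post_init__(self) -> None:
        if self.scores.shape != self.qvalues.shape:
            raise ValueError("scores and qvalues must be aligned 1:1")


def _as_score_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _count_ge(sorted_scores: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Number of entries of ``sorted_scores`` (ascending) >= each threshold."""
    return sorted_scores.size - np.searchsorted(sorted_scores, thresholds, side="left")


def estimate_pi0(target_scores, decoy_scores, lam: float = 0.5) -> float:
    """Estimate the proportion of incorrect matches among target PSMs.

    Each target score is converted to an empirical p-value against the decoy
    score distribution, ``p = (1 + #{decoys >= s}) / (1 + #decoys)`` (the
    add-one form avoids p = 0).  Incorrect targets have approximately
    uniform p-values while correct targets pile up near zero, so the density
    of p-values above a cutoff ``lam`` estimates the null fraction:

        pi0_hat = #{p > lam} / ((1 - lam) * #targets)

    clamped into [0, 1].

    Parameters
    ----------
    target_scores, decoy_scores
        Score lists from the separate target and decoy searches.
    lam
        Fixed cutoff in (0, 1).  0.5 is a robust default: correct matches
        rarely have p-values that large.
    """
    t = _as_score_array(target_scores, "target_scores")
    d = np.sort(_as_score_array(decoy_scores, "decoy_scores"))
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lambda must be in (0, 1), got {lam}")
    pvals = (1.0 + _count_ge(d, t)) / (1.0 + d.size)
    pi0 = np.count_nonzero(pvals > lam) / ((1.0 - lam) * t.size)
    return float(np.clip(pi0, 0.0, 1.0))


def compute_qvalues(target_scores, decoy_scores, pi0: float = 1.0) -> QValueResult:
    """Assign a q-value to every target PSM.

    Every observed target score is a candidate threshold.  FDR at threshold
    ``t`` is ``min(1, pi0 * #{decoys >= t} / #{targets >= t})``; the q-value
    of a target scoring ``s`` is the minimum FDR over all thresholds
    ``t <= s`` (every threshold that accepts it).

    Returns a :class:`QValueResult` aligned with the input order of
    ``target_scores``.
    """
    t = _as_score_array(target_scores, "target_scores")
    d = np.sort(_as_score_array(decoy_scores, "decoy_scores"))
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError(f"pi0 must be in [0, 1], got {pi0}")

    order = np.argsort(t, kind="stable")  # ascending thresholds
    t_sorted = t[order]
    n_targets_ge = t.size - np.searchsorted(t_sorted, t_sorted, side="left")
    n_decoys_ge = _count_ge(d, t_sorted)
    fdr = np.minimum(1.0, pi0 * n_decoys_ge / n_targets_ge)
    # q(s) = min FDR over thresholds <= s: cumulative minimum in ascending
    # threshold order.
    q_sorted = np.minimum.accumulate(fdr)

    qvalues = np.empty_like(t)
    qvalues[order] = q_sorted
    return QValueResult(scores=t.copy(), qvalues=qvalues, pi0=float(pi0))


def qvalues_at(eval_scores, target_scores, decoy_scores, pi0: float = 1.0) -> np.ndarray:
    """Evaluate the target-decoy q-value step function at arbitrary scores.

    The q-value function is defined on the observed target-score thresholds;
    an arbitrary score ``s`` receives the minimum FDR over thresholds
    ``t <= s``.  Scores below every threshold are accepted by no threshold
    and receive q = 1.  Used to attach q-values to decoy PSMs in merged
    output tables.
    """
    res = compute_qvalues(target_scores, decoy_scores, pi0)
    order = np.argsort(res.scores, kind="stable")
    t_sorted = res.scores[order]
    q_sorted = res.qvalues[order]
    s = np.asarray(eval_scores, dtype=float).ravel()
    idx = np.searchsorted(t_sorted, s, side="right") - 1
    out = np.ones_like(s)
    valid = idx >= 0
    out[valid] = q_sorted[idx[valid]]
    return out
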