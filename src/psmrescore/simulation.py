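"""Synthetic PSM datasets and the overfitting experiment.

The generator emulates a separate target/decoy search in which match
correctness is known by construction: every PSM carries ``n_features``
i.i.d. Normal(0, 1) feature values, and a fixed number of target PSMs —
the synthetic "correct" matches — get a large offset added to the first
feature.  Decoys and the remaining targets are exchangeable noise, which
is exactly the assumption target-decoy analysis rests on.

``run_experiment`` replays the study design over many independent
datasets: rescoring with the cross-validation protocol on or off, then
recording on a q-value grid how many targets are deemed significant and
what fraction of them is truly incorrect (the false discovery proportion,
observable only here because ground truth is known).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pipeline import rescore_dataset, rescore_no_cv
from .psm_io import PSMDataset
from .svm_learner import LearnerConfig

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "generate_dataset",
    "ideal_identification_count",
    "run_experiment",
    "default_q_grid",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions: 2500 targets and 2500 decoys per
    dataset, 50 standard-normal features, an offset of 10.0 added to
    feature 1 of 1000 target PSMs (the synthetic correct matches).
    ``n_datasets`` defaults to 10 independent replicates; dataset ``i``
    uses seed ``seed + i``.
    """

    n_target: int = 2500
    n_decoy: int = 2500
    n_features: int = 50
    n_correct: int = 1000
    offset: float = 10.0
    feature_mean: float = 0.0
    feature_sd: float = 1.0
    n_datasets: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_correct > self.n_target:
            raise ValueError("n_correct cannot exceed n_target")
        if self.n_correct < 0 or self.n_target < 1 or self.n_decoy < 1:
            raise ValueError("counts must be positive (n_correct may be 0)")
        if self.n_features < 1:
            raise ValueError("need at least one feature")
        if self.feature_sd <= 0:
            raise ValueError("feature_sd must be positive")
        if self.n_datasets < 1:
            raise ValueError("need at least one dataset")


def generate_dataset(
    cfg: SimulationConfig, seed: int
) -> tuple[PSMDataset, np.ndarray]:
    """Draw one synthetic dataset.

    Returns the learner-facing dataset and, separately, the hidden
    ground-truth mask (aligned with the dataset rows, True for the
    synthetic correct target PSMs).  The dataset itself carries no trace
    of the truth, so no learner can touch it.  Each PSM is its own
    spectrum: the simulation has no spectrum structure.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_target + cfg.n_decoy
    features = rng.normal(cfg.feature_mean, cfg.feature_sd, size=(n, cfg.n_features))
    features[: cfg.n_correct, 0] += cfg.offset  # correct targets, first feature

    is_decoy = np.zeros(n, dtype=bool)
    is_decoy[cfg.n_target :] = True
    is_correct = np.zeros(n, dtype=bool)
    is_correct[: cfg.n_correct] = True

    ids = np.asarray(
        [f"target_{i}" for i in range(cfg.n_target)]
        + [f"decoy_{i}" for i in range(cfg.n_decoy)],
        dtype=object,
    )
    data = PSMDataset(
        psm_ids=ids,
        spectrum_ids=ids.copy(),  # one PSM per synthetic spectrum
        is_decoy=is_decoy,
        features=features,
        feature_names=[f"feature_{j + 1}" for j in range(cfg.n_features)],
    )
    return data, is_correct


def ideal_identification_count(q: float, n_correct: int) -> float:
    """Expected accepted-target count of a perfectly calibrated analysis.

    Accepting all ``n_correct`` correct matches at false discovery rate
    ``q`` means incorrect matches make up a fraction ``q`` of the accepted
    list, giving ``n_correct / (1 - q)`` acceptances in total.
    """
    if not 0.0 <= q < 1.0:
        raise ValueError(f"q must be in [0, 1), got {q}")
    return n_correct / (1.0 - q)


def default_q_grid() -> np.ndarray:
    """q thresholds 0 to 0.1 in steps of 0.002 (51 points)."""
    return np.round(np.arange(0, 51) * 0.002, 6)


@dataclass
class SimulationResult:
    """Per-dataset curves over the q grid, plus quantile summaries.

    ``counts[d, i]`` is the number of targets dataset ``d`` deems
    significant at ``q_grid[i]``; ``fdp[d, i]`` is the ground-truth
    fraction of incorrect matches among them (0 when none are accepted).
    """

    q_grid: np.ndarray
    counts: np.ndarray
    fdp: np.ndarray
    with_cv: bool
    dataset_seeds: list[int] = field(default_factory=list)

    @property
    def median_counts(self) -> np.ndarray:
        return np.median(self.counts, axis=0)

    @property
    def median_fdp(self) -> np.ndarray:
        return np.median(self.fdp, axis=0)

    def quantiles(self, q: float) -> tuple[np.ndarray, np.ndarray]:
        return np.quantile(self.counts, q, axis=0), np.quantile(self.fdp, q, axis=0)

    def to_frame(self) -> pd.DataFrame:
        c05, f05 = self.quantiles(0.05)
        c95, f95 = self.quantiles(0.95)
        return pd.DataFrame(
            {
                "q": self.q_grid,
                "median_count": self.median_counts,
                "count_q05": c05,
                "count_q95": c95,
                "median_fdp": self.median_fdp,
                "fdp_q05": f05,
                "fdp_q95": f95,
            }
        )


def _curves(
    qvalues: np.ndarray, is_correct_targets: np.ndarray, q_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Significant-target count and true FDP at every grid threshold."""
    counts = np.empty(q_grid.size)
    fdp = np.empty(q_grid.size)
    for i, q in enumerate(q_grid):
        accepted = qvalues <= q
        n = int(accepted.sum())
        counts[i] = n
        fdp[i] = 0.0 if n == 0 else float((~is_correct_targets[accepted]).mean())
    return counts, fdp


def run_experiment(
    cfg: SimulationConfig,
    with_cv: bool = True,
    q_grid: np.ndarray | None = None,
    learner_cfg: LearnerConfig | None = None,
    pi0_mode: str = "fixed-lambda",
) -> SimulationResult:
    """Replay the rescoring study over ``cfg.n_datasets`` replicates.

    With cross-validation, every dataset goes through the full validated
    pipeline.  Without it, hyperparameter choice, self-training and
    scoring all happen on the same PSMs — the unvalidated condition whose
    q-values are expected to be anti-conservative.
    """
    q_grid = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    base_cfg = learner_cfg or LearnerConfig()

    counts = np.empty((cfg.n_datasets, q_grid.size))
    fdp = np.empty((cfg.n_datasets, q_grid.size))
    seeds = []
    for d in range(cfg.n_datasets):
        seed_d = cfg.seed + d + 1
        seeds.append(seed_d)
        data, is_correct = generate_dataset(cfg, seed=seed_d)
        cfg_d = replace(base_cfg, seed=seed_d)
        if with_cv:
            result = rescore_dataset(data, cfg_d, pi0_mode=pi0_mode)
        else:
            result = rescore_no_cv(data, cfg_d, pi0_mode=pi0_mode)
        table = result.table.set_index("psm_id")
        target_ids = data.psm_ids[~data.is_decoy]
        qvals = table.loc[target_ids, "qvalue"].to_numpy()
        correct_targets = is_correct[~data.is_decoy]
        counts[d], fdp[d] = _curves(qvals, correct_targets, q_grid)
        logger.info(
            "dataset %d (%s): %d significant at q<=0.01",
            seed_d,
            "cv" if with_cv else "no-cv",
            int(counts[d][np.searchsorted(q_grid, 0.01)]),
        )
    return SimulationResult(
        q_grid=q_grid, counts=counts, fdp=fdp, with_cv=with_cv, dataset_seeds=seeds
    )
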