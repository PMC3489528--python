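"""Shared fixtures: synthetic datasets at two scales and a toy PSM table."""

import numpy as np
import pytest

from psmrescore import (
    LearnerConfig,
    Hyperparams,
    SimulationConfig,
    generate_dataset,
)

# Study-scale configuration: 2500 targets + 2500 decoys, 50 N(0,1) features,
# offset 10.0 on feature 1 for 1000 targets.
STUDY_CONFIG = SimulationConfig()


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale dataset (seed 1) and its ground-truth mask."""
    return generate_dataset(STUDY_CONFIG, seed=1)


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled generator config for fast learner unit tests."""
    return SimulationConfig(
        n_target=300, n_decoy=300, n_features=10, n_correct=120, n_datasets=2
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config, seed=7)


@pytest.fixture()
def fast_learner_cfg():
    """Reduced iteration count and grid so unit tests stay quick."""
    return LearnerConfig(
        n_iter=3,
        grid=[Hyperparams(1.0, 1.0), Hyperparams(1.0, 3.0)],
        seed=11,
    )


@pytest.fixture()
def toy_pin(tmp_path):
    """A hand-written four-row PSM table: 2 targets, 2 decoys, 3 features."""
    path = tmp_path / "toy.pin"
    path.write_text(
        "SpecId\tLabel\tScanNr\tscore\tdeltaScore\tcharge2\tPeptide\tProteins\n"
        "t1\t1\ts1\t5.0\t1.2\t1\tPEPTIDEA\tprotA\n"
        "t2\t1\ts2\t4.0\t0.8\t0\tPEPTIDEB\tprotB\n"
        "d1\t-1\ts1\t2.0\t0.1\t1\tAEDITPEP\tdecoyA\n"
        "d2\t-1\ts2\t1.5\t0.3\t0\tBEDITPEP\tdecoyB\n"
    )
    return path


def make_separable_pin(path, n_per_class=30, seed=5):
    """Write a synthetic, strongly separable PSM table with n targets + n decoys."""
    rng = np.random.default_rng(seed)
    lines = ["SpecId\tLabel\tScanNr\tf1\tf2\tf3\tPeptide\tProteins"]
    for i in range(n_per_class):
        informative = rng.normal(8.0 if i < n_per_class // 2 else 0.0, 1.0)
        lines.append(
            f"t{i}\t1\tspec_t{i}\t{informative:.4f}\t{rng.normal():.4f}"
            f"\t{rng.normal():.4f}\tPEP{i}\tprot{i}"
        )
    for i in range(n_per_class):
        lines.append(
            f"d{i}\t-1\tspec_d{i}\t{rng.normal():.4f}\t{rng.normal():.4f}"
            f"\t{rng.normal():.4f}\tDEC{i}\tdecoy{i}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
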