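"""Self-training SVM learner: initialization, selection, fitting, grid search."""

import numpy as np
import pytest
from scipy.optimize import minimize

from psmrescore import (
    Hyperparams,
    LearnerConfig,
    choose_initial_direction,
    compute_qvalues,
    generate_dataset,
    grid_search,
    select_positives,
    self_train,
    train_weighted_svm,
)
from psmrescore.psm_io import PSMDataset, PSMRecord
from psmrescore.simulation import SimulationConfig
from psmrescore.svm_learner import INTERCEPT_SCALING, _derive_seed
from psmrescore.crossval import assign_folds


def _dataset_from_matrix(X, is_decoy):
    records = [
        PSMRecord(psm_id=f"p{i}", spectrum_id=f"p{i}", is_decoy=bool(d), features=x)
        for i, (x, d) in enumerate(zip(X, is_decoy))
    ]
    return PSMDataset.from_records(
        records, feature_names=[f"f{j}" for j in range(X.shape[1])]
    )


def reference_qp_svm(X, y, sample_weight, intercept_scaling=INTERCEPT_SCALING):
    """Independent oracle: solve the primal soft-margin QP with SLSQP.

    Variables are (w, b, xi).  The intercept enters through an augmented
    constant feature of value ``intercept_scaling`` and is regularized with
    the weights, mirroring the fitted formulation.
    """
    n, p = X.shape

    def objective(z):
        w, b, xi = z[:p], z[p], z[p + 1 :]
        return 0.5 * (w @ w + b * b) + sample_weight @ xi

    def margin(z):
        w, b, xi = z[:p], z[p], z[p + 1 :]
        return y * (X @ w + b * intercept_scaling) - 1.0 + xi

    cons = [
        {"type": "ineq", "fun": margin},
        {"type": "ineq", "fun": lambda z: z[p + 1 :]},
    ]
    z0 = np.zeros(p + 1 + n)
    res = minimize(objective, z0, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-12})
    assert res.success, res.message
    return res.x[:p], res.x[p] * intercept_scaling


class TestChooseInitialDirection:
    def test_finds_offset_feature_positive_sign(self, small_dataset):
        data, _ = small_dataset
        assert choose_initial_direction(data, 0.01) == (0, 1)

    def test_negative_offset_flips_sign(self, small_config):
        cfg = SimulationConfig(
            n_target=small_config.n_target,
            n_decoy=small_config.n_decoy,
            n_features=small_config.n_features,
            n_correct=small_config.n_correct,
            offset=-10.0,
        )
        data, _ = generate_dataset(cfg, seed=7)
        assert choose_initial_direction(data, 0.01) == (0, -1)

    def test_pure_noise_is_deterministic(self):
        rng = np.random.default_rng(0)
        data = _dataset_from_matrix(rng.normal(size=(80, 5)), rng.random(80) < 0.5)
        first = choose_initial_direction(data, 0.01)
        assert first == choose_initial_direction(data, 0.01)
        assert 0 <= first[0] < 5 and first[1] in (1, -1)


class TestSelectPositives:
    def test_worked_example(self):
        """Targets 10 and 9 have q = 0; 8 and 7 have q = 0.25 > 0.01."""
        X = np.array([[10.0], [9.0], [8.0], [7.0], [8.5], [6.0]])
        data = _dataset_from_matrix(X, [False] * 4 + [True] * 2)
        mask = select_positives(X[:, 0], data, q_select=0.01, pi0=1.0)
        assert mask.tolist() == [True, True, False, False, False, False]

    def test_threshold_one_selects_all_targets_no_decoys(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        is_decoy = np.arange(40) % 2 == 0
        data = _dataset_from_matrix(X, is_decoy)
        # q_select must be < 1; 0.9999 accepts every target (q-values <= 1)
        mask = select_positives(X[:, 0], data, q_select=0.9999, pi0=0.5)
        # decoys are never selected whatever their score
        assert not mask[is_decoy].any()

    def test_top_scoring_decoy_still_excluded(self):
        X = np.array([[99.0], [5.0], [4.0]])
        data = _dataset_from_matrix(X, [True, False, False])
        mask = select_positives(X[:, 0], data, q_select=0.9, pi0=1.0)
        assert not mask[0]


class TestTrainWeightedSVM:
    def test_separable_one_dimensional(self):
        X = np.r_[np.full((10, 1), 10.0), np.zeros((10, 1))]
        pos = np.arange(20) < 10
        model = train_weighted_svm(X, pos, ~pos, Hyperparams(1.0, 1.0))
        assert model.weights[0] > 0
        preds = model.decision_function(X) > 0
        assert (preds == pos).all()

    @pytest.mark.parametrize("hp", [Hyperparams(1.0, 1.0), Hyperparams(0.5, 2.0)])
    def test_agrees_with_reference_qp(self, hp):
        """Decision values match an independent quadratic-program solution."""
        rng = np.random.default_rng(12)
        X = np.r_[rng.normal(2.0, 1.0, size=(8, 2)), rng.normal(-2.0, 1.0, size=(10, 2))]
        pos = np.arange(18) < 8
        model = train_weighted_svm(X, pos, ~pos, hp, seed=0)
        sw = np.where(pos, hp.c_pos, hp.c_neg)
        w_ref, b_ref = reference_qp_svm(X, np.where(pos, 1.0, -1.0), sw)
        dv = model.decision_function(X)
        dv_ref = X @ w_ref + b_ref
        scale = np.abs(dv_ref).max()
        np.testing.assert_allclose(dv, dv_ref, atol=1e-3 * scale)

    def test_negating_features_negates_weights(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        X[:15] += 3.0
        pos = np.arange(30) < 15
        hp = Hyperparams(1.0, 1.0)
        m1 = train_weighted_svm(X, pos, ~pos, hp)
        m2 = train_weighted_svm(-X, pos, ~pos, hp)
        np.testing.assert_allclose(m1.weights, -m2.weights, atol=1e-3)

    def test_empty_class_raises(self):
        X = np.ones((4, 1))
        none = np.zeros(4, dtype=bool)
        some = ~none
        with pytest.raises(ValueError):
            train_weighted_svm(X, none, some, Hyperparams(1, 1))
        with pytest.raises(ValueError, match="disjoint"):
            train_weighted_svm(X, some, some, Hyperparams(1, 1))


class TestSelfTrain:
    def test_zero_iterations_returns_initial_direction(self, small_dataset):
        data, _ = small_dataset
        cfg = LearnerConfig(n_iter=0, seed=3)
        model = self_train(data, cfg, Hyperparams(1, 1))
        expected = np.zeros(data.n_features)
        expected[0] = 1.0
        np.testing.assert_array_equal(model.weights, expected)
        assert model.intercept == 0.0

    def test_informative_feature_dominates(self, small_dataset, fast_learner_cfg):
        """Only feature 1 separates classes, so it should carry the score.

        Domination is measured in standardized coordinates (weight times
        feature spread), i.e. by each feature's contribution to the score.
        """
        data, _ = small_dataset
        model = self_train(data, fast_learner_cfg, Hyperparams(1.0, 1.0))
        contrib = np.abs(model.weights) * data.features.std(axis=0)
        assert contrib[0] / np.linalg.norm(contrib) > 0.9

    def test_learning_beats_best_single_feature(self, study_dataset):
        """On separable data the learned score never identifies fewer PSMs."""
        data, _ = study_dataset
        cfg = LearnerConfig(n_iter=5, seed=2)
        model = self_train(data, cfg, Hyperparams(1.0, 3.0))
        learned = model.decision_function(data.features)
        baseline = data.features[:, 0]
        t, d = ~data.is_decoy, data.is_decoy
        n_learned = (compute_qvalues(learned[t], learned[d]).qvalues <= 0.01).sum()
        n_base = (compute_qvalues(baseline[t], baseline[d]).qvalues <= 0.01).sum()
        assert n_learned >= n_base

    def test_deterministic_given_seed(self, small_dataset, fast_learner_cfg):
        data, _ = small_dataset
        m1 = self_train(data, fast_learner_cfg, Hyperparams(1, 1))
        m2 = self_train(data, fast_learner_cfg, Hyperparams(1, 1))
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert m1.intercept == m2.intercept

    def test_decoys_never_selected_as_positives(self, small_dataset):
        """At every iteration the positive mask excludes all decoys."""
        from psmrescore import svm_learner as sl

        data, _ = small_dataset
        seen_masks = []
        original = sl.select_positives

        def spy(scores, d, q, pi0=1.0):
            mask = original(scores, d, q, pi0)
            seen_masks.append(mask)
            return mask

        sl.select_positives, orig = spy, original
        try:
            self_train(data, LearnerConfig(n_iter=3, seed=1), Hyperparams(1, 1))
        finally:
            sl.select_positives = orig
        assert seen_masks
        for mask in seen_masks:
            assert not mask[data.is_decoy].any()

    def test_no_decoys_errors(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        data = _dataset_from_matrix(X, [False] * 10)
        with pytest.raises(ValueError):
            self_train(data, LearnerConfig(), Hyperparams(1, 1))


class TestGridSearch:
    def test_single_candidate_short_circuits(self, small_dataset):
        data, _ = small_dataset
        hp = Hyperparams(2.0, 2.0)
        cfg = LearnerConfig(grid=[hp], seed=1)
        assert grid_search(data, cfg) is hp

    def test_winner_attains_maximal_heldout_count(self, small_dataset):
        """Re-evaluate every candidate independently and compare totals."""
        data, _ = small_dataset
        grid = [Hyperparams(0.1, 0.1), Hyperparams(1.0, 3.0), Hyperparams(10.0, 10.0)]
        cfg = LearnerConfig(n_iter=2, grid=grid, seed=5)
        chosen = grid_search(data, cfg)

        # independent re-evaluation with the same nested split
        split = assign_folds(data, k=3, seed=_derive_seed(cfg.seed, 0x6E65))
        fold_of = split.fold_of(data)
        totals = {}
        for hp in grid:
            total = 0
            for fold in (1, 2, 3):
                train = data.subset(fold_of != fold)
                test = data.subset(fold_of == fold)
                model = self_train(train, cfg, hp)
                s = model.decision_function(test.features)
                q = compute_qvalues(s[~test.is_decoy], s[test.is_decoy]).qvalues
                total += int((q <= cfg.q_select).sum())
            totals[hp] = total
        assert totals[chosen] == max(totals.values())

    def test_tie_breaks_to_grid_order(self, small_dataset):
        """Identical candidates tie on counts; the first one must win."""
        data, _ = small_dataset
        hp_a, hp_b = Hyperparams(1.0, 1.0), Hyperparams(1.0, 1.0)
        cfg = LearnerConfig(n_iter=1, grid=[hp_a, hp_b], seed=2)
        assert grid_search(data, cfg) is hp_a
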