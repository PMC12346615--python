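"""Attention scoring, pooling, loss, class weights, and training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import attnmil as am
from attnmil.errors import TrainingError, ValidationError
from attnmil.model import MilModelParams, full_objective, full_objective_grad


def scalar_attention_oracle(raw_scores):
    """Softmax computed with plain math on scalars, independent of the
    vectorized implementation."""
    exps = [math.exp(s - max(raw_scores)) for s in raw_scores]
    total = sum(exps)
    return [e / total for e in exps]


TINY = MilModelParams(V=np.array([[1.0, 0.0]]), w=np.array([1.0]), u=np.array([1.0, 1.0]), b=0.0)
TINY_FEATURES = np.array([[0.0, 0.0], [10.0, 0.0]])


class TestAttentionScores:
    def test_singleton_bag(self):
        alpha = am.attention_scores(np.array([[1.0, 2.0]]), TINY)
        np.testing.assert_allclose(alpha, [1.0])

    def test_identical_patches_share_weight(self):
        feats = np.tile([0.5, -0.3], (3, 1))
        np.testing.assert_allclose(am.attention_scores(feats, TINY), [1 / 3] * 3, atol=1e-12)

    def test_hand_oracle_tanh_instance(self):
        """d=2, L=1, V=[[1,0]], w=[1]: raw scores (tanh 0, tanh 10)."""
        alpha = am.attention_scores(TINY_FEATURES, TINY)
        expected = scalar_attention_oracle([math.tanh(0.0), math.tanh(10.0)])
        np.testing.assert_allclose(alpha, expected, atol=1e-9)
        np.testing.assert_allclose(alpha, [0.269, 0.731], atol=1e-3)

    def test_simplex_over_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            params = am.init_params(4, 3, rng)
            feats = rng.normal(size=(rng.integers(1, 8), 4))
            alpha = am.attention_scores(feats, params)
            assert np.all(alpha > 0)
            assert abs(alpha.sum() - 1.0) < 1e-9

    def test_nonfinite_features_rejected(self):
        feats = np.array([[np.nan, 0.0]])
        with pytest.raises(ValidationError, match="finite"):
            am.attention_scores(feats, TINY)


class TestAttentionPool:
    def test_one_hot_selects_patch(self, rng):
        feats = rng.normal(size=(5, 4))
        alpha = np.zeros(5)
        alpha[3] = 1.0
        np.testing.assert_array_equal(am.attention_pool(feats, alpha), feats[3])

    def test_identical_patches_fixed_point(self):
        feats = np.tile([2.0, -1.0, 0.5], (4, 1))
        z = am.attention_pool(feats, np.array([0.1, 0.2, 0.3, 0.4]))
        np.testing.assert_allclose(z, [2.0, -1.0, 0.5])

    def test_weighted_sum_example(self):
        z = am.attention_pool(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0.25, 0.75]))
        np.testing.assert_allclose(z, [0.25, 0.75])

    def test_joint_permutation_invariance(self, rng):
        feats = rng.normal(size=(7, 3))
        alpha = rng.dirichlet(np.ones(7))
        perm = rng.permutation(7)
        np.testing.assert_allclose(
            am.attention_pool(feats, alpha), am.attention_pool(feats[perm], alpha[perm]), atol=1e-12
        )

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            am.attention_pool(rng.normal(size=(4, 2)), np.array([0.5, 0.5]))


class TestPredictBag:
    def test_zero_head_gives_half(self, tiny_cohort):
        bag = tiny_cohort.bags[0]
        params = am.init_params(bag.dim, 4, np.random.default_rng(0))
        params.u[:] = 0.0
        params.b = 0.0
        assert am.predict_bag(bag, params) == 0.5

    def test_patch_order_invariance(self, tiny_cohort, rng):
        bag = tiny_cohort.bags[1]
        params = am.init_params(bag.dim, 8, np.random.default_rng(3))
        perm = rng.permutation(bag.n_patches)
        shuffled = am.FeatureBag(bag.patient_id, bag.slide_id, bag.features[perm],
                                 bag.coords[perm], bag.label)
        assert abs(am.predict_bag(bag, params) - am.predict_bag(shuffled, params)) <= 1e-12

    def test_composed_scalar_oracle(self):
        """p = sigmoid(z1 + z2) with z from the tiny attention instance."""
        alpha = scalar_attention_oracle([math.tanh(0.0), math.tanh(10.0)])
        z = [alpha[0] * 0.0 + alpha[1] * 10.0, 0.0]
        expected = 1.0 / (1.0 + math.exp(-(z[0] + z[1])))
        bag = am.FeatureBag("p", "s", TINY_FEATURES, np.array([[0, 0], [0, 1]]))
        assert abs(am.predict_bag(bag, TINY) - expected) < 1e-9


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        cw = am.class_weights(40, 40)
        assert cw.w_pcr == 1.0 and cw.w_nonpcr == 1.0

    def test_published_cohort_counts(self):
        cw = am.class_weights(81, 93)
        assert math.isclose(cw.w_pcr, 174 / 162)
        assert math.isclose(cw.w_nonpcr, 174 / 186)
        assert math.isclose(cw.w_pcr * 81, 87, rel_tol=1e-12)
        assert math.isclose(cw.w_nonpcr * 93, 87, rel_tol=1e-12)

    def test_small_example(self):
        cw = am.class_weights(10, 30)
        assert cw.w_pcr == 2.0
        assert math.isclose(cw.w_nonpcr, 2 / 3)

    @pytest.mark.parametrize("n_pcr,n_nonpcr", [(0, 5), (5, 0)])
    def test_degenerate_cohort_rejected(self, n_pcr, n_nonpcr):
        with pytest.raises(ValidationError):
            am.class_weights(n_pcr, n_nonpcr)

    @settings(derandomize=True, max_examples=300)
    @given(st.integers(1, 500), st.integers(1, 500))
    def test_balance_identity(self, n_pcr, n_nonpcr):
        """w_pcr * n_pcr = w_nonpcr * n_nonpcr = N/2 (up to float rounding)."""
        cw = am.class_weights(n_pcr, n_nonpcr)
        half = (n_pcr + n_nonpcr) / 2
        assert math.isclose(cw.w_pcr * n_pcr, half, rel_tol=1e-12)
        assert math.isclose(cw.w_nonpcr * n_nonpcr, half, rel_tol=1e-12)


class TestWeightedBce:
    CW_UNIT = am.ClassWeights(w_pcr=1.0, w_nonpcr=1.0, n_pcr=1, n_nonpcr=1)

    def test_perfect_prediction_near_zero(self):
        assert am.weighted_bce([1], [1 - 1e-7], self.CW_UNIT) <= 1e-6

    def test_uninformative_prediction_is_ln2(self):
        assert math.isclose(am.weighted_bce([1], [0.5], self.CW_UNIT), math.log(2), rel_tol=1e-12)

    def test_weighted_two_sample_closed_form(self):
        cw = am.ClassWeights(w_pcr=2.0, w_nonpcr=0.5, n_pcr=1, n_nonpcr=4)
        loss = am.weighted_bce([1, 0], [0.5, 0.5], cw)
        assert math.isclose(loss, 0.5 * 2.5 * math.log(2), rel_tol=1e-12)
        assert abs(loss - 0.8664) < 1e-4

    def test_label_domain_enforced(self):
        with pytest.raises(ValidationError):
            am.weighted_bce([2], [0.5], self.CW_UNIT)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValidationError):
            am.weighted_bce([], [], self.CW_UNIT)


def test_gradient_matches_finite_differences():
    """Analytic gradient of the full objective (weighted BCE + L2) vs
    central differences on a d=4, L=2, N=3 instance."""
    rng = np.random.default_rng(0)
    d, L = 4, 2
    params = am.init_params(d, L, rng)
    bags = [rng.normal(size=(3, d)), rng.normal(size=(3, d))]
    labels = [1, 0]
    cw = am.class_weights(1, 1)
    wd = 0.001
    grad = full_objective_grad(params, bags, labels, cw, wd)
    vec = params.to_vector()
    h = 1e-6
    fd = np.empty_like(vec)
    for i in range(len(vec)):
        up, down = vec.copy(), vec.copy()
        up[i] += h
        down[i] -= h
        fd[i] = (
            full_objective(MilModelParams.from_vector(up, L, d), bags, labels, cw, wd)
            - full_objective(MilModelParams.from_vector(down, L, d), bags, labels, cw, wd)
        ) / (2 * h)
    rel = np.abs(grad - fd) / np.maximum(1e-8, np.abs(grad) + np.abs(fd))
    assert rel.max() <= 1e-4


class TestTrainModel:
    @staticmethod
    def _splits(cohort, n_val=4):
        bags = cohort.bags
        pos = [b for b in bags if b.label == 1]
        neg = [b for b in bags if b.label == 0]
        val = pos[: n_val // 2] + neg[: n_val // 2]
        train = pos[n_val // 2:] + neg[n_val // 2:]
        return train, val

    def test_frozen_learning_stops_at_patience(self, tiny_cohort):
        train, val = self._splits(tiny_cohort)
        cfg = am.TrainConfig(learning_rate=0.0, max_epochs=200, patience=5, L=4, seed=0)
        result = am.train_model(train, val, cfg)
        assert result.epochs_run == 6  # 1 improving epoch + 5 stale ones
        assert result.epochs_run < cfg.max_epochs
        assert result.best_val_loss == min(result.loss_history["val"])

    def test_seeded_determinism(self, tiny_cohort):
        train, val = self._splits(tiny_cohort)
        cfg = am.TrainConfig(max_epochs=12, patience=12, L=8, seed=11)
        a = am.train_model(train, val, cfg)
        b = am.train_model(train, val, cfg)
        assert a.loss_history == b.loss_history
        np.testing.assert_array_equal(a.params.V, b.params.V)

    def test_single_class_training_split_rejected(self, tiny_cohort):
        pos = [b for b in tiny_cohort.bags if b.label == 1]
        neg = [b for b in tiny_cohort.bags if b.label == 0]
        with pytest.raises(ValidationError):
            am.train_model(pos, neg, am.TrainConfig(max_epochs=2, patience=1, L=4))

    def test_divergence_raises_training_error(self, tiny_cohort):
        train, val = self._splits(tiny_cohort)
        cfg = am.TrainConfig(learning_rate=1e12, max_epochs=50, patience=50, L=4, seed=0)
        with np.errstate(all="ignore"), pytest.raises((TrainingError, FloatingPointError)):
            am.train_model(train, val, cfg)


def test_localization_recovery(sparse_model, sparse_eval_cohort):
    """Trained attention concentrates on witness patches: mean attention
    mass on witnesses of held-out positive bags >= 5x the witness rate."""
    rate = sparse_eval_cohort.spec.witness_rate
    masses = []
    for bag in sparse_eval_cohort.bags:
        if bag.label != 1:
            continue
        alpha = am.attention_scores(bag.features, sparse_model)
        masses.append(alpha[sparse_eval_cohort.witness_flags[bag.patient_id]].sum())
    assert len(masses) >= 10
    assert np.mean(masses) >= 5 * rate


def test_checkpoint_roundtrip(tiny_cohort, tmp_path):
    train, val = TestTrainModel._splits(tiny_cohort)
    cfg = am.TrainConfig(max_epochs=5, patience=5, L=4, seed=2)
    result = am.train_model(train, val, cfg)
    path = am.save_checkpoint(result, cfg, tmp_path / "model.zip")
    loaded = am.load_checkpoint(path)
    np.testing.assert_array_equal(loaded.V, result.params.V)
    np.testing.assert_array_equal(loaded.w, result.params.w)
    np.testing.assert_array_equal(loaded.u, result.params.u)
    assert loaded.b == result.params.b
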