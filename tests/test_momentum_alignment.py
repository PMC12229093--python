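"""EMA, similarity softmax, pseudo-targets and the contrastive objective."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotfusion.encoders import GeneEncoderConfig, ImageEncoderConfig, l2_normalize
from spotfusion.fusion_igm import FusionConfig
from spotfusion.momentum_alignment import (
    AlignConfig,
    AlignmentModel,
    MomentumState,
    alignment_training_step,
    build_pseudo_targets,
    contrastive_loss,
    ema_update,
    similarity_softmax,
    train_alignment,
)
from spotfusion.nn import AdamW, Tensor


def scalar_state(theta_val, theta_m_val, beta):
    return MomentumState(
        theta={"w": Tensor(np.array([theta_val]), requires_grad=True)},
        theta_m={"w": Tensor(np.array([theta_m_val]))},
        beta=beta,
    )


class TestEMA:
    def test_beta_one_is_fixed_point(self):
        s = scalar_state(0.0, 1.0, beta=1.0)
        ema_update(s)
        assert s.theta_m["w"].data[0] == 1.0

    def test_beta_zero_copies_primary(self):
        s = scalar_state(0.3, 1.0, beta=0.0)
        ema_update(s)
        assert s.theta_m["w"].data[0] == 0.3

    def test_geometric_decay_with_frozen_primary(self):
        s = scalar_state(0.0, 1.0, beta=0.995)
        for t in range(1, 51):
            ema_update(s)
            assert np.isclose(s.theta_m["w"].data[0], 0.995 ** t, rtol=1e-12)

    def test_structural_mismatch_names_parameter(self):
        s = scalar_state(0.0, 1.0, beta=0.5)
        s.theta_m["extra"] = Tensor(np.zeros(1))
        with pytest.raises(ValueError, match="extra"):
            ema_update(s)


class TestSimilaritySoftmax:
    def test_identical_keys_give_uniform_rows(self, rng):
        Q = rng.standard_normal((4, 8))
        K = np.tile(rng.standard_normal(8), (5, 1))
        p = similarity_softmax(Q, K, tau=0.07)
        assert np.allclose(p, 1.0 / 5)

    def test_two_candidate_scalar_oracle(self):
        # cosines exactly (1, 0) against the query
        Q = np.array([[1.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        p = similarity_softmax(Q, K, tau=0.07)
        z = np.exp([1 / 0.07, 0.0])
        assert np.allclose(p[0], z / z.sum())

    def test_large_tau_limit_is_uniform(self, rng):
        Q, K = rng.standard_normal((3, 6)), rng.standard_normal((3, 6))
        p = similarity_softmax(Q, K, tau=1e9)
        assert np.allclose(p, 1.0 / 3, atol=1e-6)

    def test_nonpositive_tau_rejected(self, rng):
        with pytest.raises(ValueError):
            similarity_softmax(rng.standard_normal((2, 2)), rng.standard_normal((2, 2)), 0.0)


class TestPseudoTargets:
    def test_alpha_zero_is_identity(self, rng):
        p = _random_stochastic(rng, 5)
        assert np.array_equal(build_pseudo_targets(p, 0.0), np.eye(5))

    def test_alpha_one_is_momentum_distribution(self, rng):
        p = _random_stochastic(rng, 5)
        assert np.allclose(build_pseudo_targets(p, 1.0), p)

    def test_hand_arithmetic_uniform_s4(self):
        p = np.full((4, 4), 0.25)
        y = build_pseudo_targets(p, 0.4)
        assert np.allclose(np.diag(y), 0.7)
        off = y[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.1)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 1.0))
    def test_rows_always_sum_to_one(self, seed, alpha):
        p = _random_stochastic(np.random.default_rng(seed), 6)
        y = build_pseudo_targets(p, alpha)
        assert np.allclose(y.sum(axis=1), 1.0, atol=1e-9)

    def test_alpha_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            build_pseudo_targets(_random_stochastic(rng, 3), 1.5)


def _random_stochastic(rng, s):
    p = rng.random((s, s)) + 1e-3
    return p / p.sum(axis=1, keepdims=True)


class TestContrastiveLoss:
    def test_perfect_one_hot_prediction_near_zero(self):
        eye = np.eye(4)
        assert contrastive_loss(eye, eye, eye, eye) < 1e-9

    def test_uniform_prediction_one_hot_target_is_log_s(self):
        s = 4
        p = np.full((s, s), 1.0 / s)
        y = np.eye(s)
        assert np.isclose(contrastive_loss(p, p, y, y), np.log(s))

    def test_matches_two_loop_oracle(self, rng):
        s = 5
        p1, p2 = _random_stochastic(rng, s), _random_stochastic(rng, s)
        y1, y2 = _random_stochastic(rng, s), _random_stochastic(rng, s)

        def ce_loop(y, p):
            total = 0.0
            for i in range(s):
                for k in range(s):
                    total -= y[i, k] * np.log(max(p[i, k], 1e-12))
            return total / s

        oracle = 0.5 * (ce_loop(y1, p1) + ce_loop(y2, p2))
        assert abs(contrastive_loss(p1, p2, y1, y2) - oracle) < 1e-6

    def test_zero_probability_clamped_not_nan(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = contrastive_loss(p, p, y, y)
        assert np.isfinite(out) and out > 0


@pytest.fixture(scope="module")
def tiny_model():
    return AlignmentModel(
        ImageEncoderConfig.tiny(),
        GeneEncoderConfig.tiny(n_genes=32),
        FusionConfig(dim=64),
        seed=3,
    )


class TestTrainingStep:
    def _batch(self, rng, s=6):
        return (rng.integers(0, 255, (s, 32, 32, 3), dtype=np.uint8),
                rng.random((s, 32)) * 8)

    def test_zero_lr_keeps_primary_but_updates_momentum(self, tiny_model, rng):
        imgs, x = self._batch(rng)
        cfg = AlignConfig(lr=0.0, beta=0.5)
        tiny_model.beta = 0.5
        # desynchronize the momentum copy so the EMA visibly moves it
        probe = next(iter(tiny_model.image_encoder_m.parameters()))
        probe.data = probe.data + 1.0
        before_primary = {k: v.copy() for k, v in tiny_model.image_encoder.state_dict().items()}
        before_probe = probe.data.copy()
        opt = AdamW(tiny_model.parameters(), lr=0.0, weight_decay=0.0)
        alignment_training_step(imgs, x, tiny_model, opt, cfg)
        after_primary = tiny_model.image_encoder.state_dict()
        assert all(np.array_equal(before_primary[k], after_primary[k]) for k in after_primary)
        assert not np.array_equal(probe.data, before_probe)

    def test_batch_of_one_rejected(self, tiny_model, rng):
        imgs, x = self._batch(rng, s=1)
        opt = AdamW(tiny_model.parameters(), lr=1e-3)
        with pytest.raises(ValueError, match="at least 2"):
            alignment_training_step(imgs, x, tiny_model, opt, AlignConfig())

    def test_identical_seeds_identical_trajectories(self, rng):
        imgs, x = self._batch(rng, s=8)

        def run():
            model = AlignmentModel(ImageEncoderConfig.tiny(),
                                   GeneEncoderConfig.tiny(n_genes=32),
                                   FusionConfig(dim=64), seed=9)
            return train_alignment(imgs, x, model, AlignConfig(steps=4, batch_size=4,
                                                               lr=1e-3, seed=2))
        h1, h2 = run(), run()
        assert [r["loss"] for r in h1] == [r["loss"] for r in h2]

    def test_loss_decreases_on_fixed_tiny_batch(self, rng):
        imgs, x = self._batch(rng, s=8)
        model = AlignmentModel(ImageEncoderConfig.tiny(),
                               GeneEncoderConfig.tiny(n_genes=32),
                               FusionConfig(dim=64), seed=4)
        history = train_alignment(imgs, x, model, AlignConfig(steps=50, batch_size=8,
                                                              lr=1e-3, seed=0))
        first = np.mean([r["loss"] for r in history[:5]])
        last = np.mean([r["loss"] for r in history[-5:]])
        assert last < first
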