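import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmask.model import (
    ArchitectureSpec,
    LossConfig,
    ModelState,
    decode,
    encode,
    init_state,
    load_checkpoint,
    loss_and_grads,
    mask_loss,
    predict_mask,
    reconstruction_loss,
    save_checkpoint,
    total_loss,
)


def _random_state(rng, input_dim=4, hidden=(5,), latent=3):
    arch = ArchitectureSpec(input_dim=input_dim, hidden_dims=list(hidden), latent_dim=latent)
    return init_state(arch, rng)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestEncode:
    def test_identity_weights_relu_on_nonnegative_input(self, rng):
        arch = ArchitectureSpec(input_dim=3, hidden_dims=[3], latent_dim=2)
        state = init_state(arch, rng)
        state.enc_W[0] = np.eye(3)
        state.enc_b[0] = np.zeros(3)
        x = np.abs(rng.normal(size=(5, 3)))
        expected = x @ state.enc_W[1] + state.enc_b[1]
        np.testing.assert_allclose(encode(state, x), expected)

    def test_zero_weights_give_bias_rows(self, rng):
        state = _random_state(rng)
        for w in state.enc_W:
            w[:] = 0.0
        state.enc_b[-1] = np.array([1.0, -2.0, 3.0])
        out = encode(state, rng.normal(size=(4, 4)))
        np.testing.assert_allclose(out, np.tile([1.0, -2.0, 3.0], (4, 1)))

    def test_matches_hand_rolled_forward_chain(self, rng):
        state = _random_state(rng, input_dim=4, hidden=(6, 5), latent=3)
        x = rng.normal(size=(3, 4))
        h = np.maximum(x @ state.enc_W[0] + state.enc_b[0], 0)
        h = np.maximum(h @ state.enc_W[1] + state.enc_b[1], 0)
        expected = h @ state.enc_W[2] + state.enc_b[2]
        np.testing.assert_allclose(encode(state, x), expected)


class TestPredictMask:
    def test_zero_parameters_give_half(self, rng):
        state = _random_state(rng)
        state.mask_W[:] = 0.0
        out = predict_mask(state, rng.normal(size=(6, 3)))
        np.testing.assert_allclose(out, 0.5)

    def test_large_bias_saturates(self, rng):
        state = _random_state(rng)
        state.mask_W[:] = 0.0
        state.mask_b[0] = 50.0
        out = predict_mask(state, rng.normal(size=(6, 3)))
        np.testing.assert_allclose(out[:, 0], 1.0, atol=1e-12)

    def test_matches_hand_computed_affine_sigmoid(self, rng):
        state = _random_state(rng)
        e = rng.normal(size=(2, 3))
        np.testing.assert_allclose(
            predict_mask(state, e), _sigmoid(e @ state.mask_W + state.mask_b)
        )


class TestDecode:
    def test_zero_weights_give_bias(self, rng):
        state = _random_state(rng)
        state.dec_W[:] = 0.0
        state.dec_b[:] = np.arange(4.0)
        out = decode(state, rng.normal(size=(3, 3)), rng.random((3, 4)))
        np.testing.assert_allclose(out, np.tile(np.arange(4.0), (3, 1)))

    def test_matches_hand_computed_affine_of_concat(self, rng):
        state = _random_state(rng)
        e = rng.normal(size=(3, 3))
        m = rng.random((3, 4))
        expected = np.hstack([e, m]) @ state.dec_W + state.dec_b
        np.testing.assert_allclose(decode(state, e, m), expected)

    def test_shape_mismatch_rejected(self, rng):
        state = _random_state(rng)
        with pytest.raises(ValueError):
            decode(state, rng.normal(size=(3, 2)), rng.random((3, 4)))


class TestMaskLoss:
    def test_half_prediction_gives_log_two(self, rng):
        m = (rng.random((4, 5)) < 0.4).astype(float)
        assert mask_loss(m, np.full((4, 5), 0.5)) == pytest.approx(np.log(2))

    def test_perfect_prediction_near_zero(self):
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert mask_loss(m, m, eps=1e-7) <= -np.log(1 - 1e-7) + 1e-12

    def test_hand_evaluated_bce(self):
        m = np.array([[1.0, 0.0]])
        m_pred = np.array([[0.8, 0.4]])
        expected = -(np.log(0.8) + np.log(0.6)) / 2
        assert mask_loss(m, m_pred) == pytest.approx(expected)
        assert expected == pytest.approx(0.3670, abs=5e-5)

    def test_positive_term_only_variant(self):
        m = np.array([[1.0, 0.0]])
        m_pred = np.array([[0.8, 0.4]])
        assert mask_loss(m, m_pred, positive_term_only=True) == pytest.approx(
            -np.log(0.8) / 2
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mask_loss(np.zeros((2, 2)), np.full((2, 3), 0.5))


class TestReconstructionLoss:
    def test_zero_residual_is_zero_in_all_modes(self, rng):
        x = rng.normal(size=(3, 4))
        m = (rng.random((3, 4)) < 0.5).astype(float)
        for abl in ("full", "unmasked_only", "masked_only"):
            cfg = LossConfig(ablation=abl, lambda_mask_weight=rng.random())
            assert reconstruction_loss(x, x, m, cfg) == 0.0

    def test_lambda_half_collapses_to_half_mse(self, rng):
        x = rng.normal(size=(6, 5))
        x_hat = rng.normal(size=(6, 5))
        m = (rng.random((6, 5)) < 0.3).astype(float)
        cfg = LossConfig(lambda_mask_weight=0.5)
        assert reconstruction_loss(x, x_hat, m, cfg) == pytest.approx(
            0.5 * np.mean((x - x_hat) ** 2)
        )

    def test_hand_evaluated_weighted_mse(self):
        x = np.array([[1.0, 2.0]])
        x_hat = np.array([[0.0, 0.0]])
        m = np.array([[1.0, 0.0]])
        cfg = LossConfig(lambda_mask_weight=0.75)
        assert reconstruction_loss(x, x_hat, m, cfg) == pytest.approx(0.875)

    def test_ablation_weightings(self):
        x = np.array([[1.0, 2.0]])
        x_hat = np.array([[0.0, 0.0]])
        m = np.array([[1.0, 0.0]])
        u = reconstruction_loss(x, x_hat, m, LossConfig(ablation="unmasked_only"))
        mm = reconstruction_loss(x, x_hat, m, LossConfig(ablation="masked_only"))
        assert u == pytest.approx(4.0 / 2)  # only the unmasked entry
        assert mm == pytest.approx(1.0 / 2)  # only the masked entry

    def test_monotone_in_single_residual(self, rng):
        x = rng.normal(size=(4, 4))
        x_hat = x.copy()
        m = (rng.random((4, 4)) < 0.5).astype(float)
        cfg = LossConfig(lambda_mask_weight=0.75)
        prev = reconstruction_loss(x, x_hat, m, cfg)
        for bump in (0.5, 1.0, 2.0):
            x_hat2 = x.copy()
            x_hat2[2, 2] += bump
            cur = reconstruction_loss(x, x_hat2, m, cfg)
            assert cur >= prev
            prev = cur


class TestTotalLoss:
    @pytest.mark.parametrize("gamma,expected", [(0.0, 0.2), (1.0, 0.6), (0.5, 0.4)])
    def test_convex_combination_values(self, gamma, expected):
        cfg = LossConfig(gamma_balance=gamma)
        assert total_loss(0.2, 0.6, cfg) == pytest.approx(expected)

    def test_no_mask_loss_mode_returns_reconstruction_only(self):
        cfg = LossConfig(gamma_balance=0.9, ablation="no_mask_loss")
        assert total_loss(0.2, 0.6, cfg) == 0.2

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.floats(0, 5), st.floats(0, 5), st.floats(0, 1),
    )
    def test_bounded_by_component_losses(self, lr, lm, gamma):
        cfg = LossConfig(gamma_balance=gamma)
        t = total_loss(lr, lm, cfg)
        assert min(lr, lm) - 1e-12 <= t <= max(lr, lm) + 1e-12


class TestGradients:
    @pytest.mark.parametrize("ablation", ["full", "unmasked_only", "masked_only", "no_mask_loss"])
    def test_analytic_matches_central_differences(self, ablation):
        """Backprop gradients agree with finite differences on a 4x6 instance."""
        # seed chosen so no ReLU pre-activation sits near its kink,
        # where central differences are invalid
        rng = np.random.default_rng(2)
        arch = ArchitectureSpec(input_dim=6, hidden_dims=[5, 4], latent_dim=3)
        state = init_state(arch, rng)
        x = rng.normal(size=(4, 6))
        xm = rng.normal(size=(4, 6))
        m = (rng.random((4, 6)) < 0.3).astype(float)
        cfg = LossConfig(ablation=ablation)

        def forward_total():
            e = encode(state, xm)
            mp = predict_mask(state, e)
            lr = reconstruction_loss(x, decode(state, e, mp), m, cfg)
            lm = mask_loss(m, mp, eps=cfg.eps)
            return total_loss(lr, lm, cfg)

        _, _, _, grads = loss_and_grads(state, x, xm, m, cfg)
        h = 1e-6
        for name, p in state.params().items():
            if ablation == "no_mask_loss" and name.startswith("mask_"):
                np.testing.assert_array_equal(grads[name], 0.0)
                continue
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = p[i]
                p[i] = orig + h
                up = forward_total()
                p[i] = orig - h
                down = forward_total()
                p[i] = orig
                numeric = (up - down) / (2 * h)
                denom = max(abs(numeric), abs(grads[name][i]), 1e-8)
                assert abs(numeric - grads[name][i]) / denom < 1e-4, (name, i)


class TestCheckpoint:
    def test_round_trip_preserves_everything(self, tmp_path, rng):
        arch = ArchitectureSpec(input_dim=8, hidden_dims=[6], latent_dim=4)
        state = init_state(arch, rng)
        cfg = LossConfig(lambda_mask_weight=0.6, gamma_balance=0.3, ablation="masked_only")
        save_checkpoint(state, tmp_path / "ck.npz", loss_cfg=cfg)
        back, cfg2 = load_checkpoint(tmp_path / "ck.npz")
        assert cfg2 == cfg
        assert back.arch == arch
        x = rng.normal(size=(5, 8))
        np.testing.assert_array_equal(encode(back, x), encode(state, x))
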