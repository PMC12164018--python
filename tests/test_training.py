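"""Loss terms, alternating updates, and the fit loop at toy scale."""

import numpy as np
import pytest

from rcstpat.autodiff import Tensor
from rcstpat.network import ModelConfig
from rcstpat.simulator import PairedSample, ReconImage
from rcstpat.training import (
    Critic,
    TrainConfig,
    TrainState,
    critic_forward,
    critic_step,
    fit,
    fourier_residual_penalty,
    generator_step,
    paired_loss,
    transport_cost,
)

TINY_MODEL = dict(n_levels=2, stb_per_level=(1, 1), heads_per_level=(1, 2))


def tiny_pairs(n=4, size=16, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        x = rng.random((size, size))
        y = np.clip(x + rng.normal(0, 0.05, (size, size)), 0, 1)
        out.append(PairedSample(ReconImage(y, 32), x, 32))
    return out


def tiny_state(seed=0, **cfg_kw):
    mc = ModelConfig.toy(seed=seed, **TINY_MODEL)
    tc = TrainConfig(seed=seed, patch=16, **cfg_kw)
    return TrainState.initialize(mc, tc)


# -- loss terms ---------------------------------------------------------------


def test_fourier_penalty_identities():
    rng = np.random.default_rng(0)
    r = rng.normal(size=(8, 8))
    assert fourier_residual_penalty(np.zeros((8, 8))) == 0.0
    g1, g2 = fourier_residual_penalty(r), fourier_residual_penalty(2 * r)
    assert g2 == pytest.approx(2 * g1, rel=1e-12)
    delta = np.zeros((8, 8))
    delta[0, 0] = 1.0
    assert fourier_residual_penalty(delta, "sum") == pytest.approx(64.0)
    # mean form is sum / (H*W)
    assert fourier_residual_penalty(r, "mean") == pytest.approx(g1 / 64.0)


def test_transport_cost_mean_absolute():
    x = np.full((8, 8), 0.5)
    assert transport_cost(x, x).item() == 0.0
    assert transport_cost(x + 0.5, x).item() == pytest.approx(0.5)
    rng = np.random.default_rng(1)
    a, b = rng.random((8, 8)), rng.random((8, 8))
    assert transport_cost(a, b).item() == pytest.approx(np.abs(a - b).mean())
    with pytest.raises(ValueError):
        transport_cost(np.zeros((4, 4)), np.zeros((5, 5)))


def test_paired_loss_hand_computed_and_scaling():
    x_hat = np.array([[1.0, 2.0], [3.0, 4.0]])
    x = np.array([[0.0, 2.0], [1.0, 4.0]])
    # squared l2: 1 + 0 + 4 + 0 = 5
    assert paired_loss(x_hat, x, gamma=1.0).item() == pytest.approx(5.0)
    assert paired_loss(x_hat, x, gamma=2.0).item() == pytest.approx(10.0)
    assert paired_loss(x_hat, x, gamma=1.0, m=5).item() == pytest.approx(1.0)
    assert paired_loss(x, x, gamma=3.0).item() == 0.0
    with pytest.raises(ValueError):
        paired_loss(x, x, gamma=-1.0)


def test_penalty_in_training_shares_code_path_with_public_op():
    """The residual penalty inside the loss equals the standalone op."""
    rng = np.random.default_rng(2)
    r = rng.normal(size=(1, 8, 8))
    via_tensor = fourier_residual_penalty(Tensor(r), "mean").item()
    via_array = fourier_residual_penalty(r, "mean")
    assert via_tensor == via_array


# -- critic -------------------------------------------------------------------


def test_critic_zero_weights_scores_zero_and_deterministic():
    critic = Critic(seed=0)
    img = np.random.default_rng(3).random((16, 16))
    s1, s2 = critic_forward(critic, img), critic_forward(critic, img)
    assert s1 == s2 and np.isfinite(s1)
    for p in critic.parameters():
        p.data[:] = 0.0
    assert critic_forward(critic, img) == 0.0


def test_degenerate_fixed_point_when_y_equals_x():
    """With y = x and an identity generator, all paired/transport/penalty
    terms vanish (the zero-initialized head makes the untrained model the
    identity map)."""
    state = tiny_state()
    x = np.random.default_rng(4).random((16, 16))
    pair = PairedSample(ReconImage(x, 32), x, 32)
    x_hat, _ = state.model(pair.degraded.values)
    assert np.array_equal(x_hat.data[0], x)
    assert transport_cost(x_hat.data[0], x).item() == 0.0
    assert paired_loss(x_hat.data[0], x, gamma=100.0).item() == 0.0
    assert fourier_residual_penalty(x - x_hat.data[0]) == 0.0


def test_generator_step_moves_parameters_and_returns_finite_losses():
    state = tiny_state()
    pair = tiny_pairs(1)[0]
    before = state.model.state_vector()
    bundle = generator_step(pair, state)
    after = state.model.state_vector()
    assert (before != after).any()
    for term in (bundle.transport_cost, bundle.fourier_penalty, bundle.paired,
                 bundle.total_G):
        assert np.isfinite(term)
    assert bundle.paired >= 0.0 and bundle.fourier_penalty >= 0.0


def test_critic_step_moves_parameters_and_respects_clip_bound():
    state = tiny_state()
    pair = tiny_pairs(1)[0]
    before = state.critic.state_vector()
    critic_step(pair, state)
    after = state.critic.state_vector()
    assert (before != after).any()
    bound = state.train_cfg.clip_value
    assert np.abs(after).max() <= bound + 1e-15


def test_gradient_penalty_mode_runs():
    state = tiny_state(clip_or_gp="gp")
    bundle = critic_step(tiny_pairs(1)[0], state)
    assert np.isfinite(bundle.total_D)


def test_losses_stay_finite_over_many_steps():
    state = tiny_state()
    pairs = tiny_pairs(4)
    for i in range(20):
        b = generator_step(pairs[i % 4], state)
        d = critic_step(pairs[i % 4], state)
        assert np.isfinite(b.total_G) and np.isfinite(d.total_D)


# -- fit ----------------------------------------------------------------------


def test_fit_bookkeeping_two_epochs(tmp_path):
    pairs = tiny_pairs(4)
    mc = ModelConfig.toy(seed=0, **TINY_MODEL)
    tc = TrainConfig(seed=0, epochs=2, patch=16, checkpoint_every=1)
    state = fit(pairs[:3], pairs[3:], mc, tc, out_dir=tmp_path)
    assert len(state.metric_history) == 2
    assert state.epoch == 2
    assert state.global_step == 6
    assert (tmp_path / "epoch_0001.npz").exists()
    assert (tmp_path / "epoch_0002.npz").exists()
    assert (tmp_path / "train_log.jsonl").exists()
    for entry in state.metric_history:
        assert np.isfinite(entry["val_psnr"]) and np.isfinite(entry["val_ssim"])


def test_fit_is_bit_reproducible_under_fixed_seed():
    pairs = tiny_pairs(4)
    mc = ModelConfig.toy(seed=0, **TINY_MODEL)
    tc = TrainConfig(seed=7, epochs=2, patch=16)

    def run():
        state = fit(pairs[:3], pairs[3:], mc, tc)
        return state.model.state_vector(), state.metric_history

    v1, h1 = run()
    v2, h2 = run()
    assert np.array_equal(v1, v2)
    assert h1 == h2


def test_train_state_save_resume_is_bit_identical(tmp_path):
    pairs = tiny_pairs(4)
    mc = ModelConfig.toy(seed=0, **TINY_MODEL)

    # continuous 4-epoch run
    tc4 = TrainConfig(seed=3, epochs=4, patch=16)
    full = fit(pairs[:3], pairs[3:], mc, tc4)

    # 2 epochs, checkpoint, resume for 2 more
    tc2 = TrainConfig(seed=3, epochs=2, patch=16)
    half = fit(pairs[:3], pairs[3:], mc, tc2)
    half.save(tmp_path / "state.npz")
    resumed = TrainState.load(tmp_path / "state.npz")
    object.__setattr__(resumed.train_cfg, "epochs", 4)
    resumed = fit(pairs[:3], pairs[3:], mc, resumed.train_cfg, state=resumed)
    assert np.array_equal(full.model.state_vector(), resumed.model.state_vector())
    assert np.array_equal(full.critic.state_vector(), resumed.critic.state_vector())


def test_critic_lr_decays_on_schedule():
    pairs = tiny_pairs(3)
    mc = ModelConfig.toy(seed=0, **TINY_MODEL)
    tc = TrainConfig(seed=0, epochs=2, patch=16, critic_decay_every=1,
                     critic_decay_factor=0.5)
    state = fit(pairs[:2], pairs[2:], mc, tc)
    assert state.critic_opt.lr == pytest.approx(tc.lr_default * 0.25)
    assert state.gen_opt.lr == pytest.approx(tc.lr_default * tc.gen_lr_factor)


def test_fit_rejects_empty_sets():
    mc = ModelConfig.toy(seed=0, **TINY_MODEL)
    tc = TrainConfig(seed=0, epochs=1, patch=16)
    with pytest.raises(ValueError):
        fit([], tiny_pairs(1), mc, tc)
    with pytest.raises(ValueError):
        fit(tiny_pairs(1), [], mc, tc)
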