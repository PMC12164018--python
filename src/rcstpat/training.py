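"""Adversarial restoration training with the Fourier-residual OT objective.

The generator T (the two-phase RCST network) and a convolutional critic phi
play the minimax game

    max_w min_th  E_x[phi_w(x)] + E_y[ c(T(y), y) + g(y - T(y)) - phi_w(T(y)) ]
                  + (gamma/|M|) sum ||T(y) - x||^2

where c is a mean-absolute transport cost, g is an l1 penalty on the 2-D
Fourier transform of the transport residual (mean-normalized by default so
the loss terms share scale), and the last term is the paired supervision.
Optimization follows the protocol: RMSprop, default learning rate 1e-4 with
the generator at half that, critic learning rate decayed by a factor every
20 epochs, batch size 1, random square patch crops, checkpoints every 10
epochs, one critic update per generator update, weight clipping on the
critic (gradient penalty is available as an option).

Everything is seeded and CPU-deterministic: the same TrainConfig.seed gives
bit-identical trajectories, losses and checkpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, fourier_l1
from .layers import Conv2d, Module, RMSprop
from .network import RCST, ModelConfig, save_checkpoint
from .simulator import PairedSample

__all__ = [
    "TrainConfig",
    "LossBundle",
    "TrainState",
    "Critic",
    "fourier_residual_penalty",
    "transport_cost",
    "paired_loss",
    "critic_forward",
    "generator_step",
    "critic_step",
    "fit",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; defaults follow the training recipe above."""

    lr_default: float = 1e-4
    gen_lr_factor: float = 0.5
    critic_decay_every: int = 20
    critic_decay_factor: float = 0.5
    epochs: int = 150
    batch: int = 1
    patch: int = 128
    gamma: float = 100.0
    stage1_weight: float = 0.5
    lambda_g: float = 0.01
    critic_weight: float = 1.0
    clip_or_gp: str = "clip"  # "clip" | "gp"
    clip_value: float = 0.01
    gp_weight: float = 10.0
    momentum: float = 0.9
    augment: bool = True  # seeded flip/rot90 augmentation of each crop
    seed: int = 0
    checkpoint_every: int = 10
    max_steps: int | None = None  # cap on alternating steps (scaled-down runs)

    def __post_init__(self):
        if min(self.lr_default, self.gen_lr_factor, self.gamma) <= 0:
            raise ValueError("rates and weights must be positive")
        if self.clip_or_gp not in ("clip", "gp"):
            raise ValueError("clip_or_gp must be 'clip' or 'gp'")


@dataclass
class LossBundle:
    """All loss terms of one alternating update, as plain floats."""

    transport_cost: float
    fourier_penalty: float
    critic_real: float
    critic_fake: float
    paired: float
    total_G: float
    total_D: float


# -- loss terms --------------------------------------------------------------


def fourier_residual_penalty(r, reduction: str = "sum"):
    """g(r) = ||F(r)||_1, the l1 norm of the unnormalized 2-D DFT of r.

    Accepts a Tensor (returns a Tensor on the autodiff graph — the same
    code path training uses) or a plain array (returns a float).
    """
    if isinstance(r, Tensor):
        return fourier_l1(r, reduction)
    return float(fourier_l1(Tensor(np.asarray(r, dtype=np.float64)), reduction).item())


def transport_cost(x_hat, y):
    """Mean absolute difference c(T(y), y)."""
    x_hat, y = _pair_tensors(x_hat, y)
    return (x_hat - y).abs().mean()


def paired_loss(x_hat, x, gamma: float, m: int = 1):
    """(gamma / m) * ||x_hat - x||^2 (squared l2, summed over pixels)."""
    if gamma <= 0 or m < 1:
        raise ValueError("gamma must be > 0 and m >= 1")
    x_hat, x = _pair_tensors(x_hat, x)
    d = x_hat - x
    return (d * d).sum() * (gamma / m)


def _pair_tensors(a, b):
    a = a if isinstance(a, Tensor) else Tensor(np.asarray(a, dtype=np.float64))
    b = b if isinstance(b, Tensor) else Tensor(np.asarray(b, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


# -- critic ------------------------------------------------------------------


class Critic(Module):
    """Five-layer strided convolutional potential; scalar mean output, no
    sigmoid (Wasserstein-style score)."""

    def __init__(self, seed: int = 0, widths: tuple[int, ...] = (16, 32, 64, 64)):
        rng = np.random.default_rng(seed)
        chans = (1,) + widths
        self.convs = [
            Conv2d(chans[i], chans[i + 1], 3, rng, stride=2, padding=1)
            for i in range(len(widths))
        ]
        self.out_conv = Conv2d(widths[-1], 1, 3, rng)

    def __call__(self, img) -> Tensor:
        x = img if isinstance(img, Tensor) else Tensor(np.asarray(img, dtype=np.float64))
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        for conv in self.convs:
            x = conv(x).leaky_relu(0.2)
        return self.out_conv(x).mean()

    def clip_weights(self, bound: float) -> None:
        for p in self.parameters():
            np.clip(p.data, -bound, bound, out=p.data)


def critic_forward(critic: Critic, img) -> float:
    """Scalar potential score of an image."""
    return float(critic(img).item())


# -- train state -------------------------------------------------------------


@dataclass
class TrainState:
    """Everything needed to resume training bit-identically on CPU."""

    model: RCST
    critic: Critic
    gen_opt: RMSprop
    critic_opt: RMSprop
    rng: np.random.Generator
    train_cfg: TrainConfig
    epoch: int = 0
    global_step: int = 0
    metric_history: list = field(default_factory=list)

    @staticmethod
    def initialize(model_cfg: ModelConfig, train_cfg: TrainConfig) -> "TrainState":
        model = RCST(model_cfg)
        critic = Critic(seed=train_cfg.seed + 1)
        gen_opt = RMSprop(model.parameters(),
                          lr=train_cfg.lr_default * train_cfg.gen_lr_factor,
                          momentum=train_cfg.momentum)
        critic_opt = RMSprop(critic.parameters(), lr=train_cfg.lr_default,
                             momentum=train_cfg.momentum)
        rng = np.random.default_rng(train_cfg.seed)
        return TrainState(model, critic, gen_opt, critic_opt, rng, train_cfg)

    def save(self, path) -> None:
        arrays = {}
        for prefix, mod in (("gen", self.model), ("critic", self.critic)):
            for k, v in mod.state_dict().items():
                arrays[f"{prefix}/{k}"] = v
        for prefix, opt in (("gopt", self.gen_opt), ("copt", self.critic_opt)):
            for i, s in enumerate(opt.sq):
                arrays[f"{prefix}/sq{i}"] = s
            for i, b in enumerate(opt.buf):
                arrays[f"{prefix}/buf{i}"] = b
        meta = {
            "model_cfg": asdict(self.model.cfg),
            "train_cfg": asdict(self.train_cfg),
            "epoch": self.epoch,
            "global_step": self.global_step,
            "metric_history": self.metric_history,
            "rng_state": json.loads(json.dumps(self.rng.bit_generator.state, default=int)),
            "gen_lr": self.gen_opt.lr,
            "critic_lr": self.critic_opt.lr,
        }
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @staticmethod
    def load(path) -> "TrainState":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta_json"].tobytes()).decode())
            mc = meta["model_cfg"]
            for key in ("stb_per_level", "heads_per_level", "topk_ratios"):
                mc[key] = tuple(mc[key])
            state = TrainState.initialize(ModelConfig(**mc), TrainConfig(**meta["train_cfg"]))
            state.model.load_state(
                {k[4:]: npz[k] for k in npz.files if k.startswith("gen/")}
            )
            state.critic.load_state(
                {k[7:]: npz[k] for k in npz.files if k.startswith("critic/")}
            )
            for prefix, opt in (("gopt", state.gen_opt), ("copt", state.critic_opt)):
                opt.sq = [npz[f"{prefix}/sq{i}"].copy() for i in range(len(opt.sq))]
                opt.buf = [npz[f"{prefix}/buf{i}"].copy() for i in range(len(opt.buf))]
        state.gen_opt.lr = meta["gen_lr"]
        state.critic_opt.lr = meta["critic_lr"]
        state.epoch = meta["epoch"]
        state.global_step = meta["global_step"]
        state.metric_history = meta["metric_history"]
        state.rng.bit_generator.state = meta["rng_state"]
        return state


# -- alternating updates -----------------------------------------------------


def _losses(state: TrainState, y: np.ndarray, x: np.ndarray,
            x_hat: Tensor, r0: Tensor | None = None) -> tuple[Tensor, LossBundle]:
    cfg = state.train_cfg
    yt = Tensor(y[None] if y.ndim == 2 else y)
    xt = Tensor(x[None] if x.ndim == 2 else x)
    c = transport_cost(x_hat, yt)
    g = fourier_residual_penalty(yt - x_hat, reduction="mean")
    fake_score = state.critic(x_hat)
    p = paired_loss(x_hat, xt, cfg.gamma, cfg.batch)
    total_g = c + cfg.lambda_g * g - cfg.critic_weight * fake_score + p
    if r0 is not None and cfg.stage1_weight > 0.0:
        # deep supervision of the preliminary (phase-1) restoration x1 = y - r0
        total_g = total_g + paired_loss(yt - r0, xt, cfg.gamma * cfg.stage1_weight,
                                        cfg.batch)
    bundle = LossBundle(
        transport_cost=c.item(), fourier_penalty=g.item(),
        critic_real=np.nan, critic_fake=fake_score.item(),
        paired=p.item(), total_G=total_g.item(), total_D=np.nan,
    )
    return total_g, bundle


def generator_step(pair: PairedSample, state: TrainState) -> LossBundle:
    """One generator update on a (degraded, target) pair."""
    y, x = pair.degraded.values, pair.target
    x_hat, r0 = state.model(y)
    total_g, bundle = _losses(state, y, x, x_hat, r0)
    if not np.isfinite(bundle.total_G):
        raise FloatingPointError("generator loss diverged (non-finite)")
    state.model.zero_grad()
    state.critic.zero_grad()
    total_g.backward()
    state.gen_opt.step()
    state.model.zero_grad()
    state.critic.zero_grad()
    state.global_step += 1
    return bundle


def _critic_update(state: TrainState, x: np.ndarray, x_hat_data: np.ndarray) -> LossBundle:
    cfg = state.train_cfg
    real = state.critic(x)
    fake = state.critic(x_hat_data)
    # minimize phi(fake) - phi(real)  ==  maximize phi(real) - phi(fake)
    total_d = fake - real
    if cfg.clip_or_gp == "gp":
        eps = float(state.rng.uniform())
        mix = eps * x + (1.0 - eps) * x_hat_data
        mix_t = Tensor(mix[None] if mix.ndim == 2 else mix, requires_grad=True)
        score = state.critic(mix_t)
        state.critic.zero_grad()
        score.backward()
        gnorm = float(np.sqrt((mix_t.grad**2).sum()))
        state.critic.zero_grad()
        total_d = total_d + cfg.gp_weight * (gnorm - 1.0) ** 2
    bundle = LossBundle(
        transport_cost=np.nan, fourier_penalty=np.nan,
        critic_real=real.item(), critic_fake=fake.item(),
        paired=np.nan, total_G=np.nan, total_D=total_d.item(),
    )
    if not np.isfinite(bundle.total_D):
        raise FloatingPointError("critic loss diverged (non-finite)")
    state.critic.zero_grad()
    total_d.backward()
    state.critic_opt.step()
    state.critic.zero_grad()
    if cfg.clip_or_gp == "clip":
        state.critic.clip_weights(cfg.clip_value)
    return bundle


def critic_step(pair: PairedSample, state: TrainState) -> LossBundle:
    """One critic update; the generator output is treated as a constant."""
    x_hat, _ = state.model(pair.degraded.values)
    return _critic_update(state, pair.target, x_hat.data)


# -- fit ---------------------------------------------------------------------


def _crop(rng: np.random.Generator, y: np.ndarray, x: np.ndarray, patch: int,
          n_levels: int, augment: bool = False):
    H, W = y.shape
    p = min(patch, H, W)
    f = 2 ** (n_levels - 1)
    p -= p % f
    if not (p == H and p == W):
        i = int(rng.integers(0, H - p + 1))
        j = int(rng.integers(0, W - p + 1))
        y = y[i:i + p, j:j + p]
        x = x[i:i + p, j:j + p]
    if augment:
        k = int(rng.integers(0, 4))
        flip = bool(rng.integers(0, 2))
        y = np.rot90(y, k)
        x = np.rot90(x, k)
        if flip:
            y = y[:, ::-1]
            x = x[:, ::-1]
        y, x = np.ascontiguousarray(y), np.ascontiguousarray(x)
    return y, x


def fit(train_pairs: list[PairedSample], val_pairs: list[PairedSample],
        model_cfg: ModelConfig, train_cfg: TrainConfig,
        out_dir=None, state: TrainState | None = None,
        log_fn=None) -> TrainState:
    """Alternating critic/generator training over epochs of patch crops.

    Per iteration the generator runs once; the critic update reuses its
    detached output, and the generator update then backpropagates through
    the freshly updated critic.  Validation PSNR/SSIM are logged per epoch;
    checkpoints are written every ``checkpoint_every`` epochs when
    ``out_dir`` is given.  Returns the final TrainState.
    """
    from .evaluation import psnr, ssim

    if not train_pairs:
        raise ValueError("training set must be non-empty")
    if not val_pairs:
        raise ValueError("validation set must be non-empty")
    cfg = train_cfg
    if state is None:
        state = TrainState.initialize(model_cfg, cfg)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    stop = False
    while state.epoch < cfg.epochs and not stop:
        order = state.rng.permutation(len(train_pairs))
        epoch_g, epoch_d = [], []
        for idx in order:
            pair = train_pairs[int(idx)]
            y, x = _crop(state.rng, pair.degraded.values, pair.target, cfg.patch,
                         model_cfg.n_levels, augment=cfg.augment)
            # shared generator forward: critic consumes the detached output,
            # the generator loss reuses the same graph through the updated critic
            x_hat, r0 = state.model(y)
            d_bundle = _critic_update(state, x, x_hat.data)
            total_g, g_bundle = _losses(state, y, x, x_hat, r0)
            if not np.isfinite(g_bundle.total_G):
                raise FloatingPointError("generator loss diverged (non-finite)")
            state.model.zero_grad()
            state.critic.zero_grad()
            total_g.backward()
            state.gen_opt.step()
            state.model.zero_grad()
            state.critic.zero_grad()
            state.global_step += 1
            g_bundle.critic_real = d_bundle.critic_real
            g_bundle.total_D = d_bundle.total_D
            epoch_g.append(g_bundle.total_G)
            epoch_d.append(d_bundle.total_D)
            if log_fn is not None:
                log_fn(state.global_step, g_bundle)
            if cfg.max_steps is not None and state.global_step >= cfg.max_steps:
                stop = True
                break
        state.epoch += 1
        val_psnr, val_ssim = [], []
        for pair in val_pairs:
            restored = state.model.restore(pair.degraded.values)
            val_psnr.append(psnr(restored, pair.target, data_range=1.0))
            val_ssim.append(ssim(restored, pair.target, data_range=1.0))
        state.metric_history.append({
            "epoch": state.epoch,
            "train_loss_G": float(np.mean(epoch_g)) if epoch_g else np.nan,
            "train_loss_D": float(np.mean(epoch_d)) if epoch_d else np.nan,
            "val_psnr": float(np.mean(val_psnr)),
            "val_ssim": float(np.mean(val_ssim)),
        })
        if state.epoch % cfg.critic_decay_every == 0:
            state.critic_opt.lr *= cfg.critic_decay_factor
        if out_dir is not None and state.epoch % cfg.checkpoint_every == 0:
            save_checkpoint(out_dir / f"epoch_{state.epoch:04d}.npz", state.model,
                            epoch=state.epoch)
            state.save(out_dir / "train_state.npz")
        if out_dir is not None:
            with open(out_dir / "train_log.jsonl", "a") as fh:
                fh.write(json.dumps(state.metric_history[-1]) + "\n")
    return state
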