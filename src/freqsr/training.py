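"""Alternating GAN optimization.

Each iteration takes a batch of HR fixtures, augments them, crops 64x64,
degrades the crops (noise drawn per crop), then (1) updates the
discriminator on real HR crops vs. detached generator outputs and
(2) updates the generator on the combined perceptual loss with fresh
discriminator probabilities.  Both networks use Adam(0.5, 0.999, 1e-8) at
learning rate 1e-4 with a constant schedule.

Everything stochastic — parameter init, batch order, crops, augmentation
draws, noise sampling — derives from ``RunConfig.seed``, and a checkpoint
stores parameters, optimizer moments, batch-norm buffers and the RNG state,
so resuming reproduces the uninterrupted run's losses exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .config import RunConfig
from .degradation import NoisePool, collect_noise_pool, degrade
from .discriminator import Discriminator
from .fixtures import default_specs, make_hr_image, split_dataset
from .generator import Generator, generator_forward
from .imgio import get_logger
from .losses import (
    adversarial_loss,
    color_constancy_loss,
    discriminator_loss,
    make_feature_extractor,
    perceptual_loss,
    spatial_consistency_loss,
    LossBundle,
)
from .metrics import psnr
from .nn import Adam
from .nn.tensor import Tensor
from .resample import bicubic

__all__ = [
    "TrainState", "augment", "make_training_pair", "train_step", "train",
    "save_checkpoint", "load_checkpoint", "build_models",
    "desk_scale_config", "run_desk_scale_study", "TrainingDiverged",
]


class TrainingDiverged(RuntimeError):
    def __init__(self, iteration, snapshot):
        super().__init__(
            f"non-finite loss at iteration {iteration}; diagnostic snapshot: {snapshot}"
        )


@dataclass
class TrainState:
    config: RunConfig
    generator: Generator
    discriminator: Discriminator
    g_opt: Adam
    d_opt: Adam
    rng: np.random.Generator
    iteration: int = 0
    loss_history: list = field(default_factory=list)


def build_models(cfg: RunConfig):
    g_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    d_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    gen = Generator(g_rng, cfg.generator)
    disc = Discriminator(d_rng, cfg.discriminator)
    return gen, disc


def init_state(cfg: RunConfig) -> TrainState:
    cfg.validate()
    gen, disc = build_models(cfg)
    t = cfg.train
    g_opt = Adam(gen.named_parameters(), t.lr, t.adam_beta1, t.adam_beta2, t.adam_eps)
    d_opt = Adam(disc.named_parameters(), t.lr, t.adam_beta1, t.adam_beta2, t.adam_eps)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    return TrainState(cfg, gen, disc, g_opt, d_opt, rng)


# ---------------------------------------------------------------------------
# data pipeline
# ---------------------------------------------------------------------------

_SCALE_CHOICES = (0.7, 0.85, 1.0)


def augment(hr: np.ndarray, rng: np.random.Generator, enabled=("rot90", "hflip", "scale"),
            min_size: int | None = None) -> np.ndarray:
    """Independently apply each enabled augmentation with probability 1/2:
    rotation by k*90 deg (k uniform in 0..3), horizontal flip, and bicubic
    rescaling by a factor from {0.7, 0.85, 1.0}.  When a rescale would drop
    the image below ``min_size`` the factor is clamped to 1."""
    out = hr
    if "rot90" in enabled and rng.integers(2):
        k = int(rng.integers(4))
        out = np.rot90(out, k, axes=(1, 2)).copy()
    if "hflip" in enabled and rng.integers(2):
        out = out[:, :, ::-1].copy()
    if "scale" in enabled and rng.integers(2):
        f = _SCALE_CHOICES[int(rng.integers(len(_SCALE_CHOICES)))]
        if f != 1.0:
            h, w = out.shape[1:]
            nh, nw = int(round(h * f)), int(round(w * f))  # matches the resampler's sizing
            if min_size is None or min(nh, nw) >= min_size:
                out = np.clip(bicubic(out, f), 0.0, 1.0)
    return np.ascontiguousarray(out, dtype=np.float32)


def make_training_pair(hr: np.ndarray, cfg: RunConfig, pool: NoisePool | None,
                       rng: np.random.Generator):
    """Augment -> random crop of ``cfg.train.crop`` -> degrade the crop
    (noise sampled per crop).  Returns (lr_crop, hr_crop)."""
    crop = cfg.train.crop
    if hr.shape[1] < crop or hr.shape[2] < crop:
        raise ValueError(f"hr {hr.shape[1:]} smaller than crop {crop}")
    a = augment(hr, rng, cfg.train.augment, min_size=crop)
    r = int(rng.integers(a.shape[1] - crop + 1))
    c = int(rng.integers(a.shape[2] - crop + 1))
    hr_crop = a[:, r : r + crop, c : c + crop]
    lr_crop = degrade(hr_crop, cfg.degradation, pool=pool, rng=rng)
    return lr_crop, hr_crop


# ---------------------------------------------------------------------------
# optimization steps
# ---------------------------------------------------------------------------

def train_step(state: TrainState, batch, fx, out_dir=None):
    """One alternating update. ``batch`` is a list of (lr, hr) crop pairs.

    Returns (state, LossBundle, d_loss).  Raises :class:`TrainingDiverged`
    on non-finite losses after writing a diagnostic snapshot.
    """
    cfg = state.config
    lr_np = np.stack([p[0] for p in batch]).astype(np.float32)
    hr_np = np.stack([p[1] for p in batch]).astype(np.float32)
    ref_np = np.stack([bicubic(im, cfg.scale) for im in lr_np]).astype(np.float32)

    gen, disc = state.generator, state.discriminator
    gen.train()
    disc.train()

    fake = gen(Tensor(lr_np), clip=False)  # graph retained for the generator update

    d_loss_val = 0.0
    nb = hr_np.shape[0]
    for _ in range(cfg.train.d_steps_per_g):
        disc.zero_grad()
        # one mixed batch: real and (detached) fake crops share batch-norm
        # statistics, so the discriminator cannot separate them by
        # batch-level statistics alone
        probs = disc(Tensor(np.concatenate([hr_np, fake.data])))
        d_loss = discriminator_loss(probs[:nb], probs[nb:])
        d_loss.backward()
        state.d_opt.step()
        d_loss_val = d_loss.item()

    gen.zero_grad()
    disc.zero_grad()
    p_fake_fresh = disc(fake)
    adv = adversarial_loss(p_fake_fresh)
    spa = spatial_consistency_loss(fake, Tensor(ref_np), fx, cfg.loss.spa_region)
    col = color_constancy_loss(fake)
    per = perceptual_loss(spa, col, adv, cfg.loss)
    per.backward()
    state.g_opt.step()
    disc.zero_grad()  # discard discriminator grads from the generator pass

    bundle = LossBundle(adv=adv.item(), spa=spa.item(), col=col.item(), per=per.item())
    if not all(np.isfinite([bundle.adv, bundle.spa, bundle.col, bundle.per, d_loss_val])):
        snap = Path(out_dir or ".") / f"diverged_iter{state.iteration}.npz"
        np.savez_compressed(snap, lr=lr_np, hr=hr_np, fake=fake.data)
        raise TrainingDiverged(state.iteration, snap)

    state.iteration += 1
    state.loss_history.append(
        {"iteration": state.iteration, "d_loss": d_loss_val, **bundle.__dict__}
    )
    return state, bundle, d_loss_val


def train(cfg: RunConfig, dataset, pool: NoisePool | None = None, out_dir=None,
          state: TrainState | None = None, progress=None):
    """Run ``cfg.train.iterations`` alternating updates over HR images in
    ``dataset``; checkpoints every ``checkpoint_every`` steps when ``out_dir``
    is given.  Pass a loaded ``state`` to resume."""
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    if state is None:
        state = init_state(cfg)
    cfg = state.config
    fx = make_feature_extractor(cfg.loss, cfg.seed)
    log = get_logger("training")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(json.dumps(_config_echo(cfg), indent=2))

    while state.iteration < cfg.train.iterations:
        idx = state.rng.integers(len(dataset), size=cfg.train.batch_size)
        batch = [make_training_pair(dataset[int(i)], cfg, pool, state.rng) for i in idx]
        state, bundle, d_loss = train_step(state, batch, fx, out_dir)
        if progress is not None:
            progress(state.iteration, bundle, d_loss)
        if state.iteration % 100 == 0 or state.iteration == 1:
            log.info(
                f"iter {state.iteration}: per={bundle.per:.4f} spa={bundle.spa:.4f} "
                f"col={bundle.col:.5f} adv={bundle.adv:.3f} d={d_loss:.3f}"
            )
        if out_dir is not None and (
            state.iteration % cfg.train.checkpoint_every == 0
            or state.iteration == cfg.train.iterations
        ):
            save_checkpoint(state, out_dir / "checkpoint.npz")
            _write_history(state, out_dir / "losses.csv")
    if out_dir is not None:
        save_checkpoint(state, out_dir / "checkpoint.npz")
        _write_history(state, out_dir / "losses.csv")
    return state


def _config_echo(cfg: RunConfig) -> dict:
    def enc(o):
        if hasattr(o, "__dataclass_fields__"):
            return {k: enc(getattr(o, k)) for k in o.__dataclass_fields__}
        if isinstance(o, tuple):
            return list(o)
        return o

    return enc(cfg)


def _write_history(state: TrainState, path: Path):
    if not state.loss_history:
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(state.loss_history[0]))
        writer.writeheader()
        writer.writerows(state.loss_history)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(state: TrainState, path) -> None:
    blobs = {}
    for k, v in state.generator.state_dict().items():
        blobs["gen/" + k] = v
    for k, v in state.discriminator.state_dict().items():
        blobs["disc/" + k] = v
    for k, v in state.g_opt.state_dict().items():
        blobs["gopt/" + k] = v
    for k, v in state.d_opt.state_dict().items():
        blobs["dopt/" + k] = v
    blobs["iteration"] = np.asarray(state.iteration)
    blobs["rng_state"] = np.frombuffer(
        json.dumps(state.rng.bit_generator.state).encode(), dtype=np.uint8
    )
    blobs["history"] = np.frombuffer(
        json.dumps(state.loss_history).encode(), dtype=np.uint8
    )
    blobs["config"] = np.frombuffer(
        json.dumps(_config_echo(state.config)).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **blobs)


def load_checkpoint(path, cfg: RunConfig) -> TrainState:
    state = init_state(cfg)
    with np.load(path) as z:
        state.generator.load_state_dict(
            {k[4:]: z[k] for k in z.files if k.startswith("gen/")}
        )
        state.discriminator.load_state_dict(
            {k[5:]: z[k] for k in z.files if k.startswith("disc/")}
        )
        state.g_opt.load_state_dict({k[5:]: z[k] for k in z.files if k.startswith("gopt/")})
        state.d_opt.load_state_dict({k[5:]: z[k] for k in z.files if k.startswith("dopt/")})
        state.iteration = int(z["iteration"])
        state.rng.bit_generator.state = json.loads(bytes(z["rng_state"]).decode())
        state.loss_history = json.loads(bytes(z["history"]).decode())
    return state


# ---------------------------------------------------------------------------
# desk-scale end-to-end study
# ---------------------------------------------------------------------------

def desk_scale_config(seed: int = 0, iterations: int = 1500) -> RunConfig:
    """The CPU desk-scale study configuration: x2 model, 64x64 crops,
    batch 8, reduced widths (C=16, one RMB, one CAM, slim discriminator) so
    the full run fits in minutes on one core.  Degradation: isotropic Gaussian
    blur sigma 1.5 + noise sampled from a harvested pool."""
    cfg = RunConfig(scale=2, seed=seed)
    cfg.generator.base_channels = 16
    cfg.generator.n_rmb = 1
    cfg.generator.n_cam = 1
    cfg.discriminator.base_channels = 16
    cfg.discriminator.n_stages = 3
    cfg.train.batch_size = 8
    cfg.train.iterations = iterations
    cfg.train.crop = 64
    # 64x64 fixtures cannot absorb a sub-unity rescale of a 64-crop
    cfg.train.augment = ("rot90", "hflip")
    cfg.degradation.kernel.sigma_major = 1.5
    cfg.degradation.kernel.sigma_minor = 1.5
    cfg.degradation.noise_mode = "pool"
    return cfg.validate()


def build_study_pool(cfg: RunConfig, n_images: int = 40, noise_sigma: float = 0.03):
    """Harvest a noise pool from emulated real LR images: clean HR fixtures
    degraded with the study blur plus Gaussian sensor noise of ``noise_sigma``."""
    specs = default_specs(n_images, size=(64, 64), seed=cfg.seed + 7000)
    deg = replace(cfg.degradation, noise_mode="gaussian", noise_sigma=noise_sigma)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    lr_images = [degrade(make_hr_image(s), deg, rng=rng) for s in specs]
    window = cfg.window
    return collect_noise_pool(lr_images, window)


def run_desk_scale_study(seed: int = 0, iterations: int = 1500, n_train: int = 200,
                         n_test: int = 32, progress=None) -> dict:
    """Train the x2 model on synthetic fixtures and score it against bicubic
    upsampling on a held-out set.

    Returns a dict with mean PSNRs (model vs bicubic), their gap in dB, and
    the discriminator's mean probability on real vs generated crops.
    """
    cfg = desk_scale_config(seed, iterations)
    pool = build_study_pool(cfg)
    specs = default_specs(n_train + n_test, size=(64, 64), seed=cfg.seed)
    images = [make_hr_image(s) for s in specs]
    train_set, test_set = split_dataset(images, n_train / (n_train + n_test), seed=cfg.seed)

    state = train(cfg, train_set, pool=pool, progress=progress)

    gen, disc = state.generator, state.discriminator
    gen.eval()
    disc.eval()
    eval_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 5]))
    psnr_model, psnr_bicubic, p_real, p_fake = [], [], [], []
    for hr in test_set:
        lr = degrade(hr, cfg.degradation, pool=pool, rng=eval_rng)
        sr = generator_forward(lr, gen)
        up = np.clip(bicubic(lr, cfg.scale), 0.0, 1.0)
        psnr_model.append(psnr(hr, sr))
        psnr_bicubic.append(psnr(hr, up))
        p_real.append(float(disc(Tensor(hr[None])).data[0]))
        p_fake.append(float(disc(Tensor(sr[None])).data[0]))
    return {
        "psnr_model": float(np.mean(psnr_model)),
        "psnr_bicubic": float(np.mean(psnr_bicubic)),
        "psnr_gain_db": float(np.mean(psnr_model) - np.mean(psnr_bicubic)),
        "d_prob_real": float(np.mean(p_real)),
        "d_prob_fake": float(np.mean(p_fake)),
        "pool_size": len(pool),
        "iterations": state.iteration,
        "loss_history": state.loss_history,
        "state": state,
    }
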