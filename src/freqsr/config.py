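"""Run configuration: dataclasses with validated defaults and a YAML loader.

A run is described by one :class:`RunConfig` holding nested sub-configs for
degradation, generator, discriminator, training and losses.  ``load_config``
maps a YAML file onto these dataclasses, rejects unknown keys, and reports
every validation problem at once rather than stopping at the first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PatchWindow", "BlurKernel", "DegradationConfig", "GeneratorConfig",
    "DiscriminatorConfig", "TrainConfig", "LossWeights", "RunConfig",
    "ConfigError", "load_config",
]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


@dataclass
class PatchWindow:
    """Sliding-window geometry for smooth-patch detection.

    ``d``/``sg`` are the global patch side and stride, ``dl``/``sl`` the local
    sub-patch side and stride scanned inside each global patch; ``alpha`` and
    ``beta`` are the relative mean/variance tolerances.
    """

    d: int = 16
    dl: int = 8
    sg: int = 8
    sl: int = 4
    alpha: float = 0.1
    beta: float = 0.1

    def validate(self, errs, prefix=""):
        if self.dl >= self.d:
            errs.append(f"{prefix}dl must be < d (got dl={self.dl}, d={self.d})")
        if self.sg < 1 or self.sl < 1:
            errs.append(f"{prefix}strides must be >= 1")
        if not (0 < self.alpha < 1):
            errs.append(f"{prefix}alpha must lie in (0,1), got {self.alpha}")
        if not (0 < self.beta < 1):
            errs.append(f"{prefix}beta must lie in (0,1), got {self.beta}")


@dataclass
class BlurKernel:
    """Anisotropic Gaussian degradation kernel (covariance from the two sigmas
    rotated by theta radians)."""

    size: int = 11
    sigma_major: float = 1.5
    sigma_minor: float = 1.5
    theta: float = 0.0

    def validate(self, errs, prefix=""):
        if self.size < 1 or self.size % 2 == 0:
            errs.append(f"{prefix}kernel size must be odd and positive, got {self.size}")
        if self.sigma_major <= 0 or self.sigma_minor <= 0:
            errs.append(f"{prefix}kernel sigmas must be > 0")


@dataclass
class DegradationConfig:
    kernel: BlurKernel = field(default_factory=BlurKernel)
    scale: int = 2
    noise_mode: str = "none"  # none | pool | gaussian
    noise_sigma: float = 0.03  # gaussian mode amplitude
    downsample: str = "decimate"  # decimate (blur-then-decimate) | bicubic
    pool_path: str | None = None

    def validate(self, errs, prefix=""):
        if self.scale not in (1, 2, 4):
            errs.append(f"{prefix}scale must be one of 1, 2, 4, got {self.scale}")
        if self.noise_mode not in ("none", "pool", "gaussian"):
            errs.append(f"{prefix}noise_mode must be none|pool|gaussian, got {self.noise_mode!r}")
        if self.downsample not in ("decimate", "bicubic"):
            errs.append(f"{prefix}downsample must be decimate|bicubic, got {self.downsample!r}")
        if self.noise_sigma < 0:
            errs.append(f"{prefix}noise_sigma must be >= 0")
        self.kernel.validate(errs, prefix + "kernel.")


@dataclass
class GeneratorConfig:
    base_channels: int = 16
    n_rmb: int = 8
    mpms_per_rmb: int = 3
    n_cam: int = 8
    dilations: tuple = (1, 2, 3)
    large_kernel: int = 27
    se_reduction: int = 8
    k1: int | None = None  # default C // 4
    k2: int | None = None  # default C // 2
    kspa_w1: float = 0.1
    kspa_w2: float = 0.3
    kspa_masked_softmax: bool = False
    scale: int = 2
    block_order: str = "rmb_then_cam"  # rmb_then_cam | cam_then_rmb
    upsampling: str = "progressive"  # progressive | post
    attention: str = "cam"  # cam | cbam
    fd_method: str = "gaussian"  # gaussian | guided | bilateral | none
    fd_sigma: float = 2.0
    fd_ksize: int = 13

    @property
    def K1(self) -> int:
        return self.k1 if self.k1 is not None else self.base_channels // 4

    @property
    def K2(self) -> int:
        return self.k2 if self.k2 is not None else self.base_channels // 2

    def validate(self, errs, prefix=""):
        c = self.base_channels
        if c < 8:
            errs.append(f"{prefix}base_channels must be >= 8, got {c}")
        if self.large_kernel % 2 == 0:
            errs.append(f"{prefix}large_kernel must be odd, got {self.large_kernel}")
        if self.K1 > c or self.K2 > c:
            errs.append(f"{prefix}K1/K2 must not exceed base_channels")
        if self.K1 < 1 or self.K2 < 1:
            errs.append(f"{prefix}K1/K2 must be >= 1")
        if self.scale not in (2, 4):
            errs.append(f"{prefix}scale must be 2 or 4, got {self.scale}")
        if self.block_order not in ("rmb_then_cam", "cam_then_rmb"):
            errs.append(f"{prefix}block_order must be rmb_then_cam|cam_then_rmb")
        if self.upsampling not in ("progressive", "post"):
            errs.append(f"{prefix}upsampling must be progressive|post")
        if self.attention not in ("cam", "cbam"):
            errs.append(f"{prefix}attention must be cam|cbam")
        if self.fd_method not in ("gaussian", "guided", "bilateral", "none"):
            errs.append(f"{prefix}fd_method must be gaussian|guided|bilateral|none")
        if self.n_rmb < 1 or self.n_cam < 0 or self.mpms_per_rmb < 1:
            errs.append(f"{prefix}block counts out of range")


@dataclass
class DiscriminatorConfig:
    base_channels: int = 64
    n_stages: int = 4

    def validate(self, errs, prefix=""):
        if self.n_stages < 1:
            errs.append(f"{prefix}n_stages must be >= 1, got {self.n_stages}")
        if self.base_channels < 1:
            errs.append(f"{prefix}base_channels must be >= 1")


@dataclass
class TrainConfig:
    batch_size: int = 16
    iterations: int = 60000
    lr: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    crop: int = 64
    augment: tuple = ("rot90", "hflip", "scale")
    d_steps_per_g: int = 1
    checkpoint_every: int = 500

    def validate(self, errs, prefix=""):
        if self.batch_size < 1:
            errs.append(f"{prefix}batch_size must be >= 1")
        if self.iterations < 1:
            errs.append(f"{prefix}iterations must be >= 1")
        unknown = set(self.augment) - {"rot90", "hflip", "scale"}
        if unknown:
            errs.append(f"{prefix}unknown augmentations: {sorted(unknown)}")
        if self.d_steps_per_g < 1:
            errs.append(f"{prefix}d_steps_per_g must be >= 1")


@dataclass
class LossWeights:
    lambda1: float = 0.1
    lambda2: float = 1e-3
    features: str = "random"  # random | vgg19
    spa_region: int = 4

    def validate(self, errs, prefix=""):
        if self.lambda1 < 0 or self.lambda2 < 0:
            errs.append(f"{prefix}loss weights must be >= 0")
        if self.features not in ("random", "vgg19"):
            errs.append(f"{prefix}features must be random|vgg19")


@dataclass
class RunConfig:
    scale: int = 2
    seed: int = 0
    data_dir: str | None = None
    out_dir: str = "runs/default"
    degradation: DegradationConfig = field(default_factory=DegradationConfig)
    window: PatchWindow = field(default_factory=PatchWindow)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossWeights = field(default_factory=LossWeights)

    def validate(self):
        errs = []
        if self.scale not in (2, 4):
            errs.append(f"scale must be a power of 2 in {{2,4}}, got {self.scale}")
        if self.seed < 0:
            errs.append(f"seed must be >= 0, got {self.seed}")
        # the top-level scale is authoritative for generator and degradation
        self.generator.scale = self.scale
        self.degradation.scale = self.scale
        self.degradation.validate(errs, "degradation.")
        self.window.validate(errs, "window.")
        self.generator.validate(errs, "generator.")
        self.discriminator.validate(errs, "discriminator.")
        self.train.validate(errs, "train.")
        self.loss.validate(errs, "loss.")
        if errs:
            raise ConfigError(errs)
        return self


def _fill(cls, data, errs, prefix=""):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            errs.append(f"{prefix}unknown key {key!r}")
            continue
        ftype = fields[key].default_factory() if fields[key].default_factory is not dataclasses.MISSING else None
        if dataclasses.is_dataclass(ftype):
            if not isinstance(value, dict):
                errs.append(f"{prefix}{key} must be a mapping")
                continue
            kwargs[key] = _fill(type(ftype), value, errs, prefix + key + ".")
        else:
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        errs.append(f"{prefix}{exc}")
        return cls()


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; an empty file yields all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(["top level of the config must be a mapping"])
    errs: list[str] = []
    cfg = _fill(RunConfig, data, errs)
    if errs:
        raise ConfigError(errs)
    return cfg.validate()
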