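"""Model and run configuration with `desk` and `paper` presets.

The `paper` preset mirrors the published protocol: 256x192 inputs, a
ViT-B/16-geometry transformer branch, a ResNet-34-layout CNN branch,
Adam at learning rate 1e-4, batch size 16, and a 7:2:1 split.  The `desk`
preset is a width-reduced configuration for CPU-scale experiments and the
test suite: 64x64 synthetic inputs, a small transformer (dim 64, 4 heads,
depth 4) and a thin residual CNN.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .losses import LossConfig
from .metrics import MetricConfig

ABLATIONS = ("backbone", "backbone+tb", "backbone+cb", "complete")


@dataclass
class ModelConfig:
    preset: str = "desk"
    in_channels: int = 3
    channels: tuple = (64, 32, 16)      # fusion channel dims D0 (1/16), D1 (1/8), D2 (1/4)
    decoder_channels: int = 8           # D3 at 1/2 scale
    reduction: int = 4                  # SE / channel-attention bottleneck ratio r
    patch_size: int = 16
    embed_dim: int = 64
    depth: int = 4
    n_heads: int = 4
    mlp_ratio: float = 2.0
    cnn_stem: int = 16
    cnn_widths: tuple = (16, 32, 64)
    cnn_blocks: tuple = (1, 1, 1)
    cnn_skip: bool = True               # fuse encoder skips into the CNN upsampling path
    ablation: str = "complete"
    seed: int = 0

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}, got {self.ablation!r}")
        for c in tuple(self.channels) + (self.decoder_channels,):
            if c % self.reduction:
                raise ValueError(f"channel dim {c} not divisible by reduction {self.reduction}")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")

    @property
    def use_tb(self) -> bool:
        return self.ablation in ("backbone+tb", "complete")

    @property
    def use_attention(self) -> bool:
        return self.ablation in ("backbone+cb", "complete")


def model_preset(name: str, **overrides) -> ModelConfig:
    if name == "desk":
        base = {}
    elif name == "paper":
        base = dict(
            preset="paper",
            channels=(256, 128, 64),
            decoder_channels=32,
            reduction=16,
            embed_dim=768,
            depth=12,
            n_heads=12,
            mlp_ratio=4.0,
            cnn_stem=64,
            cnn_widths=(64, 128, 256),
            cnn_blocks=(3, 4, 6),
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    base.setdefault("preset", name)
    return ModelConfig(**base)


@dataclass
class RunConfig:
    input_size: tuple = (64, 64)        # (H, W)
    batch_size: int = 8
    lr: float = 1e-3
    epochs: int = 5
    split: tuple = (0.7, 0.2, 0.1)
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)

    def __post_init__(self):
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError(f"input size must be divisible by 16, got {h}x{w}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr < 0:
            raise ValueError("lr must be nonnegative")


def run_preset(name: str, **overrides) -> RunConfig:
    """`desk`: CPU-scale defaults.  `paper`: the published training protocol."""
    if name == "desk":
        base = {}
    elif name == "paper":
        base = dict(input_size=(192, 256), batch_size=16, lr=1e-4, epochs=30,
                    model=model_preset("paper"))
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    return RunConfig(**base)


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def _tupled(d: dict, keys) -> dict:
    return {k: tuple(v) if k in keys and isinstance(v, list) else v for k, v in d.items()}


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    model = ModelConfig(**_tupled(raw.pop("model", {}), {"channels", "cnn_widths", "cnn_blocks"}))
    loss = LossConfig(**raw.pop("loss", {}))
    metric = MetricConfig(**raw.pop("metric", {}))
    raw = _tupled(raw, {"input_size", "split"})
    return RunConfig(model=model, loss=loss, metric=metric, **raw)
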