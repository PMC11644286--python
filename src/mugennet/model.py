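"""Channel-attention fusion ("Mugen") modules, attention-gated decoder, and
the full two-branch segmentation network.

Per pyramid level the fusion module recalibrates the transformer features
with a squeeze-and-excitation block (global average pool -> C/r -> C ->
sigmoid gates) and the CNN features with a max-pool-only channel attention
(the average-pool path of CBAM removed so the gate tracks peak, pixel-level
edge evidence), then combines both with a residual projection:

    y = learned(concat(t_hat, r_hat)) + skip(concat(t, r))

The decoder walks the fused pyramid coarse-to-fine.  Each step gates the
next fused map with an additive attention gate (1x1 projections, ReLU,
psi 1x1, sigmoid) driven by the current decoder state, then upsamples
(bilinear x2 + 3x3 conv + BN + ReLU).  A final upsample + 1x1 head +
sigmoid yields the full-resolution probability map, alongside 1-channel
deeply-supervised side outputs from each branch's finest feature map.

Ablations: `backbone` (CNN encoder, plain fusion and decoder),
`backbone+tb` (adds the transformer branch, attention off),
`backbone+cb` (adds the channel attention, no transformer), and
`complete` (both branches, SE + channel attention, attention-gated decode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .config import ModelConfig
from .encoders import CnnEncoder, TransformerEncoder, UpConvBlock, check_divisible
from .nn import Tensor


class SEAttention(nn.Module):
    """Squeeze-and-Excitation: global average squeeze, C/r bottleneck, sigmoid gates."""

    def __init__(self, c: int, reduction: int, rng: np.random.Generator, dtype=None):
        super().__init__()
        if c % reduction:
            raise ValueError(f"channels {c} not divisible by reduction {reduction}")
        self.fc1 = nn.Linear(c, c // reduction, rng, dtype=dtype)
        self.fc2 = nn.Linear(c // reduction, c, rng, dtype=dtype)

    def gates(self, x: Tensor) -> Tensor:
        squeezed = x.mean(axis=(2, 3))               # (B, C)
        return self.fc2(self.fc1(squeezed).relu()).sigmoid()

    def forward(self, x: Tensor, return_gates: bool = False):
        g = self.gates(x)
        out = x * g.reshape(g.shape[0], g.shape[1], 1, 1)
        return (out, g) if return_gates else out


class ChannelAttention(nn.Module):
    """Max-pool-only channel attention (CBAM with the average-pool path removed)."""

    def __init__(self, c: int, reduction: int, rng: np.random.Generator, dtype=None):
        super().__init__()
        if c % reduction:
            raise ValueError(f"channels {c} not divisible by reduction {reduction}")
        self.fc1 = nn.Linear(c, c // reduction, rng, dtype=dtype)
        self.fc2 = nn.Linear(c // reduction, c, rng, dtype=dtype)

    def gates(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        pooled = x.reshape(b, c, h * w).max(axis=2)  # global max pool only
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def forward(self, x: Tensor, return_gates: bool = False):
        g = self.gates(x)
        out = x * g.reshape(g.shape[0], g.shape[1], 1, 1)
        return (out, g) if return_gates else out


class MugenFusion(nn.Module):
    """Per-level fusion of transformer and CNN features with a residual skip.

    The learned path is 1x1 conv -> BN -> ReLU -> 3x3 conv on the
    attention-recalibrated maps; the skip path is a 1x1 projection of the
    raw concatenation.  Zeroing the learned path's final conv reduces the
    module to its skip path exactly.
    """

    def __init__(self, c: int, cfg: ModelConfig, rng: np.random.Generator, dtype=None):
        super().__init__()
        self.use_tb = cfg.use_tb
        self.use_attention = cfg.use_attention
        c_in = 2 * c if self.use_tb else c
        if self.use_attention:
            if self.use_tb:
                self.se = SEAttention(c, cfg.reduction, rng, dtype=dtype)
            self.ca = ChannelAttention(c, cfg.reduction, rng, dtype=dtype)
        self.pre = nn.Conv2d(c_in, c, 1, rng, dtype=dtype)
        self.bn = nn.BatchNorm2d(c, dtype=dtype)
        self.post = nn.Conv2d(c, c, 3, rng, padding=1, dtype=dtype)
        self.skip = nn.Conv2d(c_in, c, 1, rng, dtype=dtype)

    def forward(self, t: Tensor | None, r: Tensor) -> Tensor:
        if self.use_tb:
            if t is None:
                raise ValueError("fusion configured with a transformer branch but got t=None")
            if t.shape != r.shape:
                raise ValueError(f"branch feature shapes differ: {t.shape} vs {r.shape}")
            t_hat = self.se(t) if self.use_attention else t
            r_hat = self.ca(r) if self.use_attention else r
            attended = nn.concatenate([t_hat, r_hat], axis=1)
            raw = nn.concatenate([t, r], axis=1)
        else:
            r_hat = self.ca(r) if self.use_attention else r
            attended, raw = r_hat, r
        learned = self.post(self.bn(self.pre(attended)).relu())
        return learned + self.skip(raw)


class AttentionGate(nn.Module):
    """Additive attention gate: alpha = sigmoid(psi(ReLU(Wg g + Wx x)))."""

    def __init__(self, c_g: int, c_x: int, rng: np.random.Generator, dtype=None):
        super().__init__()
        c_int = max(c_x // 2, 1)
        self.w_g = nn.Conv2d(c_g, c_int, 1, rng, dtype=dtype)
        self.w_x = nn.Conv2d(c_x, c_int, 1, rng, dtype=dtype)
        self.psi = nn.Conv2d(c_int, 1, 1, rng, dtype=dtype)

    def forward(self, g: Tensor, x: Tensor, return_alpha: bool = False):
        gh, xh = g.shape[2], x.shape[2]
        if gh == xh // 2:
            g = nn.upsample2x_bilinear(g)
        elif gh != xh:
            raise ValueError(f"gate scale {g.shape[2:]} incompatible with input {x.shape[2:]}")
        alpha = self.psi((self.w_g(g) + self.w_x(x)).relu()).sigmoid()
        out = x * alpha
        return (out, alpha) if return_alpha else out


@dataclass
class DecoderState:
    """All intermediate and final maps of one forward pass (numpy-backed tensors)."""

    y1: Tensor
    y2: Tensor
    y3: Tensor
    z1: Tensor
    z2: Tensor
    z3: Tensor
    zout: Tensor
    s_t: Tensor | None
    s_r: Tensor
    s_z: Tensor
    alphas: dict = field(default_factory=dict)

    def outputs(self) -> dict:
        out = {"s_r": self.s_r, "s_z": self.s_z}
        if self.s_t is not None:
            out["s_t"] = self.s_t
        return out


def _upsample_logits_to_full(x: Tensor, factor: int) -> Tensor:
    """Plain bilinear upsampling of a 1-channel logit map by a power of two."""
    while factor > 1:
        x = nn.upsample2x_bilinear(x)
        factor //= 2
    return x


class MugenNet(nn.Module):
    """Parallel CNN + transformer encoder, three fusion levels, gated decoder."""

    def __init__(self, cfg: ModelConfig, dtype=None):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d0, d1, d2 = cfg.channels
        d3 = cfg.decoder_channels
        self.cnn = CnnEncoder(cfg, rng, dtype=dtype)
        if cfg.use_tb:
            self.transformer = TransformerEncoder(cfg, rng, dtype=dtype)
        self.fuse1 = MugenFusion(d0, cfg, rng, dtype=dtype)
        self.fuse2 = MugenFusion(d1, cfg, rng, dtype=dtype)
        self.fuse3 = MugenFusion(d2, cfg, rng, dtype=dtype)
        self.up_z1 = UpConvBlock(d0, d1, rng, dtype=dtype)   # y1 (1/16) -> z1 (1/8)
        self.up_z2 = UpConvBlock(d1, d2, rng, dtype=dtype)   # gated y2 (1/8) -> z2 (1/4)
        self.up_z3 = UpConvBlock(d2, d3, rng, dtype=dtype)   # gated y3 (1/4) -> z3 (1/2)
        self.up_out = UpConvBlock(d3, d3, rng, dtype=dtype)  # z3 (1/2) -> full
        self.head = nn.Conv2d(d3, 1, 1, rng, dtype=dtype)
        self.gated = cfg.ablation == "complete"
        if self.gated:
            self.ag1 = AttentionGate(d1, d1, rng, dtype=dtype)
            self.ag2 = AttentionGate(d2, d2, rng, dtype=dtype)
        if cfg.use_tb:
            self.head_t = nn.Conv2d(d2, 1, 1, rng, dtype=dtype)
        self.head_r = nn.Conv2d(d2, 1, 1, rng, dtype=dtype)

    def forward(self, x: Tensor) -> DecoderState:
        b, c, h, w = x.shape
        check_divisible(h, w, 16)
        r0, r1, r2 = self.cnn(x)
        if self.cfg.use_tb:
            t0, t1, t2 = self.transformer(x)
        else:
            t0 = t1 = t2 = None
        y1 = self.fuse1(t0, r0)
        y2 = self.fuse2(t1, r1)
        y3 = self.fuse3(t2, r2)

        alphas = {}
        z1 = self.up_z1(y1)                       # 1/8
        if self.gated:
            g2, a2 = self.ag1(z1, y2, return_alpha=True)
            alphas["ag1"] = a2
        else:
            g2 = y2 + z1                          # plain top-down aggregation
        z2 = self.up_z2(g2)                       # 1/4
        if self.gated:
            g3, a3 = self.ag2(z2, y3, return_alpha=True)
            alphas["ag2"] = a3
        else:
            g3 = y3 + z2
        z3 = self.up_z3(g3)                       # 1/2
        zout = self.head(self.up_out(z3)).sigmoid()

        s_r = _upsample_logits_to_full(self.head_r(r2), 4).sigmoid()
        s_t = None
        if self.cfg.use_tb:
            s_t = _upsample_logits_to_full(self.head_t(t2), 4).sigmoid()
        return DecoderState(y1=y1, y2=y2, y3=y3, z1=z1, z2=z2, z3=z3,
                            zout=zout, s_t=s_t, s_r=s_r, s_z=zout, alphas=alphas)

    # -- checkpointing ----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            np.savez(fh, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def build_model(cfg: ModelConfig, dtype=None) -> MugenNet:
    return MugenNet(cfg, dtype=dtype)
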