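"""The two parallel branch encoders.

Transformer branch: the input is patchified (default 16x16 patches, the
ViT-B/16 convention), each patch linearly embedded and tagged with a fixed
2-D sinusoidal position code, then passed through a stack of pre-norm
blocks (LayerNorm -> multi-head self-attention -> LayerNorm -> MLP, both
with residual connections).  The token grid at 1/16 scale is reshaped back
to a feature map t0 and upsampled twice (bilinear x2 + 3x3 conv + BN +
ReLU) to t1 (1/8) and t2 (1/4).

CNN branch: a residual-convolution encoder in the ResNet-34 layout
(7x7 stem / max-pool / three basic-block stages) downsamples to 1/16 (r0),
then the same two upsampling stages — optionally fused with encoder skips —
produce r1 and r2 with shapes matching the transformer branch exactly.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import Tensor


def check_divisible(h: int, w: int, by: int = 16) -> None:
    if h % by or w % by:
        raise ValueError(f"spatial dims must be divisible by {by}, got {h}x{w}")


@lru_cache(maxsize=32)
def sinusoidal_position_codes(gh: int, gw: int, dim: int) -> np.ndarray:
    """Fixed 2-D sine/cosine position codes for a gh x gw token grid."""
    def axis_codes(n, d):
        pos = np.arange(n)[:, None]
        i = np.arange(d // 2)[None, :]
        angles = pos / (10000.0 ** (2 * i / d))
        out = np.zeros((n, d))
        out[:, 0::2] = np.sin(angles)
        out[:, 1::2] = np.cos(angles)
        return out

    d_half = dim // 2
    codes_y = axis_codes(gh, d_half)                     # (gh, d/2)
    codes_x = axis_codes(gw, dim - d_half)               # (gw, d - d/2)
    grid = np.concatenate(
        [np.repeat(codes_y, gw, axis=0), np.tile(codes_x, (gh, 1))], axis=1
    )                                                    # (gh*gw, dim)
    return grid.astype(nn.DEFAULT_DTYPE)


class PatchEmbed(nn.Module):
    """Split the image into PxP patches, linearly embed, add position codes."""

    def __init__(self, in_channels: int, embed_dim: int, patch_size: int,
                 rng: np.random.Generator, dtype=None):
        super().__init__()
        self.patch_size = patch_size
        self.proj = nn.Conv2d(in_channels, embed_dim, patch_size, rng,
                              stride=patch_size, dtype=dtype)

    def forward(self, x: Tensor, add_position: bool = True) -> Tensor:
        b, c, h, w = x.shape
        p = self.patch_size
        if h % p or w % p:
            raise ValueError(f"image {h}x{w} not divisible by patch size {p}")
        tok = self.proj(x)                              # (B, E, h/P, w/P)
        gh, gw = tok.shape[2], tok.shape[3]
        tok = tok.reshape(b, tok.shape[1], gh * gw).transpose(0, 2, 1)   # (B, N, E)
        if add_position:
            tok = tok + Tensor(sinusoidal_position_codes(gh, gw, tok.shape[2]))
        return tok


def multi_head_attention(q: Tensor, k: Tensor, v: Tensor, n_heads: int) -> Tensor:
    """softmax(q k^T / sqrt(D_h)) v per head, heads concatenated.

    q, k, v: (B, N, E) with E divisible by n_heads.
    """
    b, n, e = q.shape
    if e % n_heads:
        raise ValueError("embedding dim not divisible by number of heads")
    dh = e // n_heads
    if dh <= 0:
        raise ValueError("per-head dimension must be positive")

    def split(t):
        return t.reshape(b, n, n_heads, dh).transpose(0, 2, 1, 3)   # (B, H, N, Dh)

    qh, kh, vh = split(q), split(k), split(v)
    scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    attn = nn.softmax(scores, axis=-1)
    out = attn @ vh                                                  # (B, H, N, Dh)
    return out.transpose(0, 2, 1, 3).reshape(b, n, e)


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, dtype=None):
        super().__init__()
        self.n_heads = n_heads
        self.q = nn.Linear(dim, dim, rng, dtype=dtype)
        self.k = nn.Linear(dim, dim, rng, dtype=dtype)
        self.v = nn.Linear(dim, dim, rng, dtype=dtype)
        self.proj = nn.Linear(dim, dim, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        out = multi_head_attention(self.q(x), self.k(x), self.v(x), self.n_heads)
        return self.proj(out)


class TransformerBlock(nn.Module):
    """Pre-norm block: x + MSA(LN(x)), then + MLP(LN(.))."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: float,
                 rng: np.random.Generator, dtype=None):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.ln1 = nn.LayerNorm(dim, dtype=dtype)
        self.msa = MultiHeadSelfAttention(dim, n_heads, rng, dtype=dtype)
        self.ln2 = nn.LayerNorm(dim, dtype=dtype)
        self.fc1 = nn.Linear(dim, hidden, rng, dtype=dtype)
        self.fc2 = nn.Linear(hidden, dim, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.msa(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).relu())


class UpConvBlock(nn.Module):
    """Bilinear x2 upsample + 3x3 conv + batch-norm + ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=None):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, 3, rng, padding=1, dtype=dtype)
        self.bn = nn.BatchNorm2d(c_out, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(nn.upsample2x_bilinear(x))).relu()


class TransformerEncoder(nn.Module):
    """Patchify -> L transformer blocks -> token grid -> (t0, t1, t2) pyramid."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, dtype=None):
        super().__init__()
        d0, d1, d2 = cfg.channels
        self.patch_size = cfg.patch_size
        self.embed = PatchEmbed(cfg.in_channels, cfg.embed_dim, cfg.patch_size, rng, dtype=dtype)
        self.blocks = nn.Sequential(*[
            TransformerBlock(cfg.embed_dim, cfg.n_heads, cfg.mlp_ratio, rng, dtype=dtype)
            for _ in range(cfg.depth)
        ])
        self.ln = nn.LayerNorm(cfg.embed_dim, dtype=dtype)
        self.to_d0 = nn.Conv2d(cfg.embed_dim, d0, 1, rng, dtype=dtype)
        self.up1 = UpConvBlock(d0, d1, rng, dtype=dtype)
        self.up2 = UpConvBlock(d1, d2, rng, dtype=dtype)

    def forward(self, x: Tensor):
        b, c, h, w = x.shape
        check_divisible(h, w, 16)
        tok = self.embed(x)
        tok = self.ln(self.blocks(tok))
        gh, gw = h // self.patch_size, w // self.patch_size
        # token grid back to a spatial map at 1/16 scale
        grid = tok.transpose(0, 2, 1).reshape(b, tok.shape[2], gh, gw)
        t0 = self.to_d0(grid)
        t1 = self.up1(t0)
        t2 = self.up2(t1)
        return t0, t1, t2


class BasicBlock(nn.Module):
    """Two 3x3 convs with an identity (or 1x1-projected) residual."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1, dtype=None):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, stride=stride, padding=1, bias=False, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(c_out, dtype=dtype)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, padding=1, bias=False, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(c_out, dtype=dtype)
        if stride != 1 or c_in != c_out:
            self.short_conv = nn.Conv2d(c_in, c_out, 1, rng, stride=stride, bias=False, dtype=dtype)
            self.short_bn = nn.BatchNorm2d(c_out, dtype=dtype)
        else:
            self.short_conv = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        short = x if self.short_conv is None else self.short_bn(self.short_conv(x))
        return (out + short).relu()


class CnnEncoder(nn.Module):
    """Residual-convolution encoder emitting the (r0, r1, r2) pyramid."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, dtype=None):
        super().__init__()
        d0, d1, d2 = cfg.channels
        w1, w2, w3 = cfg.cnn_widths
        b1, b2, b3 = cfg.cnn_blocks
        self.use_skip = cfg.cnn_skip
        self.stem = nn.Conv2d(cfg.in_channels, cfg.cnn_stem, 7, rng, stride=2, padding=3,
                              bias=False, dtype=dtype)
        self.stem_bn = nn.BatchNorm2d(cfg.cnn_stem, dtype=dtype)

        def stage(c_in, c_out, blocks, stride):
            layers = [BasicBlock(c_in, c_out, rng, stride=stride, dtype=dtype)]
            layers += [BasicBlock(c_out, c_out, rng, dtype=dtype) for _ in range(blocks - 1)]
            return nn.Sequential(*layers)

        self.stage1 = stage(cfg.cnn_stem, w1, b1, 1)   # 1/4
        self.stage2 = stage(w1, w2, b2, 2)             # 1/8
        self.stage3 = stage(w2, w3, b3, 2)             # 1/16
        self.to_d0 = nn.Conv2d(w3, d0, 1, rng, dtype=dtype)
        self.up1 = UpConvBlock(d0, d1, rng, dtype=dtype)
        self.up2 = UpConvBlock(d1, d2, rng, dtype=dtype)
        if self.use_skip:
            self.skip1 = nn.Conv2d(w2, d1, 1, rng, bias=False, dtype=dtype)
            self.skip2 = nn.Conv2d(w1, d2, 1, rng, bias=False, dtype=dtype)

    def forward(self, x: Tensor):
        b, c, h, w = x.shape
        check_divisible(h, w, 16)
        s = nn.max_pool2x2(self.stem_bn(self.stem(x)).relu())   # 1/4
        e1 = self.stage1(s)                                     # 1/4
        e2 = self.stage2(e1)                                    # 1/8
        e3 = self.stage3(e2)                                    # 1/16
        r0 = self.to_d0(e3)
        r1 = self.up1(r0)
        if self.use_skip:
            r1 = r1 + self.skip1(e2)
        r2 = self.up2(r1)
        if self.use_skip:
            r2 = r2 + self.skip2(e1)
        return r0, r1, r2
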