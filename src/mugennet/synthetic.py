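"""Deterministic generator of polyp-like image/mask pairs.

Scenes emulate the qualitative properties of endoscopic polyp frames that
matter to a segmentation model: a textured, mottled mucosa-like background;
one or more brighter/redder blob-shaped foreground lesions with smoothly
deformed (Fourier-perturbed) outlines; optionally blurred, low-contrast
boundaries; and additive sensor noise.  Identical specs produce
byte-identical outputs, so image/mask fixtures never need to be shipped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

# Total relative radius deformation is bounded by this amplitude, so a base
# radius r0 always yields a radius inside [r0*(1-A), r0*(1+A)].
DEFORM_AMPLITUDE = 0.35
_HARMONICS = (2, 3, 4, 5)

# foreground tint: brighter and redder than the mucosa background
_FG_DELTA = np.array([1.0, 0.35, 0.25])
_BG_BASE = np.array([0.62, 0.40, 0.36])


@dataclass(frozen=True)
class PolypSceneSpec:
    seed: int = 0
    height: int = 64
    width: int = 64
    n_blobs: int = 1
    radius_range: tuple = (6.0, 14.0)
    boundary_softness: float = 1.0
    fg_bg_contrast: float = 0.35
    noise_sd: float = 0.03
    texture_scale: float = 8.0

    def __post_init__(self):
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")
        lo, hi = self.radius_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid radius_range {self.radius_range}")


def _blob_mask(spec: PolypSceneSpec, rng: np.random.Generator) -> np.ndarray:
    """One deformed-ellipse blob; radius r(theta) = r0 (1 + sum a_k cos(k theta + phi_k))."""
    h, w = spec.height, spec.width
    r0 = rng.uniform(*spec.radius_range)
    margin = min(r0 * (1 + DEFORM_AMPLITUDE), min(h, w) / 2.0 - 1)
    cy = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2.0
    cx = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2.0
    per_harm = DEFORM_AMPLITUDE / len(_HARMONICS)
    amps = rng.uniform(-per_harm, per_harm, len(_HARMONICS))
    phases = rng.uniform(0, 2 * np.pi, len(_HARMONICS))
    # mild anisotropy (ellipse) folded into the same amplitude budget
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    radius = r0 * (1.0 + sum(a * np.cos(k * theta + p)
                             for a, k, p in zip(amps, _HARMONICS, phases)))
    return (dy * dy + dx * dx) < radius * radius


def generate_sample(spec: PolypSceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene.

    Returns (image, mask): image is H x W x 3 uint8, mask is H x W uint8 in {0,1}.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_blobs):
        mask |= _blob_mask(spec, rng)
    if spec.n_blobs > 0 and not mask.any():
        logger.warning("all blobs clipped away; mask is empty for seed %d", spec.seed)

    texture = rng.standard_normal((h, w))
    if spec.texture_scale > 0:
        texture = gaussian_filter(texture, spec.texture_scale / 4.0)
        peak = np.abs(texture).max()
        if peak > 0:
            texture = texture / peak
    img = _BG_BASE[None, None, :] + 0.08 * texture[:, :, None]

    fg = mask.astype(np.float64)
    if spec.boundary_softness > 0:
        fg = gaussian_filter(fg, spec.boundary_softness)
    img = img + spec.fg_bg_contrast * fg[:, :, None] * _FG_DELTA[None, None, :]

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, (h, w, 3))

    img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return img8, mask.astype(np.uint8)


def sample_seed(base_seed: int, index: int) -> int:
    """Per-sample stream derived from (base_seed, index); order-independent."""
    return int(np.random.SeedSequence((base_seed, index)).generate_state(1)[0] % (2 ** 31))


def split_sizes(n: int, ratios=(0.7, 0.2, 0.1)) -> tuple[int, int, int]:
    n_train = int(n * ratios[0])
    n_val = int(n * ratios[1])
    return n_train, n_val, n - n_train - n_val


def generate_dataset(n: int, out_dir, base_seed: int = 0,
                     spec: PolypSceneSpec | None = None) -> list[dict]:
    """Write n image/mask PNG pairs plus a 7:2:1 train/val/test manifest CSV.

    Returns the manifest rows (id, split, seed).  Re-running with the same
    base_seed and spec reproduces every byte.
    """
    if n < 10:
        raise ValueError("generate_dataset needs n >= 10 to fill all three splits")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template = spec or PolypSceneSpec()

    n_train, n_val, _ = split_sizes(n)
    order = np.random.default_rng(base_seed).permutation(n)
    split_of = {}
    for rank, idx in enumerate(order):
        split_of[int(idx)] = "train" if rank < n_train else ("val" if rank < n_train + n_val else "test")

    rows = []
    for i in range(n):
        seed_i = sample_seed(base_seed, i)
        img, mask = generate_sample(replace(template, seed=seed_i))
        Image.fromarray(img).save(out_dir / f"img_{i:04d}.png")
        Image.fromarray(mask * 255).save(out_dir / f"mask_{i:04d}.png")
        rows.append({"id": f"{i:04d}", "split": split_of[i], "seed": seed_i})

    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "split", "seed"])
        writer.writeheader()
        writer.writerows(rows)
    return rows
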