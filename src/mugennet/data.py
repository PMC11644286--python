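"""Image/mask reading, resizing, and dataset splitting.

Images are read as RGB, bilinearly resized to the configured resolution and
normalised to [0, 1]; masks are resized nearest-neighbour (no label bleed)
and binarised at pixel value > 127.  Pairs match by index or by filename;
unpaired files are reported explicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .config import RunConfig


def load_image(path, size: tuple[int, int] | None = None) -> np.ndarray:
    """RGB image -> (3, H, W) float32 in [0, 1]; bilinear resize if size given."""
    img = Image.open(path).convert("RGB")
    if size is not None:
        h, w = size
        img = img.resize((w, h), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    return arr.transpose(2, 0, 1)


def load_mask(path, size: tuple[int, int] | None = None) -> np.ndarray:
    """8-bit grayscale mask -> (H, W) float32 in {0, 1}; pixel > 127 is foreground."""
    img = Image.open(path).convert("L")
    if size is not None:
        h, w = size
        img = img.resize((w, h), Image.NEAREST)
    return (np.asarray(img) > 127).astype(np.float32)


def load_prediction(path, size: tuple[int, int] | None = None) -> np.ndarray:
    """8-bit grayscale prediction -> (H, W) float64 map, value / 255."""
    img = Image.open(path).convert("L")
    if size is not None:
        h, w = size
        img = img.resize((w, h), Image.BILINEAR)
    return np.asarray(img, dtype=np.float64) / 255.0


@dataclass
class SplitData:
    """One split: stacked images (N,3,H,W), masks (N,H,W), and sample ids."""

    images: np.ndarray
    masks: np.ndarray
    ids: list

    def __len__(self):
        return len(self.ids)


def _pairs_from_dir(data_dir: Path) -> list[tuple[str, Path, Path]]:
    imgs = {p.stem.removeprefix("img_"): p for p in sorted(data_dir.glob("img_*.png"))}
    msks = {p.stem.removeprefix("mask_"): p for p in sorted(data_dir.glob("mask_*.png"))}
    unpaired = sorted(set(imgs) ^ set(msks))
    if unpaired:
        raise ValueError(f"unpaired image/mask ids in {data_dir}: {unpaired}")
    if not imgs:
        raise ValueError(f"no img_*.png / mask_*.png pairs found in {data_dir}")
    return [(sid, imgs[sid], msks[sid]) for sid in sorted(imgs)]


def load_dataset(data_dir, cfg: RunConfig) -> dict[str, SplitData]:
    """Load image/mask pairs and split them 7:2:1 (or per the manifest).

    If `data_dir` contains a manifest.csv its split column is honoured;
    otherwise a shuffle seeded by cfg.seed assigns train/val/test at
    cfg.split proportions.
    """
    data_dir = Path(data_dir)
    pairs = _pairs_from_dir(data_dir)
    manifest = data_dir / "manifest.csv"
    if manifest.exists():
        with open(manifest) as fh:
            split_of = {row["id"]: row["split"] for row in csv.DictReader(fh)}
        missing = [sid for sid, _, _ in pairs if sid not in split_of]
        if missing:
            raise ValueError(f"ids missing from manifest: {missing}")
    else:
        n = len(pairs)
        n_train = int(n * cfg.split[0])
        n_val = int(n * cfg.split[1])
        order = np.random.default_rng(cfg.seed).permutation(n)
        split_of = {}
        for rank, idx in enumerate(order):
            sid = pairs[int(idx)][0]
            split_of[sid] = "train" if rank < n_train else ("val" if rank < n_train + n_val else "test")

    out: dict[str, SplitData] = {}
    for split in ("train", "val", "test"):
        sel = [(sid, ip, mp) for sid, ip, mp in pairs if split_of[sid] == split]
        if not sel:
            out[split] = SplitData(images=np.zeros((0, 3) + tuple(cfg.input_size), np.float32),
                                   masks=np.zeros((0,) + tuple(cfg.input_size), np.float32),
                                   ids=[])
            continue
        images = np.stack([load_image(ip, cfg.input_size) for _, ip, _ in sel])
        masks = np.stack([load_mask(mp, cfg.input_size) for _, _, mp in sel])
        out[split] = SplitData(images=images, masks=masks, ids=[sid for sid, _, _ in sel])
    return out
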