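"""Boundary-weighted segmentation losses.

The training objective combines a soft weighted IoU loss (global overlap
constraint) with a weighted binary cross-entropy (pixel-level constraint):

    L = L_IoU^w + n * L_BCE^w          (n = 6/5 by default)

Both terms share a boundary weight map w = 1 + gain * |meanpool_k(G) - G|,
which equals 1 wherever the ground truth is locally constant and rises
toward boundaries, emphasising the hard pixels near unclear polyp edges.
Deep supervision sums the combined loss over three full-resolution side
outputs (transformer branch, CNN branch, fused map):

    L_total = alpha * L(G, S_t) + beta * L(G, S_r) + gamma * L(G, S_z)

Losses accept either numpy arrays or autodiff tensors and return a scalar
tensor so they can drive the optimiser directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .nn import Tensor


@dataclass(frozen=True)
class LossConfig:
    n: float = 6.0 / 5.0
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    weight_kernel: int = 31
    weight_gain: float = 5.0
    eps: float = 1e-8

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if self.weight_kernel < 3 or self.weight_kernel % 2 == 0:
            raise ValueError(f"weight_kernel must be odd and >= 3, got {self.weight_kernel}")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("output weights must be nonnegative")


@dataclass
class LossBreakdown:
    """Per-output (L_IoU^w, L_BCE^w, L) triples plus the weighted total."""

    per_output: dict
    total: float

    def as_record(self) -> dict:
        rec = {}
        for name, (liou, lbce, l) in self.per_output.items():
            rec[f"{name}_iou"] = liou
            rec[f"{name}_bce"] = lbce
            rec[f"{name}_loss"] = l
        rec["total"] = self.total
        return rec


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def boundary_weight_map(gt: np.ndarray, cfg: LossConfig = LossConfig()) -> np.ndarray:
    """w = 1 + gain * |mean_window(G) - G|.

    The window mean uses reflective borders so a locally constant mask keeps
    w = 1 up to the image edge.  Symmetric under mask complement.
    """
    gt = np.asarray(gt, dtype=np.float64)
    local_mean = uniform_filter(gt, size=cfg.weight_kernel, mode="reflect", axes=(-2, -1))
    return 1.0 + cfg.weight_gain * np.abs(local_mean - gt)


def weighted_bce(pred, gt, w, cfg: LossConfig = LossConfig()) -> Tensor:
    """sum(w * BCE(p, g)) / sum(w); pred is eps-clamped into (0,1)."""
    pred = _as_tensor(pred)
    if pred.data.min() < 0.0 or pred.data.max() > 1.0:
        raise ValueError(f"predictions must lie in [0,1], got range "
                         f"[{pred.data.min():.4g}, {pred.data.max():.4g}]")
    gt = np.asarray(gt, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    p = pred.clamp(1e-7, 1.0 - 1e-7)
    bce = -(Tensor(gt) * p.log() + Tensor(1.0 - gt) * (1.0 - p).log())
    return (Tensor(w) * bce).sum() / float(w.sum())


def weighted_iou(pred, gt, w, cfg: LossConfig = LossConfig()) -> Tensor:
    """1 - sum(w p g) / sum(w (p + g - p g)): the soft weighted IoU loss."""
    pred = _as_tensor(pred)
    gt_t = Tensor(np.asarray(gt, dtype=np.float64))
    w_t = Tensor(np.asarray(w, dtype=np.float64))
    inter = (w_t * pred * gt_t).sum()
    union = (w_t * (pred + gt_t - pred * gt_t)).sum()
    return 1.0 - (inter + cfg.eps) / (union + cfg.eps)


def branch_loss(pred, gt, cfg: LossConfig = LossConfig(), w: np.ndarray | None = None):
    """L = L_IoU^w + n * L_BCE^w for one full-resolution output.

    Returns the (L_IoU^w, L_BCE^w, L) triple as scalar tensors.
    """
    pred = _as_tensor(pred)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.data.shape != gt.shape:
        raise ValueError(f"prediction shape {pred.data.shape} != ground truth shape {gt.shape}; "
                         "outputs must be upsampled to ground-truth resolution before the loss")
    if w is None:
        w = boundary_weight_map(gt, cfg)
    liou = weighted_iou(pred, gt, w, cfg)
    lbce = weighted_bce(pred, gt, w, cfg)
    return liou, lbce, liou + cfg.n * lbce


def total_loss(outputs: dict, gt, cfg: LossConfig = LossConfig()) -> tuple[Tensor, LossBreakdown]:
    """Deep-supervision total: alpha*L(G,S_t) + beta*L(G,S_r) + gamma*L(G,S_z).

    `outputs` maps names in {"s_t", "s_r", "s_z"} to full-resolution
    probability maps; a branch absent from the dict (ablations) is skipped.
    Returns the differentiable total and a float breakdown for logging.
    """
    gt = np.asarray(gt, dtype=np.float64)
    weights = {"s_t": cfg.alpha, "s_r": cfg.beta, "s_z": cfg.gamma}
    w_map = boundary_weight_map(gt, cfg)
    total = None
    per_output = {}
    for name, weight in weights.items():
        pred = outputs.get(name)
        if pred is None:
            continue
        liou, lbce, l = branch_loss(pred, gt, cfg, w=w_map)
        for comp, val in (("iou", liou), ("bce", lbce), ("L", l)):
            if not np.isfinite(float(val)):
                raise FloatingPointError(f"non-finite {comp} loss component for output '{name}'")
        per_output[name] = (float(liou), float(lbce), float(l))
        term = weight * l
        total = term if total is None else total + term
    if total is None:
        raise ValueError("total_loss needs at least one output")
    return total, LossBreakdown(per_output=per_output, total=float(total))
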