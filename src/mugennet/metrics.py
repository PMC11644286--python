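"""Segmentation evaluation metrics.

Six quantities are computed per prediction/ground-truth pair and averaged
over a dataset: mean Dice and mean IoU (set overlap on the binarised
prediction), mean absolute error (on the continuous map), the weighted
F-measure F_beta^w, the structure measure S_alpha, and the alignment
(E) measure E_xi.  Conventions:

* Dice/IoU are set-based: the prediction is thresholded (default 0.5)
  before comparison.  A pair of empty masks counts as perfect agreement
  (score 1), logged at debug level.
* MAE, F_beta^w, S_alpha and E_xi consume the continuous probability map.
* The structure measure mixes an object-aware term (foreground/background
  mean-and-spread statistics of the prediction) with a region-aware term
  (SSIM-style similarity on four quadrants cut at the ground-truth
  centroid, weighted by quadrant pixel area).
* The E measure is the mean pixelwise alignment of the two mean-centered
  maps, 2*phi_G*phi_D / (phi_G^2 + phi_D^2), without any further
  enhancement function, clamped to [0, 1] for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

METRIC_NAMES = ("dice", "iou", "mae", "f_beta_w", "s_measure", "e_measure")


@dataclass(frozen=True)
class MetricConfig:
    """Constants of the metric suite.

    f_omega: weighting exponent of the weighted F-measure (fixed to 1:
        uniform pixel weighting, so weighted precision/recall reduce to the
        plain soft precision/recall).
    f_beta: precision/recall trade-off beta of F_beta^w.
    s_alpha: object/region mixing weight of the structure measure.
    s_mu: foreground/background mixing weight of the object term.
    s_lambda: spread penalty of the object term.
    bin_threshold: cut used to binarise predictions for Dice/IoU.
    eps: numerical floor added to denominators.
    """

    f_omega: float = 1.0
    f_beta: float = 0.5
    s_alpha: float = 0.5
    s_mu: float = 0.5
    s_lambda: float = 1.0
    bin_threshold: float = 0.5
    eps: float = 1e-8

    def __post_init__(self):
        if not (0.0 < self.bin_threshold < 1.0):
            raise ValueError(f"bin_threshold must lie in (0,1), got {self.bin_threshold}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: float
    tn: float
    fp: float
    fn: float

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Per-image metric rows plus their arithmetic means."""

    per_image: list
    means: dict = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return self.means[name]


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"prediction shape {pred.shape} does not match ground truth shape {gt.shape}")
    return pred, gt


def binarize(pred: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return (np.asarray(pred) > threshold).astype(np.float64)


# -- confusion-matrix metrics ---------------------------------------------

def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Soft confusion counts of a continuous map D against binary G:
    TP = sum(D*G), TN = sum((1-D)(1-G)), FP = sum(D(1-G)), FN = sum((1-D)G)."""
    pred, gt = _check_pair(pred, gt)
    tp = float((pred * gt).sum())
    tn = float(((1 - pred) * (1 - gt)).sum())
    fp = float((pred * (1 - gt)).sum())
    fn = float(((1 - pred) * gt).sum())
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def precision_recall(c: ConfusionCounts, eps: float = 1e-8) -> tuple[float, float]:
    if c.tp + c.fp <= 0 or c.tp + c.fn <= 0:
        logger.warning("degenerate confusion counts (tp=%g fp=%g fn=%g); eps-guarded", c.tp, c.fp, c.fn)
    precision = c.tp / (c.tp + c.fp + eps)
    recall = c.tp / (c.tp + c.fn + eps)
    return precision, recall


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of two binary masks."""
    pred, gt = _check_pair(pred, gt)
    inter = float((pred * gt).sum())
    total = float(pred.sum() + gt.sum())
    if total == 0:
        logger.debug("both masks empty: dice defined as 1")
        return 1.0
    return 2.0 * inter / total


def iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Jaccard overlap |A∩B|/|A∪B| of two binary masks."""
    pred, gt = _check_pair(pred, gt)
    inter = float((pred * gt).sum())
    union = float(pred.sum() + gt.sum()) - inter
    if union == 0:
        logger.debug("both masks empty: iou defined as 1")
        return 1.0
    return inter / union


def mae(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean absolute error of the continuous map against the binary mask."""
    pred, gt = _check_pair(pred, gt)
    return float(np.abs(pred - gt).mean())


def f_beta_weighted(pred: np.ndarray, gt: np.ndarray, cfg: MetricConfig = MetricConfig()) -> float:
    """(1+beta^2) P R / (beta^2 P + R) on soft precision/recall (omega = 1)."""
    c = confusion_counts(pred, gt)
    p, r = precision_recall(c, cfg.eps)
    if p <= 0 and r <= 0:
        return 0.0
    b2 = cfg.f_beta ** 2
    score = (1 + b2) * p * r / (b2 * p + r + cfg.eps)
    return float(np.clip(score, 0.0, 1.0))


# -- structure measure -----------------------------------------------------

def _object_score(x: np.ndarray, lam: float) -> float:
    """2 x̄ / (x̄² + 1 + 2 λ σ_x) over the given pixel set (population sd)."""
    if x.size == 0:
        return 0.0
    mean = float(x.mean())
    sd = float(x.std())
    return 2.0 * mean / (mean * mean + 1.0 + 2.0 * lam * sd)


def _s_object(pred: np.ndarray, gt: np.ndarray, cfg: MetricConfig) -> float:
    fg = _object_score(pred[gt > 0.5], cfg.s_lambda)
    bg = _object_score(1.0 - pred[gt <= 0.5], cfg.s_lambda)
    return cfg.s_mu * fg + (1.0 - cfg.s_mu) * bg


def _gt_centroid(gt: np.ndarray) -> tuple[int, int]:
    h, w = gt.shape
    ys, xs = np.nonzero(gt > 0.5)
    if ys.size == 0:
        return h // 2, w // 2
    # +1 then clamp keeps all four quadrants nonempty
    cy = int(np.round(ys.mean())) + 1
    cx = int(np.round(xs.mean())) + 1
    return min(max(cy, 1), h - 1) if h > 1 else 0, min(max(cx, 1), w - 1) if w > 1 else 0


def _ssim_region(p: np.ndarray, g: np.ndarray) -> float:
    """SSIM-style similarity of one quadrant (sample statistics, N-1)."""
    n = p.size
    if n == 0:
        return 1.0
    mp, mg = float(p.mean()), float(g.mean())
    if n <= 1:
        vp = vg = cov = 0.0
    else:
        vp = float(((p - mp) ** 2).sum() / (n - 1))
        vg = float(((g - mg) ** 2).sum() / (n - 1))
        cov = float(((p - mp) * (g - mg)).sum() / (n - 1))
    num = 4.0 * mp * mg * cov
    den = (mp * mp + mg * mg) * (vp + vg)
    if num != 0.0:
        return num / (den + 1e-12)
    return 1.0 if den == 0.0 else 0.0


def _s_region(pred: np.ndarray, gt: np.ndarray, cfg: MetricConfig) -> float:
    h, w = gt.shape
    cy, cx = _gt_centroid(gt)
    if cy == 0 or cx == 0:  # degenerate 1-pixel-wide axis
        return _ssim_region(pred, gt)
    total = h * w
    score = 0.0
    for ys, xs in (((0, cy), (0, cx)), ((0, cy), (cx, w)), ((cy, h), (0, cx)), ((cy, h), (cx, w))):
        p_q = pred[ys[0]:ys[1], xs[0]:xs[1]]
        g_q = gt[ys[0]:ys[1], xs[0]:xs[1]]
        weight = p_q.size / total
        score += weight * _ssim_region(p_q, g_q)
    return score


def s_measure(pred: np.ndarray, gt: np.ndarray, cfg: MetricConfig = MetricConfig()) -> float:
    """Structure measure S = alpha*S_object + (1-alpha)*S_region.

    Degenerate ground truths follow the structure-measure reference
    fallbacks: an all-background mask scores 1 - mean(pred), an
    all-foreground mask scores mean(pred).
    """
    pred, gt = _check_pair(pred, gt)
    gt_mean = float((gt > 0.5).mean())
    if gt_mean == 0.0:
        return float(np.clip(1.0 - pred.mean(), 0.0, 1.0))
    if gt_mean == 1.0:
        return float(np.clip(pred.mean(), 0.0, 1.0))
    s = cfg.s_alpha * _s_object(pred, gt, cfg) + (1.0 - cfg.s_alpha) * _s_region(pred, gt, cfg)
    return float(np.clip(s, 0.0, 1.0))


# -- alignment (E) measure --------------------------------------------------

def e_measure(pred: np.ndarray, gt: np.ndarray, cfg: MetricConfig = MetricConfig()) -> float:
    """Mean pixel alignment of the mean-centered maps, clamped to [0,1].

    phi_X = X - mean(X); term = 2 phi_G phi_D / (phi_G^2 + phi_D^2).
    Pixels where both centered values vanish contribute 1 (agreement);
    if both maps are constant the score is 1 when they are (numerically)
    equal and 0 otherwise.
    """
    pred, gt = _check_pair(pred, gt)
    phi_g = gt - gt.mean()
    phi_d = pred - pred.mean()
    den = phi_g * phi_g + phi_d * phi_d
    if not np.any(den > 0):
        return 1.0 if np.allclose(pred, gt, atol=cfg.eps) else 0.0
    num = 2.0 * phi_g * phi_d
    terms = np.where(den > 0, num / np.maximum(den, cfg.eps), 1.0)
    return float(np.clip(terms.mean(), 0.0, 1.0))


# -- aggregation ------------------------------------------------------------

def evaluate_pair(pred: np.ndarray, gt: np.ndarray, cfg: MetricConfig = MetricConfig()) -> dict:
    """All six metrics for one prediction/ground-truth pair."""
    pred, gt = _check_pair(pred, gt)
    pred_bin = binarize(pred, cfg.bin_threshold)
    return {
        "dice": dice(pred_bin, gt),
        "iou": iou(pred_bin, gt),
        "mae": mae(pred, gt),
        "f_beta_w": f_beta_weighted(pred, gt, cfg),
        "s_measure": s_measure(pred, gt, cfg),
        "e_measure": e_measure(pred, gt, cfg),
    }


def evaluate_dataset(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                     cfg: MetricConfig = MetricConfig()) -> EvalReport:
    """Per-image six-tuples plus arithmetic means over the dataset."""
    if len(pairs) == 0:
        raise ValueError("evaluate_dataset needs at least one (pred, gt) pair")
    rows = [evaluate_pair(p, g, cfg) for p, g in pairs]
    means = {name: float(np.mean([r[name] for r in rows])) for name in METRIC_NAMES}
    return EvalReport(per_image=rows, means=means)
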