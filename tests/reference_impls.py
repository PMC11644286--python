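"""Independent oracle implementations used only by the test suite.

Deliberately naive: per-pixel double loops and straight-line transliterations
of the published metric recipes, sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def bf_confusion(pred, gt):
    tp = tn = fp = fn = 0.0
    h, w = pred.shape
    for i in range(h):
        for j in range(w):
            d, g = float(pred[i, j]), float(gt[i, j])
            tp += d * g
            tn += (1 - d) * (1 - g)
            fp += d * (1 - g)
            fn += (1 - d) * g
    return tp, tn, fp, fn


def bf_dice(pred_bin, gt):
    inter = a = b = 0.0
    h, w = pred_bin.shape
    for i in range(h):
        for j in range(w):
            p, g = float(pred_bin[i, j]), float(gt[i, j])
            inter += p * g
            a += p
            b += g
    if a + b == 0:
        return 1.0
    return 2 * inter / (a + b)


def bf_iou(pred_bin, gt):
    inter = union = 0.0
    h, w = pred_bin.shape
    for i in range(h):
        for j in range(w):
            p, g = float(pred_bin[i, j]), float(gt[i, j])
            inter += min(p, g)
            union += max(p, g)
    if union == 0:
        return 1.0
    return inter / union


def bf_mae(pred, gt):
    total = 0.0
    h, w = pred.shape
    for i in range(h):
        for j in range(w):
            total += abs(float(pred[i, j]) - float(gt[i, j]))
    return total / (h * w)


def bf_f_beta(pred, gt, beta=0.5):
    tp, _, fp, fn = bf_confusion(pred, gt)
    if tp + fp == 0 or tp + fn == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


def bf_e_measure(pred, gt):
    h, w = pred.shape
    mu_g = sum(float(gt[i, j]) for i in range(h) for j in range(w)) / (h * w)
    mu_d = sum(float(pred[i, j]) for i in range(h) for j in range(w)) / (h * w)
    total = 0.0
    any_nonzero = False
    for i in range(h):
        for j in range(w):
            a = float(gt[i, j]) - mu_g
            b = float(pred[i, j]) - mu_d
            den = a * a + b * b
            if den > 0:
                any_nonzero = True
                total += 2 * a * b / den
            else:
                total += 1.0
    if not any_nonzero:
        return 1.0 if np.allclose(pred, gt, atol=1e-8) else 0.0
    return min(max(total / (h * w), 0.0), 1.0)


# -- structure measure transliteration ------------------------------------

def _ref_object(x, lam):
    if x.size == 0:
        return 0.0
    mean = x.mean()
    sd = x.std()
    return 2.0 * mean / (mean ** 2 + 1.0 + 2.0 * lam * sd)


def _ref_ssim(p, g):
    n = p.size
    if n == 0:
        return 1.0
    mp, mg = p.mean(), g.mean()
    if n <= 1:
        vp = vg = cov = 0.0
    else:
        vp = ((p - mp) ** 2).sum() / (n - 1)
        vg = ((g - mg) ** 2).sum() / (n - 1)
        cov = ((p - mp) * (g - mg)).sum() / (n - 1)
    num = 4 * mp * mg * cov
    den = (mp ** 2 + mg ** 2) * (vp + vg)
    if num != 0:
        return num / (den + 1e-12)
    return 1.0 if den == 0 else 0.0


def ref_s_measure(pred, gt, alpha=0.5, mu=0.5, lam=1.0):
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float) > 0.5
    h, w = gt.shape
    frac = gt.mean()
    if frac == 0:
        return min(max(1.0 - pred.mean(), 0.0), 1.0)
    if frac == 1:
        return min(max(pred.mean(), 0.0), 1.0)

    s_obj = mu * _ref_object(pred[gt], lam) + (1 - mu) * _ref_object(1.0 - pred[~gt], lam)

    ys, xs = np.nonzero(gt)
    cy = int(np.round(ys.mean())) + 1
    cx = int(np.round(xs.mean())) + 1
    cy = min(max(cy, 1), h - 1) if h > 1 else 0
    cx = min(max(cx, 1), w - 1) if w > 1 else 0
    if cy == 0 or cx == 0:
        s_reg = _ref_ssim(pred, gt.astype(float))
    else:
        g = gt.astype(float)
        quads = [
            (pred[:cy, :cx], g[:cy, :cx]),
            (pred[:cy, cx:], g[:cy, cx:]),
            (pred[cy:, :cx], g[cy:, :cx]),
            (pred[cy:, cx:], g[cy:, cx:]),
        ]
        s_reg = sum((p.size / (h * w)) * _ref_ssim(p, q) for p, q in quads)
    s = alpha * s_obj + (1 - alpha) * s_reg
    return min(max(s, 0.0), 1.0)
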