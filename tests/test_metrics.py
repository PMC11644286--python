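"""Metric suite: hand-worked examples, oracle agreement, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mugennet.metrics import (
    MetricConfig,
    binarize,
    confusion_counts,
    dice,
    e_measure,
    evaluate_dataset,
    evaluate_pair,
    f_beta_weighted,
    iou,
    mae,
    precision_recall,
    s_measure,
)
from conftest import random_pair
from reference_impls import (
    bf_confusion,
    bf_dice,
    bf_e_measure,
    bf_f_beta,
    bf_iou,
    bf_mae,
    ref_s_measure,
)

CFG = MetricConfig()


# -- hand-worked examples ---------------------------------------------------

def test_confusion_counts_hand_example():
    d = np.array([[1, 0], [1, 1]], dtype=float)
    g = np.array([[1, 1], [0, 1]], dtype=float)
    c = confusion_counts(d, g)
    assert (c.tp, c.tn, c.fp, c.fn) == (2, 0, 1, 1)


def test_confusion_counts_identity_and_constant(rng):
    g = (rng.random((6, 6)) > 0.5).astype(float)
    c = confusion_counts(g, g)
    assert c.fp == 0 and c.fn == 0 and c.tp == g.sum() and c.tn == (1 - g).sum()
    c = confusion_counts(np.full_like(g, 0.5), g)
    assert np.isclose(c.tp, 0.5 * g.sum()) and np.isclose(c.fp, 0.5 * (1 - g).sum())


def test_confusion_counts_shape_mismatch_names_both():
    with pytest.raises(ValueError, match=r"\(2, 2\).*\(3, 3\)"):
        confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))


def test_precision_recall_hand_example():
    from mugennet.metrics import ConfusionCounts
    p, r = precision_recall(ConfusionCounts(tp=2, tn=0, fp=1, fn=1))
    assert np.isclose(p, 2 / 3) and np.isclose(r, 2 / 3)
    p, r = precision_recall(ConfusionCounts(tp=4, tn=5, fp=0, fn=0))
    assert np.isclose(p, 1, atol=1e-6) and np.isclose(r, 1, atol=1e-6)
    p, _ = precision_recall(ConfusionCounts(tp=0, tn=0, fp=3, fn=0))
    assert p == 0


def test_dice_iou_hand_examples():
    left = np.zeros((4, 4)); left[:, :2] = 1
    top = np.zeros((4, 4)); top[:2, :] = 1
    assert dice(left, top) == pytest.approx(0.5)       # overlap 4, sizes 8+8
    assert iou(left, top) == pytest.approx(1 / 3)      # 4 / 12
    assert dice(top, top) == 1.0 and iou(top, top) == 1.0
    disjoint = 1 - top
    assert dice(top, disjoint) == 0.0
    # both-empty convention
    z = np.zeros((3, 3))
    assert dice(z, z) == 1.0 and iou(z, z) == 1.0


def test_mae_trivial_cases(rng):
    g = (rng.random((5, 5)) > 0.4).astype(float)
    assert mae(g, g) == 0.0
    assert mae(np.full_like(g, 0.5), g) == pytest.approx(0.5)
    assert mae(1 - g, g) == pytest.approx(1.0)


def test_f_beta_weighted_examples(rng):
    g = (rng.random((8, 8)) > 0.5).astype(float)
    assert f_beta_weighted(g, g) == pytest.approx(1.0, abs=1e-6)
    # P=R implies F=P for any beta: build a map with symmetric errors
    d = np.array([[1, 0.0], [1, 1]], dtype=float)
    gt = np.array([[1, 1.0], [0, 1]], dtype=float)
    assert f_beta_weighted(d, gt) == pytest.approx(2 / 3, abs=1e-6)
    assert f_beta_weighted(1 - g, g) == pytest.approx(0.0, abs=1e-6)


def test_s_measure_plugged_constants(rng):
    g = np.zeros((8, 8)); g[2:6, 2:6] = 1
    # pred == gt: object term hits its maximum of 1
    assert s_measure(g, g) == pytest.approx(1.0, abs=1e-6)
    # constant 0.5 prediction: S_FG = S_BG = 0.8 so the object term is 0.8
    from mugennet.metrics import _s_object
    assert _s_object(np.full((8, 8), 0.5), g, CFG) == pytest.approx(0.8)


def test_s_measure_degenerate_gt():
    pred = np.full((6, 6), 0.3)
    assert s_measure(pred, np.zeros((6, 6))) == pytest.approx(0.7)
    assert s_measure(pred, np.ones((6, 6))) == pytest.approx(0.3)


def test_e_measure_identity_and_inversion():
    g = np.zeros((6, 6)); g[:3, :] = 1          # balanced mask
    assert e_measure(g, g) == 1.0
    assert e_measure(1 - g, g) == 0.0           # every aligned term is -1, clamped
    # both constant: equal -> 1, different -> 0
    assert e_measure(np.ones((4, 4)), np.ones((4, 4))) == 1.0
    assert e_measure(np.zeros((4, 4)), np.ones((4, 4))) == 0.0


# -- oracle agreement -------------------------------------------------------

def test_all_metrics_match_bruteforce_oracles(rng):
    for _ in range(50):
        pred, gt = random_pair(rng, 8, 8)
        pred_bin = binarize(pred)
        assert dice(pred_bin, gt) == pytest.approx(bf_dice(pred_bin, gt), abs=1e-9)
        assert iou(pred_bin, gt) == pytest.approx(bf_iou(pred_bin, gt), abs=1e-9)
        assert mae(pred, gt) == pytest.approx(bf_mae(pred, gt), abs=1e-9)
        assert f_beta_weighted(pred, gt) == pytest.approx(bf_f_beta(pred, gt), abs=1e-6)
        assert e_measure(pred, gt) == pytest.approx(bf_e_measure(pred, gt), abs=1e-9)
        assert s_measure(pred, gt) == pytest.approx(
            ref_s_measure(pred, gt, CFG.s_alpha, CFG.s_mu, CFG.s_lambda), abs=1e-6)


def test_confusion_matches_bruteforce(rng):
    pred, gt = random_pair(rng, 7, 9)
    c = confusion_counts(pred, gt)
    tp, tn, fp, fn = bf_confusion(pred, gt)
    np.testing.assert_allclose([c.tp, c.tn, c.fp, c.fn], [tp, tn, fp, fn], atol=1e-9)


# -- invariants -------------------------------------------------------------

@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(0, 2 ** 31 - 1))
def test_binary_pair_invariants(seed):
    rng = np.random.default_rng(seed)
    a = (rng.random((8, 8)) > rng.uniform(0.1, 0.9)).astype(float)
    b = (rng.random((8, 8)) > rng.uniform(0.1, 0.9)).astype(float)
    # symmetry
    assert dice(a, b) == pytest.approx(dice(b, a))
    assert iou(a, b) == pytest.approx(iou(b, a))
    assert mae(a, b) == pytest.approx(mae(b, a))
    # algebraic identity between the two overlap scores
    j = iou(a, b)
    assert dice(a, b) == pytest.approx(2 * j / (1 + j), abs=1e-12)
    # precision and recall swap when the binary pair is exchanged
    pa, ra = precision_recall(confusion_counts(a, b))
    pb, rb = precision_recall(confusion_counts(b, a))
    assert pa == pytest.approx(rb, abs=1e-6) and ra == pytest.approx(pb, abs=1e-6)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(0, 2 ** 31 - 1))
def test_conservation_and_bounds(seed):
    rng = np.random.default_rng(seed)
    pred, gt = random_pair(rng, 8, 8)
    c = confusion_counts(pred, gt)
    assert c.total == pytest.approx(pred.size, abs=1e-6)
    row = evaluate_pair(pred, gt)
    for name, value in row.items():
        assert np.isfinite(value)
        if name != "mae":
            assert 0.0 <= value <= 1.0
        else:
            assert value >= 0.0


def test_monotonicity_toward_gt(rng):
    gt = (rng.random((10, 10)) > 0.6).astype(float)
    pred = rng.random((10, 10))
    better = pred + 0.25 * (gt - pred)  # move every pixel toward the truth
    assert mae(better, gt) <= mae(pred, gt)
    assert dice(binarize(better), gt) >= dice(binarize(pred), gt) - 1e-12


# -- aggregation ------------------------------------------------------------

def test_evaluate_dataset_means(rng):
    pred, gt = random_pair(rng)
    single = evaluate_dataset([(pred, gt)])
    assert single.means == single.per_image[0]
    doubled = evaluate_dataset([(pred, gt), (pred, gt)])
    for k in single.means:
        assert doubled.means[k] == pytest.approx(single.means[k])
    g1 = np.ones((4, 4)); g0 = np.zeros((4, 4)); g0[0, 0] = 1
    two = evaluate_dataset([(g1, g1), (1 - g0, g0)])
    assert two.means["dice"] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        evaluate_dataset([])


def test_config_validation():
    with pytest.raises(ValueError):
        MetricConfig(bin_threshold=1.5)
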