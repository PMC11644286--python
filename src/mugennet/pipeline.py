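"""Training, evaluation, prediction, and ablation orchestration.

The training loop follows the protocol of the published experiments
(adaptive-moment optimiser, sigmoid output, deep supervision over the
transformer, CNN, and fused side outputs; best checkpoint selected by
validation mean Dice), scaled down by the `desk` preset for CPU runs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .config import ABLATIONS, RunConfig
from .data import SplitData, load_image
from .losses import total_loss
from .metrics import EvalReport, MetricConfig, evaluate_dataset, METRIC_NAMES
from .model import MugenNet, build_model
from .nn import Tensor

logger = logging.getLogger(__name__)


@dataclass
class TrainLog:
    steps: list = field(default_factory=list)        # per-step loss breakdown records
    epoch_train_loss: list = field(default_factory=list)
    val_reports: list = field(default_factory=list)  # per-epoch EvalReport (or None)
    best_checkpoint: str | None = None
    last_checkpoint: str | None = None

    @property
    def first_step_loss(self) -> float:
        return self.steps[0]["total"]


def _forward_outputs(model: MugenNet, images: np.ndarray):
    state = model(Tensor(images))
    outputs = {}
    for name, t in state.outputs().items():
        b = t.shape[0]
        outputs[name] = t.reshape(b, t.shape[2], t.shape[3])
    return state, outputs


def predict_maps(model: MugenNet, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Sigmoid probability maps (N, H, W) for a stack of images, inference mode."""
    model.eval()
    preds = []
    with nn.no_grad():
        for i in range(0, len(images), batch_size):
            state = model(Tensor(images[i:i + batch_size]))
            preds.append(state.zout.data[:, 0])
    model.train()
    return np.concatenate(preds) if preds else np.zeros((0,) + images.shape[2:])


def evaluate_model(model: MugenNet, split: SplitData, cfg: MetricConfig = MetricConfig(),
                   batch_size: int = 16) -> EvalReport:
    preds = predict_maps(model, split.images, batch_size)
    return evaluate_dataset(list(zip(preds, split.masks)), cfg)


def train(cfg: RunConfig, data: dict[str, SplitData], out_dir=None,
          max_steps: int | None = None, model: MugenNet | None = None) -> tuple[MugenNet, TrainLog]:
    """Optimise the deep-supervision loss; returns the trained model and log.

    Deterministic given cfg.seed: model init, batch order, and therefore
    every logged loss value are reproducible.
    """
    train_split = data["train"]
    if len(train_split) == 0:
        raise ValueError("empty training split")
    model = model or build_model(cfg.model)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    log = TrainLog()
    out_dir = Path(out_dir) if out_dir is not None else None
    best_dice = -1.0
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_split))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            _, outputs = _forward_outputs(model, train_split.images[sel])
            loss, breakdown = total_loss(outputs, train_split.masks[sel], cfg.loss)
            if not np.isfinite(breakdown.total):
                raise RuntimeError(f"non-finite loss at step {step}: {breakdown.as_record()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            rec = {"step": step, "epoch": epoch, **breakdown.as_record()}
            log.steps.append(rec)
            epoch_losses.append(breakdown.total)
            logger.info("step %d epoch %d L_IoU=%.4f L_BCE=%.4f L_total=%.4f",
                        step, epoch,
                        breakdown.per_output.get("s_z", (np.nan,))[0],
                        breakdown.per_output.get("s_z", (0, np.nan))[1],
                        breakdown.total)
            step += 1
            if max_steps is not None and step >= max_steps:
                break
        log.epoch_train_loss.append(float(np.mean(epoch_losses)))
        if len(data.get("val", SplitData(np.zeros((0,)), np.zeros((0,)), []))) > 0:
            report = evaluate_model(model, data["val"], cfg.metric, cfg.batch_size)
            log.val_reports.append(report)
            if out_dir is not None and report.means["dice"] > best_dice:
                best_dice = report.means["dice"]
                model.save(out_dir / "best.npz")
                log.best_checkpoint = str(out_dir / "best.npz")
        else:
            log.val_reports.append(None)
        if max_steps is not None and step >= max_steps:
            break
    if out_dir is not None:
        model.save(out_dir / "last.npz")
        log.last_checkpoint = str(out_dir / "last.npz")
        _write_step_log(log, out_dir / "train_log.csv")
    return model, log


def _write_step_log(log: TrainLog, path) -> None:
    if not log.steps:
        return
    keys = sorted({k for rec in log.steps for k in rec})
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(log.steps)


def write_eval_csv(report: EvalReport, ids, path) -> None:
    """Per-image metric rows plus a final mean row; flags IoU > 0.5 detections."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id"] + list(METRIC_NAMES) + ["valid_detection"])
        for sid, row in zip(ids, report.per_image):
            writer.writerow([sid] + [f"{row[m]:.6f}" for m in METRIC_NAMES]
                            + [str(row["iou"] > 0.5).lower()])
        writer.writerow(["mean"] + [f"{report.means[m]:.6f}" for m in METRIC_NAMES] + [""])


def evaluate_checkpoint(checkpoint, split: SplitData, cfg: RunConfig, out_csv=None) -> EvalReport:
    model = build_model(cfg.model)
    model.load(checkpoint)
    report = evaluate_model(model, split, cfg.metric, cfg.batch_size)
    if out_csv is not None:
        write_eval_csv(report, split.ids, out_csv)
    return report


def predict(checkpoint, image_paths, out_dir, cfg: RunConfig, threshold: float = 0.5) -> list:
    """Write sigmoid probability maps and thresholded masks as PNGs.

    Outputs are resized back to each input's native resolution.  Unreadable
    inputs are reported and skipped.
    """
    model = build_model(cfg.model)
    model.load(checkpoint)
    model.eval()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for path in image_paths:
        path = Path(path)
        try:
            with Image.open(path) as im:
                orig_w, orig_h = im.size
            arr = load_image(path, cfg.input_size)
        except Exception as exc:  # per-file error, continue with the rest
            logger.error("cannot read %s: %s", path, exc)
            continue
        with nn.no_grad():
            prob = model(Tensor(arr[None])).zout.data[0, 0]
        prob_img = Image.fromarray(np.round(prob * 255).astype(np.uint8))
        prob_img = prob_img.resize((orig_w, orig_h), Image.BILINEAR)
        mask_img = Image.fromarray(((np.asarray(prob_img) / 255.0) > threshold).astype(np.uint8) * 255)
        prob_path = out_dir / f"{path.stem}_prob.png"
        mask_path = out_dir / f"{path.stem}_mask.png"
        prob_img.save(prob_path)
        mask_img.save(mask_path)
        written.append((prob_path, mask_path))
    return written


def ablation_suite(cfg: RunConfig, data: dict[str, SplitData], out_csv=None) -> list[dict]:
    """Train/evaluate the four ablation configurations under one protocol.

    Emits one row per configuration with mDice, mIoU, F_beta^w (on the
    evaluation split) and the parameter count.
    """
    from dataclasses import replace
    rows = []
    eval_split = data["test"] if len(data.get("test", [])) else data["train"]
    for ablation in ABLATIONS:
        run_cfg = replace(cfg, model=replace(cfg.model, ablation=ablation))
        model, log = train(run_cfg, data)
        report = evaluate_model(model, eval_split, cfg.metric, cfg.batch_size)
        rows.append({
            "setting": ablation,
            "mDice": report.means["dice"],
            "mIoU": report.means["iou"],
            "f_beta_w": report.means["f_beta_w"],
            "n_params": model.n_parameters(),
            "final_train_loss": log.epoch_train_loss[-1],
        })
        logger.info("ablation %-12s mDice=%.3f mIoU=%.3f Fbw=%.3f params=%d",
                    ablation, rows[-1]["mDice"], rows[-1]["mIoU"],
                    rows[-1]["f_beta_w"], rows[-1]["n_params"])
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return rows
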