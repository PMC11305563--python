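"""Minimal SGD training loop exercising the architecture end to end.

The optimization schedule follows the study conditions: stochastic gradient
descent with momentum 0.937 and weight decay 5e-4, a 3-epoch linear warm-up
(bias groups ramp from 0.1, others from 0, to the initial rate 0.01), then a
linear decay to the final rate 1e-4; batch size 32; mosaic-style augmentation
disabled over the final ``close_mosaic_epochs`` epochs.

The loss is a composite of the anchor-free family: an L1 + distribution-bin
cross-entropy box term, binary cross-entropy class/objectness and keypoint
visibility terms, and an OKS-kernel keypoint-location term.  Positive cells
are assigned by the box center (one cell per instance on the level whose bin
range fits the box) -- the toy-scale assignment strategy; the loop is meant to
demonstrate optimization behaviour on synthetic scenes at small resolution,
not to reproduce full-scale accuracy.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from . import data_io, metrics
from .network import REG_MAX, STRIDES, CattlePoseModel, DensePrediction, decode
from .nn import Module, Tensor
from .nn import autograd as ag
from .nn.modules import BatchNorm2d, Conv2d
from .synthetic import DatasetManifest
from .types import KeypointInstance


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    lr0: float = 0.01
    lr_final: float = 0.0001
    warmup_epochs: int = 3
    warmup_bias_lr: float = 0.1
    momentum: float = 0.937
    weight_decay: float = 0.0005
    close_mosaic_epochs: int = 10
    mosaic: bool = True
    seed: int = 0
    # loss gains (anchor-free family defaults)
    box_gain: float = 7.5
    cls_gain: float = 0.5
    dfl_gain: float = 1.5
    pose_gain: float = 12.0
    kobj_gain: float = 1.0
    val_interval: int = 5

    def __post_init__(self):
        if self.lr_final > self.lr0:
            raise ValueError("lr_final must be <= lr0")
        if self.warmup_epochs >= self.epochs:
            raise ValueError("warmup_epochs must be < epochs")


def lr_schedule(epoch: int, config: TrainConfig, group: str = "weights") -> float:
    """Learning rate at ``epoch``: linear warm-up then linear decay to lr_final.

    Bias parameter groups warm up from ``warmup_bias_lr``; all others from 0.
    """
    if not 0 <= epoch < config.epochs:
        raise ValueError("epoch out of range")
    if epoch < config.warmup_epochs:
        start = config.warmup_bias_lr if group == "bias" else 0.0
        frac = epoch / config.warmup_epochs
        return start + (config.lr0 - start) * frac
    last = config.epochs - 1
    if last == config.warmup_epochs:
        return config.lr_final
    t = (epoch - config.warmup_epochs) / (last - config.warmup_epochs)
    return config.lr0 + (config.lr_final - config.lr0) * t


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class SGD:
    """Momentum SGD with three parameter groups (conv weights with weight
    decay; BN gains without; biases without, with their own warm-up ramp)."""

    def __init__(self, model: Module, config: TrainConfig):
        self.config = config
        self.groups: dict[str, list] = {"weights": [], "bn": [], "bias": []}
        for m in model.modules():
            for name, p in m._params.items():
                if isinstance(m, BatchNorm2d):
                    self.groups["bn"].append(p)
                elif name == "bias":
                    self.groups["bias"].append(p)
                else:
                    self.groups["weights"].append(p)
        self.velocity = {id(p): np.zeros_like(p.data)
                         for ps in self.groups.values() for p in ps}

    def step(self, epoch: int) -> None:
        cfg = self.config
        for gname, params in self.groups.items():
            lr = lr_schedule(epoch, cfg, "bias" if gname == "bias" else "weights")
            for p in params:
                if p.grad is None:
                    continue
                g = p.grad
                if gname == "weights" and cfg.weight_decay:
                    g = g + cfg.weight_decay * p.data
                v = self.velocity[id(p)]
                v *= cfg.momentum
                v += g
                p.data -= (lr * v).astype(np.float32)


# ---------------------------------------------------------------------------
# data pipeline
# ---------------------------------------------------------------------------

@dataclass
class Sample:
    image: np.ndarray  # float32 CHW in [0,1]
    instances: list[KeypointInstance]


def load_samples(manifest: DatasetManifest) -> list[Sample]:
    samples = []
    root = Path(manifest.root)
    for entry in manifest.entries:
        img = np.asarray(Image.open(root / entry["image"]), dtype=np.float32) / 255.0
        img = img.transpose(2, 0, 1)
        size = entry["image_size"]
        records = data_io.read_yolo(root / entry["labels"])
        insts = [data_io.record_to_instance(r, size, size) for r in records]
        samples.append(Sample(img, insts))
    return samples


def mosaic_batch(samples: Sequence[Sample], rng: np.random.Generator) -> Sample:
    """Compose four samples into one (2x2, each downscaled by 2)."""
    picks = [samples[i] for i in rng.integers(0, len(samples), size=4)]
    c, h, w = picks[0].image.shape
    canvas = np.zeros((c, h, w), dtype=np.float32)
    insts: list[KeypointInstance] = []
    for q, s in enumerate(picks):
        oy, ox = (q // 2) * (h // 2), (q % 2) * (w // 2)
        canvas[:, oy:oy + h // 2, ox:ox + w // 2] = s.image[:, ::2, ::2]
        for inst in s.instances:
            kp = inst.keypoints.copy()
            kp[:, 0] = kp[:, 0] / 2 + ox
            kp[:, 1] = kp[:, 1] / 2 + oy
            x, y, bw, bh = inst.box
            insts.append(KeypointInstance(
                (x / 2 + ox, y / 2 + oy, bw / 2, bh / 2), 1.0, kp))
    return Sample(canvas, insts)


def _assign_level(box, input_size: int) -> int:
    """Smallest pyramid level whose bin range can represent the box."""
    for li, stride in enumerate(STRIDES):
        if max(box[2], box[3]) / stride < 2 * (REG_MAX - 1):
            return li
    return len(STRIDES) - 1


@dataclass
class LossBreakdown:
    box: float = 0.0
    cls: float = 0.0
    dfl: float = 0.0
    kpt_location: float = 0.0
    kpt_visibility: float = 0.0
    total: float = 0.0


def _bce(logits, targets) -> "ag.Tensor":
    p = ag.sigmoid(logits)
    return -(targets * ag.log(p) + (1.0 - targets) * ag.log(1.0 - p))


def compute_loss(pred: DensePrediction, batch: Sequence[Sample],
                 input_size: int, config: TrainConfig
                 ) -> tuple["ag.Tensor", LossBreakdown]:
    """Composite pose loss with center-cell positive assignment."""
    nk = pred.num_keypoints
    total_pos = 0
    cls_terms, box_terms, dfl_terms, kloc_terms, kvis_terms = [], [], [], [], []
    for li, ((box_t, cls_t, kpt_t), stride) in enumerate(
            zip(pred.levels, pred.strides)):
        _, _, h, w = cls_t.shape
        cls_target = np.zeros(cls_t.shape, dtype=np.float32)
        pos = []  # (batch, gy, gx, instance)
        for bi, sample in enumerate(batch):
            for inst in sample.instances:
                if _assign_level(inst.box, input_size) != li:
                    continue
                cx = inst.box[0] + inst.box[2] / 2
                cy = inst.box[1] + inst.box[3] / 2
                gx, gy = int(cx // stride), int(cy // stride)
                if not (0 <= gx < w and 0 <= gy < h):
                    continue
                cls_target[bi, 0, gy, gx] = 1.0
                pos.append((bi, gy, gx, inst))
        cls_terms.append(ag.mean(_bce(cls_t, cls_target)) * (h * w))
        if not pos:
            continue
        total_pos += len(pos)
        b_idx = np.array([p[0] for p in pos])
        gy_idx = np.array([p[1] for p in pos])
        gx_idx = np.array([p[2] for p in pos])
        # gather per-positive raw vectors: (P, C)
        def gather(t):
            cdim = t.shape[1]
            return ag.getitem(t, (b_idx[:, None], np.arange(cdim)[None, :],
                                  gy_idx[:, None], gx_idx[:, None]))
        box_p = gather(box_t)  # (P, 64)
        kpt_p = gather(kpt_t)  # (P, nk*3)
        # ---- box: expected side distances vs target, plus DFL on the bins
        t_ltrb = np.zeros((len(pos), 4), dtype=np.float32)
        for pi, (bi, gy, gx, inst) in enumerate(pos):
            cx, cy = (gx + 0.5) * stride, (gy + 0.5) * stride
            x1, y1, bw, bh = inst.box
            t_ltrb[pi] = ((cx - x1) / stride, (cy - y1) / stride,
                          (x1 + bw - cx) / stride, (y1 + bh - cy) / stride)
        t_ltrb = np.clip(t_ltrb, 0.0, REG_MAX - 1.01)
        dist = ag.softmax(ag.reshape(box_p, (len(pos), 4, REG_MAX)), axis=2)
        proj = np.arange(REG_MAX, dtype=np.float32)[None, None, :]
        e_ltrb = ag.sum_(dist * proj, axis=2)
        diff = e_ltrb - t_ltrb
        box_terms.append(ag.mean((diff * diff + 1e-9) ** 0.5))
        # DFL: cross-entropy against the two integer bins bracketing the target
        lo = np.floor(t_ltrb).astype(int)
        hi = np.minimum(lo + 1, REG_MAX - 1)
        w_hi = (t_ltrb - lo).astype(np.float32)
        w_lo = 1.0 - w_hi
        pi_idx = np.arange(len(pos))[:, None]
        side_idx = np.arange(4)[None, :]
        p_lo = ag.getitem(dist, (pi_idx, side_idx, lo))
        p_hi = ag.getitem(dist, (pi_idx, side_idx, hi))
        dfl_terms.append(ag.mean(-(w_lo * ag.log(p_lo) + w_hi * ag.log(p_hi))))
        # ---- keypoints: OKS-kernel location loss + visibility BCE
        kpt_p = ag.reshape(kpt_p, (len(pos), nk, 3))
        t_xy = np.zeros((len(pos), nk, 2), dtype=np.float32)
        t_vis = np.zeros((len(pos), nk), dtype=np.float32)
        area = np.zeros((len(pos), 1), dtype=np.float32)
        for pi, (bi, gy, gx, inst) in enumerate(pos):
            kp = inst.keypoints
            t_vis[pi] = (kp[:, 2] > 0).astype(np.float32)
            # invert the decode convention: p = (x/stride - gx) / 2
            t_xy[pi, :, 0] = (kp[:, 0] / stride - gx) / 2.0
            t_xy[pi, :, 1] = (kp[:, 1] / stride - gy) / 2.0
            area[pi] = max(inst.area, 1.0)
        pred_xy = ag.narrow(kpt_p, 2, 0, 2)
        d2 = ag.sum_((pred_xy - t_xy) * (pred_xy - t_xy), axis=2)  # stride units/2
        d2_px = d2 * (4.0 * stride * stride)
        sigma2 = area * (0.1 ** 2)  # s^2 k^2 with uniform k = 0.1
        kernel = ag.exp(d2_px * (-1.0 / (2.0 * sigma2)))
        vis_w = t_vis / np.maximum(t_vis.sum(axis=1, keepdims=True), 1.0)
        # the Gaussian kernel's gradient vanishes far from the target; a small
        # scale-normalized quadratic term keeps distant keypoints moving
        quad = d2_px * (0.1 / area)
        kloc_terms.append(
            ag.sum_((1.0 - kernel + quad) * vis_w) * (1.0 / len(pos)))
        v_logit = ag.narrow(kpt_p, 2, 2, 1)
        kvis_terms.append(ag.mean(_bce(ag.reshape(v_logit, t_vis.shape), t_vis)))

    n_cells = sum(b.shape[2] * b.shape[3] for b, _, _ in pred.levels)
    cls_loss = sum(cls_terms[1:], cls_terms[0]) * (1.0 / n_cells)

    def _avg(terms):
        if not terms:
            return None
        out = terms[0]
        for t in terms[1:]:
            out = out + t
        return out * (1.0 / len(terms))

    box_loss, dfl_loss = _avg(box_terms), _avg(dfl_terms)
    kloc_loss, kvis_loss = _avg(kloc_terms), _avg(kvis_terms)
    total = cls_loss * config.cls_gain
    bd = LossBreakdown(cls=cls_loss.item() * config.cls_gain)
    if box_loss is not None:
        total = (total + box_loss * config.box_gain + dfl_loss * config.dfl_gain
                 + kloc_loss * config.pose_gain + kvis_loss * config.kobj_gain)
        bd.box = box_loss.item() * config.box_gain
        bd.dfl = dfl_loss.item() * config.dfl_gain
        bd.kpt_location = kloc_loss.item() * config.pose_gain
        bd.kpt_visibility = kvis_loss.item() * config.kobj_gain
    bd.total = total.item()
    return total, bd


# ---------------------------------------------------------------------------
# validation + loop
# ---------------------------------------------------------------------------

def validate(model: CattlePoseModel, samples: Sequence[Sample],
             conf_threshold: float = 0.25) -> float:
    """AP_0.5 of decoded predictions on ``samples``."""
    was_training = model.training
    model.eval()
    dataset = []
    with ag.no_grad():
        for s in samples:
            pred = model(Tensor(s.image[None]))
            dets = decode(pred, conf_threshold=conf_threshold, iou_threshold=0.7)
            gts = [g for g in s.instances if (g.keypoints[:, 2] > 0).any()]
            if gts:
                dataset.append((gts, dets[: 3 * len(gts)]))
    if was_training:
        model.train()
    if not dataset:
        return 0.0
    return metrics.evaluate(dataset).ap50


@dataclass
class TrainResult:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_ap50: list[float] = field(default_factory=list)
    mosaic_flags: list[bool] = field(default_factory=list)
    best_ap50: float = 0.0
    best_state: Optional[dict] = None
    breakdowns: list[LossBreakdown] = field(default_factory=list)


def train(model: CattlePoseModel, manifest: DatasetManifest,
          config: TrainConfig, val_fraction: float = 0.1,
          log_path=None) -> TrainResult:
    """Train on a synthetic dataset manifest; retain the best-AP_0.5 state."""
    samples = load_samples(manifest)
    if not samples:
        raise ValueError("empty manifest")
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(len(samples) * val_fraction))
    val_samples, train_samples = samples[:n_val], samples[n_val:]
    input_size = samples[0].image.shape[1]
    optimizer = SGD(model, config)
    model.train()
    result = TrainResult()
    rows = []
    for epoch in range(config.epochs):
        mosaic_on = (config.mosaic
                     and epoch < config.epochs - config.close_mosaic_epochs)
        result.mosaic_flags.append(mosaic_on)
        order = rng.permutation(len(train_samples))
        losses = []
        bd = LossBreakdown()
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [train_samples[i] for i in idx]
            if mosaic_on:
                batch = [mosaic_batch(train_samples, rng) if rng.random() < 0.5
                         else b for b in batch]
            x = Tensor(np.stack([b.image for b in batch]))
            pred = model(x)
            loss, bd = compute_loss(pred, batch, input_size, config)
            if not math.isfinite(bd.total):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}: {bd}")
            model.zero_grad()
            loss.backward()
            optimizer.step(epoch)
            losses.append(bd.total)
        epoch_loss = float(np.mean(losses))
        result.epoch_loss.append(epoch_loss)
        result.breakdowns.append(bd)
        ap50 = -1.0
        if (epoch + 1) % config.val_interval == 0 or epoch == config.epochs - 1:
            ap50 = validate(model, val_samples)
            result.epoch_ap50.append(ap50)
            if ap50 >= result.best_ap50:
                result.best_ap50 = ap50
                result.best_state = {k: v.copy()
                                     for k, v in model.state_dict().items()}
        rows.append({"epoch": epoch, "loss": epoch_loss, "ap50": ap50,
                     "mosaic": int(mosaic_on),
                     "lr": lr_schedule(epoch, config)})
    if result.best_state is None:
        result.best_state = model.state_dict()
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    return result
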