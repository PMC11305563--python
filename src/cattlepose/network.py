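"""Model assembly: backbone, necks, pose head, decoding and complexity counts.

Two configurations are built from the same parts:

* ``pan_baseline`` -- the standard n-scale anchor-free pose network: a
  CSP-style backbone (stem, C2f stages, SPPF) feeding a PAN neck of upsample /
  concat / C2f blocks, and a decoupled head predicting a 16-bin distribution
  per box side, a class score, and 16 x (x, y, visibility) keypoint fields on
  the P3/P4/P5 grids.
* ``efficient_rep_bipan`` -- the lightweight neck: 1x1 reduce layers, BiFusion
  units blending three neighbouring pyramid levels (learned transposed-conv
  upsample of the deeper map, 1x1 projection of the current map, strided-conv
  downsample of the shallower backbone tap) and reparameterizable RepBlocks on
  both the top-down and bottom-up paths.

A parameter-free SimAM operator can be appended after the C2f block of any of
the stages feeding the P3/P4/P5 taps (before SPPF at P5).

Complexity accounting: ``count_parameters`` counts learnable scalars exactly;
``count_flops`` counts one multiply-accumulate as two floating-point
operations, for a batch-1 forward at the requested square input size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .attention import SimAM
from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, MaxPool2d, Module,
                 ModuleList, Sequential, SiLU, Tensor, UpsampleNearest2)
from .nn import autograd as ag
from .nn.modules import _Profiler
from .reparam import RepBlock
from .types import KeypointInstance


class InvalidInputError(ValueError):
    """Input spatial size incompatible with the network stride."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

NECKS = ("pan_baseline", "efficient_rep_bipan")


@dataclass(frozen=True)
class ModelConfig:
    """Fully determines the assembled model (and hence its complexity counts).

    The committed reference values pin the n-scale family: depth 1/3,
    width 1/4, max 1024 channels.  ``neck_channels`` are the widths of the
    EfficientRepBiPAN stages (top-down P4, top-down P3, bottom-up P4,
    bottom-up P5) and ``repblock_depths`` the unit counts of its four
    RepBlocks, in the same order.
    """

    depth_multiple: float = 1.0 / 3.0
    width_multiple: float = 0.25
    max_channels: int = 1024
    num_classes: int = 1
    num_keypoints: int = 16
    keypoint_dims: int = 3
    simam_stages: tuple[str, ...] = ()
    simam_omega: float = 1e-4
    neck: str = "pan_baseline"
    neck_channels: tuple[int, int, int, int] = (64, 32, 56, 128)
    repblock_depths: tuple[int, int, int, int] = (4, 4, 5, 5)
    input_size: int = 640

    def __post_init__(self):
        if self.depth_multiple <= 0 or self.width_multiple <= 0:
            raise ValueError("multipliers must be > 0")
        if self.neck not in NECKS:
            raise ValueError(f"neck must be one of {NECKS}")
        if set(self.simam_stages) - {"P3", "P4", "P5"}:
            raise ValueError("simam_stages must be a subset of {P3,P4,P5}")

    # -- scaling helpers -----------------------------------------------------
    def width(self, c: int) -> int:
        c = min(c, self.max_channels)
        return _make_divisible(c * self.width_multiple, 8)

    def depth(self, n: int) -> int:
        return max(round(n * self.depth_multiple), 1)


def baseline_config(**overrides) -> ModelConfig:
    """The reference baseline: PAN neck, no attention."""
    return replace(ModelConfig(), **overrides)


def improved_config(**overrides) -> ModelConfig:
    """The reference improved model: SimAM at P3/P4/P5 + EfficientRepBiPAN."""
    cfg = ModelConfig(simam_stages=("P3", "P4", "P5"),
                      neck="efficient_rep_bipan")
    return replace(cfg, **overrides)


def _make_divisible(x: float, divisor: int) -> int:
    return max(divisor, int(x + divisor / 2) // divisor * divisor)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def autopad(k: int) -> int:
    return k // 2


class ConvBNAct(Module):
    """Conv (no bias) + BatchNorm + SiLU, the backbone's basic unit."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, stride=s,
                           padding=autopad(k) if p is None else p, bias=False)
        self.bn = BatchNorm2d(c2)
        self.act = SiLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Bottleneck(Module):
    def __init__(self, c1: int, c2: int, shortcut: bool = True, e: float = 0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBNAct(c1, c_, 3)
        self.cv2 = ConvBNAct(c_, c2, 3)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    """Cross-stage-partial block: split, run n bottlenecks, concatenate."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = False,
                 e: float = 0.5):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = ConvBNAct(c1, 2 * self.c, 1)
        self.cv2 = ConvBNAct((2 + n) * self.c, c2, 1)
        self.m = ModuleList(Bottleneck(self.c, self.c, shortcut, e=1.0)
                            for _ in range(n))

    def forward(self, x):
        y = self.cv1(x)
        ys = [ag.narrow(y, 1, 0, self.c), ag.narrow(y, 1, self.c, self.c)]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(ag.concat(ys, axis=1))


class SPPF(Module):
    """Serial max-pool spatial pyramid pooling."""

    def __init__(self, c1: int, c2: int, k: int = 5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBNAct(c1, c_, 1)
        self.cv2 = ConvBNAct(4 * c_, c2, 1)
        self.pool = MaxPool2d(k, stride=1, padding=k // 2)

    def forward(self, x):
        y0 = self.cv1(x)
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(ag.concat([y0, y1, y2, y3], axis=1))


class BiFusion(Module):
    """Fuse three neighbouring pyramid levels to the middle one's stride.

    deep (2x coarser) is upsampled by a learned transposed convolution,
    current is projected 1x1, shallow (2x finer) is projected 1x1 then
    downsampled by a stride-2 conv; the concatenation is projected to
    ``out_channels``.
    """

    def __init__(self, deep_ch: int, current_ch: int, shallow_ch: int,
                 out_channels: int):
        super().__init__()
        self.upsample = ConvTranspose2d(deep_ch, out_channels, 2, 2)
        self.cv_current = ConvBNAct(current_ch, out_channels, 1)
        self.cv_shallow = ConvBNAct(shallow_ch, out_channels, 1)
        self.downsample = ConvBNAct(out_channels, out_channels, 3, 2)
        self.cv_out = ConvBNAct(3 * out_channels, out_channels, 1)

    def forward(self, deep: Tensor, current: Tensor, shallow: Tensor) -> Tensor:
        if (deep.shape[2] * 2 != current.shape[2]
                or shallow.shape[2] != current.shape[2] * 2):
            raise InvalidInputError("BiFusion stride relationship violated")
        up = self.upsample(deep)
        cur = self.cv_current(current)
        down = self.downsample(self.cv_shallow(shallow))
        return self.cv_out(ag.concat([up, cur, down], axis=1))


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

class Backbone(Module):
    """CSP backbone with optional SimAM after the P3/P4/P5-stage C2f blocks.

    Returns taps at strides 4 (C2), 8 (P3), 16 (P4) and 32 (P5, after SPPF).
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        w = cfg.width
        c1, c2, c3, c4, c5 = w(64), w(128), w(256), w(512), w(1024)
        self.channels = (c2, c3, c4, c5)  # C2, P3, P4, P5
        d = cfg.depth
        self.stem1 = ConvBNAct(3, c1, 3, 2)
        self.stem2 = ConvBNAct(c1, c2, 3, 2)
        self.c2f_2 = C2f(c2, c2, d(3), shortcut=True)
        self.down3 = ConvBNAct(c2, c3, 3, 2)
        self.c2f_3 = C2f(c3, c3, d(6), shortcut=True)
        self.down4 = ConvBNAct(c3, c4, 3, 2)
        self.c2f_4 = C2f(c4, c4, d(6), shortcut=True)
        self.down5 = ConvBNAct(c4, c5, 3, 2)
        self.c2f_5 = C2f(c5, c5, d(3), shortcut=True)
        self.sppf = SPPF(c5, c5)
        om = cfg.simam_omega
        self.simam_p3 = SimAM(om) if "P3" in cfg.simam_stages else None
        self.simam_p4 = SimAM(om) if "P4" in cfg.simam_stages else None
        self.simam_p5 = SimAM(om) if "P5" in cfg.simam_stages else None

    def forward(self, x: Tensor):
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise InvalidInputError("input height/width must be divisible by 32")
        x = self.stem2(self.stem1(x))
        c2 = self.c2f_2(x)
        p3 = self.c2f_3(self.down3(c2))
        if self.simam_p3 is not None:
            p3 = self.simam_p3(p3)
        p4 = self.c2f_4(self.down4(p3))
        if self.simam_p4 is not None:
            p4 = self.simam_p4(p4)
        p5 = self.c2f_5(self.down5(p4))
        if self.simam_p5 is not None:
            p5 = self.simam_p5(p5)
        p5 = self.sppf(p5)
        return c2, p3, p4, p5


# ---------------------------------------------------------------------------
# necks
# ---------------------------------------------------------------------------

class PANNeck(Module):
    """Baseline path-aggregation neck (upsample/concat/C2f both ways)."""

    def __init__(self, cfg: ModelConfig, backbone_channels):
        super().__init__()
        _, c3, c4, c5 = backbone_channels
        d = cfg.depth(3)
        self.up = UpsampleNearest2()
        self.td4 = C2f(c5 + c4, c4, d)
        self.td3 = C2f(c4 + c3, c3, d)
        self.down3 = ConvBNAct(c3, c3, 3, 2)
        self.bu4 = C2f(c3 + c4, c4, d)
        self.down4 = ConvBNAct(c4, c4, 3, 2)
        self.bu5 = C2f(c4 + c5, c5, d)
        self.out_channels = (c3, c4, c5)

    def forward(self, taps):
        _, p3, p4, p5 = taps
        t4 = self.td4(ag.concat([self.up(p5), p4], axis=1))
        t3 = self.td3(ag.concat([self.up(t4), p3], axis=1))
        n4 = self.bu4(ag.concat([self.down3(t3), t4], axis=1))
        n5 = self.bu5(ag.concat([self.down4(n4), p5], axis=1))
        return t3, n4, n5


class RepBiPANNeck(Module):
    """EfficientRepBiPAN: reduce + BiFusion + RepBlock top-down, strided conv
    + concat + RepBlock bottom-up."""

    def __init__(self, cfg: ModelConfig, backbone_channels):
        super().__init__()
        c2, c3, c4, c5 = backbone_channels
        ct4, ct3, cb4, cb5 = cfg.neck_channels
        n_td4, n_td3, n_bu4, n_bu5 = cfg.repblock_depths
        self.reduce0 = ConvBNAct(c5, ct4, 1)
        self.bifusion0 = BiFusion(ct4, c4, c3, ct4)
        self.rep_td4 = RepBlock(ct4, ct4, n_td4)
        self.reduce1 = ConvBNAct(ct4, ct3, 1)
        self.bifusion1 = BiFusion(ct3, c3, c2, ct3)
        self.rep_td3 = RepBlock(ct3, ct3, n_td3)
        self.down3 = ConvBNAct(ct3, ct3, 3, 2)
        self.rep_bu4 = RepBlock(ct3 + ct3, cb4, n_bu4)
        self.down4 = ConvBNAct(cb4, cb4, 3, 2)
        self.rep_bu5 = RepBlock(cb4 + ct4, cb5, n_bu5)
        self.out_channels = (ct3, cb4, cb5)

    def forward(self, taps):
        c2, p3, p4, p5 = taps
        r0 = self.reduce0(p5)
        t4 = self.rep_td4(self.bifusion0(r0, p4, p3))
        r1 = self.reduce1(t4)
        t3 = self.rep_td3(self.bifusion1(r1, p3, c2))
        n4 = self.rep_bu4(ag.concat([self.down3(t3), r1], axis=1))
        n5 = self.rep_bu5(ag.concat([self.down4(n4), r0], axis=1))
        return t3, n4, n5


def build_neck(cfg: ModelConfig, backbone_channels) -> Module:
    if cfg.neck == "pan_baseline":
        return PANNeck(cfg, backbone_channels)
    return RepBiPANNeck(cfg, backbone_channels)


# ---------------------------------------------------------------------------
# head
# ---------------------------------------------------------------------------

REG_MAX = 16
STRIDES = (8, 16, 32)


class PoseHead(Module):
    """Decoupled box / class / keypoint head over three pyramid levels.

    Per grid cell each level emits 4*REG_MAX box-side distribution logits,
    ``num_classes`` class logits and num_keypoints*keypoint_dims keypoint
    values.
    """

    def __init__(self, cfg: ModelConfig, in_channels):
        super().__init__()
        nc, nk = cfg.num_classes, cfg.num_keypoints * cfg.keypoint_dims
        self.nc, self.nk = nc, nk
        self.num_keypoints = cfg.num_keypoints
        ch = tuple(in_channels)
        c2 = max(16, ch[0] // 4, REG_MAX * 4)
        c3 = max(ch[0], min(nc, 100))
        c4 = max(ch[0] // 4, nk)
        self.cv_box = ModuleList(
            Sequential(ConvBNAct(c, c2, 3), ConvBNAct(c2, c2, 3),
                       Conv2d(c2, 4 * REG_MAX, 1)) for c in ch)
        self.cv_cls = ModuleList(
            Sequential(ConvBNAct(c, c3, 3), ConvBNAct(c3, c3, 3),
                       Conv2d(c3, nc, 1)) for c in ch)
        self.cv_kpt = ModuleList(
            Sequential(ConvBNAct(c, c4, 3), ConvBNAct(c4, c4, 3),
                       Conv2d(c4, nk, 1)) for c in ch)
        # fixed projection for collapsing box distributions (not learnable)
        self.register_buffer("dfl_proj", np.arange(REG_MAX, dtype=np.float32))
        # prior initialization: start class scores near a 1% positive prior so
        # untrained levels stay quiet, and box distributions near small sides
        for seq in self.cv_cls:
            seq[-1].bias.data[:] = -math.log(99.0)
        for seq in self.cv_box:
            seq[-1].bias.data[:] = 1.0

    def forward(self, feats):
        out = []
        for i, x in enumerate(feats):
            out.append((self.cv_box[i](x), self.cv_cls[i](x), self.cv_kpt[i](x)))
        return out


@dataclass
class DensePrediction:
    """Raw head outputs: per level (box logits, class logits, keypoint field)."""

    levels: list
    strides: tuple = STRIDES
    num_keypoints: int = 16

    def cells(self) -> int:
        return sum(b.shape[2] * b.shape[3] for b, _, _ in self.levels)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class CattlePoseModel(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.backbone = Backbone(cfg)
        self.neck = build_neck(cfg, self.backbone.channels)
        self.head = PoseHead(cfg, self.neck.out_channels)

    def forward(self, x: Tensor) -> DensePrediction:
        feats = self.neck(self.backbone(x))
        return DensePrediction(self.head(feats),
                               num_keypoints=self.cfg.num_keypoints)


def build_model(cfg: ModelConfig, seed: int | None = None) -> CattlePoseModel:
    if seed is not None:
        nn.seed_init(seed)
    return CattlePoseModel(cfg)


def count_parameters(model: Module) -> int:
    """Exact number of learnable scalars (buffers excluded)."""
    return model.num_parameters()


def count_flops(model: CattlePoseModel, input_size: int = 640,
                profile_size: int = 64) -> float:
    """Total forward FLOPs (GFLOPs, 1 MAC = 2 FLOPs) at batch 1.

    Convolution cost scales exactly with output area, so the model is profiled
    once at a small stride-compatible size and rescaled to ``input_size``.
    """
    if input_size % 32:
        raise InvalidInputError("input size must be divisible by 32")
    profile_size = min(profile_size, input_size)
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, 3, profile_size, profile_size), dtype=np.float32))
    with ag.no_grad(), _Profiler() as prof:
        model(x)
    if was_training:
        model.train()
    scale = (input_size / profile_size) ** 2
    return 2.0 * prof.macs * scale / 1e9


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _softmax_np(z: np.ndarray, axis: int) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid_np(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def box_iou_xywh(a: np.ndarray, b: np.ndarray) -> float:
    ax1, ay1, aw, ah = a
    bx1, by1, bw, bh = b
    ix = max(0.0, min(ax1 + aw, bx1 + bw) - max(ax1, bx1))
    iy = max(0.0, min(ay1 + ah, by1 + bh) - max(ay1, by1))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def decode(pred: DensePrediction, conf_threshold: float = 0.25,
           iou_threshold: float = 0.7) -> list[KeypointInstance]:
    """Collapse dense predictions into pixel-space instances with NMS.

    Box side distributions are reduced to their expectation; keypoints follow
    the cell-relative (2p - 0.5 + center) convention; visibility logits pass
    through a sigmoid.  Instances are returned sorted by descending score.
    """
    if not 0 <= conf_threshold <= 1 or not 0 <= iou_threshold <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    nkpt = pred.num_keypoints
    cands: list[KeypointInstance] = []
    for (box_t, cls_t, kpt_t), stride in zip(pred.levels, pred.strides):
        box = np.asarray(box_t.data if hasattr(box_t, "data") else box_t)[0]
        cls = np.asarray(cls_t.data if hasattr(cls_t, "data") else cls_t)[0]
        kpt = np.asarray(kpt_t.data if hasattr(kpt_t, "data") else kpt_t)[0]
        _, h, w = box.shape
        score = _sigmoid_np(cls).max(axis=0)  # (h, w)
        keep = np.argwhere(score >= conf_threshold)
        if keep.size == 0:
            continue
        dist = _softmax_np(box.reshape(4, REG_MAX, h, w), axis=1)
        ltrb = (dist * np.arange(REG_MAX)[None, :, None, None]).sum(axis=1)
        for gy, gx in keep:
            cx, cy = (gx + 0.5) * stride, (gy + 0.5) * stride
            l, t, r, b = ltrb[:, gy, gx] * stride
            x1, y1 = cx - l, cy - t
            bw, bh = l + r, t + b
            kp = kpt[:, gy, gx].reshape(nkpt, 3).copy()
            kp[:, 0] = (kp[:, 0] * 2.0 - 0.5 + gx + 0.5) * stride
            kp[:, 1] = (kp[:, 1] * 2.0 - 0.5 + gy + 0.5) * stride
            kp[:, 2] = _sigmoid_np(kp[:, 2]) * 2.0  # soft visibility in [0, 2)
            cands.append(KeypointInstance(
                box=(float(x1), float(y1), float(bw), float(bh)),
                score=float(score[gy, gx]), keypoints=kp))
    cands.sort(key=lambda inst: -inst.score)
    kept: list[KeypointInstance] = []
    for inst in cands:
        if all(box_iou_xywh(np.array(inst.box), np.array(k.box)) <= iou_threshold
               for k in kept):
            kept.append(inst)
    return kept
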