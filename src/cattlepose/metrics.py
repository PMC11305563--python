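"""Object keypoint similarity (OKS) scoring and the AP evaluation protocol.

For a ground-truth / prediction pair the similarity is

    OKS = sum_i exp(-d_i^2 / (2 s^2 k_i^2)) [v_i > 0] / sum_i [v_i > 0]

with d_i the Euclidean pixel distance at keypoint i, v_i the ground-truth
visibility flag, k_i a per-keypoint decay constant (s*k_i is the standard
deviation of the Gaussian tolerance) and s the object scale, taken as the
square root of the ground-truth box area.  Only keypoints observed in the
ground truth (v_i > 0) contribute.

AP at threshold t is the fraction of matched detections whose OKS reaches t
(a literal detection-accuracy reading, not a precision-recall integral);
AP_0.5:0.95 averages the ten thresholds 0.50, 0.55, ..., 0.95.  Matching is
greedy: predictions in descending score order claim the unclaimed ground
truth of maximal OKS.  Evaluation pools matches over all images and can be
stratified by per-image factor tags (scale, lighting, view, occlusion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import KeypointInstance

OKS_THRESHOLDS = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))

FACTOR_TAGS = ("large_scale", "small_scale", "bright_light", "dim_light",
               "front_view", "side_view", "back_view", "occlusion",
               "unobstructed")


class UndefinedOKSError(ValueError):
    """OKS is undefined: the ground truth has no visible keypoint."""


@dataclass(frozen=True)
class OKSConfig:
    """Per-keypoint decay constants and the object-scale rule.

    k defaults to a uniform 0.1 for all 16 cattle keypoints (the per-keypoint
    constants are not published for cattle); scale_rule 'sqrt_box_area' sets
    s = sqrt(ground-truth box area).
    """

    k: tuple = tuple([0.1] * 16)
    scale_rule: str = "sqrt_box_area"

    def __post_init__(self):
        if np.any(np.asarray(self.k) <= 0):
            raise ValueError("k must be positive")
        if self.scale_rule != "sqrt_box_area":
            raise ValueError("unknown scale rule")

    def k_array(self) -> np.ndarray:
        return np.asarray(self.k, dtype=np.float64)


def object_scale(gt: KeypointInstance, config: OKSConfig = OKSConfig()) -> float:
    return float(np.sqrt(max(gt.area, 0.0)))


def oks(gt: KeypointInstance, pred: KeypointInstance,
        config: OKSConfig = OKSConfig()) -> float:
    """Object keypoint similarity in [0, 1]; 1 iff every visible keypoint matches."""
    vis = gt.visible_mask()
    if not vis.any():
        raise UndefinedOKSError("ground truth has no visible keypoint")
    d2 = ((gt.keypoints[:, :2] - pred.keypoints[:, :2]) ** 2).sum(axis=1)
    s2 = object_scale(gt, config) ** 2
    k2 = config.k_array() ** 2
    sim = np.exp(-d2 / (2.0 * s2 * k2 + 1e-300))
    return float(sim[vis].mean())


@dataclass
class MatchRecord:
    pred: KeypointInstance
    gt: Optional[KeypointInstance]
    oks: float


def match(gts: Sequence[KeypointInstance], preds: Sequence[KeypointInstance],
          config: OKSConfig = OKSConfig()) -> list[MatchRecord]:
    """Greedy one-to-one assignment of predictions to ground truths.

    Predictions are processed in descending score (ties broken by input
    order); each claims the remaining ground truth that maximizes OKS.
    Unmatched predictions carry OKS 0.
    """
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    free = list(range(len(gts)))
    records: list[MatchRecord] = []
    for pi in order:
        best_gi, best_oks = None, -1.0
        for gi in free:
            try:
                value = oks(gts[gi], preds[pi], config)
            except UndefinedOKSError:
                continue
            if value > best_oks:
                best_gi, best_oks = gi, value
        if best_gi is None:
            records.append(MatchRecord(preds[pi], None, 0.0))
        else:
            free.remove(best_gi)
            records.append(MatchRecord(preds[pi], gts[best_gi], best_oks))
    return records


def ap_at(matches: Sequence[MatchRecord], t: float) -> float:
    """Fraction of detections with OKS >= t; 0 when there are no detections."""
    if not 0.5 <= t <= 0.95:
        raise ValueError("threshold must lie in [0.5, 0.95]")
    if not matches:
        return 0.0
    return sum(m.oks >= t for m in matches) / len(matches)


@dataclass
class EvalResult:
    ap_by_threshold: dict[float, float]
    ap50: float
    ap50_95: float
    per_factor: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "ap_by_threshold": {f"{t:.2f}": v for t, v in self.ap_by_threshold.items()},
            "ap50": self.ap50,
            "ap50_95": self.ap50_95,
            "per_factor": {k: {"ap50": a, "ap50_95": b}
                           for k, (a, b) in self.per_factor.items()},
        }

    def as_table(self) -> str:
        lines = ["threshold  AP"]
        lines += [f"   {t:.2f}    {v:.4f}" for t, v in self.ap_by_threshold.items()]
        lines.append(f"AP_0.5       {self.ap50:.4f}")
        lines.append(f"AP_0.5:0.95  {self.ap50_95:.4f}")
        if self.per_factor:
            lines.append("factor            AP_0.5  AP_0.5:0.95")
            for tag, (a, b) in self.per_factor.items():
                lines.append(f"{tag:<17} {a:.4f}  {b:.4f}")
        return "\n".join(lines)


def _pooled_ap(matches: Sequence[MatchRecord]) -> tuple[dict[float, float], float, float]:
    by_t = {t: ap_at(matches, t) for t in OKS_THRESHOLDS}
    ap50 = by_t[0.5]
    ap50_95 = float(np.mean(list(by_t.values())))
    return by_t, ap50, ap50_95


def evaluate(dataset: Iterable[tuple[Sequence[KeypointInstance],
                                     Sequence[KeypointInstance]]],
             config: OKSConfig = OKSConfig(),
             factor_tags: Optional[Sequence[Sequence[str]]] = None) -> EvalResult:
    """Pooled AP over a dataset of per-image (ground truths, predictions).

    ``factor_tags`` optionally supplies per-image condition tags drawn from
    :data:`FACTOR_TAGS`; AP is then also reported on each tag-filtered subset
    (empty subsets are omitted with a warning).
    """
    dataset = list(dataset)
    per_image = [match(gts, preds, config) for gts, preds in dataset]
    pooled = [m for ms in per_image for m in ms]
    by_t, ap50, ap50_95 = _pooled_ap(pooled)
    result = EvalResult(by_t, ap50, ap50_95)
    if factor_tags is not None:
        if len(factor_tags) != len(dataset):
            raise ValueError("one tag list per image required")
        all_tags = sorted({t for tags in factor_tags for t in tags})
        for tag in all_tags:
            subset = [m for ms, tags in zip(per_image, factor_tags)
                      if tag in tags for m in ms]
            if not subset:
                warnings.warn(f"factor {tag!r}: empty subset, omitted")
                continue
            _, a, b = _pooled_ap(subset)
            result.per_factor[tag] = (a, b)
    return result
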