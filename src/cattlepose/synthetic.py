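"""Procedural cattle-like scenes with exact ground truth.

The generator emulates the variation factors of farm imagery -- 1-3 animals
per image, large/small body scale, bright/dim lighting, front/side/back
viewing angle, fence occlusion and edge truncation -- with flat-shaded
quadruped silhouettes over a textured background.  It validates geometry and
metrics, not visual realism: it is a synthetic stand-in for farm imagery.

A parameterized skeleton template places the 16 schema keypoints (head top,
neck, spine, four legs of thigh root / knee / hoof, coccyx); visibility
follows view geometry (far-side limbs are occluded in side view, the head top
is self-occluded from behind), fence bars flip covered keypoints to occluded
(v=1) and truncation removes out-of-frame keypoints (v=0).  Every keypoint
silhouette region is drawn explicitly, so a visible (v=2) keypoint is
guaranteed to lie on its instance's rendered foreground.

A controllable pseudo-predictor (`jitter_predictions`) displaces visible
keypoints with isotropic Gaussian noise of standard deviation tau, for which
the expected OKS has the closed form 1 / (1 + tau^2 / (s^2 k^2)) under a
uniform decay constant k -- the oracle used to validate the metric stack.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from skimage.draw import disk, ellipse, polygon

from . import data_io
from .data_io import (KEYPOINT_NAMES, LabelmeDocument, LabelmeInstance,
                      labelme_to_yolo, write_labelme, write_yolo)
from .types import KeypointInstance

VIEWS = ("front", "side", "back")
SCALES = ("large", "small")
POSES = ("standing", "walking", "lying")
BRIGHTNESS = ("bright", "dim")

# instance height as a fraction of image height
SCALE_RANGES = {"large": (0.45, 0.75), "small": (0.10, 0.25)}
# dim lighting: global intensity scale + additive sensor noise (repo constants)
DIM_FACTOR = 0.35
DIM_NOISE = 6.0

_LEG_X = {"front": 0.82, "hind": 0.10}  # along-body positions of leg roots


@dataclass
class SceneSpec:
    """Parameters of one synthetic image."""

    image_size: int = 640
    n_instances: int = 1
    brightness: str = "bright"
    view: str = "side"
    scale_class: str = "large"
    pose: str = "standing"
    n_fence_bars: int = 0
    fence_positions: Optional[tuple] = None  # explicit bar left edges (px)
    truncated: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_instances <= 3:
            raise ValueError("n_instances must be in 1..3")
        for val, allowed in ((self.brightness, BRIGHTNESS), (self.view, VIEWS),
                             (self.scale_class, SCALES), (self.pose, POSES)):
            if val not in allowed:
                raise ValueError(f"{val!r} not in {allowed}")

    def tags(self) -> list[str]:
        return [f"{self.scale_class}_scale",
                "bright_light" if self.brightness == "bright" else "dim_light",
                f"{self.view}_view",
                "occlusion" if self.n_fence_bars or self.n_instances > 1
                else "unobstructed"]


@dataclass
class PseudoPredConfig:
    """Controls the pseudo-predictor: per-axis jitter tau (px), keypoint drop
    probability, and the base confidence score."""

    jitter_sigma: float = 0.0
    drop_probability: float = 0.0
    score: float = 1.0

    def __post_init__(self):
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if not 0 <= self.drop_probability <= 1:
            raise ValueError("drop_probability in [0,1]")
        if not 0 < self.score <= 1:
            raise ValueError("score in (0,1]")


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------

def _template(pose: str, rng: np.random.Generator) -> np.ndarray:
    """Side-profile template, unit body length, y down; returns (16, 2)."""
    ground = 0.78 if pose != "lying" else 0.30
    knee_y = 0.46 if pose != "lying" else 0.22
    root_y = 0.22
    pts = np.zeros((16, 2))

    def put(name, x, y):
        pts[KEYPOINT_NAMES.index(name)] = (x, y)

    put("head top", 1.16, -0.30)
    put("neck", 1.00, -0.06)
    put("spine", 0.52, -0.12)
    put("coccyx", 0.02, -0.06)
    for side, dx in (("right", 0.035), ("left", -0.035)):
        for part, base_x in (("front", _LEG_X["front"]), ("hind", _LEG_X["hind"])):
            walk = rng.uniform(-0.08, 0.08) if pose == "walking" else 0.0
            fold = rng.uniform(0.10, 0.2) if pose == "lying" else 0.0
            put(f"{side} {part} thigh root", base_x + dx, root_y)
            put(f"{side} {part} knee", base_x + dx + walk + fold, knee_y)
            put(f"{side} {part} hoof", base_x + dx + 1.5 * walk + 2 * fold, ground)
    # mild anatomical jitter
    pts += rng.normal(0, 0.012, size=pts.shape)
    return pts


def _view_project(pts: np.ndarray, view: str) -> tuple[np.ndarray, np.ndarray]:
    """Foreshorten the template and assign visibility flags per view."""
    vis = np.full(16, 2, dtype=int)
    idx = {n: i for i, n in enumerate(KEYPOINT_NAMES)}
    if view == "side":
        for name in KEYPOINT_NAMES:
            if name.startswith("left"):
                vis[idx[name]] = 1  # far-side limbs self-occluded
        return pts, vis
    # front/back: compress along the body axis, spread legs laterally
    out = pts.copy()
    out[:, 0] = pts[:, 0] * 0.30
    for name in KEYPOINT_NAMES:
        if "right" in name:
            out[idx[name], 0] += 0.14
        elif "left" in name:
            out[idx[name], 0] -= 0.14
    if view == "front":
        vis[idx["coccyx"]] = 1
        for name in KEYPOINT_NAMES:
            if "hind" in name:
                vis[idx[name]] = 1
    else:  # back view: the head top is self-occluded behind the body
        vis[idx["head top"]] = 1
        vis[idx["neck"]] = 1
        for name in KEYPOINT_NAMES:
            if "front" in name and "hoof" not in name:
                vis[idx[name]] = 1
    return out, vis


def sample_skeleton(rng: np.random.Generator, view: str = "side",
                    scale: str = "large", pose: str = "standing",
                    image_size: int = 640,
                    center: Optional[tuple[float, float]] = None
                    ) -> KeypointInstance:
    """Sample one cattle instance in pixel coordinates.

    Deterministic given the generator state; the box tightly encloses the
    observed (v > 0) keypoints with a 6% margin.
    """
    if view not in VIEWS or scale not in SCALES or pose not in POSES:
        raise ValueError("invalid view/scale/pose")
    pts = _template(pose, rng)
    pts, vis = _view_project(pts, view)
    lo, hi = SCALE_RANGES[scale]
    target_h = rng.uniform(lo, hi) * image_size
    span = pts[:, 1].max() - pts[:, 1].min()
    s = target_h / span
    pts = pts * s
    if center is None:
        cx = rng.uniform(0.25, 0.75) * image_size
        cy = rng.uniform(0.3, 0.7) * image_size
    else:
        cx, cy = center
    pts[:, 0] += cx - pts[:, 0].mean()
    pts[:, 1] += cy - pts[:, 1].mean()
    kp = np.concatenate([pts, vis[:, None].astype(float)], axis=1)
    box = _tight_box(kp)
    return KeypointInstance(box=box, score=1.0, keypoints=kp)


def _tight_box(kp: np.ndarray, margin: float = 0.06) -> tuple:
    obs = kp[kp[:, 2] > 0]
    x1, y1 = obs[:, 0].min(), obs[:, 1].min()
    x2, y2 = obs[:, 0].max(), obs[:, 1].max()
    mx, my = margin * (x2 - x1), margin * (y2 - y1)
    return (float(x1 - mx), float(y1 - my),
            float(x2 - x1 + 2 * mx), float(y2 - y1 + 2 * my))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _draw_instance(canvas: np.ndarray, owner: np.ndarray, inst_id: int,
                   inst: KeypointInstance, color: np.ndarray) -> None:
    """Flat-shaded silhouette: trunk/head ellipses, limb quads, joint disks.

    ``owner`` records which instance currently covers each pixel (later
    instances overdraw earlier ones).
    """
    h, w = owner.shape
    kp = inst.keypoints
    idx = {n: i for i, n in enumerate(KEYPOINT_NAMES)}

    def xy(name):
        return kp[idx[name], 0], kp[idx[name], 1]

    mask = np.zeros((h, w), dtype=bool)
    nx, ny = xy("neck")
    cxx, cyy = xy("coccyx")
    sx, sy = xy("spine")
    body_len = max(np.hypot(nx - cxx, ny - cyy), 4.0)
    rr, cc = ellipse(sy + 0.18 * body_len, sx, 0.34 * body_len,
                     0.62 * body_len, shape=(h, w))
    mask[rr, cc] = True
    hx, hy = xy("head top")
    rr, cc = ellipse((hy + ny) / 2 + 0.04 * body_len, (hx + nx) / 2,
                     0.30 * body_len, 0.22 * body_len, shape=(h, w))
    mask[rr, cc] = True
    thick = max(2.0, 0.05 * body_len)
    for side in ("right", "left"):
        for part in ("front", "hind"):
            chain = [xy(f"{side} {part} thigh root"),
                     xy(f"{side} {part} knee"), xy(f"{side} {part} hoof")]
            for (x0, y0), (x1, y1) in zip(chain[:-1], chain[1:]):
                d = np.hypot(x1 - x0, y1 - y0) + 1e-9
                ox, oy = thick * (y1 - y0) / d, thick * (x0 - x1) / d
                rr, cc = polygon([y0 + oy, y1 + oy, y1 - oy, y0 - oy],
                                 [x0 + ox, x1 + ox, x1 - ox, x0 - ox],
                                 shape=(h, w))
                mask[rr, cc] = True
    for x, y, v in kp:
        if v > 0:
            rr, cc = disk((y, x), max(2.5, 0.04 * body_len), shape=(h, w))
            mask[rr, cc] = True
    canvas[mask] = color
    owner[mask] = inst_id


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, LabelmeDocument]:
    """Render one scene; annotations are exactly consistent with the pixels.

    Returns the uint8 RGB image and its Labelme document.  Later-drawn
    instances, fence bars and image edges demote covered/clipped keypoints to
    v=1 / v=0 before annotations are emitted.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    # textured background: low-frequency noise, earth-toned
    coarse = rng.uniform(0.55, 0.95, size=(n // 16 + 1, n // 16 + 1))
    bg = np.kron(coarse, np.ones((16, 16)))[:n, :n]
    base = np.array([120.0, 125.0, 100.0])
    canvas = (bg[..., None] * base).astype(np.float64)

    owner = np.full((n, n), -1, dtype=np.int32)
    instances: list[KeypointInstance] = []
    for i in range(spec.n_instances):
        center = None
        if spec.truncated and i == 0:
            # push the first instance partly off-frame
            center = (rng.uniform(-0.05, 0.08) * n, rng.uniform(0.3, 0.7) * n)
        inst = sample_skeleton(rng, spec.view, spec.scale_class, spec.pose,
                               image_size=n, center=center)
        shade = rng.uniform(0.25, 0.8)
        color = np.array([150.0, 110.0, 90.0]) * shade + rng.uniform(-10, 10, 3)
        _draw_instance(canvas, owner, i, inst, np.clip(color, 0, 255))
        instances.append(inst)

    # inter-instance occlusion: covered keypoints of earlier instances -> v=1
    for i, inst in enumerate(instances):
        for kp in inst.keypoints:
            if kp[2] == 2:
                x, y = int(round(kp[0])), int(round(kp[1]))
                if 0 <= x < n and 0 <= y < n and owner[y, x] != i:
                    kp[2] = 1

    # fence bars: vertical strips overdrawing everything
    bar_color = np.array([70.0, 65.0, 60.0])
    bar_w = max(3, n // 64)
    if spec.fence_positions is not None:
        positions = list(spec.fence_positions)
    else:
        positions = [int(rng.uniform(0.1, 0.9) * n)
                     for _ in range(spec.n_fence_bars)]
    for x0 in positions:
        if not 0 <= x0 < n:
            raise ValueError("occluder outside image")
        canvas[:, x0:x0 + bar_w] = bar_color
        owner[:, x0:x0 + bar_w] = -2
        for inst in instances:
            for kp in inst.keypoints:
                # demote keypoints whose nearest pixel falls under the bar
                if kp[2] == 2 and x0 - 0.5 <= kp[0] < x0 + bar_w - 0.5:
                    kp[2] = 1

    # truncation: out-of-frame keypoints are unlabeled
    for inst in instances:
        for kp in inst.keypoints:
            if kp[2] > 0 and not (0 <= kp[0] < n and 0 <= kp[1] < n):
                kp[:] = (0.0, 0.0, 0.0)

    # lighting
    if spec.brightness == "dim":
        canvas = canvas * DIM_FACTOR + rng.normal(0, DIM_NOISE, canvas.shape)
    image = np.clip(canvas, 0, 255).astype(np.uint8)

    doc = LabelmeDocument("", n, n)
    for inst in instances:
        if not (inst.keypoints[:, 2] > 0).any():
            continue  # fully truncated
        box = _tight_box(inst.keypoints)
        x1, y1 = max(box[0], 0.0), max(box[1], 0.0)
        x2 = min(box[0] + box[2], n - 1.0)
        y2 = min(box[1] + box[3], n - 1.0)
        points = {}
        for name, (x, y, v) in zip(KEYPOINT_NAMES, inst.keypoints):
            if v > 0:
                points[name] = (float(x), float(y), bool(v == 1))
        doc.instances.append(LabelmeInstance((x1, y1, x2, y2), points))
    return image, doc


def instance_mask(image_shape, inst: KeypointInstance) -> np.ndarray:
    """Re-render one instance's silhouette mask (for consistency checks)."""
    h, w = image_shape[:2]
    canvas = np.zeros((h, w, 3))
    owner = np.full((h, w), -1, dtype=np.int32)
    _draw_instance(canvas, owner, 0, inst, np.array([1.0, 1.0, 1.0]))
    return owner == 0


# ---------------------------------------------------------------------------
# pseudo-predictor
# ---------------------------------------------------------------------------

def jitter_predictions(gts: Sequence[KeypointInstance],
                       config: PseudoPredConfig,
                       rng: np.random.Generator) -> list[KeypointInstance]:
    """Gaussian-jittered copies of ground truths (metric-validation oracle)."""
    preds = []
    for gt in gts:
        kp = gt.keypoints.copy()
        vis = kp[:, 2] > 0
        kp[vis, :2] += rng.normal(0, config.jitter_sigma, size=(vis.sum(), 2))
        if config.drop_probability > 0:
            drop = rng.random(len(kp)) < config.drop_probability
            kp[drop] = 0.0
        score = float(config.score * rng.uniform(0.9, 1.0))
        preds.append(KeypointInstance(box=gt.box, score=score, keypoints=kp))
    return preds


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

DEFAULT_MIXTURE = {
    # per-axis category weights mirroring the stratified evaluation pools
    "scale": {"large": 2, "small": 1},
    "brightness": {"bright": 1, "dim": 1},
    "view": {"front": 1, "side": 1, "back": 1},
    "occlusion": {"occluded": 1, "unobstructed": 2},
}


@dataclass
class DatasetManifest:
    root: str
    entries: list[dict] = field(default_factory=list)

    def image_paths(self) -> list[str]:
        return [e["image"] for e in self.entries]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for e in self.entries:
            h.update(json.dumps(e, sort_keys=True).encode())
            h.update(Path(self.root, e["labelme"]).read_bytes())
            h.update(Path(self.root, e["labels"]).read_bytes())
        return h.hexdigest()

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"root": self.root, "entries": self.entries}, indent=1))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        raw = json.loads(Path(path).read_text())
        return cls(raw["root"], raw["entries"])


def _choose(rng, weights: dict):
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def generate_dataset(n_images: int, seed: int, out_dir,
                     mixture: Optional[dict] = None,
                     image_size: int = 320) -> DatasetManifest:
    """Write images, Labelme JSON, YOLO txt and factor-tag sidecars.

    Deterministic per seed (byte-identical annotations on rerun); the factor
    mixture gives per-axis category weights.
    """
    mixture = mixture or DEFAULT_MIXTURE
    out = Path(out_dir)
    for sub in ("images", "labelme", "labels", "tags"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest(str(out))
    master = np.random.SeedSequence(seed)
    child_seeds = master.generate_state(n_images)
    for i in range(n_images):
        img_seed = int(child_seeds[i]) % (2 ** 31)
        rng = np.random.default_rng(img_seed)
        occluded = _choose(rng, mixture["occlusion"]) == "occluded"
        spec = SceneSpec(
            image_size=image_size,
            n_instances=int(rng.integers(1, 4)),
            brightness=_choose(rng, mixture["brightness"]),
            view=_choose(rng, mixture["view"]),
            scale_class=_choose(rng, mixture["scale"]),
            pose=POSES[rng.integers(0, 3)],
            n_fence_bars=int(rng.integers(1, 3)) if occluded else 0,
            truncated=bool(rng.random() < 0.15),
            seed=img_seed)
        image, doc = render_scene(spec)
        stem = f"scene_{i:05d}"
        doc.image_path = f"../images/{stem}.png"
        Image.fromarray(image).save(out / "images" / f"{stem}.png")
        write_labelme(doc, out / "labelme" / f"{stem}.json")
        write_yolo(labelme_to_yolo(doc), out / "labels" / f"{stem}.txt")
        (out / "tags" / f"{stem}.json").write_text(json.dumps(spec.tags()))
        manifest.entries.append({
            "image": f"images/{stem}.png",
            "labelme": f"labelme/{stem}.json",
            "labels": f"labels/{stem}.txt",
            "tags": spec.tags(),
            "image_size": image_size,
        })
    manifest.save(out / "manifest.json")
    return manifest
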