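"""Synthetic camera-trap detection scenes with COCO JSON round-trip I/O.

Real camera-trap archives of protected-area wildlife are rarely public, so
this module generates stand-in detection datasets with the failure modes
that make such imagery hard: nine animal classes rendered as textured
parametric sprites (ellipse body plus appendage lobes, per-class hue and
shape) over multi-octave value-noise backgrounds, with

* *camouflage*: sprite colors mixed toward the local background mean, so
  objects partially resemble earth mounds / stumps / leaf piles;
* *night*: luminance and saturation collapse plus sensor noise;
* *rain*: semi-transparent near-vertical streaks and a slight global blur.

Everything is deterministic per ``(config, index)``; degradations never
move the ground-truth boxes.  Classes are synthetic (``class_0..class_8``),
mildly imbalanced by default, with no attempt to imitate real species.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .model_core import BoxSet
from .nn import _interp_matrix

N_MAX_STREAKS = 200


@dataclass
class SceneConfig:
    image_size: int = 256
    num_classes: int = 9
    objects_per_image: tuple = (1, 3)
    night_probability: float = 0.3
    rain_probability: float = 0.3
    camouflage_level: float = 0.3
    class_weights: tuple | None = None   # None -> mildly imbalanced default
    seed: int = 0

    def validate(self) -> "SceneConfig":
        for name in ("night_probability", "rain_probability", "camouflage_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.objects_per_image
        if lo < 0 or hi < lo:
            raise ValueError("objects_per_image must be a (min, max) range with min >= 0")
        return self

    def weights(self) -> np.ndarray:
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=np.float64)
        else:
            w = 1.0 / (1.0 + 0.15 * np.arange(self.num_classes))
        return w / w.sum()


@dataclass
class SyntheticScene:
    image: np.ndarray          # (H, W, 3) uint8
    boxes: BoxSet              # ground truth (scores None)
    night_level: float
    rain_density: float
    index: int = 0


# ---------------------------------------------------------------------------
# background and sprites
# ---------------------------------------------------------------------------


def _upsample(grid: np.ndarray, size: int) -> np.ndarray:
    """Bilinear upsample a (k, k, 3) grid to (size, size, 3)."""
    ah = _interp_matrix(size, grid.shape[0])
    aw = _interp_matrix(size, grid.shape[1])
    gc = grid.astype(np.float32).transpose(2, 0, 1)      # (3, k, k)
    out = np.matmul(np.matmul(ah, gc), aw.T)             # (3, size, size)
    return out.transpose(1, 2, 0)


def _value_noise(rng: np.random.Generator, size: int) -> np.ndarray:
    """Multi-octave value noise in [0, 1], (size, size, 3)."""
    img = np.zeros((size, size, 3), dtype=np.float32)
    amp, total = 1.0, 0.0
    for cells in (4, 8, 16, 32):
        img += amp * _upsample(rng.random((cells, cells, 3), dtype=np.float32), size)
        total += amp
        amp *= 0.55
    return img / total


def _class_style(label: int, num_classes: int) -> dict:
    """Deterministic per-class sprite parameters (hue, shape, appendages)."""
    rng = np.random.default_rng(1000 + label)
    hue = label / max(num_classes, 1)
    base = np.array([0.35 + 0.5 * abs(np.cos(np.pi * hue)),
                     0.25 + 0.5 * abs(np.sin(2.1 * np.pi * hue + 0.7)),
                     0.15 + 0.5 * abs(np.sin(np.pi * hue + 2.0))], dtype=np.float32)
    return {
        "color": base,
        "aspect": 0.5 + 1.2 * rng.random(),
        "n_lobes": 2 + label % 4,
        "lobe_len": 0.5 + 0.5 * rng.random(),
        "lobe_angles": rng.uniform(0, 2 * np.pi, size=6),
    }


def _sprite_alpha(style: dict, half: int, rot: float, rng: np.random.Generator) -> np.ndarray:
    """Soft alpha mask (2*half, 2*half) of a rotated body-plus-lobes blob."""
    n = 2 * half
    ys, xs = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n), indexing="ij")
    c, s = np.cos(rot), np.sin(rot)
    xr = c * xs + s * ys
    yr = -s * xs + c * ys
    a = 0.62
    b = a / style["aspect"]
    r = (xr / a) ** 2 + (yr / b) ** 2
    alpha = np.clip((1.0 - r) * 3.0, 0.0, 1.0)
    for k in range(style["n_lobes"]):
        ang = style["lobe_angles"][k % len(style["lobe_angles"])]
        cx = a * 0.9 * np.cos(ang)
        cy = b * 0.9 * np.sin(ang)
        rl = ((xr - cx) / (0.35 * style["lobe_len"])) ** 2 + ((yr - cy) / 0.22) ** 2
        alpha = np.maximum(alpha, np.clip((1.0 - rl) * 3.0, 0.0, 1.0))
    return alpha.astype(np.float32)


def generate_scene(config: SceneConfig, index: int) -> SyntheticScene:
    """Render one scene; deterministic per ``(config, index)``."""
    config.validate()
    size = config.image_size
    rng = np.random.default_rng([config.seed, index])
    img = _value_noise(rng, size) * np.array([0.55, 0.5, 0.4], dtype=np.float32) + 0.18

    n_obj = int(rng.integers(config.objects_per_image[0], config.objects_per_image[1] + 1))
    boxes, labels = [], []
    weights = config.weights()
    for _ in range(n_obj):
        label = int(rng.choice(config.num_classes, p=weights))
        style = _class_style(label, config.num_classes)
        for _attempt in range(10):
            half = int(rng.uniform(0.06, 0.16) * size)
            if half < 6:
                half = 6
            cx = int(rng.uniform(half, size - half))
            cy = int(rng.uniform(half, size - half))
            rot = rng.uniform(0, 2 * np.pi)
            alpha = _sprite_alpha(style, half, rot, rng)
            mask = alpha > 0.1
            if not mask.any():
                continue
            ys, xs = np.nonzero(mask)
            x0, x1 = cx - half + xs.min(), cx - half + xs.max() + 1
            y0, y1 = cy - half + ys.min(), cy - half + ys.max() + 1
            if x1 - x0 < 4 or y1 - y0 < 4:
                continue
            sl = np.s_[cy - half : cy + half, cx - half : cx + half]
            patch = img[sl]
            local_mean = patch.reshape(-1, 3).mean(axis=0)
            texture = 0.75 + 0.5 * _value_noise(rng, 2 * half)[..., :1]
            color = ((1 - config.camouflage_level) * style["color"]
                     + config.camouflage_level * local_mean)
            sprite = np.clip(color * texture, 0, 1)
            a3 = alpha[..., None]
            img[sl] = patch * (1 - a3) + sprite * a3
            boxes.append([x0, y0, x1, y1])
            labels.append(label)
            break

    night_level = float(rng.uniform(0.5, 1.0)) if rng.random() < config.night_probability else 0.0
    rain_density = float(rng.uniform(0.3, 1.0)) if rng.random() < config.rain_probability else 0.0
    deg_seed = int(rng.integers(0, 2**31 - 1))
    img8 = (np.clip(img, 0, 1) * 255).astype(np.uint8)
    if night_level > 0:
        img8 = apply_night(img8, night_level, seed=deg_seed)
    if rain_density > 0:
        img8 = apply_rain(img8, rain_density, seed=deg_seed + 1)
    gt = (BoxSet(np.array(boxes, dtype=np.float32), np.array(labels))
          if boxes else BoxSet(np.zeros((0, 4)), np.zeros(0, dtype=np.int64)))
    return SyntheticScene(img8, gt, night_level, rain_density, index)


# ---------------------------------------------------------------------------
# degradations (never move ground-truth boxes)
# ---------------------------------------------------------------------------


def apply_night(image: np.ndarray, level: float, seed: int = 0) -> np.ndarray:
    """Nighttime degradation: luminance x(1 - 0.8*level), saturation
    x(1 - 0.9*level), plus zero-mean monochrome sensor noise with
    sigma proportional to ``level``.  ``level = 0`` is the identity."""
    if not 0.0 <= level <= 1.0:
        raise ValueError("night level must lie in [0, 1]")
    if level == 0:
        return image
    img = image.astype(np.float32) / 255.0
    gray = img.mean(axis=2, keepdims=True)
    img = gray + (img - gray) * (1.0 - 0.9 * level)      # desaturate
    img = img * (1.0 - 0.8 * level)                      # darken
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 0.04 * level, size=img.shape[:2]).astype(np.float32)
    img = img + noise[..., None]                         # monochrome sensor noise
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def rain_streak_count(density: float, n_max: int = N_MAX_STREAKS) -> int:
    return int(round(density * n_max))


def apply_rain(image: np.ndarray, density: float, seed: int = 0,
               n_max: int = N_MAX_STREAKS) -> np.ndarray:
    """Overlay ``round(density * n_max)`` semi-transparent near-vertical
    streaks plus a slight global blur; ``density = 0`` is the identity."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("rain density must lie in [0, 1]")
    n = rain_streak_count(density, n_max)
    if n == 0:
        return image
    h, w = image.shape[:2]
    img = image.astype(np.float32) / 255.0
    # slight global blur (3x3 box) first, then sharp streaks on top; the
    # blur strength is fixed so the streak set grows monotonically with density
    pad = np.pad(img, ((1, 1), (1, 1), (0, 0)), mode="edge")
    blur = np.zeros_like(img)
    for dy in range(3):
        for dx in range(3):
            blur += pad[dy : dy + h, dx : dx + w]
    blur /= 9.0
    img = 0.75 * img + 0.25 * blur
    rng = np.random.default_rng(seed)
    streak_color = 0.85
    for _ in range(n):
        x0 = rng.uniform(0, w)
        y0 = rng.uniform(-0.1 * h, h)
        length = rng.uniform(0.04, 0.1) * h
        angle = rng.normal(0.0, 0.12)                    # radians off vertical
        alpha = rng.uniform(0.15, 0.35)
        t = np.arange(int(length))
        xs = np.clip(np.round(x0 + t * np.sin(angle)).astype(int), 0, w - 1)
        ys = np.clip(np.round(y0 + t * np.cos(angle)).astype(int), 0, h - 1)
        img[ys, xs] = img[ys, xs] * (1 - alpha) + streak_color * alpha
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# datasets and COCO JSON
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """In-memory detection dataset: images plus per-image ground truth."""

    scenes: list = field(default_factory=list)
    num_classes: int = 9

    def __len__(self):
        return len(self.scenes)


def generate_dataset(config: SceneConfig, n: int) -> Dataset:
    return Dataset([generate_scene(config, i) for i in range(n)], config.num_classes)


def to_coco_dict(dataset: Dataset, file_names: list[str] | None = None) -> dict:
    images, annotations = [], []
    ann_id = 1
    for i, scene in enumerate(dataset.scenes):
        h, w = scene.image.shape[:2]
        images.append({
            "id": i + 1,
            "file_name": file_names[i] if file_names else f"scene_{i:05d}.png",
            "width": w, "height": h,
            "night_level": scene.night_level,
            "rain_density": scene.rain_density,
        })
        for box, label in zip(scene.boxes.boxes, scene.boxes.labels):
            x0, y0, x1, y1 = (float(v) for v in box)
            annotations.append({
                "id": ann_id, "image_id": i + 1, "category_id": int(label) + 1,
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": (x1 - x0) * (y1 - y0), "iscrowd": 0,
            })
            ann_id += 1
    categories = [{"id": c + 1, "name": f"class_{c}"} for c in range(dataset.num_classes)]
    return {"images": images, "annotations": annotations, "categories": categories}


def write_coco(dataset: Dataset, path, image_dir=None) -> None:
    """Write COCO detection JSON (and PNG images when ``image_dir`` given)."""
    file_names = None
    if image_dir is not None:
        from PIL import Image

        os.makedirs(image_dir, exist_ok=True)
        file_names = []
        for i, scene in enumerate(dataset.scenes):
            name = f"scene_{i:05d}.png"
            Image.fromarray(scene.image).save(os.path.join(image_dir, name))
            file_names.append(name)
    with open(path, "w") as fh:
        json.dump(to_coco_dict(dataset, file_names), fh)


def read_coco(path, image_dir=None) -> Dataset:
    """Read COCO detection JSON back into a Dataset.

    Boxes, labels and image references round-trip exactly; pixel data is
    reloaded only when ``image_dir`` is provided, otherwise images are
    zero-filled placeholders of the recorded size.
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValueError(f"malformed COCO JSON: missing top-level key '{key}' in {path}")
    by_image: dict[int, list] = {}
    for k, ann in enumerate(doc["annotations"]):
        for key in ("image_id", "category_id", "bbox"):
            if key not in ann:
                raise ValueError(f"malformed COCO JSON: annotations[{k}] missing '{key}'")
        by_image.setdefault(ann["image_id"], []).append(ann)
    scenes = []
    for k, info in enumerate(doc["images"]):
        for key in ("id", "width", "height"):
            if key not in info:
                raise ValueError(f"malformed COCO JSON: images[{k}] missing '{key}'")
        h, w = info["height"], info["width"]
        if image_dir is not None:
            from PIL import Image

            img = np.asarray(Image.open(os.path.join(image_dir, info["file_name"])).convert("RGB"))
        else:
            img = np.zeros((h, w, 3), dtype=np.uint8)
        anns = by_image.get(info["id"], [])
        boxes = np.array([[a["bbox"][0], a["bbox"][1],
                           a["bbox"][0] + a["bbox"][2], a["bbox"][1] + a["bbox"][3]]
                          for a in anns], dtype=np.float32).reshape(-1, 4)
        labels = np.array([a["category_id"] - 1 for a in anns], dtype=np.int64)
        scenes.append(SyntheticScene(img, BoxSet(boxes, labels),
                                     info.get("night_level", 0.0),
                                     info.get("rain_density", 0.0), index=k))
    return Dataset(scenes, num_classes=len(doc["categories"]))
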