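"""Procedural top-down corn-canopy scenes with center-whorl annotations.

The generator stands in for overhead field imagery (camera 0.5–1 m above
V6–V8 corn): each plant is rendered as radially arranged elongated leaves
around a bright central whorl on textured soil, and annotated with one
bounding box per plant covering the whorl ("center leaf area") in YOLO
normalized format.  Augmentations mirror the usual field recipe: random
brightness within ±25%, rotation, and directional motion blur.

No photorealism is attempted — downstream consumers need consistent
structure (a bright compact target on a darker textured background), not
realistic texture statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["SceneConfig", "AugmentParams", "generate_scene", "augment",
           "generate_detection_stream", "write_dataset"]


@dataclass
class SceneConfig:
    image_size: int = 320
    n_plants: int = 3
    whorl_radius: tuple[int, int] = (14, 22)
    leaves_per_plant: int = 7
    row_spacing_m: float = 0.6
    px_per_m: float = 400.0
    max_place_tries: int = 200

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image size must be >= 64")
        if self.whorl_radius[0] > self.whorl_radius[1]:
            raise ValueError("whorl radius range inverted")


@dataclass
class AugmentParams:
    brightness: float = 0.0        # fractional delta, within [-0.25, 0.25]
    rotation_deg: float = 0.0
    blur_len: int = 0              # motion-blur kernel length (pixels)
    blur_angle_deg: float = 0.0

    def __post_init__(self):
        if abs(self.brightness) > 0.25 + 1e-12:
            raise ValueError("brightness delta must stay within ±25%")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _soil(size: int, rng: np.random.Generator) -> np.ndarray:
    base = np.array([98.0, 74.0, 52.0])
    coarse = rng.normal(0, 18, size=(size // 16 + 1, size // 16 + 1))
    noise = ndimage.zoom(coarse, 16, order=1)[:size, :size]
    noise += rng.normal(0, 4, size=(size, size))
    img = base[None, None, :] + noise[:, :, None]
    return img


def _draw_leaf(img, cx, cy, angle, length, width, color):
    size = img.shape[0]
    x0 = int(max(0, cx - length - 2))
    x1 = int(min(size, cx + length + 2))
    y0 = int(max(0, cy - length - 2))
    y1 = int(min(size, cy + length + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(angle) + dy * np.sin(angle)       # along the leaf
    v = -dx * np.sin(angle) + dy * np.cos(angle)      # across
    # elongated ellipse centered half a length out from the whorl
    mask = ((u - length / 2) / (length / 2)) ** 2 + (v / width) ** 2 <= 1.0
    shade = 1.0 - 0.3 * np.clip(u / max(length, 1), 0, 1)
    for c in range(3):
        img[y0:y1, x0:x1, c] = np.where(mask, color[c] * shade,
                                        img[y0:y1, x0:x1, c])


def _draw_whorl(img, cx, cy, r, color):
    size = img.shape[0]
    x0, x1 = int(max(0, cx - r)), int(min(size, cx + r + 1))
    y0, y1 = int(max(0, cy - r)), int(min(size, cy + r + 1))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    mask = d2 <= r * r
    glow = 1.0 + 0.35 * (1.0 - np.sqrt(np.maximum(d2, 0)) / max(r, 1))
    for c in range(3):
        img[y0:y1, x0:x1, c] = np.where(mask, np.minimum(color[c] * glow, 255),
                                        img[y0:y1, x0:x1, c])


def generate_scene(cfg: SceneConfig, seed: int = 0):
    """Render one scene.  Returns ``(image_uint8_hwc, labels)`` with labels
    as an (n_plants, 5) array of YOLO-normalized ``cls cx cy w h`` rows.
    Deterministic for a fixed (cfg, seed)."""
    rng = np.random.default_rng(seed)
    size = cfg.image_size
    img = _soil(size, rng)
    rmin, rmax = cfg.whorl_radius
    margin = int(rmax * 2.5)
    min_sep = 2.0 * rmax * 2.2    # non-overlapping at whorl scale

    centers, radii = [], []
    tries = 0
    while len(centers) < cfg.n_plants:
        tries += 1
        if tries > cfg.max_place_tries * max(cfg.n_plants, 1):
            raise ValueError(
                f"cannot place {cfg.n_plants} plants in a {size}px scene "
                "without whorl-scale overlap")
        c = rng.uniform(margin, size - margin, size=2)
        if all(np.hypot(*(c - p)) >= min_sep for p in centers):
            centers.append(c)
            radii.append(rng.integers(rmin, rmax + 1))

    labels = np.zeros((cfg.n_plants, 5))
    for i, ((cx, cy), r) in enumerate(zip(centers, radii)):
        leaf_color = np.array([45.0, 120.0, 40.0]) + rng.normal(0, 6, 3)
        whorl_color = np.array([150.0, 200.0, 80.0]) + rng.normal(0, 6, 3)
        base = rng.uniform(0, 2 * np.pi)
        for j in range(cfg.leaves_per_plant):
            ang = base + 2 * np.pi * j / cfg.leaves_per_plant \
                + rng.normal(0, 0.12)
            length = r * rng.uniform(2.2, 3.2)
            width = r * rng.uniform(0.35, 0.55)
            _draw_leaf(img, cx, cy, ang, length, width, leaf_color)
        _draw_whorl(img, cx, cy, r, whorl_color)
        side = 2 * r * 1.5
        labels[i] = [0, cx / size, cy / size,
                     min(side / size, 1.0), min(side / size, 1.0)]

    return np.clip(img, 0, 255).astype(np.uint8), labels


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _motion_kernel(length: int, angle_deg: float) -> np.ndarray:
    k = np.zeros((length, length))
    c = (length - 1) / 2
    th = np.deg2rad(angle_deg)
    for t in np.linspace(-c, c, 4 * length):
        y = int(round(c + t * np.sin(th)))
        x = int(round(c + t * np.cos(th)))
        k[y, x] = 1.0
    return k / k.sum()


def augment(image: np.ndarray, labels: np.ndarray, params: AugmentParams,
            seed: int = 0):
    """Apply brightness / rotation / motion blur; boxes are transformed as
    rotated-extent AABBs and clipped; boxes rotated fully out of frame are
    dropped (with a warning)."""
    img = image.astype(np.float64)
    labels = np.asarray(labels, dtype=np.float64).reshape(-1, 5).copy()
    h, w = img.shape[:2]

    if params.brightness:
        img = img * (1.0 + params.brightness)

    if params.rotation_deg:
        th = np.deg2rad(params.rotation_deg)
        cth, sth = np.cos(th), np.sin(th)
        # forward map on (x, y), y down: p' - c = [[c,-s],[s,c]] (p - c)
        cx0, cy0 = (w - 1) / 2.0, (h - 1) / 2.0
        inv = np.array([[cth, sth], [-sth, cth]])      # inverse rotation
        # ndimage works in (row, col) = (y, x)
        mat = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
        offset = np.array([cy0, cx0]) - mat @ np.array([cy0, cx0])
        chans = [ndimage.affine_transform(img[:, :, c], mat, offset=offset,
                                          order=1, mode="nearest")
                 for c in range(img.shape[2])]
        img = np.stack(chans, axis=2)

        kept = []
        # boxes rotate about the exact image center (w/2, h/2) so that a 90°
        # turn maps normalized (cx, cy) -> (1-cy, cx) exactly
        bcx, bcy = w / 2.0, h / 2.0
        for row in labels:
            _, ncx, ncy, nw, nh = row
            bx, by = ncx * w, ncy * h
            bw, bh = nw * w / 2, nh * h / 2
            corners = np.array([[bx - bw, by - bh], [bx + bw, by - bh],
                                [bx - bw, by + bh], [bx + bw, by + bh]])
            rel = corners - [bcx, bcy]
            rot = rel @ np.array([[cth, sth], [-sth, cth]]) + [bcx, bcy]
            x1, y1 = rot[:, 0].min(), rot[:, 1].min()
            x2, y2 = rot[:, 0].max(), rot[:, 1].max()
            x1, x2 = np.clip([x1, x2], 0, w)
            y1, y2 = np.clip([y1, y2], 0, h)
            if x2 - x1 < 1 or y2 - y1 < 1:
                warnings.warn("box rotated out of frame; dropped")
                continue
            kept.append([row[0], (x1 + x2) / 2 / w, (y1 + y2) / 2 / h,
                         (x2 - x1) / w, (y2 - y1) / h])
        labels = np.array(kept).reshape(-1, 5)

    if params.blur_len > 1:
        k = _motion_kernel(params.blur_len, params.blur_angle_deg)
        img = np.stack([ndimage.convolve(img[:, :, c], k, mode="nearest")
                        for c in range(img.shape[2])], axis=2)

    return np.clip(img, 0, 255).astype(np.uint8), labels


# ---------------------------------------------------------------------------
# Detection streams
# ---------------------------------------------------------------------------

def generate_detection_stream(cfg: SceneConfig, speed_px_per_frame: float,
                              frames: int, center_jitter_sd: float = 0.0,
                              dropout_prob: float = 0.0, seed: int = 0,
                              conf: float = 0.9, plant_gap_px: float | None = None):
    """Simulated per-frame detection lists for a platform driving along a
    row at ``speed_px_per_frame`` (nominal 30 fps video).

    Plants sit on a virtual row ahead of the camera and translate down the
    frame as the platform advances.  Returns a list of frame dicts
    ``{"frame": i, "boxes": [{x, y, w, h, conf, cls}, ...]}`` suitable for
    JSON-lines serialization.
    """
    rng = np.random.default_rng(seed)
    size = cfg.image_size
    gap = plant_gap_px or cfg.row_spacing_m * cfg.px_per_m
    rmin, rmax = cfg.whorl_radius
    plant_y = [-(i + 1) * gap for i in range(cfg.n_plants)]   # ahead of view
    plant_x = [size / 2 + rng.normal(0, size * 0.05) for _ in plant_y]
    plant_r = [rng.integers(rmin, rmax + 1) for _ in plant_y]

    stream = []
    for f in range(frames):
        boxes = []
        for x0, y0, r in zip(plant_x, plant_y, plant_r):
            y = y0 + f * speed_px_per_frame
            if not (0 <= y < size):
                continue
            if dropout_prob and rng.random() < dropout_prob:
                continue
            jx = rng.normal(0, center_jitter_sd) if center_jitter_sd else 0.0
            jy = rng.normal(0, center_jitter_sd) if center_jitter_sd else 0.0
            boxes.append({
                "x": float(x0 + jx), "y": float(y + jy),
                "w": float(3 * r), "h": float(3 * r),
                "conf": float(np.clip(conf + rng.normal(0, 0.02), 0.05, 1.0)),
                "cls": 0,
            })
        stream.append({"frame": f, "boxes": boxes})
    return stream


def write_dataset(out_dir, cfg: SceneConfig, n_scenes: int, seed: int = 0,
                  augment_multiplicity: int = 0):
    """Write ``images/*.png`` + ``labels/*.txt`` (+ manifest.yaml).

    ``augment_multiplicity`` extra augmented copies are emitted per scene;
    the factor is configurable because published dataset expansions vary.
    """
    import yaml
    from pathlib import Path
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = {"seed": seed, "n_scenes": n_scenes,
                "augment_multiplicity": augment_multiplicity, "items": []}

    def emit(name, img, labels):
        Image.fromarray(img).save(out / "images" / f"{name}.png")
        with open(out / "labels" / f"{name}.txt", "w") as fh:
            for row in labels:
                fh.write("%d %.6f %.6f %.6f %.6f\n" % (int(row[0]), *row[1:]))
        manifest["items"].append(name)

    for i in range(n_scenes):
        s = int(rng.integers(0, 2 ** 31 - 1))
        img, labels = generate_scene(cfg, seed=s)
        emit(f"scene_{i:04d}", img, labels)
        for j in range(augment_multiplicity):
            params = AugmentParams(
                brightness=float(rng.uniform(-0.25, 0.25)),
                rotation_deg=float(rng.uniform(0, 360)),
                blur_len=int(rng.integers(0, 9)),
                blur_angle_deg=float(rng.uniform(0, 180)),
            )
            aimg, albl = augment(img, labels, params, seed=s + j + 1)
            emit(f"scene_{i:04d}_aug{j}", aimg, albl)

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest
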