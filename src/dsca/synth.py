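"""Synthetic satellite-like scenes with paired field masks.

The generator emulates the regime of high-resolution (sub-meter) RGB
imagery over a sugarcane-growing landscape: convex polygonal crop
fields carrying a periodic row texture, on a heterogeneous background
of low-frequency terrain color with scene-class-specific distractors
(a river ribbon, bright building blocks). The mask is exactly the union
of the field polygons; distractors are painted before the fields and
never enter the mask.

Three scene classes are cycled across a corpus — ``river``,
``resident`` and ``farmland`` — mirroring the landscape variety a real
tile corpus would contain. Everything is deterministic under the
scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import GenerationError
from .seeds import derive_seed

SCENE_CLASSES = ("river", "resident", "farmland")

# 8-bit base colors: winter-season earth tones and canopy greens
_BACKGROUND_RGB = {"river": (112, 108, 92), "resident": (120, 112, 100),
                   "farmland": (116, 110, 88)}
_FIELD_GREENS = [(62, 96, 44), (74, 110, 50), (56, 88, 40), (80, 118, 58)]
_RIVER_RGB = (62, 88, 96)
_BUILDING_RGB = (190, 185, 178)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    size: tuple[int, int] = (4096, 4096)
    n_fields: int | None = None        # explicit field count; None = coverage-driven
    foreground_fraction_range: tuple[float, float] = (0.30, 0.50)
    texture_period_px: tuple[float, float] = (6.0, 16.0)
    texture_amplitude: float = 18.0
    texture_noise_sd: float = 6.0
    field_radius_rel: tuple[float, float] = (0.06, 0.18)
    scene_class: str | None = None     # None: chosen from the seed
    seed: int = 0
    max_retries: int = 8

    def validate(self) -> None:
        lo, hi = self.foreground_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"invalid coverage range {self.foreground_fraction_range}")
        if self.scene_class is not None and self.scene_class not in SCENE_CLASSES:
            raise ValueError(f"unknown scene class {self.scene_class!r}")


def _bilinear_upsample(grid: np.ndarray, h: int, w: int) -> np.ndarray:
    """Fast float32 bilinear upsample of a coarse (gh, gw, C) grid."""
    gh, gw = grid.shape[:2]
    ys = np.linspace(0, gh - 1, h, dtype=np.float32)
    xs = np.linspace(0, gw - 1, w, dtype=np.float32)
    y0 = np.minimum(ys.astype(np.intp), gh - 2)
    x0 = np.minimum(xs.astype(np.intp), gw - 2)
    fy = (ys - y0)[:, None, None]
    fx = (xs - x0)[None, :, None]
    rows = grid[y0] * (1 - fy) + grid[y0 + 1] * fy        # (h, gw, C)
    return rows[:, x0] * (1 - fx) + rows[:, x0 + 1] * fx  # (h, w, C)


def _low_freq_background(rng: np.random.Generator, h: int, w: int,
                         base_rgb: tuple[int, int, int]) -> np.ndarray:
    """Base color plus bilinearly upsampled coarse noise (terrain mottle)."""
    gh, gw = max(h // 64, 4), max(w // 64, 4)
    coarse = rng.normal(0.0, 14.0, size=(gh, gw, 3)).astype(np.float32)
    img = _bilinear_upsample(coarse, h, w)
    img += np.asarray(base_rgb, dtype=np.float32)
    img += rng.standard_normal((h, w, 1), dtype=np.float32) * np.float32(4.0)  # fine grain
    return img


def _convex_polygon(rng: np.random.Generator, center, radii) -> np.ndarray:
    """Convex hull of random points inside an axis-aligned ellipse."""
    pts = rng.normal(size=(12, 2)) * np.asarray(radii) / 1.5 + np.asarray(center)
    from scipy.spatial import ConvexHull
    hull = ConvexHull(pts)
    return pts[hull.vertices]  # counter-clockwise (row, col) vertices


def _fill_convex(poly: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices inside a convex polygon (half-plane test on the bbox)."""
    r0 = max(int(np.floor(poly[:, 0].min())), 0)
    r1 = min(int(np.ceil(poly[:, 0].max())) + 1, shape[0])
    c0 = max(int(np.floor(poly[:, 1].min())), 0)
    c1 = min(int(np.ceil(poly[:, 1].max())) + 1, shape[1])
    if r1 <= r0 or c1 <= c0:
        return (np.empty(0, dtype=np.intp),) * 2
    # orient counter-clockwise in (row, col) so the interior is left of each edge
    area2 = float(np.sum(poly[:, 0] * np.roll(poly[:, 1], -1)
                         - np.roll(poly[:, 0], -1) * poly[:, 1]))
    if area2 < 0:
        poly = poly[::-1]
    rr = np.arange(r0, r1, dtype=np.float32)[:, None]
    cc = np.arange(c0, c1, dtype=np.float32)[None, :]
    inside = np.ones((r1 - r0, c1 - c0), dtype=bool)
    for i in range(len(poly)):
        ar, ac = poly[i]
        br, bc = poly[(i + 1) % len(poly)]
        inside &= ((br - ar) * (cc - ac) - (bc - ac) * (rr - ar)) >= 0
    ridx, cidx = np.nonzero(inside)
    return ridx + r0, cidx + c0


def _paint_field(img: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                 spec: SceneSpec, shrink: float = 1.0) -> int:
    """Draw one striped convex field; returns the pixel count painted.

    ``shrink`` scales the radius range down as a coverage target nears,
    to avoid overshooting it with one oversized field.
    """
    h, w = mask.shape
    rmin = spec.field_radius_rel[0] * min(h, w)
    rmax = max(spec.field_radius_rel[1] * min(h, w) * shrink, rmin)
    center = rng.uniform([0, 0], [h, w])
    radii = rng.uniform(rmin, rmax, size=2)
    poly = _convex_polygon(rng, center, radii)
    rr, cc = _fill_convex(poly, mask.shape)
    if rr.size == 0:
        return 0
    base = np.asarray(_FIELD_GREENS[rng.integers(len(_FIELD_GREENS))], dtype=np.float32)
    theta = rng.uniform(0, np.pi)
    period = rng.uniform(*spec.texture_period_px)
    phase = rng.uniform(0, 2 * np.pi)
    stripes = np.sin(2 * np.pi * (np.cos(theta) * cc + np.sin(theta) * rr) / period + phase)
    tex = base[None, :] + spec.texture_amplitude * stripes[:, None]
    tex += rng.normal(0.0, spec.texture_noise_sd, size=(rr.size, 1))
    img[rr, cc] = tex
    mask[rr, cc] = 1
    return rr.size


def _paint_river(img: np.ndarray, rng: np.random.Generator) -> None:
    """A meandering ribbon crossing the full scene (never in the mask)."""
    h, w = img.shape[:2]
    n = 24
    ys = np.linspace(0, h - 1, n)
    xs = w * (0.5 + 0.25 * np.sin(np.linspace(0, 3 * np.pi, n) + rng.uniform(0, 2 * np.pi)))
    xs += rng.normal(0, 0.02 * w, n)
    width = rng.uniform(0.02, 0.05) * w
    centers = np.interp(np.arange(h), ys, xs)  # one center column per row
    color = np.asarray(_RIVER_RGB, dtype=np.float32)
    for r in range(h):
        c0 = max(int(centers[r] - width / 2), 0)
        c1 = min(int(centers[r] + width / 2) + 1, w)
        if c1 > c0:
            img[r, c0:c1] = color + rng.normal(0, 5.0)


def _paint_buildings(img: np.ndarray, rng: np.random.Generator) -> None:
    """Bright rectangular blocks (roofs); density scales with scene area."""
    h, w = img.shape[:2]
    count = max(4, int(30 * (h * w) / 4096 ** 2))
    for _ in range(count):
        bh = int(rng.uniform(0.01, 0.03) * h) + 1
        bw = int(rng.uniform(0.01, 0.03) * w) + 1
        r0 = rng.integers(0, max(h - bh, 1))
        c0 = rng.integers(0, max(w - bw, 1))
        tone = np.asarray(_BUILDING_RGB, dtype=np.float32) + rng.normal(0, 8.0, 3)
        img[r0:r0 + bh, c0:c0 + bw] = tone


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene; returns (H×W×3 uint8 image, H×W uint8 {0,1} mask)."""
    spec.validate()
    h, w = spec.size
    lo, hi = spec.foreground_fraction_range
    for attempt in range(spec.max_retries):
        rng = np.random.default_rng(derive_seed(spec.seed, "scene-render", attempt))
        scene_class = spec.scene_class or SCENE_CLASSES[rng.integers(len(SCENE_CLASSES))]
        img = _low_freq_background(rng, h, w, _BACKGROUND_RGB[scene_class])
        if scene_class == "river":
            _paint_river(img, rng)
        elif scene_class == "resident":
            _paint_buildings(img, rng)
        mask = np.zeros((h, w), dtype=np.uint8)

        if spec.n_fields is not None:
            for _ in range(spec.n_fields):
                _paint_field(img, mask, rng, spec)
            image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
            return image, mask

        target = rng.uniform(lo, hi)
        total = h * w
        max_fields = 256
        placed = 0
        frac = 0.0
        while frac < target and placed < max_fields:
            shrink = min(1.0, (target - frac) / 0.08)
            _paint_field(img, mask, rng, spec, shrink=shrink)
            placed += 1
            frac = mask.sum(dtype=np.int64) / total
        if lo - 0.05 <= frac <= hi + 0.05:
            image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
            return image, mask
    raise GenerationError(
        f"could not reach coverage in {spec.foreground_fraction_range} "
        f"after {spec.max_retries} attempts (seed {spec.seed})")


def iter_corpus(n_scenes: int = 20, template: SceneSpec | None = None, seed: int = 0):
    """Yield (scene_id, image, mask) for a corpus; classes are cycled."""
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    template = template or SceneSpec()
    for i in range(n_scenes):
        scene_class = template.scene_class or SCENE_CLASSES[i % len(SCENE_CLASSES)]
        spec = replace(template, scene_class=scene_class,
                       seed=derive_seed(seed, "corpus", i))
        image, mask = generate_scene(spec)
        yield f"scene_{i:03d}", image, mask


def generate_corpus(out_dir: str | Path, n_scenes: int = 20,
                    template: SceneSpec | None = None, seed: int = 0) -> list[dict]:
    """Write a corpus of scene/mask PNG pairs; returns manifest rows."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for scene_id, image, mask in iter_corpus(n_scenes, template, seed):
        img_path = out_dir / f"{scene_id}.png"
        mask_path = out_dir / f"{scene_id}_mask.png"
        iio.imwrite(img_path, image)
        iio.imwrite(mask_path, (mask * 255).astype(np.uint8))
        rows.append({"scene_id": scene_id, "image_path": str(img_path),
                     "mask_path": str(mask_path),
                     "foreground_fraction": float(mask.mean())})
    return rows
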