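"""Simultaneous augmentation of training tiles.

Every augmented copy applies the full transform list at once, with
parameters drawn independently per copy from a seed derived from the
tile's identity — so any copy can be re-generated bit-identically
without storing it:

    geometric  rotation (±45°) and scaling (0.9–1.1), applied as one
               affine resample about the tile center; horizontal and
               vertical flips. Image borders are reflection-padded,
               mask borders are background (0); the mask uses
               nearest-neighbour interpolation and stays binary.
    photometric (image only) brightness/contrast (±0.2), hue/
               saturation/value shifts (20/30/20 on 8-bit scale),
               Gaussian blur (kernel 3–7), Gaussian noise
               (variance 10–50 on 8-bit scale).

The parameter ranges are configuration, not contract — dataset counts
and determinism are what downstream stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .data import TileRecord
from .errors import DataError
from .seeds import derive_seed


@dataclass(frozen=True)
class AugSpec:
    """Transform ranges and the number of augmented copies per original."""

    copies_per_original: int = 5
    rotation_limit_deg: float = 45.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    brightness_limit: float = 0.2
    contrast_limit: float = 0.2
    noise_var_range: tuple[float, float] = (10.0, 50.0)
    blur_kernel_range: tuple[int, int] = (3, 7)
    hsv_shift: tuple[float, float, float] = (20.0, 30.0, 20.0)
    seed: int = 0

    def validate(self) -> None:
        if self.copies_per_original < 0:
            raise ValueError("copies_per_original must be >= 0")
        if self.blur_kernel_range[0] % 2 == 0:
            raise ValueError("blur kernels must be odd")


def draw_params(spec: AugSpec, record: TileRecord, copy_index: int) -> dict:
    """Draw one copy's transform parameters, reproducibly."""
    rng = np.random.default_rng(derive_seed(
        spec.seed, "augment", record.scene_id, record.row, record.col, copy_index))
    lo_k, hi_k = spec.blur_kernel_range
    return {
        "angle_deg": float(rng.uniform(-spec.rotation_limit_deg, spec.rotation_limit_deg)),
        "scale": float(rng.uniform(*spec.scale_range)),
        "hflip": bool(rng.random() < 0.5),
        "vflip": bool(rng.random() < 0.5),
        "brightness": float(rng.uniform(-spec.brightness_limit, spec.brightness_limit)),
        "contrast": float(rng.uniform(-spec.contrast_limit, spec.contrast_limit)),
        "hue_shift": float(rng.uniform(-spec.hsv_shift[0], spec.hsv_shift[0])),
        "sat_shift": float(rng.uniform(-spec.hsv_shift[1], spec.hsv_shift[1])),
        "val_shift": float(rng.uniform(-spec.hsv_shift[2], spec.hsv_shift[2])),
        "blur_kernel": int(rng.choice(np.arange(lo_k, hi_k + 1, 2))),
        "noise_var": float(rng.uniform(*spec.noise_var_range)),
        "noise_seed": int(rng.integers(0, 2 ** 31)),
    }


def _rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    """Vectorised float32 RGB→HSV on [0,1] (same convention as colorsys)."""
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    v = maxc
    delta = maxc - minc
    s = np.where(maxc > 0, delta / np.maximum(maxc, 1e-12), 0.0)
    safe = np.where(delta > 0, delta, 1.0)
    rc = (maxc - r) / safe
    gc = (maxc - g) / safe
    bc = (maxc - b) / safe
    h = np.where(maxc == r, bc - gc, np.where(maxc == g, 2.0 + rc - bc, 4.0 + gc - rc))
    h = np.where(delta > 0, (h / 6.0) % 1.0, 0.0)
    return np.stack([h, s, v], axis=-1).astype(np.float32)


def _hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Vectorised float32 HSV→RGB inverse of :func:`_rgb_to_hsv`."""
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    i = np.floor(h * 6.0)
    f = h * 6.0 - i
    i = i.astype(np.int32) % 6
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.select([i == 0, i == 1, i == 2, i == 3, i == 4, i == 5], [v, q, p, p, t, v])
    g = np.select([i == 0, i == 1, i == 2, i == 3, i == 4, i == 5], [t, v, v, q, p, p])
    b = np.select([i == 0, i == 1, i == 2, i == 3, i == 4, i == 5], [p, p, t, v, v, q])
    return np.stack([r, g, b], axis=-1).astype(np.float32)


def _affine(image: np.ndarray, mask: np.ndarray, angle_deg: float, scale: float):
    """One bilinear resample for rotation+scale; nearest for the mask.

    Quarter-turns at unit scale take an exact array-rotation path so
    they are lossless (the resampling path drops border pixels whose
    mapped coordinates fall an epsilon outside the grid).
    """
    if scale == 1.0 and angle_deg % 90.0 == 0.0:
        k = int(angle_deg / 90.0) % 4
        return np.rot90(image, k, axes=(0, 1)), np.rot90(mask, k)
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    # output->input mapping: inverse of (scale * rotation)
    inv = rot.T / scale
    center = (np.array(mask.shape, dtype=np.float64) - 1) / 2.0
    offset = center - inv @ center
    img_out = np.empty_like(image)
    for ch in range(image.shape[2]):
        img_out[..., ch] = ndimage.affine_transform(
            image[..., ch], inv, offset=offset, order=1, mode="reflect",
            output=image.dtype)
    mask_out = ndimage.affine_transform(mask, inv, offset=offset, order=0,
                                        mode="constant", cval=0, output=mask.dtype)
    return img_out, mask_out


def apply_augmentation(image: np.ndarray, mask: np.ndarray, params: dict
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the full simultaneous transform chain for one copy."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    img, msk = _affine(image, mask, params["angle_deg"], params["scale"])
    if params["hflip"]:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if params["vflip"]:
        img, msk = img[::-1], msk[::-1]

    out = img.astype(np.float32)
    # brightness / contrast on 8-bit scale
    out = out * (1.0 + params["contrast"]) + params["brightness"] * 255.0
    out = np.clip(out, 0, 255)
    # hue / saturation / value
    hsv = _rgb_to_hsv(out / np.float32(255.0))
    hsv[..., 0] = (hsv[..., 0] + params["hue_shift"] / 360.0) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] + params["sat_shift"] / 255.0, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] + params["val_shift"] / 255.0, 0.0, 1.0)
    out = _hsv_to_rgb(hsv) * np.float32(255.0)
    # Gaussian blur with the OpenCV kernel-size -> sigma convention
    k = params["blur_kernel"]
    sigma = 0.3 * ((k - 1) * 0.5 - 1) + 0.8
    radius = (k - 1) // 2
    out = ndimage.gaussian_filter(out, sigma=(sigma, sigma, 0), truncate=radius / sigma)
    # additive Gaussian noise
    noise_rng = np.random.default_rng(params["noise_seed"])
    out = out + noise_rng.standard_normal(out.shape, dtype=np.float32) \
        * np.float32(np.sqrt(params["noise_var"]))
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)

    msk = np.ascontiguousarray(msk)
    if not np.isin(msk, (0, 1)).all():
        raise DataError("mask left the binary domain during augmentation")
    return out, msk


def realize_augmented(source: TileRecord, spec: AugSpec, copy_index: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Materialise one augmented copy of ``source`` (copy_index >= 1)."""
    params = draw_params(spec, source, copy_index)
    return apply_augmentation(source.load_image(), source.load_mask(), params)


def augment_training_set(train_records: list[TileRecord], spec: AugSpec
                         ) -> list[TileRecord]:
    """Return originals plus ``copies_per_original`` augmented records each.

    Augmented records carry provenance only; their rasters are derived
    lazily (and reproducibly) via :func:`realize_augmented`, or written
    eagerly by the CLI.
    """
    spec.validate()
    out: list[TileRecord] = []
    for rec in train_records:
        if rec.aug_index != 0:
            raise DataError(f"refusing to augment an augmented tile: {rec.key()}")
        if rec.split not in (None, "train"):
            raise DataError(f"only training tiles may be augmented, got split={rec.split}")
        out.append(rec)
        for k in range(1, spec.copies_per_original + 1):
            out.append(TileRecord(scene_id=rec.scene_id, row=rec.row, col=rec.col,
                                  split=rec.split, aug_index=k,
                                  aug_spec=spec, source=rec))
    return out
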