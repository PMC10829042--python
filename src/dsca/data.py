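"""Tile pipeline: cropping scenes into 512×512 tiles, per-scene
train/val/test allocation, and the training-set augmentation bookkeeping.

A 4096×4096 scene yields an 8×8 grid of 64 non-overlapping tiles; with
20 scenes and a 70/15/15 split this is the 896/192/192 original-tile
allocation, and 5 augmented copies per training original give
896 + 4480 = 5376 training images.

Tiles are represented by :class:`TileRecord`, which may be backed either
by in-memory arrays or by image files; augmented records store only the
provenance (source tile + copy index) and re-derive their rasters
deterministically from the augmentation seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import DataError, TilingError
from .seeds import derive_seed

SPLITS = ("train", "val", "test")


@dataclass
class TileRecord:
    """One image/mask tile with provenance.

    ``aug_index`` 0 marks an original crop; 1..k mark augmented copies.
    Exactly one of (``image``, ``image_path``) should be set per raster.
    """

    scene_id: str
    row: int
    col: int
    split: str | None = None
    aug_index: int = 0
    image: np.ndarray | None = None
    mask: np.ndarray | None = None
    image_path: str | None = None
    mask_path: str | None = None
    aug_spec: "object | None" = None    # AugSpec for augmented records
    source: "TileRecord | None" = None  # original record for augmented copies

    def load_image(self) -> np.ndarray:
        """H×W×3 uint8 image (augmented copies are re-derived on demand)."""
        if self.aug_index > 0 and self.image is None and self.image_path is None:
            img, _ = self._realize()
            return img
        if self.image is not None:
            return self.image
        if self.image_path is None:
            raise DataError(f"tile {self.key()} has no image data or path")
        return np.asarray(iio.imread(self.image_path))[..., :3]

    def load_mask(self) -> np.ndarray:
        """H×W uint8 mask with values {0, 1} (255 on disk maps to 1)."""
        if self.aug_index > 0 and self.mask is None and self.mask_path is None:
            _, mask = self._realize()
            return mask
        if self.mask is not None:
            return self.mask
        if self.mask_path is None:
            raise DataError(f"tile {self.key()} has no mask data or path")
        raw = np.asarray(iio.imread(self.mask_path))
        if raw.ndim == 3:
            raw = raw[..., 0]
        return (raw > 127).astype(np.uint8)

    def _realize(self) -> tuple[np.ndarray, np.ndarray]:
        from .augment import realize_augmented
        if self.source is None or self.aug_spec is None:
            raise DataError(f"augmented tile {self.key()} lacks source/aug_spec")
        return realize_augmented(self.source, self.aug_spec, self.aug_index)

    def key(self) -> str:
        return f"{self.scene_id}/r{self.row}c{self.col}/a{self.aug_index}"


def tile_scene(image: np.ndarray, mask: np.ndarray, tile_size: int = 512,
               scene_id: str = "scene") -> list[TileRecord]:
    """Crop a scene into a row-major grid of non-overlapping tiles.

    Both dimensions must be exact multiples of ``tile_size``; partial
    tiles are refused rather than padded.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.ndim != 3 or image.shape[2] < 3:
        raise TilingError(f"scene image must be H×W×3, got {image.shape}")
    if mask.shape != image.shape[:2]:
        raise TilingError(f"mask shape {mask.shape} != image {image.shape[:2]}")
    h, w = image.shape[:2]
    if h % tile_size or w % tile_size:
        raise TilingError(f"scene {h}×{w} is not divisible by tile size {tile_size}")
    records = []
    for r in range(h // tile_size):
        for c in range(w // tile_size):
            sl = (slice(r * tile_size, (r + 1) * tile_size),
                  slice(c * tile_size, (c + 1) * tile_size))
            records.append(TileRecord(scene_id=scene_id, row=r, col=c,
                                      image=image[sl], mask=mask[sl]))
    return records


def stitch_tiles(records: list[TileRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Reassemble original tiles of one scene; exact inverse of tiling."""
    originals = [r for r in records if r.aug_index == 0]
    if not originals:
        raise DataError("no original tiles to stitch")
    ts = originals[0].load_image().shape[0]
    nrow = max(r.row for r in originals) + 1
    ncol = max(r.col for r in originals) + 1
    image = np.zeros((nrow * ts, ncol * ts, 3), dtype=np.uint8)
    mask = np.zeros((nrow * ts, ncol * ts), dtype=np.uint8)
    for r in originals:
        sl = (slice(r.row * ts, (r.row + 1) * ts), slice(r.col * ts, (r.col + 1) * ts))
        image[sl] = r.load_image()
        mask[sl] = r.load_mask()
    return image, mask


# ---------------------------------------------------------------------------
# split allocation
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Per-scene and global train/val/test tile counts."""

    fractions: tuple[float, float, float]
    per_scene: list[tuple[int, int, int]]
    totals: tuple[int, int, int]

    def as_dict(self) -> dict:
        return {"fractions": list(self.fractions),
                "per_scene": [list(t) for t in self.per_scene],
                "totals": list(self.totals)}


def _largest_remainder(count: int, fractions: tuple[float, float, float]) -> list[int]:
    """Round fraction·count to integers; ties favour train > val > test."""
    exact = [f * count for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    leftover = count - sum(base)
    # sort by remainder descending, position ascending breaks ties
    order = sorted(range(3), key=lambda i: (-(exact[i] - base[i]), i))
    for i in range(leftover):
        base[order[i % 3]] += 1
    return base


def allocate_split(tiles_per_scene: list[int],
                   fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                   seed: int = 0) -> SplitPlan:
    """Largest-remainder per-scene allocation with a global correction pass.

    Per scene the fraction·count targets are rounded by largest
    remainder (ties broken train > val > test). Because 70% of 64 is
    44.8, per-scene rounding drifts from the global targets
    round(fraction·total); a deterministic correction pass then
    reassigns single tiles in seeded scene order until the global totals
    are exact.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative")
    per_scene = [_largest_remainder(n, fractions) for n in tiles_per_scene]
    total = sum(tiles_per_scene)
    targets = _largest_remainder(total, fractions)
    current = [sum(s[i] for s in per_scene) for i in range(3)]
    rng = np.random.default_rng(seed)
    scene_order = rng.permutation(len(per_scene))
    guard = 0
    while current != targets:
        moved = False
        over = [i for i in range(3) if current[i] > targets[i]]
        under = [i for i in range(3) if current[i] < targets[i]]
        for si in scene_order:
            scene = per_scene[si]
            done = False
            for o in over:
                if scene[o] > 0:
                    for u in under:
                        scene[o] -= 1
                        scene[u] += 1
                        current[o] -= 1
                        current[u] += 1
                        moved = done = True
                        break
                if done:
                    break
            if done and current == targets:
                break
            over = [i for i in range(3) if current[i] > targets[i]]
            under = [i for i in range(3) if current[i] < targets[i]]
            if not over:
                break
        guard += 1
        if not moved or guard > total:
            raise DataError("split correction pass failed to converge")
    return SplitPlan(fractions=tuple(fractions),
                     per_scene=[tuple(s) for s in per_scene],
                     totals=tuple(current))


def assign_splits(records: list[TileRecord], plan: SplitPlan,
                  scene_ids: list[str], seed: int = 0) -> list[TileRecord]:
    """Set each record's split according to ``plan`` (seeded in-scene shuffle)."""
    by_scene: dict[str, list[TileRecord]] = {sid: [] for sid in scene_ids}
    for r in records:
        if r.scene_id not in by_scene:
            raise DataError(f"record scene {r.scene_id} not in plan")
        by_scene[r.scene_id].append(r)
    for sid, counts in zip(scene_ids, plan.per_scene):
        tiles = sorted(by_scene[sid], key=lambda r: (r.row, r.col))
        if len(tiles) != sum(counts):
            raise DataError(f"scene {sid}: {len(tiles)} tiles but plan has {sum(counts)}")
        rng = np.random.default_rng(derive_seed(seed, "split", sid))
        order = rng.permutation(len(tiles))
        labels = (["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2])
        for idx, label in zip(order, labels):
            tiles[idx].split = label
    return records


# ---------------------------------------------------------------------------
# manifests and batch loading
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["scene_id", "row", "col", "split", "aug_index", "image_path", "mask_path"]


def write_manifest(records: list[TileRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in records:
            writer.writerow([r.scene_id, r.row, r.col, r.split or "", r.aug_index,
                             r.image_path or "", r.mask_path or ""])


def read_manifest(path: str | Path) -> list[TileRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise DataError(f"manifest missing columns: {sorted(missing)}")
        for row in reader:
            records.append(TileRecord(
                scene_id=row["scene_id"], row=int(row["row"]), col=int(row["col"]),
                split=row["split"] or None, aug_index=int(row["aug_index"]),
                image_path=row["image_path"] or None, mask_path=row["mask_path"] or None))
    return records


def load_batch(records: list[TileRecord], normalization=None) -> tuple[np.ndarray, np.ndarray]:
    """Stack records into a float N×3×H×W batch plus N×H×W mask array."""
    missing = [r.key() for r in records
               if r.image is None and r.image_path is None and r.aug_index == 0]
    if missing:
        raise DataError(f"missing image data for tiles: {missing}")
    images = np.stack([r.load_image() for r in records]).astype(np.float32) / 255.0
    masks = np.stack([r.load_mask() for r in records]).astype(np.int64)
    images = images.transpose(0, 3, 1, 2)
    if normalization is not None:
        mean, std = normalization
        images = (images - np.asarray(mean, dtype=np.float32)[None, :, None, None]) \
            / np.asarray(std, dtype=np.float32)[None, :, None, None]
    return images, masks


def compute_normalization(records: list[TileRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std of the (original) training tiles, on [0,1] scale."""
    originals = [r for r in records if r.aug_index == 0]
    if not originals:
        raise DataError("no original tiles to normalize from")
    s = np.zeros(3)
    s2 = np.zeros(3)
    n = 0
    for r in originals:
        img = r.load_image().astype(np.float64) / 255.0
        s += img.sum(axis=(0, 1))
        s2 += (img ** 2).sum(axis=(0, 1))
        n += img.shape[0] * img.shape[1]
    mean = s / n
    std = np.sqrt(np.maximum(s2 / n - mean ** 2, 1e-8))
    return mean.astype(np.float32), std.astype(np.float32)
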