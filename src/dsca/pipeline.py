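"""End-to-end dataset construction: synth → tile → split → augment.

Scenes are processed as a stream so a full-size corpus (20 scenes of
4096×4096) never has to live in memory at once. The split plan is
computed up front from the per-scene tile counts (which follow from the
geometry alone), then each scene is generated, tiled, labelled and —
for training tiles — augmented.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .augment import AugSpec, augment_training_set, realize_augmented
from .data import (SplitPlan, TileRecord, allocate_split, assign_splits,
                   tile_scene, write_manifest)
from .errors import ConfigError
from .seeds import derive_seed
from .synth import SceneSpec, iter_corpus


@dataclass
class DatasetSummary:
    """Counts and provenance of a constructed dataset."""

    tiles_per_scene: int
    total_tiles: int
    originals: dict[str, int]            # per split
    augmented_train: int
    total_train_images: int
    plan: SplitPlan
    records: list[TileRecord] = field(default_factory=list)
    augmented_checksum: int | None = None

    def table(self) -> dict[str, tuple[int, int, int]]:
        """Original / augmented / total counts per split."""
        return {
            "train": (self.originals["train"], self.augmented_train, self.total_train_images),
            "val": (self.originals["val"], 0, self.originals["val"]),
            "test": (self.originals["test"], 0, self.originals["test"]),
        }


def build_dataset(n_scenes: int = 20, scene_template: SceneSpec | None = None,
                  tile_size: int = 512,
                  fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  aug_spec: AugSpec | None = None, seed: int = 0,
                  out_dir: str | Path | None = None,
                  materialize: str = "none") -> DatasetSummary:
    """Construct a tile dataset from a synthetic corpus.

    ``materialize`` controls what happens to augmented rasters:

    * ``"none"``  — keep records lazy (in-memory tiles; small corpora).
    * ``"stream"`` — realize every augmented raster once during the
      scene pass (checksummed), then drop all pixel data; used to
      validate a full-size corpus without holding it.
    * ``"drop"``  — record-keeping only: drop pixel data after tiling
      without realizing augmented rasters (count audits).
    * ``"store"`` — write every tile and augmented copy under
      ``out_dir`` and point records at the files.
    """
    if materialize not in ("none", "stream", "drop", "store"):
        raise ConfigError(f"unknown materialize mode {materialize!r}")
    if materialize == "store" and out_dir is None:
        raise ConfigError("materialize='store' requires out_dir")
    scene_template = scene_template or SceneSpec()
    aug_spec = aug_spec if aug_spec is not None else AugSpec(seed=derive_seed(seed, "augment"))

    h, w = scene_template.size
    if h % tile_size or w % tile_size:
        raise ConfigError(f"scene size {scene_template.size} not divisible by tile {tile_size}")
    tiles_per_scene = (h // tile_size) * (w // tile_size)
    scene_ids = [f"scene_{i:03d}" for i in range(n_scenes)]
    plan = allocate_split([tiles_per_scene] * n_scenes, fractions,
                          seed=derive_seed(seed, "split"))

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "tiles").mkdir(parents=True, exist_ok=True)

    all_records: list[TileRecord] = []
    originals = {"train": 0, "val": 0, "test": 0}
    augmented = 0
    checksum = 0
    for scene_id, image, mask in iter_corpus(n_scenes, scene_template, seed):
        records = tile_scene(image, mask, tile_size, scene_id)
        assign_splits(records, SplitPlan(plan.fractions,
                                         [plan.per_scene[scene_ids.index(scene_id)]],
                                         plan.totals),
                      [scene_id], seed=derive_seed(seed, "assign"))
        for rec in records:
            originals[rec.split] += 1
        train_recs = [r for r in records if r.split == "train"]
        augmented_recs = [r for r in augment_training_set(train_recs, aug_spec)
                          if r.aug_index > 0]
        augmented += len(augmented_recs)

        if materialize == "store":
            for rec in records + augmented_recs:
                img = rec.load_image()
                msk = rec.load_mask()
                stem = f"{rec.scene_id}_r{rec.row}c{rec.col}_a{rec.aug_index}"
                rec.image_path = str(out_path / "tiles" / f"{stem}.png")
                rec.mask_path = str(out_path / "tiles" / f"{stem}_mask.png")
                iio.imwrite(rec.image_path, img)
                iio.imwrite(rec.mask_path, (msk * 255).astype(np.uint8))
                rec.image = rec.mask = None
                rec.source = None
        elif materialize in ("stream", "drop"):
            if materialize == "stream":
                for rec in augmented_recs:
                    img, msk = realize_augmented(rec.source, aug_spec, rec.aug_index)
                    checksum = zlib.crc32(img.tobytes(), checksum)
                    checksum = zlib.crc32(msk.tobytes(), checksum)
            for rec in records + augmented_recs:
                rec.image = rec.mask = None
                rec.source = None
        all_records.extend(records)
        all_records.extend(augmented_recs)

    summary = DatasetSummary(
        tiles_per_scene=tiles_per_scene,
        total_tiles=tiles_per_scene * n_scenes,
        originals=originals,
        augmented_train=augmented,
        total_train_images=originals["train"] + augmented,
        plan=plan,
        records=all_records,
        augmented_checksum=checksum if materialize == "stream" else None,
    )
    if out_path is not None:
        write_manifest(all_records, out_path / "manifest.csv")
    return summary


def tiny_corpus(n_tiles: int = 8, tile_size: int = 64, seed: int = 0,
                foreground_fraction_range: tuple[float, float] = (0.30, 0.50)
                ) -> list[TileRecord]:
    """A small in-memory tile set for desk-scale training experiments.

    Builds one scene shaped to yield exactly ``n_tiles`` tiles in a
    near-square grid.
    """
    ncol = int(np.ceil(np.sqrt(n_tiles)))
    while n_tiles % ncol:
        ncol += 1
    nrow = n_tiles // ncol
    spec = SceneSpec(size=(nrow * tile_size, ncol * tile_size),
                     foreground_fraction_range=foreground_fraction_range,
                     scene_class="farmland", seed=derive_seed(seed, "tiny"))
    from .synth import generate_scene
    image, mask = generate_scene(spec)
    records = tile_scene(image, mask, tile_size, "tiny_000")
    for r in records:
        r.split = "train"
    return records
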