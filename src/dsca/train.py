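"""Training recipe: cross-entropy loss, AdamW, triangular cyclical
learning rate, seeded shuffling, best-validation-IoU checkpointing.

The learning-rate policy rises linearly from the base rate (1e-4) to
the maximum (1e-3) over the first half of a cycle and falls back over
the second; one cycle spans 10 epochs by default. The loss is plain
two-class pixel cross-entropy — the simplest loss consistent with the
four-cell confusion-count evaluation; a Dice or weighted variant can be
swapped in through the config.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .data import TileRecord, compute_normalization, load_batch
from .errors import ConfigError, DataError, DivergenceError
from .metrics import ConfusionCounts, accumulate, metrics, predict_mask
from .model import DSCAPSPNet, ModelSpec, build_model
from .nn import AdamW, Tensor
from .seeds import derive_seed


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    base_lr: float = 1e-4
    max_lr: float = 1e-3
    weight_decay: float = 1e-2
    cycle_epochs: int = 10
    seed: int = 0
    max_steps: int | None = None    # optional hard cap on optimizer steps

    def validate(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.base_lr >= self.max_lr:
            raise ConfigError(f"base_lr {self.base_lr} must be < max_lr {self.max_lr}")


def segmentation_loss(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Mean pixel-wise 2-class cross-entropy of N×2×H×W logits."""
    mask = np.asarray(mask)
    if mask.ndim == logits.ndim - 2:
        mask = mask[None]
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    return nn.softmax_cross_entropy(logits, mask.astype(np.int64))


def cyclical_lr(step: int, steps_per_cycle: int, base_lr: float, max_lr: float) -> float:
    """Triangular policy: base→max over a half cycle, max→base over the next."""
    if steps_per_cycle < 2:
        raise ConfigError("steps_per_cycle must be >= 2")
    if base_lr >= max_lr:
        raise ConfigError(f"base_lr {base_lr} must be < max_lr {max_lr}")
    pos = (step % steps_per_cycle) / steps_per_cycle
    tri = 1.0 - abs(2.0 * pos - 1.0)
    return base_lr + (max_lr - base_lr) * tri


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)

    def log_lines(self) -> list[str]:
        lines = []
        for e in range(len(self.train_loss)):
            lines.append(json.dumps({
                "epoch": e + 1, "train_loss": self.train_loss[e],
                "val_loss": self.val_loss[e] if e < len(self.val_loss) else None,
                "val_iou": self.val_iou[e] if e < len(self.val_iou) else None}))
        return lines


@dataclass
class TrainResult:
    history: TrainHistory
    best_state: dict
    best_val_iou: float
    normalization: tuple[np.ndarray, np.ndarray]
    steps: int


def _split_metrics(model: DSCAPSPNet, records, normalization, batch_size):
    counts = ConfusionCounts()
    losses = []
    model.eval()
    with nn.no_grad():
        for start in range(0, len(records), batch_size):
            batch = records[start:start + batch_size]
            images, masks = load_batch(batch, normalization)
            logits = model(Tensor(images))
            losses.append(float(segmentation_loss(logits, masks).item()) * len(batch))
            accumulate(predict_mask(logits.data), masks.astype(np.uint8), counts)
    model.train()
    return sum(losses) / len(records), metrics(counts).iou


def train(model: DSCAPSPNet, train_records: list[TileRecord],
          cfg: TrainConfig, val_records: list[TileRecord] | None = None,
          normalization: tuple | None = None) -> TrainResult:
    """Run the training loop; returns history plus the best checkpoint state.

    'Best' means highest validation IoU (training IoU when no validation
    split is given). Shuffling, and therefore the whole trajectory, is
    deterministic under ``cfg.seed`` on a fixed machine.
    """
    cfg.validate()
    if not train_records:
        raise DataError("training split is empty")
    if normalization is None:
        normalization = compute_normalization(train_records)
    steps_per_epoch = max(1, int(np.ceil(len(train_records) / cfg.batch_size)))
    steps_per_cycle = max(2, cfg.cycle_epochs * steps_per_epoch)
    optimizer = AdamW(model.parameters(), lr=cfg.base_lr, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_state: dict = copy.deepcopy(model.state_dict())
    best_iou = -1.0
    step = 0
    model.train()
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(derive_seed(cfg.seed, "epoch", epoch))
        order = rng.permutation(len(train_records))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_records[i] for i in order[start:start + cfg.batch_size]]
            images, masks = load_batch(batch, normalization)
            optimizer.lr = cyclical_lr(step, steps_per_cycle, cfg.base_lr, cfg.max_lr)
            history.lr_trace.append(optimizer.lr)
            logits = model(Tensor(images))
            loss = segmentation_loss(logits, masks)
            if not np.isfinite(loss.item()):
                raise DivergenceError(epoch + 1, step)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                break
        history.train_loss.append(float(np.mean(epoch_losses)))
        eval_records = val_records if val_records else train_records
        val_loss, val_iou = _split_metrics(model, eval_records, normalization, cfg.batch_size)
        history.val_loss.append(val_loss)
        history.val_iou.append(val_iou)
        if val_iou > best_iou:
            best_iou = val_iou
            best_state = copy.deepcopy(model.state_dict())
        if cfg.max_steps is not None and step >= cfg.max_steps:
            break
    return TrainResult(history=history, best_state=best_state, best_val_iou=best_iou,
                       normalization=normalization, steps=step)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: DSCAPSPNet,
                    normalization: tuple | None = None,
                    optimizer: AdamW | None = None, extra: dict | None = None) -> None:
    """Persist weights + ModelSpec + normalization (npz container)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload: dict[str, np.ndarray] = {}
    for key, value in model.state_dict().items():
        payload["state//" + key] = value
    meta = {"spec": model.spec.to_dict(), "extra": extra or {}}
    payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if normalization is not None:
        payload["norm_mean"], payload["norm_std"] = normalization
    if optimizer is not None:
        payload["opt_t"] = np.asarray(optimizer.t)
        for i, (m, v) in enumerate(zip(optimizer.m, optimizer.v)):
            payload[f"opt_m//{i}"] = m
            payload[f"opt_v//{i}"] = v
    np.savez(path, **payload)


def load_checkpoint(path: str | Path, seed: int = 0
                    ) -> tuple[DSCAPSPNet, tuple | None, dict]:
    """Rebuild the model from a checkpoint; forward passes match bit-for-bit."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        spec = ModelSpec.from_dict(meta["spec"])
        model = build_model(spec, seed=seed)
        state = {key[len("state//"):]: data[key] for key in data.files
                 if key.startswith("state//")}
        model.load_state_dict(state)
        norm = None
        if "norm_mean" in data.files:
            norm = (data["norm_mean"], data["norm_std"])
    model.eval()
    return model, norm, meta.get("extra", {})
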