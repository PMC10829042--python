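"""Pixel-level segmentation metrics from accumulated confusion counts.

All five scores are derived from the 2×2 pixel confusion table with
sugarcane (mask value 1) as the positive class:

    IoU       = TP / (TP + FP + FN)
    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2·Precision·Recall / (Precision + Recall)

The dataset-level protocol is micro-averaging: one global confusion
table pooled over all evaluated tiles, under which F1 = 2·IoU/(1+IoU)
holds as an exact identity. A macro average (mean of per-tile scores)
is reported alongside for comparison, since the two can differ
materially on heterogeneous tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


@dataclass
class ConfusionCounts:
    """Accumulated TP/FP/FN/TN pixel tallies."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def accumulate(pred_mask: np.ndarray, true_mask: np.ndarray,
               counts: ConfusionCounts | None = None) -> ConfusionCounts:
    """Add the per-pixel tallies of one prediction/truth pair to ``counts``."""
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    for name, arr in (("prediction", pred), ("truth", true)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary (0/1)")
    counts = counts or ConfusionCounts()
    p = pred.astype(bool)
    t = true.astype(bool)
    counts.tp += int(np.count_nonzero(p & t))
    counts.fp += int(np.count_nonzero(p & ~t))
    counts.fn += int(np.count_nonzero(~p & t))
    counts.tn += int(np.count_nonzero(~p & ~t))
    return counts


@dataclass
class MetricsReport:
    """The five scores as fractions in [0, 1]; ``percent()`` rescales."""

    iou: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    flags: tuple[str, ...] = ()

    def percent(self) -> dict[str, float]:
        return {k: round(100.0 * getattr(self, k), 2)
                for k in ("iou", "accuracy", "precision", "recall", "f1")}

    def as_dict(self) -> dict:
        d = self.percent()
        if self.flags:
            d["flags"] = list(self.flags)
        return d


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Compute the five scores; zero-denominator ratios with TP = 0 are 0."""
    if counts.total == 0:
        raise DataError("cannot compute metrics from zero evaluated pixels")
    flags = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(f"{name}: zero denominator, defined as 0")
            return 0.0
        return num / den

    iou = ratio(counts.tp, counts.tp + counts.fp + counts.fn, "iou")
    acc = counts.tp + counts.tn, counts.total
    accuracy = acc[0] / acc[1]
    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    if precision + recall == 0:
        flags.append("f1: zero denominator, defined as 0")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(iou, accuracy, precision, recall, f1, tuple(flags))


def predict_mask(logits: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over class logits (K,H,W) or (N,K,H,W) -> binary mask."""
    logits = np.asarray(logits)
    axis = 0 if logits.ndim == 3 else 1
    return logits.argmax(axis=axis).astype(np.uint8)


@dataclass
class DatasetReport:
    """Micro (pooled counts) and macro (mean of per-tile scores) summaries."""

    micro: MetricsReport
    macro: MetricsReport
    counts: ConfusionCounts
    per_tile: list[MetricsReport] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"protocol": "micro (global pixel counts); macro shown for comparison",
                "micro": self.micro.as_dict(), "macro": self.macro.as_dict(),
                "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                           "fn": self.counts.fn, "tn": self.counts.tn},
                "n_tiles": len(self.per_tile)}


def evaluate_dataset(model, records, normalization=None, batch_size: int = 4) -> DatasetReport:
    """Evaluate ``model`` on tile ``records``; micro-average is the headline.

    ``records`` is a sequence of :class:`dsca.data.TileRecord`;
    ``normalization`` is an optional (mean, std) pair of per-channel
    arrays applied to images before the forward pass.
    """
    from . import nn
    from .nn import Tensor
    from .data import load_batch

    records = list(records)
    if not records:
        raise DataError("evaluation split is empty")
    model.eval()
    total = ConfusionCounts()
    per_tile: list[MetricsReport] = []
    with nn.no_grad():
        for start in range(0, len(records), batch_size):
            batch = records[start:start + batch_size]
            images, masks = load_batch(batch, normalization)
            logits = model(Tensor(images)).data
            preds = predict_mask(logits)
            for p, t in zip(preds, masks):
                c = accumulate(p, t)
                per_tile.append(metrics(c))
                total = total + c
    micro = metrics(total)
    keys = ("iou", "accuracy", "precision", "recall", "f1")
    macro = MetricsReport(*[float(np.mean([getattr(r, k) for r in per_tile])) for k in keys])
    return DatasetReport(micro=micro, macro=macro, counts=total, per_tile=per_tile)
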