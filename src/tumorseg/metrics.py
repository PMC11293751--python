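"""Evaluation measures at image level (classification) and pixel level (segmentation).

``auc`` here is balanced accuracy, the arithmetic mean of sensitivity and
specificity — not a ROC integral. Stored values are fractions in [0, 1];
percentage formatting is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from tumorseg.core_io import BinaryMask, ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_metrics",
    "dice",
    "pixel_confusion",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Metric bundle; ``None`` marks a metric with a zero denominator.

    ``undefined`` names the offending denominator for each missing metric.
    """

    accuracy: float | None = None
    tpr: float | None = None
    tnr: float | None = None
    ppv: float | None = None
    f_score: float | None = None
    auc: float | None = None
    dsc: float | None = None
    undefined: dict = field(default_factory=dict)

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        out = {}
        for name in ("accuracy", "tpr", "tnr", "ppv", "f_score", "auc", "dsc"):
            v = getattr(self, name)
            out[name] = None if v is None else v * scale
        return out


def confusion_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, TPR, TNR, PPV, F-score and balanced-accuracy AUC from counts.

    Zero-denominator metrics are reported as ``None`` (never 0), with the
    offending denominator recorded in ``undefined``.
    """
    if c.total <= 0:
        raise ValidationError("cannot evaluate metrics on empty counts")
    undefined: dict[str, str] = {}

    accuracy = (c.tp + c.tn) / c.total

    tpr = None
    if c.tp + c.fn > 0:
        tpr = c.tp / (c.tp + c.fn)
    else:
        undefined["tpr"] = "TP+FN == 0"

    tnr = None
    if c.tn + c.fp > 0:
        tnr = c.tn / (c.tn + c.fp)
    else:
        undefined["tnr"] = "TN+FP == 0"

    ppv = None
    if c.tp + c.fp > 0:
        ppv = c.tp / (c.tp + c.fp)
    else:
        undefined["ppv"] = "TP+FP == 0"

    f_score = None
    if ppv is not None and tpr is not None and (ppv + tpr) > 0:
        f_score = 2.0 * ppv * tpr / (ppv + tpr)
    else:
        undefined["f_score"] = "PPV+TPR == 0 or component undefined"

    auc = None
    if tpr is not None and tnr is not None:
        auc = (tpr + tnr) / 2.0
    else:
        undefined["auc"] = "TPR or TNR undefined"

    return MetricsReport(
        accuracy=accuracy, tpr=tpr, tnr=tnr, ppv=ppv,
        f_score=f_score, auc=auc, undefined=undefined,
    )


def dice(seg: BinaryMask, gt: BinaryMask) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); defined as 1 when both are empty."""
    if seg.shape != gt.shape:
        raise ValidationError(f"mask shapes differ: {seg.shape} vs {gt.shape}")
    a, b = seg.pixels, gt.pixels
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def pixel_confusion(seg: BinaryMask, gt: BinaryMask) -> ConfusionCounts:
    """Full-frame pixel-level confusion counts between a segmentation and truth."""
    if seg.shape != gt.shape:
        raise ValidationError(f"mask shapes differ: {seg.shape} vs {gt.shape}")
    a, b = seg.pixels, gt.pixels
    tp = int((a & b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())
    tn = a.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
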