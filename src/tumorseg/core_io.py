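"""Canonical image / dataset types and readers for the formats the pipeline touches.

Intensities are stored as floats in ``[0, 1]``; all histogram and threshold
math operates on the 256-level quantized view ``q = round(p * 255)``.
Gray-level indexing is 0-based and bins are exact integers.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "GrayImage",
    "Histogram",
    "BinaryMask",
    "DatasetItem",
    "LabeledDataset",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "compute_histogram",
    "read_manifest",
    "write_manifest",
    "write_report",
]

LEVELS = 256

#: Rec.601 luminance weights used to collapse RGB-encoded grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

VALID_LABELS = ("normal", "abnormal")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D intensity field with values in ``[0, 1]``.

    Attributes
    ----------
    pixels : ndarray of float64, shape (U, V)
        Intensities in ``[0, 1]``.
    levels : int
        Number of gray levels of the quantized view (always 256 here).
    """

    pixels: np.ndarray
    levels: int = LEVELS

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValidationError(f"image must be 2-D and non-empty, got shape {p.shape}")
        if np.min(p) < 0.0 or np.max(p) > 1.0:
            raise ValidationError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def quantized(self) -> np.ndarray:
        """Integer view ``round(p * (L - 1))`` in ``{0, ..., L-1}``."""
        return np.rint(self.pixels * (self.levels - 1)).astype(np.int64)


@dataclass(frozen=True)
class Histogram:
    """256-bin occurrence counts and normalized probabilities of a gray image."""

    counts: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        h = np.asarray(self.probs, dtype=np.float64)
        if c.shape != (LEVELS,) or h.shape != (LEVELS,):
            raise ValidationError("histogram must have exactly 256 bins")
        if np.any(c < 0) or np.any(h < 0):
            raise ValidationError("histogram entries must be non-negative")
        if abs(float(h.sum()) - 1.0) > 1e-12:
            raise ValidationError("probabilities must sum to 1")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "probs", h)

    @classmethod
    def from_probs(cls, probs: Sequence[float]) -> "Histogram":
        """Build a histogram fixture directly from a probability vector.

        Counts are synthesized by scaling to a nominal 10^6 pixels; they are
        only used for bookkeeping, the threshold math reads ``probs``.
        """
        h = np.zeros(LEVELS, dtype=np.float64)
        h[: len(probs)] = probs
        h = h / h.sum()
        c = np.rint(h * 1_000_000).astype(np.int64)
        return cls(counts=c, probs=h)

    def occupied_levels(self) -> np.ndarray:
        return np.flatnonzero(self.probs > 0)


@dataclass(frozen=True)
class BinaryMask:
    """Pixel-level binary segmentation or ground truth."""

    pixels: np.ndarray
    role: str = "segmentation"  # or "ground_truth"

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=bool)
        if p.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {p.shape}")
        object.__setattr__(self, "pixels", p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class DatasetItem:
    """One labeled slice: an image (in memory or on disk) plus optional mask."""

    label: str
    image: GrayImage | None = None
    path: Path | None = None
    mask: BinaryMask | None = None
    mask_path: Path | None = None

    def load_image(self) -> GrayImage:
        if self.image is not None:
            return self.image
        if self.path is None:
            raise ValidationError("dataset item has neither an in-memory image nor a path")
        return read_image(self.path)

    def load_mask(self) -> BinaryMask | None:
        if self.mask is not None:
            return self.mask
        if self.mask_path is not None:
            return read_mask(self.mask_path)
        return None


@dataclass
class LabeledDataset:
    """An ordered collection of labeled slices."""

    items: list[DatasetItem] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in VALID_LABELS}
        for item in self.items:
            counts[item.label] += 1
        return counts

    def labels(self) -> list[str]:
        return [item.label for item in self.items]


def read_image(path: str | Path) -> GrayImage:
    """Read an 8- or 16-bit grayscale PNG/TIFF (RGB collapsed by luminance).

    Intensities are rescaled to ``[0, 1]`` by dividing by the format's
    maximum representable value.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    if arr.ndim == 3:  # RGB(A) encoded grayscale
        arr = arr[..., :3].astype(np.float64) @ _LUMA
        maxval = 255.0
    elif arr.dtype == np.uint16:
        maxval = 65535.0
    elif arr.dtype == np.uint8:
        maxval = 255.0
    elif np.issubdtype(arr.dtype, np.bool_):
        arr = arr.astype(np.float64)
        maxval = 1.0
    else:
        raise ValidationError(f"unsupported pixel type {arr.dtype} in {path}")
    return GrayImage(pixels=np.clip(arr / maxval, 0.0, 1.0))


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write the 8-bit quantized view of ``img`` as PNG/TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    q = img.quantized().astype(np.uint8)
    Image.fromarray(q, mode="L").save(path)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_mask(path: str | Path, role: str = "ground_truth") -> BinaryMask:
    img = read_image(path)
    return BinaryMask(pixels=img.pixels > 0.5, role=role)


def compute_histogram(img: GrayImage) -> Histogram:
    """256-bin histogram of the quantized view; bin m collects round(p*255) == m."""
    q = img.quantized().ravel()
    counts = np.bincount(q, minlength=LEVELS).astype(np.int64)
    probs = counts / counts.sum()
    return Histogram(counts=counts, probs=probs)


def read_manifest(path: str | Path) -> LabeledDataset:
    """Read a dataset manifest CSV with header ``path,label[,mask]``.

    Paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    base = path.parent
    items: list[DatasetItem] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return LabeledDataset(items=[])
        required = {"path", "label"}
        if not required.issubset(set(reader.fieldnames)):
            raise ValidationError(
                f"manifest {path} must have columns path,label[,mask]; got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=1):
            label = (row["label"] or "").strip()
            if label not in VALID_LABELS:
                raise ValidationError(
                    f"unknown label {label!r} in row {i} of {path}; expected one of {VALID_LABELS}"
                )
            img_path = base / row["path"]
            mask_raw = (row.get("mask") or "").strip()
            mask_path = base / mask_raw if mask_raw else None
            items.append(DatasetItem(label=label, path=img_path, mask_path=mask_path))
    return LabeledDataset(items=items)


def write_manifest(ds: LabeledDataset, path: str | Path, base: Path | None = None) -> None:
    """Write a manifest CSV; image/mask paths are stored relative to ``base``."""
    path = Path(path)
    base = base if base is not None else path.parent
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "mask"])
        for item in ds.items:
            if item.path is None:
                raise ValidationError("cannot write manifest for in-memory-only items")
            writer.writerow(
                [_relativize(item.path, base), item.label,
                 _relativize(item.mask_path, base) if item.mask_path else ""]
            )


def _relativize(path: Path, base: Path) -> str:
    """Path relative to ``base`` when possible, else the absolute path."""
    if not path.is_absolute():
        return str(path)
    try:
        return str(path.relative_to(base))
    except ValueError:
        return str(path)


def write_report(report: Mapping | Sequence[Mapping], path: str | Path) -> None:
    """Write a report both as JSON and (for tabular input) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
    rows: Iterable[Mapping] | None = None
    if isinstance(report, Sequence) and report and isinstance(report[0], Mapping):
        rows = report
    if rows is not None:
        fieldnames = list(rows[0].keys())
        with open(path.with_suffix(".csv"), "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: row.get(k, "") for k in fieldnames})


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
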