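"""Geometric data augmentation.

Expands a labeled dataset by a fixed replication factor using random affine
transforms (rotation, translation, scale, shear) and horizontal reflection.
The first member of each replication group is the unmodified original, so a
factor of 9 turns 264 inputs into 2376 outputs while preserving the class
ratio exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from tumorseg.core_io import DatasetItem, GrayImage, LabeledDataset, ValidationError

__all__ = ["AugmentConfig", "TransformSpec", "sample_transform", "apply_transform", "augment_dataset"]


@dataclass(frozen=True)
class AugmentConfig:
    """Replication factor and symmetric parameter ranges for augmentation.

    ``replication_factor`` counts the original: each input yields the
    original plus ``replication_factor - 1`` transformed copies.
    """

    replication_factor: int = 9
    rotation_range: float = 15.0       # degrees, sampled in [-r, r]
    translation_range: float = 10.0    # pixels, per axis
    scale_range: tuple[float, float] = (0.9, 1.1)
    shear_range: float = 10.0          # degrees
    reflect: bool = True               # horizontal reflection with p = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replication_factor < 1:
            raise ValidationError(
                f"replication_factor must be >= 1, got {self.replication_factor}"
            )
        if self.scale_range[0] > self.scale_range[1]:
            raise ValidationError("scale_range must be (low, high) with low <= high")


@dataclass(frozen=True)
class TransformSpec:
    """Sampled parameters of a single geometric transform."""

    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)  # (rows, cols)
    scale: float = 1.0
    shear: float = 0.0
    reflect: bool = False


def sample_transform(rng: np.random.Generator, cfg: AugmentConfig) -> TransformSpec:
    return TransformSpec(
        rotation=float(rng.uniform(-cfg.rotation_range, cfg.rotation_range)),
        translation=(
            float(rng.uniform(-cfg.translation_range, cfg.translation_range)),
            float(rng.uniform(-cfg.translation_range, cfg.translation_range)),
        ),
        scale=float(rng.uniform(cfg.scale_range[0], cfg.scale_range[1])),
        shear=float(rng.uniform(-cfg.shear_range, cfg.shear_range)),
        reflect=bool(cfg.reflect and rng.random() < 0.5),
    )


def _affine_matrix(spec: TransformSpec) -> np.ndarray:
    """Forward affine map in (row, col) coordinates, about the origin."""
    th = np.deg2rad(spec.rotation)
    sh = np.deg2rad(spec.shear)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shear = np.array([[1.0, np.tan(sh)], [0.0, 1.0]])
    scale = np.eye(2) * spec.scale
    m = rot @ shear @ scale
    if spec.reflect:
        m = m @ np.array([[1.0, 0.0], [0.0, -1.0]])  # flip columns
    return m


def apply_transform(
    img: GrayImage, spec: TransformSpec, cfg: AugmentConfig | None = None
) -> GrayImage:
    """Apply one affine transform; bilinear interpolation, zero fill.

    The transform is taken about the image center and the output keeps the
    input dimensions. When ``cfg`` is given, the parameters are validated
    against its configured ranges.
    """
    if cfg is not None:
        _validate_spec(spec, cfg)
    if spec == TransformSpec():
        return img  # exact identity
    m = _affine_matrix(spec)
    center = (np.asarray(img.shape, dtype=np.float64) - 1.0) / 2.0
    # ndimage maps output coords through `matrix @ x + offset` to input coords,
    # so pass the inverse of the forward map.
    minv = np.linalg.inv(m)
    offset = center - minv @ (center + np.asarray(spec.translation))
    out = ndimage.affine_transform(
        img.pixels, minv, offset=offset, order=1, mode="constant", cval=0.0
    )
    return GrayImage(pixels=np.clip(out, 0.0, 1.0))


def _validate_spec(spec: TransformSpec, cfg: AugmentConfig) -> None:
    if abs(spec.rotation) > cfg.rotation_range + 1e-9:
        raise ValidationError(f"rotation {spec.rotation} outside +/-{cfg.rotation_range}")
    if any(abs(t) > cfg.translation_range + 1e-9 for t in spec.translation):
        raise ValidationError(f"translation {spec.translation} outside range")
    if not (cfg.scale_range[0] - 1e-9 <= spec.scale <= cfg.scale_range[1] + 1e-9):
        raise ValidationError(f"scale {spec.scale} outside {cfg.scale_range}")
    if abs(spec.shear) > cfg.shear_range + 1e-9:
        raise ValidationError(f"shear {spec.shear} outside +/-{cfg.shear_range}")
    if spec.reflect and not cfg.reflect:
        raise ValidationError("reflection disabled in config")


def augment_dataset(ds: LabeledDataset, cfg: AugmentConfig | None = None) -> LabeledDataset:
    """Replicate every item ``replication_factor`` times (original included).

    Output order groups each original with its transformed copies, so item 0
    of each group is untouched. Deterministic under a fixed ``cfg.seed``.
    Masks, when present, are not propagated to transformed copies (the
    classifier consumes labels only); the original keeps its mask.
    """
    cfg = cfg if cfg is not None else AugmentConfig()
    if len(ds) == 0:
        raise ValidationError("cannot augment an empty dataset")
    rng = np.random.default_rng(cfg.seed)
    out: list[DatasetItem] = []
    for item in ds.items:
        out.append(item)
        if cfg.replication_factor == 1:
            continue
        img = item.load_image()
        for _ in range(cfg.replication_factor - 1):
            spec = sample_transform(rng, cfg)
            aug = apply_transform(img, spec, cfg)
            out.append(DatasetItem(label=item.label, image=aug))
    return LabeledDataset(items=out)
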