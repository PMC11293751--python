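"""Seeded T2-like brain phantoms with exact ground-truth tumor masks.

The phantoms are deliberately simple: an elliptical "head" containing
layered tissue strata (CSF-like rim, parenchyma) plus 0-3 hyperintense
circular lesions, additive Gaussian noise, and an optional smooth
multiplicative bias field. Lesion radii are kept >= 13 px so a radius-10
morphological opening cannot erase a true lesion. Intensity strata are
chosen so that the aggregate of a 6-threshold entropic segmentation
separates lesion from parenchyma; that property is verified by tests, not
assumed.

Also provides named histogram fixtures used as oracle inputs for the
entropy objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tumorseg.core_io import (
    BinaryMask,
    DatasetItem,
    GrayImage,
    Histogram,
    LabeledDataset,
    ValidationError,
    write_image,
    write_manifest,
    write_mask,
)

__all__ = [
    "TumorSpec",
    "PhantomSpec",
    "make_phantom",
    "make_dataset",
    "make_histogram_fixture",
    "HISTOGRAM_FIXTURES",
]

CANVAS = 256

# Default tissue strata: (mean intensity, noise SD). Lesions must stay
# strictly brighter than every stratum mean (T2-like hyperintensity).
DEFAULT_TISSUES = (
    ("background", 0.03, 0.010),
    ("csf_rim", 0.70, 0.020),
    ("parenchyma", 0.42, 0.025),
)
DEFAULT_TUMOR_INTENSITY = 0.92
MIN_TUMOR_RADIUS = 13


@dataclass(frozen=True)
class TumorSpec:
    center: tuple[float, float]  # (row, col)
    radius: float
    intensity: float = DEFAULT_TUMOR_INTENSITY


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to render one phantom deterministically."""

    seed: int = 0
    size: int = CANVAS
    head_center: tuple[float, float] = (128.0, 128.0)
    head_axes: tuple[float, float] = (105.0, 85.0)  # (row semi-axis, col semi-axis)
    rim_width: float = 10.0
    tissues: tuple = DEFAULT_TISSUES
    tumors: tuple[TumorSpec, ...] = ()
    bias_amplitude: float = 0.0
    noise_scale: float = 1.0
    boundary_noise: float = 0.0  # low-frequency lesion-boundary perturbation

    def __post_init__(self) -> None:
        if len(self.tumors) > 3:
            raise ValidationError("at most 3 tumors per phantom")
        tissue_max = max(mean for _, mean, _ in self.tissues)
        cy, cx = self.head_center
        ay, ax = self.head_axes
        for t in self.tumors:
            if t.intensity <= tissue_max:
                raise ValidationError(
                    f"tumor intensity {t.intensity} must exceed all tissue means ({tissue_max})"
                )
            if t.radius < MIN_TUMOR_RADIUS:
                raise ValidationError(
                    f"tumor radius {t.radius} below minimum {MIN_TUMOR_RADIUS}"
                )
            # the whole lesion disk must fit inside the head ellipse
            ty, tx = t.center
            margin = ((ty - cy) / (ay - t.radius)) ** 2 + ((tx - cx) / (ax - t.radius)) ** 2
            if ay - t.radius <= 0 or ax - t.radius <= 0 or margin > 1.0:
                raise ValidationError(f"tumor at {t.center} r={t.radius} extends outside head")


def _ellipse_mask(size: int, center, axes, shrink: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = center
    ay, ax = max(axes[0] - shrink, 1e-6), max(axes[1] - shrink, 1e-6)
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[GrayImage, BinaryMask, str]:
    """Render a phantom; returns (image, ground-truth mask, label).

    Identical specs (same seed) produce byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    img = np.full((n, n), spec.tissues[0][1], dtype=np.float64)

    head = _ellipse_mask(n, spec.head_center, spec.head_axes)
    interior = _ellipse_mask(n, spec.head_center, spec.head_axes, shrink=spec.rim_width)
    rim = head & ~interior
    img[rim] = spec.tissues[1][1]
    img[interior] = spec.tissues[2][1]

    mask = np.zeros((n, n), dtype=bool)
    yy, xx = np.mgrid[0:n, 0:n]
    for t in spec.tumors:
        ty, tx = t.center
        rr = np.hypot(yy - ty, xx - tx)
        radius = t.radius
        if spec.boundary_noise > 0:
            theta = np.arctan2(yy - ty, xx - tx)
            phase = rng.uniform(0, 2 * np.pi, size=3)
            wobble = sum(
                np.cos((k + 2) * theta + phase[k]) for k in range(3)
            ) * spec.boundary_noise / 3.0
            radius = t.radius * (1.0 + wobble)
        disk = rr <= radius
        img[disk] = t.intensity
        mask |= disk

    # per-stratum additive noise
    sds = np.zeros((n, n))
    sds[~head] = spec.tissues[0][2]
    sds[rim] = spec.tissues[1][2]
    sds[interior] = spec.tissues[2][2]
    sds[mask] = 0.02
    img = img + rng.standard_normal((n, n)) * sds * spec.noise_scale

    if spec.bias_amplitude > 0:
        gy = rng.uniform(-1, 1)
        gx = rng.uniform(-1, 1)
        ramp = (gy * (yy - n / 2) + gx * (xx - n / 2)) / n
        img = img * (1.0 + spec.bias_amplitude * ramp)

    img = np.clip(img, 0.0, 1.0)
    label = "abnormal" if spec.tumors else "normal"
    return GrayImage(pixels=img), BinaryMask(pixels=mask, role="ground_truth"), label


def random_phantom_spec(
    rng: np.random.Generator,
    n_tumors: int,
    *,
    min_radius: float = 14.0,
    max_radius: float = 28.0,
    size: int = CANVAS,
) -> PhantomSpec:
    """Sample a valid phantom spec with ``n_tumors`` non-degenerate lesions."""
    seed = int(rng.integers(0, 2**31 - 1))
    center = (size / 2.0 + rng.uniform(-6, 6), size / 2.0 + rng.uniform(-6, 6))
    axes = (rng.uniform(95, 110), rng.uniform(78, 90))
    tumors = []
    local = np.random.default_rng(seed + 1)
    attempts = 0
    while len(tumors) < n_tumors and attempts < 500:
        attempts += 1
        radius = float(local.uniform(min_radius, max_radius))
        # sample inside the shrunken ellipse so the disk fits
        ang = local.uniform(0, 2 * np.pi)
        rho = np.sqrt(local.uniform(0, 1)) * 0.85
        ty = center[0] + rho * np.cos(ang) * (axes[0] - radius - 2)
        tx = center[1] + rho * np.sin(ang) * (axes[1] - radius - 2)
        cand = TumorSpec(center=(float(ty), float(tx)), radius=radius)
        if any(
            np.hypot(cand.center[0] - t.center[0], cand.center[1] - t.center[1])
            < cand.radius + t.radius + 4
            for t in tumors
        ):
            continue
        tumors.append(cand)
    if len(tumors) < n_tumors:
        raise ValidationError("could not place requested tumors inside head")
    return PhantomSpec(
        seed=seed, size=size, head_center=center, head_axes=axes, tumors=tuple(tumors)
    )


def make_dataset(
    n_abnormal: int = 194,
    n_normal: int = 70,
    seed: int = 0,
    out_dir: str | Path | None = None,
    *,
    size: int = CANVAS,
    min_radius: float = 14.0,
    max_radius: float = 28.0,
) -> LabeledDataset:
    """Generate a labeled phantom dataset, optionally writing it to disk.

    Abnormal phantoms carry 1-3 lesions; normal phantoms none. When
    ``out_dir`` is given, images and masks are written as PNG together with
    a ``manifest.csv`` consumable by every pipeline command.
    """
    if n_abnormal < 0 or n_normal < 0:
        raise ValidationError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    items: list[DatasetItem] = []
    for i in range(n_abnormal + n_normal):
        abnormal = i < n_abnormal
        n_tumors = int(rng.integers(1, 4)) if abnormal else 0
        spec = random_phantom_spec(
            rng, n_tumors, min_radius=min_radius, max_radius=max_radius, size=size
        )
        img, mask, label = make_phantom(spec)
        items.append(DatasetItem(label=label, image=img, mask=mask if abnormal else None))

    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for i, item in enumerate(items):
            img_rel = Path("images") / f"phantom_{i:04d}.png"
            write_image(item.image, out / img_rel)
            item.path = out / img_rel
            if item.mask is not None:
                mask_rel = Path("masks") / f"phantom_{i:04d}_mask.png"
                write_mask(item.mask, out / mask_rel)
                item.mask_path = out / mask_rel
        write_manifest(LabeledDataset(items=items), out / "manifest.csv", base=out)
    return LabeledDataset(items=items)


def _trimodal() -> Histogram:
    h = np.zeros(256)
    for mode, weight, width in ((40, 0.5, 8), (130, 0.3, 6), (220, 0.2, 4)):
        k = np.arange(256)
        h += weight * np.exp(-0.5 * ((k - mode) / width) ** 2)
    # truncate far tails: real integer-count histograms have exact zeros,
    # and the entropy objective is discontinuous at vanishing class mass
    h[h < 1e-9 * h.max()] = 0.0
    return Histogram.from_probs(h)


def _uniform_over(levels) -> Histogram:
    h = np.zeros(256)
    h[list(levels)] = 1.0
    return Histogram.from_probs(h)


def _two_spike() -> Histogram:
    h = np.zeros(256)
    h[50] = 0.5
    h[200] = 0.5
    return Histogram.from_probs(h)


def _eight_level() -> Histogram:
    h = np.zeros(256)
    h[:8] = [0.1, 0.2, 0.1, 0.1, 0.15, 0.15, 0.1, 0.1]
    return Histogram.from_probs(h)


HISTOGRAM_FIXTURES = {
    "two_spike": _two_spike,
    "trimodal": _trimodal,
    "uniform8": lambda: _uniform_over(range(0, 256, 32)),
    "uniform16": lambda: _uniform_over(range(0, 256, 16)),
    "eight_level": _eight_level,
}


def make_histogram_fixture(kind: str) -> Histogram:
    """Deterministic named histogram fixtures for entropy-objective oracles."""
    try:
        factory = HISTOGRAM_FIXTURES[kind]
    except KeyError:
        raise ValidationError(
            f"unknown fixture {kind!r}; choose from {sorted(HISTOGRAM_FIXTURES)}"
        ) from None
    return factory()
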