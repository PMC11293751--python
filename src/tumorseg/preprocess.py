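"""Percentile-based contrast enhancement.

Stretches each image so that the ``low_tail`` and ``high_tail`` input
quantiles map to 0 and 1, with a linear transfer in between and clipping
outside. Quantiles are order statistics at ``ceil(q * N)`` of the sorted
pixel list, which gives deterministic saturation-count semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from tumorseg.core_io import GrayImage, ValidationError

__all__ = ["StretchLimits", "enhance_contrast"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StretchLimits:
    """Input-side saturation quantiles for contrast stretching."""

    low_tail: float = 0.01
    high_tail: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_tail < 0.5):
            raise ValidationError(f"low_tail must be in [0, 0.5), got {self.low_tail}")
        if not (0.5 < self.high_tail <= 1.0):
            raise ValidationError(f"high_tail must be in (0.5, 1], got {self.high_tail}")
        if self.low_tail >= self.high_tail:
            raise ValidationError("low_tail must be strictly below high_tail")


def _order_statistic(sorted_pixels: np.ndarray, q: float) -> float:
    """Order statistic at rank ceil(q * N) (1-based) of the sorted pixels."""
    n = sorted_pixels.size
    rank = int(np.ceil(q * n))
    rank = min(max(rank, 1), n)
    return float(sorted_pixels[rank - 1])


def enhance_contrast(img: GrayImage, limits: StretchLimits | None = None) -> GrayImage:
    """Linearly stretch ``img`` so its tail quantiles saturate at 0 and 1.

    Returns the image unchanged (with a warning) when the two quantiles
    coincide, e.g. on constant images, where no stretch is possible.
    """
    limits = limits if limits is not None else StretchLimits()
    flat = np.sort(img.pixels, axis=None)
    lo = _order_statistic(flat, limits.low_tail)
    hi = _order_statistic(flat, limits.high_tail)
    if hi <= lo:
        logger.warning(
            "degenerate image: low/high quantiles coincide at %.6f; returning input unchanged",
            lo,
        )
        return img
    stretched = np.clip((img.pixels - lo) / (hi - lo), 0.0, 1.0)
    return GrayImage(pixels=stretched)
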