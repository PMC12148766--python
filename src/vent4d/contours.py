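"""Percentile images, threshold functional contours, and Dice similarity.

Function images on different scales (specific volume change vs Jacobian vs
mass-change magnitude) are made comparable by rank-transforming each to a
percentile image over the lung mask; functional contours are then the
voxels at or above the 25/50/75 percentile levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .core import FunctionImage, LungMask

log = logging.getLogger(__name__)

__all__ = ["PercentileImage", "FunctionContour", "to_percentile", "threshold_contour", "dice"]


@dataclass
class PercentileImage:
    """Rank-percentile map in [0, 100] on lung voxels, NaN elsewhere."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        defined = np.isfinite(self.values)
        if defined.any() and (
            self.values[defined].min() < 0 or self.values[defined].max() > 100
        ):
            raise ValueError("percentile values must lie in [0, 100]")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class FunctionContour:
    """Binary high-function subvolume at a given percentile threshold."""

    values: np.ndarray
    level: int
    method: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


def to_percentile(f: FunctionImage, mask: LungMask) -> PercentileImage:
    """Convert a function image to mid-rank percentiles over the mask.

    Each defined mask voxel gets 100 * (rank - 0.5) / n with average ranks
    for ties, making the result invariant to any strictly increasing
    transform of the input.
    """
    m = mask.values & f.defined_mask
    n = int(m.sum())
    if n == 0:
        raise ValueError("no defined function values inside the mask")
    vals = f.values[m]
    ranks = rankdata(vals, method="average")
    pct = 100.0 * (ranks - 0.5) / n
    out = np.full(f.shape, np.nan)
    out[m] = pct
    return PercentileImage(out, f.spacing.copy(), f.origin.copy())


def threshold_contour(p: PercentileImage, level: int, method: str = "") -> FunctionContour:
    """Voxels with percentile >= level (inclusive, matching the >=25/50/75 convention)."""
    if not 0 < level < 100:
        raise ValueError("level must lie strictly between 0 and 100")
    with np.errstate(invalid="ignore"):
        sel = np.nan_to_num(p.values, nan=-np.inf) >= level
    return FunctionContour(sel, level=int(level), method=method)


def dice(a: FunctionContour, b: FunctionContour) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|).

    Two empty contours are defined as perfectly similar (DSC = 1, logged).
    """
    if a.values.shape != b.values.shape:
        raise ValueError(
            f"contour grids differ: {a.values.shape} vs {b.values.shape}"
        )
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        log.info("dice: both contours empty; DSC defined as 1")
        return 1.0
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)
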