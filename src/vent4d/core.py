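"""Shared image and geometry types for 4DCT lung-function imaging.

Conventions used throughout the package:

* Volumes are 3-D numpy arrays indexed ``[ix, iy, iz]`` with a fixed
  (x, y, z) axis order in memory and on disk.
* Voxel indices are 0-based; the world coordinate of the *center* of voxel
  ``i`` is ``origin + i * spacing`` (mm).
* A displacement field lives on the exhale (reference) grid and points to
  inhale space: a tissue element at exhale world position ``x`` is found at
  inhale world position ``x + u(x)`` (pull/backward-warp semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

HU_AIR = -1000.0
HU_MIN = -1024.0
HU_MAX = 3071.0

__all__ = [
    "HUImage",
    "DensityImage",
    "DisplacementField",
    "LungMask",
    "FunctionImage",
    "Subregion",
    "SubregionPartition",
    "hu_to_density",
    "density_to_hu",
    "pull_values",
    "build_partition",
]


def _check_grid(spacing, origin):
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,):
        raise ValueError("spacing and origin must be length-3 vectors")
    if not np.all(spacing > 0):
        raise ValueError(f"voxel spacing must be positive, got {spacing}")
    return spacing, origin


@dataclass
class HUImage:
    """CT volume in Hounsfield units with grid metadata."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("HUImage requires a 3-D array")
        self.spacing, self.origin = _check_grid(self.spacing, self.origin)
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite HU value at voxel index {tuple(int(i) for i in bad)}"
            )
        if self.values.min() < HU_MIN or self.values.max() > HU_MAX:
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: "
                f"range [{self.values.min():.1f}, {self.values.max():.1f}]"
            )

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def world_coordinates(self):
        """Per-axis world coordinates of voxel centers (broadcastable)."""
        return tuple(
            (self.origin[a] + self.spacing[a] * np.arange(self.shape[a])).reshape(
                [-1 if k == a else 1 for k in range(3)]
            )
            for a in range(3)
        )


@dataclass
class DensityImage:
    """Dimensionless mass density under the two-material model (air 0, water 1)."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("DensityImage requires a 3-D array")
        self.spacing, self.origin = _check_grid(self.spacing, self.origin)
        if np.any(self.values < 0):
            raise ValueError("density values must be >= 0")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class DisplacementField:
    """Vector field u (mm) on the exhale grid; exhale x maps to inhale x + u(x).

    ``u`` has shape ``(nx, ny, nz, 3)``.
    """

    u: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError("DisplacementField requires shape (nx, ny, nz, 3)")
        self.spacing, self.origin = _check_grid(self.spacing, self.origin)
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self):
        return self.u.shape[:3]

    def interp(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolate u at world ``points`` of shape (..., 3)."""
        pts = np.asarray(points, dtype=float)
        idx = (pts - self.origin) / self.spacing
        coords = np.moveaxis(idx, -1, 0).reshape(3, -1)
        out = np.empty((coords.shape[1], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.u[..., c], coords, order=1, mode="nearest"
            )
        return out.reshape(pts.shape)

    def mapped_points(self, points: np.ndarray) -> np.ndarray:
        """Inhale-space world positions x + u(x) for exhale world ``points``."""
        return np.asarray(points, dtype=float) + self.interp(points)


@dataclass
class LungMask:
    """Binary lung mask on the exhale grid."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("LungMask requires a 3-D array")
        self.spacing, self.origin = _check_grid(self.spacing, self.origin)
        if not self.values.any():
            raise ValueError("lung mask is empty")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume


FUNCTION_KINDS = ("specific-volume-change", "jacobian", "mass-change-magnitude")


@dataclass
class FunctionImage:
    """Voxelwise lung-function map, finite on mask voxels and NaN elsewhere."""

    values: np.ndarray
    kind: str
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("FunctionImage requires a 3-D array")
        if self.kind not in FUNCTION_KINDS:
            raise ValueError(f"kind must be one of {FUNCTION_KINDS}, got {self.kind!r}")
        self.spacing, self.origin = _check_grid(self.spacing, self.origin)
        defined = np.isfinite(self.values)
        if self.kind == "jacobian" and np.any(self.values[defined] <= 0):
            raise ValueError("jacobian function image must be > 0 on defined voxels")
        if self.kind == "mass-change-magnitude" and np.any(self.values[defined] < 0):
            raise ValueError("mass-change magnitude must be >= 0 on defined voxels")

    @property
    def shape(self):
        return self.values.shape

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class Subregion:
    """One lung subregion: the lung voxels inside a cubic index window."""

    key: tuple
    indices: np.ndarray  # (n, 3) voxel indices

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]

    @property
    def center_index(self) -> np.ndarray:
        return self.indices.mean(axis=0)


@dataclass
class SubregionPartition:
    """Overlapping cubic windows covering the lung mask.

    ``tau`` is the relative standard-error bound used by the subregional
    estimators that consume the partition.
    """

    regions: list
    window: int
    stride: int
    tau: float
    shape: tuple

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tolerance tau must be > 0")

    def __len__(self):
        return len(self.regions)


def hu_to_density(hu: HUImage) -> DensityImage:
    """Convert HU to dimensionless density via the two-material (air/water) mix.

    density = (HU + 1000) / 1000; values below 0 (HU < -1000, scanner noise)
    are clipped to 0 and the clip count logged.
    """
    if not np.all(np.isfinite(hu.values)):
        bad = np.argwhere(~np.isfinite(hu.values))[0]
        raise ValueError(
            f"non-finite HU value at voxel index {tuple(int(i) for i in bad)}"
        )
    rho = (hu.values + 1000.0) / 1000.0
    n_clip = int((rho < 0).sum())
    if n_clip:
        log.info("hu_to_density: clipped %d voxels with density < 0", n_clip)
        rho = np.clip(rho, 0.0, None)
    return DensityImage(rho, hu.spacing.copy(), hu.origin.copy())


def density_to_hu(rho: DensityImage) -> HUImage:
    """Inverse of :func:`hu_to_density`: HU = 1000*density - 1000."""
    hu = 1000.0 * rho.values - 1000.0
    return HUImage(np.clip(hu, HU_MIN, HU_MAX), rho.spacing.copy(), rho.origin.copy())


def pull_values(
    field_: DisplacementField,
    moving,
    interp: str = "trilinear",
    fill: float = HU_AIR,
):
    """Resample ``moving`` at the mapped points x + u(x) of the exhale grid.

    Returns ``(image, inbounds)`` where ``image`` holds the interpolated
    moving-image values on the exhale grid (``fill`` where the mapped point
    leaves the moving grid) and ``inbounds`` flags the valid voxels.
    """
    if interp not in ("trilinear", "nearest"):
        raise ValueError("interp must be 'trilinear' or 'nearest'")
    mv = np.asarray(moving.values, dtype=float)
    if not np.all(np.isfinite(mv)):
        raise ValueError("moving image contains non-finite values")
    nx, ny, nz = field_.shape
    ax = [field_.origin[a] + field_.spacing[a] * np.arange((nx, ny, nz)[a]) for a in range(3)]
    X = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    mapped = X + field_.u
    idx = (mapped - moving.origin) / moving.spacing
    shp = np.array(mv.shape)
    inbounds = np.all((idx >= 0) & (idx <= shp - 1), axis=-1)
    coords = np.moveaxis(idx, -1, 0).reshape(3, -1)
    order = 1 if interp == "trilinear" else 0
    vals = ndimage.map_coordinates(mv, coords, order=order, mode="nearest")
    out = vals.reshape(nx, ny, nz)
    out = np.where(inbounds, out, fill)
    img = HUImage(
        np.clip(out, HU_MIN, HU_MAX), field_.spacing.copy(), field_.origin.copy()
    )
    return img, inbounds


def _window_starts(lo: int, hi: int, window: int, stride: int):
    """Window (start, size) pairs covering [lo, hi] inclusive.

    With stride == window the tail window is clipped (keeps the tiling
    pairwise disjoint); with overlap it is shifted back to full size.
    """
    extent = hi - lo + 1
    if extent <= window:
        return [(lo, extent)]
    starts = [(s, window) for s in range(lo, hi - window + 2, stride)]
    last_start, last_size = starts[-1]
    if last_start + last_size - 1 < hi:
        if stride == window:
            # extend the last tile over the remainder: stays disjoint and
            # avoids thin tail slabs that would fail the 8-voxel minimum
            starts[-1] = (last_start, hi - last_start + 1)
        else:
            starts.append((hi - window + 1, window))
    return starts


def build_partition(
    mask: LungMask, window: int = 8, stride: int = 4, tau: float = 0.01
) -> SubregionPartition:
    """Cover the lung mask with sliding cubic windows clipped to the mask.

    Windows containing fewer than 8 lung voxels are dropped; an error is
    raised if any lung voxel then remains uncovered.
    """
    if window < 2:
        raise ValueError("window must be >= 2 voxels")
    if not (1 <= stride <= window):
        raise ValueError("stride must satisfy 1 <= stride <= window")
    m = mask.values
    occupied = np.argwhere(m)
    lo = occupied.min(axis=0)
    hi = occupied.max(axis=0)
    starts = [_window_starts(lo[a], hi[a], window, stride) for a in range(3)]
    regions = []
    covered = np.zeros_like(m, dtype=bool)
    for sx, wx in starts[0]:
        for sy, wy in starts[1]:
            for sz, wz in starts[2]:
                sl = (
                    slice(sx, sx + wx),
                    slice(sy, sy + wy),
                    slice(sz, sz + wz),
                )
                sub = m[sl]
                n = int(sub.sum())
                if n < 8:
                    continue
                idx = np.argwhere(sub) + np.array([sx, sy, sz])
                regions.append(Subregion(key=(int(sx), int(sy), int(sz)), indices=idx))
                covered[sl] |= sub
    uncovered = int((m & ~covered).sum())
    if uncovered:
        raise ValueError(
            f"partition does not cover the mask: {uncovered} lung voxels "
            "fall only in windows with < 8 lung voxels"
        )
    return SubregionPartition(
        regions=regions, window=window, stride=stride, tau=tau, shape=m.shape
    )
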