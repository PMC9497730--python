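"""In-memory containers shared across the pipeline.

Conventions (used everywhere, documented once):

* array indices are 0-based;
* world coordinates are in millimetres and refer to voxel/pixel *centers*:
  ``world = origin + index * pitch`` along each axis;
* volume arrays are indexed ``(x, y, z)`` with x fastest-varying in memory
  order of the first axis; planar images are indexed ``(row, col)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeImage",
    "PlanarGeometry",
    "PlanarImageSeries",
    "RoiSpec",
    "VoiSpec",
]


@dataclass
class VolumeImage:
    """A 3-D scalar image with physical geometry.

    Parameters
    ----------
    voxels : (nx, ny, nz) array
        Scalar values, typically Hounsfield units.
    voxel_size : 3-tuple of float
        Pitch (dx, dy, dz) in mm; all strictly positive.
    origin : 3-tuple of float
        World position (mm) of the center of voxel (0, 0, 0).
    units : str
        Physical unit tag, e.g. ``"HU"``, ``"GL"`` or ``"mgI/mL"``.
    valid : bool array or None
        Per-voxel validity mask; ``None`` means all voxels valid. Resampling
        marks voxels that fell outside the source domain invalid.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "HU"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3-D, got ndim={self.voxels.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)
        if self.valid is not None and self.valid.shape != self.voxels.shape:
            raise ValueError("valid mask shape must match voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (n, 3) to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.voxel_size)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return (xyz - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def copy_with(self, **changes) -> "VolumeImage":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PlanarGeometry:
    """Row-band layout of a planar radiograph: bath above cartilage above bone.

    Each band is a half-open row interval ``(start, stop)``. The cartilage
    surface is the first cartilage row (adjacent to the bath) and the tidemark
    the last (adjacent to bone).
    """

    shape: tuple[int, int]
    bath_rows: tuple[int, int]
    cartilage_rows: tuple[int, int]
    bone_rows: tuple[int, int]

    def __post_init__(self) -> None:
        nrow = self.shape[0]
        for name in ("bath_rows", "cartilage_rows", "bone_rows"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= nrow):
                raise ValueError(f"{name}={lo, hi} outside image of {nrow} rows")

    @property
    def n_cartilage_rows(self) -> int:
        return self.cartilage_rows[1] - self.cartilage_rows[0]


@dataclass
class PlanarImageSeries:
    """A time series of planar radiographs plus the pre-contrast baseline."""

    images: np.ndarray  # (n_times, rows, cols), gray levels
    times: np.ndarray  # hours
    pixel_size: float  # mm
    baseline: np.ndarray  # (rows, cols)
    geometry: PlanarGeometry | None = None
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.times = np.asarray(self.times, dtype=float)
        self.baseline = np.asarray(self.baseline)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_times, rows, cols) stack")
        if len(self.images) != len(self.times):
            raise ValueError(
                f"image/time count mismatch: {len(self.images)} vs {len(self.times)}"
            )
        if self.baseline.shape != self.images.shape[1:]:
            raise ValueError("baseline shape must match image shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.images)


@dataclass(frozen=True)
class RoiSpec:
    """A 2-D region of interest, rectangular or circular, in pixel units.

    ``center`` is (row, col) of the ROI center in fractional pixel indices.
    Rectangles take ``width`` (columns) and ``height`` (rows); circles take
    ``radius``. Membership is decided by pixel center.
    """

    shape: str  # "rect" | "circle"
    center: tuple[float, float]
    width: float | None = None
    height: float | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.shape == "rect":
            if self.width is None or self.height is None:
                raise ValueError("rect ROI needs width and height")
            if self.width <= 0 or self.height <= 0:
                raise ValueError("ROI dimensions must be positive")
        elif self.shape == "circle":
            if self.radius is None or self.radius <= 0:
                raise ValueError("circle ROI needs a positive radius")
        else:
            raise ValueError(f"unknown ROI shape {self.shape!r}")


@dataclass(frozen=True)
class VoiSpec:
    """A cylindrical volume of interest in voxel index units.

    The cylinder axis runs along ``axis``; ``center`` is the (x, y, z)
    fractional index of the cylinder center, ``radius`` the in-plane radius in
    the units of the two transverse axes (isotropic transverse pitch assumed),
    ``half_length`` half the extent along the axis, in index units.
    """

    center: tuple[float, float, float]
    radius: float
    half_length: float
    axis: int = 2

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.half_length <= 0:
            raise ValueError("VOI dimensions must be positive")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
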