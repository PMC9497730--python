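"""Clinical-CT-scale volumetric analysis.

The workflow mirrors a paired pre/post contrast acquisition: estimate the
rigid motion between the two scans from fiducial markers, resample the post
volume into the pre (baseline) frame, subtract, threshold-segment the iodine
enhancement, convert it to concentration through the clinical calibration,
and measure cartilage volume and thickness from the segmented mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .calibration import CalibrationCurve
from .containers import VoiSpec, VolumeImage

__all__ = [
    "RigidTransform",
    "fit_rigid_from_fiducials",
    "resample_volume",
    "subtract_volumes",
    "segment_iodine_mask",
    "voi_statistics",
    "map_iodine",
    "estimate_cartilage_volume",
    "estimate_cartilage_thickness",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R @ p + t`` in world (mm) coordinates."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), mm

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthonormal (R^T R != I)")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-10):
            raise ValueError("rotation must be proper (det +1); reflections rejected")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler(cls, angles_deg, translation_mm, order: str = "xyz") -> "RigidTransform":
        r = Rotation.from_euler(order, angles_deg, degrees=True).as_matrix()
        return cls(r, np.asarray(translation_mm, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        return float(
            np.degrees(Rotation.from_matrix(self.rotation).magnitude())
        )


def fit_rigid_from_fiducials(
    src: np.ndarray, dst: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping fiducials ``src`` onto ``dst``.

    Solves ``min_T sum_i ||T(src_i) - dst_i||^2`` over proper rigid motions
    (Kabsch/Wahba problem; reflections excluded by construction).

    Parameters
    ----------
    src, dst : (n, 3) arrays, mm
        Matched marker coordinates, n >= 3, not collinear.

    Returns
    -------
    (RigidTransform, float)
        The fitted transform and the RMS fiducial registration error (mm).
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape:
        raise ValueError(f"marker count mismatch: {src.shape} vs {dst.shape}")
    if src.shape[0] < 3 or src.shape[1] != 3:
        raise ValueError("need at least 3 markers of dimension 3")
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    # collinear (or coincident) markers leave a rotation axis unconstrained
    if np.linalg.matrix_rank(src_c, tol=1e-9 * max(1.0, np.abs(src_c).max())) < 2:
        raise ValueError("markers are collinear or coincident; rotation unconstrained")
    rot, _ = Rotation.align_vectors(dst_c, src_c)
    r = rot.as_matrix()
    t = dst.mean(axis=0) - r @ src.mean(axis=0)
    fitted = RigidTransform(r, t)
    rms = float(np.sqrt(np.mean(np.sum((fitted.apply(src) - dst) ** 2, axis=1))))
    return fitted, rms


def resample_volume(
    vol: VolumeImage, transform: RigidTransform, fill_value: float = 0.0
) -> VolumeImage:
    """Pull-resample: output voxel at world point ``p`` takes the value
    ``vol`` holds at ``transform(p)``, by trilinear interpolation.

    To register a moved scan back into the baseline frame, pass the
    transform that maps baseline-frame points into the moved frame (i.e. the
    fitted fiducial transform itself when fiducials were fitted
    baseline -> moved). Voxels sampling outside the source domain receive
    ``fill_value`` and are marked invalid.
    """
    shape = vol.shape
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    world = vol.index_to_world(idx)
    src_idx = vol.world_to_index(transform.apply(world)).T
    out = ndimage.map_coordinates(
        np.asarray(vol.voxels, dtype=float), src_idx, order=1, mode="constant",
        cval=fill_value,
    ).reshape(shape)
    inside = np.ones(src_idx.shape[1], dtype=bool)
    for ax in range(3):
        inside &= (src_idx[ax] >= 0) & (src_idx[ax] <= shape[ax] - 1)
    valid = inside.reshape(shape)
    if vol.valid is not None:
        # linear interpolation of the validity field flags every voxel whose
        # stencil touched an invalid source voxel
        prior = ndimage.map_coordinates(
            vol.valid.astype(float), src_idx, order=1, mode="constant", cval=0.0
        ).reshape(shape)
        valid &= prior >= 1.0 - 1e-9
    return vol.copy_with(voxels=out, valid=valid)


def subtract_volumes(post_registered: VolumeImage, pre: VolumeImage) -> VolumeImage:
    """Voxelwise ``post - pre`` on a shared grid, propagating validity masks."""
    if post_registered.shape != pre.shape:
        raise ValueError(
            f"grid mismatch: {post_registered.shape} vs {pre.shape}"
        )
    if post_registered.voxel_size != pre.voxel_size or not np.allclose(
        post_registered.origin, pre.origin
    ):
        raise ValueError("volumes must share voxel size and origin")
    diff = np.asarray(post_registered.voxels, dtype=float) - np.asarray(
        pre.voxels, dtype=float
    )
    valid = None
    for v in (post_registered.valid, pre.valid):
        if v is not None:
            valid = v if valid is None else (valid & v)
    return pre.copy_with(voxels=diff, valid=valid, units=f"delta-{pre.units}")


def segment_iodine_mask(
    diff: VolumeImage, threshold_hu: float, min_component_voxels: int = 27
) -> np.ndarray:
    """Threshold the difference volume and drop small speckle components.

    A voxel enters the mask when ``delta >= threshold_hu`` (and is valid);
    26-connected components smaller than ``min_component_voxels`` are
    removed — the automated stand-in for manual removal of subtraction and
    registration artifacts.
    """
    if threshold_hu <= 0:
        raise ValueError("threshold_hu must be positive")
    mask = np.asarray(diff.voxels) >= threshold_hu
    if diff.valid is not None:
        mask &= diff.valid
    if min_component_voxels > 1:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        if n:
            counts = np.bincount(labels.ravel())
            keep = counts >= min_component_voxels
            keep[0] = False
            mask = keep[labels]
    return mask


def _voi_membership(vol: VolumeImage, voi: VoiSpec) -> np.ndarray:
    """Boolean membership of voxel centers in a cylindrical VOI."""
    shape = vol.shape
    ax = voi.axis
    trans = [a for a in range(3) if a != ax]
    grids = np.indices(shape, dtype=float)
    r2 = (grids[trans[0]] - voi.center[trans[0]]) ** 2 + (
        grids[trans[1]] - voi.center[trans[1]]
    ) ** 2
    along = np.abs(grids[ax] - voi.center[ax])
    return (r2 <= voi.radius**2) & (along <= voi.half_length)


def voi_statistics(
    vol: VolumeImage, vois: list[VoiSpec]
) -> tuple[pd.DataFrame, dict]:
    """Per-VOI mean/sd/n of voxel values, plus a pooled summary.

    Membership is decided by voxel center. Returns a DataFrame with one row
    per VOI (columns ``mean``, ``sd``, ``n``) and a dict with the pooled
    mean/sd/n over all member voxels.
    """
    rows = []
    pooled: list[np.ndarray] = []
    vox = np.asarray(vol.voxels, dtype=float)
    for i, voi in enumerate(vois):
        # the analytic extent of the cylinder must fit the grid
        ax = voi.axis
        trans = [a for a in range(3) if a != ax]
        lo_ok = (
            voi.center[ax] - voi.half_length >= -0.5
            and voi.center[ax] + voi.half_length <= vol.shape[ax] - 0.5
        )
        tr_ok = all(
            voi.center[a] - voi.radius >= -0.5
            and voi.center[a] + voi.radius <= vol.shape[a] - 0.5
            for a in trans
        )
        if not (lo_ok and tr_ok):
            raise ValueError(f"VOI {i} extends outside the volume")
        member = _voi_membership(vol, voi)
        if vol.valid is not None:
            member = member & vol.valid
        vals = vox[member]
        rows.append(
            {
                "voi": i,
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        )
        pooled.append(vals)
    table = pd.DataFrame(rows, columns=["voi", "mean", "sd", "n"])
    if pooled:
        allv = np.concatenate(pooled)
        summary = {
            "mean": float(allv.mean()) if allv.size else np.nan,
            "sd": float(allv.std(ddof=1)) if allv.size > 1 else 0.0,
            "n": int(allv.size),
        }
    else:
        summary = {"mean": np.nan, "sd": np.nan, "n": 0}
    return table, summary


def map_iodine(
    diff: VolumeImage,
    calib: CalibrationCurve,
    mask: np.ndarray,
    intercept_mode: str = "affine",
) -> VolumeImage:
    """Convert subtracted attenuation to iodine concentration inside a mask.

    ``c = (delta - a)/b`` under the affine convention (the calibration curve
    applied to the subtracted signal as-is) or ``c = delta/b`` under the
    slope-only convention; the mode must match the one the difference signal
    was formed under. Voxels outside the mask are invalid and set to zero.
    """
    if calib.units != "HU":
        raise ValueError(f"expected an HU calibration, got units={calib.units!r}")
    if mask.shape != diff.shape:
        raise ValueError("mask shape must match volume")
    delta = np.asarray(diff.voxels, dtype=float)
    if intercept_mode == "affine":
        conc = (delta - calib.a) / calib.b
    elif intercept_mode == "slope_only":
        conc = delta / calib.b
    else:
        raise ValueError(f"unknown intercept_mode {intercept_mode!r}")
    out = np.where(mask, conc, 0.0)
    valid = mask.copy()
    if diff.valid is not None:
        valid &= diff.valid
    return diff.copy_with(voxels=out, valid=valid, units="mgI/mL")


def estimate_cartilage_volume(mask: np.ndarray, voxel_size) -> float:
    """Segmented cartilage volume in cm^3: voxel count times voxel volume."""
    dx, dy, dz = (float(v) for v in voxel_size)
    return float(np.count_nonzero(mask)) * dx * dy * dz / 1000.0


def estimate_cartilage_thickness(
    mask: np.ndarray,
    vois: list[VoiSpec] | None,
    axis: int,
    pixel_size: float,
) -> tuple[float, float, np.ndarray]:
    """Cartilage thickness from the transversal extent of the mask.

    For every mask column along ``axis``, the thickness is the *longest
    contiguous run* of masked voxels times ``pixel_size`` (robust to
    speckle, unlike a plain count, when the mask is non-convex). Per VOI the
    mean over its non-empty columns is taken; the aggregate is the mean and
    sd across VOIs. With ``vois=None`` every non-empty column forms one
    pool and the sd is taken across columns.

    Returns ``(mean_mm, sd_mm, per_voi_mm)``.
    """
    mask = np.asarray(mask, dtype=bool)
    runs = _longest_runs(mask, axis)
    if vois is None:
        vals = runs[runs > 0] * pixel_size
        if vals.size == 0:
            return 0.0, 0.0, np.array([])
        return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0, vals
    per_voi = []
    for i, voi in enumerate(vois):
        member = _voi_columns(mask.shape, voi, axis)
        col_runs = runs[member]
        col_runs = col_runs[col_runs > 0]
        if col_runs.size == 0:
            warnings.warn(f"VOI {i} contains no masked voxels; thickness 0", stacklevel=2)
            per_voi.append(0.0)
        else:
            per_voi.append(float(col_runs.mean()) * pixel_size)
    per_voi = np.asarray(per_voi)
    mean = float(per_voi.mean()) if per_voi.size else 0.0
    sd = float(per_voi.std(ddof=1)) if per_voi.size > 1 else 0.0
    return mean, sd, per_voi


def _longest_runs(mask: np.ndarray, axis: int) -> np.ndarray:
    """Longest contiguous True run along ``axis`` for each column."""
    m = np.moveaxis(mask, axis, 0)
    n = m.shape[0]
    best = np.zeros(m.shape[1:], dtype=int)
    cur = np.zeros(m.shape[1:], dtype=int)
    for k in range(n):
        cur = np.where(m[k], cur + 1, 0)
        best = np.maximum(best, cur)
    return best


def _voi_columns(shape, voi: VoiSpec, axis: int) -> np.ndarray:
    """In-plane membership of columns (perpendicular to ``axis``) in a VOI."""
    trans = [a for a in range(3) if a != axis]
    plane_shape = tuple(shape[a] for a in trans)
    gi, gj = np.indices(plane_shape, dtype=float)
    r2 = (gi - voi.center[trans[0]]) ** 2 + (gj - voi.center[trans[1]]) ** 2
    return r2 <= voi.radius**2
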