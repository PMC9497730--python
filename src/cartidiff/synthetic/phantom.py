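"""Paired pre/post clinical-CT phantom of a tibial plateau.

The phantom stacks three tissues along the x axis of each (y, z) column:
subchondral/trabecular bone at the bottom, an articular cartilage layer of
smoothly varying thickness, connective tissue above it, and air beyond.
Pre-contrast, cartilage and connective tissue are nearly iso-attenuating
(soft tissues are not separable before contrast); the post volume adds the
calibration-forward attenuation of a known iodine map inside cartilage, is
rigidly displaced by a known transform, resampled, and both volumes receive
independent Gaussian HU noise. All ground truth (labels, iodine map,
transform, fiducials, per-column thickness) is retained for validation.

The cartilage layer is stacked along x (0.32 mm pitch) rather than along the
0.625 mm slice axis so the default 1.8–2.8 mm layer spans 6–9 voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..calibration import CalibrationCurve
from ..containers import VolumeImage
from ..volumetric import RigidTransform, resample_volume
from .planar import contrast_increment

__all__ = [
    "CtPhantomPair",
    "build_ct_phantom_pair",
    "TISSUE_LABELS",
    "TISSUE_HU",
    "CLINICAL_VOXEL_MM",
    "DEFAULT_CLINICAL_CALIBRATION",
]

#: Integer codes of the label map.
TISSUE_LABELS = {"background": 0, "connective": 1, "bone": 2, "cartilage": 3}

#: Nominal pre-contrast attenuation per tissue. Cartilage sits 5 HU from
#: connective tissue — indistinguishable before contrast — while bone is far
#: above both.
TISSUE_HU = {"background": -1000.0, "connective": 40.0, "bone": 1200.0, "cartilage": 45.0}

#: In-plane pixel 0.32 mm, slice thickness 0.625 mm.
CLINICAL_VOXEL_MM = (0.32, 0.32, 0.625)

#: Affine HU calibration the phantom's contrast forward model uses by
#: default (intercept -5.589 HU, slope 23.537 HU/(mgI/mL)).
DEFAULT_CLINICAL_CALIBRATION = CalibrationCurve(a=-5.589, b=23.537, units="HU")


@dataclass
class CtPhantomPair:
    """A pre/post CT volume pair with full generation ground truth."""

    pre: VolumeImage
    post: VolumeImage
    true_transform: RigidTransform
    true_iodine: np.ndarray  # (nx, ny, nz) mgI/mL, zero outside cartilage
    tissue_labels: np.ndarray  # integer codes per TISSUE_LABELS
    fiducials_pre: np.ndarray  # (4, 3) mm
    fiducials_post: np.ndarray  # (4, 3) mm, exactly true_transform(fiducials_pre)
    thickness_map_mm: np.ndarray  # (ny, nz) continuous truth
    intercept_mode: str = "affine"
    calibration: CalibrationCurve = DEFAULT_CLINICAL_CALIBRATION
    noise_sd_hu: float = 0.0

    @property
    def cartilage_mask(self) -> np.ndarray:
        return self.tissue_labels == TISSUE_LABELS["cartilage"]

    def true_volume_cm3(self) -> float:
        dx, dy, dz = self.pre.voxel_size
        return float(np.count_nonzero(self.cartilage_mask)) * dx * dy * dz / 1000.0

    def true_thickness_mm(self) -> np.ndarray:
        """Per-column cartilage thickness from the label map (mm), along x."""
        return self.cartilage_mask.sum(axis=0) * self.pre.voxel_size[0]


def _default_fiducials(extent_mm: np.ndarray) -> np.ndarray:
    # a well-spread tetrahedral arrangement inside the volume
    frac = np.array(
        [
            [0.15, 0.15, 0.15],
            [0.85, 0.20, 0.30],
            [0.20, 0.85, 0.50],
            [0.75, 0.75, 0.85],
        ]
    )
    return frac * extent_mm


def build_ct_phantom_pair(
    shape: tuple[int, int, int] = (96, 96, 64),
    voxel_size: tuple[float, float, float] = CLINICAL_VOXEL_MM,
    iodine_map_params: dict | None = None,
    transform_params: dict | None = None,
    noise_sd_hu: float = 0.0,
    seed: int = 0,
    calib: CalibrationCurve = DEFAULT_CLINICAL_CALIBRATION,
    intercept_mode: str = "affine",
    fiducials_mm: np.ndarray | None = None,
    margin_mm: float = 2.5,
) -> CtPhantomPair:
    """Build a paired pre/post CT phantom with known ground truth.

    Parameters
    ----------
    iodine_map_params : dict
        ``concentration`` (mgI/mL, default 10) and optional
        ``depth_gradient`` (relative linear change surface -> tidemark,
        default 0 for a uniform map).
    transform_params : dict
        ``angles_deg`` (3 Euler angles) and ``translation_mm``; defaults are
        a small realistic repositioning (~2 deg, ~1 mm).
    noise_sd_hu : float
        Gaussian noise added independently to pre and post.
    fiducials_mm : (4, 3) array, optional
        Marker positions in the pre frame; defaults to a spread tetrahedron.
    margin_mm : float
        Background (air) margin along y and z between the sample and the
        volume faces, so a repositioned scan keeps the whole sample inside
        the field of view.
    """
    if noise_sd_hu < 0:
        raise ValueError("noise_sd_hu must be nonnegative")
    iod = {"concentration": 10.0, "depth_gradient": 0.0, **(iodine_map_params or {})}
    tf = {"angles_deg": (1.2, -0.8, 1.5), "translation_mm": (0.9, -0.6, 1.1),
          **(transform_params or {})}
    true_transform = RigidTransform.from_euler(tf["angles_deg"], tf["translation_mm"])

    nx, ny, nz = shape
    dx, dy, dz = voxel_size
    extent = np.array([nx * dx, ny * dy, nz * dz])
    rng = np.random.default_rng(seed)

    # geometry along x: bone base, cartilage layer of varying thickness,
    # connective band, then air
    yy, zz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    bone_top_mm = 0.30 * extent[0] * np.ones((ny, nz))
    thickness = 2.3 + 0.5 * np.sin(2 * np.pi * yy / ny) * np.cos(2 * np.pi * zz / nz)
    connective_top_mm = bone_top_mm + thickness + 0.45 * extent[0]
    x_centers = (np.arange(nx) + 0.0) * dx  # origin at voxel centers, see below

    labels = np.zeros(shape, dtype=np.uint8)
    xc = x_centers[:, None, None]
    in_sample = (
        (yy * dy >= margin_mm) & (yy * dy <= (ny - 1) * dy - margin_mm)
        & (zz * dz >= margin_mm) & (zz * dz <= (nz - 1) * dz - margin_mm)
    )[None]
    in_bone = (xc < bone_top_mm[None]) & in_sample
    in_cart = (
        (xc >= bone_top_mm[None]) & (xc < (bone_top_mm + thickness)[None]) & in_sample
    )
    in_conn = (
        (xc >= (bone_top_mm + thickness)[None]) & (xc < connective_top_mm[None])
        & in_sample
    )
    labels[in_bone] = TISSUE_LABELS["bone"]
    labels[in_cart] = TISSUE_LABELS["cartilage"]
    labels[in_conn] = TISSUE_LABELS["connective"]

    hu = np.full(shape, TISSUE_HU["background"])
    for name in ("connective", "bone", "cartilage"):
        hu[labels == TISSUE_LABELS[name]] = TISSUE_HU[name]

    # iodine map, nonzero only in cartilage
    conc = float(iod["concentration"])
    grad = float(iod["depth_gradient"])
    iodine = np.zeros(shape)
    if grad == 0.0:
        iodine[in_cart] = conc
    else:
        # relative depth within the layer: 1 at the surface (connective side)
        depth = (((bone_top_mm + thickness)[None] - xc) / thickness[None]).clip(0, 1)
        iodine = np.where(in_cart, conc * (1.0 + grad * (depth - 0.5)), 0.0)

    enhanced = hu + contrast_increment(iodine, calib, intercept_mode)

    pre = VolumeImage(hu.copy(), voxel_size, units="HU")
    post_still = VolumeImage(enhanced, voxel_size, units="HU")
    # moving the object by T means the new scan holds enhanced(T^-1(p)) at p,
    # i.e. a pull-resample along T^-1
    post_moved = resample_volume(
        post_still, true_transform.inverse(), fill_value=TISSUE_HU["background"]
    )
    post_moved.valid = None  # a real scan has no invalid voxels

    fid_pre = np.asarray(
        fiducials_mm if fiducials_mm is not None else _default_fiducials(extent),
        dtype=float,
    )
    if fid_pre.shape != (4, 3):
        raise ValueError("exactly 4 fiducials of dimension 3 required")
    centered = fid_pre - fid_pre.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("degenerate fiducial placement (collinear/coincident)")
    fid_post = true_transform.apply(fid_pre)

    if noise_sd_hu > 0:
        pre.voxels = pre.voxels + rng.normal(0.0, noise_sd_hu, shape)
        post_moved.voxels = post_moved.voxels + rng.normal(0.0, noise_sd_hu, shape)

    return CtPhantomPair(
        pre=pre,
        post=post_moved,
        true_transform=true_transform,
        true_iodine=iodine,
        tissue_labels=labels,
        fiducials_pre=fid_pre,
        fiducials_post=fid_post,
        thickness_map_mm=thickness,
        intercept_mode=intercept_mode,
        calibration=calib,
        noise_sd_hu=noise_sd_hu,
    )
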