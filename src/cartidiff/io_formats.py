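"""File formats: TIFF radiograph stacks, NIfTI volumes, JSON configs.

Every writer/reader pair is a lossless inverse on its declared dtype:

* planar series — 16-bit multi-page TIFF plus a CSV sidecar of acquisition
  times (columns ``index,time_h``) and a separate baseline TIFF;
* volumes — NIfTI-1, voxel size in the header zooms, origin in the affine;
* run configuration, fiducials, transforms — JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, field_validator

from .containers import PlanarImageSeries, VolumeImage
from .synthetic.planar import MICROCT_PIXEL_SIZE_MM
from .synthetic.slab import PLUG_TIME_GRID_H

__all__ = [
    "write_planar_series",
    "read_planar_series",
    "write_volume",
    "read_volume",
    "RunConfig",
    "load_run_config",
    "dump_run_config",
    "write_fiducials",
    "read_fiducials",
]


def _series_paths(path) -> tuple[Path, Path, Path]:
    base = Path(path)
    stem = base.with_suffix("")
    return stem.with_suffix(".tif"), stem.with_name(stem.name + "_times.csv"), \
        stem.with_name(stem.name + "_baseline.tif")


def write_planar_series(series: PlanarImageSeries, path, quantize: bool = False) -> Path:
    """Write a planar series as 16-bit TIFF stack + CSV time sidecar.

    Images must be integral and within [0, 65535] (detector counts); pass
    ``quantize=True`` to round first. Returns the TIFF path.
    """
    tif, csv, base_tif = _series_paths(path)
    imgs = np.asarray(series.images, dtype=float)
    baseline = np.asarray(series.baseline, dtype=float)
    if quantize:
        imgs = np.clip(np.rint(imgs), 0, 65535)
        baseline = np.clip(np.rint(baseline), 0, 65535)
    for name, arr in (("images", imgs), ("baseline", baseline)):
        if np.any(arr < 0) or np.any(arr > 65535) or not np.allclose(arr, np.rint(arr)):
            raise ValueError(
                f"{name} are not 16-bit integral gray levels; "
                "pass quantize=True to round"
            )
    tifffile.imwrite(tif, imgs.astype(np.uint16), photometric="minisblack")
    tifffile.imwrite(base_tif, baseline.astype(np.uint16), photometric="minisblack")
    pd.DataFrame(
        {"index": np.arange(len(series.times)), "time_h": series.times}
    ).to_csv(csv, index=False)
    meta = tif.with_suffix(".json")
    meta.write_text(json.dumps({"pixel_size_mm": series.pixel_size}))
    return tif


def read_planar_series(path) -> PlanarImageSeries:
    """Read a planar series written by :func:`write_planar_series`."""
    tif, csv, base_tif = _series_paths(path)
    if not tif.exists():
        raise FileNotFoundError(tif)
    imgs = tifffile.imread(tif)
    if imgs.ndim == 2:
        imgs = imgs[None]
    if imgs.size == 0:
        raise ValueError("empty TIFF stack")
    sidecar = pd.read_csv(csv)
    if len(sidecar) != len(imgs):
        raise ValueError(
            f"image/time count mismatch: {len(sidecar)} vs {len(imgs)}"
        )
    baseline = tifffile.imread(base_tif)
    meta = json.loads(tif.with_suffix(".json").read_text()) if tif.with_suffix(".json").exists() else {}
    return PlanarImageSeries(
        images=imgs,
        times=sidecar["time_h"].to_numpy(dtype=float),
        pixel_size=float(meta.get("pixel_size_mm", MICROCT_PIXEL_SIZE_MM)),
        baseline=baseline,
    )


def write_volume(vol: VolumeImage, path) -> Path:
    """Write a volume as NIfTI-1; voxel size and origin go into the affine."""
    path = Path(path)
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.voxel_size
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.voxels), affine)
    img.header.set_zooms(vol.voxel_size)
    img.header["descrip"] = vol.units.encode()[:79]
    nib.save(img, path)
    return path


def read_volume(path) -> VolumeImage:
    """Read a NIfTI-1 volume written by :func:`write_volume`."""
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={data.ndim}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    units = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "HU"
    return VolumeImage(voxels=data, voxel_size=zooms, origin=origin, units=units)


class RunConfig(BaseModel):
    """Validated pipeline configuration with bench-protocol defaults.

    Unknown keys are rejected so typos cannot silently fall back to
    defaults.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    times_h: tuple[float, ...] = PLUG_TIME_GRID_H
    microct_pixel_size_mm: float = MICROCT_PIXEL_SIZE_MM
    ct_voxel_size_mm: tuple[float, float, float] = (0.32, 0.32, 0.625)
    roi_width_px: int = 100
    roi_radius_px: float = 5.0
    n_vois: int = 18
    cartilage_thickness_mm: float = 2.0
    bath_concentration_mgi_ml: float = 10.0
    intercept_mode: str = "affine"
    washout_times_h: tuple[float, ...] = (0.0, 24.0, 48.0)
    seed: int = 0

    @field_validator("microct_pixel_size_mm", "cartilage_thickness_mm",
                     "bath_concentration_mgi_ml")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @field_validator("ct_voxel_size_mm")
    @classmethod
    def _positive_tuple(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("ct_voxel_size_mm entries must be positive")
        return v

    @field_validator("intercept_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("affine", "slope_only"):
            raise ValueError("intercept_mode must be 'affine' or 'slope_only'")
        return v


def load_run_config(path) -> RunConfig:
    """Load and validate a JSON run configuration; defaults fill gaps,
    unknown keys raise with the offending key named."""
    payload = json.loads(Path(path).read_text())
    return RunConfig(**payload)


def dump_run_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(cfg.model_dump_json(indent=2))
    return path


def write_fiducials(points: np.ndarray, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"fiducials_mm": np.asarray(points).tolist()}, indent=2))
    return path


def read_fiducials(path) -> np.ndarray:
    pts = np.asarray(json.loads(Path(path).read_text())["fiducials_mm"], dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("fiducials must be an (n, 3) array")
    return pts
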