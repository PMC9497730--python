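"""Forward model for planar microCT radiographs of an immersed plug.

Each radiograph is a row-banded image: the contrast bath on top, the
cartilage layer below it (surface at the top row of the band, tidemark at
the bottom), and subchondral bone underneath. Iodine adds signal on top of a
fixed baseline tissue pattern through the same affine calibration the
analysis side inverts, plus additive Gaussian detector noise.

Two intercept conventions are supported for how the calibration intercept
interacts with baseline-subtracted signals (``intercept_mode``):

* ``"affine"`` (default): pixels holding contrast gain ``a + b*c``; the
  analysis-side conversion of a subtracted signal is then the full affine
  inverse ``(delta - a)/b``, mirroring how calibration curves are applied to
  subtracted images in practice.
* ``"slope_only"``: pixels gain ``b*c`` — the physically linear difference
  signal; the matching inverse is ``delta/b``.

Pixels with ``c = 0`` are never offset, so a zero-concentration rendering
equals the baseline exactly under either convention.
"""

from __future__ import annotations

import numpy as np

from ..calibration import CalibrationCurve
from ..containers import PlanarGeometry, PlanarImageSeries
from .slab import ConcentrationField

__all__ = [
    "make_plug_geometry",
    "render_planar_series",
    "contrast_increment",
    "MICROCT_PIXEL_SIZE_MM",
    "BASELINE_GL",
]

#: Detector pixel pitch of the planar acquisitions (mm).
MICROCT_PIXEL_SIZE_MM = 0.01152

#: Baseline gray levels of the three bands (arbitrary detector units chosen
#: so bone is far brighter than the soft bands, which sit close together).
BASELINE_GL = {"bath": 9800.0, "cartilage": 10000.0, "bone": 30000.0}


def contrast_increment(c, curve: CalibrationCurve, intercept_mode: str = "affine"):
    """Gray-level (or HU) increment produced by iodine concentration ``c``.

    Zero wherever ``c == 0``; elsewhere ``a + b*c`` (affine) or ``b*c``
    (slope_only).
    """
    c = np.asarray(c, dtype=float)
    if intercept_mode == "affine":
        delta = np.where(c > 0, curve.a + curve.b * c, 0.0)
    elif intercept_mode == "slope_only":
        delta = curve.b * c
    else:
        raise ValueError(f"unknown intercept_mode {intercept_mode!r}")
    return delta


def make_plug_geometry(
    shape: tuple[int, int] = (256, 256),
    pixel_size_mm: float = MICROCT_PIXEL_SIZE_MM,
    cartilage_thickness_mm: float = 2.0,
) -> PlanarGeometry:
    """Band layout for a plug radiograph: bath / cartilage / bone.

    The cartilage band gets ``round(thickness / pixel)`` rows; the remaining
    rows are split evenly between bath (above) and bone (below).
    """
    nrow = shape[0]
    n_cart = int(round(cartilage_thickness_mm / pixel_size_mm))
    if n_cart < 1 or n_cart > nrow - 4:
        raise ValueError(
            f"cartilage of {cartilage_thickness_mm} mm does not fit {nrow} rows "
            f"at {pixel_size_mm} mm/px"
        )
    n_rest = nrow - n_cart
    n_bath = n_rest // 2
    return PlanarGeometry(
        shape=shape,
        bath_rows=(0, n_bath),
        cartilage_rows=(n_bath, n_bath + n_cart),
        bone_rows=(n_bath + n_cart, nrow),
    )


def render_planar_series(
    field: ConcentrationField,
    calib: CalibrationCurve,
    geometry: PlanarGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept_mode: str = "affine",
    quantize: bool = False,
) -> PlanarImageSeries:
    """Render a simulated concentration field into a radiograph time series.

    Cartilage-band rows sample the field's depth profile (row centers mapped
    proportionally onto [0, L], surface at the top of the band); the bath
    band carries the bath concentration; bone carries no contrast. The
    baseline image is the zero-concentration rendering. Noise is i.i.d.
    Gaussian per pixel, independent across images and baseline.

    With ``quantize=True`` images are rounded to integral gray levels
    (detector counts), which is what the 16-bit TIFF writer stores.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    geo = geometry or make_plug_geometry(cartilage_thickness_mm=field.config.L)
    nrow, ncol = geo.shape
    rng = np.random.default_rng(seed)

    baseline = np.empty((nrow, ncol))
    baseline[slice(*geo.bath_rows)] = BASELINE_GL["bath"]
    baseline[slice(*geo.cartilage_rows)] = BASELINE_GL["cartilage"]
    baseline[slice(*geo.bone_rows)] = BASELINE_GL["bone"]

    r0, r1 = geo.cartilage_rows
    n_cart = r1 - r0
    # row centers of the cartilage band, mapped onto depth [0, L]
    depth = (np.arange(n_cart) + 0.5) / n_cart * field.config.L

    images = np.empty((len(field.times), nrow, ncol))
    for j in range(len(field.times)):
        frame = baseline.copy()
        c_rows = np.interp(depth, field.depth_grid, field.c[j])
        frame[r0:r1] += contrast_increment(c_rows, calib, intercept_mode)[:, None]
        frame[slice(*geo.bath_rows)] += contrast_increment(
            field.c_bath[j], calib, intercept_mode
        )
        images[j] = frame
    if noise_sd > 0:
        images += rng.normal(0.0, noise_sd, images.shape)
        baseline = baseline + rng.normal(0.0, noise_sd, baseline.shape)
    if quantize:
        images = np.clip(np.rint(images), 0, 65535)
        baseline = np.clip(np.rint(baseline), 0, 65535)
    return PlanarImageSeries(
        images=images,
        times=field.times.copy(),
        pixel_size=MICROCT_PIXEL_SIZE_MM,
        baseline=baseline,
        geometry=geo,
    )
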