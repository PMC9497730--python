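"""End-to-end synthetic studies tying the modules together.

Three studies mirror the bench protocol on generated data with known ground
truth:

* :func:`microct_study` — plug immersion: calibration-phantom fit, slab
  diffusion, planar rendering, baseline subtraction, ROI uptake curve,
  saturating-exponential fit, saturation time, concentrations at 24 h;
* :func:`ct_study` — paired pre/post clinical CT: calibration, fiducial
  registration, subtraction, segmentation, iodine mapping, VOI statistics,
  morphometry and the tissue-distinguishability battery;
* :func:`washout_study` — exponential washout fit and the 5% washout time.

Study-level noise defaults are the package's standing simulation
conditions; they are set once here, not tuned per run.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .calibration import (
    CalibrationCurve,
    attenuation_to_concentration,
    fit_linear_calibration,
)
from .containers import RoiSpec, VoiSpec
from .kinetics import (
    centered_cartilage_roi,
    fit_uptake_curve,
    roi_mean,
    saturation_time,
    subtract_baseline,
)
from .stats import tissue_distinguishability
from .synthetic.phantom import (
    DEFAULT_CLINICAL_CALIBRATION,
    TISSUE_LABELS,
    build_ct_phantom_pair,
)
from .synthetic.planar import render_planar_series
from .synthetic.slab import SlabDiffusionConfig, solve_slab_diffusion
from .volumetric import (
    estimate_cartilage_thickness,
    estimate_cartilage_volume,
    fit_rigid_from_fiducials,
    map_iodine,
    resample_volume,
    segment_iodine_mask,
    subtract_volumes,
    voi_statistics,
)
from .washout import fit_washout, simulate_washout_curve, washout_time

__all__ = [
    "microct_study",
    "ct_study",
    "washout_study",
    "coregister_and_segment",
    "MICRO_CALIBRATION_TRUE",
    "MICRO_CALIB_CONCENTRATIONS",
    "CLINICAL_CALIB_CONCENTRATIONS",
]

#: True microCT-scale calibration the simulator renders with.
MICRO_CALIBRATION_TRUE = CalibrationCurve(a=0.7531, b=1.6189, units="GL")
#: Flask concentrations measured for the two calibration curves (mgI/mL).
MICRO_CALIB_CONCENTRATIONS = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0)
CLINICAL_CALIB_CONCENTRATIONS = (0.0, 5.0, 10.0, 15.0, 20.0)

# Standing noise conditions of the synthetic studies: ~1 GL of scatter on
# flask gray levels, 5 GL of planar detector noise, ~13 HU on flask CT
# numbers, 40 HU per clinical scan (SNR ~5.7 on a 10 mgI/mL enhancement).
MICRO_CALIB_NOISE_GL = 0.8
PLANAR_NOISE_GL = 5.0
CLINICAL_CALIB_NOISE_HU = 13.0
CLINICAL_NOISE_HU = 40.0


def _fit_calibration_phantom(
    true_curve: CalibrationCurve, concentrations, noise_sd: float, rng
) -> CalibrationCurve:
    c = np.asarray(concentrations, dtype=float)
    atten = true_curve.a + true_curve.b * c + rng.normal(0.0, noise_sd, c.size)
    return fit_linear_calibration(c, atten, units=true_curve.units)


def microct_study(
    seed: int = 0,
    config: SlabDiffusionConfig | None = None,
    noise_sd_gl: float = PLANAR_NOISE_GL,
    intercept_mode: str = "affine",
) -> dict:
    """Simulated plug-immersion experiment at the microCT scale.

    Returns fitted calibration coefficients, the uptake fit (plateau, tau,
    tau95), the cartilage and bath iodine concentrations at the 24 h point
    and their ratio.
    """
    rng = np.random.default_rng(seed)
    cfg = config or SlabDiffusionConfig()
    calib = _fit_calibration_phantom(
        MICRO_CALIBRATION_TRUE, MICRO_CALIB_CONCENTRATIONS, MICRO_CALIB_NOISE_GL, rng
    )
    field = solve_slab_diffusion(cfg)
    series = render_planar_series(
        field, MICRO_CALIBRATION_TRUE, noise_sd=noise_sd_gl,
        seed=int(rng.integers(2**31)), intercept_mode=intercept_mode,
    )
    sub = subtract_baseline(series)
    roi = centered_cartilage_roi(sub)
    uptake_gl = np.array([roi_mean(img, roi)[0] for img in sub.images])
    geo = sub.geometry
    bath_roi = RoiSpec(
        shape="rect",
        center=((geo.bath_rows[0] + geo.bath_rows[1] - 1) / 2.0,
                (geo.shape[1] - 1) / 2.0),
        width=100, height=max(geo.bath_rows[1] - geo.bath_rows[0] - 2, 1),
    )
    bath_gl = np.array([roi_mean(img, bath_roi)[0] for img in sub.images])

    fit = fit_uptake_curve(sub.times, uptake_gl)
    i24 = int(np.argmin(np.abs(sub.times - 24.0)))
    c_cart_24 = attenuation_to_concentration(calib, uptake_gl[i24])
    c_bath_24 = attenuation_to_concentration(calib, bath_gl[i24])
    return {
        "calibration_a_gl": calib.a,
        "calibration_b_gl_per_mgi_ml": calib.b,
        "calibration_r2": calib.r2,
        "plateau_gl": fit.a,
        "tau_h": fit.tau,
        "tau95_h": saturation_time(fit),
        "tau95_exact_h": saturation_time(fit, exact=True),
        "uptake_fit_r2": fit.r2,
        "c24_mgi_ml": c_cart_24,
        "c_bath_24_mgi_ml": c_bath_24,
        "relative_c24": c_cart_24 / c_bath_24,
        "n_time_points": int(len(sub.times)),
    }


def coregister_and_segment(
    pair, smooth_sigma: float = 1.0, min_component_voxels: int = 27
) -> dict:
    """Register post onto pre, subtract, and auto-segment the enhancement.

    The difference volume is Gaussian-smoothed for segmentation only; the
    threshold is half the robustly estimated enhancement plateau (median of
    smoothed values above 3x the noise floor), which keeps the boundary of
    a blurred step unbiased. Concentration mapping downstream uses the
    unsmoothed difference.
    """
    transform, fre = fit_rigid_from_fiducials(pair.fiducials_pre, pair.fiducials_post)
    post_reg = resample_volume(pair.post, transform,
                               fill_value=float(pair.post.voxels.min()))
    diff = subtract_volumes(post_reg, pair.pre)
    smoothed = ndimage.gaussian_filter(diff.voxels, smooth_sigma)
    noise_sd = 1.4826 * float(np.median(np.abs(smoothed - np.median(smoothed))))
    # fixed-point plateau estimate: threshold at half the median enhancement
    # of supra-threshold voxels, iterated so the blurred shell stops biasing
    # the plateau; half-plateau keeps a blurred step edge unbiased
    threshold = max(3.0 * noise_sd, 1e-6)
    for _ in range(4):
        above = smoothed[smoothed > threshold]
        if above.size == 0:
            break
        threshold = float(np.median(above)) / 2.0
    mask = segment_iodine_mask(
        diff.copy_with(voxels=smoothed), threshold,
        min_component_voxels=min_component_voxels,
    )
    return {
        "transform": transform,
        "fre_rms_mm": fre,
        "diff": diff,
        "mask": mask,
        "threshold_hu": threshold,
        "noise_sd_hu": noise_sd,
    }


def _interior_vois(mask: np.ndarray, n_vois: int, radius_px: float, axis: int = 0):
    """Cylindrical VOIs centered inside the segmented layer, axis along the
    thickness direction, half-length 30% of the local layer extent."""
    ny, nz = [s for a, s in enumerate(mask.shape) if a != axis]
    vois = []
    grid = int(np.ceil(np.sqrt(n_vois)))
    margin = radius_px + 2
    ys = np.linspace(margin, ny - 1 - margin, grid)
    zs = np.linspace(margin, nz - 1 - margin, grid)
    for y in ys:
        for z in zs:
            if len(vois) >= n_vois:
                break
            col = mask[:, int(round(y)), int(round(z))]
            idx = np.flatnonzero(col)
            if idx.size < 4:
                continue
            center_x = float(idx.mean())
            half = max(1.0, 0.3 * idx.size)
            vois.append(VoiSpec(center=(center_x, float(y), float(z)),
                                radius=radius_px, half_length=half, axis=axis))
    return vois


def ct_study(
    seed: int = 0,
    shape: tuple[int, int, int] = (96, 96, 64),
    noise_sd_hu: float = CLINICAL_NOISE_HU,
    concentration: float = 10.0,
    n_vois: int = 18,
    intercept_mode: str = "affine",
) -> dict:
    """Simulated paired pre/post clinical-CT experiment.

    Builds the phantom, runs the full volumetric pipeline and compares every
    recovered quantity with the generator's ground truth.
    """
    rng = np.random.default_rng(seed)
    calib_fit = _fit_calibration_phantom(
        DEFAULT_CLINICAL_CALIBRATION, CLINICAL_CALIB_CONCENTRATIONS,
        CLINICAL_CALIB_NOISE_HU, rng,
    )
    pair = build_ct_phantom_pair(
        shape=shape,
        iodine_map_params={"concentration": concentration},
        noise_sd_hu=noise_sd_hu,
        seed=int(rng.integers(2**31)),
        intercept_mode=intercept_mode,
    )
    seg = coregister_and_segment(pair)
    mask, diff = seg["mask"], seg["diff"]
    truth = pair.cartilage_mask

    inter = np.count_nonzero(mask & truth)
    dice = 2.0 * inter / (np.count_nonzero(mask) + np.count_nonzero(truth))

    conc_vol = map_iodine(diff, DEFAULT_CLINICAL_CALIBRATION, mask,
                          intercept_mode=intercept_mode)
    vois = _interior_vois(mask, n_vois=n_vois, radius_px=12.0, axis=0)
    voi_table, pooled = voi_statistics(conc_vol, vois)

    volume = estimate_cartilage_volume(mask, pair.pre.voxel_size)
    thick_mean, thick_sd, _ = estimate_cartilage_thickness(
        mask, vois, axis=0, pixel_size=pair.pre.voxel_size[0]
    )
    true_thick = pair.true_thickness_mm()
    true_thick = true_thick[true_thick > 0]  # columns actually holding cartilage
    rot_err = seg["transform"].compose(pair.true_transform.inverse()).rotation_angle_deg()
    # registered frame equals pre frame, so the same translation comparison
    trans_err = float(np.linalg.norm(
        seg["transform"].translation - pair.true_transform.translation))

    # tissue samples: circular in-slice ROIs inside each (eroded) tissue region
    post_reg = resample_volume(pair.post, seg["transform"],
                               fill_value=float(pair.post.voxels.min()))
    samples_pre, samples_post = {}, {}
    for name in ("connective", "bone", "cartilage"):
        region = ndimage.binary_erosion(pair.tissue_labels == TISSUE_LABELS[name],
                                        iterations=2)
        if post_reg.valid is not None:
            region &= post_reg.valid  # stay inside the registered field of view
        coords = np.argwhere(region)
        take = coords[rng.choice(coords.shape[0], size=min(1944, coords.shape[0]),
                                 replace=False)]
        samples_pre[name] = pair.pre.voxels[tuple(take.T)]
        samples_post[name] = post_reg.voxels[tuple(take.T)]
    stats_pre = tissue_distinguishability(samples_pre)
    stats_post = tissue_distinguishability(samples_post)

    return {
        "calibration_a_hu": calib_fit.a,
        "calibration_b_hu_per_mgi_ml": calib_fit.b,
        "calibration_r2": calib_fit.r2,
        "fre_rms_mm": seg["fre_rms_mm"],
        "rotation_error_deg": rot_err,
        "translation_error_mm": trans_err,
        "dice": float(dice),
        "voi_mean_concentration_mgi_ml": pooled["mean"],
        "true_concentration_mgi_ml": concentration,
        "segmentation_threshold_hu": seg["threshold_hu"],
        "volume_cm3": volume,
        "true_volume_cm3": pair.true_volume_cm3(),
        "thickness_mm": thick_mean,
        "thickness_sd_mm": thick_sd,
        "true_thickness_mm": float(true_thick.mean()),
        "n_vois": len(vois),
        "cohens_d_cartilage_connective_pre": float(stats_pre.table.loc["C-L", "cohens_d"]),
        "cohens_d_cartilage_connective_post": float(stats_post.table.loc["C-L", "cohens_d"]),
        "cohens_d_bone_cartilage_post": float(stats_post.table.loc["B-C", "cohens_d"]),
        "mw_p_cartilage_connective_post": float(stats_post.table.loc["C-L", "mw_p"]),
        "tables": {"pre": stats_pre, "post": stats_post},
    }


def washout_study(
    seed: int = 0,
    c0: float = 21.2,
    bw: float = 0.01,
    noise_frac: float = 0.05,
    times=(0.0, 24.0, 48.0),
) -> dict:
    """Simulated washout experiment: 3-point decay, exponential fit, and the
    time to reach 5% of the post-immersion concentration."""
    t, c = simulate_washout_curve(c0, bw, times=times,
                                  noise_sd=noise_frac * c0, seed=seed)
    fit = fit_washout(t, c)
    return {
        "aw_mgi_ml": fit.aw,
        "bw_per_h": fit.bw,
        "washout_r2": fit.r2,
        "washout_time_h": washout_time(fit, fit.aw),
        "n_points": int(len(t)),
    }
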