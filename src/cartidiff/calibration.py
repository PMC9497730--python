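"""Affine attenuation-to-iodine calibration.

Both imaging scales use the same linear model ``attenuation = a + b * c``
with ``c`` the iodine concentration in mgI/mL: at the microCT scale the
attenuation is in detector gray levels (GL), at the clinical-CT scale in
Hounsfield units (HU). The curve is fitted by ordinary least squares on
phantom flask measurements and inverted to convert observed attenuation to
effective iodine concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "fit_linear_calibration",
    "attenuation_to_concentration",
    "concentration_to_attenuation",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine attenuation <-> concentration map.

    Attributes
    ----------
    a : float
        Intercept, in attenuation units (GL or HU).
    b : float
        Slope, attenuation units per mgI/mL; positive for a usable curve.
    r2 : float
        Coefficient of determination of the fit (squared Pearson r of
        observed vs fitted). ``pearson_r`` is exposed alongside because both
        conventions circulate in calibration reports.
    units : str
        ``"GL"`` or ``"HU"``.
    """

    a: float
    b: float
    r2: float = 1.0
    units: str = "GL"

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")

    @property
    def pearson_r(self) -> float:
        return float(np.sqrt(self.r2))


def fit_linear_calibration(
    concentrations, attenuations, units: str = "GL"
) -> CalibrationCurve:
    """Ordinary least-squares fit of ``attenuation = a + b * concentration``.

    Parameters
    ----------
    concentrations : array-like, mgI/mL
        At least two distinct values.
    attenuations : array-like
        Same length as ``concentrations``, in ``units``.
    units : str
        Attenuation unit tag recorded on the curve.

    Returns
    -------
    CalibrationCurve

    Raises
    ------
    ValueError
        On length mismatch or if all concentrations coincide (the slope is
        then undefined).
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(attenuations, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError(f"length mismatch: {c.shape} vs {y.shape}")
    if c.size < 2:
        raise ValueError("need at least 2 calibration points")
    if np.ptp(c) == 0:
        raise ValueError("all concentrations equal: slope undefined")
    res = stats.linregress(c, y)
    # r is NaN when the response is exactly constant; the line still fits.
    r2 = 1.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    if res.slope <= 0:
        warnings.warn(
            f"calibration slope b={res.slope:.4g} is not positive; "
            "curve is not usable for concentration conversion",
            stacklevel=2,
        )
    return CalibrationCurve(a=float(res.intercept), b=float(res.slope), r2=r2, units=units)


def attenuation_to_concentration(curve: CalibrationCurve, value):
    """Invert the calibration: ``c = (value - a) / b`` in mgI/mL.

    Negative predicted concentrations are returned as-is with a warning —
    clamping would bias downstream washout fits; segmentation handles them.
    """
    if curve.b == 0:
        raise ValueError("calibration slope is zero; inversion undefined")
    c = (np.asarray(value, dtype=float) - curve.a) / curve.b
    if np.any(c < 0):
        warnings.warn("negative predicted concentration(s) returned unclamped", stacklevel=2)
    if np.isscalar(value) or np.ndim(value) == 0:
        return float(c)
    return c


def concentration_to_attenuation(curve: CalibrationCurve, concentration):
    """Forward map ``a + b * c``, the exact inverse of
    :func:`attenuation_to_concentration`."""
    out = curve.a + curve.b * np.asarray(concentration, dtype=float)
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return float(out)
    return out
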