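"""Calibrated intracompartmental pressure.

The raw channel is converted to mmHg with an affine calibration plus a
linear residual temperature-drift term; hydrostatic water-column checks
fit gain/offset against rho*g*h.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from . import constants as C
from .config import PressureCalibration
from .errors import FitError, InputError

__all__ = [
    "calibrate_pressure",
    "fit_hydrostatic",
    "mmhg_to_pa",
    "pa_to_mmhg",
    "mmhg_to_kpa",
    "kpa_to_mmhg",
    "HydrostaticFit",
]


def mmhg_to_pa(p):
    return np.asarray(p, dtype=float) * C.MMHG_PA


def pa_to_mmhg(p):
    return np.asarray(p, dtype=float) / C.MMHG_PA


def mmhg_to_kpa(p):
    return np.asarray(p, dtype=float) * (C.MMHG_PA / 1000.0)


def kpa_to_mmhg(p):
    return np.asarray(p, dtype=float) / (C.MMHG_PA / 1000.0)


def calibrate_pressure(raw, t_dev, cal: PressureCalibration):
    """icp = gain * raw - offset - temp_coeff * (t_dev - t_ref), in mmHg."""
    raw = np.asarray(raw, dtype=float)
    t_dev = np.asarray(t_dev, dtype=float)
    icp = cal.gain * raw - cal.offset - cal.temp_coeff * (t_dev - cal.t_ref)
    return float(icp) if icp.ndim == 0 else icp


class HydrostaticFit(NamedTuple):
    calibration: PressureCalibration
    residuals_mmhg: np.ndarray
    reference_mmhg: np.ndarray


def fit_hydrostatic(depths_m, readings_mmhg,
                    fluid_density: float = C.WATER_DENSITY) -> HydrostaticFit:
    """Fit gain/offset against the water-column reference P = rho g h.

    Solves least squares for gain * reading - offset = P(h).  Requires
    at least two distinct depths (otherwise the design is rank
    deficient).
    """
    depths = np.asarray(depths_m, dtype=float)
    readings = np.asarray(readings_mmhg, dtype=float)
    if depths.shape != readings.shape or depths.ndim != 1:
        raise InputError("depths and readings must be equal-length 1-D arrays")
    if np.unique(depths).size < 2:
        raise FitError("hydrostatic fit needs >= 2 distinct depths")
    reference = fluid_density * C.STANDARD_GRAVITY * depths / C.MMHG_PA
    design = np.column_stack([readings, -np.ones_like(readings)])
    (gain, offset), *_ = np.linalg.lstsq(design, reference, rcond=None)
    if gain <= 0:
        raise FitError(f"fitted nonpositive gain {gain:.3g}")
    cal = PressureCalibration(gain=float(gain), offset=float(offset))
    residuals = gain * readings - offset - reference
    return HydrostaticFit(calibration=cal, residuals_mmhg=residuals,
                          reference_mmhg=reference)
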