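"""Validated configuration and parameter models (pydantic).

These are the plain-scalar domain types shared across stages: episode
generation, thermal transport, optics, hemoglobin state, pressure
calibration and the diagnostic rule.  Array-carrying containers live in
:mod:`acsmon.trace` and :mod:`acsmon.simulate`.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import constants as C
from .errors import ConfigurationError


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


# ---------------------------------------------------------------------------
# episode simulator
# ---------------------------------------------------------------------------

class RampStep(_Model):
    """One loading step: ramp to ``target`` starting at ``start`` over ``ramp``."""

    start: float = Field(ge=0)
    target: float
    ramp: float = Field(default=60.0, ge=0)


class EpisodeConfig(_Model):
    """Parameters of a synthetic physiological episode."""

    duration: float = Field(default=900.0, gt=0, description="seconds")
    sample_rate: float = Field(default=20.0, gt=0, description="Hz")
    icp_profile: list[RampStep] = Field(
        default_factory=lambda: [
            RampStep(start=0.0, target=0.0, ramp=0.0),
            RampStep(start=180.0, target=50.0, ramp=60.0),
            RampStep(start=420.0, target=100.0, ramp=60.0),
            RampStep(start=660.0, target=150.0, ramp=60.0),
        ])
    dbp: float = Field(default=70.0, description="diastolic blood pressure, mmHg")
    heart_rate: float = Field(default=72.0, gt=0, description="beats per minute")
    flow_lag_tau: float = Field(default=10.0, ge=0, description="s, first-order lag")
    sto2_baseline: float = Field(default=C.DEFAULT_STO2_BASELINE, gt=0, le=1)
    flow_baseline: float = Field(default=10.0, ge=0, description="mm/s")
    coupling_slope_sto2: float = Field(default=-2e-3, le=0, description="1/mmHg")
    coupling_slope_flow: float = Field(default=-0.06, le=0, description="mm/s per mmHg")
    ac_fraction: float = Field(default=0.02, ge=0, description="AC amplitude / DC")
    i0_red: float = Field(default=1.0, description="source intensity, red")
    i0_ir: float = Field(default=1.0, description="source intensity, IR")
    tissue_temp: float = Field(default=310.15, gt=0, description="K baseline tissue")
    device_temp: float = Field(default=310.15, gt=0, description="K, pressure die")
    device_temp_drift: float = Field(default=0.0, ge=0, description="K, slow sinusoid amplitude")
    pressure_offset: float = Field(default=0.0, description="mmHg raw-channel offset")
    pressure_temp_coeff: float = Field(default=0.0, description="mmHg/K")
    pressure_t_ref: float = Field(default=310.15, gt=0, description="K")
    heater_schedule: list[tuple[float, float]] | None = Field(
        default=None, description="(on, off) intervals in s; None = always on")
    noise_sd: dict[str, float] = Field(
        default_factory=lambda: {"pressure": 0.5, "ppg": 1e-4, "thermistor": 5e-3})
    seed: int = 0

    @field_validator("icp_profile")
    @classmethod
    def _profile_ordered(cls, profile: list[RampStep]) -> list[RampStep]:
        starts = [s.start for s in profile]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("icp_profile start times must be strictly increasing")
        for cur, nxt in zip(profile, profile[1:]):
            if cur.start + cur.ramp > nxt.start:
                raise ValueError(
                    f"ramp starting at {cur.start} s overlaps the next step at {nxt.start} s")
        return profile

    @field_validator("noise_sd")
    @classmethod
    def _noise_nonnegative(cls, sd: dict[str, float]) -> dict[str, float]:
        if any(v < 0 for v in sd.values()):
            raise ValueError("noise SDs must be nonnegative")
        return sd

    def heater_on(self, t: np.ndarray) -> np.ndarray:
        """Boolean heater state per sample."""
        if self.heater_schedule is None:
            return np.ones_like(t, dtype=bool)
        on = np.zeros_like(t, dtype=bool)
        for a, b in self.heater_schedule:
            on |= (t >= a) & (t < b)
        return on


# ---------------------------------------------------------------------------
# thermal flow
# ---------------------------------------------------------------------------

class NTCCalibration(_Model):
    """Negative-temperature-coefficient thermistor calibration."""

    beta: float = Field(default=C.NTC_BETA_K, gt=0, description="K")
    r0: float = Field(default=C.NTC_R0_OHM, gt=0, description="ohm")
    t0: float = Field(default=C.NTC_T0_K, gt=0, description="K")
    mode: Literal["beta_model", "linear"] = "beta_model"
    linear_slope: float = Field(default=-320.0, description="ohm/K, linear mode")
    linear_intercept: float = Field(default=1.06e5, description="ohm at 0 K, linear mode")

    @model_validator(mode="after")
    def _linear_is_ntc(self) -> "NTCCalibration":
        if self.mode == "linear" and self.linear_slope >= 0:
            raise ValueError("linear NTC slope must be negative")
        return self


class ThermalModelParams(_Model):
    """Heater/spreader geometry and transport constants for the flow model."""

    q_heat: float = Field(default=C.DEFAULT_Q_HEAT, gt=0, description="W/m^2")
    big_r: float = Field(default=C.DEFAULT_SPREADER_RADIUS, gt=0, description="m")
    k_tissue: float = Field(default=C.DEFAULT_K_TISSUE, gt=0, description="W/(m K)")
    alpha_fluid: float = Field(default=C.DEFAULT_ALPHA_BLOOD, gt=0, description="m^2/s")
    s_blood: float = Field(default=C.DEFAULT_BLOOD_CONTENT, gt=0)
    r_list: tuple[float, ...] = Field(default=C.DEFAULT_THERMISTOR_R, description="m")

    @field_validator("r_list")
    @classmethod
    def _r_valid(cls, r_list: Sequence[float]) -> tuple[float, ...]:
        r_list = tuple(float(r) for r in r_list)
        if any(r <= 0 for r in r_list):
            raise ValueError("thermistor distances must be strictly positive")
        if any(b <= a for a, b in zip(r_list, r_list[1:])):
            raise ValueError("r_list must be strictly ascending")
        return r_list


# ---------------------------------------------------------------------------
# oximetry
# ---------------------------------------------------------------------------

class OpticalConstants(_Model):
    """Dual-wavelength extinction/pathlength constants for the log-attenuation model."""

    wavelengths: tuple[float, float] = (C.WAVELENGTH_RED_NM, C.WAVELENGTH_IR_NM)
    eps_hbo2: tuple[float, float] = (C.EPS_HBO2[660.0], C.EPS_HBO2[880.0])
    eps_hb: tuple[float, float] = (C.EPS_HB[660.0], C.EPS_HB[880.0])
    dpf: tuple[float, float] = (C.DEFAULT_DPF, C.DEFAULT_DPF)
    d_led_pd: float = Field(default=C.DEFAULT_LED_PD_CM, gt=0, description="cm")

    @model_validator(mode="after")
    def _positive(self) -> "OpticalConstants":
        if any(v <= 0 for v in (*self.eps_hbo2, *self.eps_hb, *self.dpf)):
            raise ValueError("extinction coefficients and DPF must be positive")
        return self

    @property
    def extinction_matrix(self) -> np.ndarray:
        """Rows per wavelength: [eps_HbO2 * DPF, eps_Hb * DPF] (L/mol/cm)."""
        return np.array([
            [self.eps_hbo2[0] * self.dpf[0], self.eps_hb[0] * self.dpf[0]],
            [self.eps_hbo2[1] * self.dpf[1], self.eps_hb[1] * self.dpf[1]],
        ])

    def require_invertible(self, max_cond: float = 1e8) -> np.ndarray:
        m = self.extinction_matrix
        cond = float(np.linalg.cond(m))
        if not np.isfinite(cond) or cond > max_cond:
            raise ConfigurationError(
                f"extinction matrix is near singular (condition number {cond:.3g})")
        return m


class HemoState(_Model):
    """Baseline oxygenated/deoxygenated hemoglobin split."""

    total_hb_conc: float = Field(default=C.TOTAL_HB_G_PER_L, gt=0, description="g/L")
    molar_mass_hb: float = Field(default=C.HB_MOLAR_MASS_G_PER_MOL, gt=0, description="g/mol")
    sto2_baseline: float = Field(default=C.DEFAULT_STO2_BASELINE, ge=0, le=1)

    @property
    def total_molar(self) -> float:
        """Total hemoglobin concentration, mol/L."""
        return self.total_hb_conc / self.molar_mass_hb

    @property
    def hbo2_0(self) -> float:
        return self.sto2_baseline * self.total_molar

    @property
    def hb_0(self) -> float:
        return (1.0 - self.sto2_baseline) * self.total_molar


# ---------------------------------------------------------------------------
# pressure + diagnostics
# ---------------------------------------------------------------------------

class PressureCalibration(_Model):
    """Affine pressure calibration with a linear temperature-drift term."""

    offset: float = 0.0
    gain: float = Field(default=1.0, gt=0)
    temp_coeff: float = Field(default=0.0, description="mmHg/K")
    t_ref: float = Field(default=310.15, gt=0, description="K")


class DiagnosticRule(_Model):
    """Perfusion-differential alarm rule: deltaP below threshold for min_duration."""

    delta_p_threshold: float = Field(default=30.0, gt=0, description="mmHg")
    min_duration: float = Field(default=7200.0, gt=0, description="s")
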