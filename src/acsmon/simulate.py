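"""Synthetic physiological-episode generator.

Produces raw multichannel sensor streams with the structure the analysis
assumes — stepped compartment-pressure loading, inverse StO2 and flow
responses (flow with a first-order lag), cardiac pulsatility on the PPG
channels, heater-gated thermistor rises and additive Gaussian sensor
noise — together with the ground truth needed for round-trip testing.

Determinism: every channel draws from its own `numpy` generator seeded
as (config.seed, stage tag), so identical configs give bit-identical
output regardless of which stages are generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import EpisodeConfig, HemoState, OpticalConstants, ThermalModelParams
from .errors import ConfigurationError
from .thermal import _shape_factor_cached, _default_denominator
from .trace import MultiChannelTrace, TimeSeries

__all__ = [
    "GroundTruth",
    "generate_icp_trace",
    "derive_physiology",
    "forward_ppg",
    "forward_thermistors",
    "forward_pressure",
    "simulate_episode",
    "SimulatedEpisode",
]

_STAGE_SEEDS = {"ppg": 1, "thermistor": 2, "pressure": 3}


@dataclass
class GroundTruth:
    """True physiological series underlying a simulated episode.

    All arrays share ``time``; ``sto2`` is consistent with
    (``d_hbo2``, ``d_hb``, ``hemo``) under the saturation identity at
    constant total hemoglobin.
    """

    time: np.ndarray
    icp: np.ndarray      # mmHg
    u: np.ndarray        # mm/s, lagged flow velocity
    sto2: np.ndarray     # fraction
    d_hbo2: np.ndarray   # mol/L change from baseline
    d_hb: np.ndarray     # mol/L change from baseline
    hemo: HemoState


def _rng(config: EpisodeConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGE_SEEDS[stage]])


def time_base(config: EpisodeConfig) -> np.ndarray:
    n = int(round(config.duration * config.sample_rate))
    return np.arange(n) / config.sample_rate


def generate_icp_trace(config: EpisodeConfig) -> TimeSeries:
    """Noise-free piecewise-linear loading profile in mmHg.

    Each profile step ramps linearly from the previous target to its own
    over ``ramp`` seconds starting at ``start``, then holds the plateau.
    An empty profile gives a constant zero trace.  Overlapping ramps are
    rejected at config validation.
    """
    t = time_base(config)
    icp = np.zeros_like(t)
    profile = config.icp_profile
    prev_target = 0.0
    for i, step in enumerate(profile):
        seg_end = profile[i + 1].start if i + 1 < len(profile) else np.inf
        in_seg = (t >= step.start) & (t < seg_end)
        tt = t[in_seg]
        if step.ramp > 0:
            frac = np.clip((tt - step.start) / step.ramp, 0.0, 1.0)
        else:
            frac = np.ones_like(tt)
        icp[in_seg] = prev_target + (step.target - prev_target) * frac
        prev_target = step.target
    return TimeSeries(t, icp, unit="mmHg", name="icp")


def _first_order_lag(target: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Exact zero-order-hold discretization of du/dt = (target - u)/tau."""
    if tau <= 0:
        return target.copy()
    out = np.empty_like(target)
    out[0] = target[0]
    decay = np.exp(-dt / tau)
    for i in range(1, target.size):
        out[i] = target[i] + (out[i - 1] - target[i]) * decay
    return out


def derive_physiology(icp: TimeSeries, config: EpisodeConfig,
                      hemo: HemoState | None = None) -> GroundTruth:
    """Clamped-linear coupling of pressure to saturation and flow.

    sto2 = clip(baseline + slope_s * icp, 0, 1); flow target
    max(0, baseline_u + slope_u * icp) passes through a first-order lag
    with time constant ``flow_lag_tau``.  Concentration changes
    redistribute oxygenation at constant total hemoglobin:
    d_hbo2 = (sto2 - baseline) * total, d_hb = -d_hbo2.
    """
    hemo = hemo or HemoState(sto2_baseline=config.sto2_baseline)
    if hemo.sto2_baseline != config.sto2_baseline:
        raise ConfigurationError("hemo state baseline disagrees with episode config")
    p = np.asarray(icp.values, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ConfigurationError("icp trace must be finite")
    sto2 = np.clip(config.sto2_baseline + config.coupling_slope_sto2 * p, 0.0, 1.0)
    u_target = np.maximum(0.0, config.flow_baseline + config.coupling_slope_flow * p)
    dt = 1.0 / config.sample_rate
    u = _first_order_lag(u_target, config.flow_lag_tau, dt)
    d_hbo2 = (sto2 - hemo.sto2_baseline) * hemo.total_molar
    return GroundTruth(time=icp.time.copy(), icp=p.copy(), u=u, sto2=sto2,
                       d_hbo2=d_hbo2, d_hb=-d_hbo2, hemo=hemo)


def forward_ppg(gt: GroundTruth, oc: OpticalConstants,
                config: EpisodeConfig) -> MultiChannelTrace:
    """Dual-wavelength PPG intensities from the ground-truth concentrations.

    I(l, t) = I0(l) * exp(-q * DPF(l) * (eps_hbo2(l) d_hbo2 + eps_hb(l) d_hb))
    * (1 + ac * sin(2 pi f_hr t)) + noise; log-linear in the
    concentration changes by construction.
    """
    if config.i0_red <= 0 or config.i0_ir <= 0:
        raise ConfigurationError("source intensities must be positive")
    rng = _rng(config, "ppg")
    f_hr = config.heart_rate / 60.0
    pulsatile = 1.0 + config.ac_fraction * np.sin(2.0 * np.pi * f_hr * gt.time)
    sd = config.noise_sd.get("ppg", 0.0)
    channels, units = {}, {}
    for name, i0, k in (("ppg_red", config.i0_red, 0), ("ppg_ir", config.i0_ir, 1)):
        od = oc.d_led_pd * oc.dpf[k] * (oc.eps_hbo2[k] * gt.d_hbo2
                                        + oc.eps_hb[k] * gt.d_hb)
        intensity = i0 * np.exp(-od) * pulsatile
        intensity = intensity + rng.normal(0.0, sd, size=gt.time.size)
        channels[name] = intensity
        units[name] = "au"
    return MultiChannelTrace(gt.time, channels, units,
                             {"seed": config.seed, "stage": "forward_ppg"})


def forward_thermistors(gt: GroundTruth, tp: ThermalModelParams,
                        config: EpisodeConfig) -> MultiChannelTrace:
    """Thermistor temperatures (K) plus the heater schedule channel.

    While the heater is on each channel reads tissue baseline plus the
    steady flow-dependent rise; while off it reads the baseline.  The
    common baseline cancels in channel differences.
    """
    rng = _rng(config, "thermistor")
    on = config.heater_on(gt.time)
    denom = _default_denominator(gt.u, tp)
    sd = config.noise_sd.get("thermistor", 0.0)
    channels, units = {}, {}
    for i, r in enumerate(tp.r_list, start=1):
        amp = (tp.q_heat * tp.big_r / tp.k_tissue) * _shape_factor_cached(r, tp.big_r)
        delta = np.where(on, amp / denom, 0.0)
        channels[f"t{i}"] = (config.tissue_temp + delta
                             + rng.normal(0.0, sd, size=gt.time.size))
        units[f"t{i}"] = "K"
    channels["heater"] = on.astype(float)
    units["heater"] = "1"
    return MultiChannelTrace(gt.time, channels, units,
                             {"seed": config.seed, "stage": "forward_thermistors"})


def forward_pressure(gt: GroundTruth, config: EpisodeConfig) -> MultiChannelTrace:
    """Raw pressure channel with offset/temperature drift, plus device temperature."""
    rng = _rng(config, "pressure")
    t_dev = config.device_temp + config.device_temp_drift * np.sin(
        2.0 * np.pi * gt.time / 600.0)
    sd = config.noise_sd.get("pressure", 0.0)
    raw = (gt.icp + config.pressure_offset
           + config.pressure_temp_coeff * (t_dev - config.pressure_t_ref)
           + rng.normal(0.0, sd, size=gt.time.size))
    return MultiChannelTrace(
        gt.time, {"pressure_raw": raw, "temp_device": t_dev},
        {"pressure_raw": "mmHg", "temp_device": "K"},
        {"seed": config.seed, "stage": "forward_pressure"})


@dataclass
class SimulatedEpisode:
    config: EpisodeConfig
    ground_truth: GroundTruth
    ppg: MultiChannelTrace
    thermal: MultiChannelTrace
    pressure: MultiChannelTrace


def simulate_episode(config: EpisodeConfig,
                     oc: OpticalConstants | None = None,
                     tp: ThermalModelParams | None = None,
                     hemo: HemoState | None = None) -> SimulatedEpisode:
    """Generate a full episode: all raw sensor streams plus ground truth."""
    oc = oc or OpticalConstants()
    tp = tp or ThermalModelParams()
    icp = generate_icp_trace(config)
    gt = derive_physiology(icp, config, hemo)
    return SimulatedEpisode(
        config=config,
        ground_truth=gt,
        ppg=forward_ppg(gt, oc, config),
        thermal=forward_thermistors(gt, tp, config),
        pressure=forward_pressure(gt, config),
    )


def ground_truth_trace(gt: GroundTruth, seed: int | None = None) -> MultiChannelTrace:
    """Pack the ground truth as a trace for CSV round-tripping."""
    meta = {"stage": "ground_truth"}
    if seed is not None:
        meta["seed"] = seed
    return MultiChannelTrace(
        gt.time,
        {"icp": gt.icp, "u": gt.u, "sto2": gt.sto2,
         "d_hbo2": gt.d_hbo2, "d_hb": gt.d_hb},
        {"icp": "mmHg", "u": "mm/s", "sto2": "1",
         "d_hbo2": "mol/L", "d_hb": "mol/L"},
        meta)
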