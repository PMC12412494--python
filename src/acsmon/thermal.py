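"""Thermal-anemometry flow model.

The probe heats the tissue through a circular spreader of radius ``R``
and reads the steady temperature rise at four thermistors placed at
distances ``r`` from the heater.  The temperature rise follows

    dT(u, r) = (q R / lambda) * F(r / R) / (1 + 0.76 s u R / alpha_fluid)

where ``u`` is the flow velocity and ``F`` is the dimensionless shape
factor

    F(r, R) = integral_0^inf J0(g r) J1(g R) dg / g,

an oscillatory Bessel integral evaluated here by quadrature between
consecutive zeros of the integrand with alternating-series (Wynn
epsilon) acceleration.  The grouping of the flow term is the only
arrangement of the published symbols that is monotone decreasing in
``u`` (forced convection cools the probe) and reduces to pure conduction
at ``u = 0``; it is pluggable via ``flow_denominator`` for
reconciliation with other formulations.

Because the transport constants are configuration, not measured device
values, inverted velocities should be interpreted as relative flow
trends unless the parameters have been calibrated.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import special
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .config import NTCCalibration, ThermalModelParams
from .errors import InputError, MissingDataError, QuadratureError

__all__ = [
    "ntc_to_temperature",
    "temperature_to_resistance",
    "shape_factor",
    "forward_delta_t",
    "invert_flow",
    "relative_flow_index",
    "FlowEstimate",
]


# ---------------------------------------------------------------------------
# NTC thermistors
# ---------------------------------------------------------------------------

def ntc_to_temperature(resistance, cal: NTCCalibration | None = None):
    """Convert NTC resistance (ohm) to absolute temperature (K).

    ``beta_model``: 1/T = 1/T0 + ln(R/R0)/beta.  ``linear``: affine map
    fitted over the calibration range.  Monotone decreasing in
    resistance in both modes.
    """
    cal = cal or NTCCalibration()
    r = np.asarray(resistance, dtype=float)
    if np.any(r <= 0):
        raise InputError("thermistor resistance must be positive")
    if cal.mode == "beta_model":
        t = 1.0 / (1.0 / cal.t0 + np.log(r / cal.r0) / cal.beta)
    else:
        t = (r - cal.linear_intercept) / cal.linear_slope
    return float(t) if np.isscalar(resistance) else t


def temperature_to_resistance(temperature, cal: NTCCalibration | None = None):
    """Inverse of :func:`ntc_to_temperature` (used by the simulator)."""
    cal = cal or NTCCalibration()
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise InputError("temperature must be positive (K)")
    if cal.mode == "beta_model":
        r = cal.r0 * np.exp(cal.beta * (1.0 / t - 1.0 / cal.t0))
    else:
        r = cal.linear_intercept + cal.linear_slope * t
    return float(r) if np.isscalar(temperature) else r


# ---------------------------------------------------------------------------
# shape factor
# ---------------------------------------------------------------------------

def _wynn_epsilon(partial_sums: np.ndarray) -> float:
    """Accelerate a sequence of partial sums with the Wynn epsilon algorithm.

    Returns the highest-order even-column estimate that stays finite.
    """
    n = len(partial_sums)
    eps_prev = np.zeros(n + 1)            # epsilon_{-1} = 0
    eps_cur = np.array(partial_sums, dtype=float)
    best = eps_cur[-1]
    for k in range(1, n):
        m = n - k
        nxt = np.empty(m)
        for j in range(m):
            diff = eps_cur[j + 1] - eps_cur[j]
            if diff == 0.0 or not math.isfinite(diff):
                nxt[j] = math.nan
            else:
                nxt[j] = eps_prev[j + 1] + 1.0 / diff
        eps_prev, eps_cur = eps_cur, nxt
        if k % 2 == 0 and math.isfinite(eps_cur[-1]):
            best = eps_cur[-1]
    return float(best)


def _asymptotic_tail(g0: float, x: float) -> float:
    """Integral over (g0, inf) of the leading large-argument form of the integrand.

    For g -> inf, J0(g x) J1(g) / g ~ -(sin((x-1) g) + cos((x+1) g)) /
    (pi g^2 sqrt(x)); both pieces integrate in closed form via the sine
    and cosine integrals.
    """
    total = 0.0
    b = x - 1.0
    if b != 0.0:
        ab = abs(b)
        si, ci = special.sici(ab * g0)
        total += math.copysign(1.0, b) * (math.sin(ab * g0) / g0 - ab * ci)
    c = x + 1.0
    si, ci = special.sici(c * g0)
    total += math.cos(c * g0) / g0 - c * (math.pi / 2.0 - si)
    return -total / (math.pi * math.sqrt(x))


def shape_factor(r: float, big_r: float, *, atol: float = 1e-8,
                 max_intervals: int = 2400) -> float:
    """Dimensionless geometric factor F(r, R) of the heated-disk field.

    Evaluates ``integral_0^inf J0(g r) J1(g R) / g dg``.  The axis is
    split into half-periods of the fastest oscillation of the Bessel
    product (so consecutive pieces alternate in sign), the analytic
    integral of the leading asymptotic tail is added to every partial
    sum, and the resulting sequence is accelerated with the Wynn epsilon
    algorithm.  The interval count escalates automatically near the
    slowly beating r ~ R resonance.  Scale invariant:
    F(r, R) == F(c r, c R); nonincreasing in r; F(0, R) == 1.

    Raises :class:`QuadratureError` (with the last estimate and residual
    attached) if the accelerated estimates do not settle below ``atol``.
    """
    if big_r <= 0:
        raise InputError("spreader radius R must be positive")
    if r < 0:
        raise InputError("thermistor distance r must be nonnegative")
    if r == 0.0:
        return 1.0  # integral of J1(x)/x over (0, inf) is exactly 1

    x = r / big_r  # reduce to R = 1 by scale invariance
    h = math.pi / max(x, 1.0)  # half-period of the fast (x+1) oscillation

    def integrand(g: float) -> float:
        return special.j0(g * x) * special.j1(g) / g

    terms: list[float] = []
    prev_wynn = prev_raw = None
    window = 30
    for target in (60, 120, 480, 960, 1920, max_intervals):
        target = min(target, max_intervals)
        while len(terms) < target:
            k = len(terms)
            val, _ = quad(integrand, k * h, (k + 1) * h, limit=60)
            terms.append(val)
        sums = np.cumsum(terms[-window:]) + sum(terms[:-window])
        g_ends = h * np.arange(len(terms) - window + 1, len(terms) + 1)
        corrected = sums + np.array([_asymptotic_tail(g, x) for g in g_ends])
        est_wynn = _wynn_epsilon(corrected)
        est_raw = float(corrected[-1])
        g_max = h * len(terms)
        # The tail formula is exact only to leading asymptotic order; when
        # the (x-1) beat has not completed a few cycles inside the summed
        # range the systematic deficit (~0.1/g_max^2) must itself be small
        # before either estimate can be trusted.
        slow_resolved = abs(x - 1.0) * g_max > 3.0 * math.pi
        systematic = 0.1 / g_max**2
        if prev_wynn is not None:
            if abs(est_wynn - prev_wynn) < atol and (slow_resolved
                                                     or systematic < atol):
                return est_wynn
            if systematic < atol and abs(est_raw - prev_raw) < atol:
                return est_raw
        prev_wynn, prev_raw = est_wynn, est_raw
        if target >= max_intervals:
            break
    raise QuadratureError(
        f"shape factor quadrature did not converge to atol={atol} "
        f"after {len(terms)} intervals (last estimate {prev_wynn})",
        estimate=prev_wynn, residual=abs(terms[-1]), intervals=len(terms))


@lru_cache(maxsize=4096)
def _shape_factor_cached(r: float, big_r: float) -> float:
    return shape_factor(r, big_r)


# ---------------------------------------------------------------------------
# forward model and inversion
# ---------------------------------------------------------------------------

def _default_denominator(u_mm_s, tp: ThermalModelParams):
    """1 + 0.76 s u R / alpha_fluid with u converted from mm/s to m/s."""
    u_m_s = np.asarray(u_mm_s, dtype=float) * 1e-3
    return 1.0 + 0.76 * tp.s_blood * u_m_s * tp.big_r / tp.alpha_fluid


def forward_delta_t(u, tp: ThermalModelParams, r: float,
                    flow_denominator: Callable = _default_denominator,
                    _f_cache: dict | None = None):
    """Steady temperature rise (K) at distance ``r`` (m) for flow ``u`` (mm/s).

    Strictly decreasing in ``u``; equals (q R / lambda) F(r/R) at u = 0.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise InputError("flow velocity must be nonnegative")
    if _f_cache is not None and r in _f_cache:
        f = _f_cache[r]
    else:
        f = _shape_factor_cached(r, tp.big_r)
        if _f_cache is not None:
            _f_cache[r] = f
    dt = (tp.q_heat * tp.big_r / tp.k_tissue) * f / flow_denominator(u, tp)
    return float(dt) if dt.ndim == 0 else dt


class FlowEstimate(NamedTuple):
    """Result of a flow inversion."""

    u_hat: float          # mm/s
    residual: float       # root-mean-square residual, K
    at_boundary: bool     # True when the optimum hit the search boundary
    n_channels: int       # finite channels used


def invert_flow(delta_t_vec: Sequence[float], tp: ThermalModelParams,
                *, u_max: float = 50.0,
                flow_denominator: Callable = _default_denominator) -> FlowEstimate:
    """Estimate flow velocity from per-thermistor temperature rises.

    Least-squares fit of :func:`forward_delta_t` over ``u in [0, u_max]``
    across the finite channels (bounded scalar minimization).  Exact on
    noiseless forward data.  Raises :class:`MissingDataError` if every
    channel is missing.
    """
    dt = np.asarray(delta_t_vec, dtype=float)
    if dt.shape != (len(tp.r_list),):
        raise InputError(
            f"expected {len(tp.r_list)} channels, got shape {dt.shape}")
    finite = np.isfinite(dt)
    if not finite.any():
        raise MissingDataError("all thermistor channels missing")
    dt = dt[finite]
    r_used = np.asarray(tp.r_list, dtype=float)[finite]
    amp = np.array([  # u = 0 rise per channel: (qR/lambda) F(r/R)
        (tp.q_heat * tp.big_r / tp.k_tissue) * _shape_factor_cached(r, tp.big_r)
        for r in r_used])

    def sse(u: float) -> float:
        model = amp / flow_denominator(u, tp)
        return float(np.sum((model - dt) ** 2))

    res = minimize_scalar(sse, bounds=(0.0, u_max), method="bounded",
                          options={"xatol": 1e-10})
    u_hat = float(res.x)
    # Bounded Brent never lands exactly on a bound: snap when the edge is at
    # least as good as the interior optimum.
    for edge in (0.0, u_max):
        if sse(edge) <= res.fun + 1e-30:
            u_hat = edge
    at_boundary = u_hat >= u_max - 1e-8
    rms = math.sqrt(sse(u_hat) / dt.size)
    return FlowEstimate(u_hat=u_hat, residual=rms,
                        at_boundary=at_boundary, n_channels=int(dt.size))


def invert_flow_series(delta_t: np.ndarray, tp: ThermalModelParams,
                       *, u_max: float = 50.0) -> np.ndarray:
    """Vectorized inversion: rows are samples, columns thermistor channels."""
    delta_t = np.atleast_2d(np.asarray(delta_t, dtype=float))
    out = np.full(delta_t.shape[0], np.nan)
    for i, row in enumerate(delta_t):
        if np.isfinite(row).any():
            out[i] = invert_flow(row, tp, u_max=u_max).u_hat
    return out


def relative_flow_index(t1, t4):
    """Temperature difference T1 - T4 between the extreme thermistors (K).

    Invariant to any common additive baseline, so the absolute tissue
    temperature cancels; decreases as flow increases.
    """
    return np.asarray(t1, dtype=float) - np.asarray(t4, dtype=float)
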