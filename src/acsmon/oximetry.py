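"""Dual-wavelength reflection oximetry.

Chain: optical density from raw intensities, AC/DC separation with a
zero-phase 0.1 Hz low pass, 2x2 log-attenuation inversion for the
hemoglobin concentration changes, tissue oxygen saturation relative to a
baseline hemoglobin state, and pulse rate/variability from the AC band.

The concentration inversion solves, per sample,

    [d_hbo2, d_hb]^T = (1/q) M^{-1} [OD(l1), OD(l2)]^T

with M rows [eps_hbo2(l) * DPF(l), eps_hb(l) * DPF(l)] and q the LED-to-
photodetector distance in cm, so concentrations come out in mol/L.
Saturation is

    sto2 = (hbo2_0 + d_hbo2) / (hbo2_0 + d_hbo2 + hb_0 + d_hb)

clamped to [0, 1]; with nominal baselines it is a relative, not
absolute, saturation.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .config import HemoState, OpticalConstants
from .errors import InputError, UndefinedRateError
from .trace import MultiChannelTrace

__all__ = [
    "optical_density",
    "separate_dc",
    "invert_beer_lambert",
    "compute_sto2",
    "pulse_metrics",
    "oximetry_pipeline",
]

DEFAULT_CUTOFF_HZ = 0.1
DEFAULT_BASELINE_WINDOW_S = 30.0


def optical_density(i_t, i_0):
    """OD = -ln(i_t / i_0).  Nonpositive intensities become NaN (masked)."""
    i_t = np.asarray(i_t, dtype=float)
    i_0 = np.asarray(i_0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        od = -np.log(np.where((i_t > 0) & (i_0 > 0), i_t / i_0, np.nan))
    return float(od) if od.ndim == 0 else od


def separate_dc(values, sample_rate: float, cutoff: float = DEFAULT_CUTOFF_HZ,
                order: int = 4):
    """Split a signal into (dc, ac) with a zero-phase Butterworth low pass.

    ``dc`` is the forward-backward filtered signal, ``ac`` the residual;
    a constant input passes through unchanged (unit DC gain).
    """
    values = np.asarray(values, dtype=float)
    if sample_rate <= 2.0 * cutoff:
        raise InputError(
            f"sample rate {sample_rate} Hz too low for a {cutoff} Hz cutoff")
    sos = sps.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    # filtfilt warm-up: default odd-padding needs a minimum record length
    padlen = 3 * (2 * order + 1)
    if values.size <= padlen:
        raise InputError(
            f"trace of {values.size} samples shorter than filter warm-up ({padlen + 1})")
    dc = sps.sosfiltfilt(sos, values)
    return dc, values - dc


def invert_beer_lambert(od_pair, oc: OpticalConstants):
    """Solve the 2x2 attenuation system for (d_hbo2, d_hb) in mol/L.

    ``od_pair`` is (od_l1, od_l2): scalars or equal-length arrays.
    Linear in OD; raises ConfigurationError for near-singular optics.
    """
    m = oc.require_invertible()
    od = np.vstack([np.atleast_1d(np.asarray(od_pair[0], dtype=float)),
                    np.atleast_1d(np.asarray(od_pair[1], dtype=float))])
    sol = np.linalg.solve(m, od) / oc.d_led_pd
    d_hbo2, d_hb = sol[0], sol[1]
    if np.isscalar(od_pair[0]) or np.asarray(od_pair[0]).ndim == 0:
        return float(d_hbo2[0]), float(d_hb[0])
    return d_hbo2, d_hb


def compute_sto2(d_hbo2, d_hb, hs: HemoState):
    """Saturation from concentration changes relative to the baseline state.

    Clamped to [0, 1]; samples with a nonpositive denominator are NaN.
    At zero change returns ``hs.sto2_baseline``.
    """
    d_hbo2 = np.asarray(d_hbo2, dtype=float)
    d_hb = np.asarray(d_hb, dtype=float)
    num = hs.hbo2_0 + d_hbo2
    den = hs.hbo2_0 + d_hbo2 + hs.hb_0 + d_hb
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2 = np.where(den > 0, num / den, np.nan)
    sto2 = np.clip(sto2, 0.0, 1.0)
    return float(sto2) if sto2.ndim == 0 else sto2


class PulseMetrics(NamedTuple):
    rate_bpm: float
    variability_ms: float
    peak_frequency_hz: float


def pulse_metrics(ac, sample_rate: float, *, band=(0.5, 4.0),
                  min_snr: float = 10.0) -> PulseMetrics:
    """Pulse rate and beat-to-beat variability from the AC band.

    Rate comes from the dominant periodogram peak inside ``band``;
    variability is the SD of successive peak-to-peak intervals, with
    parabolic sub-sample refinement of the peak times.  Raises
    :class:`UndefinedRateError` when no peak rises ``min_snr`` times
    above the median in-band power.
    """
    ac = np.asarray(ac, dtype=float)
    if ac.size < 10 * sample_rate:
        raise InputError("need at least 10 s of data for pulse metrics")
    freqs, power = sps.periodogram(ac, fs=sample_rate)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise InputError("sample rate too low for the pulse band")
    pb, fb = power[in_band], freqs[in_band]
    floor = float(np.median(pb))
    peak_idx = int(np.argmax(pb))
    if floor <= 0 or pb[peak_idx] < min_snr * floor:
        raise UndefinedRateError("no spectral peak above the noise floor")
    f_peak = float(fb[peak_idx])

    min_dist = max(1, int(round(0.5 * sample_rate / f_peak)))
    peaks, _ = sps.find_peaks(ac, distance=min_dist,
                              prominence=0.5 * float(np.std(ac)))
    if peaks.size < 3:
        raise UndefinedRateError("too few beats detected for variability")
    # parabolic interpolation of each peak against its neighbours
    t_peaks = []
    for p in peaks:
        if 0 < p < ac.size - 1:
            denom = ac[p - 1] - 2 * ac[p] + ac[p + 1]
            shift = 0.5 * (ac[p - 1] - ac[p + 1]) / denom if denom != 0 else 0.0
            t_peaks.append((p + shift) / sample_rate)
    intervals = np.diff(t_peaks)
    variability_ms = float(np.std(intervals, ddof=1) * 1e3)
    return PulseMetrics(rate_bpm=60.0 * f_peak, variability_ms=variability_ms,
                        peak_frequency_hz=f_peak)


def oximetry_pipeline(trace: MultiChannelTrace, oc: OpticalConstants,
                      hs: HemoState, *, cutoff: float = DEFAULT_CUTOFF_HZ,
                      baseline_window: float = DEFAULT_BASELINE_WINDOW_S,
                      red_channel: str = "ppg_red",
                      ir_channel: str = "ppg_ir") -> MultiChannelTrace:
    """Run the full oximetry chain on a PPG trace.

    The intensities are low-passed first (the DC component carries the
    saturation information), the per-wavelength reference intensity I0
    is the mean of the first ``baseline_window`` seconds of the DC
    signal, and the OD pair is inverted sample by sample.  Returns a new
    trace with od_red, od_ir, d_hbo2, d_hb and sto2 channels.
    """
    fs = trace.sample_rate
    red = trace.channels[red_channel]
    ir = trace.channels[ir_channel]
    dc_red, _ = separate_dc(red, fs, cutoff)
    dc_ir, _ = separate_dc(ir, fs, cutoff)

    in_window = trace.time <= trace.time[0] + baseline_window
    if not in_window.any():
        raise InputError("baseline window contains no samples")
    i0_red = float(np.nanmean(dc_red[in_window]))
    i0_ir = float(np.nanmean(dc_ir[in_window]))

    od_red = optical_density(dc_red, i0_red)
    od_ir = optical_density(dc_ir, i0_ir)
    d_hbo2, d_hb = invert_beer_lambert((od_red, od_ir), oc)
    sto2 = compute_sto2(d_hbo2, d_hb, hs)

    out = trace
    for name, vals, unit in [("od_red", od_red, "1"), ("od_ir", od_ir, "1"),
                             ("d_hbo2", d_hbo2, "mol/L"), ("d_hb", d_hb, "mol/L"),
                             ("sto2", sto2, "1")]:
        out = out.with_channel(name, vals, unit)
    out.metadata["stage"] = "oximetry"
    return out
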