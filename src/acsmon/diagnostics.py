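"""Clinical fusion of the calibrated channels.

Computes the perfusion differential deltaP = DBP - ICP, flags sustained
sub-threshold runs per the fasciotomy decision rule (below 30 mmHg for
at least 2 h by default), summarizes cross-modality linearity on
pressure plateaus, estimates the flow-response lag, and provides the
battery endurance utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

from .config import DiagnosticRule
from .errors import AlignmentError, InputError, InsufficientDataError
from .trace import TimeSeries

__all__ = [
    "delta_p",
    "fasciotomy_flag",
    "correlate_modalities",
    "estimate_flow_lag",
    "endurance_hours",
    "AlertReport",
    "ModalitySummary",
]


class ModalitySummary(NamedTuple):
    """OLS summary of a measured modality against reference pressure."""

    slope: float
    intercept: float
    pearson_r: float
    n_points: int


@dataclass
class AlertReport:
    """Outcome of the decision rule plus cross-modality summaries."""

    alert_intervals: list[tuple[float, float]]
    earliest_flag_time: float | None
    delta_p: TimeSeries
    modality_summaries: dict[str, ModalitySummary] = field(default_factory=dict)

    @property
    def flagged(self) -> bool:
        return self.earliest_flag_time is not None

    def to_dict(self) -> dict:
        return {
            "flagged": self.flagged,
            "earliest_flag_time_s": self.earliest_flag_time,
            "alert_intervals_s": [list(iv) for iv in self.alert_intervals],
            "modality_summaries": {
                k: dict(v._asdict()) for k, v in self.modality_summaries.items()},
        }


def delta_p(dbp, icp: TimeSeries) -> TimeSeries:
    """deltaP(t) = DBP(t) - ICP(t) on the ICP time base, mmHg.

    ``dbp`` may be a scalar (single clinical measurement) or a
    TimeSeries, which is linearly interpolated onto the ICP time base;
    disjoint time ranges raise :class:`AlignmentError`.
    """
    if isinstance(dbp, TimeSeries):
        if dbp.time[-1] < icp.time[0] or dbp.time[0] > icp.time[-1]:
            raise AlignmentError("DBP and ICP series do not overlap in time")
        dbp_vals = np.interp(icp.time, dbp.time, dbp.values)
    else:
        dbp_vals = float(dbp)
    return TimeSeries(icp.time, dbp_vals - icp.values, unit="mmHg", name="delta_p")


def fasciotomy_flag(dp: TimeSeries, rule: DiagnosticRule | None = None) -> AlertReport:
    """Flag maximal sub-threshold runs lasting at least the rule duration.

    Strict-run semantics: any sample at or above threshold ends the run,
    as does a sampling gap longer than twice the nominal interval.  The
    earliest flag time is the start of the first qualifying run plus the
    rule duration (the moment the criterion is first met).
    """
    rule = rule or DiagnosticRule()
    t = dp.time
    v = dp.values
    if t.size == 0:
        raise InputError("empty deltaP series")
    below = v < rule.delta_p_threshold
    max_gap = 2.0 * float(np.median(np.diff(t))) if t.size > 1 else math.inf

    intervals: list[tuple[float, float]] = []
    start = None
    prev_t = None
    for ti, bi in zip(t, below):
        broke = prev_t is not None and (ti - prev_t) > max_gap
        if start is not None and (broke or not bi):
            intervals.append((start, prev_t))
            start = None
        if bi and start is None:
            start = ti
        prev_t = ti
    if start is not None:
        intervals.append((start, prev_t))

    qualifying = [(a, b) for a, b in intervals if (b - a) >= rule.min_duration]
    earliest = qualifying[0][0] + rule.min_duration if qualifying else None
    return AlertReport(alert_intervals=qualifying, earliest_flag_time=earliest,
                       delta_p=dp)


def _moving_average(v: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return v
    kernel = np.ones(width) / width
    return np.convolve(v, kernel, mode="same")


def detect_plateaus(reference: TimeSeries, *, deriv_tol: float = 0.05,
                    min_length: float = 30.0, smooth_s: float = 5.0,
                    settle_time: float = 0.0) -> list[tuple[float, float]]:
    """Windows where the reference pressure is steady.

    A plateau is a contiguous region with |d ref/dt| <= ``deriv_tol``
    (mmHg/s, after ``smooth_s`` moving-average smoothing) lasting at
    least ``min_length`` seconds; the first ``settle_time`` seconds of
    each window are trimmed so lagged modalities have settled.
    """
    t, v = reference.time, reference.values
    if t.size < 3:
        raise InsufficientDataError("reference too short for plateau detection")
    fs = reference.sample_rate
    smooth = _moving_average(v, max(1, int(round(smooth_s * fs))))
    rate = np.gradient(smooth, t)
    steady = np.abs(rate) <= deriv_tol
    windows = []
    start = None
    for i, s in enumerate(steady):
        if s and start is None:
            start = t[i]
        elif not s and start is not None:
            windows.append((start, t[i - 1]))
            start = None
    if start is not None:
        windows.append((start, t[-1]))
    out = []
    for a, b in windows:
        a2 = a + settle_time
        if b - a2 >= min_length:
            out.append((a2, b))
    return out


def correlate_modalities(reference: TimeSeries, measured: dict[str, TimeSeries],
                         plateau_windows: list[tuple[float, float]] | None = None,
                         *, min_plateaus: int = 3,
                         **plateau_kwargs) -> dict[str, ModalitySummary]:
    """Per-modality OLS of plateau means against reference-pressure plateau means.

    Plateau-mean regression suppresses transient/lag artifacts: for each
    steady window the reference and each measured channel are averaged
    over their own samples inside the window, then slope, intercept and
    Pearson r are computed across windows.
    """
    windows = plateau_windows or detect_plateaus(reference, **plateau_kwargs)
    if len(windows) < min_plateaus:
        raise InsufficientDataError(
            f"found {len(windows)} plateaus, need >= {min_plateaus}")

    def window_means(ts: TimeSeries) -> np.ndarray:
        means = []
        for a, b in windows:
            mask = (ts.time >= a) & (ts.time <= b)
            if not mask.any():
                raise AlignmentError(f"no samples of '{ts.name}' in window ({a}, {b})")
            means.append(float(np.nanmean(ts.values[mask])))
        return np.asarray(means)

    ref_means = window_means(reference)
    summaries = {}
    for name, ts in measured.items():
        y = window_means(ts)
        res = stats.linregress(ref_means, y)
        summaries[name] = ModalitySummary(slope=float(res.slope),
                                          intercept=float(res.intercept),
                                          pearson_r=float(res.rvalue),
                                          n_points=len(windows))
    return summaries


class LagEstimate(NamedTuple):
    tau_s: float
    correlation: float


def estimate_flow_lag(reference: TimeSeries, flow: TimeSeries,
                      max_lag_s: float = 60.0) -> LagEstimate:
    """First-order lag constant of the flow response behind the reference.

    The argmax of a plain cross-correlogram does not recover a
    first-order time constant (the peak sits near zero for
    plateau-dominated loading), so instead the reference is passed
    through candidate first-order lags on a one-sample grid and the
    candidate maximizing the Pearson correlation with the (inverted)
    flow is returned.
    """
    if flow.time[-1] < reference.time[0] or flow.time[0] > reference.time[-1]:
        raise AlignmentError("flow and reference series do not overlap in time")
    ref = np.interp(flow.time, reference.time, reference.values)
    y = -flow.values  # flow anticorrelates with pressure
    if np.std(ref) == 0.0 or np.std(y) == 0.0:
        return LagEstimate(0.0, 0.0)  # constant input: lag undefined
    dt = 1.0 / flow.sample_rate
    best = LagEstimate(0.0, -np.inf)
    taus = np.arange(0.0, max_lag_s + dt / 2, dt)
    for tau in taus:
        if tau == 0.0:
            lagged = ref
        else:
            decay = math.exp(-dt / tau)
            lagged = np.empty_like(ref)
            lagged[0] = ref[0]
            for i in range(1, ref.size):
                lagged[i] = ref[i] + (lagged[i - 1] - ref[i]) * decay
        r = float(np.corrcoef(lagged, y)[0, 1])
        if r > best.correlation:
            best = LagEstimate(float(tau), r)
    return best


def endurance_hours(capacity_mah: float, current_ma: float,
                    floor_to_int: bool = False) -> float:
    """Battery endurance = capacity / current, in hours."""
    if capacity_mah <= 0 or current_ma <= 0:
        raise InputError("capacity and current must be positive")
    hours = capacity_mah / current_ma
    return float(math.floor(hours)) if floor_to_int else hours
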