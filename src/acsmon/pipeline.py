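"""End-to-end composition: simulate -> calibrate -> invert -> fuse.

Also provides the directory-based stage runners used by the CLI, so the
four commands compose through plain CSV files.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import (DiagnosticRule, EpisodeConfig, HemoState, OpticalConstants,
                     PressureCalibration, ThermalModelParams)
from .diagnostics import (AlertReport, LagEstimate, correlate_modalities,
                          delta_p, estimate_flow_lag, fasciotomy_flag)
from .errors import StageError
from .oximetry import oximetry_pipeline
from .pressure import calibrate_pressure
from .simulate import SimulatedEpisode, ground_truth_trace, simulate_episode
from .thermal import invert_flow_series
from .trace import MultiChannelTrace, TimeSeries, read_trace, write_trace

from pydantic import BaseModel, ConfigDict, Field

log = logging.getLogger("acsmon")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "simulate_to_dir", "process_dir", "diagnose_dir"]

HEATER_WARMUP_S = 60.0  # thermal equilibration window excluded from inversion


class PipelineConfig(BaseModel):
    """Full pipeline configuration (validates on construction)."""

    model_config = ConfigDict(extra="forbid")

    episode: EpisodeConfig = Field(default_factory=EpisodeConfig)
    optical: OpticalConstants = Field(default_factory=OpticalConstants)
    hemo: HemoState = Field(default_factory=HemoState)
    thermal: ThermalModelParams = Field(default_factory=ThermalModelParams)
    pressure_cal: PressureCalibration = Field(default_factory=PressureCalibration)
    rule: DiagnosticRule = Field(default_factory=DiagnosticRule)
    flow_rate_hz: float = Field(default=1.0, gt=0,
                                description="flow-inversion output rate")
    warmup_s: float = Field(default=HEATER_WARMUP_S, ge=0)
    max_lag_s: float = Field(default=60.0, gt=0)

    def model_post_init(self, __context) -> None:
        if self.hemo.sto2_baseline != self.episode.sto2_baseline:
            self.hemo = self.hemo.model_copy(
                update={"sto2_baseline": self.episode.sto2_baseline})


@dataclass
class PipelineResult:
    episode: SimulatedEpisode
    icp: TimeSeries
    sto2: TimeSeries
    flow: TimeSeries
    report: AlertReport
    flow_lag: LagEstimate


def _stage(name):
    def wrap(fn, *args, **kwargs):
        t0 = _time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        log.info("stage %-12s done in %.2f s", name, _time.perf_counter() - t0)
        return out
    return wrap


def recover_icp(pressure: MultiChannelTrace, cal: PressureCalibration) -> TimeSeries:
    icp = calibrate_pressure(pressure.channels["pressure_raw"],
                             pressure.channels["temp_device"], cal)
    return TimeSeries(pressure.time, icp, unit="mmHg", name="icp")


def recover_flow(thermal: MultiChannelTrace, tp: ThermalModelParams,
                 *, tissue_temp: float, flow_rate_hz: float = 1.0,
                 warmup_s: float = HEATER_WARMUP_S) -> TimeSeries:
    """Invert the thermistor channels into a decimated flow-velocity series.

    Temperature rises are referenced to ``tissue_temp`` (ideally
    estimated from heater-off samples; the common baseline cancels
    between channels only in the relative index, not in the absolute
    inversion), averaged into bins of 1/flow_rate_hz, and inverted bin
    by bin.  Samples with the heater off, or within ``warmup_s`` of a
    heater-on transition, are excluded as equilibration.
    """
    t = thermal.time
    heater = thermal.channels.get("heater")
    on = np.ones(t.size, dtype=bool) if heater is None else heater > 0.5
    # heater-off samples refine the baseline estimate when available
    if (~on).any():
        offsets = [np.nanmean(thermal.channels[c][~on])
                   for c in thermal.channels if c.startswith("t")]
        tissue_temp = float(np.nanmean(offsets))
    # exclude warm-up after every off->on transition
    usable = on.copy()
    rising = np.flatnonzero(np.diff(on.astype(int)) > 0) + 1
    starts = list(t[rising])
    if on[0]:
        starts.append(t[0])
    for s in starts:
        usable &= ~((t >= s) & (t < s + warmup_s))

    names = sorted(c for c in thermal.channels if c.startswith("t"))
    dt_mat = np.column_stack([thermal.channels[c] - tissue_temp for c in names])
    dt_mat[~usable] = np.nan

    bin_w = 1.0 / flow_rate_hz
    edges = np.arange(t[0], t[-1] + bin_w, bin_w)
    centers, rows = [], []
    for a, b in zip(edges, edges[1:]):
        mask = (t >= a) & (t < b) & usable
        if mask.any():
            centers.append(0.5 * (a + b))
            rows.append(np.nanmean(dt_mat[mask], axis=0))
    if not rows:
        return TimeSeries(np.array([]), np.array([]), unit="mm/s", name="u")
    u = invert_flow_series(np.vstack(rows), tp)
    return TimeSeries(np.asarray(centers), u, unit="mm/s", name="u")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Simulate an episode and run every processing stage in memory."""
    sim = _stage("simulate")(simulate_episode, config.episode, config.optical,
                             config.thermal, config.hemo)
    icp = _stage("pressure")(recover_icp, sim.pressure, config.pressure_cal)
    oxi = _stage("oximetry")(oximetry_pipeline, sim.ppg, config.optical, config.hemo)
    sto2 = oxi.series("sto2")
    flow = _stage("flow")(recover_flow, sim.thermal, config.thermal,
                          tissue_temp=config.episode.tissue_temp,
                          flow_rate_hz=config.flow_rate_hz,
                          warmup_s=config.warmup_s)

    reference = TimeSeries(sim.ground_truth.time, sim.ground_truth.icp,
                           unit="mmHg", name="reference_p")
    dp = _stage("delta_p")(delta_p, config.episode.dbp, icp)
    report = _stage("rule")(fasciotomy_flag, dp, config.rule)
    try:
        report.modality_summaries = correlate_modalities(
            reference, {"pressure": icp, "sto2": sto2, "flow": flow},
            settle_time=4.0 * config.episode.flow_lag_tau)
    except Exception as exc:  # noqa: BLE001 - summaries are best-effort
        log.warning("modality summaries unavailable: %s", exc)
    lag = _stage("flow_lag")(estimate_flow_lag, reference, flow, config.max_lag_s)
    return PipelineResult(episode=sim, icp=icp, sto2=sto2, flow=flow,
                          report=report, flow_lag=lag)


# ---------------------------------------------------------------------------
# directory-based stage runners (CLI)
# ---------------------------------------------------------------------------

def simulate_to_dir(config: PipelineConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_episode(config.episode, config.optical, config.thermal,
                           config.hemo)
    for name, trace in (("ppg", sim.ppg), ("thermal", sim.thermal),
                        ("pressure", sim.pressure)):
        trace.metadata["config_seed"] = config.episode.seed
        write_trace(trace, out / f"{name}.csv")
    write_trace(ground_truth_trace(sim.ground_truth, config.episode.seed),
                out / "ground_truth.csv")
    (out / "pipeline_config.json").write_text(config.model_dump_json(indent=2))


def _load_config(in_dir: Path, override: PipelineConfig | None) -> PipelineConfig:
    if override is not None:
        return override
    cfg_path = in_dir / "pipeline_config.json"
    if cfg_path.exists():
        return PipelineConfig.model_validate_json(cfg_path.read_text())
    return PipelineConfig()


def process_dir(in_dir: str | Path, out_dir: str | Path,
                config: PipelineConfig | None = None) -> None:
    in_dir, out = Path(in_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _load_config(in_dir, config)

    pressure = read_trace(in_dir / "pressure.csv")
    icp = _stage("pressure")(recover_icp, pressure, cfg.pressure_cal)
    ppg = read_trace(in_dir / "ppg.csv")
    oxi = _stage("oximetry")(oximetry_pipeline, ppg, cfg.optical, cfg.hemo)
    thermal = read_trace(in_dir / "thermal.csv")
    flow = _stage("flow")(recover_flow, thermal, cfg.thermal,
                          tissue_temp=cfg.episode.tissue_temp,
                          flow_rate_hz=cfg.flow_rate_hz, warmup_s=cfg.warmup_s)

    meta = {"stage": "processed", "seed": cfg.episode.seed}
    write_trace(MultiChannelTrace(icp.time, {"icp": icp.values},
                                  {"icp": "mmHg"}, meta), out / "icp.csv")
    write_trace(oxi, out / "oximetry.csv")
    write_trace(MultiChannelTrace(flow.time, {"u": flow.values},
                                  {"u": "mm/s"}, meta), out / "flow.csv")
    if (in_dir / "pipeline_config.json").exists() and in_dir != out:
        (out / "pipeline_config.json").write_text(
            (in_dir / "pipeline_config.json").read_text())


def diagnose_dir(in_dir: str | Path, rule: DiagnosticRule | None = None,
                 out_dir: str | Path | None = None) -> AlertReport:
    in_dir = Path(in_dir)
    out = Path(out_dir) if out_dir is not None else in_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg = _load_config(in_dir, None)
    rule = rule or cfg.rule

    icp_trace = read_trace(in_dir / "icp.csv")
    icp = icp_trace.series("icp")
    dp = delta_p(cfg.episode.dbp, icp)
    report = fasciotomy_flag(dp, rule)

    measured = {"pressure": icp}
    oxi_path = in_dir / "oximetry.csv"
    if oxi_path.exists():
        measured["sto2"] = read_trace(oxi_path).series("sto2")
    flow_path = in_dir / "flow.csv"
    if flow_path.exists():
        measured["flow"] = read_trace(flow_path).series("u")
    gt_path = in_dir / "ground_truth.csv"
    reference = (read_trace(gt_path).series("icp") if gt_path.exists() else icp)
    try:
        report.modality_summaries = correlate_modalities(
            reference, measured,
            settle_time=4.0 * cfg.episode.flow_lag_tau)
    except Exception as exc:  # noqa: BLE001
        log.warning("modality summaries unavailable: %s", exc)

    write_trace(MultiChannelTrace(dp.time, {"delta_p": dp.values},
                                  {"delta_p": "mmHg"},
                                  {"stage": "diagnose"}), out / "delta_p.csv")
    (out / "alert_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return report


def format_report(report_dict: dict) -> str:
    lines = ["=== compartment monitoring report ==="]
    if report_dict.get("flagged"):
        lines.append(f"FASCIOTOMY ADVISED: deltaP criterion met at "
                     f"t = {report_dict['earliest_flag_time_s']:.0f} s")
    else:
        lines.append("no alert: deltaP criterion not met")
    for a, b in report_dict.get("alert_intervals_s", []):
        lines.append(f"  sub-threshold run: {a:.0f} s -> {b:.0f} s "
                     f"({(b - a) / 3600:.2f} h)")
    summaries = report_dict.get("modality_summaries", {})
    if summaries:
        lines.append("modality vs reference pressure (plateau means):")
        for name, s in summaries.items():
            lines.append(f"  {name:>9}: slope {s['slope']:+.4g}, "
                         f"r {s['pearson_r']:+.3f} (n={s['n_points']})")
    return "\n".join(lines)
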