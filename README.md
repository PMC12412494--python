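# acsmon

Sensor-to-physiology pipeline for a multimodal intracompartmental
monitoring probe, plus a synthetic episode generator so every stage is
testable without hardware or downloads.

The package computes, from raw multichannel time series:

- **Flow velocity** by inverting a thermal-anemometry transport model
  `dT = (qR/λ) · F(r/R) / (1 + 0.76·s·u·R/α_fluid)`, where the
  dimensionless shape factor `F(r, R) = ∫₀^∞ J₀(γr)J₁(γR) dγ/γ` is
  evaluated by oscillation-aware quadrature (half-period splitting,
  analytic asymptotic tail, Wynn-epsilon acceleration).  NTC thermistor
  resistances convert to temperature via the beta equation
  (B = 3380 K, 10 kΩ) or a linear calibration.
- **Tissue oxygen saturation (StO₂)** from dual-wavelength (660/880 nm)
  PPG intensities: optical density `OD = −ln(I_t/I₀)`, zero-phase
  0.1 Hz AC/DC separation, 2×2 log-attenuation inversion for
  Δ[HbO₂]/Δ[Hb], and saturation relative to a baseline hemoglobin
  state.  Pulse rate and variability come from the AC band.
- **Intracompartmental pressure (ICP)** via affine calibration with a
  residual linear temperature-compensation term, plus hydrostatic
  water-column calibration fitting.
- **The ΔP decision rule**: ΔP = DBP − ICP; a sustained run of
  ΔP < 30 mmHg lasting ≥ 2 h raises the fasciotomy flag.  Cross-modality
  plateau-mean regressions and a first-order flow-lag estimate summarize
  episode structure.  A battery endurance utility covers the power
  budget (370 mAh: ≈88 h at 4.2 mA, ≈26 h at 14 mA).

Because the probe's transport constants (heater flux, spreader radius,
tissue conductivity, blood content) are configuration rather than
published device values, inverted flow should be read as a relative
trend unless those parameters are calibrated.

## CLI

Four composable commands operate on directories of CSV traces
(first column `time [s]`, remaining columns `name [unit]`, JSON
metadata sidecars):

```bash
acsmon simulate --config cfg.json --out raw/      # synthetic episode
acsmon process  --in raw/ --out proc/             # calibrate + invert
acsmon diagnose --in proc/ --rule rule.json       # deltaP rule -> alert_report.json
acsmon report   --in proc/                        # human-readable summary
```

`cfg.json` is a serialized `PipelineConfig` (see
`acsmon.pipeline.PipelineConfig`); omitting `--config` uses defaults.
Everything is deterministic under the episode seed.

In Python:

```python
from acsmon import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig())
print(result.report.flagged, result.flow_lag, result.report.modality_summaries)
```

## Layout

- `src/acsmon/simulate.py` — episode generator with ground truth
- `src/acsmon/thermal.py` — shape factor, forward ΔT model, flow inversion
- `src/acsmon/oximetry.py` — OD, AC/DC split, concentration inversion, StO₂
- `src/acsmon/pressure.py` — calibration + hydrostatic fitting
- `src/acsmon/diagnostics.py` — ΔP rule, plateau regressions, lag, endurance
- `src/acsmon/trace.py`, `config.py`, `pipeline.py`, `cli.py` — I/O,
  validated configuration, stage composition, CLI
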