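"""Versioned default physical constants.

All values here are bundled defaults, overridable through the config
objects that consume them.  Extinction coefficients come from standard
tabulated hemoglobin compilations; thermal parameters are representative
soft-tissue / whole-blood literature values.  Flow output obtained with
the thermal defaults should be read as a relative trend, not an absolute
velocity, until the parameters are calibrated for a specific probe.
"""

CONSTANTS_VERSION = "2025.1"

# --- unit conversions -------------------------------------------------------
MMHG_PA = 133.322          # Pa per mmHg
STANDARD_GRAVITY = 9.80665  # m/s^2
WATER_DENSITY = 1000.0      # kg/m^3

# --- optics -----------------------------------------------------------------
# Molar extinction coefficients, L mol^-1 cm^-1, tabulated compilation.
WAVELENGTH_RED_NM = 660.0
WAVELENGTH_IR_NM = 880.0
EPS_HBO2 = {660.0: 319.6, 880.0: 1214.0}
EPS_HB = {660.0: 3226.56, 880.0: 736.4}
DEFAULT_DPF = 1.0           # per wavelength; scales concentration magnitudes only
DEFAULT_LED_PD_CM = 0.25    # reflection-mode module geometry

# --- hemoglobin -------------------------------------------------------------
TOTAL_HB_G_PER_L = 150.0
HB_MOLAR_MASS_G_PER_MOL = 64_500.0
DEFAULT_STO2_BASELINE = 0.70

# --- NTC thermistors --------------------------------------------------------
NTC_BETA_K = 3380.0
NTC_R0_OHM = 10_000.0
NTC_T0_K = 298.15

# --- thermal transport ------------------------------------------------------
DEFAULT_Q_HEAT = 500.0          # W/m^2 heater flux
DEFAULT_SPREADER_RADIUS = 2e-3  # m
DEFAULT_K_TISSUE = 0.5          # W/(m K), effective soft tissue
DEFAULT_ALPHA_BLOOD = 1.35e-7   # m^2/s, whole blood thermal diffusivity
DEFAULT_BLOOD_CONTENT = 0.15    # dimensionless perfusion content

# Thermistor-to-heater distances (m).  The probe geometry places the heater
# just behind the first thermistor; the remaining spacings follow the probe
# layout, with the nearest distance floored at 0.5 mm to stay out of the
# near field of the spreader.
DEFAULT_THERMISTOR_R = (0.5e-3, 6.5e-3, 7.25e-3, 8.0e-3)

# --- power budget -----------------------------------------------------------
BATTERY_CAPACITY_MAH = 370.0
CURRENT_FULL_RATE_MA = 14.0   # 20 Hz, all modalities
CURRENT_LOW_RATE_MA = 4.2     # 1 Hz low-power mode
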