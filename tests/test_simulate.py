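import numpy as np
import pytest

from acsmon.config import EpisodeConfig, HemoState, RampStep
from acsmon.errors import ConfigurationError
from acsmon.oximetry import compute_sto2, invert_beer_lambert, optical_density
from acsmon.simulate import (derive_physiology, forward_ppg, forward_pressure,
                             forward_thermistors, generate_icp_trace,
                             simulate_episode)


def noiseless(**kw):
    base = dict(duration=300.0, sample_rate=10.0, ac_fraction=0.0,
                noise_sd={"pressure": 0.0, "ppg": 0.0, "thermistor": 0.0})
    base.update(kw)
    return EpisodeConfig(**base)


class TestIcpTrace:
    def test_stepped_profile_plateaus(self):
        cfg = noiseless(duration=300.0, icp_profile=[
            RampStep(start=0, target=0, ramp=0),
            RampStep(start=60, target=50, ramp=60),
            RampStep(start=120, target=100, ramp=60),
            RampStep(start=180, target=150, ramp=60),
        ])
        ts = generate_icp_trace(cfg)
        at = lambda t: ts.values[np.searchsorted(ts.time, t)]
        assert at(59.9) == 0.0
        assert at(120.0) == pytest.approx(50.0)
        assert at(180.0) == pytest.approx(100.0)
        assert at(240.0) == pytest.approx(150.0)
        assert ts.values[-1] == pytest.approx(150.0)

    def test_empty_profile_constant_zero(self):
        ts = generate_icp_trace(noiseless(icp_profile=[]))
        assert np.all(ts.values == 0.0)

    def test_single_step_max_is_plateau(self):
        cfg = noiseless(icp_profile=[RampStep(start=30, target=70, ramp=10)])
        assert generate_icp_trace(cfg).values.max() == pytest.approx(70.0)

    def test_overlapping_ramps_rejected(self):
        with pytest.raises(ValueError):
            EpisodeConfig(icp_profile=[RampStep(start=0, target=10, ramp=100),
                                       RampStep(start=50, target=20, ramp=10)])

    def test_nonincreasing_starts_rejected(self):
        with pytest.raises(ValueError):
            EpisodeConfig(icp_profile=[RampStep(start=50, target=10, ramp=0),
                                       RampStep(start=50, target=20, ramp=0)])


class TestDerivePhysiology:
    def test_zero_drive(self):
        cfg = noiseless(icp_profile=[])
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        np.testing.assert_allclose(gt.sto2, cfg.sto2_baseline)
        np.testing.assert_allclose(gt.u, cfg.flow_baseline)
        np.testing.assert_allclose(gt.d_hbo2, 0.0)

    def test_first_order_lag_63_percent(self):
        tau = 10.0
        cfg = noiseless(duration=300.0, sample_rate=20.0, flow_lag_tau=tau,
                        icp_profile=[RampStep(start=100, target=100, ramp=0)])
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        u0 = cfg.flow_baseline
        u_inf = cfg.flow_baseline + cfg.coupling_slope_flow * 100.0
        # step becomes effective one sample after the last pre-step time
        t_step = gt.time[np.flatnonzero(gt.icp > 0)[0] - 1]
        u_at = np.interp(t_step + tau, gt.time, gt.u)
        frac = (u_at - u0) / (u_inf - u0)
        assert frac == pytest.approx(1.0 - np.exp(-1.0), abs=5e-3)

    def test_inverse_signs_on_step(self):
        cfg = noiseless(icp_profile=[RampStep(start=50, target=100, ramp=10)])
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        assert gt.sto2[-1] - gt.sto2[0] < 0
        assert gt.u[-1] - gt.u[0] < 0

    def test_sto2_clamped_to_unit_interval(self):
        cfg = noiseless(icp_profile=[RampStep(start=10, target=1000, ramp=0)])
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        assert gt.sto2.min() >= 0.0 and gt.sto2.max() <= 1.0
        assert gt.u.min() >= 0.0

    def test_concentrations_consistent_with_sto2(self):
        cfg = noiseless(icp_profile=[RampStep(start=30, target=80, ramp=20)])
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        recon = compute_sto2(gt.d_hbo2, gt.d_hb, gt.hemo)
        np.testing.assert_allclose(recon, gt.sto2, atol=1e-12)

    def test_negative_correlations_invariant(self):
        cfg = noiseless()
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        assert np.corrcoef(gt.icp, gt.sto2)[0, 1] < 0
        assert np.corrcoef(gt.icp, gt.u)[0, 1] < 0


class TestForwardPPG:
    def test_zero_change_returns_i0(self, optical):
        cfg = noiseless(icp_profile=[], i0_red=1.5, i0_ir=2.5)
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        tr = forward_ppg(gt, optical, cfg)
        np.testing.assert_allclose(tr.channels["ppg_red"], 1.5)
        np.testing.assert_allclose(tr.channels["ppg_ir"], 2.5)

    def test_noiseless_round_trip_concentrations(self, optical):
        cfg = noiseless()
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        tr = forward_ppg(gt, optical, cfg)
        od_red = optical_density(tr.channels["ppg_red"], cfg.i0_red)
        od_ir = optical_density(tr.channels["ppg_ir"], cfg.i0_ir)
        d_hbo2, d_hb = invert_beer_lambert((od_red, od_ir), optical)
        np.testing.assert_allclose(d_hbo2, gt.d_hbo2, atol=1e-12)
        np.testing.assert_allclose(d_hb, gt.d_hb, atol=1e-12)

    def test_seeded_reproducibility(self, optical):
        cfg = EpisodeConfig(duration=60.0, seed=99)
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        a = forward_ppg(gt, optical, cfg)
        b = forward_ppg(gt, optical, cfg)
        np.testing.assert_array_equal(a.channels["ppg_red"], b.channels["ppg_red"])

    def test_nonpositive_i0_rejected(self, optical):
        cfg = noiseless(i0_red=0.0)
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        with pytest.raises(ConfigurationError):
            forward_ppg(gt, optical, cfg)


class TestForwardThermistors:
    def test_heater_off_zero_rise(self, thermal_params):
        cfg = noiseless(heater_schedule=[])
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        tr = forward_thermistors(gt, thermal_params, cfg)
        for i in range(1, 5):
            np.testing.assert_allclose(tr.channels[f"t{i}"], cfg.tissue_temp)
        assert np.all(tr.channels["heater"] == 0.0)

    def test_doubled_flow_lowers_every_rise(self, thermal_params):
        slow = noiseless(icp_profile=[], flow_baseline=2.0)
        fast = noiseless(icp_profile=[], flow_baseline=4.0)
        for cfg_lo, cfg_hi in [(slow, fast)]:
            lo = forward_thermistors(
                derive_physiology(generate_icp_trace(cfg_lo), cfg_lo),
                thermal_params, cfg_lo)
            hi = forward_thermistors(
                derive_physiology(generate_icp_trace(cfg_hi), cfg_hi),
                thermal_params, cfg_hi)
            for i in range(1, 5):
                assert np.all(hi.channels[f"t{i}"] < lo.channels[f"t{i}"])

    def test_nearest_thermistor_hottest(self, thermal_params):
        cfg = noiseless(icp_profile=[])
        tr = forward_thermistors(
            derive_physiology(generate_icp_trace(cfg), cfg), thermal_params, cfg)
        means = [tr.channels[f"t{i}"].mean() for i in range(1, 5)]
        assert means[0] == max(means)
        assert np.all(np.diff(means) < 0)  # ascending distances -> cooler


class TestForwardPressure:
    def test_identity(self):
        cfg = noiseless()
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        tr = forward_pressure(gt, cfg)
        np.testing.assert_allclose(tr.channels["pressure_raw"], gt.icp)

    def test_additive_offset(self):
        cfg = noiseless(pressure_offset=5.0)
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        tr = forward_pressure(gt, cfg)
        np.testing.assert_allclose(tr.channels["pressure_raw"] - gt.icp, 5.0)

    def test_device_temperature_channel_present(self):
        cfg = noiseless(device_temp_drift=0.5)
        gt = derive_physiology(generate_icp_trace(cfg), cfg)
        tr = forward_pressure(gt, cfg)
        assert tr.units["temp_device"] == "K"
        assert tr.channels["temp_device"].std() > 0


class TestDeterminism:
    def test_full_episode_bit_identical(self):
        cfg = EpisodeConfig(duration=30.0, seed=5)
        a = simulate_episode(cfg)
        b = simulate_episode(cfg)
        for name in a.ppg.channels:
            np.testing.assert_array_equal(a.ppg.channels[name], b.ppg.channels[name])
        for name in a.thermal.channels:
            np.testing.assert_array_equal(a.thermal.channels[name],
                                          b.thermal.channels[name])
        np.testing.assert_array_equal(a.pressure.channels["pressure_raw"],
                                      b.pressure.channels["pressure_raw"])

    def test_different_seed_differs(self):
        a = simulate_episode(EpisodeConfig(duration=30.0, seed=1))
        b = simulate_episode(EpisodeConfig(duration=30.0, seed=2))
        assert not np.array_equal(a.ppg.channels["ppg_red"],
                                  b.ppg.channels["ppg_red"])

    def test_baseline_disagreement_rejected(self):
        cfg = noiseless(sto2_baseline=0.6)
        with pytest.raises(ConfigurationError):
            derive_physiology(generate_icp_trace(cfg), cfg,
                              HemoState(sto2_baseline=0.8))
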