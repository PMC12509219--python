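"""Four-stage calibration: phase curves, bias solving, offsets, gain."""

import math

import numpy as np
import pytest

from flp import (
    FluorophoreSpecies,
    InstrumentConfig,
    SceneTimeline,
    calibrate,
    estimate_trace,
    simulate_dark,
    simulate_phase_ramp,
    simulate_recording,
)
from flp.calibration import (
    CalibrationResult,
    fit_phase_curves,
    measure_conversion_gain,
    measure_dark_offsets,
    solve_bias_voltages,
)
from flp.estimation import downsample_recording
from flp.instrument import NOMINAL_SHIFTS, ChannelState, DarkRecording, PhaseRampRecording


def make_config(**kw):
    return InstrumentConfig(**kw)


class TestFitPhaseCurves:
    def test_noiseless_recovery_of_true_curves(self, config, standard, ctx):
        ramp = simulate_phase_ramp(config, standard, noisy=False)
        fits = fit_phase_curves(ramp, ctx)
        vb = np.linspace(0.5, 9.5, 50)
        for fit, ch in zip(fits, config.channels):
            # limited by discrete sampling of the sweep extrema (~1e-5 rad,
            # i.e. < 0.1 ps equivalent), not by the fit itself
            assert fit.residual_rms_rad < 2e-5
            assert np.allclose(fit(vb), ch.achieved_phase(vb), atol=1e-4)

    def test_phase_at_vif_max_is_quarter_turn_minus_lag(self, config, standard, ctx):
        ramp = simulate_phase_ramp(config, standard, noisy=False)
        fits = fit_phase_curves(ramp, ctx)
        lag = math.atan(float(ctx.omega_tau(standard.lifetime_ns)))
        i_max = int(np.argmax(ramp.vif[0]))
        phi = float(fits[0](ramp.bias_voltage[i_max]))
        assert phi == pytest.approx(math.pi / 2 - lag, abs=5e-3)

    def test_constant_offset_invariance(self, config, standard, ctx):
        ramp = simulate_phase_ramp(config, standard, noisy=False)
        shifted = PhaseRampRecording(
            bias_voltage=ramp.bias_voltage,
            vif=ramp.vif + 0.37,
            vdc=ramp.vdc,
            standard_lifetime_ns=ramp.standard_lifetime_ns,
        )
        f1 = fit_phase_curves(ramp, ctx)
        f2 = fit_phase_curves(shifted, ctx)
        vb = np.linspace(0, 10, 50)
        for a, b in zip(f1, f2):
            assert np.allclose(a(vb), b(vb), atol=1e-9)

    def test_flat_channel_rejected(self, config, standard, ctx):
        ramp = simulate_phase_ramp(config, standard, noisy=False)
        ramp.vif[2] = 0.05
        with pytest.raises(ValueError, match="flat channel"):
            fit_phase_curves(ramp, ctx)


class TestSolveBiasVoltages:
    def test_linear_curve_targets(self):
        from flp.calibration import PhaseCurveFit

        fits = tuple(
            PhaseCurveFit(
                coefficients=(0.0, math.pi / 5), residual_rms_rad=0.0, bias_range=(0, 10)
            )
            for _ in range(4)
        )
        vb = solve_bias_voltages(fits)
        assert np.allclose(vb, (0.0, 2.5, 5.0, 7.5), atol=1e-8)

    def test_recovers_simulator_ground_truth(self, config, standard, ctx):
        ramp = simulate_phase_ramp(config, standard, noisy=False)
        fits = fit_phase_curves(ramp, ctx)
        vb = solve_bias_voltages(fits)
        assert np.allclose(vb, config.resolved_bias_voltages(), atol=1e-3)

    def test_out_of_range_target_raises(self):
        from flp.calibration import PhaseCurveFit

        fits = tuple(
            PhaseCurveFit(
                coefficients=(0.0, 0.1), residual_rms_rad=0.0, bias_range=(0, 10)
            )
            for _ in range(4)
        )
        with pytest.raises(ValueError, match="outside achievable"):
            solve_bias_voltages(fits)


class TestDarkOffsets:
    def test_noiseless_arithmetic(self):
        vif = np.stack(
            [
                np.full(10, 0.05 + 0.3),
                np.full(10, 0.05 + 0.0),
                np.full(10, 0.05 + 0.1),
                np.full(10, 0.05 + 0.0),
            ]
        )
        dark = DarkRecording(vdc=np.full(10, 0.123), vif=vif)
        ob, d13, d24 = measure_dark_offsets(dark)
        assert ob == pytest.approx(0.123)
        assert d13 == pytest.approx(0.2)
        assert d24 == pytest.approx(0.0)

    def test_unbiased_over_seeds(self, config):
        d13s = []
        for seed in range(50):
            dark = simulate_dark(config.with_seed(seed), duration=0.2, noisy=True)
            _, d13, _ = measure_dark_offsets(dark)
            d13s.append(d13)
        true_d13 = config.channels[0].channel_offset - config.channels[2].channel_offset
        assert np.mean(d13s) == pytest.approx(true_d13, abs=3e-6)


class TestConversionGain:
    def test_hand_check_of_gain_formula(self, ctx):
        # span 0.4 V, F = 0.1 V, omega*tau = 0.754 -> MB = 2 * sqrt(1.5685)
        bias = np.linspace(0, 10, 200)
        phase = 0.8 * bias
        wt = 0.754
        amp = 0.2
        vif = np.stack([amp * np.sin(phase + math.atan(wt)) for _ in range(4)])
        tau_ns = wt / ctx.angular_frequency * 1e9
        ramp = PhaseRampRecording(
            bias_voltage=bias, vif=vif, vdc=0.1, standard_lifetime_ns=tau_ns
        )
        gain, per_channel = measure_conversion_gain(ramp, 0.0, ctx)
        assert gain == pytest.approx(0.4 / (2 * 0.1) * math.sqrt(1 + wt**2), rel=1e-3)
        assert gain == pytest.approx(2.505, abs=2e-3)

    def test_round_trip_against_simulator(self, config, standard, ctx):
        ramp = simulate_phase_ramp(config, standard, noisy=False)
        gain, _ = measure_conversion_gain(ramp, config.dc_offset_true, ctx)
        assert gain == pytest.approx(config.true_conversion_gain, rel=1e-3)

    def test_no_light_rejected(self, config, standard, ctx):
        ramp = simulate_phase_ramp(config, standard, noisy=False)
        with pytest.raises(ValueError, match="no light"):
            measure_conversion_gain(ramp, ramp.vdc + 0.1, ctx)


class TestFullCalibration:
    def test_idempotent(self, config, standard, ctx):
        ramp = simulate_phase_ramp(config, standard, noisy=False)
        dark = simulate_dark(config, duration=0.5, noisy=False)
        c1 = calibrate(ramp, dark, standard, ctx)
        c2 = calibrate(ramp, dark, standard, ctx)
        assert c1.bias_voltages == c2.bias_voltages
        assert c1.conversion_gain == c2.conversion_gain

    def test_channel_offsets_change_only_d13_d24(self, standard, ctx):
        base = make_config()
        chans = tuple(
            ChannelState(
                nominal_shift=c.nominal_shift,
                channel_offset=c.channel_offset + extra,
                shifter_curve=c.shifter_curve,
            )
            for c, extra in zip(base.channels, (0.05, 0.0, -0.02, 0.01))
        )
        perturbed = make_config(channels=chans)
        cals = []
        for cfg in (base, perturbed):
            ramp = simulate_phase_ramp(cfg, standard, noisy=False)
            dark = simulate_dark(cfg, duration=0.5, noisy=False)
            cals.append(calibrate(ramp, dark, standard, ctx))
        assert cals[1].conversion_gain == pytest.approx(
            cals[0].conversion_gain, rel=1e-6
        )
        assert cals[1].d13 - cals[0].d13 == pytest.approx(0.05 - (-0.02), abs=1e-9)
        assert cals[1].d24 - cals[0].d24 == pytest.approx(0.0 - 0.01, abs=1e-9)

    def test_common_offset_invariance_of_lifetime(self, standard, ctx):
        taus = []
        for common in (0.0, 0.5):
            cfg = make_config(common_offset=common)
            ramp = simulate_phase_ramp(cfg, standard, noisy=False)
            dark = simulate_dark(cfg, duration=0.5, noisy=False)
            cal = calibrate(ramp, dark, standard, ctx)
            rec = simulate_recording(
                SceneTimeline.from_species(standard, ctx, 5e6),
                cfg.with_bias_voltages(cal.bias_voltages),
                0.01,
                noisy=False,
            )
            taus.append(np.nanmean(estimate_trace(rec, cal).lifetime_ns))
        assert taus[0] == pytest.approx(taus[1], abs=1e-9)

    def test_noiseless_round_trip_within_1ps(self, config, standard, ctx):
        ramp = simulate_phase_ramp(config, standard, noisy=False)
        dark = simulate_dark(config, duration=0.5, noisy=False)
        cal = calibrate(ramp, dark, standard, ctx)
        rec = simulate_recording(
            SceneTimeline.from_species(standard, ctx, 5e6),
            config.with_bias_voltages(cal.bias_voltages),
            0.05,
            noisy=False,
        )
        tau = np.nanmean(estimate_trace(rec, cal).lifetime_ns)
        assert tau == pytest.approx(standard.lifetime_ns, abs=1e-3)

    def test_noisy_round_trip_within_10ps_at_1hz(self, standard, ctx):
        cfg = make_config(rng_seed=11)
        ramp = simulate_phase_ramp(cfg, standard, noisy=True)
        dark = simulate_dark(cfg, duration=5.0, noisy=True)
        cal = calibrate(ramp, dark, standard, ctx)
        rec = simulate_recording(
            SceneTimeline.from_species(standard, ctx, 5e6),
            cfg.with_bias_voltages(cal.bias_voltages).with_seed(12),
            5.0,
            noisy=True,
        )
        trace = estimate_trace(downsample_recording(rec, 1.0), cal)
        assert np.all(np.abs(trace.lifetime_ns - standard.lifetime_ns) < 0.010)

    def test_json_round_trip(self, noiseless_calibration, tmp_path):
        path = tmp_path / "cal.json"
        noiseless_calibration.to_json(path)
        loaded = CalibrationResult.from_json(path)
        assert loaded.dc_offset == noiseless_calibration.dc_offset
        assert loaded.bias_voltages == noiseless_calibration.bias_voltages
        assert (
            loaded.phase_polynomials[0].coefficients
            == noiseless_calibration.phase_polynomials[0].coefficients
        )
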