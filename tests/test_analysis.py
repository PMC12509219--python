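"""Tonic/phasic decomposition, autofluorescence correction, SNR."""

import numpy as np
import pytest

from flp import (
    EventSet,
    autofluorescence_correct,
    compute_snr,
    downsample_compare,
    epoch_tonic_change,
    event_aligned_transients,
    rolling_median_baseline,
)
from flp.analysis import PhasicResult
from flp.estimation import LifetimeTrace


def make_trace(lifetime, rate=100.0):
    n = len(lifetime)
    return LifetimeTrace(
        time=np.arange(n) / rate,
        lifetime_ns=np.asarray(lifetime, dtype=float),
        intensity=np.ones(n),
        g=np.zeros(n),
        s=np.zeros(n),
        rate=rate,
    )


class TestAutofluorescenceCorrect:
    def test_hand_checked_inversion(self):
        # (2.0*10 - 1.0*1) / (10 - 1) = 19/9
        assert autofluorescence_correct(2.0, 10.0, 1.0, 1.0) == pytest.approx(19 / 9)

    def test_zero_autofluorescence_is_identity(self):
        assert autofluorescence_correct(2.0, 10.0, 1.0, 0.0) == pytest.approx(2.0)

    def test_forward_then_inverse_round_trip(self):
        tau_sensor, i_sensor = 2.1, 9.0
        tau_af, i_af = 1.3, 1.5
        tau_obs = (tau_sensor * i_sensor + tau_af * i_af) / (i_sensor + i_af)
        rec = autofluorescence_correct(tau_obs, i_sensor + i_af, tau_af, i_af)
        assert rec == pytest.approx(tau_sensor, abs=1e-12)

    def test_ordering_preserved_below_30pct_af(self):
        # region A truly above region B; correction must keep the order
        rng = np.random.default_rng(0)
        for _ in range(100):
            tau_a, tau_b = 2.1, 1.9
            af_tau = rng.uniform(0.5, 3.5)
            fa, fb = rng.uniform(0, 0.3, 2)
            obs_a = tau_a * (1 - fa) + af_tau * fa
            obs_b = tau_b * (1 - fb) + af_tau * fb
            cor_a = autofluorescence_correct(obs_a, 1.0, af_tau, fa)
            cor_b = autofluorescence_correct(obs_b, 1.0, af_tau, fb)
            assert cor_a > cor_b

    def test_uncorrectable_when_af_exceeds_observed(self):
        with pytest.raises(ValueError, match="uncorrectable"):
            autofluorescence_correct(2.0, 1.0, 1.0, 2.0)


class TestRollingMedianBaseline:
    def test_constant_trace(self):
        trace = make_trace(np.full(12_000, 1.8))
        tonic = rolling_median_baseline(trace, window_s=60.0)
        assert np.allclose(tonic.baseline_ns, 1.8)
        assert np.allclose(tonic.delta_baseline_ns, 0.0)

    def test_median_ignores_brief_transient(self):
        rate = 100.0
        n = 12_000
        x = np.full(n, 1.8)
        x[6000:6100] += 0.5  # 1 s transient in a 60 s window
        trace = make_trace(x, rate)
        tonic = rolling_median_baseline(trace, window_s=60.0)
        assert np.allclose(tonic.baseline_ns, 1.8, atol=1e-12)

    def test_tracks_slow_ramp(self):
        rate = 100.0
        t = np.arange(24_000) / rate
        ramp = 1.8 + 0.001 * t
        trace = make_trace(ramp, rate)
        tonic = rolling_median_baseline(trace, window_s=60.0)
        interior = slice(3000, -3000)
        assert np.allclose(tonic.baseline_ns[interior], ramp[interior], atol=1e-3)

    def test_empty_trace_rejected(self):
        trace = make_trace(np.full(100, 1.8))
        with pytest.raises(ValueError):
            rolling_median_baseline(trace, window_s=60.0)


class TestEpochTonicChange:
    def trace_with_dip(self, dip_ns):
        rate = 100.0
        n = 36_000  # 360 s
        x = np.full(n, 1.8)
        x[18_000:24_000] += dip_ns  # 180-240 s epoch
        return make_trace(x, rate)

    def test_flat_session_zero(self):
        trace = make_trace(np.full(30_000, 1.8))
        tonic = rolling_median_baseline(trace, window_s=60.0)
        assert epoch_tonic_change(tonic, (120.0, 180.0)) == pytest.approx(0.0)

    def test_recovers_injected_dip(self):
        tonic = rolling_median_baseline(self.trace_with_dip(-0.010), window_s=60.0)
        change = epoch_tonic_change(tonic, (180.0, 240.0))
        assert change == pytest.approx(-0.010, abs=0.002)

    def test_sign_flips_with_rise(self):
        tonic = rolling_median_baseline(self.trace_with_dip(+0.010), window_s=60.0)
        assert epoch_tonic_change(tonic, (180.0, 240.0)) == pytest.approx(
            0.010, abs=0.002
        )

    def test_out_of_range_epoch_rejected(self):
        tonic = rolling_median_baseline(make_trace(np.full(30_000, 1.8)), 60.0)
        with pytest.raises(ValueError):
            epoch_tonic_change(tonic, (400.0, 500.0))


def kernel(t, rise=0.2, decay=1.5):
    tp = np.clip(t, 0.0, None)
    k = np.where(t >= 0, np.exp(-tp / decay) - np.exp(-tp / rise), 0.0)
    return k / k.max()


class TestEventAlignedTransients:
    def test_constant_trace_zero_transients(self):
        trace = make_trace(np.full(6000, 1.8))
        events = EventSet(event_times=np.array([20.0, 40.0]))
        phasic = event_aligned_transients(trace, events, post_s=10.0)
        assert np.allclose(phasic.mean_transient_ns, 0.0)
        assert np.allclose(phasic.peak_delta_ns, 0.0)

    def test_recovers_known_kernel(self):
        rate = 100.0
        n = 12_000
        t = np.arange(n) / rate
        amp = 0.030
        x = np.full(n, 1.8)
        for et in (30.0, 60.0, 90.0):
            x += amp * kernel(t - et)
        trace = make_trace(x, rate)
        events = EventSet(event_times=np.array([30.0, 60.0, 90.0]))
        phasic = event_aligned_transients(trace, events, post_s=10.0)
        rel = phasic.relative_time
        expected = amp * kernel(rel)
        assert np.allclose(phasic.mean_transient_ns, expected, atol=1e-3)
        assert np.nanmean(phasic.peak_delta_ns) == pytest.approx(amp, abs=2e-3)

    def test_peak_invariant_to_constant_offset(self):
        rate = 100.0
        n = 12_000
        t = np.arange(n) / rate
        x = 1.8 + 0.030 * kernel(t - 50.0)
        events = EventSet(event_times=np.array([50.0]))
        p1 = event_aligned_transients(make_trace(x, rate), events, post_s=10.0)
        p2 = event_aligned_transients(make_trace(x + 5.0, rate), events, post_s=10.0)
        assert p1.peak_delta_ns == pytest.approx(p2.peak_delta_ns, abs=1e-12)

    def test_boundary_events_dropped(self):
        trace = make_trace(np.full(3000, 1.8))
        events = EventSet(event_times=np.array([0.5, 15.0, 29.5]))
        phasic = event_aligned_transients(trace, events, post_s=10.0)
        assert len(phasic.used_event_times) == 1
        with pytest.raises(ValueError):
            event_aligned_transients(
                trace, EventSet(event_times=np.array([0.5])), post_s=10.0
            )


class TestDownsampleCompare:
    def trace_with_transients(self, width_decay, n_events=6, rate=1000.0):
        n = int(rate * 60 * 2)
        t = np.arange(n) / rate
        x = np.full(n, 1.8)
        times = 15.0 + 18.0 * np.arange(n_events)
        for et in times:
            x += 0.030 * kernel(t - et, rise=width_decay / 7.5, decay=width_decay)
        return make_trace(x, rate), EventSet(event_times=times)

    def test_short_transient_attenuated_at_1hz(self):
        trace, events = self.trace_with_transients(width_decay=0.5)
        peaks = downsample_compare(trace, events, rates=[1.0, 20.0], post_s=8.0)
        assert abs(peaks[1.0]) < abs(peaks[20.0])

    def test_long_transient_nearly_rate_independent(self):
        trace, events = self.trace_with_transients(width_decay=6.0)
        peaks = downsample_compare(trace, events, rates=[1.0, 20.0], post_s=12.0)
        assert peaks[1.0] == pytest.approx(peaks[20.0], rel=0.15)

    def test_constant_trace_zero_at_all_rates(self):
        trace = make_trace(np.full(120_000, 1.8), rate=1000.0)
        events = EventSet(event_times=np.array([30.0, 60.0]))
        peaks = downsample_compare(trace, events, rates=[1.0, 20.0], post_s=8.0)
        assert peaks[1.0] == pytest.approx(0.0, abs=1e-12)
        assert peaks[20.0] == pytest.approx(0.0, abs=1e-12)


class TestComputeSnr:
    def phasic_stub(self, peaks, sds):
        k = len(peaks)
        return PhasicResult(
            relative_time=np.linspace(-2, 10, 10),
            snippets=np.zeros((k, 10)),
            mean_transient_ns=np.zeros(10),
            sem_transient_ns=np.zeros(10),
            peak_delta_ns=np.asarray(peaks, dtype=float),
            baseline_sd_ns=np.asarray(sds, dtype=float),
            used_event_times=np.arange(k, dtype=float),
        )

    def test_hand_example(self):
        assert compute_snr(self.phasic_stub([4, 6], [1, 1])) == pytest.approx(5.0)

    def test_scale_invariance(self):
        a = compute_snr(self.phasic_stub([4, 6], [1, 2]))
        b = compute_snr(self.phasic_stub([4000, 6000], [1000, 2000]))
        assert a == pytest.approx(b)

    def test_doubling_noise_halves_snr(self):
        rate = 100.0
        n = 24_000
        t = np.arange(n) / rate
        times = np.arange(20.0, 230.0, 20.0)
        base = np.full(n, 1.8)
        for et in times:
            base += 0.050 * kernel(t - et)
        events = EventSet(event_times=times)
        snrs = []
        for sigma in (0.005, 0.010):
            rng = np.random.default_rng(4)
            trace = make_trace(base + rng.normal(0, sigma, n), rate)
            snrs.append(compute_snr(event_aligned_transients(trace, events, post_s=8.0)))
        assert snrs[0] / snrs[1] == pytest.approx(2.0, rel=0.25)

    def test_zero_baseline_sd_flagged_infinite(self):
        assert compute_snr(self.phasic_stub([4.0], [0.0])) == np.inf
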