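"""Synthetic photometry sessions with known ground truth.

Generates in-vivo-like recordings for validating the full stack: a slow
tonic occupancy drift plus event-locked phasic transients drive a two-state
sensor; the resulting emission is mixed with a constant autofluorescence
background, multiplied by bleaching and motion/hemodynamic gain artifacts
(intensity only -- per-molecule lifetime is unaffected by collection
efficiency), and rendered to the five instrument voltages with shot noise.

Every stochastic element derives from the session seed, and the generator
returns the complete ground truth (occupancy, tonic component, gain series,
autofluorescence fraction, event times) for use as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .analysis import EventSet
from .instrument import InstrumentConfig, RawRecording, SceneTimeline, simulate_recording
from .phasor import FluorophoreSpecies, single_exp_phasor
from .sensor import TwoStateSensor

__all__ = [
    "EventKernel",
    "ArtifactSpec",
    "SessionSpec",
    "SessionGroundTruth",
    "generate_occupancy",
    "generate_session",
]


@dataclass(frozen=True)
class EventKernel:
    """Difference-of-exponentials transient in occupancy units.

    amplitude is the peak change in f (negative for a binding event of an
    s1-fraction trace, since ligand binding moves sensors out of s1).
    Defaults give a fast-rising (0.2 s), seconds-decaying (1.5 s) transient
    typical of phasic neuromodulator release.
    """

    amplitude: float = -0.2
    rise_s: float = 0.2
    decay_s: float = 1.5

    def __post_init__(self) -> None:
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.decay_s <= self.rise_s:
            raise ValueError("decay must be slower than rise")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Kernel evaluated at times t (s) after the event, peak-normalized."""
        tp = np.clip(t, 0.0, None)  # avoid overflow in exp for t << 0
        raw = np.where(
            t >= 0, np.exp(-tp / self.decay_s) - np.exp(-tp / self.rise_s), 0.0
        )
        t_peak = (
            self.rise_s
            * self.decay_s
            / (self.decay_s - self.rise_s)
            * math.log(self.decay_s / self.rise_s)
        )
        peak = math.exp(-t_peak / self.decay_s) - math.exp(-t_peak / self.rise_s)
        return self.amplitude * raw / peak

    def area(self) -> float:
        """Closed-form integral of the peak-normalized kernel (f * s)."""
        t_peak = (
            self.rise_s
            * self.decay_s
            / (self.decay_s - self.rise_s)
            * math.log(self.decay_s / self.rise_s)
        )
        peak = math.exp(-t_peak / self.decay_s) - math.exp(-t_peak / self.rise_s)
        return self.amplitude * (self.decay_s - self.rise_s) / peak


@dataclass(frozen=True)
class ArtifactSpec:
    """Multiplicative intensity-gain artifacts: bleaching + hemodynamic band.

    The band artifact is a sum of sinusoids with random phases at
    frequencies drawn uniformly from ``band_hz``, scaled so the combined
    modulation has the requested peak amplitude (e.g. 0.2 for +/-20%).
    """

    gain_amplitude: float = 0.0  # fractional, 0.2 -> +/-20%
    band_hz: tuple[float, float] = (0.5, 2.0)
    n_components: int = 3
    bleach_time_constant_s: float | None = None

    def gain_series(self, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        gain = np.ones_like(t)
        if self.gain_amplitude > 0:
            freqs = rng.uniform(*self.band_hz, self.n_components)
            phases = rng.uniform(0, 2 * math.pi, self.n_components)
            mod = np.zeros_like(t)
            for fr, ph in zip(freqs, phases):
                mod += np.sin(2 * math.pi * fr * t + ph)
            mod /= self.n_components
            gain = gain * (1.0 + self.gain_amplitude * mod)
        if self.bleach_time_constant_s:
            gain = gain * np.exp(-t / self.bleach_time_constant_s)
        return gain


@dataclass
class SessionSpec:
    """Everything needed to generate one synthetic session."""

    duration_s: float = 120.0
    sensor: TwoStateSensor = field(default_factory=TwoStateSensor)
    tonic_breakpoints: tuple[tuple[float, float], ...] = ((0.0, 0.7), (120.0, 0.7))
    events: EventSet | None = None
    event_kernel: EventKernel = field(default_factory=EventKernel)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    autofluorescence: FluorophoreSpecies | None = None
    af_intensity_fraction: float = 0.0  # fraction of total observed intensity
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    base_photon_rate: float = 5e6  # photons/s at gain 1, all sensors in s1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.af_intensity_fraction < 0.5:
            raise ValueError("autofluorescence fraction must be in [0, 0.5)")
        if self.af_intensity_fraction > 0 and self.autofluorescence is None:
            raise ValueError("autofluorescence species required when fraction > 0")


@dataclass
class SessionGroundTruth:
    """True latent trajectories behind a generated session."""

    time: np.ndarray
    f_true: np.ndarray
    tonic_true: np.ndarray
    lifetime_true_ns: np.ndarray  # photon-weighted mean lifetime incl. autofluorescence
    sensor_lifetime_true_ns: np.ndarray  # sensor-only photon-weighted lifetime
    phase_lifetime_true_ns: np.ndarray  # s/(g*omega) of the observed scene phasor:
    # what a frequency-domain phase estimator measures; for a multi-exponential
    # scene it sits slightly below the photon-weighted mean
    gain_true: np.ndarray
    af_fraction_true: np.ndarray
    event_times: np.ndarray


def generate_occupancy(spec: SessionSpec):
    """Occupancy trajectory f(t) = tonic + sum of event kernels, clipped.

    Returns ``(time, f, tonic, phasic)`` at the instrument sample rate.
    Deterministic given the spec (the seed only feeds downstream noise).
    """
    fs = spec.instrument.sample_rate
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    bp = np.asarray(spec.tonic_breakpoints, dtype=float)
    tonic = np.interp(t, bp[:, 0], bp[:, 1])
    phasic = np.zeros(n)
    if spec.events is not None:
        for et in spec.events.event_times:
            rel = t - et
            phasic += spec.event_kernel.waveform(rel)
    f = tonic + phasic
    if np.any((f < 0) | (f > 1)):
        import warnings

        warnings.warn("occupancy clipped to [0, 1]")
        f = np.clip(f, 0.0, 1.0)
    return t, f, tonic, phasic


def generate_session(
    spec: SessionSpec, noisy: bool = True
) -> tuple[RawRecording, SessionGroundTruth]:
    """Render a full synthetic session to raw voltages plus ground truth."""
    t, f, tonic, _ = generate_occupancy(spec)
    rng = np.random.default_rng(spec.seed)
    sensor = spec.sensor
    ctx = spec.instrument.ctx

    # Sensor emission: photon-weighted mix of the two state lifetimes.
    R = sensor.brightness_ratio
    F = f * (1.0 - R) + R  # relative intensity, F(1)=1
    p1 = single_exp_phasor(sensor.tau1_ns, ctx)
    p2 = single_exp_phasor(sensor.tau2_ns, ctx)
    g_sens = (f * p1.g + R * (1.0 - f) * p2.g) / F
    s_sens = (f * p1.s + R * (1.0 - f) * p2.s) / F
    tau_sens = (f * sensor.tau1_ns + R * (1.0 - f) * sensor.tau2_ns) / F

    rate_sensor = spec.base_photon_rate * F

    # Constant autofluorescence background sized against the mean sensor rate.
    if spec.af_intensity_fraction > 0:
        af = spec.autofluorescence
        p_af = single_exp_phasor(af.lifetime_ns, ctx)
        rate_af = (
            spec.af_intensity_fraction
            / (1.0 - spec.af_intensity_fraction)
            * float(np.mean(rate_sensor))
        )
    else:
        p_af = None
        rate_af = 0.0

    rate_total = rate_sensor + rate_af
    af_frac = np.full_like(t, rate_af) / rate_total
    if p_af is not None:
        g_obs = (rate_sensor * g_sens + rate_af * p_af.g) / rate_total
        s_obs = (rate_sensor * s_sens + rate_af * p_af.s) / rate_total
        tau_obs = (
            rate_sensor * tau_sens + rate_af * spec.autofluorescence.lifetime_ns
        ) / rate_total
    else:
        g_obs, s_obs, tau_obs = g_sens, s_sens, tau_sens

    # Gain artifacts scale collected photons only; phasor is untouched.
    gain = spec.artifacts.gain_series(t, rng)
    scene = SceneTimeline(g=g_obs, s=s_obs, photon_rate=rate_total * gain)
    config = spec.instrument.with_seed(int(rng.integers(0, 2**31 - 1)))
    rec = simulate_recording(scene, config, spec.duration_s, noisy=noisy)

    phase_tau = s_obs / (g_obs * ctx.angular_frequency) * 1e9
    truth = SessionGroundTruth(
        time=t,
        f_true=f,
        tonic_true=tonic,
        lifetime_true_ns=tau_obs,
        sensor_lifetime_true_ns=tau_sens,
        phase_lifetime_true_ns=np.broadcast_to(phase_tau, t.shape).copy(),
        gain_true=gain,
        af_fraction_true=af_frac,
        event_times=(
            spec.events.event_times.copy() if spec.events is not None else np.array([])
        ),
    )
    return rec, truth
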