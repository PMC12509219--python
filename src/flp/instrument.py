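"""Digital twin of the analog lifetime-photometry processing unit.

The instrument splits the PMT output into a DC intensity channel (VDC) and a
radio-frequency component that is mixed against four copies of the laser
reference, each phase-shifted by a nominal 0, pi/2, pi or 3pi/2.  After the
mixers and 1 kHz low-pass filters the four intermediate-frequency voltages
(VIF) encode the sine/cosine quadratures of the fluorescence fundamental.

After the stated 70 MHz front-end filtering only DC and the repetition-rate
fundamental survive, so each channel is modeled in closed form as

    vdc   = O_B + rate / photons_per_volt
    vif_i = O_common + d_i + gain * (vdc - O_B) * (g*sin(theta_i) + s*cos(theta_i))

where (g, s) is the scene phasor, theta_i the phase actually achieved by
channel i's shifter at its bias voltage, O_B the DC offset, O_common the
shared IF offset, d_i the channel-specific offset and ``gain`` the combined
mixer/bias-tee conversion gain (the M*B measured during calibration).  A
slow, explicit waveform-level simulation (:func:`waveform_oracle`) guards
this harmonic shortcut.

A time-correlated single-photon-counting (TCSPC) reference instrument with a
photon-pileup model is included for cross-method comparisons: it counts only
the first photon per excitation cycle and therefore underestimates the
lifetime at high photon rates, which the analog instrument does not.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .phasor import (
    NS,
    EmissionMixture,
    FluorophoreSpecies,
    ModulationContext,
    mixture_phasor,
    single_exp_phasor,
)

__all__ = [
    "ChannelState",
    "InstrumentConfig",
    "SceneTimeline",
    "RawRecording",
    "PhaseRampRecording",
    "DarkRecording",
    "simulate_recording",
    "simulate_phase_ramp",
    "simulate_dark",
    "waveform_oracle",
    "simulate_tcspc_histogram",
]

NOMINAL_SHIFTS = (0.0, 0.5 * math.pi, math.pi, 1.5 * math.pi)


@dataclass(frozen=True)
class ChannelState:
    """One mixer channel: nominal shift, offset, and the shifter's bias curve.

    ``shifter_curve`` holds ascending polynomial coefficients of the achieved
    phase (radians) as a function of bias voltage over the 0-10 V control
    range; the curve must be monotone increasing over that range.
    """

    nominal_shift: float
    channel_offset: float = 0.0  # volts, the d_i term
    shifter_curve: tuple[float, ...] = (0.0, 0.75)

    def achieved_phase(self, bias_voltage):
        return np.polynomial.polynomial.polyval(
            np.asarray(bias_voltage, dtype=float), np.asarray(self.shifter_curve)
        )

    def bias_for_phase(self, target: float) -> float:
        """Invert the (monotone) shifter curve on the 0-10 V range."""
        lo, hi = self.achieved_phase(0.0), self.achieved_phase(10.0)
        if not (lo <= target <= hi):
            raise ValueError(
                f"target phase {target:.4f} rad outside achievable "
                f"range [{lo:.4f}, {hi:.4f}]"
            )
        return brentq(lambda v: float(self.achieved_phase(v)) - target, 0.0, 10.0)


def _default_channels() -> tuple[ChannelState, ...]:
    # Mildly nonlinear, channel-specific curves so that calibration has real
    # work to do; all monotone, all reach > nominal_shift + reserve by 10 V.
    offsets = (0.003, 0.001, 0.002, 0.0015)
    curves = (
        (-0.30, 0.74, 0.004),
        (-0.22, 0.76, 0.003),
        (-0.35, 0.75, 0.005),
        (-0.27, 0.77, 0.002),
    )
    return tuple(
        ChannelState(nominal_shift=ns, channel_offset=d, shifter_curve=c)
        for ns, d, c in zip(NOMINAL_SHIFTS, offsets, curves)
    )


@dataclass(frozen=True)
class InstrumentConfig:
    """Ground-truth parameters of the simulated analog unit."""

    ctx: ModulationContext = field(default_factory=ModulationContext)
    true_conversion_gain: float = 2.5  # V/V, the M*B product
    dc_offset_true: float = 0.1  # volts, O_B
    common_offset: float = 0.05  # volts, shared IF offset O(P_RF)
    channels: tuple[ChannelState, ...] = field(default_factory=_default_channels)
    photons_per_volt: float = 1e8  # photons/s per volt of (vdc - O_B)
    if_bandwidth: float = 1e3  # Hz
    sample_rate: float = 1e4  # Hz
    shot_noise_scale: float = 1.0  # dimensionless c in the shot-noise sigma
    electronic_noise_v: float = 1e-4  # volts RMS, constant floor per channel
    rng_seed: int = 0
    bias_voltages: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.sample_rate < 2 * self.if_bandwidth:
            raise ValueError("sample_rate must be >= 2 * if_bandwidth")
        if not self.photons_per_volt > 0:
            raise ValueError("photons_per_volt must be positive")
        if len(self.channels) != 4:
            raise ValueError("exactly four mixer channels required")
        shifts = [c.nominal_shift for c in self.channels]
        if len(set(shifts)) != 4:
            raise ValueError("nominal shifts must be distinct")

    def resolved_bias_voltages(self) -> tuple[float, ...]:
        """Bias voltages in use; defaults to exact inversion of the true curves."""
        if self.bias_voltages is not None:
            return self.bias_voltages
        return tuple(c.bias_for_phase(c.nominal_shift) for c in self.channels)

    def achieved_phases(self) -> tuple[float, ...]:
        vb = self.resolved_bias_voltages()
        return tuple(float(c.achieved_phase(v)) for c, v in zip(self.channels, vb))

    def with_bias_voltages(self, voltages) -> "InstrumentConfig":
        cfg = copy.copy(self)
        object.__setattr__(cfg, "bias_voltages", tuple(float(v) for v in voltages))
        return cfg

    def with_seed(self, seed: int) -> "InstrumentConfig":
        cfg = copy.copy(self)
        object.__setattr__(cfg, "rng_seed", int(seed))
        return cfg


@dataclass
class SceneTimeline:
    """Per-sample phasor coordinates and photon rate of the fluorophore scene.

    ``g``, ``s`` and ``photon_rate`` may be scalars (static scene) or arrays
    sampled at the instrument rate.
    """

    g: np.ndarray | float
    s: np.ndarray | float
    photon_rate: np.ndarray | float  # photons/s

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.photon_rate) < 0):
            raise ValueError("photon rate must be non-negative everywhere")

    @classmethod
    def from_mixture(
        cls, mix: EmissionMixture, ctx: ModulationContext, photon_rate
    ) -> "SceneTimeline":
        p = mixture_phasor(mix, ctx)
        return cls(g=p.g, s=p.s, photon_rate=photon_rate)

    @classmethod
    def from_species(
        cls, species: FluorophoreSpecies, ctx: ModulationContext, photon_rate
    ) -> "SceneTimeline":
        p = single_exp_phasor(species.lifetime_ns, ctx)
        return cls(g=p.g, s=p.s, photon_rate=photon_rate)


@dataclass
class RawRecording:
    """Sampled voltages: DC intensity channel plus four mixer IF channels."""

    time: np.ndarray  # seconds
    vdc: np.ndarray  # volts
    vif: np.ndarray  # shape (4, n), ordered by nominal shift
    config_snapshot: InstrumentConfig

    def __post_init__(self) -> None:
        n = len(self.time)
        if self.vdc.shape != (n,) or self.vif.shape != (4, n):
            raise ValueError("time, vdc and vif lengths must agree")


@dataclass
class PhaseRampRecording:
    """VIF (and VDC) versus phase-shifter bias voltage, swept 0-10 V."""

    bias_voltage: np.ndarray
    vif: np.ndarray  # shape (4, n)
    vdc: float
    standard_lifetime_ns: float


@dataclass
class DarkRecording:
    """Shutter-closed recording used for offset calibration."""

    vdc: np.ndarray
    vif: np.ndarray  # shape (4, n)


def _shot_sigma(rate, config: InstrumentConfig):
    """Per-sample shot-noise RMS in volts on the DC channel.

    With N = rate*dt photons per sample and vdc-O_B = N/(ppv*dt), the Poisson
    std sqrt(N) maps to sqrt(rate*dt)/(ppv*dt) volts, scaled by the config
    constant.  SNR therefore grows as sqrt(rate).
    """
    dt = 1.0 / config.sample_rate
    return (
        config.shot_noise_scale
        * np.sqrt(np.asarray(rate, dtype=float) * dt)
        / (config.photons_per_volt * dt)
    )


def simulate_recording(
    scene: SceneTimeline,
    config: InstrumentConfig,
    duration: float,
    noisy: bool = True,
) -> RawRecording:
    """Render the five voltage channels for a scene.

    The noiseless expectation follows the closed-form harmonic model; shot
    noise (sigma proportional to sqrt(rate)) and a constant electronic floor
    are added as independent Gaussian perturbations per sample and channel.
    """
    n = int(round(duration * config.sample_rate))
    if n < 2:
        raise ValueError("duration too short: need at least 2 samples")
    dt = 1.0 / config.sample_rate
    time = np.arange(n) * dt

    rate = np.broadcast_to(np.asarray(scene.photon_rate, dtype=float), (n,))
    g = np.broadcast_to(np.asarray(scene.g, dtype=float), (n,))
    s = np.broadcast_to(np.asarray(scene.s, dtype=float), (n,))

    vdc = config.dc_offset_true + rate / config.photons_per_volt
    amp = config.true_conversion_gain * (vdc - config.dc_offset_true)
    thetas = config.achieved_phases()
    vif = np.empty((4, n))
    for i, (ch, th) in enumerate(zip(config.channels, thetas)):
        vif[i] = (
            config.common_offset
            + ch.channel_offset
            + amp * (g * np.sin(th) + s * np.cos(th))
        )

    if noisy:
        rng = np.random.default_rng(config.rng_seed)
        sig = _shot_sigma(rate, config)
        vdc = vdc + rng.normal(0.0, 1.0, n) * sig + rng.normal(
            0.0, config.electronic_noise_v, n
        )
        for i in range(4):
            vif[i] = (
                vif[i]
                + rng.normal(0.0, 1.0, n) * sig * config.true_conversion_gain
                + rng.normal(0.0, config.electronic_noise_v, n)
            )

    return RawRecording(time=time, vdc=vdc, vif=vif, config_snapshot=config)


def simulate_phase_ramp(
    config: InstrumentConfig,
    standard: FluorophoreSpecies,
    n_points: int = 2000,
    photon_rate: float = 5e6,
    samples_per_point: int = 1000,
    noisy: bool = False,
) -> PhaseRampRecording:
    """Sweep the shifter bias 0-10 V while measuring a lifetime standard.

    Each channel traces offset + amplitude*sin(phase(Vb) + arctan(omega*tau))
    with amplitude gain*(vdc-O_B)/sqrt(1+(omega*tau)^2).  With ``noisy``,
    each bias point is the average of ``samples_per_point`` raw samples, as
    in a slow hardware sweep through the 1 kHz IF filter.
    """
    bias = np.linspace(0.0, 10.0, n_points)
    p = single_exp_phasor(standard.lifetime_ns, config.ctx)
    vdc = config.dc_offset_true + photon_rate / config.photons_per_volt
    amp = config.true_conversion_gain * (vdc - config.dc_offset_true)
    vif = np.empty((4, n_points))
    for i, ch in enumerate(config.channels):
        phase = ch.achieved_phase(bias)
        vif[i] = (
            config.common_offset
            + ch.channel_offset
            + amp * (p.g * np.sin(phase) + p.s * np.cos(phase))
        )
    if noisy:
        rng = np.random.default_rng(config.rng_seed + 1)
        sig = float(_shot_sigma(photon_rate, config)) / math.sqrt(samples_per_point)
        sig = math.hypot(
            sig * config.true_conversion_gain,
            config.electronic_noise_v / math.sqrt(samples_per_point),
        )
        vif = vif + rng.normal(0.0, sig, vif.shape)
    return PhaseRampRecording(
        bias_voltage=bias,
        vif=vif,
        vdc=vdc,
        standard_lifetime_ns=standard.lifetime_ns,
    )


def simulate_dark(
    config: InstrumentConfig, duration: float = 10.0, noisy: bool = True
) -> DarkRecording:
    """Shutter-closed recording: only offsets plus electronic noise remain."""
    n = max(int(round(duration * config.sample_rate)), 1)
    vdc = np.full(n, config.dc_offset_true)
    vif = np.empty((4, n))
    for i, ch in enumerate(config.channels):
        vif[i] = config.common_offset + ch.channel_offset
    if noisy:
        rng = np.random.default_rng(config.rng_seed + 2)
        vdc = vdc + rng.normal(0.0, config.electronic_noise_v, n)
        vif = vif + rng.normal(0.0, config.electronic_noise_v, vif.shape)
    return DarkRecording(vdc=vdc, vif=vif)


def waveform_oracle(
    species: FluorophoreSpecies,
    config: InstrumentConfig,
    n_pulses: int = 200,
    samples_per_period: int = 4096,
    photon_rate: float = 5e6,
) -> dict:
    """Slow waveform-level check of the harmonic channel model.

    Builds the explicit periodic emission waveform (pulse train convolved
    with the exponential decay), keeps only DC plus the repetition-rate
    fundamental (the ideal 70 MHz low-pass), multiplies by each channel's
    phase-shifted reference sinusoid and time-averages, reproducing the
    mixer/IF-filter chain from first principles.

    Returns expected ``vdc`` and the four ``vif`` values for a static scene.
    """
    if n_pulses < 100:
        raise ValueError("n_pulses must be >= 100 for stable averaging")
    ctx = config.ctx
    period_s = 1.0 / ctx.modulation_frequency
    n = n_pulses * samples_per_period
    t = np.arange(n) * (period_s / samples_per_period)
    tau_s = species.lifetime_ns * NS
    # Periodized exponential decay: sum over all prior pulses has closed form
    # exp(-t_mod/tau) / (1 - exp(-T/tau)); normalized to unit mean.
    t_mod = np.mod(t, period_s)
    decay = np.exp(-t_mod / tau_s) / (1.0 - math.exp(-period_s / tau_s))
    decay = decay / decay.mean()

    vdc_expected = config.dc_offset_true + photon_rate / config.photons_per_volt
    f_volts = photon_rate / config.photons_per_volt

    # Ideal brick-wall filter at the fundamental: project onto DC + first
    # harmonic and reconstruct.
    w = ctx.angular_frequency
    c1 = 2.0 * np.mean(decay * np.cos(w * t))
    s1 = 2.0 * np.mean(decay * np.sin(w * t))
    ac = c1 * np.cos(w * t) + s1 * np.sin(w * t)  # mean-removed filtered signal

    thetas = config.achieved_phases()
    vif = []
    for ch, th in zip(config.channels, thetas):
        lo = np.sin(w * t + th)
        mixed = config.true_conversion_gain * f_volts * np.mean(ac * lo)
        vif.append(config.common_offset + ch.channel_offset + mixed)
    return {"vdc": vdc_expected, "vif": np.array(vif)}


def simulate_tcspc_histogram(
    lifetime_ns: float,
    photons_per_pulse: float,
    n_pulses: int,
    rng: np.random.Generator,
    bin_width_ns: float = 0.05,
    ctx: ModulationContext | None = None,
):
    """TCSPC reference measurement with photon pileup.

    Per excitation cycle the number of detected photons is Poisson with mean
    ``photons_per_pulse``; only the first photon is time-stamped (the minimum
    of k iid exponentials, itself exponential with mean tau/k).  Arrival
    times wrap at the laser period.  As the rate rises the recorded
    distribution compresses toward early times, biasing the mean-arrival-time
    lifetime estimate downward -- the classic pileup artifact.

    Returns ``(bin_times_ns, counts)`` for use with the histogram estimators.
    """
    if lifetime_ns <= 0:
        raise ValueError("lifetime must be positive")
    ctx = ctx or ModulationContext()
    period_ns = ctx.period_ns
    k = rng.poisson(photons_per_pulse, n_pulses)
    k = k[k >= 1]
    # min of k iid Exp(mean tau) is Exp(mean tau/k)
    arrivals = rng.exponential(lifetime_ns / k)
    arrivals = np.mod(arrivals, period_ns)
    n_bins = int(math.ceil(period_ns / bin_width_ns))
    counts, edges = np.histogram(
        arrivals, bins=n_bins, range=(0.0, n_bins * bin_width_ns)
    )
    bin_times = 0.5 * (edges[:-1] + edges[1:])
    return bin_times, counts
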