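"""Lifetime, intensity and phasor estimators.

The analog instrument's four IF voltages encode the sine/cosine quadratures
of the fluorescence fundamental.  With the calibration constants in hand the
per-sample estimators are pure arithmetic:

    tau = (1/omega) * (vif1 - vif3 - d13) / (vif2 - vif4 - d24)
    F   = vdc - O_B
    g   = (vif2 - vif4 - d24) / (2 * F * MB)
    s   = (vif1 - vif3 - d13) / (2 * F * MB)

(The opposed-channel subtractions cancel the shared, intensity-dependent IF
offset, keeping the estimate stable across photon rates.)  Channels 1 and 3
(shifts 0 and pi) always pair through d13, channels 2 and 4 (pi/2 and 3pi/2)
through d24.

Histogram-based estimators for the time-domain reference instruments are
also provided: the mean-arrival-time lifetime of a TCSPC photon histogram
(with a truncation window rejecting delayed reflection autofluorescence) and
the per-frame mean lifetime of a 31-bin imaging histogram.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .calibration import CalibrationResult
from .instrument import RawRecording
from .phasor import NS, ModulationContext

__all__ = [
    "LifetimeTrace",
    "DecayHistogram",
    "estimate_trace",
    "tcspc_mean_lifetime",
    "flim_frame_lifetime",
    "moving_mean_downsample",
    "downsample_recording",
]


@dataclass
class LifetimeTrace:
    """Time series of lifetime, baseline-corrected intensity, and phasor."""

    time: np.ndarray  # seconds
    lifetime_ns: np.ndarray
    intensity: np.ndarray  # volts, vdc - O_B
    g: np.ndarray
    s: np.ndarray
    rate: float  # Hz

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("lifetime_ns", "intensity", "g", "s"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time")

    @property
    def duration(self) -> float:
        return len(self.time) / self.rate


@dataclass
class DecayHistogram:
    """TCSPC photon-arrival histogram relative to the laser pulse."""

    bin_times_ns: np.ndarray
    counts: np.ndarray
    truncation_window_ns: tuple[float, float] = (0.0, 8.0)
    smoothing_bins: int = 3

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        lo, hi = self.truncation_window_ns
        if not lo < hi:
            raise ValueError("truncation window must be a non-empty interval")

    def t0_ns(self) -> float:
        """Peak position: max-count bin after light boxcar smoothing.

        Stands in for the peak of a fitted exponential; smoothing keeps a
        single noisy bin from displacing the peak.
        """
        smooth = uniform_filter1d(
            self.counts.astype(float), size=max(self.smoothing_bins, 1), mode="nearest"
        )
        return float(self.bin_times_ns[int(np.argmax(smooth))])


def estimate_trace(
    rec: RawRecording,
    cal: CalibrationResult,
    ctx: ModulationContext | None = None,
    denominator_floor_scale: float = 1e-6,
) -> LifetimeTrace:
    """Convert a raw recording into a lifetime/intensity/phasor trace.

    Samples where the lifetime denominator |vif2 - vif4 - d24| falls below
    ``denominator_floor_scale * conversion_gain`` (no usable modulated
    signal, e.g. a dark stretch) are masked to NaN.
    """
    if cal is None:
        raise ValueError("calibration is required")
    ctx = ctx or rec.config_snapshot.ctx
    omega = ctx.angular_frequency

    numer = rec.vif[0] - rec.vif[2] - cal.d13  # sine quadrature, volts
    denom = rec.vif[1] - rec.vif[3] - cal.d24  # cosine quadrature, volts
    intensity = rec.vdc - cal.dc_offset

    floor = denominator_floor_scale * cal.conversion_gain
    bad = np.abs(denom) < floor
    if bad.all():
        warnings.warn("all samples below denominator floor; trace is all-NaN")

    with np.errstate(divide="ignore", invalid="ignore"):
        lifetime = np.where(bad, np.nan, numer / np.where(bad, np.nan, denom)) / omega
        norm = 2.0 * intensity * cal.conversion_gain
        norm = np.where(np.abs(norm) < floor, np.nan, norm)
        g = denom / norm
        s = numer / norm

    return LifetimeTrace(
        time=rec.time.copy(),
        lifetime_ns=lifetime / NS,
        intensity=intensity,
        g=g,
        s=s,
        rate=rec.config_snapshot.sample_rate,
    )


def tcspc_mean_lifetime(h: DecayHistogram) -> float:
    """Mean photon arrival time after t0, within the truncation window (ns).

    tau = sum(t * F(t)) / sum(F(t)) - t0 over bins with t - t0 inside the
    window.  The window's upper edge rejects delayed reflection
    autofluorescence from the fiber path.
    """
    t0 = h.t0_ns()
    rel = h.bin_times_ns - t0
    lo, hi = h.truncation_window_ns
    inside = (rel >= lo) & (rel <= hi)
    total = h.counts[inside].sum()
    if total <= 0:
        raise ValueError("no photons inside the truncation window")
    mean_t = float(np.dot(h.bin_times_ns[inside], h.counts[inside]) / total)
    return mean_t - t0


def flim_frame_lifetime(bin_counts, bin_width_ns: float = 0.391) -> float:
    """Frame lifetime from an imaging photon histogram (ns).

    tau = sum(F(t)*t)/sum(F(t)) with t the bin times (bin index times the
    0.391 ns bin width, counted from the laser pulse).
    """
    counts = np.asarray(bin_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero photons in frame")
    t = (np.arange(len(counts)) + 1) * bin_width_ns
    return float(np.dot(counts, t) / total)


def downsample_recording(rec: RawRecording, target_rate: float) -> RawRecording:
    """Boxcar-average the raw voltages down to ``target_rate``.

    Averaging the voltages *before* forming the lifetime ratio avoids the
    small positive ratio bias that appears when noisy per-sample lifetimes
    are averaged instead (E[N/D] > E[N]/E[D] for independent noise on the
    denominator); it is the digital analogue of sampling the DAQ slower.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    fs = rec.config_snapshot.sample_rate
    if target_rate > fs:
        raise ValueError("target_rate exceeds the recording rate")
    k = int(round(fs / target_rate))
    if k == 1:
        return rec
    n = (len(rec.time) // k) * k
    if n == 0:
        raise ValueError("recording shorter than one downsampling window")

    def box(x):
        return x[:n].reshape(-1, k).mean(axis=1)

    import copy

    config = copy.copy(rec.config_snapshot)
    object.__setattr__(config, "sample_rate", fs / k)
    object.__setattr__(config, "if_bandwidth", min(config.if_bandwidth, fs / (2 * k)))
    return RawRecording(
        time=box(rec.time),
        vdc=box(rec.vdc),
        vif=np.stack([box(rec.vif[i]) for i in range(4)]),
        config_snapshot=config,
    )


def moving_mean_downsample(trace: LifetimeTrace, target_rate: float) -> LifetimeTrace:
    """Non-overlapping boxcar average down to ``target_rate``.

    The window is rate/target_rate samples (rounded); a partial trailing
    window is dropped.  Independent-noise variance therefore falls exactly
    as 1/k for a k-fold reduction.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > trace.rate:
        raise ValueError("target_rate exceeds the trace rate")
    k = int(round(trace.rate / target_rate))
    if k == 1:
        return trace
    n = (len(trace.time) // k) * k
    if n == 0:
        raise ValueError("trace shorter than one downsampling window")

    def box(x):
        return x[:n].reshape(-1, k).mean(axis=1)

    return LifetimeTrace(
        time=box(trace.time),
        lifetime_ns=box(trace.lifetime_ns),
        intensity=box(trace.intensity),
        g=box(trace.g),
        s=box(trace.s),
        rate=trace.rate / k,
    )
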