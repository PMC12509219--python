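"""Session-level signal analysis: tonic baseline, phasic transients, SNR.

Neuromodulator signals decompose into a slow *tonic* component (baseline
level over tens of seconds to minutes) and fast *phasic* transients locked
to behavioral events.  The operations here implement that decomposition for
lifetime traces:

- a centered 60 s rolling-median baseline tracks tonic level while
  rejecting brief transients;
- epoch means relative to the prior-2-minute baseline quantify slow shifts
  during a stimulus period;
- event-aligned snippets with a -2..0 s pre-event baseline subtraction
  extract phasic transients, their peak amplitudes and SNR (mean peak over
  mean per-event baseline standard deviation);
- a downsampling comparison shows how boxcar averaging to low rates
  attenuates short transients;
- an intensity-weighted correction removes a known autofluorescence
  contribution from an observed lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import LifetimeTrace, moving_mean_downsample

__all__ = [
    "EventSet",
    "TonicResult",
    "PhasicResult",
    "autofluorescence_correct",
    "rolling_median_baseline",
    "epoch_tonic_change",
    "event_aligned_transients",
    "downsample_compare",
    "compute_snr",
    "lifetime_spectrum",
]


@dataclass
class EventSet:
    """Behavioral event timestamps with category labels."""

    event_times: np.ndarray  # seconds
    labels: tuple[str, ...] = ()
    epoch: tuple[float, float] | None = None  # stimulus period, seconds

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if not np.all(np.diff(self.event_times) >= 0):
            raise ValueError("event times must be sorted")
        if self.labels and len(self.labels) != len(self.event_times):
            raise ValueError("one label per event required")

    def select(self, label: str) -> "EventSet":
        mask = np.array([lb == label for lb in self.labels])
        return EventSet(
            event_times=self.event_times[mask],
            labels=tuple(lb for lb in self.labels if lb == label),
            epoch=self.epoch,
        )


@dataclass
class TonicResult:
    """Rolling-median tonic baseline and its change from a reference."""

    time: np.ndarray
    baseline_ns: np.ndarray
    delta_baseline_ns: np.ndarray
    reference_interval: tuple[float, float]


@dataclass
class PhasicResult:
    """Event-aligned, baseline-subtracted transients."""

    relative_time: np.ndarray  # seconds, spans [-pre, post)
    snippets: np.ndarray  # (n_events, n_samples), baseline-subtracted
    mean_transient_ns: np.ndarray
    sem_transient_ns: np.ndarray
    peak_delta_ns: np.ndarray  # per event, signed
    baseline_sd_ns: np.ndarray  # per event, SD over the pre-event window
    used_event_times: np.ndarray


def autofluorescence_correct(
    observed_lifetime_ns,
    observed_intensity,
    af_lifetime_ns: float,
    af_intensity,
):
    """Remove a known autofluorescence term from an observed lifetime.

    The observed lifetime is the intensity-weighted average of the sensor
    and autofluorescence lifetimes; solving for the sensor term gives

        tau_sensor = (tau_obs*I_obs - tau_af*I_af) / (I_obs - I_af).
    """
    tau_obs = np.asarray(observed_lifetime_ns, dtype=float)
    i_obs = np.asarray(observed_intensity, dtype=float)
    i_af = np.asarray(af_intensity, dtype=float)
    if np.any(i_af < 0):
        raise ValueError("autofluorescence intensity must be non-negative")
    if np.any(i_obs <= i_af):
        raise ValueError(
            "uncorrectable: observed intensity must exceed the "
            "autofluorescence intensity"
        )
    out = (tau_obs * i_obs - af_lifetime_ns * i_af) / (i_obs - i_af)
    return float(out) if out.ndim == 0 else out


def rolling_median_baseline(
    trace: LifetimeTrace,
    window_s: float = 60.0,
    reference_interval: tuple[float, float] | None = None,
) -> TonicResult:
    """Centered rolling-median tonic baseline, truncated at the edges.

    The median's robustness leaves brief phasic transients out of the
    baseline as long as they occupy less than half the window.
    ``delta_baseline`` subtracts the baseline's mean over
    ``reference_interval`` (default: the first ``window_s`` seconds).
    """
    n = len(trace.time)
    if n == 0:
        raise ValueError("empty trace")
    w = int(round(window_s * trace.rate))
    if w > n:
        raise ValueError("window longer than the trace")
    baseline = (
        pd.Series(trace.lifetime_ns)
        .rolling(window=max(w, 1), center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    if reference_interval is None:
        reference_interval = (float(trace.time[0]), float(trace.time[0]) + window_s)
    lo, hi = reference_interval
    ref_mask = (trace.time >= lo) & (trace.time < hi)
    if not ref_mask.any():
        raise ValueError("reference interval contains no samples")
    ref = float(np.nanmean(baseline[ref_mask]))
    return TonicResult(
        time=trace.time.copy(),
        baseline_ns=baseline,
        delta_baseline_ns=baseline - ref,
        reference_interval=(lo, hi),
    )


def epoch_tonic_change(
    tonic: TonicResult,
    epoch: tuple[float, float],
    baseline_minutes: float = 2.0,
) -> float:
    """Mean tonic baseline during an epoch minus the prior-baseline mean (ns)."""
    t = tonic.time
    e_lo, e_hi = epoch
    b_lo, b_hi = e_lo - baseline_minutes * 60.0, e_lo
    epoch_mask = (t >= e_lo) & (t < e_hi)
    base_mask = (t >= b_lo) & (t < b_hi)
    if not epoch_mask.any() or not base_mask.any():
        raise ValueError("epoch or prior baseline window outside the trace")
    return float(
        np.nanmean(tonic.baseline_ns[epoch_mask])
        - np.nanmean(tonic.baseline_ns[base_mask])
    )


def event_aligned_transients(
    trace: LifetimeTrace,
    events: EventSet,
    pre_s: float = 2.0,
    post_s: float = 10.0,
) -> PhasicResult:
    """Extract baseline-subtracted snippets around each event.

    Each snippet spans [-pre_s, post_s) around its event; its mean over
    [-pre_s, 0) is subtracted.  Events without full coverage are dropped.
    The per-event peak is read at the time of the mean transient's signed
    extremum, so all events are measured at a common latency with a common
    polarity.
    """
    n_pre = int(round(pre_s * trace.rate))
    n_post = int(round(post_s * trace.rate))
    t0 = trace.time[0]
    used, snippets = [], []
    for et in events.event_times:
        i = int(round((et - t0) * trace.rate))
        if i - n_pre < 0 or i + n_post > len(trace.time):
            continue
        seg = trace.lifetime_ns[i - n_pre : i + n_post].astype(float)
        base = np.nanmean(seg[:n_pre])
        snippets.append(seg - base)
        used.append(et)
    if not snippets:
        raise ValueError("no events with full pre/post coverage")
    snippets = np.asarray(snippets)
    rel_time = (np.arange(-n_pre, n_post)) / trace.rate
    mean_tr = np.nanmean(snippets, axis=0)
    sem_tr = np.nanstd(snippets, axis=0, ddof=1) / np.sqrt(len(snippets)) if len(
        snippets
    ) > 1 else np.zeros_like(mean_tr)

    post_mask = rel_time >= 0
    post_mean = mean_tr[post_mask]
    peak_idx = int(np.nanargmax(np.abs(post_mean)))
    baseline_sd = np.nanstd(snippets[:, :n_pre], axis=1, ddof=1)
    peak_col = np.flatnonzero(post_mask)[peak_idx]
    peak_delta = snippets[:, peak_col]
    return PhasicResult(
        relative_time=rel_time,
        snippets=snippets,
        mean_transient_ns=mean_tr,
        sem_transient_ns=sem_tr,
        peak_delta_ns=peak_delta,
        baseline_sd_ns=baseline_sd,
        used_event_times=np.asarray(used),
    )


def downsample_compare(
    trace: LifetimeTrace,
    events: EventSet,
    rates,
    pre_s: float = 2.0,
    post_s: float = 10.0,
) -> dict:
    """Mean peak transient amplitude after downsampling to each rate.

    Boxcar averaging to rates comparable to the transient's inverse width
    attenuates and distorts the measured peak, which is why acquisition
    faster than the transient matters.
    Returns ``{rate: mean signed peak delta (ns)}``.
    """
    out = {}
    for rate in rates:
        ds = moving_mean_downsample(trace, rate)
        phasic = event_aligned_transients(ds, events, pre_s=pre_s, post_s=post_s)
        out[rate] = float(np.nanmean(phasic.peak_delta_ns))
    return out


def compute_snr(phasic: PhasicResult) -> float:
    """Mean peak signal divided by the mean per-event baseline SD."""
    if len(phasic.peak_delta_ns) == 0:
        raise ValueError("at least one event required")
    mean_sd = float(np.nanmean(phasic.baseline_sd_ns))
    mean_peak = float(np.abs(np.nanmean(phasic.peak_delta_ns)))
    if mean_sd == 0:
        return float("inf")
    return mean_peak / mean_sd


def lifetime_spectrum(trace: LifetimeTrace):
    """One-sided magnitude spectrum of the lifetime series.

    Thin utility for inspecting where signal and noise power live; makes no
    statistical claims.  Returns ``(frequency_hz, magnitude)``.
    """
    x = trace.lifetime_ns - np.nanmean(trace.lifetime_ns)
    x = np.nan_to_num(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / trace.rate)
    mag = np.abs(np.fft.rfft(x)) / len(x)
    return freqs, mag
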