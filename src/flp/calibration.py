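"""Four-stage calibration of the analog lifetime photometry unit.

The instrument is calibrated against a fluorescence lifetime standard
(coumarin 6, lifetime 2.39-2.41 ns) measured through the same fiber as the
experiment:

1. *Phase curves*: a 0-10 V ramp over each phase shifter traces a sinusoid
   in each VIF channel.  Normalizing by the observed span and taking the
   arcsine recovers the achieved phase up to branch; subtracting the
   standard's known phase lag arctan(omega*tau_std) anchors phase zero at
   instantaneous (0 ns) lifetime.  A polynomial fit of the unwrapped branch
   suppresses electrical noise.
2. *Bias voltages*: the fitted curves are inverted to find the control
   voltages at which the four channels achieve 0, pi/2, pi and 3pi/2.
3. *Dark offsets*: with the PMT shuttered, the DC offset O_B and the
   channel-difference offsets d13 = d1-d3, d24 = d2-d4 are read off as
   channel means (the common IF offset cancels in the differences).
4. *Conversion gain*: the ramp's span per channel gives the combined
   mixer/bias-tee gain M*B = (VIFmax-VIFmin)/(2*(VDC-O_B)) * sqrt(1+(wt)^2),
   averaged over channels.

Following the hardware procedure, the bias voltages are re-determined after
the offsets are known.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq

from .instrument import NOMINAL_SHIFTS, DarkRecording, PhaseRampRecording
from .phasor import FluorophoreSpecies, ModulationContext

__all__ = [
    "PhaseCurveFit",
    "CalibrationResult",
    "fit_phase_curves",
    "solve_bias_voltages",
    "measure_dark_offsets",
    "measure_conversion_gain",
    "calibrate",
]

#: Coumarin 6 in ethanol, the standard used to anchor phase zero.
DEFAULT_STANDARD_LIFETIME_NS = 2.40

_ARG_WARN_TOL = 1e-6
_ARG_ERROR_TOL = 1e-2


@dataclass
class PhaseCurveFit:
    """Fitted phase-vs-bias polynomial for one channel."""

    coefficients: tuple[float, ...]  # ascending power order
    residual_rms_rad: float
    bias_range: tuple[float, float]

    def __call__(self, bias):
        return np.polynomial.polynomial.polyval(
            np.asarray(bias, dtype=float), np.asarray(self.coefficients)
        )


@dataclass
class CalibrationResult:
    """Everything needed to turn raw voltages into lifetime and phasor."""

    dc_offset: float  # O_B, volts
    d13: float  # volts
    d24: float  # volts
    conversion_gain: float  # M*B, volts/volt, channel average
    conversion_gain_per_channel: tuple[float, ...] = ()
    bias_voltages: tuple[float, ...] = ()
    phase_polynomials: tuple[PhaseCurveFit, ...] = ()
    standard_lifetime_ns: float = DEFAULT_STANDARD_LIFETIME_NS

    def __post_init__(self) -> None:
        if not self.conversion_gain > 0:
            raise ValueError("conversion_gain must be positive")

    def to_json(self, path=None) -> str:
        payload = {
            "dc_offset": self.dc_offset,
            "d13": self.d13,
            "d24": self.d24,
            "conversion_gain": self.conversion_gain,
            "conversion_gain_per_channel": list(self.conversion_gain_per_channel),
            "bias_voltages": list(self.bias_voltages),
            "phase_polynomials": [
                {
                    "coefficients": list(p.coefficients),
                    "residual_rms_rad": p.residual_rms_rad,
                    "bias_range": list(p.bias_range),
                }
                for p in self.phase_polynomials
            ],
            "standard_lifetime_ns": self.standard_lifetime_ns,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationResult":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        polys = tuple(
            PhaseCurveFit(
                coefficients=tuple(p["coefficients"]),
                residual_rms_rad=p["residual_rms_rad"],
                bias_range=tuple(p["bias_range"]),
            )
            for p in payload.get("phase_polynomials", [])
        )
        return cls(
            dc_offset=payload["dc_offset"],
            d13=payload["d13"],
            d24=payload["d24"],
            conversion_gain=payload["conversion_gain"],
            conversion_gain_per_channel=tuple(
                payload.get("conversion_gain_per_channel", ())
            ),
            bias_voltages=tuple(payload.get("bias_voltages", ())),
            phase_polynomials=polys,
            standard_lifetime_ns=payload.get(
                "standard_lifetime_ns", DEFAULT_STANDARD_LIFETIME_NS
            ),
        )


def _refined_extremes(v: np.ndarray) -> tuple[float, float]:
    """(vmax, vmin) of a sampled sinusoid, robust to noise and sampling.

    Extremes are located on a lightly smoothed copy of the trace and refined
    by a local parabola fit on the raw samples: raw extremes of a noisy
    sweep are biased outward by the noise, smoothed extremes are biased
    inward by peak flattening, and the discrete sample grid misses the true
    peak; the parabola vertex avoids all three.
    """
    n = len(v)
    k = max(n // 50, 1)
    v_smooth = uniform_filter1d(v, size=k, mode="nearest")

    def refine(idx: int, sign: float) -> float:
        half = max(n // 40, 2)
        lo, hi = max(idx - half, 0), min(idx + half + 1, n)
        x = np.arange(lo, hi, dtype=float)
        c = np.polynomial.polynomial.polyfit(x, v[lo:hi], 2)
        if c[2] * sign < 0 and abs(c[2]) > 0:
            vertex = -c[1] / (2.0 * c[2])
            if lo <= vertex <= hi:
                return float(np.polynomial.polynomial.polyval(vertex, c))
        return float(v_smooth[idx])

    return refine(int(np.argmax(v_smooth)), +1.0), refine(int(np.argmin(v_smooth)), -1.0)


def _normalized_argument(v: np.ndarray) -> np.ndarray:
    """Map a channel's VIF trace onto the arcsine argument in [-1, 1].

    The sinusoid's max/min come from :func:`_refined_extremes`.
    """
    vmax, vmin = _refined_extremes(v)
    span = vmax - vmin
    if span <= 0 or span < 1e-12 * max(abs(vmax), 1.0):
        raise ValueError("degenerate ramp: channel span is zero (flat channel)")
    arg = (2.0 * v - (vmax + vmin)) / span
    excess = np.max(np.abs(arg)) - 1.0
    if excess > _ARG_ERROR_TOL:
        raise ValueError(
            f"arcsine argument exceeds [-1, 1] by {excess:.3g}; ramp inconsistent"
        )
    if excess > _ARG_WARN_TOL:
        warnings.warn(
            f"arcsine argument exceeds [-1, 1] by {excess:.3g}; clipping",
            stacklevel=3,
        )
    return np.clip(arg, -1.0, 1.0)


def _unwrap_monotone_arcsin(arg: np.ndarray) -> np.ndarray:
    """Reconstruct a monotone-increasing phase from sin(phase) samples.

    The sweep is assumed to drive the (monotone) shifter through more than a
    full turn, so the sinusoid alternates rising and falling segments.  On
    rising segments the phase sits on a principal branch 2m*pi + arcsin, on
    falling segments on (2m+1)*pi - arcsin.  The initial phase is assumed to
    lie in (-pi/2, 3pi/2), which holds for shifters whose curve starts near
    zero phase.
    """
    n = len(arg)
    # sin(psi) is given; the sign of cos(psi) follows from the sweep
    # direction: psi is monotone increasing, so d sin(psi)/d bias has the
    # sign of cos(psi).  Near the extremes cos(psi) ~ 0, so a noisy sign
    # there perturbs the reconstructed angle only marginally.
    k = max(min(n // 50, 25), 2)
    smooth = uniform_filter1d(arg, size=k, mode="nearest")
    slope = uniform_filter1d(np.gradient(smooth), size=k, mode="nearest")
    cos_psi = np.sign(slope) * np.sqrt(np.clip(1.0 - arg * arg, 0.0, None))
    psi = np.unwrap(np.arctan2(arg, cos_psi))
    # Anchor the 2*pi branch: the sweep is assumed to start at a phase in
    # (-pi/2, 3*pi/2), which holds for shifter curves starting near zero.
    if psi[0] < -0.5 * math.pi:
        psi += 2.0 * math.pi * math.ceil((-0.5 * math.pi - psi[0]) / (2 * math.pi))
    return psi


def fit_phase_curves(
    ramp: PhaseRampRecording,
    ctx: ModulationContext,
    order: int = 7,
    drop_extreme_fraction: float = 0.995,
) -> tuple[PhaseCurveFit, ...]:
    """Extract and polynomial-fit the phase-vs-bias curve of each channel.

    Points where |arcsine argument| exceeds ``drop_extreme_fraction`` are
    excluded from the least-squares fit: near the sinusoid extremes the
    arcsine amplifies electrical noise without bound.

    The sinusoid's offset and amplitude are refined iteratively: after an
    initial polynomial fit of the phase, the channel voltage is regressed
    linearly on sin(fitted phase) to re-estimate (offset, amplitude), the
    normalized argument is recomputed, and the phase is refit.  This removes
    the small systematic span error of the initial max/min normalization,
    which otherwise tilts the recovered curve near the turning points.
    """
    wt = float(ctx.omega_tau(ramp.standard_lifetime_ns))
    lag = math.atan(wt)
    fits = []
    for i in range(4):
        v = ramp.vif[i]
        arg = _normalized_argument(v)
        for _ in range(3):
            psi = _unwrap_monotone_arcsin(arg)
            keep = np.abs(arg) <= drop_extreme_fraction
            series = np.polynomial.Polynomial.fit(
                ramp.bias_voltage[keep], psi[keep], deg=order
            )
            # Refine offset/amplitude against the fitted phase model.
            model = np.sin(series(ramp.bias_voltage))
            design = np.column_stack([np.ones_like(model), model])
            (offset, amplitude), *_ = np.linalg.lstsq(design, v, rcond=None)
            if amplitude <= 0:
                raise ValueError("degenerate ramp: fitted amplitude non-positive")
            arg = np.clip((v - offset) / amplitude, -1.0, 1.0)
        phase = psi - lag
        series = np.polynomial.Polynomial.fit(
            ramp.bias_voltage[keep], phase[keep], deg=order
        )
        resid = phase[keep] - series(ramp.bias_voltage[keep])
        fits.append(
            PhaseCurveFit(
                coefficients=tuple(series.convert().coef),
                residual_rms_rad=float(np.sqrt(np.mean(resid**2))),
                bias_range=(
                    float(ramp.bias_voltage.min()),
                    float(ramp.bias_voltage.max()),
                ),
            )
        )
    return tuple(fits)


def solve_bias_voltages(
    phase_polynomials: tuple[PhaseCurveFit, ...],
    targets=NOMINAL_SHIFTS,
    residual_tol: float = 1e-4,
) -> tuple[float, ...]:
    """Find the bias voltage at which each channel attains its target phase."""
    voltages = []
    for fit, target in zip(phase_polynomials, targets):
        lo, hi = fit.bias_range
        flo, fhi = float(fit(lo)) - target, float(fit(hi)) - target
        if flo * fhi > 0:
            raise ValueError(
                f"target phase {target:.4f} rad outside achievable range "
                f"[{float(fit(lo)):.4f}, {float(fit(hi)):.4f}]"
            )
        vb = brentq(lambda v: float(fit(v)) - target, lo, hi, xtol=1e-10)
        if abs(float(fit(vb)) - target) > residual_tol:
            raise ValueError("bias solve did not converge to requested tolerance")
        voltages.append(float(vb))
    return tuple(voltages)


def measure_dark_offsets(dark: DarkRecording) -> tuple[float, float, float]:
    """(O_B, d13, d24) from a shutter-closed recording.

    The shared IF offset appears identically on all four channels, so the
    1-3 and 2-4 differences isolate the channel-specific terms.
    """
    if dark.vdc.size == 0:
        raise ValueError("dark recording is empty")
    means = dark.vif.mean(axis=1)
    return (
        float(dark.vdc.mean()),
        float(means[0] - means[2]),
        float(means[1] - means[3]),
    )


def measure_conversion_gain(
    ramp: PhaseRampRecording,
    dc_offset: float,
    ctx: ModulationContext,
) -> tuple[float, tuple[float, ...]]:
    """Combined mixer/bias-tee gain M*B from the ramp's per-channel span.

    The sinusoid's span is 2*gain*(VDC-O_B)/sqrt(1+(wt)^2); inverting and
    averaging across the four channels gives the scalar gain used in the
    phasor formulas, with the per-channel values kept as a dispersion
    diagnostic.
    """
    f = ramp.vdc - dc_offset
    if f <= 0:
        raise ValueError("no light: ramp VDC does not exceed the DC offset")
    wt = float(ctx.omega_tau(ramp.standard_lifetime_ns))
    demod = math.sqrt(1.0 + wt * wt)
    per_channel = []
    for i in range(4):
        vmax, vmin = _refined_extremes(ramp.vif[i])
        per_channel.append(float((vmax - vmin) / (2.0 * f) * demod))
    per_channel = tuple(per_channel)
    return float(np.mean(per_channel)), per_channel


def calibrate(
    ramp: PhaseRampRecording,
    dark: DarkRecording,
    standard: FluorophoreSpecies | None = None,
    ctx: ModulationContext | None = None,
    order: int = 7,
) -> CalibrationResult:
    """Run the full calibration sequence and assemble the result.

    Stage order follows the hardware procedure: phase-curve fit, dark
    offsets, bias re-determination with offsets known, then conversion gain.
    (Offsets enter the normalized arcsine argument symmetrically, so the
    re-determination is a consistency pass rather than a correction.)
    """
    ctx = ctx or ModulationContext()
    std_tau = standard.lifetime_ns if standard else ramp.standard_lifetime_ns
    if standard is not None and abs(std_tau - ramp.standard_lifetime_ns) > 1e-9:
        warnings.warn(
            "standard lifetime differs from the one recorded with the ramp; "
            "using the explicitly supplied value",
            stacklevel=2,
        )
        ramp = PhaseRampRecording(
            bias_voltage=ramp.bias_voltage,
            vif=ramp.vif,
            vdc=ramp.vdc,
            standard_lifetime_ns=std_tau,
        )
    polys = fit_phase_curves(ramp, ctx, order=order)
    dc_offset, d13, d24 = measure_dark_offsets(dark)
    bias = solve_bias_voltages(polys)
    gain, per_channel = measure_conversion_gain(ramp, dc_offset, ctx)
    return CalibrationResult(
        dc_offset=dc_offset,
        d13=d13,
        d24=d24,
        conversion_gain=gain,
        conversion_gain_per_channel=per_channel,
        bias_voltages=bias,
        phase_polynomials=polys,
        standard_lifetime_ns=std_tau,
    )
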