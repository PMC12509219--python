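"""Closed-form photophysics for frequency-domain lifetime measurement.

A fluorophore excited by a pulsed laser re-emits with an exponential delay
distribution of mean ``tau`` (the fluorescence lifetime).  At a modulation
(repetition) frequency ``f`` with angular frequency ``omega = 2*pi*f`` the
normalized first-harmonic Fourier projections of the emission,

    g = 1 / (1 + (omega*tau)**2)
    s = omega*tau / (1 + (omega*tau)**2)

define the *phasor* of the decay.  Every single-exponential decay lands on
the "universal circle" of radius 0.5 centered at (0.5, 0); any non-negative
mixture of lifetimes lands at the intensity-weighted convex combination of
its components' phasors, strictly inside the circle when two distinct
lifetimes contribute.

All public interfaces take lifetimes in nanoseconds and frequencies in hertz;
the ``ModulationContext`` is the single place where the two are combined into
the dimensionless product ``omega*tau``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModulationContext",
    "PhasorPoint",
    "FluorophoreSpecies",
    "EmissionMixture",
    "single_exp_phasor",
    "mixture_phasor",
    "phase_lifetime",
    "intensity_weighted_lifetime",
]

NS = 1e-9  # seconds per nanosecond


@dataclass(frozen=True)
class ModulationContext:
    """Modulation (laser repetition) frequency and derived angular frequency.

    The default 50 MHz corresponds to a standard picosecond pulsed diode
    laser; the repetition-rate fundamental is the sole analysis frequency
    because the analog chain low-pass filters away all higher harmonics.
    """

    modulation_frequency: float = 50e6  # Hz

    def __post_init__(self) -> None:
        if not self.modulation_frequency > 0:
            raise ValueError("modulation_frequency must be positive")

    @property
    def angular_frequency(self) -> float:
        """omega in rad/s."""
        return 2.0 * math.pi * self.modulation_frequency

    @property
    def period_ns(self) -> float:
        return 1e9 / self.modulation_frequency

    def omega_tau(self, lifetime_ns):
        """Dimensionless omega*tau for a lifetime given in nanoseconds."""
        return self.angular_frequency * np.asarray(lifetime_ns) * NS


@dataclass(frozen=True)
class PhasorPoint:
    """Normalized first-harmonic Fourier coordinates (g: cosine, s: sine)."""

    g: float
    s: float

    def radius_from_center(self) -> float:
        """Distance from the universal-circle center (0.5, 0)."""
        return math.hypot(self.g - 0.5, self.s)


@dataclass(frozen=True)
class FluorophoreSpecies:
    """A single-exponential emitter.

    ``relative_brightness`` is a per-molecule emission weight used when
    composing mixtures from molecular fractions; intensity fractions in
    :class:`EmissionMixture` are already photon-weighted so brightness does
    not enter the phasor arithmetic there.
    """

    name: str
    lifetime_ns: float
    relative_brightness: float = 1.0

    def __post_init__(self) -> None:
        if not self.lifetime_ns > 0:
            raise ValueError(f"lifetime must be positive, got {self.lifetime_ns}")
        if not self.relative_brightness > 0:
            raise ValueError("relative_brightness must be positive")


_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class EmissionMixture:
    """Species with intensity (photon) fractions summing to one."""

    species: tuple[FluorophoreSpecies, ...]
    intensity_fractions: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.species) == 0:
            raise ValueError("mixture needs at least one species")
        fracs = self.intensity_fractions
        if len(fracs) == 0:
            fracs = tuple(1.0 / len(self.species) for _ in self.species)
            object.__setattr__(self, "intensity_fractions", fracs)
        if len(fracs) != len(self.species):
            raise ValueError("one intensity fraction per species required")
        if any(f < -_FRACTION_TOL for f in fracs):
            raise ValueError("intensity fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > _FRACTION_TOL:
            raise ValueError("intensity fractions must sum to 1")


def single_exp_phasor(lifetime_ns: float, ctx: ModulationContext) -> PhasorPoint:
    """Phasor of a single-exponential decay; lies on the universal circle.

    g = 1/(1+(wt)^2), s = wt/(1+(wt)^2) with wt = omega*tau.  tau = 0 maps to
    (1, 0) (instantaneous emission, zero phase shift, full modulation depth).
    """
    if lifetime_ns < 0:
        raise ValueError(f"lifetime must be non-negative, got {lifetime_ns}")
    wt = float(ctx.omega_tau(lifetime_ns))
    denom = 1.0 + wt * wt
    return PhasorPoint(g=1.0 / denom, s=wt / denom)


def mixture_phasor(mix: EmissionMixture, ctx: ModulationContext) -> PhasorPoint:
    """Intensity-fraction-weighted convex combination of species phasors."""
    g = 0.0
    s = 0.0
    for sp, frac in zip(mix.species, mix.intensity_fractions):
        p = single_exp_phasor(sp.lifetime_ns, ctx)
        g += frac * p.g
        s += frac * p.s
    return PhasorPoint(g=g, s=s)


def phase_lifetime(p: PhasorPoint, ctx: ModulationContext) -> float:
    """Phase lifetime tau_phi = tan(phase)/omega = s/(g*omega), in ns.

    Equals the true lifetime only for single-exponential decays; for a
    mixture it falls strictly between the component lifetimes and below the
    intensity-weighted mean lifetime.
    """
    if p.g <= 0:
        raise ValueError(f"degenerate phasor: g must be positive, got g={p.g}")
    return p.s / (p.g * ctx.angular_frequency) / NS


def intensity_weighted_lifetime(mix: EmissionMixture) -> float:
    """Photon-weighted mean lifetime sum(frac_i * tau_i), in ns."""
    return float(
        sum(f * sp.lifetime_ns for sp, f in zip(mix.species, mix.intensity_fractions))
    )
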