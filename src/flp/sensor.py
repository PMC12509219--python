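"""Two-state ligand-binding sensor model and joint occupancy fitting.

A conformational sensor (e.g. a dopamine indicator) is modeled as switching
between two states s1 and s2 with distinct lifetimes tau1 and tau2 and a
brightness ratio R = F(0)/F(1), the intensity with all sensors in s2
relative to all in s1.  With f the fraction of sensors in s1 (for a
dopamine sensor, s1 is the ligand-free state, so the bound fraction is
1 - f):

    F(f)    = f*(1-R) + R                    (intensity, normalized to F(1)=1)
    F'(f)   = gain * F(f)                    (intensity in DAQ volts)
    tau(f)  = (f*(tau1 - R*tau2) + R*tau2) / F(f)   (photon-weighted lifetime)
    [L]     = K_D * (1-f)/f                  (ligand concentration)

``gain`` is the illumination/collection scale factor (the model's overall
intensity scale; it drifts with bleaching, which is why fitting is done on
short windows).

Because intensity and lifetime are two simultaneous readouts of the same
hidden f(t), a window of n samples gives 2n equations for n + 4 unknowns
(f_1..f_n, tau1, tau2, R, gain); :func:`fit_occupancy` solves this jointly
with box-constrained sparse least squares, optionally holding any of the
four global parameters fixed at independently measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix

from .estimation import LifetimeTrace
from .phasor import EmissionMixture, FluorophoreSpecies

__all__ = [
    "TwoStateSensor",
    "WindowFit",
    "OccupancyFit",
    "predict_intensity",
    "predict_lifetime",
    "fit_occupancy",
    "ligand_concentration",
    "lifetime_intensity_curve",
    "sensor_emission_mixture",
]

GLOBAL_PARAMS = ("tau1", "tau2", "R", "gain")


@dataclass(frozen=True)
class TwoStateSensor:
    """Lifetimes, brightness ratio and affinity of a two-state sensor.

    Defaults describe a dopamine sensor anchored at the in vivo ligand-free
    lifetime of 1.55 ns; tau2, R and K_D are configurable placeholders
    pending full sensor characterization.
    """

    tau1_ns: float = 1.55  # state s1 (ligand-free)
    tau2_ns: float = 2.0  # state s2 (ligand-bound)
    brightness_ratio: float = 2.0  # R = F(0)/F(1)
    kd_molar: float = 148e-9

    def __post_init__(self) -> None:
        for name in ("tau1_ns", "tau2_ns", "brightness_ratio", "kd_molar"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def _check_f(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("f must lie in [0, 1]")
    return f


def predict_intensity(f, sensor: TwoStateSensor, gain: float = 1.0):
    """Device intensity F'(f) = gain * (f*(1-R) + R)."""
    f = _check_f(f)
    R = sensor.brightness_ratio
    out = gain * (f * (1.0 - R) + R)
    return float(out) if out.ndim == 0 else out


def predict_lifetime(f, sensor: TwoStateSensor):
    """Photon-weighted population lifetime tau(f), in ns.

    Equals tau1 at f=1 and tau2 at f=0; reduces to linear interpolation when
    the two states are equally bright (R=1).
    """
    f = _check_f(f)
    t1, t2, R = sensor.tau1_ns, sensor.tau2_ns, sensor.brightness_ratio
    out = (f * (t1 - R * t2) + R * t2) / (f * (1.0 - R) + R)
    return float(out) if out.ndim == 0 else out


def sensor_emission_mixture(f: float, sensor: TwoStateSensor) -> EmissionMixture:
    """The two-species emission mixture equivalent to occupancy f.

    Photon fractions are f/F(f) for s1 and R*(1-f)/F(f) for s2, so the
    mixture's intensity-weighted lifetime reproduces :func:`predict_lifetime`.
    """
    F = f * (1.0 - sensor.brightness_ratio) + sensor.brightness_ratio
    return EmissionMixture(
        species=(
            FluorophoreSpecies("s1", sensor.tau1_ns),
            FluorophoreSpecies("s2", sensor.tau2_ns),
        ),
        intensity_fractions=(f / F, sensor.brightness_ratio * (1.0 - f) / F),
    )


def ligand_concentration(f, sensor: TwoStateSensor):
    """[L] = K_D * (1-f)/f, with f the fraction in the *ligand-free* state.

    (1-f)/f is the bound/unbound odds ratio, so f = 0.5 maps to [L] = K_D
    and f -> 1 maps to zero ligand.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("f must lie in (0, 1]: f=0 implies infinite concentration")
    out = sensor.kd_molar * (1.0 - f) / f
    return float(out) if out.ndim == 0 else out


def lifetime_intensity_curve(
    sensor: TwoStateSensor, gain: float = 1.0, f_grid=None
):
    """Parametric (F', tau) curve over an occupancy grid.

    Exposes the sublinear lifetime-versus-intensity relationship expected of
    a sensor whose brightness and lifetime both change on ligand binding.
    Returns ``(intensity, lifetime_ns)`` arrays ordered by the grid.
    """
    if f_grid is None:
        f_grid = np.linspace(0.0, 1.0, 101)
    f_grid = _check_f(f_grid)
    return predict_intensity(f_grid, sensor, gain), predict_lifetime(f_grid, sensor)


@dataclass
class WindowFit:
    """Joint fit result for one window."""

    start_time: float
    f: np.ndarray
    sensor: TwoStateSensor
    gain: float
    residual_norm: float
    flags: tuple[str, ...] = ()


@dataclass
class OccupancyFit:
    """Per-window occupancy fits over a trace.

    ``bound_fraction`` is the concatenated per-sample f series (fraction in
    state s1; see module docstring for the bound/unbound convention).
    """

    window_times: np.ndarray  # window start times, seconds
    bound_fraction: np.ndarray
    sample_times: np.ndarray
    gain: np.ndarray  # per window, volts
    windows: list[WindowFit]
    fixed_parameters: tuple[str, ...]

    @property
    def tau2_ns(self) -> np.ndarray:
        return np.array([w.sensor.tau2_ns for w in self.windows])

    @property
    def brightness_ratio(self) -> np.ndarray:
        return np.array([w.sensor.brightness_ratio for w in self.windows])

    @property
    def residual_norm(self) -> np.ndarray:
        return np.array([w.residual_norm for w in self.windows])


def _fit_window(
    tau_obs: np.ndarray,
    int_obs: np.ndarray,
    fixed: dict,
    start_time: float,
    max_nfev: int,
) -> WindowFit:
    n = len(tau_obs)
    free = [p for p in GLOBAL_PARAMS if p not in fixed]

    sig_tau = max(float(np.std(tau_obs)), 1e-6)
    sig_int = max(float(np.std(int_obs)), 1e-9 * max(abs(float(np.mean(int_obs))), 1.0))

    # Initialization from window statistics.
    init = {
        "tau1": fixed.get("tau1", float(np.min(tau_obs))),
        "tau2": fixed.get("tau2", float(np.max(tau_obs))),
        "R": fixed.get("R", max(float(np.max(int_obs) / max(np.min(int_obs), 1e-12)), 1.01)),
        "gain": fixed.get("gain", max(float(np.min(int_obs)), 1e-12)),
    }

    bounds_lo = {"tau1": 0.05, "tau2": 0.05, "R": 0.05, "gain": 1e-12}
    bounds_hi = {"tau1": 20.0, "tau2": 20.0, "R": 50.0, "gain": np.inf}

    def unpack(x):
        f = x[:n]
        params = dict(fixed)
        for j, name in enumerate(free):
            params[name] = x[n + j]
        return f, params

    def residuals(x):
        f, p = unpack(x)
        F = f * (1.0 - p["R"]) + p["R"]
        r_int = (int_obs - p["gain"] * F) / sig_int
        r_tau = (tau_obs - (f * (p["tau1"] - p["R"] * p["tau2"]) + p["R"] * p["tau2"]) / F) / sig_tau
        return np.concatenate([r_int, r_tau])

    x0 = np.concatenate([np.full(n, 0.5), [init[p] for p in free]])
    lo = np.concatenate([np.zeros(n), [bounds_lo[p] for p in free]])
    hi = np.concatenate([np.ones(n), [bounds_hi[p] for p in free]])

    m = len(free)
    sparsity = lil_matrix((2 * n, n + m), dtype=np.uint8)
    idx = np.arange(n)
    sparsity[idx, idx] = 1  # intensity residual j depends on f_j
    sparsity[n + idx, idx] = 1  # lifetime residual j depends on f_j
    if m:
        sparsity[:, n:] = 1  # global parameters touch every residual

    sol = least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        jac_sparsity=sparsity,
        method="trf",
        max_nfev=max_nfev,
        x_scale="jac",
    )
    f_hat, p_hat = unpack(sol.x)

    flags = []
    if np.std(f_hat) < 0.02 and m:
        flags.append("non_identifiable_flat_f")
    sensor = TwoStateSensor(
        tau1_ns=p_hat["tau1"],
        tau2_ns=p_hat["tau2"],
        brightness_ratio=p_hat["R"],
        kd_molar=fixed.get("kd", 148e-9),
    )
    return WindowFit(
        start_time=start_time,
        f=f_hat,
        sensor=sensor,
        gain=float(p_hat["gain"]),
        residual_norm=float(np.sqrt(np.mean(sol.fun**2))),
        flags=tuple(flags),
    )


def fit_occupancy(
    trace: LifetimeTrace,
    window_length_s: float = 40.0,
    fixed: dict | None = None,
    max_nfev: int = 200,
) -> OccupancyFit:
    """Jointly fit occupancy and sensor parameters on successive windows.

    Each ``window_length_s`` stretch of the trace is fit independently so
    that the slowly bleaching ``gain`` can be treated as constant within a
    window.  ``fixed`` maps any of ``tau1``, ``tau2``, ``R``, ``gain`` to
    known values (e.g. ``{"tau1": 1.55}`` when the ligand-free lifetime has
    been measured independently); the remaining globals and the per-sample
    f are free, with f box-constrained to [0, 1].

    Windows in which the fitted f is essentially flat while global
    parameters were free are flagged ``non_identifiable_flat_f`` rather than
    rejected: with no occupancy dynamics the joint system is degenerate.
    """
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(GLOBAL_PARAMS) - {"kd"}
    if unknown:
        raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")

    ok = np.isfinite(trace.lifetime_ns) & np.isfinite(trace.intensity)
    if not ok.any():
        raise ValueError("trace has no finite samples")
    t = trace.time[ok]
    tau_obs = trace.lifetime_ns[ok]
    int_obs = trace.intensity[ok]

    w = int(round(window_length_s * trace.rate))
    if w < 10:
        raise ValueError("window must contain at least 10 samples")
    n_windows = len(t) // w
    if n_windows == 0:
        raise ValueError("trace shorter than one window")

    windows = []
    for i in range(n_windows):
        sl = slice(i * w, (i + 1) * w)
        windows.append(
            _fit_window(tau_obs[sl], int_obs[sl], fixed, float(t[sl][0]), max_nfev)
        )
    if any(wf.flags for wf in windows):
        warnings.warn(
            f"{sum(bool(wf.flags) for wf in windows)} of {n_windows} windows "
            "flagged as non-identifiable"
        )
    return OccupancyFit(
        window_times=np.array([wf.start_time for wf in windows]),
        bound_fraction=np.concatenate([wf.f for wf in windows]),
        sample_times=t[: n_windows * w],
        gain=np.array([wf.gain for wf in windows]),
        windows=windows,
        fixed_parameters=tuple(sorted(fixed)),
    )
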