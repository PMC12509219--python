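# Methods

This note documents the models behind `flp`, the parameter choices that
matter, what the synthetic data does and does not emulate, and the numerical
decisions a user should know before trusting the outputs.

## Signal model

The instrument is modeled at the level of its post-filter harmonics. A
50 MHz pulsed laser excites the scene; the PMT signal is low-pass filtered
at 70 MHz, so only the DC component and the 50 MHz fundamental survive into
the mixers. Each of the four mixer channels multiplies the fluorescence
fundamental with a phase-shifted copy of the laser reference and keeps the
DC product (1 kHz IF filter), giving the closed-form channel model

    vdc      = O_B + rate / photons_per_volt
    vif_i    = O_common + d_i + MB · (vdc − O_B) · (g·sin θ_i + s·cos θ_i)

with (g, s) the scene phasor at the fundamental, θ_i the phase achieved by
channel i's shifter, O_B the DC offset, O_common a shared IF offset, d_i
channel-specific offsets, and MB the combined mixer/bias-tee conversion
gain. The sine convention makes the phase-ramp calibration curve an arcsine,
and the θ = 0 reference is anchored at instantaneous (0 ns) emission via the
lifetime standard. A waveform-level oracle (`waveform_oracle`) rebuilds the
same quantities from an explicit pulse train, brick-wall filter and mixer
product; the harmonic shortcut agrees with it to better than 1e-3 relative,
which is the basis for trusting the fast simulator everywhere else.

Only the repetition-rate fundamental is analyzed. Higher harmonics of the
pulse train are removed by the 70 MHz filtering, so no harmonic index is
exposed anywhere in the API.

### Phase lifetime versus mean lifetime

The per-sample estimator τ = s/(g·ω) is the *phase lifetime*. For
single-exponential scenes it equals the true lifetime exactly. For
mixtures — including a two-state sensor — it lies strictly between the
component lifetimes but slightly *below* the photon-weighted mean lifetime
(about 13 ps below for a 1.55/2.0 ns sensor at 50 MHz, worst near mid
occupancy). The synthetic-session ground truth therefore carries both
`lifetime_true_ns` (photon-weighted) and `phase_lifetime_true_ns` (what the
instrument measures); estimator round-trip tests assert against the latter.
When the two-state model is fit to measured lifetimes the same small
systematic is present; it is absorbed almost entirely by the fitted globals
and matters only when absolute occupancies at the percent level are needed.

## Noise model

Shot noise is modeled as independent Gaussian perturbations per sample:
σ = c·√(rate·Δt)/(photons_per_volt·Δt) on VDC (the Gaussian limit of
Poisson photon counting), scaled by MB on the IF channels, plus a constant
electronic floor (10⁻⁴ V RMS). SNR therefore grows as √rate. Defaults:
c = 1, photons_per_volt = 10⁸ photons·s⁻¹/V, so the default 5 MHz scene
sits at 0.05 V — mid-range for a fiber recording — and gives ≈150 ps RMS
per 10 kHz sample, ≈15 ps at 100 Hz, single-digit ps at 1 Hz. Sample-to-
sample correlation introduced by the 1 kHz IF filter is *not* modeled;
samples are independent, which makes the 1/k variance-downsampling law
exact and is the one intentional idealization of the noise path.

Averaging order matters: because τ is a ratio, averaging noisy per-sample
lifetimes inherits a positive bias of order (σ_D/μ_D)² (≈ +6 ps at the
default 10 kHz settings). `downsample_recording` averages the raw voltages
*before* the ratio — the digital analogue of sampling the DAQ slower — and
should be preferred for slow readouts; `moving_mean_downsample` averages an
existing trace and is appropriate once the per-sample SNR is already high.

## Calibration

Four stages, mirroring bench practice:

1. **Phase curves.** A 0–10 V bias ramp sweeps each shifter through >2π.
   Normalizing each VIF sinusoid and taking the arcsine recovers the
   achieved phase up to branch; the monotone branch is reconstructed by
   taking sign(cos ψ) from the smoothed sweep derivative and unwrapping
   atan2(sin ψ, ±√(1−sin²ψ)). The curve, minus the standard's phase lag
   arctan(ωτ_std), is fit with a degree-7 polynomial (configurable; 7
   captures smooth shifter nonlinearity without ringing). Points with
   |argument| > 0.995 are excluded from the fit — the arcsine's noise
   amplification diverges at the extremes. The sinusoid's offset and
   amplitude are then refined by regressing the voltage on sin(fitted
   phase) and the fit repeated (3 passes); without this refinement the
   span error of raw max/min normalization tilts the curve by ~2 mrad,
   i.e. ~10 ps of lifetime bias.
2. **Dark offsets.** Shutter closed: O_B = mean(VDC), d13 and d24 from the
   1−3 and 2−4 channel-mean differences (the shared IF offset cancels).
3. **Bias voltages.** The fitted polynomials are inverted (Brent's method)
   for the voltages achieving 0, π/2, π, 3π/2; residual < 1e-4 rad. Per
   the hardware procedure this runs after the offsets are known, although
   in this model offsets cancel inside the normalized argument, so the
   re-determination is a consistency pass.
4. **Conversion gain.** MB = (VIFmax−VIFmin)/(2(VDC−O_B))·√(1+(ωτ_std)²)
   per channel, averaged; per-channel values are kept as a dispersion
   diagnostic. Extremes are refined by a local parabola fit (raw extremes
   are biased outward by noise, smoothed ones inward by peak flattening).

The standard defaults to coumarin 6 at 2.40 ns (literature band
2.39–2.41 ns), configurable. Calibration constants are assumed
temperature-stable between calibration and recording; no drift model is
included.

With noisy calibration recordings at the default noise settings, an
independent noisy re-measurement of the standard lands within ~6 ps of
truth at 1 Hz (10 ps is the tested bound).

## Two-state sensor fitting

A window of n samples supplies 2n observations (intensity and lifetime) for
n + 4 unknowns (per-sample occupancy f plus τ₁, τ₂, R, gain). The joint fit
is box-constrained sparse nonlinear least squares (`scipy.optimize.
least_squares`, TRF, sparse Jacobian pattern); f is constrained to [0, 1],
and intensity/lifetime residuals are standardized by their within-window
scatter before stacking, since the two observables have incommensurate
units and the relative weighting is otherwise arbitrary. Initialization:
f = 0.5 everywhere, τ₂ from the window's max lifetime, R from the max/min
intensity ratio, gain from the minimum intensity. Windows default to 40 s
at 100 Hz; the window should be short enough that bleaching leaves the gain
approximately constant within it.

The system is well conditioned only when the occupancy explores a wide
range within the window: with f confined to a narrow band (e.g. 0.55–0.85)
and all four globals free, the fit is degenerate and parameter estimates
drift while the f series stays serviceable. Windows whose fitted f is
essentially flat while globals were free are flagged
(`non_identifiable_flat_f`), not rejected. Fixing independently known
parameters (typically the ligand-free lifetime τ₁, e.g. 1.55 ns for the
default dopamine-sensor parameterization) is strongly recommended. With τ₁
fixed, 1% noise and f sweeping 0.1–0.9, τ₂ and R are recovered within a few
percent and f with RMSE < 0.05.

Convention: f is the fraction of sensors in state s1 (the *ligand-free*
state for the default parameterization, with s2 brighter, R > 1), so the
bound fraction is 1−f and [L] = K_D·(1−f)/f. τ₂, R and K_D defaults
(2.0 ns, 2, 148 nM) are configurable placeholders pending full sensor
characterization; tests never treat them as ground truth except where a
synthetic scene was generated from them.

## Session analysis

- **Tonic baseline**: centered rolling median (default 60 s), truncated at
  session edges — centering avoids the phase lag of trailing windows. The
  median ignores transients occupying less than half the window.
  `delta_baseline` subtracts the baseline mean over a reference interval
  (default: the first window-length of the session).
- **Epoch change**: mean of the rolling-median baseline inside a stimulus
  epoch minus its mean over the prior 2 min (both windows configurable).
  This is the slow-timescale counterpart of the per-event measure below;
  which one applies depends on whether the effect outlives single events.
- **Phasic transients**: per-event snippets over [−2, post) s with the
  [−2, 0) s mean subtracted; events without full coverage are dropped, not
  padded. The per-event peak is read at the latency of the mean transient's
  signed extremum, so all events share one latency and polarity (per-event
  peak-picking would rectify noise).
- **SNR**: mean peak amplitude divided by the mean per-event baseline
  standard deviation.
- **Downsampling comparison**: peak amplitudes recomputed after boxcar
  downsampling to each requested rate; transients shorter than the boxcar
  are attenuated, which is the quantitative argument for fast acquisition.
- **Autofluorescence correction** inverts the intensity-weighted lifetime
  mixture: τ_sensor = (τ_obs·I_obs − τ_af·I_af)/(I_obs − I_af), defined only
  when the observed intensity exceeds the autofluorescence intensity.

## Synthetic sessions

`generate_session` composes: a piecewise-linear tonic occupancy profile;
difference-of-exponentials event kernels (defaults 0.2 s rise, 1.5 s decay
— phasic-release-like timescales, configurable); the two-state sensor
forward model; an optional constant autofluorescence background (mixed by
photon rate); multiplicative gain artifacts (a random-phase sinusoid bank
in a configurable band, default 0.5–2 Hz hemodynamic-like, plus exponential
bleaching) applied to collected photons only — per-molecule lifetime is
untouched by collection efficiency, which is the core physical claim the
stack exists to exploit; and the instrument model with shot noise. All
randomness derives from the session seed; occupancy trajectories are
deterministic given the spec.

What the generator does *not* emulate: mixer compression and RF
reflections (the instrument is modeled as already corrected), IF-filter
noise correlation, temperature drift of calibration constants, behavioral
structure in event timing, and spectral bleed-through between channels.
Passing tests therefore demonstrate correctness of the computation stack
under the stated physics, not robustness to pathologies of uncorrected
hardware.

## Numerical choices and degenerate inputs

- Lifetimes are nanoseconds everywhere in the API; angular frequency in
  rad/s; the ωτ product is formed in one place (`ModulationContext`).
- Lifetime samples with |quadrature denominator| < 10⁻⁶·MB are masked NaN
  (dark stretches); an all-NaN trace warns rather than raises.
- TCSPC histogram t0 is the max-count bin after 3-bin boxcar smoothing
  (configurable), standing in for an exponential-fit peak; the mean-arrival
  estimator truncates at 0–8 ns after t0 by default to reject delayed
  reflection autofluorescence, and carries an inherent half-bin-width
  offset plus the analytic truncation bias of a finite window.
- Boxcar downsampling uses non-overlapping windows (remainder dropped) so
  variance scaling is exactly 1/k for independent noise.
- Mixture fractions must sum to 1 within 1e-9; occupancy trajectories are
  clipped to [0, 1] with a warning.
- The calibration ramp must start at a phase in (−π/2, 3π/2) for branch
  anchoring — satisfied by shifters whose curves start near zero phase.

## Known limitations

- The Gaussian shot-noise surrogate has the right √rate scaling but no
  Poisson skew; at very low photon rates (≲10⁴ photons/s) the surrogate is
  optimistic.
- The phase-lifetime/mean-lifetime distinction above means multi-component
  scenes are summarized by a single slightly-biased number; full phasor
  coordinates are always available and unbiased.
- Occupancy fits are only as identifiable as the occupancy dynamics within
  a window; flags are advisory, not a hypothesis test.
- The linearity of measured lifetime against mixture fraction is itself
  slightly convex (phase-lifetime physics): for a 2.4/2.0 ns pair at
  50 MHz the ideal R² of a linear fit over an 11-point fraction grid is
  0.99893, not 1.
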