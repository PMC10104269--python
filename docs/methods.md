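# Methods

## Physical model

The aqueduct is treated as a rigid canal of length L and mean radius a
carrying fully developed oscillatory flow of an incompressible Newtonian
fluid. Cycle-averaged pressure magnitude, made dimensionless with the
inertial scale ρω²LLs, depends only on (a/L, Ls/L, α). The forward model
has two parts:

1. **Linear viscous-inertial impedance.** Each Fourier harmonic n of the
   dimensionless flow Q̄ maps to a pressure harmonic through
   Π̂ₙ = i n Q̄̂ₙ / F(α√n), F(α) = 1 − 2J₁(Λ)/(ΛJ₀(Λ)), Λ = i³ᐟ²α —
   Womersley's rigid-tube solution. Limits: F → iα²/8 as α → 0 recovers
   Poiseuille resistance (⟨|Π|⟩ → (8/π)α⁻², φ → 0); F → 1 as α → ∞ leaves
   pure inertial reactance (⟨|Π|⟩ → 1/π, φ → π/2). The approach to the
   inertial limit is slow: 1/|F(α)| = 1 + √2/α + O(α⁻²), so at α = 100 the
   amplitude still sits 1.4% above its limit. That excess is physics, not
   truncation, and the unit tests assert the √2/α rate rather than the
   limit value.
2. **Entrance loss.** The nearly inviscid openings into the ventricles add
   a minor loss quadratic in the section-mean velocity,
   (K/2)(Ls/L) ū|ū| in dimensionless form, with sign preserved so the loss
   always opposes the flow. K defaults to 0.7 — the sum of typical
   rounded-entry (~0.2) and sudden-expansion (~0.5) coefficients — and is
   exposed as a calibration knob; it is the only nonlinearity and the only
   place Ls/L enters the model. With the default K the model shows the
   qualitative behaviour observed on real anatomies: ⟨|Π|⟩ noticeably above
   the straight-cylinder value, a ≈ 41% drop in ⟨|Π|⟩ from α = 2 to α = 4,
   and <10% variation of ⟨|Π|⟩ and φ across Ls/L ∈ [0.5, 1.5].

An optional quasi-one-dimensional variable-area treatment integrates the
per-slice uniform-tube impedance along a measured area profile (local
radius, local section velocity, contributions in series). It is an
approximation — no secondary flows, no redevelopment lengths — and is
labelled as such.

Out of scope by design: wall compliance and elastic-wave effects (the bench
reservoir balloon is treated as ideal pressure relief), 3-D CFD, and
turbulence.

## Harmonic truncation

The harmonic waveform uses a single mode. Anharmonic cardiac-like
waveforms use 8 harmonics, mirroring the 8x-fundamental low-pass bandwidth
such signals need; `HarmonicDecomposition.from_samples` refuses a
truncation that leaves more than 0.5% RMS reconstruction error.

## Similarity design

Scaled experiments satisfy a_E/L_E = a_H/L_H, equal α, and equal Ls/L; the
designer inverts α for the drive frequency (ω = α²ν/a², reported raw and
rounded to integer BPM, ties away from zero) and maps pressures by
(ρ_E/ρ_H)(ν_E/ν_H)²χ⁻². Pump-envelope violations (3–200 BPM, 0–180 mL)
warn rather than fail, so the designer remains usable for other hardware.
Similarity residuals are reported relative for a/L, α and Ls/L with a 2%
default pass tolerance.

Glycerol-water properties combine the Cheng (2008) viscosity correlation
(mass-fraction power-law blend of pure-component viscosities, a few percent
accuracy over 0–100 °C) with a volume-fraction-weighted density using
temperature-dependent component densities. The three bench mixtures
(84/16, 80/20, 74/26 by volume at 21.5 °C) are shipped as exact lookup
overrides so their measured values (ν = 10.5, 6.82, 3.83 ×10⁻⁵ m²/s;
ρ = 1225.6, 1216.4, 1202.2 kg/m³) are returned verbatim; the correlation
reproduces them to ~0.5% and fills the continuum.

## Signal pipeline

Processing order and numerical choices, with rationale where the choice was
genuinely open:

- **Despiking**: classic Hampel filter (per-window median and MAD about
  that median), half-window 0.1 period, threshold 5 robust sigmas. The
  per-window MAD matters: comparing each sample against its own rolling
  median deflates the scale near smooth extrema and flags legitimate
  curvature. Median replacement is unbiased on monotone stretches and
  carries a curvature bias near extrema that is inherent to the method.
- **Resampling**: polyphase anti-aliased resampling of the 2500 Hz piston
  channel onto the 80 Hz pressure rate, then central-difference
  differentiation (one-sided at endpoints) and multiplication by the
  piston area.
- **Filtering**: zero-phase 4th-order Butterworth, applied
  forward-backward, cutoff at 5x the drive frequency for harmonic runs and
  8x for cardiac-like runs. Zero phase is mandatory — any filter phase at
  the fundamental would bias φ directly.
- **Alignment**: channels aligned by timestamps; the pressure channel is
  linearly interpolated onto the piston-derived 80 Hz grid.
- **Cycle handling**: half a period is discarded at each end (filter edge
  transients), then the trace is trimmed to the largest whole number of
  periods (1%-of-period tolerance); at least 2 whole cycles are required
  (phase resolution), and recordings under 5 cycles warn at construction.
  Zero-averaging of the pressure is per-recording, over the trimmed
  whole-cycle window.
- **Summaries**: ⟨|·|⟩ by the trapezoidal rule on the sampled grid (no
  resampling); φ from the FFT bin nearest ω/2π, wrapped to (−π, π],
  positive when pressure leads flow.

`RecordingAnalysis.fit()` additionally reports the cycle-by-cycle spread of
⟨|Π|⟩ as a standard error; this captures run stability only, not
systematic errors (transducer calibration, trapped air).

## Synthetic recordings

The generator inverts the measurement chain: the commanded waveform drives
the forward model for the pressure channel (80 Hz) and is integrated into
a piston trajectory (2500 Hz, centred so it starts and ends at the same
value). Emulated defects, all derived from one integer seed:

- 10-bit ADC quantization of the piston signal over a full scale of 1.2x
  the commanded peak-to-peak stroke;
- Poisson-placed single-sample readout spikes, default 0.5 per 1000
  samples at 100x the signal peak with random sign;
- additive Gaussian noise: default 2% of peak on pressure, 0.1% of stroke
  on position (the bench noise levels are not published; these defaults
  are the levels used throughout the validation suite).

Defaults follow the reference bench where published (sampling rates, ADC
depth, spike magnitude, 40-cycle recordings, 25 cm² piston area of a
50 mm-bore-class pulsatile pump). The validation and acceptance tests use
8–10-cycle recordings — cycle averages converge quickly and the shorter
records keep the suite brisk; the pipeline itself is cycle-count agnostic.

The *physiologic* waveform is a frozen 8-harmonic synthesis standing in
for a subject's PC-MRI aqueduct waveform, which is not publicly tabulated.
It was designed once, against shape constraints only: exactly three local
maxima and three minima per cycle (echoing the percussion, tidal and
dicrotic peaks of intracranial pressure waveforms), systolic dominance
(peak/|trough| ≈ 1.3), zero net volume, stroke-normalized, and ⟨|Π|⟩ within
a few percent of the harmonic waveform at matched stroke — the observed
behaviour of real aqueduct waveforms. Results obtained with it say nothing
about any individual subject's harmonic content.

What passing synthetic-closure tests do show: the pipeline's filters,
resampling, despiking and estimators are unbiased at the percent level
under the modelled defects. What they do not show: robustness to defects
the generator omits — reservoir sloshing, balloon compliance dynamics,
trapped-air compressibility, drift, or non-Gaussian transducer noise.

## Clinical estimator

⟨|Δp|⟩ = ⟨|Π|⟩ ρω²L Vs/(πa²), with ⟨|Π|⟩ computed by the model (physiologic
waveform by default; the harmonic option differs by a few percent) unless
supplied. The canal length L is user-supplied: segmentation conventions for
where the aqueduct ends differ, and the estimate scales linearly with L.
A warning is attached outside α ∈ [0.5, 10]. Because ⟨|Π|⟩ itself falls
with α = a√(ω/ν), aqueduct enlargement reduces the estimate faster than
the explicit a⁻² — which is why patients with both increased stroke volume
and an enlarged aqueduct can show normal transmantle pressures.

## Units and conventions

SI throughout the library (m, s, kg, Pa, rad/s); BPM, mL, mm and inH₂O are
converted at I/O boundaries only (`aqueductflow.units`;
1 inH₂O(4 °C) = 249.082 Pa). Typical physiological ranges
(1/20 ≤ a/L ≤ 1/10, 0.5 ≤ Ls/L ≤ 1.5, 2 ≤ α ≤ 4) are advisory: outside
them the framework still evaluates but warns that results are
extrapolations.

## Known limitations

- The entrance-loss coefficient K = 0.7 is a plausible minor-loss default,
  not a fitted constant; anatomy-specific values require calibration
  against measurements or CFD.
- The variable-area treatment is quasi-one-dimensional.
- The glycerol-water correlation degrades near 100% glycerol and at
  temperature extremes (~±5% on ν).
- The Bessel evaluation is capped near α ≈ 600 per harmonic; cap the
  harmonic count for extreme Womersley numbers.
- φ estimation needs ≥2 whole cycles and benefits from many; single-cycle
  clinical waveforms are out of scope.
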