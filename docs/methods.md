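# Methods

## Equivalent circuit

The electrode/electrolyte interface of a graphene microelectrode is
modelled as

    Z(ω) = R_s + [ Z_CPE(ω) + Z_Cq(ω) ] ∥ [ R_ct + Z_W(ω) ]

with

* `Z_CPE = 1/(Q (jω)^α)` — the Helmholtz double layer as a constant
  phase element. `Q` has units F·s^(α−1) and is obtained from the
  specific value (µF cm⁻²) × geometric area × roughness. α ∈ (0, 1];
  α = 1 recovers an ideal capacitor, and the CPE phase is −α·90°.
* `Z_Cq = 1/(jωC_q)` — graphene's quantum capacitance, a consequence
  of its low density of states near the Dirac point. It sits in
  *series* with the double layer, which is why it dominates the
  interfacial impedance: theoretical C_q (~1–4 µF cm⁻²) is smaller
  than C_dl (~10 µF cm⁻²), and the smaller series capacitance wins.
* `Z_W = W · tanh(B √(jω)) / √(jω)` — bounded (finite-length-diffusion)
  Warburg element. For ω → 0 it is resistive with value `W·B`; for
  large `B√ω` it approaches the semi-infinite Warburg `W/√(jω)` at
  −45° phase. Principal branches of the complex square root and tanh
  are used, with tanh saturated to 1 for Re(argument) > 20 to avoid
  overflow. `B` is treated as having units s^½ so that `B√ω` is
  dimensionless; this is the only reading under which the tanh form is
  dimensionally consistent.
* `R_s`, `R_ct` — solution series resistance and charge-transfer
  resistance.

The wiring — quantum capacitance inside the capacitive branch, in
parallel with the faradaic `R_ct + W` branch — follows standard
electrode-interface practice for graphene (C_q in series with C_dl);
`z_circuit` takes a `topology` callable so an alternative netlist can
be swapped in without touching the element functions.

Useful exact limits (used as invariants in the tests): `Z → R_s` as
f → ∞, and `Re Z → R_s + R_ct + W·B` as f → 0.

Two representative parameter sets ship with the package
(`preset_parameters("PET"/"SU-8")`), for 100 µm square electrode sites
with AFM-derived roughness factors of 1.015 (PET) and 1.07 (SU-8).
The default frequency grid is 50 log-spaced points, 1 Hz–100 kHz, the
span of a standard EIS sweep for neural electrodes.

## Spectrum fitting

`fit_spectrum` minimizes Σ_f w_f |Z_meas − Z_model|² with real and
imaginary residuals stacked. Weightings:

* `modulus` (default): w_f = 1/|Z_meas|², so each frequency decade
  contributes comparably although |Z| spans ~4 orders of magnitude;
* `unit`: unweighted; `proportional`: each component divided by its
  own magnitude.

Positive parameters are fitted in log space and α through a logistic
transform into (0, 1) — positivity and the α-range are enforced by the
parameterization rather than by clipping. The optimizer is
trust-region-reflective least squares (ftol = xtol = gtol = 1e-10, at
most 2000 evaluations). Standard errors are delta-method propagated
from the Gauss–Newton covariance in transformed space; a rank-deficient
Jacobian is flagged (`jacobian_singular`) and handled with a
pseudo-inverse. Only the *absolute* capacitances Q·area·roughness are
identifiable from a spectrum, so the geometry must be supplied for
per-area values to be on the right scale.

When no starting point is given, a deterministic multistart is run
around a heuristic guess (R_s from the high-frequency real part, the
interfacial capacitance from 1/(ω|Im Z|) at the phase minimum — the
most capacitive point; at the lowest frequencies a large faradaic
branch can shunt the capacitive branch and inflate the estimate
~40-fold — α from the median log-log slope of |Z|, and the faradaic
parameters at order-of-magnitude values from the low-frequency real
part). Six starts varying `B` (×¼, ×1, ×4) and `R_ct` (×1, ×10⁻²) are
explored with a reduced budget (200 evaluations, tol 1e-8) and the
best is polished with the full budget; the exploration cap matters
because bad starts can wander for thousands of evaluations along the
nearly flat charge-transfer direction. The objective has genuine local
minima in the Warburg/charge-transfer corner — a single heuristic
start converges to one for the SU-8 preset — while the multistart
recovers both presets to machine precision on noiseless data.

`reference_protocol_config(c_dl)` reproduces the standard laboratory
protocol: C_dl measured independently on gold electrodes and held
fixed, C_q and everything else free.

### Identifiability

With 1% proportional noise on a 1 Hz–100 kHz sweep (20 replicates),
all free parameters of the PET preset are recovered with median
relative errors below ~2%. For the SU-8 preset every parameter except
R_ct behaves the same way; R_ct (1.36 MΩ) sits beneath a ~450 MΩ
Warburg branch and contributes less than the noise floor at every
measured frequency, so its estimate scatters by tens of percent. This
is a property of the measurement, not of the optimizer — the scatter
persists when the fit is started at the true values — and would
require either sub-0.1% noise or data well below 1 Hz to resolve. The
acceptance suite keeps the blanket ≤5% recovery contract for both
presets, so that check documents the limit by failing for SU-8 R_ct;
the module tests assert the attainable statement.

## Accelerated aging

The time-compression factor is f = 2^((T − T_ref)/10) with
T_ref = 37 °C (mouse body temperature): chemical degradation rates
roughly double per 10 °C. 87 °C gives exactly f = 32; equivalent
lifetime is days × f, converted to years with 365.25 days/year
(configurable; 365 and 365.25 give identical 2-decimal results for all
packaged durations) and displayed with half-up rounding to 2 decimals.
The packaged eight-array outcome set (4 PET arrays completing 30 days;
4 SU-8 arrays failing at 22/17/8/7 days from cracks over electrodes or
wires) yields the equivalent-lifetime column
2.63/2.63/2.63/2.63/1.93/1.49/0.70/0.61 years.

## Longitudinal tracking

A channel is *working* on a day iff its 1 kHz impedance magnitude is
present and strictly below 2 MΩ (the practical limit for usable SNR on
high-input-impedance acquisition systems; the threshold is a
parameter). Open-circuit channels are unmeasurable and recorded as
NaN. Summaries are computed over working channels only — mean, sample
SD (n−1, reported only with ≥2 working channels) and yield
(working/total) per day. Because the observed failure modes are
irreversible opens, failure detection requires persistence: a
channel's failure day is the first day of a nonworking stretch that
lasts to the end of the record, a single bad measurement is not a
failure, and a never-working channel fails at its first timepoint.
When several arrays are tracked the pipeline summarizes each array
separately; pooling channels across arrays versus averaging per-array
means is left to the caller (both are one-liners over the returned
summaries) since they answer different questions.

## Permeation quantification

Images are processed in grayscale (RGB collapsed with ITU-R 601
luminance weights). Thresholding is either Otsu's
between-class-variance criterion or a caller-supplied fixed level that
plays the role of a manually adjusted threshold; a constant image
yields an empty mask with a warning. The permeated area is reported
as a percentage of a caller-supplied ROI — the denominator is a
genuine free choice (typically a rectangle around one electrode
opening) and the % value is meaningless without stating it. Maximum
permeation distance is the largest minimum Euclidean distance from a
permeated pixel to the electrode-opening boundary (0-based pixel
centers), computed with the exact Euclidean distance transform and
multiplied by the pixel size; the test suite pins it to an all-pairs
brute-force oracle exactly. Shorting risk uses a midpoint rule —
flagged once the distance reaches half the inter-electrode spacing
(default 400 µm → 200 µm) — because fronts can grow from both
neighbouring sites.

## Recording QC

* RMS noise: √(mean of squared mean-subtracted samples) over a window,
  by convention a stimulus-free segment.
* Trial averaging: epochs are cut around stimulus onsets, each
  baseline-subtracted by its pre-stimulus mean; incomplete epochs are
  dropped and counted. The default window is (−0.5 s, +1 s).
* Onset latency: first post-stimulus time at which |average| exceeds
  k×SD of the pre-stimulus baseline and stays above for a sustained
  duration (defaults k = 3, 20 ms) — a plain threshold-crossing rule
  that is exact to one sample on noiseless synthetic responses.
* Band power: per-epoch Hann spectrograms (256 ms window, 75% overlap),
  power averaged over trials, each frequency row expressed in dB
  relative to its own mean over *fully* pre-stimulus windows (a window
  straddling the onset would leak stimulus power into the baseline).
  The band time course averages linear power over the frequency bins
  whose centers lie in the closed band before converting to dB;
  averaging per-bin dB instead would be biased low by several dB for
  small trial counts (Jensen's inequality on log of a few-dof
  chi-square).

## Synthetic data

All generators are pure functions of their arguments; one top-level
seed is expanded into fixed per-generator substreams
(`numpy.random.SeedSequence` spawn keys), so adding a generator never
perturbs existing outputs.

* **Spectra**: Z(f)·(1 + ε_re + j·ε_im), ε ~ N(0, noise_frac) i.i.d.
  per frequency and component; 1% is the default measurement-noise
  level for a well-conditioned EIS rig.
* **Impedance time courses**: z(d) = z_plateau + (z0 −
  z_plateau)e^(−d/τ) with defaults z0 = 900 kΩ, plateau = 585 kΩ
  (a typical end-of-soak working-array average), τ = 3 days — the
  characteristic initial drop and stabilization of soaked electrodes —
  times i.i.d. lognormal noise (σ = 0.1, a ~10% channel/day CV).
  Injected failures make a channel NaN from its failure day onward.
  For the 64-channel mean-curve check the tolerance follows from the
  noise model: +e^(σ²/2) ≈ 0.5% mean bias plus a per-day SE of
  σ/√64 ≈ 1.25% gives a 5% (≈ bias + 3·SE) bound on the worst day.
* **Permeation images**: Gaussian background (level 60, σ 8) plus a
  +120 lobe grown rightward from a straight boundary column with a
  Gaussian along-boundary envelope; the peak extent is growth ×
  day. Defaults (0.6 µm/day over 30 days, envelope width 10% of the
  image) top out at 18 µm and ~17% of the packaged ROI, the magnitude
  of a minor-but-visible permeation. Day 0 has no lobe. The metadata
  carries the boundary, ROI and the mid-contrast fixed threshold; Otsu
  is appropriate for strongly bimodal frames, the fixed threshold for
  the low-foreground-fraction ones.
* **ECoG**: pink (1/f-amplitude) background via FFT spectral shaping
  at 20 µV RMS; per trial an on-response stepping to the target
  amplitude exactly at the configured latency and decaying with
  τ = 150 ms (the sharp rise makes the injected latency recoverable to
  one sample); during each stimulus, band-limited noise scaled so
  in-band power is `band_gain` × its measured baseline value;
  onset-to-onset intervals uniform in 7–9 s, 4 s stimuli, 12
  orientations 30° apart in pseudorandom blocks.

What the generators do *not* emulate: real spectra deviate from any
finite circuit (the fit χ² to real data is never ~0); real impedance
drift has slow correlated components, not i.i.d. daily noise; real
permeation fronts are irregular and imaged with uneven illumination;
real ECoG is nonstationary with movement and line artifacts. Passing
round trips therefore demonstrate correctness of the estimators under
their stated models, not robustness to every artifact of real
recordings.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script
each run in about a minute: 50-point spectra, 20-replicate Monte
Carlo, 16–64 channels over 11–31 days, 192² images, 10–40 trial ECoG
sessions at 1 kHz. All scale up linearly via the obvious arguments.

## Known limitations

* The circuit topology is fixed by default (configurable hook); no
  automatic model selection or Kramers–Kronig validation.
* Aging uses the 2^(ΔT/10) rule only — no Arrhenius activation
  energies, humidity or reactive-oxygen acceleration.
* Permeation analysis does not register images across days and does
  not detect cracks (a qualitative, SEM-level judgement).
* The R_ct identifiability limit above applies to any fitter given
  this frequency span and noise level.
* Statistical comparison between substrates (survival analysis of
  channel lifetimes etc.) is out of scope.
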