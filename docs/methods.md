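# Methods

This note documents the models behind each stage, the defaults that matter
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Decay-chain evolution (`nuclear_data`)

The ²²⁵Ac network is configuration, not code: a versioned JSON table
(`data/ac225_chain.json`) with half-lives, branch fractions and the gamma
lines the analysis uses, taken from evaluated nuclear data (ENSDF/NuDat).
Only the chain ²²⁵Ac → … → ²⁰⁹Bi is bundled; the schema permits other
nuclides but nothing is promised for them. Sub-0.01% branches (e.g. the
²¹⁷At β⁻ branch) are omitted.

Evolution uses the analytic Bateman solution summed over the branch paths of
the decay DAG, with two robustness measures:

* **Instantaneous equilibrium for µs-scale nuclides.** ²¹³Po (3.7 µs) is not
  an ODE state; its feeder's β-branch is routed directly to ²⁰⁹Pb and its
  activity is reported as the feeding rate (λN likewise). Threshold:
  half-life < 1 ms. ²¹⁷At (32 ms) stays analytic — its λ ratios are well
  inside double precision.
* **Stiff ODE fallback.** If any two decay constants agree within 1e-10
  relative the Bateman denominators cancel catastrophically and the package
  integrates the full rate equations with Radau instead. The bundled chain
  never triggers this; it guards user-supplied tables.

Verified properties: agreement with an independently coded stiff ODE oracle
to better than 1e-6 relative over 0–30 d; atom conservation (stable terminus
included) to 1e-9; step additivity.

Times are float seconds on an arbitrary absolute axis internally; file
interfaces accept ISO-8601 (naive timestamps read as UTC).

## Spectroscopy (`spectroscopy`)

This module consumes *peak areas*, not spectra: peak fitting, resolution
broadening and efficiency calibration are upstream concerns.

* **Dead time** is modelled as non-paralyzable, r_true = r/(1 − rτ), with τ
  a per-measurement parameter. The model choice is exposed rather than
  hard-coded because counting chains differ.
* **Coincidence estimator.** Accidental coincidences are estimated as
  2·τ_w·R₁·R₂ and subtracted by default (the 200 ns window makes them small
  but not zero at kBq activities); the subtraction can be disabled. The
  estimator's σ neglects the small correlation introduced by the accidental
  term — at the ~10⁴-coincidence-count regime this is far below the Poisson
  width. The estimator carries an O(1/N_c) multiplicative bias inherent to
  ratio estimators; at 10⁴ coincidence counts this is ≤0.1%.
* **Gamma line assignment.** The bundled table assigns 440 keV → ²¹³Bi and
  218 keV → ²²¹Fr, the standard assignment. (Source descriptions that swap
  the two lines exist; the table is the single point of truth here.)
* **Alpha counting.** Each alpha decay recoils its daughter with ~100 keV,
  ejecting a fraction from the counting geometry, so the effective solid
  angle of the n-th chain member is geometry × Π(per-decay retention of its
  ancestors). Retention fractions are configuration with no universal
  default — they depend on implantation depth and sample morphology — so a
  missing entry is an error, not a silent 1.0.

## EOC back-extrapolation (`eoc_extrapolation`)

Every predicted activity is linear in the single unknown A_Ac(t_f), so the
fit is closed-form weighted least squares with w = 1/σ² on the activity
scale (not log-activity): the probes are high-count gamma peaks with
near-Gaussian errors. σ comes from the curvature of the weighted residual
sum; χ² is reported as a diagnostic, not used to inflate σ.

The daughter inventory at t_f defaults to **equilibrium** (daughters grown
in during the multi-hour collection). Since every measured probe
re-equilibrates within hours and real measurements happen days later, the
pure-parent alternative changes estimates by <0.5%; both are kept.

Measurements with σ = 0 are treated as exact and fitted unweighted (only
among themselves); mixing exact and noisy points is not meaningful.

## Temperature calibration (`temperature_calibration`)

Both models are fitted and inverted in **kelvin** — the T⁴ radiative term is
only physical on an absolute scale — while all interfaces speak °C. The
power model is linear in the (T, T⁴) basis and solved by non-negative least
squares (a, b > 0 is the physical resistive+radiative decomposition); the
current model by bounded, unweighted nonlinear least squares with the power
fit providing starting values. Inversion is bracketed root finding on
[300 K, 4000 K] — beyond tantalum's melting point — so a missing root means
a bad fit, never silent extrapolation. The combined estimate is the mean of
the two model inversions with 1σ = half their absolute difference;
residual summaries are stored on the model object as diagnostics.

## Beam current (`beam_current`)

* **Background.** Alpha recoil from implanted activity produces a negative
  current that grows as activity accumulates; it is modelled as a sigmoid
  b₀ + (b₁−b₀)/(1+e^(−(t−t₀)/w)) fitted to Faraday-cup-in (beam-blocked)
  samples only, which are pure background. A constant blocked pool
  degenerates to a flat model rather than failing.
* **Integration** is trapezoidal on the irregular timestamps (the data are
  slow drifts sampled densely relative to their variation). Equivalent
  activity at t_ref: A = λ∫ I/(q·e)·e^(−λ(t_ref−t)) dt. Beam-blocked samples
  are excluded, with the integral restarted per contiguous run; negative net
  samples contribute as-is — they are unbiased noise, and clipping would
  bias the integral upward. Laser-test dips are *retained* by default (the
  beam is still being implanted, only enhancement is off); excluding flagged
  intervals is a caller choice.
* **Charge state** defaults to +1 (surface/laser ionization at 60 kV
  extraction), exposed in configuration.
* **Gap losses** are bootstrapped: donor samples are collecting, beam-on
  readings whose heater current lies within ±5 A of the gap's. Heater
  current, not derived temperature, is the matching variable because
  temperature is itself a two-model extrapolation with ~40–50 °C
  uncertainty. The gap is filled by resampling donors with replacement on
  the trace's median sampling step and integrated; mean and sd over
  n_resamples draws are reported, and a single draw leaves σ = NaN.
* The per-sample noise used for the integration σ is estimated from the
  median absolute first difference (robust to the slow signal drift) unless
  supplied.

## Release kinetics (`release_kinetics`)

The series Σφᵢe^(−λᵢt) + c is fitted by nonlinear least squares in
normalized current units — picoampere-scale amplitudes would otherwise sit
below the optimizer's step tolerances. Starting values: c from the final 10%
of samples, λ and φ from a log-linear fit of (signal − c).

Term selection quantifies a qualitative stopping rule: start at one term and
add terms while they remain *supported*, where a candidate model is rejected
(and the previous one kept) if

* two fitted rates agree within 10% relative (configurable) — equal rates
  render a term redundant; or
* any amplitude is consistent with zero (|φ| ≤ 2σ_φ, or below 1e-6 of the
  signal scale) — the rate criterion alone is blind to the φ→0 degeneracy.

On single-exponential truth this keeps λ₁ within its standard error
regardless of `max_terms`; on two-exponential truth with rates (0.3, 3.0)/h
both terms are recovered.

## Efficiency calculus (`efficiency`)

All four operations propagate uncertainty to first order with inputs
assumed uncorrelated (no covariances are available for the measured
inputs); `propagate_mc` provides a Monte-Carlo audit, which agrees with the
first-order σ within 5% at the study's values. ε_T is computed *without*
decay-correcting the loaded activity from its assay reference to t_f — that
is the convention under which the published inputs reproduce the published
ratios — and a decay-corrected variant is available behind a flag.
ε_diff and ε_eff cannot be separated by these measurements and are carried
as "unknown" in the breakdown unless supplied. The ionization efficiency is
reported on both the rounded-input path (published inputs as printed) and
the full-precision path; they differ in the third decimal, which is why a
recomputed 15.0% sits alongside a published 15.1% — both inside the quoted
0.6-point uncertainty.

## Synthetic data (`synthetic_data`)

The generator's defaults *are* the study conditions: 10.11 MBq loaded,
~6–10% of it implanted over a 20 h collection sampled every 60 s at pA-scale
currents, release (φ, λ₁, c) = (10 pA, 0.34 h⁻¹, 0.5 pA), picoammeter noise
0.5 pA (amplitude/noise ≈ 20), a sigmoid recoil background drifting to
−0.05 pA, five 10-min Faraday-cup intervals, two 5-min laser-off dips
(signal ×0.1 — the surface-ionization remnant), a 1 h mass-scan gap, and
six 6 h spectroscopy measurements 3–20 d after EOC with %-level detector
efficiencies. Noise models are the minimal structure the analysis assumes:
Gaussian on current, Poisson on counts, Gaussian on the pyrometer.

The implanted inventory handed to the counting generator is the parent plus
equilibrated daughters at EOC — the same convention the estimator assumes —
so EOC pull distributions test estimator calibration, not convention
mismatch. Every generator is a pure function of (truth, seed).

What the generator does **not** emulate, and hence what passing tests do
not establish about real data: contaminant mass spectra (the broad
molecular-ion structure seen with oxide matrices), detector drift and
efficiency-calibration error, correlated picoammeter noise, peak-fitting
systematics, and time-varying release during temperature steps.

## Problem sizes

Statistical tests use seeded replicate counts chosen to make the assertions
sharp at modest cost: 100 seeds for EOC pull calibration and release-rate
recovery in the acceptance suite (40 in the module suite), 200 replicates
for estimator bias, 10⁵ draws for Monte-Carlo propagation audits. The
whole suite runs in well under two minutes on one core.

## Known limitations

* Uncertainties on fitted release parameters come from the least-squares
  covariance; no bootstrap over the trace is offered.
* The coincidence σ ignores accidental-subtraction correlations (negligible
  at the supported regimes; see above).
* The EOC fit assumes a single scale parameter — joint fitting of several
  samples or a drifting detector is out of scope.
* `estimate_gap_loss` resamples donors i.i.d., ignoring serial correlation
  in the current; its σ is therefore slightly optimistic for strongly
  drifting signals.
* The temperature models are validated for tantalum-container/rhenium-source
  geometries; other emissivities require refitting, not new physics.
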