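# Methods

This note documents the models, measurement conventions and numerical
choices behind `buzzpause`, and what the synthetic data do and do not
establish about real recordings.

## Response model

The post-buzz pause is an integer number of milliseconds and can never be
zero, so all modelling uses the zero-truncated Poisson (ZTP):

P(K = k | λ) = λᵏ e^{−λ} / (k! (1 − e^{−λ})), k ≥ 1, with mean
μ(λ) = λ / (1 − e^{−λ}). At pause-scale rates (λ ≈ 100–200) the truncation
correction is below double precision, so the rate is effectively the mean;
the correction matters, and is always applied, when the model is exercised
at small rates.

Log-scale quantities use `log1p(−exp(−λ))` / `log(−expm1(−λ))` branches so
the pmf is accurate for λ from 1e−10 to 1e4. Sampling is exact: rejection
from the untruncated Poisson for λ ≥ 1 (acceptance ≥ 1 − e^{−1}), inverse
CDF over k ≥ 1 for λ < 1. The suite checks the sampler against the analytic
pmf by χ² goodness of fit at 10⁶ draws.

### Mixed model

log λᵢ = xᵢ′β + u_{date(i)} + v_{bat(i)}, u ∼ N(0, σ²_date),
v ∼ N(0, σ²_bat), bat nested within date (every bat appears on exactly one
date). The marginal likelihood factorises over dates; each date block
integrates a (1 + B_d)-dimensional Gaussian (one date intercept, B_d bat
intercepts).

- **Laplace (default).** The block integral is approximated jointly at the
  penalized mode, found by damped Newton on the (1 + B_d) intercepts. The
  block Hessian is an arrowhead matrix (diagonal over bats plus a date
  border); blocks are small, so it is solved densely. Modes are warm-started
  across outer-optimizer iterations.
- **Nested AGHQ (optional).** Each bat's 1-D integral given the date effect
  is computed by adaptive Gauss–Hermite quadrature (mode and curvature by
  scalar Newton), and the date effect is then integrated by a second 1-D
  AGHQ layer. One node reproduces Laplace; the suite checks that 15-node
  estimates agree with Laplace to 1e−3 on well-separated data and that the
  log-likelihood settles as nodes increase. Laplace is the default because
  date blocks are few and the Poisson rates are large, which makes the
  integrands very nearly Gaussian; on test data the Laplace fit agrees with
  glmmTMB (an independent implementation) to ~1e−6 in coefficients and
  log-likelihood.

Estimation maximizes the approximate marginal likelihood over
(β, σ_date, σ_bat) with L-BFGS-B; σ is bounded below by 1e−6 and a fit
ending with σ < 1e−4 is reported with a boundary flag (σ̂ = 0 is a legal
MLE, not an error). Starting values: β from a fixed-effects-only ZTP fit
(BFGS with analytic score), σ = 0.1. Fixed-effect covariance is the inverse
observed information of β with the variance components held at their
estimates (the usual conditional convention).

### Inference conventions

- **Parameter count** k = fixed effects + variance components, used both in
  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) and in the residual df.
- **Contrast df** = n − k (87 observations, 3 fixed coefficients and 2
  variance components give df 82); contrast p-values use the t distribution
  at that df, Bonferroni-multiplied by the number of pairs (3).
- **Type-II Wald** for a term in an additive model is the Wald χ² of that
  term's coefficient block in the full fit, df = block size.
- **Estimated means** back-transform the level's linear predictor through
  μ(λ); CIs transform the Wald interval on the link scale.
- **Dispersion check**: the observed variance of Pearson residuals is
  compared with its simulation distribution under the fitted model
  (informational only; the ZTP has no free dispersion parameter).

## Signal measurement

The envelope is the short-time in-band power: 128-point FFT, Han window,
magnitude squared summed over 30–100 kHz (the fundamental's band), in dB
referenced to a full-scale sine, floored at −120 dB. Frame times are window
centres. Detection runs a coarse scan (hop 8) against a median noise floor
plus a 6 dB margin, merges regions closer than 0.5 ms, then recomputes a
hop-1 envelope in a padded window around each candidate — numerically
identical to full sample-level overlap, without its memory cost on long
recordings.

Endpoints are the outermost crossings of (per-pulse peak − 15 dB), linearly
interpolated between frames; if that level falls below the noise floor the
bound clips to the floor crossing and the event is flagged. Events shorter
than 0.2 ms are dropped. With equal peaks, the earliest frame is the peak.
The 128-sample window (0.256 ms support) bounds endpoint accuracy; on
synthetic data at ≥ 20 dB SNR the median endpoint error is well under
0.1 ms, and because true pauses are exact integers, a combined two-endpoint
bias under 0.5 ms makes the rounded measured pause equal the ground truth
exactly — which the suite verifies on noiseless data for every attack.

Phase labels follow the inter-pulse interval (onset to onset) to each
pulse's successor: buzz ≤ 15 ms, search ≥ 40 ms, approach between (the
trailing pulse inherits its predecessor's label). A terminal buzz is a
maximal run of buzz labels extended by the one trailing pulse that closes
the last buzz interval, of at least 5 pulses total. The pause runs from the
last buzz pulse's end to the next detected pulse's start — by default any
pulse, not only a search-labelled one, because the first post-attack pulse
can be transitional; `strict_search_resume` restores the stricter reading.
Pauses round to the nearest integer ms with a floor of 1; gaps beyond 2 s
are treated as bout boundaries and censored rather than recorded.

## Synthetic data

The generator's defaults are the package's reference study conditions:
outcome probabilities 0.518 / 0.292 / 0.190 and per-outcome ZTP rates
200 / 153 / 114 ms for captured / dropped / failed, with log-scale random
intercept SDs 0.10 (bat) and 0.05 (date). Calls are hyperbolic
(constant-period-slope) downward sweeps, 90 → 40 kHz fundamental with a
second harmonic at 0.35 relative amplitude. Because a hyperbolic sweep
spends dt/df ∝ 1/f² at frequency f, the amplitude envelope
(f/f_peak)·exp(−(f − f_peak)²/4s²) gives a Gaussian *energy* spectrum
centred on the 50 kHz peak (s = 15 kHz). `n_harmonics` counts total
components (fundamental included), so the default of 2 stays below Nyquist
at 500 kHz; the anti-aliasing precondition is
sample_rate ≥ 2·n_harmonics·f_start.

Durations and intervals are conventions, not measured facts, and are fully
configurable: search pulses 4 ms at 90 ms IPI, a 6-pulse approach ramp
40 → 20 ms, twelve 0.5 ms buzz pulses at 6 ms IPI, then the drawn pause and
resumed search pulses. Pulse onsets land on exact sample indices, so the
scheduled integer-ms pause is exact in the waveform. Noise is white
Gaussian at a configurable RMS (optionally high-passed at 10 kHz to mimic a
band-pass front end whose upper edge sits at Nyquist). A single seed fans
out into named substreams (outcomes, pauses, effects, assignment,
covariates, noise), so each stage is independently reproducible.

What the synthetic data deliberately omit: propagation and Doppler effects,
echoes and prey echoes, multi-microphone geometry, amplitude variation
across a pass, overlapping bats, and buzz-I/buzz-II substructure. Passing
tests therefore demonstrate that the measurement chain is correct *given*
the assumed call structure and stationarity of noise — not that detection
thresholds are optimal for any particular field deployment. The per-date
weather and temperature covariates are generated with **no** effect on the
pause, so model selection should, and does, prefer the outcome-only model.

Observed field data are typically more dispersed than a pure ZTP (a
reported s.e.m. of ~11 ms at n = 37 implies an SD near 68 ms, far above
√200); the generator's random-effect SDs are the lever for reproducing
either regime, since the ZTP itself has no dispersion parameter.

## Problem sizes and tolerances

The replication entry points (`buzzpause.calibration`) use 500 replicate
datasets of 87 observations for contrast recovery and 5 000 observations
per outcome for mean recovery; the type-I-error study uses 500 null
replicates and checks the rejection rate at α = 0.05 against [0.03, 0.08].
Rendered-audio test fixtures use ~10 attacks per dataset at ~30 dB SNR —
enough for exact pause recovery to be a stringent check while keeping
synthesis fast. Outer optimizer tolerance is 1e−8 on the projected
gradient; inner Newton solves to 1e−10 relative. Degenerate inputs are
contracts, not crashes: empty datasets yield empty tables, a buzz at the
end of a recording is "unmeasurable", a single-level factor or rank
deficient design raises a validation error, and non-convergence is flagged
on the fit rather than silently returned.
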