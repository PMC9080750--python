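# buzzpause

Acoustic analysis of prey-capture success in trawling bats, built around the
**post-buzz pause**: the silent interval between the end of a terminal
("feeding") buzz and the next echolocation pulse. In field recordings of
*Myotis*-type trawling bats, that pause separates attack outcomes — longest
when the prey is captured and handled, intermediate when it is dropped, and
shortest after a failed attempt — which makes it an acoustic indicator of
predation success that needs no video confirmation.

`buzzpause` implements the full measurement and inference chain as a tested,
reusable pipeline:

1. **Synthesis** (`buzzpause.synth`) — ground-truthed single-channel
   ultrasonic recordings (16-bit PCM WAV, 500 kHz): downward hyperbolic FM
   calls (fundamental ≈ 90 → 40 kHz, spectral peak near 50 kHz, harmonics),
   search → approach → buzz phase structure, outcome-dependent integer-ms
   pauses from a zero-truncated Poisson, bat-within-date random effects,
   Gaussian background noise.
2. **Pulse detection** (`buzzpause.detect`) — in-band short-time power
   envelope (128-point FFT, Han window, up to sample-level overlap), robust
   noise floor, and per-pulse endpoints refined to the **−15 dB** points
   below each pulse's own peak power, with sub-frame interpolation.
3. **Buzz segmentation** (`buzzpause.segment`) — inter-pulse-interval phase
   labelling, terminal-buzz location, and the post-buzz pause in integer
   milliseconds (floored at 1; over-long gaps censored).
4. **Inference** (`buzzpause.glmm`, `buzzpause.inference`) — a
   **zero-truncated Poisson GLMM**,

   log λᵢ = xᵢ′β + u_date(i) + v_bat(i),   kᵢ | u,v ∼ ZTPoisson(λᵢ),

   with Gaussian random intercepts for date and for bat nested within date,
   fitted by direct maximum likelihood under a joint Laplace approximation
   (optionally nested adaptive Gauss–Hermite quadrature). On top of the fit:
   AICc model selection, a likelihood-ratio test against the
   random-effects-only null, type-II Wald χ² per factor, Bonferroni-adjusted
   pairwise rate-ratio contrasts, and truncation-corrected estimated means
   λ̂/(1 − e^{−λ̂}) with 95% CIs.
5. **Orchestration** (`buzzpause.pipeline`, `buzzpause.cli`) — a seeded,
   deterministic simulate → detect → measure → fit → report run with an
   attrition funnel, JSON/CSV outputs and the two report figures.

The statistical core is a scikit-learn-style estimator
(`ZeroTruncatedPoissonGLMM` with `fit`, `predict`, `get_params`); the
detector and segmenter follow the same parameter conventions.

## Worked example

```python
from buzzpause.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_attacks=40, n_bats=6, n_dates=3, seed=7, out_dir="run")
report = run_pipeline(cfg)
```

Everything below is actual output of that run. The funnel shows no attrition
because at ~30 dB SNR every buzz is found and every pause is measurable:

```
funnel: {"attacks_simulated": 40, "pulses_detected": 960,
         "buzzes_found": 40, "pauses_measurable": 40,
         "observations_modelled": 40}
best model: outcome          (AICc 333.34; +temperature ΔAICc 2.76,
                              +weather ΔAICc 2.78, null ΔAICc 230.92)
LRT vs null:   χ² = 236.02, df = 2, p < 1e-51
type-II Wald:  χ² = 227.87, df = 2, p < 1e-49
contrasts (ratio ± se, df 35, Bonferroni p):
  captured/dropped  1.297 ± 0.034   p = 3.6e-11
  captured/failed   1.723 ± 0.068   p = 2.7e-15
  dropped/failed    1.328 ± 0.053   p = 9.6e-08
estimated means (ms, 95% CI):
  captured 202.9 [194.0, 212.3]
  dropped  156.5 [149.0, 164.3]
  failed   117.8 [109.3, 127.0]
```

The generator draws pauses at 200/153/114 ms for captured/dropped/failed, so
the fitted means land on the truth within sampling error, the pairwise
ratios recover 200/153 ≈ 1.31, 200/114 ≈ 1.75 and 153/114 ≈ 1.34, and the
nuisance covariates (weather, temperature), which have no generating effect,
lose the AICc comparison. `run/` also contains the per-stage CSVs, the JSON
report, and the two figures (pause-by-outcome box plot with model means,
per-bat attack accumulation with pause-coded markers).

The same stages are available from the shell:

```bash
buzzpause simulate --config cfg.yaml --seed 7 --out-dir run
buzzpause detect   --wav run/recordings/rec0000.wav --out pulses.csv
buzzpause measure  --pulses pulses.csv --annotations run/ground_truth_attacks.csv --out attacks.csv
buzzpause fit      --data attacks.csv --models outcome,outcome+weather --out fit.json
buzzpause run-all  --config cfg.yaml --seed 7 --out-dir run
```

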