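# ventltf

Model-based analysis of **ventilatory long-term facilitation (LTF)** during
interval exercise with mild (3%) CO2 inhalation.

LTF is a persistent, slowly developing increase in respiratory motor output
that outlasts the stimulus that induced it — classically elicited with
intermittent hypoxia. Combining interval cycling exercise with 3% inhaled
CO2 provides comparable chemoreceptor stimulation without hypoxia's
complications. The analytical problem this package addresses: ventilation
measured during the post-exercise recovery interval mixes the
chemoreceptor-mediated response to CO2 with the neural LTF augmentation.
Separating them requires a model of each.

The package is aimed at respiratory physiologists and modelers. It provides:

- **`ventltf.neuropool`** — the neural substrate model: coupled
  self-excitatory / self-inhibitory neuronal pools,

  t₁ dI₁/dt = −I₁ + C₁₁I₁ − C₂₁I₂ + D,  t₂ dI₂/dt = −I₂ + C₁₂I₁ − C₂₂I₂,

  whose drive→I₁ transfer is the canonical second-order system
  (A s + B) / (s ((s/wₙ)² + 2ζ(s/wₙ) + 1)); simulation (RK4), the exact
  mapping to (wₙ, ζ, A, B), and closed-form step responses in all damping
  regimes. The initially upward-curved second-order step response is what
  distinguishes LTF from first-order (decaying-exponential) short-term
  potentiation.
- **`ventltf.chemoreflex`** — central + peripheral first-order compartments
  with gains G_c, G_p ((L/min)/mmHg), fixed time constants (120 s / 15 s)
  and transport delays (10 s / 6 s), predicting the ventilation deviation
  driven by PetCO2 deviations from baseline.
- **`ventltf.synthetic`** — a generator for 7-subject groups on the
  five-step protocol (rest 5 min; 40 W 6 min; 45% VO2max 6 min; 40 W 6 min;
  80% VO2max 6 min, sampled every 30 s), with work-rate-dependent exercise
  drive, chemoreflex response, a delayed second-order LTF augmentation in
  the recovery interval, between-subject variability and measurement noise.
  Every component is stored separately so pipeline stages can be verified
  against ground truth.
- **`ventltf.decompose`** — the analysis pipeline: least-squares chemoreflex
  gain fit on the initial 40 W interval, removal of the predicted
  chemoreceptor contribution over the whole record, rebaselining to the
  start of the 45% VO2max interval, threshold-based onset detection, a
  second-order LTF fit, and extrapolation to the model asymptote with
  combined-variance bookkeeping.
- **`ventltf.stats`** — Bartlett variance-equality test (from summary
  variances), chi-square critical values, quadrature SD combination,
  standard errors, paired t tests.

## Worked example

```sh
ventltf simulate --seed 1 --out group.csv          # 7 synthetic subjects, 3% CO2
ventltf decompose --traces group.csv --seed 1 --out results.json
ventltf report --results results.json
```

prints

```
Decomposition summary
---------------------
Chemoreflex gains: Gc = 1.978, Gp = 2.315 (L/min)/mmHg (fit SD 0.90 L/min)
Augmentation onset: not detected
LTF fit: wn = 0.375 rad/min, zeta = 0.70, B = 7.96 L/min, baseline = 7.25 L/min, onset delay = 2.00 min
Model asymptote: 15.2 L/min above control (8.0 above initial augmentation)
Final augmentation: 15.2 +/- 1.00 L/min (SE), p = 2.65e-05 vs zero (n = 7)
Combined SD: 2.65 L/min (group 2.49, fit 0.90)
```

Reading this: the fitted gains absorb both the CO2 response and the 40 W
exercise drive (deliberately — the recovery interval repeats the same work
rate, so the absorbed drive cancels there; see `docs/methods.md`). The
corrected, rebaselined neural series shows an initial augmentation of about
7.3 L/min at recovery onset and a slow further rise; fitting the
second-order response (published dynamics wₙ = 0.375 rad/min, ζ = 0.7,
onset delay 2 min held fixed) estimates the rise amplitude B ≈ 8.0 L/min,
i.e. a model asymptote of ≈ 15.2 L/min above the pre-exercise control —
for this seed, within noise of the generator's true 16.6 (7.6 + 9). The
2·SD onset-threshold rule did not trigger at this noise level (the rise is
slow); the fit then uses its default onset delay. The paired t test
confirms the augmentation differs from zero.

The same steps are available as library calls
(`generate_group`, `run_pipeline`) — see the test suite for examples.

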