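# Methods

## Models

### Neural pools and the second-order form

Respiratory motor output is modeled as the instantaneous average activity
I₁ of a self-excitatory neuronal pool coupled to a self-inhibitory pool I₂:

    t₁ dI₁/dt = −I₁ + C₁₁ I₁ − C₂₁ I₂ + D
    t₂ dI₂/dt = −I₂ + C₁₂ I₁ − C₂₂ I₂

t₁, t₂ (min) are effective build-up/decay time constants, the Cᵢⱼ
dimensionless interconnection strengths, D a tonic chemical drive. The
model is linear and unclamped: activities may go negative (no threshold
nonlinearity is imposed). With

    K = C₂₁C₁₂ − (C₁₁ − 1)(1 + C₂₂)

a finite steady state exists iff K > 0, with I₁* = D(1+C₂₂)/K. Eliminating
I₂ gives the drive→I₁ transfer (A s + B) / (s·((s/wₙ)² + 2ζ(s/wₙ) + 1))
with

    wₙ² = K/(t₁t₂)
    ζ   = [t₁(1+C₂₂) − t₂(C₁₁−1)] / (2 wₙ t₁ t₂)
    A   = D t₂ / K
    B   = D (1+C₂₂) / K

The ζ expression is derived directly from the characteristic polynomial
t₁t₂s² + [t₁(1+C₂₂) − t₂(C₁₁−1)]s + K of the ODE pair, which is the
authoritative definition; −ζwₙ ± wₙ√(ζ²−1) reproduce the eigenvalues of
the 2×2 system matrix to 1e−8 (property-tested). The I₂ transfer is not
given a closed form; I₂ is only ever simulated from the ODEs. Its
derivative-of-I₁ character (a rate sensitivity) is the mechanistic reading
of why *intermittent* stimulation initiates LTF.

Step responses are evaluated in closed form in all damping regimes
(underdamped, critical, overdamped), including the A·s numerator term,
which contributes A·h(t) with h the impulse response of the normalized
denominator and nothing at steady state — the asymptote is always
baseline + B. Closed forms agree with RK4 integration of the ODEs to
better than 1e−4 relative on randomized stable parameter draws.

Units: canonical parameters carry an explicit `time_unit`. Animal phrenic
step-response parameters are per second (wₙ = 0.075 rad/s); the human
recovery-segment LTF parameters are interpreted per minute
(wₙ = 0.375 rad/min) — the 6-min recovery window and a ~30-min approach to
asymptote are only consistent with rad/min.

### Chemoreflex

The ventilation deviation driven by a PetCO2 deviation from baseline is the
sum of a central and a peripheral first-order compartment:

    τ_c dx_c/dt = −x_c + G_c·ΔPet(t − d_c)
    τ_p dx_p/dt = −x_p + G_p·ΔPet(t − d_p)

Defaults: τ_c = 120 s, τ_p = 15 s, d_c = 10 s, d_p = 6 s (configurable,
never fitted). Only the gains G_c, G_p ((L/min)/mmHg) are free parameters.
Because every signal is a deviation from baseline, chemoreceptor
thresholds/set-points drop out. Hypoxic drive, CO2 body stores and
breath-by-breath (non-uniform) sampling are out of scope.

Numerics: input deviations are linearly interpolated onto an internal grid
fine enough to resolve τ_p (substep ≤ τ_p/10), delays are applied by linear
interpolation into the history (sub-sample delays supported, zero history
before t = 0), and each compartment is advanced with the exact exponential
update for piecewise-linear input. Discontinuous step inputs are therefore
smeared by at most half an input sample; against the analytic step solution
the error is < 1e−3 L/min at 0.01-s sampling.

## Synthetic data generator

The generator emulates the statistical structure of a 7-subject interval
study sampled every 30 s over five segments (rest 5 min; 40 W 6 min;
45% VO2max 6 min; 40 W 6 min; 80% VO2max 6 min). Samples are stamped at
interval starts (t = 0, 0.5, …, 28.5 min; 58 samples), so "the value at
the start of exercise X" is a pre-transient boundary sample — matching the
baseline conventions below.

Per subject, ventilation is the sum of separately stored components:

- resting baseline 10 L/min;
- exercise drive: first-order rise (τ = 0.5 min) to a work-rate amplitude —
  40 W → 10, 45% VO2max → 22, 80% VO2max → 40 L/min above rest. These are
  plausible magnitudes for young active males; only differences between the
  two 40 W intervals and the 45% interval matter to the pipeline.
- chemoreflex component: the two-compartment response (truth
  G_c = 2.0, G_p = 1.0 (L/min)/mmHg) to the PetCO2 deviation profile. Under
  3% CO2 the deviation is +7 mmHg sustained through all exercise segments
  (comparable protocols controlled PetCO2 ~8 mmHg above control); under air
  a +1.5 mmHg transient during the first 2 min of each exercise step. Both
  approach their targets with a 0.5-min time constant.
- LTF component, recovery (second 40 W) segment only: an initial
  augmentation (baseline 7.6 L/min) plus a delayed second-order rise
  (wₙ = 0.375 rad/min, ζ = 0.7, A = 0, B = 9, onset delay 2 min) — i.e. an
  asymptote 16.6 L/min above the 45%-start control, of which only ~53% of
  the rise falls inside the 6-min window.
- subject offset ~ N(0, 5.3² L/min²) and i.i.d. per-sample noise
  ~ N(0, 1.7² L/min²); PetCO2 measurement noise SD 0.3 mmHg. The VE SDs
  echo the study-scale group variances (≈ 28–31 (L/min)²) and group fit SD
  (1.73 L/min). No autocorrelated noise is modeled.

Generation is a pure function of (config, condition, seed); subject seeds
derive from the master seed via `numpy.random.SeedSequence`. Ventilation is
floored at 0.1 L/min (never binding in noise-off configurations).

What the generator does *not* emulate: breath-by-breath variability and
autocorrelation, gas exchange (VO2/VCO2), cardiovascular coupling,
condition- or subject-specific LTF magnitudes, and drift in PetCO2
baselines. Passing recovery tests on these traces therefore shows the
pipeline is correct *under its own model assumptions*, not that real data
satisfy them.

## Decomposition pipeline

Two explicit baselines (both logged): the **40 W-start baseline** (first
sample of the initial 40 W interval) for the chemoreflex correction, and
the **45%-start baseline** (first sample of the 45% VO2max interval) for
the augmentation itself.

1. **Gain fit.** (G_c, G_p) minimize the squared difference between the
   group-average ΔVE and the chemoreflex prediction over the initial 40 W
   interval only, by Nelder-Mead simplex with non-negativity enforced by
   reflection at zero (restarts on non-convergence; flagged, not raised).
   The exercise drive at 40 W is collinear with the sustained CO2 stimulus,
   so the fitted gains deliberately absorb it; because the recovery
   interval repeats the same 40 W work rate, the absorbed drive cancels
   there, which is precisely why only 40 W data are used for estimation. A
   PetCO2 peak-to-peak swing < 2 mmHg over the fit window (air breathing)
   makes the gains unidentifiable: the fit is flagged and gains set to the
   zero bound. Residual SD is reported with 2 degrees of freedom removed.
2. **Correction.** The prediction (fitted gains, fixed dynamics) is
   evaluated over the whole record and subtracted from ΔVE.
3. **Rebaseline** to the 45%-start sample (exact grid match required).
4. **Onset detection.** First time in the recovery interval at which the
   neural series exceeds its initial-recovery plateau mean by 2·SD for two
   consecutive samples (SD = chemoreflex-fit residual SD). The plateau is
   the 1.0–2.0-min window after recovery start — later than the segment
   boundary because the first ~1 min is dominated by the exercise
   off-transient (τ = 0.5 min), which is not LTF. The threshold multiplier
   sensitivity (1.5–3.0) is reported in diagnostics. On a noiseless
   second-order rise with a 2-min delay the rule triggers at 2.5 min; the
   false-trigger rate on flat noise is ≤ 5%. With the default noise and the
   truth's slow rise the rule often does not trigger inside the window —
   detection failure is reported, and the fit falls back to its default
   onset delay.
5. **LTF fit.** Least squares of baseline + B·u(t′ − τ) on the recovery
   window, excluding its first 1.5 min (off-transient; the step model
   cannot represent it and its large deviations would otherwise dominate
   the objective). `fit_ltf` can free any of (wₙ, ζ, τ); amplitude B is
   reflected at zero (a negative-amplitude "fit" of the off-transient decay
   is not an augmentation), ζ is confined to (0.05, 2] by a logistic
   transform, wₙ is kept positive by a log transform. Multi-start
   Nelder-Mead (deterministic grid + seeded jitter) with a polishing pass.

   *Identifiability.* With 30-s sampling, a 6-min window, group-average
   noise ≈ 0.6 L/min and a response completing only ~half its rise
   in-window, the Fisher information leaves B essentially unconstrained
   when the shape is free (the B–wₙ–τ trade-off admits wₙ→0 ramp solutions
   with unbounded B; the Cramér-Rao SE of B exceeds 100 L/min with ζ free).
   The pipeline therefore holds the dynamics at the published human LTF
   values (wₙ = 0.375 rad/min, ζ = 0.7, τ = 2 min — ζ = 0.7 is the
   convention carried over from phrenic-activity modeling and is used in
   the animal fit as well) and estimates amplitude and baseline. The
   all-free fit remains available for clean or near-complete responses and
   recovers all five parameters of a noiseless curve to ~1e−3 relative or
   better (property-tested).
6. **Extrapolation and bookkeeping.** The asymptote above control is
   baseline + B; above the initial augmentation it is B. The model past the
   observation window is a prediction, not a measurement — the package
   reports both the model asymptote and the measured end-window estimate
   without reconciling them. Per-subject finals (mean of the last two
   recovery samples of each subject's corrected, rebaselined series, using
   the group-fitted gains and individual baselines) give the group SD;
   combined SD = √(group SD² + fit SD²), SE = combined SD/√n, plus a paired
   t test of the finals against zero. The 80% VO2max segment is generated
   but never modeled or fitted.

## Statistics

Bartlett's variance-equality test is computed from summary statistics
(sample variances and group sizes) with the standard correction factor C;
the uncorrected numerator is exposed for diagnostics. At the study's
printed variances (28.07, 31.36; n = 7 each) the corrected statistic is
0.0170 against the χ²(0.95, 1) threshold 3.84. Chi-square quantiles, SD
combination in quadrature and standard errors are thin, validated wrappers;
the paired t test delegates to scipy with an explicit zero-variance error
path.

## Problem sizes and runtime

Monte-Carlo assessments in the test suite use 10–200 replicates (20 groups
for end-to-end recovery, 200 for variance calibration and false-positive
rates), chosen so the whole suite runs in under a minute on one core while
keeping Monte-Carlo error well inside the asserted tolerances. The
acceptance script averages the pipeline over 20 independently seeded
groups.

## Known limitations

- The chemoreflex gains estimated during exercise are *effective* gains:
  they include the exercise drive and are interpretable only through the
  interval design (same work rate in fit and recovery intervals).
- The LTF asymptote is a model extrapolation beyond the data window; its
  stability rests on the assumed published dynamics.
- The threshold onset rule is an algorithmic stand-in for visual detection
  and is insensitive to slow rises at realistic noise; the fit does not
  depend on it when dynamics are fixed.
- The generator applies one LTF truth to both gas conditions; condition
  differences in LTF magnitude (air being weaker/later) are not modeled.
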