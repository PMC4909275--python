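# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic experiments demonstrate.

## Signal model

A pulse record is modeled as `Y(t) = A(t) s(φ(t)) + σ(t) Φ(t)`:

* `s` — the wave-shape function: 1-periodic, unit L2 energy over one
  period, written as a truncated Fourier series with cutoff D (default 6;
  pulse harmonics above the 6th carry negligible energy). Its dominance
  parameter δ = max_{ℓ≠1} a_ℓ/a₁ (with a_ℓ the harmonic magnitudes)
  expresses that the fundamental dominates; the tail parameter θ is 0 for
  an exactly truncated series.
* `A(t) > 0` — amplitude modulation (pulsus alternans and slower drifts).
* `φ(t)` — phase in cycles, strictly increasing; `φ′(t)` is the
  instantaneous frequency (IF) in Hz, i.e. the beat-to-beat heart rate.
* Regularity: `|A′| ≤ ε φ′` and `|φ″| ≤ ε φ′` for a small ε. The generator
  computes the realized discrete ε of every trace and the validator checks
  it; typical study-condition fixtures have ε ≈ 0.06–0.1.
* `Φ` — stationary, unit standard deviation, possibly colored and
  heavy-tailed; `σ(t)` a slowly varying level.

**Identifiability and gauge.** `(A, s, φ)` are determined only up to an
amplitude scale (`A·s = (cA)·(s/c)`) and a phase origin
(`s(·+c), φ−c`). The package fixes the gauge canonically: shapes have unit
energy and their fundamental in cosine phase (β₁ = 0, α₁ > 0). Estimated
signatures are reported raw and renormalized to unit shape energy
(`normalize_sps`); comparisons against generator truth use the normalized
form. The estimated phase origin is absorbed by the estimator itself,
which is why generated cohorts keep β₁ = 0 per record.

## Synthetic generator

Defaults emulate the study conditions end to end: fs = 100 Hz, 10-s
records; sinusoidal HRV — IF = 1.1 Hz ± 10% at 0.1 Hz modulation
frequency, random phase per record; sinusoidal AM — 1 ± 0.1 at 0.15 Hz; a
six-harmonic control template with decaying harmonic magnitudes and
spread-out harmonic phases, and a case template with attenuated higher
harmonics (a flatter pulse); within-group variation N(0, 0.02) per Fourier
coefficient (re-normalized); ARMA(1,1) noise `a(z) = 1 + 0.5z`,
`b(z) = 1 − 0.3z` under the convention `a(B)x = b(B)e`, driven by i.i.d.
Student-t₃ innovations, standardized to unit sample s.d. after a
500-sample burn-in, added at 0 dB SNR (`20 log₁₀(std signal/std noise)`).
The lag-1 autocorrelation of this noise is ρ₁ ≈ −0.662 (closed form),
which the tests verify against the generator.

What the generator does **not** emulate: baseline wander and contact
artifacts of real tonometry, beat-to-beat wave-shape changes (premature
contractions), respiration-locked modulation structure, and any
physiological coupling between IF, AM and shape. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
clinical performance.

## Time-frequency analysis

STFT per the definition `V(t,η) = ∫ f(s) h(t−s) e^{−i2πη(t−s)} ds` with
the Gaussian window `h(t) = (2πσ)^{−1/2} e^{−t²/σ²}`, σ = 0.5 s. Notes:

* The printed normalization is not unit-integral; it cancels in the band
  reconstruction through the h(0)^{−1} factor.
* The kernel phase runs in `t−s`; for a real signal the positive-frequency
  coefficients then carry the **conjugate** analytic phase (a tone
  `cos(2πξ₀t)` appears as `∝ e^{−i2πξ₀t}` near η = ξ₀). Under this
  convention the reassignment frequency is
  `ω = η + Im(V_{h′}/V_h)/(2π)` (exactly ξ₀ for a tone, verified to the
  bin width), and the demodulator conjugates and doubles the band
  integral, `R = 2·conj(∫_band S dξ)/h(0)`, so that a unit tone yields
  Ã ≈ 1 and an increasing phase.
* Window truncation at 4σ; hop 1 sample (the regression needs estimates
  at every sample); frequency axis 0–10 Hz in 0.02-Hz bins (10-s records
  have 0.1 Hz native resolution; the oversampled binning sharpens ridge
  reading without inventing resolution); coefficients below 10⁻⁴ of the
  frame maximum are excluded from reassignment (guards the division).
* The synchrosqueezed transform uses a histogram kernel: each retained
  complex coefficient is added to the output bin containing its ω, scaled
  by dη/dξ so the result is a density in frequency; per-frame complex
  mass is conserved up to the thresholded and out-of-range coefficients
  (asserted exactly in the tests).
* An O(N²) direct evaluation of the discretized definition serves as the
  correctness oracle (agreement to 10⁻¹⁶ relative on a 64-sample signal).

## Ridge extraction and demodulation

The IF curve maximizes `Σ_t log(|S(t,c_t)| + 10⁻¹²) − λ Σ_t (Δc_t)²`,
solved exactly by dynamic programming over the 0.5–3 Hz search band
(30–180 bpm). The jump penalty is measured in **bins** (λ = 1 per squared
bin): in Hz units the default penalty would be numerically inert at this
bin width, while in bin units it suppresses noise-driven jumps yet costs
real HRV drifts (< 0.1 bin/frame at hop 1) essentially nothing.

Reconstruction sums SST coefficients within ±0.25 Hz of the ridge — wide
enough for ±10% HRV excursions, narrow enough to exclude the 2nd harmonic
for fundamentals ≥ 0.5 Hz. Edge frames (within one window half-width,
2 s, of either end) are excluded from quantitative use; all quoted errors
are interior-frame errors.

Two accuracy refinements beyond the bare chain, both the package's own
choices:

1. **Detrending.** The baseline term `A(t)α₀` sits at 0–0.3 Hz, and the
   short σ = 0.5 window leaks it into the band around the ~1.1 Hz
   fundamental, rippling Ã. A zero-phase 4th-order Butterworth high-pass
   at 0.4 Hz (reflect-padded by 3 filter time constants) is applied before
   the TF analysis. The regression still sees the raw record, so α₀ is
   estimated unharmed.
2. **Second pass.** After a provisional SPS fit, the fitted non-fundamental
   harmonics (baseline + harmonics 2..D) are subtracted and the
   demodulation is repeated on the residual; the final SPS is refit on the
   raw record with the refined Ã, φ̃. One pass leaves ~13% relative L2
   ripple on Ã under study conditions (2nd-harmonic leakage); two passes
   reach ~3%. `n_passes=1` disables the refinement.

Measured on 20 study-condition fixtures: median interior max-IF error
≈ 0.025 Hz (about one 0.02-Hz bin), median AM relative L2 error ≈ 0.03.

## Wave-shape regression

Design rows `c₀ = Ã`, `c_ℓ = Ã cos(2πℓφ̃)`, `d_ℓ = Ã sin(2πℓφ̃)`
(2D+1 rows); the SPS is the least-squares solution, computed by a
rank-revealing factorization rather than inversion of the normal matrix
(identical when the normal matrix is invertible; a conditioning error is
raised for degenerate phases, and a warning above condition 10⁸). With
oracle Ã, φ̃ on noiseless records the fit recovers the generator
coefficients to ≈ 10⁻¹⁴ relative. With the full estimated path plus 0 dB
ARMA-t₃ noise, the median per-harmonic relative error is below 8% for
harmonics carrying ≥ 5% of the shape energy. Harmonic powers
`p_ℓ = (α̃_ℓ² + β̃_ℓ²)/4` discard the phase information the SPS retains —
two shapes with equal harmonic magnitudes but different harmonic phases
have identical powers and distinct SPS.

Because the phase is a regressor and not a resampling target, the SPS is
invariant to the particular admissible phase function: two noiseless
records sharing (A, s) but with different HRV give SPS vectors agreeing
to ≈ 0.5% relative.

## Cohort statistics

* **Functional ANOVA.** Pointwise one-way F at each SPS coordinate,
  summed over coordinates; significance by label permutation with
  `p = (1 + #{perm ≥ obs})/(1 + n_perm)` (999 permutations by default,
  significance level 0.01). Measured type-I rate at nominal 0.05: ≈ 0.043
  over 1000 null simulations with 199 permutations.
* **GPS.** PLS1 regression of the 0/1 label on the SPS matrix
  (scikit-learn, `scale=False` since SPS coordinates are commensurate;
  2 latent components by default, configurable), folded into one affine
  coefficient vector β so scoring is a dot product. The sign of β is a
  gauge: which group scores higher depends on the label coding, so the
  ROC layer takes an explicit orientation flag.
* **ROC / AUC.** Full threshold sweep; AUC as the trapezoidal area
  (equal to the rank statistic); Youden-optimal operating point, with the
  cut placed at the midpoint of the optimal inter-score interval so
  marginal held-out scores are split evenly; percentile bootstrap CI
  (1000 replicas; degenerate single-class resamples are redrawn).
* **Cross-validated evaluation.** Three views are reported: the ROC on
  pooled leave-one-out GPS scores (needed for thresholds and the CI), the
  **leave-pair-out AUC** — refit without one control and one case, count
  which scores higher — which is the headline generalization AUC because
  pooled leave-one-out scores are biased pessimistic in small samples
  (measured null mean ≈ 0.44 at n = 40, vs ≈ 0.49 for leave-pair-out),
  and the apparent in-sample AUC for reference (strongly optimistic:
  ≈ 0.9 on null cohorts of this size). LOOCV accuracy refits per fold,
  picks the threshold on training scores, classifies the held-out record,
  and repeats 200 times with seeded tie-breaking (a tie-free pipeline
  makes all repeats identical; the spread is reported).
* The analysis unit is the record, not the subject.

Separable synthetic cohorts (20+20, template difference ≥ 3× the
within-group spread, 0 dB noise) give GPF p ≤ 0.01 (floor of the
permutation count), leave-pair-out AUC 1.0 and LOOCV accuracy 1.0; null
cohorts give held-out AUC ≈ 0.47 ± 0.13 per cohort (mean over 7 replicate
cohorts is reported to tame that sampling noise) and GPF rejections at
the nominal rate.

## Numerical conventions and degenerate inputs

Time is in seconds, sample k at `t₀ + k/fs`, 0-based; phases in cycles;
frequencies in Hz. Zero-amplitude demodulation frames inherit the
neighboring phase by interpolation. Signals must be finite and uniformly
sampled (1-column files need an explicit rate; timestamp gaps that are
whole multiples of the sampling period — dropped rows — are tolerated,
jitter above 10⁻⁶ relative is not). All randomness flows from explicit
seeds through splittable generators; identical invocations are
byte-identical.

## Problem sizes

Validation batteries use 20 fixtures per recovery experiment, 1000 null
simulations for permutation-test calibration, 20+20-record cohorts, and
7 replicate null cohorts — sizes at which every reported quantity's
sampling noise is small against its acceptance margin while a full run
stays in the minutes range on one core.

## Known limitations

* Single-component model: one oscillatory mode only (no multi-ridge
  extraction), per the model's scope.
* The wave shape is time-invariant within a record; morphology changes
  mid-record (ectopic beats) are treated as noise.
* The demodulation refinements assume the fundamental carries
  non-negligible energy; shapes with a nearly absent fundamental
  (δ-pathological) would need the search band and bandwidths revisited.
* Boundary frames (2 s per edge at the default window) are structurally
  unreliable and excluded from all quantitative outputs.
* Clinical figures from recordings of real cohorts are out of scope;
  synthetic-cohort results characterize the algorithms, not patients.
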