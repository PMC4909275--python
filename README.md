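# pulsesst

Adaptive non-harmonic analysis of arterial pulse waveforms.

Single-channel pulse recordings (radial tonometry, PPG, ...) oscillate at
the heart rate, but neither the rate nor the beat strength is constant:
heart-rate variability (HRV) and pulsus alternans are always present, and
they confound classical spectral pulse analysis, which assumes a steady
rhythm. `pulsesst` models a pulse record as

    Y(t) = A(t) · s(φ(t)) + σ(t) Φ(t)

where `s` is a 1-periodic, unit-energy **wave-shape function** (the
morphology of one pulse cycle, described by its Fourier coefficients
α₀, α₁..α_D, β₁..β_D with harmonic cutoff D = 6), `A(t) > 0` a slowly
varying amplitude modulation, `φ(t)` a strictly increasing phase whose
derivative φ′(t) is the instantaneous frequency (the beat-to-beat heart
rate), and Φ a stationary unit-variance noise process that need be neither
white nor Gaussian.

The analysis chain:

1. **Time-frequency analysis** — short-time Fourier transform with a
   Gaussian window `h(t) = (2πσ)^(-1/2) e^(-t²/σ²)`, σ = 0.5 s, sharpened
   by the **synchrosqueezing transform** (SST): each STFT coefficient is
   reallocated along frequency to its reassignment frequency
   ω = η + Im(V_h′/V_h)/(2π), preserving per-time invertibility.
2. **Ridge demodulation** — the dominant SST curve (extracted by exact
   dynamic programming with a smoothness penalty) estimates φ′(t); summing
   the complex SST coefficients in a narrow band around the ridge and
   dividing by h(0) recovers the fundamental component, giving Ã(t) and,
   by phase unwrapping, φ̃(t).
3. **Wave-shape regression** — the model is linear in the shape
   coefficients given Ã and φ̃: regressing Y on the functional vectors
   c_ℓ(k) = Ã(k)cos(2πℓφ̃(k)), d_ℓ(k) = Ã(k)sin(2πℓφ̃(k)) yields the
   (2D+1)-dimensional **spectral pulse signature (SPS)**
   γ̃ = (α̃₀, α̃₁..α̃_D, β̃₁..β̃_D). Because the non-linear phase is absorbed
   into the regressors, the SPS is insensitive to HRV, and unlike the
   power spectrum it retains the harmonic phases.
4. **Cohort statistics** — groups of SPS vectors are compared with a
   permutation-calibrated functional ANOVA (globalized pointwise F), and
   folded into a scalar **global pulse signature (GPS)** by partial least
   squares regression on the group label, evaluated by ROC/AUC with a
   1000-replica bootstrap CI, leave-pair-out AUC, and 200× leave-one-out
   cross-validated accuracy.

Because no public pulse corpus accompanies this method, the package ships
a first-class synthetic generator (`simulate_cohort`) emulating the study
conditions: 10-s records at 100 Hz, six-harmonic pulse shapes, sinusoidal
HRV near 1.1 Hz and slow AM (±10%), and ARMA(1,1) noise with i.i.d.
Student-t₃ innovations at 0 dB SNR.

## Worked example

```sh
pulsesst simulate --seed 11 --n-control 10 --n-case 10 --out-dir cohort
pulsesst classify cohort/manifest.tsv --out classify.tsv
pulsesst report classify.tsv
```

prints

```
Cohort classification summary
  functional ANOVA (GPF): statistic=1.51e+03, p=0.002
  GPS ROC (leave-one-out scores): AUC=1.000 (95% CI 1.000-1.000)
  operating point: sen=1.000 spe=1.000 acc=1.000
  LOOCV accuracy: 1.000 ± 0.000
```

The simulated control and case groups use different wave-shape templates
(the case template emulates the flatter, harmonically poorer pulse of
impaired ventricular ejection), so the SPS distributions differ strongly:
the functional ANOVA rejects equality (p = 0.002 is the smallest value a
499-permutation test can report beyond 0.002), and the GPS separates the
groups perfectly despite the 0 dB heavy-tailed noise. On a *null* cohort
(both groups drawn from one template, `pulsesst simulate --null`) the
held-out AUC drops to ≈ 0.5 and the test rejects only at its nominal rate.

Per-record inspection:

```sh
pulsesst demod cohort/rec000.tsv --out demod.tsv
head -3 demod.tsv
# pulsesst v0.1.0 config=77043d9acc2d seed=0
# mean_if_hz=1.10056 std_if_hz=0.0840648
# t_s if_hz A phase_cycles
```

The mean instantaneous frequency 1.10 Hz (66 bpm) and its s.d. 0.084 Hz
recover the generator's 1.1 Hz heart rate with ±10% sinusoidal HRV
(0.11 Hz modulation amplitude ≈ 0.078 Hz RMS).

The same steps are available as library calls: `simulate_cohort`,
`analyze_record` (returns ridge, demodulation and SPS), `gpf_test`,
`fit_gps`, `roc_analysis`, `loocv_accuracy`.

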