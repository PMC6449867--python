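# Methods

This note documents the signal models, the parameter choices that matter,
and the limits of what the test suite demonstrates.

## Signal chain

### Respiratory events

Tracheal breathing sound occupies roughly 200–2000 Hz. The chain is:

1. **Bandpass 200–2000 Hz.** A 401-tap linear-phase FIR (Hamming design,
   > 50 dB stopband) with the constant group delay compensated, so event
   timing is preserved. For full-night processing the filter's *magnitude
   response* is instead applied as a zero-phase per-bin gain inside the STFT
   pass below — equivalent for envelope detection and one large array pass
   cheaper; the time-domain form remains the reference implementation for
   the unit-level operation.
2. **Spectral subtraction.** One-sided STFT (hann, 1024 samples ≈ 205 ms,
   50 % overlap); the noise template is the mean magnitude spectrum of the
   quietest 10 % of frames (energy ranking), which tracks the stationary
   floor while excluding breath bursts. Cleaned magnitude
   `max(|X| − α|T|, 0.01·|X|)` with the original phase, weighted
   overlap-add reconstruction. α = 2 over-subtracts deliberately: the
   template is the *mean* of a Rayleigh-distributed magnitude, and about
   10 % of matched-noise energy would survive α = 1.
3. **Envelope.** Short-term RMS `E = sqrt((1/N) Σ x_i²)` over 200 ms
   windows hopped by 50 ms — long enough to smooth heart-sound energy,
   short enough to resolve breaths ≥ 0.3 s. A mean-absolute variant is
   available via `resp.envelope_kind`; both satisfy E(const a) = |a| and
   scale equivariance.
4. **Breath detection.** Threshold 1.2 × median(E) (values below are "no
   breathing"); maximal supra-threshold runs lasting 0.3–10 s become
   breaths (onset = run start, amplitude = run max). The median-based rule
   adapts to recording gain; BB intervals outside 1–15 s (4–60 breaths/min)
   are excluded from statistics.

### Cardiac events

Heart sounds S1/S2 dominate 5–30 Hz. Audio is decimated to 250 Hz
(anti-aliased), bandpassed 5–30 Hz with a zero-phase 4th-order Butterworth,
and the analytic (Hilbert) envelope is thresholded at median + 3·MAD.
Two refinements matter in noise:

- **Relative amplitude gate.** Peaks below 0.35 × the 80th percentile of
  detected peak heights are discarded. The MAD threshold tracks the noise
  floor; the gate tracks the S1/S2 amplitude scale. Without it, noise
  excursions just above the floor occasionally usurp a true peak during
  pairing and displace the beat by 100–300 ms.
- **Centroid timing.** Beat-peak times are the squared-envelope centroid
  over ±60 ms rather than the envelope argmax; on the broad heart-sound
  envelope this reduces NN-interval RMSE from ~30 ms to < 17 ms at 10 dB
  in-band SNR.

**Pairing.** Each beat is a pair of adjacent peaks whose gap lies in the
S1–S2 plausibility window 0.15–0.45 s. Among all matchings of disjoint
adjacent pairs the one with the most pairs, then minimal total gap, is
selected by a dynamic program (ties pair the earlier peak). A greedy
smallest-gap-first scan is *not* equivalent — it can strand two pairable
peaks around a locally minimal gap — and the test suite checks the DP
against exhaustive enumeration for up to 12 peaks. The beat is timed at the
first peak (S1), matching the ECG R-peak convention for HRV.

**Gap repair.** NN intervals exceeding 1.5 × the rolling median of the
preceding 10 intervals are treated as detection dropouts (bad coupling,
movement) and filled with synthetic beats spaced at that median, flagged in
`interpolated_mask`; gaps with no preceding context stay unfilled. The
fraction of interpolated beats is itself a feature, so the classifier can
discount movement-corrupted epochs.

### Movement

Madgwick's gradient-descent IMU filter fuses gyroscope integration
(`q̇ = ½ q ⊗ ω`) with an accelerometer gravity-alignment correction of gain
β = 0.1 (his published stable default; units 1/s). Two implementation
details: the normalized gradient is projected onto the tangent space of the
unit quaternion sphere (its radial component is cancelled by
renormalization and otherwise dominates far from the solution, stalling
convergence near the antipodal saddle), and the filter is initialized from
the tilt implied by the first accelerometer sample. Zero-norm accelerometer
samples fall back to gyro-only updates. The inner loop is numba-compiled;
a full night at 250 Hz fuses in about a second.

Sleeping position is the canonical body direction nearest the gravity
vector in the sensor frame, under the default mounting (z dorsal-ventral,
y cranial): supine ↔ gravity −z, prone +z, left +x, right −x, upright −y;
exact ties resolve in that priority order. The classification is invariant
to rotation about gravity (yaw is unobservable without a magnetometer,
which the device lacks). A 5-sample hysteresis debounces label flicker so
jitter does not inflate the position-change count. Activity features use
| ‖a‖ − g | rather than full gravity-vector subtraction, avoiding
dependence on fusion accuracy during vigorous movement.

## Features (30 per 30-s epoch)

13 respiratory: breathing rate, BB mean/SD/CV/RMSSD/range/lag-1
autocorrelation, breath-amplitude mean/SD/CV, envelope energy, fraction of
epoch above the breath threshold, envelope spectral peak in 0.1–0.5 Hz.
13 cardiac: HR, NN mean/SDNN/RMSSD/pNN50/CV/lag-1 autocorrelation, LF
power (0.04–0.15 Hz), HF power (0.15–0.4 Hz), LF/HF, normalized LF,
fraction of interpolated beats, NN range. 4 movement: dominant position,
position changes, mean | ‖a‖ − g |, mean ‖ω‖.

Interval statistics pool events from the epoch ± 60 s (a 30-s epoch holds
only ~5–8 breaths, too few for stable variability estimates); spectral HRV
uses ± 120 s, the standard short-term HRV length, on the NN series
linearly resampled at 4 Hz; amplitude/energy features use the epoch alone.
Degenerate epochs (no usable events) yield NaN cells that are imputed at
matrix assembly with the recording median of that feature and flagged —
never exceptions.

## Classifier

Gaussian linear discriminant on the 30 features, standardized by
training-set location/scale (global, not per-subject normalization —
subject-specific normalization is deliberately out of scope). Pooled
within-class covariance with diagonal shrinkage
Σ* = (1−λ)Σ + λ·diag(Σ), λ = 0.1 by default: with 30 features and rare
deep-sleep epochs the plain pooled estimate is fragile. Priors are the
empirical class frequencies (uniform available). Ties in the discriminant
break toward wake, then training class order. No temporal smoothing of the
predicted hypnogram by default (an optional median filter exists but is
off). The estimator follows the scikit-learn protocol (`fit`, `predict`,
`predict_proba`, `get_params`) and serializes to JSON.

## Validation layer

Leave-one-out cross-validation trains on all-but-one subject. Per-stage
accuracy is reported both averaged over folds and from the pooled
confusion matrix (the two common readings of "averaged over all data
sets"); the unweighted Cohen κ is computed from the pooled epochs.
Sleep efficiency = sleep epochs / all epochs × 100; TST/TWT at 0.5 min per
epoch; WASO counts wake after the first sleep epoch (a first-of-3-
consecutive onset rule is available). SE groups use half-open bins with
the boundary in the upper group (SE = 40 → 40–59). Screening dichotomizes
at each threshold; the ROC sweeps the *continuous* estimated SE against
fixed reference membership, and the test suite proves the trapezoid AUC
equal to the Mann–Whitney U formulation.

## Synthetic nights

The generator emulates exactly the structure the chain assumes:

- **Hypnogram**: first-order Markov chain over 30-s epochs, starting in
  wake, with a dwell-calibrated transition matrix (stationary mix at
  default bias ≈ 19 % W, 15 % REM, 12 % N1, 34 % N2, 20 % N3).
- **Per-stage physiology** (defaults): breathing rate 16/17/15/14/13
  breaths·min⁻¹ and BB CV 0.25/0.30/0.15/0.08/0.05 for W/REM/N1/N2/N3;
  heart rate 70/64/62/58/55 bpm with SDNN 55/70/50/40/25 ms and LF/HF
  3.0/3.5/2.0/1.0/0.5; movement bursts 60/2/6/2/0.5 h⁻¹ and
  position-change probability 0.10/0.01/0.02/0.01/0.003 per epoch. These
  encode the directions the method relies on — regular breathing and low
  HRV in deep sleep, the most irregular respiration and highest HRV in
  REM, movement concentrated in wake.
- **Audio**: breaths are 1.5-s bursts of 200–2000 Hz band-limited noise
  with fast attack; beats are 20 Hz Gabor pairs (σ = 25 ms, S2 at +0.3 s
  with 0.6 relative amplitude) superimposed additively so the two
  band-separated extractors face realistic crosstalk; NN intervals carry
  LF (0.10 Hz) and HF (0.27 Hz) sinusoidal modulation split to match the
  stage's SDNN and LF/HF, plus white jitter. White noise is added at the
  configured SNR (default 10 dB, defined against in-burst breath RMS).
- **IMU**: gravity-consistent accelerometer for the current roll angle,
  smooth 2-s roll transitions with matching gyroscope traces, sensor noise,
  and stage-rate movement bursts.
- **Cohort SE spread**: each subject gets a wake-propensity multiplier,
  log-evenly spaced over [0.3, 5]: transitions into wake scale linearly
  and the wake dwell time sub-linearly (√bias), mapping the cohort onto
  sleep efficiencies from roughly 10 % to 95 %. This emulates the wide SE
  range of a clinical referral population and gives the screening analysis
  members on both sides of every threshold.
- **Determinism**: all draws flow from `default_rng([seed, subject])`;
  identical seeds reproduce bit-identical nights.

What the generator does *not* emulate — and hence what green tests do not
show about clinical data: snoring and speech artefacts overlapping the
breath band, apneas/hypopneas, electrode-style signal loss, S2 amplitude
variation with respiration, between-subject physiology overlap (each stage
has one parameter set per subject), and scorer disagreement in the
reference hypnogram. Synthetic staging scores (κ ≈ 0.9) are therefore an
upper bound of chain correctness, not a clinical performance claim; on real
referral cohorts, cardiorespiratory staging is known to be limited by
subject variability.

## Numerical choices and degenerate inputs

- Epochs are half-open `[30k, 30(k+1))`; trailing partial epochs are
  discarded. Audio at rates other than 5 kHz is resampled so filter
  designs have one reference rate.
- Full-night STFT work runs in float32 (amplitudes are O(1), detection
  thresholds adaptive); unit-level operations keep float64.
- Constant features get unit scale in normalization; all-NaN feature
  columns impute to 0; covariance rows of constant features get unit
  diagonal before inversion, and a Cholesky check raises on residual
  singularity.
- κ with chance agreement 1 (both raters constant on the same label)
  returns 1 for perfect agreement, else 0, with a warning; screening with
  all subjects on one side of the reference threshold reports NaN rates
  and skips the AUC.
- Problem sizes in the test suite: event-detection checks use 5-minute
  single-stage recordings; end-to-end staging, physiology recovery and
  screening share one 10-subject × 2-hour cohort generated per session.
  These sizes give stable statistics (≈ 2 400 pooled epochs, ≈ 76 000
  beats) at desk-scale runtimes.

## Known limitations

- Sleep onset for WASO defaults to the first sleep epoch; clinical
  definitions vary.
- The LF/HF spectral estimate uses a periodogram of the linearly
  interpolated NN series; Lomb–Scargle would avoid interpolation bias at
  high HRV.
- Position classification assumes the declared mounting; a mis-mounted
  sensor permutes position labels (configurable, not auto-detected).
- The 4-stage system's deep-sleep class rests on HRV/respiratory
  regularity alone and degrades first as noise rises — consistent with the
  ordering 2-stage ≥ 3-stage ≥ 4-stage accuracy that the suite asserts.
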