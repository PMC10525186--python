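# Methods

## Problem

Rest tremor in the hand is driven by rhythmic contraction of antagonist
forearm muscles. Electromyography distinguishes two contraction patterns:
**alternating** (A — flexor and extensor bursts out of phase, typical of
Parkinsonian tremor) and **synchronous** (S — bursts in phase, typical of
essential-tremor-like syndromes). The package asks whether this muscular
pattern can be recovered from *inertial* data alone: 10 s segments from a
6-axis IMU (3 accelerometer axes in g, 3 gyroscope axes in deg/s, 100
samples/s) worn on a finger of the tremulous hand.

The flexo-extension movement projects mainly onto the `a_y`/`a_z`
accelerometer axes and the `w_x` gyroscope axis; those three channels carry
most of the engineered features.

## Pipeline

1. **Band-pass filtering** — 2–10 Hz, 4th-order Butterworth applied
   forward–backward (`sosfiltfilt`), i.e. zero phase and the squared
   single-pass magnitude. "4th order" follows the MATLAB/Octave `butter`
   convention (order-4 low-pass prototype, 8 poles after the band-pass
   transform). Edge transients are handled by odd-reflection padding of
   3 time constants of the 2 Hz edge (150 samples).
2. **Periodicity quality check** — on the dominant (largest peak-to-peak)
   acceleration axis: the Welch-spectrum maximum over 2–10 Hz must fall in
   [3, 8] Hz, and the zero-crossing count of the mean-subtracted channel
   must be at least `ceil(f_peak · T)` — half the `2·f_peak·T` crossings of
   a pure sine at the peak frequency. The peak is *located* in 2–10 Hz and
   then *tested* against [3, 8] (the narrower band is an acceptance
   criterion, not a search restriction). Ties in the dominant-axis choice
   break in the fixed order `a_y, a_z, a_x`. Failure is a value
   (`peak_out_of_band` / `aperiodic`), not an exception, and propagates to
   a `fail` classification response.
3. **Spectral estimation** — every auto-/cross-spectrum and the coherence
   use the same Welch setup: 3 s Hann window (300 samples), 75% overlap,
   zero-padded to 2^16 FFT points (grid ≈ 0.0015 Hz), density scaling.
   Ten windows average over a 10 s segment.
4. **Feature extraction** — 63 canonical features (see
   `segmentio.FEATURE_NAMES`): peak frequencies of the six axis PSDs and
   of the `a_y`–`a_z` cross-spectrum; spectral densities at the peak;
   Pearson correlation, magnitude-squared coherence and absolute
   cross-spectral phase of the `a_y`/`a_z` pair; −3 dB band powers and
   bandwidths; per-second concentration statistics; peak-to-peak
   amplitudes and their vectorial magnitudes; the sum of the first two
   harmonics on `a_z`; and db2 3-level wavelet band summaries of all six
   raw channels.
5. **Group statistics** — per-feature Shapiro–Wilk (α = 0.05) on each
   class, Welch t-test if both classes look normal, otherwise Wilcoxon
   rank-sum (normal approximation with continuity correction);
   Benjamini–Hochberg adjustment across the 63 p-values jointly;
   significance at adjusted p < 0.05.
6. **Learning procedure** — stratified 50/50 split; feature ranking by
   Random-Forest mean impurity decrease or XGBoost gain on the training
   half; training on growing prefixes k = 1…63 with the prefix of highest
   *testing* accuracy selected (smallest k on ties); repeated stratified
   5-fold cross-validation (5 × 5 = 25 folds, each 80% train / 20%
   validate) characterizes the selected subset; full confusion-matrix
   metrics, Clopper–Pearson 95% CI on accuracy, Cohen's kappa, trapezoidal
   ROC/AUC and a 10-bin calibration table on the testing half.

### Definitions chosen where the construction was open

* **−3 dB band**: the maximal contiguous frequency run containing the peak
  where spectral magnitude stays ≥ half the peak value; band power and the
  2–10 Hz total power are trapezoidal integrals. Peak finding returns the
  lowest-frequency bin on exact ties.
* **Per-second concentration ("1 s coherence")**: the filtered signal (or
  `a_y`/`a_z` pair) is cut into ten non-overlapping 1 s blocks; each block
  gets a full-block Hann window and the same 2^16 zero-padding (grid
  consistency with the 3 s machinery); the block statistic is
  (−3 dB-band power)/(2–10 Hz total power), using the cross-periodogram
  magnitude for the pair. The four summary moments are *population*
  moments over the ten ratios and kurtosis is **non-excess** (normal → 3).
  An all-zero block contributes a flagged 0 ratio.
* **Wavelet summaries**: `db2`, 3 levels, *periodization* boundary mode
  (keeps the transform orthonormal; a constant c gives an a3 band of
  c·2^{3/2}). Each band's coefficient array is reduced to its RMS — the
  reduction is not standardized anywhere, RMS is consistent with the
  reported magnitudes (gravity-scale a3 values on `a_y`), and it is
  isolated in one function (`wavelet_band_summaries`) for easy
  substitution. Wavelets see the **raw** channels (the approximation band
  must keep the gravity offset); all other features see filtered channels.
* **Units**: accelerations convert g → m/s² (× 9.80665) *before* spectral
  estimation and before the wavelet transform, so densities are m²/s⁴/Hz
  and wavelet summaries m/s²; peak-to-peak amplitudes are mG (g × 1000)
  for the accelerometer and deg/s for the gyroscope.
* **First two harmonics** = fundamental + 2nd harmonic densities (the
  reported sums exceed the single-peak densities on the same axis).
* **Normality gate**: the t-test requires *both* groups to pass
  Shapiro–Wilk; the parametric branch uses the Welch (unequal-variance)
  statistic because the class variances are wildly unequal.
* **Positive class** = A for sensitivity/PPV/ROC.
* **Best-k selection on the testing half** reproduces the published
  procedure even though it leaks the test set into model selection; the
  per-k repeated CV is run for the selected subset (that is the only place
  its numbers are used — the curve is selected on testing accuracy). Pass
  `cv_final_only=False` to also record per-k CV accuracies.
* **"5-fold CV" vs 25 fold rows** is reconciled as 5 repeats × 5 folds.
* **RF trees** = 500 (not stated in the reference material; `mtry` = 1 is);
  XGBoost uses nrounds 300, depth 4, eta 0.05, gamma 0, colsample 0.4,
  min-child-weight 1, subsample 0.75. These shipped defaults are the only
  grid point required; the config accepts overrides.

## Synthetic-data generator

The clinical recordings behind the reference statistics are not deposited,
so `synthgen` generates stand-ins and the whole validation is
simulation-based. Per segment: tremor frequency from a truncated normal
(A: 4.96 ± 0.65 Hz, S: 5.63 ± 0.69 Hz, truncated to (3, 8)); gyro
amplitude lognormal (right-skew matches reported SDs that exceed their
means); base oscillation `E(t)·[sin θ + h·sin 2θ]` with slow frequency
wander (low-pass noise) and an amplitude-modulation envelope; `w_x`
carries the reference oscillation, other channels scaled phase-offset
copies; gravity ≈ (0.25, 0.95, 0.19)/‖·‖ on the accelerometer (so raw
`a_y` carries most of 1 g); per-segment `a_y`–`a_z` phase offset
|N(0, σ_Δφ)| plus a slow **within-segment phase wander**; white sensor
noise; clipping to ±2 g / ±500 deg/s.

The within-segment wander is the one mechanism not forced by the reported
table: a *constant* inter-axis phase offset leaves magnitude-squared
coherence at ≈ 1, but the synchronous class is reported at 0.81, so some
within-segment decoherence must exist in the real signals; slow relative
phase wander is the minimal model that produces it (and simultaneously
widens the −3 dB band and lowers the per-second concentration, all in the
reported directions).

Class contrast encoding: A = larger amplitude, lower frequency, stronger
harmonics, tighter phase coupling, narrower band; S = the converse. The
calibration targets (frequencies, `w_x` peak-to-peak, `a_y`–`a_z`
correlation/coherence/phase, `w_x` 3 dB bandwidth — see
`synthgen.CALIBRATION_TARGETS`) are matched in value; the remaining
features are only required to separate in the reported direction
(`synthgen.EXPECTED_DIRECTION`) — 63 simultaneous moment constraints would
over-determine a parsimonious signal model.

Randomness: every segment draws from a child stream keyed by
(class, index) under one root seed, so enlarging a dataset never perturbs
existing segments; fixed seed ⇒ byte-identical output.

**What the generator does not emulate** — voluntary movement artifacts,
posture changes, sensor bias/drift beyond white noise, inter-subject
correlation between the five segments of one patient, or EMG traces.
Passing tests therefore demonstrate that the *pipeline* recovers a
class contrast of the reported geometry from plausible oscillatory
signals; they do not certify clinical performance on real recordings.
Classification on the synthetic classes is in fact somewhat easier than
the published task (testing accuracies ≈ 0.97–1.00 vs 0.89–0.92): real
class overlap is driven by biological variability the generator only
partially reproduces.

## Problem sizes and numerics

The shipped experiments use the study's own sizes: 168 segments
(91 A / 77 S) for the classification reproduction, 200 segments per class
for calibration means, 25 CV folds. Smaller sizes appear in unit tests
(e.g. 200 noise seeds for the QC regression rate, where ≈ 15% of pure-noise
records are rejected). Degenerate inputs are defined, not errors: constant
features test at p = 1 (flagged), all-zero concentration blocks contribute
flagged 0 ratios, QC failure is a typed value. Clipping tolerances on
sensor range validation allow 1e-12/1e-9 float slack.

## Known limitations

* The generator's forward model (muscle pattern → inertial signal) is a
  modeling inference, not measured physics.
* The RMS wavelet reduction and the 1 s-periodogram windowing are
  interpretation choices (both isolated behind single functions).
* Best-k selection on the held-out half is reproduced as published;
  reported testing accuracies are therefore optimistically biased model-
  selection statistics, not honest generalization estimates.
* Feature extraction assumes fs = 100 samples/s scale analysis bands
  (wavelet level edges move with fs).
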