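# tremorpattern

Classification of the **rest-tremor muscle-contraction pattern** —
alternating ("A", out-of-phase antagonist bursts, the Parkinsonian
pattern) vs synchronous ("S", in-phase bursts, essential-tremor-like) —
from 6-axis inertial recordings alone, without electromyography.

The input is a 10 s segment from an IMU worn on a finger of the tremulous
hand: accelerations `a_x, a_y, a_z` (g) and angular rates `w_x, w_y, w_z`
(deg/s) at 100 samples/s. The pipeline band-pass filters to 2–10 Hz
(4th-order zero-phase Butterworth), rejects non-periodic segments (Welch
peak in 3–8 Hz and a zero-crossing count of at least half that of a sine
at the peak frequency), extracts **63 features** — spectral peaks,
`a_y`–`a_z` cross-spectral amplitude/coherence/phase/correlation, −3 dB
band powers and bandwidths, second-by-second spectral-concentration
statistics, peak-to-peak amplitudes, harmonic content, and db2 3-level
wavelet band summaries — and classifies with importance-ranked Random
Forest / XGBoost models selected by incremental feature-subset search
with repeated stratified 5-fold cross-validation.

Because the underlying clinical recordings are not public, the package
ships a **calibrated synthetic-signal generator** (`synthgen`): amplitude-
modulated, phase-coupled tremor oscillations with class-dependent
frequency, amplitude, harmonic content, inter-axis phase coupling and
sensor noise, tuned so that extracted feature distributions reproduce the
published class statistics. All end-to-end validation runs on it. See
`docs/methods.md` for the model and every interpretation choice.

Audience: biomedical-signal-processing and movement-disorder researchers
who want a reproducible, scriptable reference implementation of the
method.

## Worked example

```bash
tremorpattern run --n-per-class 84 --seed 42 --out runs/demo
```

simulates 168 labeled segments, filters and quality-checks them, extracts
`features.csv` (63 columns), writes the per-feature A-vs-S comparison
(`comparison.csv`, Benjamini–Hochberg corrected), and trains both models.
The same experiment through the API:

```python
import tremorpattern as tp
from tremorpattern.segmentio import feature_table

segs = tp.generate_class("A", 91, 42) + tp.generate_class("S", 77, 42)
ft = feature_table((s.segment_id, s.label, tp.extract_features(s)) for s in segs)

cfg = tp.TrainConfig(algorithm="RF", seed=42)
train, test = tp.split_dataset(ft, cfg)          # stratified 84/84
ranking = tp.rank_features(train, cfg)           # impurity-decrease order
artifact, curve = tp.incremental_train(train, test, ranking, cfg)
report = tp.evaluate(artifact, test)
print(len(artifact.feature_subset), report["accuracy"], report["auc"])
```

With these settings the API run prints a 40-feature best prefix with
testing accuracy **0.976** and AUC **0.994** for RF (XGBoost: 11 features,
accuracy 0.976, AUC 0.997); the training-half repeated 5×5-fold CV of the
selected RF subset averages accuracy 0.945 / kappa 0.890. (The CLI demo
above, which simulates balanced 84/84 classes instead of 91/77, lands at
RF k=45, accuracy 0.976, AUC 0.994 and XGB k=9, accuracy 0.964,
AUC 0.995.) Top-ranked features are the reference-gyro-axis wavelet/power
features and the `a_y`–`a_z` correlation — i.e. amplitude, regularity and
inter-axis coupling carry the pattern information. Single segments
classify in well under a second:

```bash
tremorpattern classify runs/demo/model_rf runs/demo/segments/A0003.csv
# -> A prob_A=1.0000   (or "fail:peak_out_of_band" if QC rejects it)
```

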