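# pacdetect

A delineation-free detector for premature atrial complexes (PACs) and
ventricular beats in 2-lead ambulatory ECG. Beats annotated with R-peak
positions are classified as normal (N), supraventricular/PAC (S) or
ventricular (V) by a random forest fed with:

* **HRV features (42)** — beat-local RR/dRR values plus mean/SD of RR, SD of
  dRR, pNN10..pNN50 and RMSSD over four time windows (1 and 5 min preceding
  the beat, 2 and 10 min centered on it);
* **morphology features (72 + 72)** — fixed windows around the R peak
  (whole beat, P wave, PR interval, QRS complex) are scored against
  intra-patient templates built from 80/20/4 neighboring beats via
  cross-correlation alignment with outlier exclusion; each comparison yields
  the maximum normalized cross-correlation, its lag, and the template's
  median per-sample spread, on both leads, for the preprocessed signal and
  for the scale-4 detail of an undecimated quadratic-spline wavelet
  transform.

Records are first resampled to 250 Hz, baseline-corrected with cascaded
200/600 ms median filters, and low-passed at 35 Hz (equiripple FIR,
group-delay compensated). Evaluation is strictly patient-wise: a 10-fold
(configurable) cross-validation assigns whole patients to folds balanced on
their S-beat counts, caps each training class at 10,000 beats, and fits the
feature conditioning (physiological RR clipping, variance and Pearson
correlation pruning, z-scoring) on training folds only.

A first-class synthetic ECG generator (sum-of-Gaussians beat kernels with
controllable PAC/PVC morphology and timing, bigeminy/trigeminy/atrial-run
patterns, noise and baseline wander) makes every stage testable without any
data downloads.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the structural
feature counts (48 templates and 72+72 morphology values per beat), the
analytic RR clipping bounds, the 40-beat record trim, the DWT/template/NCC
property suites, and an end-to-end parameter recovery run (20 synthetic
patients, patient-wise 2-fold CV; S and V sensitivity must both reach 90%).
The full run takes a few minutes on one CPU.

## Command line

```bash
pacdetect synth   --out data/ --n-patients 20 --n-beats 150 --seed 1
pacdetect extract --records-dir data/ --out features.csv
pacdetect cv      --features features.csv --mode multiclass --k 10 --seed 1 --out report/
pacdetect all     --out demo/ --k 2          # synth -> extract -> cv in one pass
pacdetect replicate-physionet                # prints the full-data recipe
```

`cv` writes `metrics.json` (beat-wise pooled metrics plus per-patient
median/IQR summaries), `predictions.csv`, `confusion.csv`,
`importances.csv` (top-10 per fold) and a `run_config.json` echo; every
output directory is reproducible from its config echo and seed.

## Layout

```
src/pacdetect/
  io.py           record/annotation reading, beat-symbol simplification
  preprocess.py   resampling, median-filter baseline removal, 35 Hz FIR
  hrv.py          RR/dRR series and windowed HRV statistics
  dwt.py          undecimated quadratic-spline wavelet, scale-4 detail
  morphology.py   segment extraction, template building, NCC features
  features.py     matrix assembly, clipping, pruning, z-scoring
  model.py        fold planning, class caps, random forest, metrics
  synth.py        synthetic annotated 2-lead ECG generator
  cli.py          click CLI and pipeline orchestration
```
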