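# pwave

P-wave measurement and inference for signal-averaged 12-lead ECGs.

Changes in the atrial component of the surface ECG — the P-wave — track
left-atrial remodeling, and are used to evaluate the effect of catheter
ablation for paroxysmal atrial fibrillation: a fall in the P-wave terminal
force in lead V1 directly after a repeat pulmonary-vein isolation is a
candidate marker of procedural success. This package implements the full
measurement chain needed to study that question, together with a
calibrated synthetic 12-lead ECG cohort generator so the chain can be
validated against analytically known ground truth and exercised at
realistic study sizes.

The four indices, per recording:

| Index | Definition | Units |
|---|---|---|
| PWD | P-wave onset to offset; global value = max across leads | ms |
| PWV | isoelectric line to P peak, summed over the 12 leads | mV |
| PWDisp | max − min of per-lead P-wave durations | ms |
| PTFV1 | −(max depth of the V1 terminal negative phase) × (its duration) | mV·ms |

The chain: 16-bit ±5 mV quantization → zero-phase 1–50 Hz Butterworth
band-pass + 50/60 Hz notch → R-peak detection → averaging of 20
consecutive pre-QRS segments per lead → geometric delineation (chord-knee
rule with support refinement against a locally fitted isoelectric line) →
index computation → two-arm pre/post statistics (mean ± SEM, paired /
Welch t-tests gated by the D'Agostino–Pearson normality test, rank-based
fallbacks). `docs/methods.md` documents every model and convention.

## Worked example

Simulate and analyze the packaged calibrated cohort (43 success-arm and
29 failed-arm patients, pre- and post-ablation 60-s records):

```python
from pwave import load_calibration, run_study

report = run_study(load_calibration(), seed=1)
print(report.to_text())
```

prints

```
P-wave parameter study report
seed=1 config=9125a9cc64ee
patients: fail n=29, success n=43 (total 72)
excluded: 0

pwd_ms after fail repeat ablation: 136.2 to 126.7 ms (paired-t, p = 0.000224)
pwv_mv after fail repeat ablation: 1.3 to 1.3 mV (paired-t, p = 0.497)
pwdisp_ms after fail repeat ablation: 31.1 to 31.1 ms (paired-t, p = 1)
ptfv1 after fail repeat ablation: -2.7 to -2.6 mV.ms (paired-t, p = 0.726)
pwd_ms after success repeat ablation: 137.6 to 124.7 ms (paired-t, p = 1.39e-06)
pwv_mv after success repeat ablation: 1.2 to 1.3 mV (paired-t, p = 0.0968)
pwdisp_ms after success repeat ablation: 30.6 to 29.4 ms (paired-t, p = 0.412)
ptfv1 after success repeat ablation: -2.9 to -4.3 mV.ms (paired-t, p = 2.8e-07)

pwd_ms change between arms: insignificant (welch-t, p = 0.295)
pwv_mv change between arms: insignificant (welch-t, p = 0.397)
pwdisp_ms change between arms: insignificant (welch-t, p = 0.668)
ptfv1 change between arms: significant (welch-t, p = 3.41e-06)
```

Reading the output: P-wave duration shortens after ablation in **both**
arms (a generic acute effect of the procedure), while the terminal force
in V1 falls only in the arm whose ablation succeeds — within-arm p ≤ 0.05
in the success arm, p > 0.05 in the failed arm, and the between-arm
comparison of the pre-to-post changes is itself significant. Voltage and
dispersion do not change significantly anywhere. That is the signature
the calibrated generator is built to reproduce.

The same flow is scriptable from the shell, including a file-based path
through the plain-text record dialect:

```bash
pwave simulate --config src/pwave/data/calibration.yaml --seed 1 --out cohort/
pwave measure  --manifest cohort/manifest.csv --out cohort/params.csv
pwave report   --measurements cohort/params.csv --out cohort/report/
pwave intraobserver --config src/pwave/data/calibration.yaml --jitter 2 --seed 1
```

Single-record measurement is two calls:

```python
from pwave import measure_record, read_record
params, template = measure_record(read_record("cohort/success-001-pre.txt"))
print(params.pwd_ms, params.pwv_mv, params.pwdisp_ms, params.ptfv1)
```

## Layout

```
src/pwave/
  ecg_io.py        text dialect + acquisition-contract validation
  preprocess.py    zero-phase band-pass and notch
  delineate.py     beat detection, template averaging, fiducial rules
  pwave_params.py  the four indices
  cohort_stats.py  normality-gated comparisons, intraobserver variability
  synthetic_ecg.py waveform model, ground truth, cohort generator
  pipeline.py      study orchestration and reports
  cli.py           `pwave` command-line interface
  data/calibration.yaml  packaged two-arm cohort calibration
```
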