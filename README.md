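# amdprog

Drusen imaging-biomarker extraction from segmented SD-OCT volumes and
recurrent-network prediction of the risk of a first exudation event in
non-exudative AMD eyes, with longitudinal outcome labeling, padding-based
sequence augmentation and a patient-level evaluation protocol.  Everything is
exercisable end-to-end on synthetic data with known ground truth.

## What is in here

| Module | Purpose |
| --- | --- |
| `amdprog.synthetic` | Spherical-cap drusen phantoms with closed-form area/volume, and longitudinal cohort simulation with a planted feature-dependent exudation hazard |
| `amdprog.biomarkers` | The 21 drusen features (count, areas, volumes, extent/density, height/slope, normalized reflectivity, 3/5 mm regional, device pass-through columns) plus same-session averaging |
| `amdprog.labeling` | Per-horizon outcome labels {progressor, non-progressor, censored} for horizons 3–21 months with end-of-follow-up censoring |
| `amdprog.model` | Feature encoding, padding augmentation (label 2), a numpy two-layer stacked LSTM (50/20 units, per-timestep sigmoid head) trained with a time-distributed weighted cross-entropy, Adam and early stopping |
| `amdprog.evaluation` | Patient-level stratified tenfold CV, visit-variant analysis, external-cohort testing, fixed-first-visits sensitivity/specificity, ROC/PR metrics, leakage audits |
| `amdprog.benchmark` | The end-to-end planted-signal benchmark shared by the tests and the acceptance report |
| `amdprog.cli` | `amdprog simulate / extract / label / train / evaluate` |

The recurrent network is implemented directly in numpy (forward, full
backprop-through-time, Adam) so no deep-learning framework is required; its
gradients are verified against finite differences in the test suite.

## CLI

```bash
# simulate a 200-eye, 24-month cohort and write the canonical visit CSV
amdprog simulate --n-eyes 200 --seed 1 --out runs/sim

# label every dry observation for each horizon
amdprog label --visits runs/sim/visits.csv --horizons 3,6,9,12,15,18,21 --out runs/labels

# train one model per horizon
amdprog train --visits runs/sim/visits.csv --horizons 3 --seed 1 --out runs/models

# patient-level tenfold cross-validation report
amdprog evaluate --mode cv --visits runs/sim/visits.csv --horizons 3 --seed 1 --out runs/eval
```

Feature extraction from volumetric inputs (NIfTI + JSON sidecar bundles, as
written by `DrusenScanBundle.save`) is exposed via
`amdprog extract --volumes <dir> --out features.csv`.

## Data formats

* **Visit CSV** — one row per observation: `patient_id, eye_id, month` (or
  ISO `date`), demographics (`age_months, gender, race, smoking_status,
  visual_acuity`), `dx_status, treated`, and the 21 feature columns.  Event
  rows carry `dx_status=exudative` / `treated=1`.
* **Scan bundle** — a directory with `drusen_mask.nii.gz`,
  `elevation_mm.nii.gz`, `intensity.nii.gz` and `sidecar.json`
  (`voxel_size_mm`, `fovea_center_mm`, `laterality`).
* **Labels CSV** — long format: `eye_id, patient_id, obs_month, horizon,
  label` with `label ∈ {1, 0, -1}` (−1 = censored).
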