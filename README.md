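# cinetfc

Synthetic cine-CMR ventricular volumetry and 2010 Task Force Criteria (TFC)
classification for arrhythmogenic right ventricular cardiomyopathy (ARVC),
with the full agreement-analysis machinery needed to compare manual and
automatic-style short-axis segmentations.

ARVC is diagnosed by a point-based consensus system in which cardiovascular
magnetic resonance (CMR) contributes one category: a regional right-ventricular
wall-motion abnormality *plus* a functional or dimensional threshold.
Automatic segmentation of short-axis cine CMR makes these measurements cheap,
but its errors concentrate in the most basal slice, where the
ventricular–atrial transition is ambiguous — and because the TFC cutoffs are
hard thresholds, a few millilitres can change a diagnosis category. This
package provides a fully synthetic, reproducible test bed for that chain:

* **`cinetfc.cohort`** — generates cohorts of control / at-risk / ARVC
  subjects, each with a ground-truth ("manual reference") 4D cine label
  volume (LV disc, RV crescent, tapering toward the apex, a smooth cyclic
  volume curve), and a degraded "automatic-like" segmentation whose errors
  follow a configurable slice-location distribution
  (basal / mid-ventricular / apical / outside the heart).
* **`cinetfc.measure`** — voxel-count volumetry, automatic end-diastole /
  end-systole selection (ED = argmax, ES = argmin of the volume curve),
  EDV/ESV/SV/EF with body-surface-area indexing, and the simulated expert
  correction that replaces the most basal slice of an automatic segmentation
  with the reference (`automatic-basal`).
* **`cinetfc.tfc`** — the 2010 CMR criterion: major if RVEF ≤ 40 % or
  RVEDVI ≥ 110 (men) / ≥ 100 (women) ml/m²; minor if 40 < RVEF ≤ 45 % or
  RVEDVI in [100, 110) / [90, 100) ml/m²; always conditional on a wall-motion
  abnormality. Minor = 1 point, major = 2; a total of ≥ 4 points across the
  six categories is a definite diagnosis.
* **`cinetfc.segnet`** — a toy Bayesian dilated-residual segmentation network
  (numpy, hand-written backprop): soft-Dice + cross-entropy loss, Monte-Carlo
  dropout inference averaged over stochastic forward passes, and
  largest-3D-connected-component post-processing.
* **`cinetfc.agreement`** — 3D Dice, exact 3D Hausdorff distance in mm,
  slice-location error attribution, Bland–Altman bias and limits of
  agreement, Pearson r with Fisher-z CI, Cohen's κ with its large-sample SE,
  sensitivity/specificity, and the McNemar test.
* **`cinetfc.pipeline` / `cinetfc.cli`** — the end-to-end experiment
  (simulate → degrade → measure → correct → classify → evaluate) behind a
  `cinetfc` command with `simulate`, `segment`, `measure`, `classify`,
  `evaluate` and `run-all` subcommands.

## Worked example

```python
from cinetfc import ExperimentConfig, run_experiment
from cinetfc.cohort import CohortConfig

cfg = ExperimentConfig(cohort=CohortConfig(n_subjects=40, seed=1), seed=1)
res = run_experiment(cfg)
rep = res.report["methods"]
print(rep["automatic"]["error_attribution"]["rv"])
print(rep["automatic"]["measurements"]["rv_edv_ml"]["bias"],
      rep["automatic-basal"]["measurements"]["rv_edv_ml"]["bias"])
print(rep["automatic"]["kappa"])
```

On this 40-subject cohort (5 % of each structure's voxels flipped per
measured phase, allocated 30.7 / 61 / 5.4 / 2.9 % to
basal/mid/apical/outside slices for the RV and 18.3 / 70 / 7.5 / 4.2 % for
the LV) the run prints, in ~20 s:

* RV error attribution `{'basal': 0.311, 'mid_ventricular': 0.607,
  'apical': 0.055, 'outside': 0.027}` — the generator's allocation is
  recovered from the degraded segmentations;
* RV EDV bias 0.22 ml against manual, shrinking to 0.08 ml after the
  simulated basal-slice correction, with Pearson r > 0.999;
* mean 3D RV Dice at ES 0.9750 before and 0.9754 after correction
  (the correction never lowers Dice on any subject);
* Cohen's κ = 1.0 for the CMR criterion category (none/minor/major): at
  this error level no subject crosses a TFC threshold.

`cinetfc run-all --n-subjects 40 --seed 1 --out results/` produces the same
analysis as CSV, JSON and a Markdown report.

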