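# cortiqct

Vertebral cortical-bone quantification on synthetic CT, end to end:

* **phantom** — voxelized L1-like vertebra phantoms (elliptic cylinder with a
  dense cortical shell around a trabecular core, optional PSF blur and noise)
  with analytic ground truth, plus synthetic cohort tables and a screening
  registry drawn from bundled reference summary statistics.
* **segmentation** — a documented threshold + morphology surrogate that
  splits a CT volume into cortical and trabecular masks.
* **morphometry** — the four cortical parameters: average density
  (ΣHU / volume), average thickness (12-ray casting per slice with sub-voxel
  boundary interpolation, slice means averaged), average area, total volume.
* **qct** — elliptical trabecular ROI placement (90–110 mm²), linear
  HU → mg/cm³ calibration, and the three-class vBMD grouping
  (normal > 120, osteopenia 80–120 inclusive, osteoporosis < 80 mg/cm³).
* **cohort_stats** — Levene's test, one-way ANOVA (raw and
  summary-statistic forms) with LSD post hoc, empirical ROC with the
  Youden-optimal cutoff, DeLong AUC variance/comparison, and a closed-form
  binormal-mixture AUC.
* **pipeline** — screening-flow filtering, stratification, and a seeded
  end-to-end run that emits ANOVA/ROC/DeLong tables plus a summary-replay
  comparison against the bundled reference values.

## CLI

```bash
cortiqct phantom generate --seed 0 --thickness 2.0 --out ph/
cortiqct measure --volume ph/phantom.nii --out morph.csv
cortiqct qct --volume ph/phantom.nii --out qct.json
cortiqct cohort generate --seed 0 --out cohort.csv
cortiqct stats anova --csv cohort.csv --value-col average_thickness --group-col bmd_class
cortiqct stats roc --csv cohort.csv --score-col average_thickness --label-col op
cortiqct run --seed 0 --out results/
cortiqct report --bundle results/bundle.json
```

`cortiqct run` writes `bundle.json` (byte-stable for a fixed seed),
`tables.txt`, `cohort.csv` and `registry.csv` to the output directory.

## Notes

* Volumes are NIfTI-1 (int16 HU, masks uint8); tables are CSV; every
  generated artifact gets a JSON parameter sidecar.
* Total volume is carried in raw mm³; reports and the bundled reference
  tables use the ×10³ display convention.
* The phantom world uses an identity HU↔mg/cm³ calibration, so a phantom's
  trabecular HU equals its target vBMD.
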