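# painsense

Individual-differences pain neuroimaging analysis toolkit: voxelwise
brain–behavior correlation mapping with FDR control, dependent-correlation
comparison (Steiger's z), bootstrap detection-probability / minimal-sample-size
estimation, a LASSO-PCR multivariate sensitivity signature with nested
cross-validation and virtual-lesion interpretation, and an fMRI + behavior
stacking ensemble — all exercisable on a bundled synthetic-cohort generator
with known ground truth.

## Modules

| module | contents |
|---|---|
| `painsense.simcohort` | synthetic cohorts: sparse smooth weight patterns, trial ratings, confounds, twin families, nonpain modalities, treatment arms, NIfTI/CSV fixtures |
| `painsense.unimap` | voxelwise Pearson/Spearman maps, BH-FDR, partial correlation with dataset-wise standardization, ROI summaries, Dice/conjunction, Steiger's z, family mixed-effects maps |
| `painsense.powerboot` | bootstrap detection-probability surfaces, minimal sample sizes, closed-form Fisher-z power oracle, ROI power curves |
| `painsense.signature` | LASSO-PCR fitting (nested 5-fold CV), evaluation (r and variance-explained R²), voxel-space back-projection, learning curves, covariate-adjusted / behavior-only / stacked models, NIfTI+JSON serialization |
| `painsense.probe` | virtual-lesion region importance, signature application, signature comparison, treatment-reduction prediction (with family random intercepts and baseline adjustment), single-trial prediction |
| `painsense.shell` | NIfTI/CSV I/O (documented voxel ordering), pipeline runner with reproducibility manifests, CLI |

## CLI

```bash
painsense simulate --n 100 --seed 1 --out cohort/
painsense map --fixture cohort/ --method pearson --q 0.05 --out maps/
painsense power --fixture cohort/ --sizes 100:400:10 --reps 100 --rule fdr:0.05 --out power/
painsense fit --fixture cohort/ --lambda-grid 1e-2:1e2:100 --folds 5 --seed 1 --out model/
painsense apply --model model/signature --fixture cohort/ --out expressions.csv
painsense lesion --fixture cohort/ --mode remove --out lesion.tsv
painsense run --config run.yaml --seed 1 --out out/
```

`painsense run` executes a multi-stage pipeline (simulate → map → power →
fit → lesion) from a YAML/JSON config and writes a `manifest.json` recording
the config snapshot, master seed, per-stage substream seeds and SHA-256
digests of every output; rerunning the same config + seed reproduces all
outputs bit-identically.

## Library quick start

```python
from painsense import simcohort, unimap, powerboot, signature, probe

cfg = simcohort.SimulationConfig(n_participants=300, seed=0)
bundle = simcohort.simulate_cohort(cfg)
maps = bundle.maps["pain"]
y = bundle.mean_ratings("pain")

stat = unimap.voxelwise_correlation(maps, y, q_level=0.05)
model, report = signature.fit_lasso_pcr(maps, y, seed=0)
weights, constant = signature.backproject_weights(model)
expressions = probe.apply_signature(weights, constant, maps)
```

## Conventions

- Masked voxel vectors are in Fortran order (first image axis fastest);
  world coordinates only via the affine.
- CSV tables are comma-separated UTF-8 with a header; missing values are
  spelled `NA`.
- The LASSO penalty is parameterized on the raw loss
  `||y - Xb||^2 + lambda * ||b||_1`; grids are log-uniform in [1e-2, 1e2].
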