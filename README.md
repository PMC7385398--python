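# braindiff

A tested, reusable pipeline for multimodal brain-imaging group-difference
analysis, driven entirely by a synthetic-cohort generator with known ground
truth. It covers:

- **synth** — synthetic cohorts: subject tables (two gender groups with age
  and education confounds), voxel-wise gray-matter-volume (GMV) maps with
  planted cluster effects, and 4D BOLD runs whose local temporal coherence
  and inter-regional correlation structure differ between groups in planted
  locations. Deterministic under a single master seed.
- **features** — band-pass filtering (zero-phase frequency-domain masking),
  nuisance regression, regional homogeneity (ReHo; Kendall's coefficient of
  concordance over 6/18/26-voxel neighborhoods) with standardization and
  mask-renormalized Gaussian smoothing, atlas region time series, and
  Fisher-z functional connectivity (FC) matrices.
- **stats** — voxel-wise and edge-wise GLM group comparisons with partialled
  covariates (female-minus-male sign convention), family-wise error control
  by Bonferroni or max-statistic permutation, positive/negative weighted
  degree, and demographic two-sample t tests.
- **convergence** — voxel overlap between thresholded difference maps
  (corrected and relaxed "trend" thresholds) and spatial correlation of the
  unthresholded maps.
- **mvpa** — the classification protocol: per-feature covariate removal,
  per-subject z-normalization within modality, modality concatenation,
  group-stratified k-fold CV with embedded |SVM-weight|-ranked feature
  selection over a feature-count grid, accuracy/sensitivity/specificity,
  pooled ROC/AUC, and a permutation null built by shuffling training labels
  within folds (with Bonferroni correction across the grid).
- **io / pipeline / cli** — NIfTI/TSV/JSON round-trips, a YAML-configured
  end-to-end runner with a reproducibility manifest, and a markdown report
  with figures.

## CLI

```bash
braindiff simulate --config examples/cohort.yaml --out cohort/ --seed 42
braindiff features reho --in cohort/ --mask cohort/mask.nii --out feats/
braindiff features fc   --in cohort/ --mask cohort/mask.nii --atlas cohort/atlas.nii --out feats/
braindiff stats voxel --in cohort/ --subjects cohort/subjects.tsv --mask cohort/mask.nii --out stats/
braindiff stats edges --in feats/  --subjects cohort/subjects.tsv --out stats/
braindiff overlap --sig-a stats/sig.nii --sig-b stats/sig.nii --out overlap.json
braindiff mvpa --features X.tsv --subjects cohort/subjects.tsv --folds 10 --grid-step 100 --n-perm 200 --out mvpa/
braindiff run --config examples/cohort.yaml --out run/     # everything
braindiff report --in run/                                 # markdown + figures
```

The full demo (`braindiff run` with `examples/cohort.yaml`) finishes in
well under a minute on one CPU.

## Conventions

- Positive voxel/edge t values mean female > male.
- Sensitivity is the fraction of males classified male; specificity the
  fraction of females classified female; males are the ROC positive class.
- Overall CV accuracy is the unweighted mean of fold accuracies (a
  pooled-count accuracy is reported alongside).
- Per-subject z-normalization uses the population-SD convention.
- Voxel coordinates are 0-based grid indices; synthetic space has no
  anatomical mapping.
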