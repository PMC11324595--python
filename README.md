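# bwaspipe

A brain-wide association (BWAS) pipeline for resting-state fMRI functional
connectivity, built around link-level mass-univariate testing:

- **Preprocessing tail** (`bwaspipe.prep`): Friston-24 nuisance regression
  with WM/CSF and linear-trend regressors, Gaussian smoothing, hard
  frequency-domain band-pass (0.01–0.1 Hz), framewise displacement, and
  intracranial volume.
- **Link-level core** (`bwaspipe.bwas`): all-pairs voxel Pearson FC with
  Fisher z-transform, a vectorized covariate-adjusted group GLM per link,
  Bonferroni family-wise error control over the link family, the per-voxel
  measure-of-association (MA) count of significant incident links, and
  MA-thresholded 26-connectivity cluster extraction.
- **ROI stage** (`bwaspipe.roi`): atlas-anchored ROIs from significant
  voxels, mean-signal ROI time series, ROI-pair FC group tests with
  Benjamini–Hochberg FDR.
- **Cognition** (`bwaspipe.cognition`): composite domain z-scores,
  covariate residualization, and percentile-bootstrap Pearson correlation
  between FC circuits and cognition.
- **Reliability** (`bwaspipe.reliability`): time-domain half-split MA
  recomputation with Dice/Spearman agreement and ROI cross-validation.
- **Cohort statistics** (`bwaspipe.cohort_stats`): pooled two-sample
  t-tests (raw or summary inputs) and the uncorrected Pearson chi-squared.
- **Synthetic cohorts** (`bwaspipe.synthetic`): two-group fMRI-like data
  with analytically controlled circuit correlations, covariates, motion
  traces and cognition couplings, so every stage has a
  parameter-recovery test against known ground truth.

## CLI

All stages are exposed as subcommands of `bwaspipe`:

```bash
# generate a synthetic study (cohort NIfTIs, atlas, labels, phenotype, motion)
bwaspipe simulate --config sim.yaml --out study/

# per-subject preprocessing
bwaspipe prep --in study/sub-001_bold.nii.gz --motion study/sub-001_motion.txt \
    --mask study/mask.nii.gz --out cleaned.nii.gz --tr 2.0 --fwhm 8 --voxel-size 4

# link-level association stack
bwaspipe bwas --cohort study/ --pheno study/phenotype.csv --out out/ \
    --alpha 0.0333 --ma-min 40 --cluster-min 20

# ROI-wise FC group tests
bwaspipe roifc --cohort study/ --pheno study/phenotype.csv --ma out/ma.nii.gz \
    --sig-voxels out/significant_voxels.tsv --atlas study/atlas.nii.gz \
    --labels study/labels.tsv --out out/ --q 0.05

# cognition correlation, half-split reliability, demographics
bwaspipe cognition --pheno study/phenotype.csv --fc out/roi_fc.tsv \
    --domains domains.yaml --out cognition.tsv --nboot 10000 --seed 7
bwaspipe reliability --cohort study/ --pheno study/phenotype.csv --out rel.tsv
bwaspipe cohortstats --pheno study/phenotype.csv --out table1.tsv

# or the whole pipeline from one YAML config
bwaspipe run --config pipeline.yaml
```

A minimal simulation config:

```yaml
grid_shape: [10, 10, 6]
n_timepoints: 200
n_subjects_per_group: [40, 40]
signal_clusters:
  A: [[0, 2, 1], [0, 2, 2], [1, 2, 1]]   # voxel coordinates per cluster
  B: [[8, 2, 1], [8, 2, 2], [9, 2, 1]]
circuit_effects:
  - {cluster_a: A, cluster_b: B, r_cn: 0.6, r_scd: 0.2}
seed: 1
```

Full-scale defaults (alpha = 3.33e-2, MA > 40, cluster >= 20 voxels,
ROI >= 20 significant voxels, FDR q = 0.05, 10,000 bootstrap reps) live in
`bwaspipe.config.PipelineConfig`; toy-scale runs pass scaled thresholds,
since MA magnitude grows with voxel count.

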