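# segtbm

Global-to-local segmentation of tensor-based-morphometry Jacobian maps by
population-level hierarchical spectral clustering, plus the statistical
framework to test segmental **size** and **shape** differences between groups.

Given a cohort of co-registered Jacobian-determinant volumes, the package:

1. builds a voxel affinity `A(i,j) = 0.5 * (corr(J_i, J_j) + 1)` from Pearson
   correlations across subjects, embeds voxels with the top-2 eigenvectors of
   the normalized Laplacian `D^(-1/2) A D^(-1/2)` (averaged Nyström
   estimations on random landmark subsets), and bipartitions them with
   consensus k-means — recursively, for a binary hierarchy of up to 8 levels
   (255 segments when complete);
2. summarizes each segment per subject as a size feature (mean Jacobian) and
   shape features (PCA scores of size-normalized residuals, retained by
   parallel analysis);
3. tests carrier-vs-non-carrier contrasts with covariate-adjusted Student's t
   (size) and CCA (shape), pooling all p-values into one Benjamini–Yekutieli
   ("dep") FDR family;
4. produces thresholded significance maps, weighted Jacobians, phenotype
   ANOVAs, Dice overlap matrices and circular-dendrogram exports.

A first-class synthetic-cohort module plants a binary block hierarchy with
group size/shape effects and covariate confounds, so the whole pipeline is
testable without any clinical data.

## Modules

| module                | contents |
|-----------------------|----------|
| `segtbm.volume_io`    | NIfTI <-> subjects×voxels matrix (`VoxelMask`, `JacobianCohort`), cohort CSV, label-map export, sample-homogeneity QC |
| `segtbm.synthetic`    | `SyntheticSpec`, `generate_cohort`, planted hierarchies, effect planting |
| `segtbm.spectral`     | affinity, normalized Laplacian, Nyström embedding + averaging, consensus k-means, `build_hierarchy` → `SegmentTree` |
| `segtbm.features`     | segmental size, size-normalized residuals, PCA shape space, parallel analysis |
| `segtbm.stats`        | design building, residualization, `size_test`, `shape_test` (CCA), `fdr_dep` (BY), `run_all_contrasts` |
| `segtbm.maps`         | thresholded maps, weighted Jacobians, phenotype ANOVA, Dice, dendrogram export |

## CLI

```bash
segtbm simulate --config spec.yaml --out cohort/          # synthetic cohort
segtbm segment  --cohort cohort/ --levels 8 --seed 7 --out tree.json
segtbm features --cohort cohort/ --tree tree.json --out feats/
segtbm test     --cohort cohort/ --tree tree.json --features-dir feats/ --out results.tsv
segtbm report   --cohort cohort/ --tree tree.json --results results.tsv --out report/
```

`cohort/` is a directory with `volumes/<subject_id>.nii.gz`, `mask.nii.gz`
and `cohort.csv` (columns: subject_id, mutation, status, phenotype, age, sex,
site, family), as written by `simulate`.

Example `spec.yaml`:

```yaml
grid_shape: [10, 10, 10]
levels_planted: 3
factor_sd: 1.0
noise_sd: 0.1
n_per_group:
  "C9orf72:non-carrier": 30
  "C9orf72:asymptomatic": 30
group_size_effect:
  "C9orf72:asymptomatic@4": -0.1   # group@planted-node-id: delta
seed: 7
```

## Conventions

- Matrix columns follow ascending Fortran-order linear indices of the mask
  grid (x fastest); all segment voxel indices are column positions in that
  fixed order.
- Jacobian baseline is 1.0 (volume preserving); values < 1 mean local volume
  loss. Non-positive values inside the mask warn but do not fail.
- Segmentation is unsupervised and uses all subjects; group labels enter only
  at the statistics stage.
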