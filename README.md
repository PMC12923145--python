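# ithkit

Topology-aware intratumoral heterogeneity (ITH) scoring for segmented CT
nodules, plus the downstream machine-learning machinery to use the scores as
biomarkers.

A nodule is scored at two scales:

* **2D score** — on the largest axial cross-section of the mask: per-pixel
  local features (2×2 sliding kernel, a fixed bank of 104 features) are
  clustered with K-means (K = 6 by default) into phenotypic subregions, each
  subregion is decomposed into 8-connected components, and the score is
  `1 − (1/S_total) · Σ_i S_i,max / n_i` where `S_i,max` is the largest
  component of cluster *i* and `n_i` its component count.
* **3D score** — the same construction over the full volume with a 2×2×2
  kernel and 26-connectivity.

A score of 0 means every subregion is one contiguous blob; values approach 1
under extreme spatial fragmentation. Scores are element-count based and do
not depend on voxel-spacing metadata.

On top of the scores the package provides:

* **`phantom_generator`** — synthetic ellipsoidal nodule phantoms with a
  controllable number of phenotypes and disconnected blobs per phenotype
  (known ground-truth topology), and synthetic clinicoradiologic cohort
  tables (two classes at ≈2:1 prevalence, demographic/morphologic columns,
  `ith2d`/`ith3d` columns; one `effect` knob scales every label association,
  with the 3D score carrying the dominant effect).
* **`model_bench`** — six classifiers (GBDT, AdaBoost, XGBoost, LightGBM,
  CatBoost, RF) grid-searched inside stratified 5-fold CV with out-of-fold
  AUC selection, 7:3 stratified splitting, held-out metrics
  (AUC/accuracy/precision/recall/F1), a six-configuration feature-ablation
  study, and a rank-sum comparison of scores between classes. When the
  native XGBoost/LightGBM/CatBoost libraries are not installed, documented
  scikit-learn gradient-boosting stand-ins are used (see
  `ithkit.model_bench.CLASSIFIER_BACKENDS`).
* **`shap_selection`** — SHAP-guided forward feature selection: global
  importance = mean |SHAP| over the cohort, per-classifier prefix-AUC
  trajectories, best-classifier selection, and knee-point identification
  (first prefix whose marginal AUC gain drops to ≤ ε). SHAP values come from
  a built-in path-dependent TreeSHAP engine for scikit-learn tree ensembles
  (`ithkit._treeshap`), validated against brute-force Shapley enumeration.

## CLI

```bash
ith phantom --out-dir ph --phenotypes 3 --fragmentation 2 --seed 7
ith score --image ph/phantom_image.nii.gz --mask ph/phantom_mask.nii.gz \
          --mode both --k 6 --seed 7 --out scores.json
ith cohort --n 600 --effect 1.0 --seed 7 --out cohort.csv
ith bench --cohort cohort.csv --seed 7 --ablation --out report.json
ith ablate --cohort cohort.csv --epsilon 0 --seed 7 --out trajectories.json
```

Images are NIfTI (`.nii`/`.nii.gz`) or NRRD; arrays are handled in
`(slice, row, column)` order. Every command writes a `*.manifest.json` with
the parameters, seed and library versions used, and reruns with the same
manifest produce identical numeric outputs. `bench` accepts a YAML config
overriding any `BenchConfig` field (classifier set, grids, folds, ratio,
averaging mode).

## Notes on fixed conventions

* "Largest cross-section" = maximal in-mask pixel count on axial slices,
  ties to the lowest slice index.
* The 104-feature bank is a documented, versioned stand-in (`v1`): center
  intensities (raw + lung-window clipped), first-order statistics over the
  anchored kernel and 3/5/7 box neighbourhoods, 16-level local entropies,
  finite-difference and Gaussian derivatives, separable edge/spot filter
  responses, and neighbour-comparison fractions. Exactly 104 features in
  both modes; the count is asserted at build time.
* Features are standardized (population z-score) before clustering by
  default; K-means uses seeded k-means++ with 10 restarts.
* Empty clusters contribute 0 to the score sum.
* ε defaults to 0 in knee-point detection; a trajectory with no gain ≤ ε
  returns the full feature count.
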