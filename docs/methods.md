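# Methods

This note documents the statistical model, the algorithmic choices and
their parameters, and the known limitations of the implementation.

## Problem setting

A case-control morphometry cohort: each subject contributes one
gray-matter volume per atlas region, a group label (patient / control),
and nuisance covariates (age, total intracranial volume). The working
hypothesis is that only a *subset* of patients carries a coherent
morphological alteration, so whole-group patient-vs-control contrasts
dilute the effect ("masking"). The package finds patient subtypes that are
defined by how patients deviate *from controls*, not by how patients
differ from each other — a semi-supervised formulation.

## Covariate adjustment

Per region, volume is regressed on the covariates (ordinary least squares
with intercept) using **controls only**; the fitted effect is subtracted
from all subjects and the residuals are standardized by the control
residual mean and SD (ddof=1). Fitting on controls only prevents
disease-related volume differences from being absorbed into the nuisance
model. After adjustment, a patient's feature vector is a z-score profile
relative to the normative control distribution.

## Max-margin polytope subtyping

Patients are separated from controls by K linear soft-margin classifiers
("faces"). Each face is fit with hinge loss; every control enters every
face on the negative side with weight 1/K, while each patient enters only
its currently assigned face, on the positive side, with weight 1. The K
positive half-spaces form a convex polytope around the control
distribution, and the face a patient exits through defines its subtype.

Fitting alternates:

1. **Face refit** — each face is a weighted linear SVM (hinge loss,
   regularization C, default 1.0) over its assigned patients vs all
   controls.
2. **Reassignment** — every patient moves to the face with the largest
   margin-normalized signed score (w·x + b)/‖w‖, i.e. the closest face on
   the positive side. Normalization matters: raw scores favor faces with
   large ‖w‖ (typically those fit to few patients), which destabilizes the
   partition.

Iteration stops when the assignment is stable (default cap 50 rounds). A
face that empties is re-seeded with the patient currently worst-served by
its own face, so all K faces stay live.

### Initialization

The alternation only refines; with region counts exceeding subject counts
it converges to whatever structure the initial split contains, so the
initial split carries most of the statistical weight. Restarts are seeded
with a *shrunken-discriminant* split:

- soft-threshold the patient-minus-control mean-difference direction at
  1.0 standard error per (standardized) feature — the
  nearest-shrunken-centroid idea, which zeroes features whose apparent
  difference is noise;
- k-means (K clusters) on the 1-D projection onto that direction;
- up to 6 refinement rounds: re-estimate one shrunken direction per
  current cluster, project all patients onto all K directions, re-cluster
  in that K-dimensional space. A cluster member's projection onto its own
  cluster's direction is computed leave-one-out (direction re-estimated
  without that patient), which removes the self-selection bias that
  otherwise inflates exactly the projections of the patients that defined
  the direction.

Two such splits (different k-means seeds), a PCA-subspace k-means split
and a raw k-means split lead the restart list; remaining restarts are
random.

### Restart selection

The regularized-hinge objective is *not* a reliable arbiter when features
outnumber subjects: restarts regularly reach lower objective values on
partitions that are pure noise. The kept restart is therefore the one
whose patient partition has the highest mean pairwise adjusted Rand index
(ARI) with the other restarts' partitions — the solution the optimization
keeps rediscovering — with the objective used only to break ties. Within a
single restart the objective is still tracked and is non-increasing across
alternating iterations.

## Choosing K: stability profiling

For each candidate K (default 2..10): split the cohort into 5
group-stratified folds; refit the polytope on each fold's training
portion; assign the **full** patient set with every fold's model; record
the mean pairwise ARI over the 10 fold pairs. The selected K maximizes the
mean ARI (ties go to the smallest K). A planted two-subtype structure
yields a pronounced peak at K = 2 (mean ARI ≈ 0.9 vs ≤ 0.6 for K ≥ 3 on
the default synthetic cohort); a null cohort yields uniformly low values
(≲ 0.2).

## Consensus labeling

The final labeling majority-votes the full-data fit together with the five
fold models' assignments at the selected K, after aligning labels by the
optimal permutation (Hungarian algorithm on the label contingency table).
Ties go to the lowest aligned label.

## Difference maps

Region level: per-region two-sample t-tests (pooled by default, Welch by
flag) of one patient subset vs all controls, Benjamini–Hochberg FDR across
regions at α = 0.05, Cohen's d with (n−1)-weighted pooled SD. Voxel level:
the same mass-univariate test per voxel, BH-FDR across in-mask voxels,
then a cluster-extent filter that keeps connected components strictly
larger than 40 voxels (26-connectivity by default; 6 and 18 available).
FDR precedes extent filtering (threshold-then-cluster). Zero-variance
voxels follow the conventions t = 0, p = 1 (equal means) and t = ±∞,
p = 0 (unequal means).

Subtype numbering in pipeline outputs is canonicalized by descending count
of significant regions vs controls, so "subtype 1" is always the
morphologically altered subtype and reports are comparable across runs.

## Clinical comparisons

Between-subtype two-sample t-tests from raw scores or from published
summaries (mean/SD/n). When only a 95% CI of the mean is available, the SD
is recovered as CI-half-width / t₀.₉₇₅,ₙ₋₁ · √n. Partial correlations
residualize both variables on an explicit covariate set by least squares;
p from t = r·√(df/(1−r²)) with df = n − 2 − #covariates.

## Synthetic cohorts

The generator plants: per-region baselines ~ N(2.5, 0.5²) mL (floored at
0.5), age and TIV confounds (−0.008 mL/year, +0.0015 mL/mL), i.i.d.
Gaussian noise (SD 0.25 mL), and a mean shift of effect_size·noise_sd in
the affected regions for subtype-1 patients only — so effect_size is the
planted per-region Cohen's d. Subtype-2 patients are drawn from the
control model. Default composition: 93 controls, 38 + 37 patients, 246
regions with 30 affected regions named after bilateral subdivisions of
seven pain-processing structures (caudate, putamen, thalamus,
hippocampus, amygdala, precuneus, parahippocampal gyrus), spread evenly
across the region index range. Truth labels live in a separate sidecar
table and never enter the clustering path.

Realism limitations, by design: regions are conditionally independent
given the covariates (no spatial covariance), effects are homogeneous
within a subtype, noise is Gaussian and homoscedastic, and there is
exactly one altered subtype. These make planted-truth recovery measurable
but overstate how cleanly real cohorts separate.

## Problem sizes and runtimes (single CPU)

- One polytope fit (K=2, 10 restarts, default cohort): ~0.2 s.
- One stability profile (K = 2..10, 5 folds, 3 restarts per fold): ~7 s.
- Full pipeline on the demo workspace (K scan 2..10, split-half and
  cross-parcellation validation): ~1 minute.
- The acceptance suite (10-seed panels) runs in roughly 10 minutes.

## Numerical choices

- Linear SVM faces use hinge loss with tol 1e-4, max_iter 5000 and
  intercept_scaling 10 (liblinear regularizes the intercept; the scaling
  reduces that bias).
- Tables are written with %.17g and parsed with correctly-rounded float
  conversion, so write/read cycles are bit-exact and pipeline reports are
  byte-identical across reruns with the same config.
- JSON reports use sorted keys and contain no timestamps; a SHA-256 hash
  of the report payload is embedded for cheap determinism checks.
- All randomness flows from explicit integer seeds through
  numpy.random.default_rng; cross-validation fold f uses seed + 1000·f.

## Limitations

- Subtype boundaries are linear; genuinely non-linear patient
  heterogeneity would need kernelized faces.
- Stability selection of K favors small K when subtypes are of very
  unequal size (a small subtype's fold models vary more).
- At planted effect sizes ≤ 0.8 the subtype distributions overlap; even an
  oracle projection misclassifies patients on unlucky draws, so recovery
  criteria are stated as panel means rather than per-draw guarantees.
- Split-half consistency compares each half against a full-data run that
  shares those subjects, so its null baseline exceeds naive chance; treat
  it as a relative, not absolute, measure.
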