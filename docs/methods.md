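# Methods

`petrad` implements a sex-stratified radiomic analysis of amino-acid
PET lesions: feature extraction from SUV and TBR-normalized volumes,
redundancy reduction, aligned Monte-Carlo resampling with fold
diagnostics, and occurrence-based feature ranking with non-parametric
confirmation. This note records the models, conventions and numerical
choices behind each stage, and what the synthetic cohort generator does
and does not emulate.

## Inputs and normalization

A case is a 3D PET volume in SUV units with a binary lesion mask and a
binary contralateral background mask on the same voxel grid (NIfTI).
Masks are binarized (any nonzero voxel is a member) and must match the
volume's grid; delineation itself is out of scope — masks are inputs.
Cases whose lesion falls below a minimum voxel count (default 64,
configurable) are excluded and logged: texture matrices on very small
ROIs are dominated by discretization noise.

Background statistics use the sample (n−1) standard deviation, matching
common clinical reporting. TBR values are SUVs divided by the mean SUV
of the background region; the implementation scales the whole volume by
1/background-mean so that features whose support extends past the ROI
(the intensity-peak spheres) see consistently normalized context. For
all lesion-restricted features this is exactly voxel-wise division of
the lesion SUVs.

## Feature extraction

Each lesion yields exactly 154 named features (the versioned manifest
`data/manifest_v1.txt`), in eleven IBSI-style families:

| family | n | content |
|---|---|---|
| stat | 18 | intensity statistics (population moments) |
| ih | 23 | discretized intensity histogram |
| ivh | 7 | intensity-volume histogram |
| loc | 2 | local / global intensity peak (6.2 mm sphere) |
| morph | 9 | mesh-free morphology (voxel volume, face area, sphericity family, max diameter) |
| cm | 25 | grey-level co-occurrence |
| rlm | 16 | grey-level run length |
| szm | 16 | grey-level size zone |
| dzm | 16 | grey-level distance zone |
| ngt | 5 | neighbourhood grey tone difference |
| ngl | 17 | neighbouring grey level dependence |

Key conventions:

* **Moments.** `stat.skew = m3 / m2^{3/2}`, `stat.kurt` is excess
  kurtosis, `stat.cov = σ/μ`, all with the population (n) denominator.
  Zero-variance input yields skewness and kurtosis 0; the zero-variance
  test uses a relative floor (1e-12 of the value scale) so constant
  inputs with floating-point dust stay degenerate. Any ratio with a
  zero denominator is 0. No feature is ever emitted as missing.
* **Discretization.** Default is fixed bin size, width 0.1 SUV,
  anchored at the ROI minimum: `level = floor((x − min)/w) + 1`. Fixed
  bin number (`level = min(floor(Ng·(x−min)/(max−min)) + 1, Ng)`) is
  available and makes every histogram/texture feature invariant under
  positive rescaling. The fixed-bin-size default is deliberate: with it
  the histogram coefficient of variation differs slightly between SUV
  and TBR runs of the same lesion, whereas the moment statistics
  (`stat.skew`, `stat.cov`, ...) are identical by construction — the
  behaviour expected of TBR normalization, which is a pure positive
  scaling.
* **Histogram gradient.** For counts n₁..n_Ng: ∇₁ = n₂ − n₁,
  ∇ᵢ = (nᵢ₊₁ − nᵢ₋₁)/2, ∇_Ng = n_Ng − n_Ng₋₁; `ih.min.grad` /
  `ih.max.grad` are the extreme gradients and `*.g` their levels.
* **Texture aggregation.** GLCM and GLRLM are merged over the 13 unique
  3D directions into a single matrix (GLCM symmetric); GLSZM/GLDZM use
  one VOI-level matrix with 26-connected equal-level zones. The GLDZM
  zone distance is the minimum over zone voxels of the 6-connected
  city-block distance to the ROI border, border voxels at distance 1
  and off-grid voxels counting as border. Run percentage under merged
  aggregation divides by 13·Nv so it stays in (0, 1]. The NGLDM
  dependence count is 1 + the number of same-level 26-neighbours
  (distance 1, coarseness 0); its dependence-count percentage is then
  identically 1 and is removed downstream as a constant. NGTDM
  coarseness is capped at 1e6 when Σpᵢsᵢ = 0.
* **Morphology** is mesh-free by design: voxel-counting volume, exposed
  voxel-face surface area, and the compactness/sphericity family built
  from those two, plus the maximum centre-to-centre surface-voxel
  diameter. Mesh-based variants would shift absolute values but not the
  rank-based downstream analysis.

Every texture matrix is checked in the test suite against independent
brute-force enumeration (flood-fill zones, per-voxel run walking, BFS
border distances, direct pair counting) on random ≤5×5×5 grids.

## Redundancy reduction

The patient × feature table (per dataset, SUV and TBR independently)
is collapsed by clustering features as the connected components of the
graph with an edge wherever |Pearson r| exceeds 0.85 (strict by
default; a toggle allows ≥). Each cluster is represented by its
highest-variance member, variance computed on raw feature values (this
is scale-sensitive, documented as such), ties broken by manifest order.
Constant columns are dropped up front (their correlation is undefined;
recorded in the report). Connected components were chosen over
hierarchical alternatives because they are parameter-free,
order-independent, and guarantee the invariant that no retained pair
correlates above the threshold. The Bonferroni factor downstream is the
larger of the two post-reduction feature counts (policy `auto`;
`fixed` pins it, e.g. to 31).

## Monte-Carlo resampling and fold diagnostics

For a binary labeling (sex F/M or IDH +/−), each of the 100 folds holds
out exactly one patient per class; holdout pairs are drawn uniformly
without replacement from all cross-class pairs, so no configuration
repeats (an error is raised if more folds are requested than pairs
exist). One plan per labeling is reused for the SUV and TBR tables —
the "aligned" design that makes dataset comparisons paired.

Each fold's training subset receives two diagnostics:

* **Borderline score** — features are z-scored column-wise, Euclidean
  nearest neighbours computed (ties to the lowest patient index), and a
  Tomek link is a mutual nearest-neighbour pair with opposite labels.
  The score is the fraction of samples in at least one link, in [0, 1].
  This fraction-in-link definition is this package's choice of a
  bounded Tomek-link borderline statistic. Z-scoring makes the score
  invariant under uniform positive rescaling and is toggleable.
* **Outlier score** — mean isolation-forest anomaly score
  s(x) = 2^(−E[h(x)]/c(ψ)) over the subset (scikit-learn forest, 100
  trees, subsample min(256, n), per-fold seeds derived from the plan
  seed). Absolute isolation-forest scales are implementation-specific;
  only relative SUV-vs-TBR comparisons are meaningful, and no absolute
  score level is asserted anywhere.

## Ranking and inference

Per fold, each feature is scored by R² against the 0/1 label — the
squared point-biserial (Pearson) correlation, equivalently the R² of a
single-feature linear fit; constant features score 0. The top k = 6
features per fold (curse-of-dimensionality rule for ~33 training
samples; ties by manifest order) are "selected"; a feature's occurrence
rate is the fraction of folds selecting it. Features occurring in
strictly more than 90% of folds are confirmed on the **full cohort**
with a two-sided Mann-Whitney U-test (U reported as min(U_a, U_b);
exact enumeration when n_a + n_b ≤ 20 without ties, otherwise normal
approximation with tie and continuity corrections) at the
Bonferroni-corrected level α/m (α = 0.05; threshold displayed to 4
decimals, e.g. 0.05/31 → 0.0016, but decided unrounded). Subgroup
summaries report mean ± sample SD of chosen features (default `ih.cov`
and `stat.skew`) per sex × IDH cell and dataset; single-patient cells
report SD as not available.

## Synthetic cohort generator

The generator exists so every downstream stage is testable without
patient data. The default spec encodes a 35-patient cohort — 13 F
(6 IDH+) and 22 M (8 IDH+) — with per-cell targets: between-patient
mean ± SD of per-lesion mean SUV (F+ 1.20 ± 0.26, F− 1.78 ± 0.64,
M+ 1.40 ± 0.25, M− 1.38 ± 0.31), background SUV (F+ 1.19 ± 0.31,
F− 1.11 ± 0.16, M+ 1.15 ± 0.16, M− 1.03 ± 0.16), within-lesion CV
(0.264/0.440/0.308/0.385) and within-lesion skewness
(−0.327/0.483/−0.123/0.519). Cell SDs are interpreted as
between-patient spread of per-lesion means; CV and skewness are
within-lesion voxel-distribution targets.

Voxel values come from a standardized gamma deviate with shape
k = 4/skew² (gamma skewness 2/√k = |skew|), reflected for negative
skewness, scaled to sd = mean·CV and shifted to the mean; a normal is
used when the skewness target is 0, and a constant when CV = 0. The
closed-form gamma moments are the analytic oracle the tests check
against. Values are clipped positive and the clip rate reported.

Geometry: an ellipsoidal brain (semi-axes 0.46 of the grid) filled with
background uptake (within-patient CV 0.10 around the patient's
background mean, itself drawn from the cell's between-patient
distribution by redraw-truncation at 0.05 SUV), one spherical lesion
per patient (radius uniform in 4–7 voxels on a 48³ grid at 2 mm
isotropic — free choices, as no lesion volumes are published for this
setting) placed in one hemisphere with small jitter, and the
contralateral background sphere mirrored across the midline with the
centre clamped so the two masks can never touch. Optional Gaussian
smoothing (default 1 voxel) adds spatial correlation for realism;
smoothing perturbs voxel moments, so moment-recovery tests run
unsmoothed. Fixed seeds give bit-identical cohorts.

What the generator does **not** emulate: scanner/reconstruction physics
and partial-volume effects, anatomically realistic brains, non-spherical
lesion shapes, and any real spatial texture beyond smoothing-induced
correlation. Passing tests therefore demonstrate the correctness and
calibration of the analysis machinery under known ground truth — not
clinical reproduction of any particular cohort's feature values, which
depend on the undeposited patient data.

## Problem sizes and determinism

The default end-to-end run (35 patients, two datasets, two labelings,
100 folds) completes in about a minute on one CPU; the test suite runs
smaller cohorts (12 patients, 8–10 folds) for orchestration tests and
full scale for acceptance properties. All randomness flows through
explicit seeds (cohort, splits, forest); identical config and seeds
produce byte-identical reports (stage timings are deliberately kept out
of report.json). The JSON report validates against the pydantic schema
shipped as `data/report_schema.json`.

## Known limitations

* The 154-feature manifest matches the published count and the IBSI
  family structure, but the exact original feature list, discretization
  parameters and minimum-voxel threshold are not public; all are
  configurable with the defaults above.
* Absolute borderline/outlier score levels depend on the score
  definitions and are not comparable across implementations.
* Exact Mann-Whitney p-values are only used for small tie-free groups;
  cohort-scale comparisons use the corrected normal approximation.
* Morphology features are voxel-based approximations; surface area in
  particular overestimates a smooth-surface mesh value.
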