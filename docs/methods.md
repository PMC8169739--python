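# Methods

`pettex` implements a fixed, fully deterministic FDG-PET texture-analysis
workflow for differentiating malignant lung lesions from radiation
pneumonitis (RP), exercised end to end on synthetic phantoms.  This note
documents the model choices, the numerical conventions, and what the
synthetic cohort can and cannot show.

## Segmentation

The lesion VOI is the 26-connected component, containing an SUVmax voxel,
of all voxels within an operator-supplied search region whose SUV is at
least `fraction x SUVmax` (default fraction 0.40).  Choices:

* **Connectivity** is the 26-neighborhood in 3D — the standard convention
  for PET lesion delineation.
* **Ties** at exactly the threshold are included (`>=`, not `>`).
* If several voxels share the maximum and fall in different candidate
  components, the component of the lexicographically first maximum voxel is
  kept and a warning is logged (deterministic tie-break).
* The search region stands in for manual lesion localization; the phantom
  generator supplies the ground-truth support as the search mask.  An
  optional exclusion mask removes physiological uptake (`mask AND NOT
  exclusion`).

## Conventional metrics

SUVmax and SUVmean are the maximum and arithmetic mean inside the VOI.
SUVpeak is the mean over all in-grid voxels whose centers lie within
`r = (3V/4pi)^(1/3)` (≈ 6.2035 mm for the default 1 cm³ sphere) of the
center of the hottest VOI voxel.  The sphere is *centered on the maximum
voxel* (no repositioning search), clipped to the grid but **not** to the
VOI — the usual PERCIST-style behavior.  Membership is by voxel center;
a sphere smaller than one voxel degrades to the hot voxel itself.
MTV is `voxel count x voxel volume / 1000` (cm³) and TLG is
`SUVmean x MTV`.

## Discretization

In-mask SUVs are rescaled between the VOI's 1st and 99th percentiles into
64 bins: `level = clamp(floor((x - P1)/(P99 - P1) * 64) + 1, 1, 64)`.

* Percentiles use linear interpolation between order statistics (NumPy
  default).
* Values outside the window are **clamped** into bins 1 and 64 rather than
  excluded, so the voxel set is identical for every downstream matrix.
* Bins are half-open with the top bin closed; a degenerate window
  (`P99 == P1`) maps everything to level 1.
* The wording "equalized histograms by rescaling" is interpreted as this
  linear percentile-window rescale, not rank-based histogram equalization.

A consequence used throughout the tests: levels — hence all 56 texture
parameters — are invariant to positive affine rescaling of the SUVs.

## Texture families

Gray-level indices `i, j` in every formula are the 1-based bin numbers.
All entropies are base 2.  Co-occurrence distance is one voxel (Chebyshev)
in index space; anisotropic spacing is ignored when enumerating offsets.

* **NGLCM** — co-occurrence matrices for the 4 unique in-plane offsets,
  pairs pooled across axial slices, accumulated symmetrically and
  normalized.  Seven Haralick-style features (uniformity/angular second
  moment, entropy, dissimilarity, contrast, homogeneity, inverse difference
  moment, correlation), aggregated as mean and max over the 4 directions.
* **NGLCM3D** — the same construction over the 13 unique 3D offsets; six
  features (no IDM) with mean/max aggregation.
* **NGLCM3DMean** — the 13 matrices are averaged element-wise first and the
  six features computed once.  Correlation is defined as 0 when a marginal
  is degenerate.
* **GLRLM** — maximal colinear same-level runs along each of the 13
  offsets (Galloway): short/long-run emphasis, gray-level and run-length
  nonuniformity, run percentage (`runs / voxels`), mean/max over
  directions.  Every voxel lies in exactly one run per direction, an
  identity the tests check exactly.
* **GLSZM** — zones are 26-connected equal-level components (Thibault).
  Seven features; the reporting names keep the run-length analogy:
  "Intensity Variability" is gray-level variability and "Run Length
  Variability" is zone-size variability.
* **NGTDM** — per voxel, the mean level of its in-mask 26-neighbors;
  Amadasun–King coarseness, contrast, busyness, complexity, strength.
  Voxels with no in-mask neighbor are skipped.  `eps = 1e-6`; coarseness is
  capped at `1e6` (the value a perfectly uniform VOI attains).  Contrast is
  0 with a single occupied level; busyness is 0 when its denominator
  vanishes.  The busyness denominator sums `|i p_i - j p_j|` over
  *unordered* occupied level pairs; complexity and strength use the full
  double sum (diagonal terms vanish identically).
* **SUVHistogram** — variance and entropy of the gray-level histogram.

This yields exactly 56 texture parameters (10 + 7 + 12 + 6 + 14 + 5 + 2),
plus the 5 conventional metrics, per lesion.

## Statistics

* **Wilcoxon rank-sum**: two-sided Mann–Whitney with normal approximation,
  tie and continuity corrections (`scipy.stats.mannwhitneyu`).  The normal
  approximation is the appropriate tool at cohort sizes near n = 30; at
  n = m <= 4 it can deviate from the exact permutation p by up to ~0.09
  (a property of the approximation itself, reproduced exactly by the
  enumeration oracle in the tests).
* **ROC**: empirical curve over all distinct thresholds, trapezoid AUC
  (equal to the normalized Mann–Whitney pair count).  Orientation is chosen
  automatically so the reported AUC is >= 0.5 and is recorded.
* **Optimal cutoff**: the operating point minimizing
  `sqrt((1-sens)^2 + (1-spec)^2)` (upper-left corner); ties break toward
  higher sensitivity, then higher cutoff.  Sensitivity, specificity, PPV,
  NPV and accuracy are recomputed from the confusion matrix at that cutoff.
* **AUC comparison**: DeLong's test for correlated (paired) or independent
  curves, on oriented scores; zero-variance differences give p = 1.
* No multiple-testing correction is applied by default (61 uncorrected
  tests mirror the reporting layout); Benjamini–Hochberg can be layered on
  by the caller.

## Synthetic phantoms

Real images behind the motivating cohort are not publicly available, so the
generator realizes the *statistical contrast the analysis assumes*:

| parameter | tumor-like | pneumonitis-like |
|---|---|---|
| diameter (mm) | Normal(29, 16), >= 10 | Normal(51, 21), >= 20 |
| base uptake (SUV) | LogNormal(log 3.3, 1.0), >= 0.8 | Normal(1.9, 0.5), >= 0.8 |
| heterogeneity amplitude | 0.5 | 0.15 |
| correlation length (mm) | 12 | 3 |

Shared defaults: background 0.5 SUV with white noise sd 0.1 (a plausible
aerated-lung level; any positive value exercises thresholding identically),
8 mm FWHM isotropic Gaussian PSF, 128 x 128 x 81 grid at (3.9, 3.9, 2.0) mm.

Construction per lesion: a union of 1–5 jittered spheres (satellite centers
inside the primary sphere, guaranteeing 26-connected support of roughly the
nominal equivalent diameter); intra-lesional uptake
`base x (1 + amplitude x G)` with `G` a unit-variance Gaussian random field
built by Gaussian-filtering white noise with `sigma = correlation_length/2`
— so the field's autocorrelation falls to 1/e at exactly the stated
correlation length; background white noise; whole-volume PSF blur; the
ground-truth mask is the pre-blur support.

Two deliberate calibrations, made once:

* **Correlation length is the class-separating knob.**  NGTDM coarseness
  and busyness respond directly to texture granularity, which is the
  qualitative contrast the analysis is built to detect: coarse blobby
  malignant uptake versus fine "busy" inflammatory uptake.
* **Tumor base uptake is set below the SUVmax target.**  The coarse
  heterogeneity field overshoots the base level at the hot spot by roughly
  1.5x, so a LogNormal base with median 3.3 realizes extracted SUVmax with
  median ≈ 5 and coefficient of variation ≈ 1 — the strongly right-skewed
  malignant SUVmax distribution — while pneumonitis lesions stay near
  SUVmax ≈ 1.9.

What the phantoms do **not** model: PET physics (projection, Poisson
sinogram noise, reconstruction artifacts), partial-volume effects beyond
the Gaussian PSF, respiratory motion, anatomical context, or any
intralesional texture ground truth beyond the two-scale field.  Passing the
end-to-end tests therefore shows the pipeline is internally consistent and
reproduces the *direction* and approximate magnitude ordering of the
class effects (texture AUC above SUV AUC; coarseness and SUVmax higher in
tumors, busyness and MTV higher in pneumonitis) — not that it would attain
any particular accuracy on clinical images.

## Problem sizes and determinism

The shipped cohort default is 32 tumor-like and 31 pneumonitis-like lesions
on the full reconstruction grid; a complete simulate → extract → stats run
takes well under a minute on one CPU.  Feature extraction crops each VOI to
its bounding box (a pure optimization; features are unchanged).  All
randomness flows from a single master seed through
`numpy.random.default_rng`; per-lesion seeds are drawn from the master
stream, and identical configuration + seed reproduces every output file
byte for byte.

## Known limitations

* The three co-occurrence family variants (slice-pooled 2D, per-direction
  3D, averaged-matrix 3D) follow the only reading consistent with the
  reporting layout's mean/max rows; other viewers may define them
  differently.
* NGTDM pairwise-sum conventions differ between published restatements of
  the Amadasun–King features; the choices above are fixed and
  oracle-tested, but absolute values are not comparable across tools.
* Percentile-window discretization makes features scale-free, which also
  means absolute-SUV information enters only through the conventional
  metrics.
* The Wilcoxon normal approximation is inaccurate below n ≈ 5 per group;
  use the exact test (or the permutation oracle) for very small pilot
  cohorts.
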