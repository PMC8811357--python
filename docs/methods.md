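# Methods

This note documents the models, parameters and design choices behind
`cmbselect`, and what the synthetic benchmarks do and do not demonstrate.

## Problem setting

Cerebral microbleeds (CMBs) appear on T2\*-sensitive MRI as small round
hypointense lesions, conventionally 2–10 mm, with a further microbleed
(2–5 mm) / macrobleed (> 5 mm) subdivision. They share their appearance
with numerous mimics — vessel flow voids seen in cross-section, sulci,
calcifications, haemorrhage rims — which makes voxel-level detection
noisy. The package's goal is deliberately coarser: decide per *subject*
whether a scan likely contains CMBs, so that manual rating effort can be
concentrated on an enriched subset of a large cohort. The unit of success
is the subject-level accuracy of that triage, with cluster-level recall as
a secondary, indicative measure.

## Pipeline

### Preprocessing

Images are reoriented to canonical (RAS) axis labels by axis permutations
and flips only — voxel intensities are never interpolated, because the
lesions of interest span only a few voxels. No registration to a template
is performed, for the same reason. Brain masks are expected as inputs
(phantoms provide exact masks); a fallback (Otsu threshold, largest
3-D component, closing, hole fill) covers mask-free use but is not a
skull-stripping replacement. Bias-field correction is not performed:
phantoms have no bias field, and pre-corrected inputs can be supplied
where real data requires it. Intensities are standardized to zero mean /
unit population variance within the brain mask; outside voxels are set to
zero. Standardization makes the intensity-derived features invariant to
affine intensity rescalings of the input.

### Stage 1 — vessel and sulci removal

All second-order filtering is 2-D and slice-wise. This is a deliberate
choice, not a shortcut: with 3–5 mm slices against ~0.8 mm in-plane
resolution, through-plane second derivatives are dominated by
partial-volume steps, and the two-eigenvalue structure-tensor machinery is
planar anyway.

Per slice, three features are computed within the brain:

* **Frangi vesselness** (dark ridges), maximum over scales {1, 2, 3}
  voxels, with β₁ = 0.9 and β₂ = 20. β₁ close to 1 deliberately weakens
  the response on blob-like (CMB) structure so that round lesions are not
  removed as vessels. The scale set spans vessel radii while staying below
  CMB radii.
* **λ₁**, the principal eigenvalue of the structure tensor
  (Gaussian-derivative gradients at σ = 1, tensor window σ = 3 voxels).
* **Linearity** *l* = |λ₁ − λ₂| / 2 from the same tensor.

The tensor window of 3 voxels — roughly a lesion radius — matters: over a
window spanning a whole blob, rim gradient orientations cancel and
linearity collapses, while a vessel keeps a single dominant orientation.
At a smaller window (1.5 voxels) lesion rims and vessel walls are locally
indistinguishable (both look like edges) and the subsequent clustering
cannot separate them.

Voxels are clustered into two classes with k-means (k-means++
initialization, 10 restarts, fixed seed) on the z-scored feature columns,
weighted (Frangi 1.0, λ₁ 0.25, linearity 2.0); the cluster with the higher
mean raw Frangi response is the vessel class. The weights encode the same
observation as the window size: λ₁ is an omnidirectional edge detector
that fires equally on lesion rims and vessels, so it must not dominate the
cluster geometry; the elongation-specific features carry the
discrimination. Clustering is per-image, so the operating point adapts to
each scan's mimic load.

Vessel voxels are inpainted slice-wise with the mean of their 3 nearest
(in-slice Euclidean distance, voxel units) unmasked voxels, in onion-peel
order: shells of increasing distance to the unmasked set are filled
outside-in, each filled shell becoming a neighbour source for deeper
shells, so thick masked regions receive locally plausible values rather
than long-range averages. Unmasked voxels are never modified. A fully
masked slice falls back to the mean of its neighbouring slices.

### Stage 2 — voxel-wise candidate detection

Seven features per voxel on the vessel-removed, standardized image
(defaults in `FeatureConfig`):

| feature | definition | default parameters |
|---|---|---|
| intensity | vessel-removed standardized intensity | — |
| exp_intensity | exp(*p* · intensity) | *p* = 1 |
| clahe | slice-wise CLAHE on the volume min-max rescaled to [0,1] | clip 0.01, 8×8 tiles |
| frst_mean | fast radial symmetry transform, dark symmetry only, averaged over radii | radii {2, 3, 4, 6} vox, α = 2, gradient floor at the 5th percentile |
| st_lambda1 | principal structure-tensor eigenvalue | σ_grad = 1, σ_window = 1.5 vox |
| blobness | I − G<sub>σ</sub> ∗ I (high-pass residual) | σ = 1.5 vox |
| log | Laplacian of Gaussian | σ = 1.5 vox |

σ = 1.5 voxels matches the in-plane radius of a typical small CMB. Each
map is divided by its per-image maximum absolute value (signed features
such as LoG have negative extrema, so a plain maximum would be
ill-defined); an identically zero map stays zero.

The voxel classifier is an RBF-kernel SVM (C = 1) with Platt-style sigmoid
probability calibration fitted on internal cross-validation folds, after
feature standardization. Training pools, per subject, all lesion-truth
voxels as positives and 10 uniformly sampled in-brain background voxels
per positive (seeded). Truth voxels that stage 1 painted over are
excluded from the positives: an inpainted voxel no longer carries lesion
signal, and labelling it positive measurably destabilized the classifier
across training cohorts. The probability map is thresholded at
*th*<sub>prob</sub> = 0.8 (strict >); `sweep_th_prob` reproduces the FROC
sweep over [0, 1] in steps of 0.1 from which that operating point is
chosen (highest cluster TPR at acceptable FP load).

### Stage 3 — shape filtering and subject decision

Candidate voxels are grouped with 26-connectivity. Per component, in
physical units:

* **Volume** = voxel count × voxel volume; pass iff 5 < V < 120 mm³
  (open interval).
* **Ellipticity** = 1 − minor/major principal-axis ratio from second
  moments on the component's maximal-area axial slice; each voxel
  contributes its own patch moment s²/12, i.e. components are measured as
  unions of solid squares, not point sets. Pass iff ε < 0.2 (strict). The
  in-plane definition is deliberate: at 3–5 mm slices the through-plane
  extent of a genuinely spherical 2–5 mm lesion is an artefact of
  anisotropy.
* **Solidity** = voxel count / count of lattice voxels inside the convex
  hull of the component's voxel centers (the rasterized convex image;
  the count ratio is affine-invariant, so anisotropic spacing needs no
  correction). For single-slice components the 2-D area ratio is used; a
  component too degenerate for any hull (single voxel, straight line) is
  convex by construction and scores 1. Pass iff S ≥ 0.6 (inclusive).
* **Diameter** = longest line through the candidate: maximum pairwise
  voxel-center distance plus one in-plane pitch for the two end-voxel
  halves (a single voxel spans one pitch). Pass iff 2 < D < 10 mm (open).

A candidate survives only if all four criteria hold. A subject is a CMB
subject iff the surviving count strictly exceeds *Th*<sub>NCMB</sub>;
per-modality defaults are 35 (SWI) and 30 (GRE) — SWI enhances mimics as
well as lesions, so a higher count threshold performs better there.
`sweep_th_ncmb` produces the subject-level ROC over thresholds 10–80 in
steps of 5 and reports the Youden-index knee.

### Baseline

The intensity-percentile baseline replaces stage 2 with "every in-brain
voxel strictly below the within-mask 5th-percentile intensity", keeping
all other stages identical, so comparisons isolate the contribution of
the learned voxel detector.

### Evaluation

Subject level: TPR, specificity, accuracy; ROC by sweeping
*Th*<sub>NCMB</sub>, trapezoidal AUC with (0,0)/(1,1) anchors. Cluster
level: a truth cluster is TP if any detected cluster overlaps it by at
least one voxel, FN otherwise; a detected cluster with no truth overlap is
FP; FPavg = total FPs / subjects. One detection covering two truth
clusters scores two TPs and no FP — truth clusters are the units of
recall, and FP is defined by absence of any truth overlap. Undefined
ratios (empty denominators) are reported as missing, never coerced to
0 or 1.

## Phantom generator

The generator emulates the structures the pipeline must discriminate, on
the default geometry of 96 × 96 × 24 voxels at 0.8 × 0.8 × 3 mm:

* an ellipsoidal brain mask (semi-axes 44% of the grid extent);
* background level 100, additive Gaussian noise σ = 5 (5% of background);
* CMBs: dark spheres, intensity = background × (1 − contrast), default
  contrast 0.5, diameters drawn uniformly from 4.0–5.8 mm, placed without
  overlap (one-voxel exclusion zone) against mimics and each other;
* vessels: dark tubes (radius 0.6–1.2 mm, contrast 0.5) along smooth,
  mostly in-plane random-walk polylines;
* sulci: dark ribbons constrained to within ~2 voxels of the mask surface,
  Poisson count with mean `sulci_density` (default 2);
* optionally one large haemorrhage blob.

Voxel membership is by voxel-center position; all randomness derives from
the spec seed, so identical specs give bit-identical subjects. Cohorts
draw per-subject seeds and lesion counts (2–6 per positive subject by
default) deterministically from one cohort seed.

**Default lesion sizes.** The 2–10 mm convention is the clinical size
band, but a binary center-sampled rasterization at 3 mm slices cannot
represent its lower end: a sphere smaller than ~3.8 mm can land between
slice centers and rasterize to a 1–10 voxel fragment whose measured
diameter, volume and ellipticity are meaningless (and fall outside the
stage-3 window), while spheres above ~6 mm exceed the 120 mm³ volume
criterion. The default range 4.0–5.8 mm is the band this grid represents
faithfully: within it ≥ 96% of rasterized lesions are measurable inside
the shape window. This is a limitation of the phantom, not of the
pipeline definition — real sub-slice lesions produce partial-volume
blooming rather than vanishing, which a binary intensity model cannot
imitate.

**What the phantom does not emulate** — and therefore what passing
benchmarks do *not* show about clinical data: susceptibility physics and
phase effects, partial-volume intensity blending, bias fields, Rician
noise (additive Gaussian is used; the magnitude bias is irrelevant at
phantom contrasts), motion/Gibbs artefacts, anatomical texture, and the
blooming that makes real CMBs appear larger on SWI. Results on phantoms
bound the pipeline's mechanics (mimic removal, feature separability,
shape-filter logic, thresholding), not its clinical operating points;
*Th*<sub>NCMB</sub> in particular must be re-tuned on any real dataset.

## Numerical and design notes

* Voxel-center coordinates (index × spacing) are the physical convention
  everywhere; masks are {0, 1} with 1 = foreground.
* Inpainting distance ties are resolved by the deterministic nearest-
  neighbour query; end-to-end runs with one seed are bit-identical
  (verified by the determinism suite).
* `exp_intensity` clips |p·I| at 50 to avoid overflow, with a warning.
* Degenerate inputs follow explicit paths: constant images are rejected by
  standardization (zero variance), yield zero maps in CLAHE/FRST/LoG, and
  an empty vessel mask (with a warning) in clustering.
* The FRST implementation follows the gradient-voting construction with
  radial-strictness α = 2, per-slice gradient-magnitude floor at the 5th
  percentile, dark-symmetry votes only (CMBs are hypointense), k_n = 8 for
  radius 1 and 9.9 otherwise, and per-radius Gaussian smoothing at
  σ = n/2; per-radius outputs are averaged without further normalization.
* CLAHE is applied to the vessel-removed image (the natural reading of the
  stage ordering); a config switch could trivially re-point it at the raw
  image, but the difference is confined to inpainted regions.
* K-means on all three stage-1 features (rather than a subset) follows the
  plain reading of "the above features"; clustering is per-image rather
  than per-cohort so that a scan's own mimic load sets its operating
  point.
* Whether shape attributes should be 2-D or 3-D is genuinely open; the
  in-plane choices above (ellipticity, single-slice solidity fallback) are
  this package's answer for strongly anisotropic data and are kept
  configurable at the criteria level.

## Benchmark problem sizes

The shipped suites use 64 × 64 × 16 phantoms for unit/monotonicity/
determinism checks and the full 96 × 96 × 24 geometry with a 40-subject
test cohort (prevalence 0.5, 10-subject training cohort) for the
end-to-end recovery benchmark; these sizes keep the whole suite in the
minutes range on a single CPU while leaving every stage's behaviour
observable. On the recovery benchmark the pipeline reaches subject-level
accuracy ≥ 0.85 and cluster-wise TPR ≥ 0.85 after shape filtering, with
FPavg well below one per subject — figures recomputed, not quoted, by
`tests/test_acceptance.py` on every run.

## Known limitations

* The phantom's binary intensity model understates partial-volume effects;
  see above.
* The brain-mask fallback is not a skull-stripping substitute.
* The vessel stage's per-image clustering can bite into lesion rims
  (worst observed on phantoms: ~20% of one lesion's voxels); training
  excludes such voxels, and partially bitten lesions usually remain
  detectable, but a lesion misclassified wholesale as vessel is
  unrecoverable — the same failure mode exists in the underlying method.
* Subject thresholds (*Th*<sub>NCMB</sub>) are dataset-dependent by
  construction; defaults are starting points, not universal constants.
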