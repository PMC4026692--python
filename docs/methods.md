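# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `shapedx`, at the level of detail a user would need to
judge what the package computes and what its passing tests do and do not
show.

## Problem setting

Three diagnostic groups — normal controls (NC), Alzheimer's disease (AD) and
behavioral-variant frontotemporal dementia (FTD) — are to be discriminated
*simultaneously* from shape features of segmented subcortical structures.
The package takes binary segmentations (NIfTI), surfaces in vertex
correspondence (PLY/OBJ, correspondence by vertex order), per-subject
intracranial volume (ICV) and diagnostic labels (CSV). Segmentation and the
diffeomorphic template injection that establishes vertex correspondence are
upstream of this package; the synthetic generator produces correspondence
exactly, by construction.

## Volumes

`V_abs` is the foreground voxel count times the voxel volume
(dx·dy·dz mm³). Head-size effects are removed by the covariance method:

    V_norm = V_abs − k (ICV − ICV_mean)

`k` is the OLS slope (with intercept) of `V_abs` on ICV and `ICV_mean` the
mean ICV, both over the control group by default. Fitting on controls avoids
disease-driven slope bias; an all-subjects fit is available
(`fit_on_all=True`). `k` is fitted per structure. Within the reference
group the normalized volumes are exactly uncorrelated with ICV (the tests
check the residual slope to 1e-9).

## Laplacian spectral invariants

The intrinsic shape descriptor is the low end of the Dirichlet spectrum of
the voxel domain: Δu + λu = 0 in Ω, u = 0 on ∂Ω. The operator is the
7-point finite-difference negative Laplacian restricted to foreground
voxels, with stencil weights 1/dx², 1/dy², 1/dz² (native anisotropic spacing
is honored; no resampling). Out-of-domain neighbors are simply omitted,
which imposes the Dirichlet condition half a grid step outside the
outermost voxel centers — hence a digitized cube of side L voxels behaves
like a box of side L+1, a fact the analytic tests account for. A
finite-difference operator was chosen over integral-operator constructions
because it is verifiable against closed-form spectra (box, ball) and the
ratio features depend only on the spectrum.

Only the largest 6-connected component is kept before assembly (a bounded
domain is connected; stray voxels would contribute spurious near-zero-coupled
blocks); a warning reports when more than 1% of voxels are dropped. The
default minimum domain size is 200 voxels.

Eigenvalues (ascending, counting multiplicity) are computed by:

* **shift-invert Lanczos** (`eigsh`, σ = 0, seeded start vector) for domains
  up to 20 000 voxels;
* **LOBPCG** above that, preconditioned by the *exact inverse of the
  bounding-box Dirichlet Laplacian* applied through fast sine transforms
  (DST-I diagonalizes the box operator). This keeps memory flat at ~N
  where a sparse LU of a 3D stencil at 64³ does not fit in a few GB; the
  box inverse is spectrally close to A⁻¹ for domains filling a reasonable
  fraction of their bounding box, giving convergence in a few hundred
  iterations. The block is oversampled by max(5, n/5) columns because
  LOBPCG's trailing eigenpairs converge slowest; the first n are kept.

Every returned eigenpair must satisfy ‖Av − λv‖/‖v‖ ≤ 1e-8; otherwise an
`EigensolverError` with diagnostics is raised. Both paths are deterministic
given the seed (default 0). On domains ≤ 300 voxels the sparse path is
tested against a dense full eigendecomposition at 1e-8 relative.

Feature families over the first n = 100 eigenvalues (99 entries each):
F1 = λ₁/λ_i; F2 = λ_{i−1}/λ_i (the default); F3 = λ₁/λ_i − d₁/d_i, where
d_i is the Dirichlet spectrum of the unit ball — squared zeros of the
spherical Bessel functions j_l with multiplicity 2l+1, computed by bracketed
root-finding at call time and cached. F1/F2 lie in (0, 1], F3 in [−1, 1]
and vanishes identically for a ball, so it measures deviation from a
sphere. Translation/rotation invariance is inherited from the spectrum
(axis permutations are exact on the grid; general rotations agree up to
discretization); scale invariance holds because a uniform rescaling
multiplies every eigenvalue by the same factor.

## Surface displacements

Given template and target surfaces with shared vertex indexing, the target
is first rigidly aligned to the template by the least-squares (Kabsch)
transform of the corresponding vertices — rotation constrained proper
(det = +1), no scaling; reflection-related configurations therefore align
with nonzero residual rather than flipping. The displacement magnitude at
vertex j is the Euclidean distance between template vertex j and the aligned
target vertex j. A signed variant (projection of the displacement vector on
the template's outward vertex normal) is also produced: magnitudes feed the
classifier, the signed field feeds group-difference maps, where
expansion/contraction direction matters. With pre-alignment the field is
invariant to any rigid motion of the target to ≤ 1e-6 mm.

Dimensionality reduction: k-means on the template vertex coordinates
(k-means++ init, 10 restarts, 100 iterations, fixed seed 42 by default)
partitions the surface into N = 300 patches; the feature vector is the mean
magnitude per patch. Patch means conserve the vertex-count-weighted global
mean exactly. Patch sizes come out roughly uniform without being enforced.

Patch-wise group differences use a per-patch Welch t test on the signed
field with Benjamini–Hochberg correction across patches at q = 0.05. This
deliberately replaces random-field-theory cluster correction: it is
desk-scale, dependency-free, and calibrated (the tests verify ≤ 5% flags
under the null), at the cost of ignoring spatial correlation between
patches.

## Classification protocol

One fixed protocol for every biomarker, so predictive values are comparable:

1. **Feature selection** — information gain in bits per feature,
   H(labels) − Σ_b p(b) H(labels|b), with equal-frequency discretization
   (10 bins, reduced until every nonempty bin has ≥ 2 samples); the top
   k = 5 features are kept, ties broken by original column order. Selection
   always runs on training rows only, inside every resampling loop.
2. **Model selection** — RBF-kernel SVM tuned over the integer-exponent
   grid log₁₀C = −3…8 × log₁₀γ = −3…3 (84 points) by stratified 5-fold CV
   accuracy on the training set (3-fold, then leave-one-out, when the
   smallest class cannot fill the folds); ties resolve toward smaller C,
   then smaller γ. Features are standardized by a scaler fit on the
   training rows — raw features span mm³ (≈10³) to eigenvalue ratios (≤ 1),
   a spread a single kernel width cannot absorb.
3. **Scoring** — the selected model is refit on all training rows; test
   subjects receive per-class membership scores by pairwise coupling of the
   one-vs-one SVM decision values: each pairwise decision is mapped through
   a sigmoid and the class scores solve the coupling least-squares problem
   min ½ ΣΣ (r_ji p_i − r_ij p_j)², Σp = 1 (closed-form KKT solution).
   This is deterministic and its argmax agrees with the SVM's own voting
   rule; Platt-style calibrated probabilities were rejected because with
   ~30–60 training subjects the internal calibration fit can invert the
   score ordering outright. Scores sum to 1 per subject; argmax is the
   predicted label.
4. **Resampling** — stratified 75/25 hold-out (per class,
   floor(0.75·n_c) training subjects; class sizes 30/34/14 give the 57/21
   split), leave-one-out CV with selection and grid search repeated inside
   every fold, and a 10-repetition repeated hold-out reporting the mean and
   SD of the weighted AUC.
5. **Sample-size bound** — N_min = d/(2·p(e)): with d = 5 selected features
   and p(e) = 0.05, 50 subjects suffice, below both the 57-subject training
   set and the 78-subject cohort.

Alternative classifiers plug into the same protocol: a linear SVM (grid over
C only) and a Gaussian naive-Bayes baseline. libsvm iterations are capped at
10⁵ per fit: at C = 10⁸ on non-separable data the solver otherwise spins
effectively forever; converged solutions are unaffected.

## Evaluation

Multi-class performance is the weighted mean of the per-class one-vs-rest
ROC AUCs (Mann–Whitney estimator, half credit for ties), with weights
w_i = n_i/Σn_j over test-set class sizes; "one-vs-rest" is the only reading
under which three ROCs with class-size weights are defined. Classes absent
from a test set are excluded and the weights renormalized, with a warning.
The confusion matrix's K(K−1) ordered off-diagonal row-normalized rates form
the cobweb (radar) plot — six axes for three classes; each axis runs 0 at
the center to 1 at the rim. Pairwise runs additionally report sensitivity
and specificity at the coupled-score argmax operating point (the
classifier's own decision rule, not an ROC-optimized threshold).

## Synthetic cohort

The generator emulates the statistical regime the pipeline is designed for,
with one generic structure per subject:

* **Template**: an icosphere (subdivisions 4, 2562 vertices) mapped radially
  onto an ellipsoid with semi-axes (22, 12, 9) mm — ventricle-scale,
  elongated. All subjects share its vertex indexing.
* **Shapes are star-convex**: the surface radius along unit direction u is
  ρ(u) = s·r_E(u) + A·exp(−θ(u)²/2σ²), with r_E the ellipsoid radius, s the
  subject's isotropic size factor, A the focal bump amplitude and θ the
  angle to the group's bump locus. Voxelization (1 mm isotropic default) is
  an exact point-in-shape test against ρ, so mesh and mask describe the same
  surface; i.i.d. vertex jitter (SD 0.05 mm) is applied to the mesh only, as
  measurement noise.
* **Groups** (NC 14 / AD 34 / FTD 30): volume multipliers 1.00/1.10/1.10
  with multiplicative volume noise SD 0.12, so all three volume
  distributions overlap heavily and AD/FTD volumes are *identically*
  distributed — gross atrophy cannot separate the diseases by construction.
  Disease bumps: amplitude 2 mm, angular width σ = 0.25 rad, at the −x pole
  for the AD-like group ("posterior") and +x for FTD-like ("anterior");
  controls have none. σ = 0.25 rad makes the bump genuinely focal: its
  ~2σ support (0.5 rad) is several times smaller than a 5-patch parcel
  (half-angle ≈ 1.2 rad) but spans several 300-patch parcels (half-angle
  ≈ 0.21 rad), which is the geometry under which coarse partitions average
  the discriminating signal away and fine ones retain it. Because the two
  loci are mirror images through the ellipsoid's symmetry plane, the AD-like
  and FTD-like groups have nearly identical Laplacian spectra — the
  intrinsic-feature biomarker is informative about disease presence but not
  disease identity, mirroring the intended contrast with the spatially
  resolved displacement features.
* **ICV**: Normal(1.45e6, 1.5e5) mm³, coupled into the subject's target
  volume at slope 0.003 mm³/mm³ so volume normalization has something to
  remove.

What passing tests on this cohort show: the pipeline end-to-end recovers
planted effects — ranking of biomarkers, localization of group differences,
the partition-count direction — under exact correspondence, star-convex
geometry, Gaussian noise and a single structure. What they do not show:
performance on real segmentations with registration error, non-star-convex
anatomy (true ventricles), correlated multi-structure features, or any
specific AUC level from a clinical cohort; clinical headline numbers depend
on data that is not distributable, and no attempt is made to reproduce them
numerically.

## Problem sizes used in tests

The test suite runs the recovery experiments on the default 78-subject
cohort at reduced resolution (icosphere subdivisions 3 = 642 vertices,
1.5 mm voxels, ≈2 700 foreground voxels per mask), which preserves every
protocol constant (n = 100 eigenvalues, N = 300 patches, top-5 selection,
full 84-point SVM grid) while keeping a full pipeline run in minutes. The
spectral oracles run at 64³ (cube and ball) where the analytic comparisons
are tight; the permutation-null calibration uses 100 repetitions of the full
selection + grid-search + hold-out loop at a reduced SVM grid, which leaves
the leakage surface (selection and tuning inside the loop) fully exercised.

## Known limitations

* The finite-difference spectrum carries O(h²) discretization error;
  absolute eigenvalues differ from continuum values at coarse resolution,
  and ratio features inherit a smaller, partially cancelling error.
* Information-gain binning is equal-frequency with a fixed bin budget; an
  MDL-based discretization could rank features differently on small n.
* The argmax operating point makes sensitivity/specificity depend on the
  coupled-score calibration, not on an ROC sweep.
* k-means patches are geometric, not anatomical labels; patch identity is
  only meaningful relative to a fixed template and seed.
* BH-FDR across patches ignores spatial correlation of neighboring patches;
  it controls the expected false-discovery fraction per map, not
  cluster-level inference.
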