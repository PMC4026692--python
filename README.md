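# shapedx

Subcortical shape morphometry for three-class differential diagnosis of
dementia (Alzheimer's disease vs behavioral-variant frontotemporal dementia
vs normal controls) from binary structure segmentations and corresponding
surface meshes.

Distinguishing AD from bvFTD on structural MRI is hard because both diseases
produce overlapping gross atrophy: hippocampal and ventricular *volumes* of
the two patient groups overlap almost completely. This package implements a
pipeline that compares three shape biomarkers of a segmented structure under
one fixed classification protocol, so their differential-diagnostic value can
be measured on the same test set:

1. **Normalized volume** — `V_norm = V_abs − k (ICV − ICV_mean)`, where `k`
   is the OLS slope of structure volume on intracranial volume over the
   control group, removing head-size effects.
2. **Laplacian spectral invariants** — the ascending Dirichlet eigenvalues
   λ₁ ≤ … ≤ λ_n of the voxel domain Ω (Helmholtz problem Δu + λu = 0 in Ω,
   u = 0 on ∂Ω), reduced to pose- and scale-invariant ratio families:
   F1 = (λ₁/λ_i), F2 = (λ_{i−1}/λ_i) (default, n = 100), and
   F3 = (λ₁/λ_i − d₁/d_i) with d_i the unit-ball spectrum, so F3 measures
   deviation from a sphere.
3. **Patch-averaged surface displacements** — per-vertex Euclidean distances
   d(v_j) between a template surface and a target surface in vertex
   correspondence, after least-squares rigid pre-alignment, averaged inside
   N = 300 k-means patches of the template vertices.

The protocol: features are ranked by information gain on training rows only
and the top 5 kept; an RBF-kernel SVM is tuned by grid search over
log₁₀C = −3…8, log₁₀γ = −3…3 with stratified 5-fold CV on the training set
alone; held-out subjects receive per-class scores by pairwise coupling.
Performance is the size-weighted mean of the per-class one-vs-rest ROC AUCs
(weights w_i = n_i/Σn_j over test-set class sizes), with the confusion
structure summarized by a six-axis "cobweb" radar of misclassification
rates. Pairwise runs (LOOCV and 75/25 hold-out) report AUC, sensitivity and
specificity.

Because no imaging data ships with the package, a synthetic cohort generator
produces a 78-subject three-group cohort (NC = 14, AD = 34, FTD = 30) of
deformed ellipsoids with overlapping volume distributions and group-specific
focal surface bumps (posterior pole for the AD-like group, anterior for the
FTD-like group), in exact template vertex correspondence.

## Worked example

```bash
python examples/05_three_class_classification.py
```

```
     biomarker  weighted AUC
  displacement         1.000
        volume         0.615
    invariants         0.533

cobweb axes for displacement (misclassification rates, 0 = none):
  AD → FTD: 0.00
  AD → NC: 0.00
  FTD → AD: 0.00
  FTD → NC: 0.00
  NC → AD: 0.00
  NC → FTD: 0.25
```

The displacement biomarker separates the three groups nearly perfectly
because the implanted atrophy signal is focal and spatially resolved by the
patch reduction, while the volume biomarker hovers near chance (the AD-like
and FTD-like volume distributions are identical by construction) and the
spectral invariants likewise (the two disease shapes are near mirror images,
and the spectrum cannot see orientation). This reproduces, at synthetic desk
scale, the qualitative biomarker ordering the pipeline is designed to
measure. Sweep results (`06_partition_sweep.py`) are noisier at this mesh
resolution: a 300-patch parcel holds only ~2 of the 642 template vertices,
so the fine-partition end carries selection noise that clinical-scale
meshes (30 000+ vertices) average away.

Other examples: `01_synthetic_cohort.py` (cohort structure),
`02_volume_normalization.py` (ICV regression), `03_spectral_invariants.py`
(eigenvalue oracles), `04_surface_displacements.py` (patch-wise group
difference maps), `06_partition_sweep.py` (AUC vs patch count).

A thin CLI mirrors the stages: `shapedx synth|volumes|spectral|displace|classify|sweep|report`
(see `shapedx --help`).

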