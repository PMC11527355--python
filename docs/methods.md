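# Methods

This note documents the models, algorithms, and design choices in
`neurosal`, in the order data flows through the pipeline.

## Phantom cohort (`neurosal.phantom`)

Each subject is a cubic, skull-stripped-style volume built from nested
ellipsoids: a brain ellipsoid (semi-axes anisotropy 1 : 0.92 : 0.85,
scaled by `brain_radius_frac` of the half-grid) whose outer shell is
non-white-matter tissue (NWM, a stand-in for cortex and deep gray
matter), an inner white-matter (WM) core at 0.78 of the brain semi-axes,
and a bilateral pair of lateral-ventricle (LV) ellipsoids (semi-axes
r : 1.3r : r, centers offset ±0.45 of the WM x-semi-axis) embedded in
the WM. The LV radius grows linearly with chronological age:

    r(ca) = base_ventricle_radius_vox + growth · (ca − age_min)

with defaults base 1.5 vox, growth 0.05 vox/year, ages 40–90. At the
default 32³ grid this spans roughly 30–700 LV voxels across the age
range, keeps the two ventricles disjoint, and keeps the oldest
subject's ventricles strictly inside the WM core (checked exactly on
the voxel grid at construction). Ventricular size is deliberately the
*only* age-dependent feature, so a trained regressor's attention has a
known target.

Intensities are drawn per tissue class from Gaussians on a unit scale
(WM 0.45 ± 0.035, NWM 0.28 ± 0.045, LV 0.10 ± 0.025, clipped at zero),
giving distinct but overlapping tissue histograms — enough texture for
histogram-based metrics (NMI) to be non-trivial. Background is exactly
zero, matching the skull-stripped convention that the brain-mask default
of the masked-gradient method relies on.

What the phantom does **not** emulate: cortical folding, partial-volume
effects, bias fields, scanner/site variation, hippocampal or sulcal
aging features, lesions. Results on phantoms therefore demonstrate that
a method *can* recover a localized, learnable signal through this CNN —
not that it will rank identically on real MRI.

## Ventricular dilation (`neurosal.perturb`)

Ages map to dilation coefficients through the cohort CA distribution:
0 at/below the 5th percentile, 1 at/above the 95th, linear *in CA*
between the two percentile ages (not in percentile rank; the anchors
make the two readings agree at the boundaries). Degenerate cohorts
(5th = 95th percentile) are rejected.

Edge voxels of the LV are those with a 6-connected (face) neighbor of a
different label; adjacency throughout uses face connectivity, the
conservative volumetric convention. The non-LV face-neighbors of the
edge split into adjacent white matter (AWM) and adjacent non-white
matter (ANWM; background excluded). Exactly `round(c·|AWM|)` AWM voxels
(banker's rounding, unbiased across a cohort) are drawn uniformly
without replacement — exact-count sampling, so a coefficient of 0.8 on
100 AWM voxels replaces exactly 80. Each selected voxel copies the
intensity of its nearest LV edge voxel, ties broken by lexicographic
coordinate order (a deterministic reading of "corresponding" ventricle
voxels). Finally, newly added voxels that lie on the boundary of the
enlarged LV region are set to the mean ANWM intensity, modeling the
distinct intensity distribution of structure boundaries; this step is
skipped when ANWM is empty or nothing was replaced.

The surrogate ground truth is the voxelwise cohort mean of
|perturbed − original|, normalized to unit mass; absolute differences
are used because replacement lowers intensity (WM → CSF-like values)
and the saliency convention downstream is likewise magnitude-based.
The fixation map is the indicator of the ground truth's support — the
simplest deterministic binarization.

## Brain-age CNN (`neurosal.bamodel`, `neurosal.nn`)

Blocks are conv(k³, stride 1, 'same' zero padding) → batch-norm → ReLU
→ max-pool(2³), with inverted dropout where configured; then flatten,
one hidden dense layer with ReLU, and a linear scalar head (BA is
unbounded regression, so no output activation). ReLU is placed after
batch normalization, the conventional ordering. Training minimizes MAE
with Adam; early stopping fires after `patience` consecutive epochs
without validation improvement and the best-validation weights are
restored. The scalar head's bias is initialized to the mean training
age — the standard head initialization for regression onto an
uncentered target, without which MAE's bounded gradients make Adam
close the ~65-year offset impractically slowly.

The default configuration is the full-scale architecture (input 128³,
four blocks of 16/32/64/128 filters of size 6³, dropout 0.2 on blocks
2–4, lr 1e-4, patience 20). `CNNConfig.reduced()` — input 32³, two
blocks of 4/8 filters of size 3³, dense width 32, lr 1e-3, patience 5,
max 40 epochs, batch 8 — is the desk-scale configuration used by the
default experiment; on the default cohort it reaches validation MAE
≈ 1.5 years against a cohort age SD of ≈ 14.4 years in a few minutes on
one CPU core. Both run through the same code path.

The engine is NumPy with explicit per-layer backward passes; the three
convolution inner loops are numba-JIT-compiled. Explicit backward was a
deliberate choice: every attribution method below consumes input
gradients, and two (GB, GGC) require *modified* backward rules, which
are awkward hooks in a framework but one keyword argument here. All
engine gradients are validated against central finite differences in
the test suite. Computation is float64; determinism is exact across
runs in one environment (seeded init, seeded shuffling, seeded dropout
streams; per-stage and per-subject streams are spawned from the master
seed so subject-level results do not depend on processing order).

## Attribution (`neurosal.attribution`)

All methods return signed fields; absolute value is applied only at
normalization, so G, IXG, and MG share one raw gradient definition.

* **G** — ∂(output)/∂(input), evaluation mode.
* **IXG** — x ⊙ G.
* **MG** — G zeroed outside a binary brain mask; the default mask is the
  nonzero-intensity support of the skull-stripped input.
* **GB** — gradient with every ReLU backward pass zeroing entries that
  are negative *or* whose forward activation was non-positive (the full
  guided convention; gating on gradients alone is obtained by a model
  without ReLUs, where GB provably equals G).
* **GGC** — Grad-CAM at the final conv layer: channel weights are the
  spatial means of the output's gradient on that feature map; the
  ReLU-rectified weighted activation map is upsampled trilinearly
  (nearest-neighbor available) to input shape and multiplied with GB.
* **IG** — (x − baseline) ⊙ ∫₀¹ ∇f(baseline + t(x − baseline)) dt, the
  integral approximated by Gauss–Legendre quadrature with nodes mapped
  affinely from [−1, 1] to [0, 1]; default 50 nodes, zero baseline.
  Because the integrand is only piecewise smooth (ReLU/max-pool switch
  points), completeness (Σ attributions = f(x) − f(baseline)) holds to
  quadrature accuracy: ~1% at 50 nodes on trained desk-scale models,
  tighter as nodes increase — this is checked, not assumed, in the
  tests. IXG is the degenerate one-point version of this construction:
  collapsing the path to the input itself gives x ⊙ ∇f(x) (with the
  zero baseline), which is exactly input × gradient; the single
  Gauss–Legendre node sits at the path midpoint rather than the
  endpoint, so `n_points=1` approximates, but does not reduce to, IXG.
* **GSHAP** — Monte-Carlo expectation over `n_samples` draws (default 5)
  of (x̃ − b) ⊙ ∇f at a uniformly random point on the segment from a
  uniformly chosen baseline b to the noise-perturbed input
  x̃ = x + N(0, σ²); the interpolation point is uniform on [0, 1], the
  natural choice absent a stated distribution. With σ = 0 and a single
  baseline, a linear model yields exactly (x − b) ⊙ w, and the
  estimator converges to IG in expectation.

## Normalization and metrics (`neurosal.simmetrics`)

Raw fields become saliency probability densities: |field| / Σ|field|;
all-zero fields are rejected as degenerate. Cohort aggregation is the
mean of per-subject densities, renormalized — averaging densities (not
raw fields) keeps subjects equally weighted regardless of gradient
scale.

* **DC** uses the standard Sørensen–Dice denominator |A| + |B|.
  Continuous saliency is binarized by taking the N highest-saliency
  voxels with N = |fixation support| (threshold-free and
  scale-invariant), ties broken lexicographically.
* **NMI** = (H(A) + H(B)) / H(A,B) from a joint histogram over 64
  equal-width bins (configurable) spanning each map's own range;
  constant maps (zero entropy) are rejected.
* **NSS** z-scores the saliency map (population SD) and averages over
  the fixation support.
* **CC** is the Pearson correlation over all voxels (population SD).
* **SIM** = Σ min(a, b) for two unit-mass densities.

DC and NSS consume the binary fixation map; NMI, CC, and SIM the
continuous normalized ground truth — the fixation-based metrics are
defined on fixations, the others compare distributions. Percent
differences are 100 · (s − s_MG)/|s_MG| per metric, with a zero baseline
flagged as NaN rather than inflated.

## Default experiment scale

The default `ExperimentConfig` is 200 subjects, ages uniform on 40–90,
32³ phantoms, 80/10/10 split, the reduced CNN, IG at 50 nodes, GSHAP
with 5 draws (σ = 0.05, baselines drawn from training volumes). These
sizes were chosen so the full pipeline — including training both the
dilated-trained (M_D) and non-dilated-trained (M_ND) models — completes
in minutes on a single CPU core while leaving the recovery effect
unambiguous: every metric scores the M_D IG map above a 100-fold
spatial-permutation null.

## Known limitations

* The phantom's age signal is single-featured and strong; methods that
  exploit input magnitude (IXG) are structurally favored on
  skull-stripped inputs.
* On this single-feature phantom, a model trained on *non-dilated*
  volumes already concentrates its saliency on the original ventricular
  boundary — which coincides voxel-for-voxel with the dilation ground
  truth — so dilation training does not improve, and geometrically
  shifts, localization relative to that ground truth. The
  dilated-over-non-dilated improvement observed on real multi-featured
  brains (where dilation amplifies the ventricle's share of the model's
  attention among many competing aging features) is therefore *not*
  expected to replicate here, and the corresponding directional test is
  expected to fail by design of the generator. Both models' maps do
  beat spatial-permutation nulls decisively.
* Guided backpropagation's gating makes GB (and hence GGC) act like an
  edge detector of the forward activations; their poor recovery scores
  here mirror their known insensitivity to the output, and should not
  be read as a bug.
* NMI discriminates weakly between methods (most maps share the
  background/tissue histogram structure); it is included for
  completeness of the metric battery.
* The quadrature error of IG near ReLU/max-pool kinks means
  completeness at 50 nodes is approximate for small output differences;
  use more nodes when exact bookkeeping matters.
* Full-scale (128³) training is supported by the same code path but is
  not practical without substantial compute; all shipped defaults are
  desk-scale.
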