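# Methods

## Model

Adult-brain aging is modelled as a continuous, topology-preserving
deformation of a global structural template G.  The deformation is
parameterized in the log-Euclidean framework: a stationary velocity
field (SVF) v defines a diffeomorphism through the group exponential
φ = exp(v), computed by scaling and squaring.  The model has three
components:

- **G** — the average anatomy of all input age-group templates,
  normalizing over both aging and non-aging (inter-subject) variation;
- **γ(t)** — a scalar aging-rate curve with γ(t_M) = 0 at the reference
  age and γ = 1 at the data endpoints, capturing the temporally
  non-uniform pace of structural change (atrophy accelerates in the
  elderly range);
- **Π(v_f), Π(v_b)** — the forward and backward aging SVFs, extracted at
  the reference template and parallel-transported into G's space.

Age-specific templates are G ∘ exp(γ(t)·Π(v_f)) for t ≥ t_M and
G ∘ exp(γ(t)·Π(v_b)) for t ≤ t_M.  Because γ only rescales a fixed SVF,
every generated deformation lies on a one-parameter subgroup: inverses
are exact (negate the field) and positivity of the Jacobian is inherited
from the exponential, including under extrapolation.

### Assumptions

- Aging deformations between neighbouring age groups are *small and
  smooth*; large deformations between templates are attributed to
  inter-subject (non-aging) variability.  The SVF registration's
  smoothing acts as the filter: deformations below its spatial scale are
  captured, larger ones rejected.
- Residual smooth non-aging deformations are *temporally inconsistent*
  across consecutive pairs; folding the pairwise fields into one SVF
  with the Baker–Campbell–Hausdorff (BCH) series averages them out,
  keeping only the consistent trend.
- Aging is monotone along each direction from the reference; the model
  describes a single average path, not a distribution of paths.

## Conventions that everything else depends on

- All algebra runs on the voxel grid; vectors are in voxel units.
  Spacing metadata survives I/O but does not rescale vectors (anisotropy
  is a documented limitation).
- `warp(I, d)(x) = I(x + u(x))` with linear interpolation and border
  replication; derivatives are central inside, one-sided at borders.
- `compose(d1, d2)` is the displacement of the point-map φ1∘φ2.  Since
  warps act by pullback, `warp(I, compose(d1, d2)) = warp(warp(I, d1), d2)`
  — the left argument is applied to the image first.
- `svf_register(moving, fixed)` returns v with
  `warp(moving, exp(v)) ≈ fixed`.  Under this convention the generation
  formula uses +γ·Π(v) (see above) and the Lie-bracket sign
  `[u,v] = (Du)v − (Dv)u` makes u + v + ½[u,v] the second-order BCH
  approximation of log(exp(u)∘exp(v)); the sign is pinned by a test
  against the direct-composition oracle.

## Numerical choices

- **Group exponential**: scaling and squaring with the per-voxel step
  bound 0.5 voxels (smallest K with max|v|/2^K < 0.5).
- **Group logarithm**: damped fixed-point iteration
  v ← v + δ·(disp ⊖ exp(v)) with δ = 0.5, start v₀ = u, stop at RMS
  update < 10⁻³ voxels or 40 iterations; inputs beyond max|u| = 5 voxels
  are rejected (outside the contraction domain), and a final RMS
  residual above 0.5 voxels raises with the residual attached.  The
  residual norm is recorded in the result's metadata.
- **Displacement inversion**: fixed point u⁻(x) = −u(x + u⁻(x)), 20
  iterations.
- **BCH truncation**: order 3 by default (through the double
  commutators), configurable to 1 or 2.  Fields being folded in are
  subdivided so each part stays below 0.5 voxels max magnitude — the
  per-point small-deformation condition.  Truncation is the dominant
  composition error source; the sequence-fold endpoint error against
  direct composition is ~0.005 voxels at 1-voxel field magnitudes.
- **SVF registration**: log-demons over a 3-level pyramid, 50
  iterations/level with an MSE-plateau early stop (relative improvement
  < 10⁻⁴, 3 strikes).  The force is the symmetric (ESM-style) demons
  force using the mean of the warped and fixed gradients — a one-sided
  force biases expansion against contraction, which skews the SVF-norm
  distances that drive reference selection.  The update is smoothed with
  a fluid Gaussian (σ = 2 voxels), folded in by a second-order BCH step,
  and the field smoothed with a diffusion Gaussian (σ = 1.5 voxels).
  These σ set the scale separation between captured (aging) and rejected
  (non-aging) deformations.
- **Affine pre-alignment**: full affine (d²+d parameters), Powell on
  MSE over the same pyramid, deterministic.  Fitted affines whose
  largest induced displacement over the grid is below 0.25 voxels are
  snapped to the identity: re-alignment below a quarter voxel carries no
  information, while resampling through it blurs the image enough to
  perturb the norm-based reference selection.
- **Groupwise template**: G starts as the voxelwise mean; each of 5
  outer iterations registers every template to G, subtracts the mean SVF
  from every field (log-Euclidean de-biasing, making the returned field
  list exactly centered), and averages the warped templates.  The
  builder is order-invariant to ~10⁻⁷ relative MSE.
- **γ(t)**: shape-preserving piecewise cubic (PCHIP) through the R knots
  plus the (t_M, 0) anchor — monotone knot runs stay monotone, so γ
  cannot overshoot below 0 near t_M.  Outside [t₁, t_N] the curve
  continues linearly with the boundary slope (needed for age
  extrapolation; any polynomial tail would be unsupported guesswork).
- **Degenerate inputs**: identical templates yield exactly zero pairwise
  SVFs; the aging-rate ratio is then undefined and γ falls back to the
  uniform ramp (the deformation is zero, so γ's shape is immaterial but
  must be well-defined).  Ties in reference selection break to the
  smallest index.

## Synthetic validation cohort

The built-in benchmark emulates a cross-sectional aging study with known
truth.  Defaults (all in `SimulationConfig`, all recorded in reports):
128×128 grid, 50 subjects, 5 time points at ages 30–70, subject
variability as 8 Gaussian-windowed displacement bumps (radius 10 voxels,
window σ = radius/2, amplitudes ~ N(0, 2²) voxels per axis), and one
shared aging bump pattern scaled to max magnitudes (0.5, 1.0, 1.5, 2.0,
2.5) voxels — uniform increments, so the expected γ is symmetric about
the middle age.  Bump amplitudes are rescaled (×0.8, bounded retries)
until the field's interior Jacobian stays above 0.1, so every simulated
deformation is a diffeomorphism.  Per-time-point templates are built
with the package's own groupwise builder (2 outer iterations — the
cohort images differ only by small bump fields, so the builder converges
quickly); the proxy ground truth is the aging map applied directly to
the base phantom.

What the benchmark emulates: inter-subject variability, a slow smooth
monotone aging trend, template construction noise.  What it does not:
realistic brain anatomy, MRI noise and bias fields, atrophy biophysics,
subject-varying aging trajectories.  Passing it shows the pipeline
recovers a consistent deformation trend from noisy per-age templates —
not that the defaults are tuned for clinical data.

The simulation runs in 2D (the displacement model is X/Y bumps); the
pipeline itself is dimension-agnostic and the Lie-algebra suite runs in
3D on 32³ grids.  Problem sizes throughout (32³ oracle fields, 128²
phantoms, 50×5 cohort) are chosen so the full validation runs in minutes
on a single CPU while keeping every effect it measures comfortably above
its tolerance.

## Determinism

Every stage is a pure function of (inputs, parameters, seed): seeded
`numpy` Generators, derivative-free deterministic optimizers, no
parallel nondeterminism.  Models serialize to uncompressed `.nii` plus
JSON/YAML (gzip would embed a timestamp); repeated runs are
byte-identical, which the suite asserts.

## Known limitations

- Anisotropic voxel spacing is carried as metadata but ignored by the
  algebra; strongly anisotropic data should be resampled first.
- The affine model is full-affine with an MSE metric; multi-modal inputs
  (different contrasts) are out of scope.
- Reference selection compares registration-derived SVF norms, which
  only "see" deformation where image gradients exist; with very similar
  neighbouring templates the argmin can sit within the noise (the
  symmetric force and identity-snapping exist to keep that noise small).
- The aging-rate knots are the composed-endpoint norm ratios — one knot
  per age point and side; denser temporal sampling of the input
  templates is the only way to refine γ.
- Large or non-monotone deformations (development, pathology) violate
  the model's assumptions and are rejected by design, not modelled.
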