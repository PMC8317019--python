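# Methods

`eqrecon` implements learned proximal gradient reconstruction for two linear
inverse problems — low-dose CT and subsampled Cartesian MRI — in which each
learned proximal step is a convolutional network equivariant under the
roto-translation group R² ⋊ Z_m.  This note records the model, the numerical
choices, and what the desk-scale experiments do and do not demonstrate.

## Model

**Groups and fields.**  The symmetry groups are the cyclic rotation groups
Z_m ⊂ SO(2), stored as integers `k ∈ {0, …, m−1}` (angle 2πk/m) so group
arithmetic is exact.  Feature maps are `FeatureField`s: `[C, H, W]` arrays
whose channel blocks carry declared representations — trivial (each channel a
scalar field) or regular (m channels permuted among themselves by rotations).
The induced action rotates the grid about the image centre, translates it,
and multiplies each block by its representation matrix.  For m ∈ {1, 2, 4}
the spatial rotation is an exact array permutation (`rot90`); other orders
use bilinear interpolation and all exactness claims are restricted to the
on-grid case.

**Steerable convolutions.**  A linear roto-translation-equivariant map is a
convolution whose kernel satisfies k(Rx) = π_out(R) k(x) π_in(R⁻¹).  We solve
this constraint directly on the discrete s×s grid: the constraint for the
group generator (which implies it for every element of a cyclic group) is a
linear map on kernels; its null space, computed by SVD with singular values
below 1e−10 kept, gives a Frobenius-orthonormal kernel basis.  Layer
parameters are coefficients in this basis plus one bias per output field,
replicated across the field's channels — per-channel biases would break
equivariance under the channel-permuting regular representation.  For
trivial→trivial 3×3 kernels the basis dimension equals the number of Z_m
orbits on the 9 grid cells (9, 5, 3 for m = 1, 2, 4), which the tests check
against a brute-force orbit-counting oracle.  An alternative route through
irreducible-representation decompositions exists but is unnecessary for
trivial/regular representations of small cyclic groups; the direct null-space
construction is exact and testable.

**Nonlinearities.**  Pointwise nonlinearities (default: leaky ReLU with
slope 0.01) are equivariant exactly when every field type acts by
permutation matrices (trivial or regular); this is enforced.  Norm
nonlinearities f ↦ f·φ(‖f‖), valid for any unitary type, are provided as
well.

**Forward models.**  The CT operator is a parallel-beam ray transform with
50 uniform view angles in [0, π), built as an explicit sparse matrix of
ray-driven line integrals (bilinear sampling at half-pixel steps,
`ceil(√2·N)+1` detectors so the diagonal is covered).  The adjoint is the
algebraic transpose, so the dot-product identity holds to machine precision
by construction.  FBP uses the discrete-space Ram-Lak kernel (frequency-domain
ramps computed from the spatial kernel to avoid DC bias) and the transpose
backprojection scaled by π/(2·n_angles).  Low-dose measurements follow the
post-log model y = −(1/μ)·log(max(n/N_in, η)) with n ~ Pois(N_in·exp(−μ·R u)),
N_in = 10 000 photons and η = 1e−8.  The attenuation scale μ is not a property
of the phantom generator, so by default it is calibrated once per dataset so
that the strongest ray attenuates to e⁻⁵ — a genuinely low-dose regime.  The
MRI operator is the unitary 2-D DFT with whole k-space columns masked
(variable-density Cartesian lines: a fully sampled centre, remaining columns
drawn without replacement under a Gaussian-decaying density until the target
fraction, default 20.3 %, is reached).  Its nonzero singular values are all 1,
and complex images travel as two real channels.

**Unrolled reconstruction.**  The reconstruction operator runs `it = 8`
untied iterations of (u, s) ← proxnet_i(u, s, ∇E_y(u)) from u⁰ = 0, s⁰ = 0,
with a five-channel scalar memory state s and E_y(u) = ½‖Au − y‖².  Each
prox-net is exactly three affine convolution layers with one residual
nonlinearity: K_project ∘ (id + φ ∘ K_intermediate) ∘ K_lift, all kernels
3×3.  The equivariant flavour lifts the trivial input fields (1 or 2 image
channels + 5 memory + 1 or 2 gradient channels) to `width/m` regular fields
and projects back to trivial fields; the ordinary flavour uses unconstrained
convolutions with identical channel counts, so activation shapes match
layer-for-layer and the ordinary parameterisation strictly contains the
equivariant one (`subsumption_embed` materialises the containment and the
tests check bit-level agreement).  The reference-scale width |H|·n_fields is
96; the desk-scale default is 32.

## Numerical choices

* **Gradient preconditioning.**  The prox-nets receive τ·∇E_y with the fixed
  scalar τ = 1/‖A‖² (power iteration, 30 steps).  A fixed scalar commutes
  with rotations and is absorbable into K_lift, so this changes conditioning,
  not the model family; without it the raw gradient's ‖A‖² scale compounds
  over 8 iterations and training from a cold start diverges.
* **Initialisation.**  K_intermediate starts at zero (bias included), making
  the residual branch the identity and each prox-net an analytically known
  linear map at init.  K_lift and K_project use a fan-in He-style draw; the
  steerable coefficients additionally exploit basis orthonormality.  Because
  expanded steerable kernels are correlated across a field's channels, the
  naive draw misestimates the layer gain, so each prox-net's composed gain is
  then calibrated on a white-noise probe to 0.5 — a mild contraction that
  keeps the 8-fold unrolling bounded at init.  The same calibration is
  applied to both flavours so the width-matched comparison starts level.
* **Training.**  Empirical risk (1/N)Σ‖u_i − Φ(y_i)‖², Adam (β₁ = 0.9,
  β₂ = 0.999, ε = 1e−8), minibatch 1, deterministic given the seed.  The
  reference recipe is lr 1e−4 for 10⁵ iterations; at desk scale we use
  lr 1e−3 for 500 iterations, the largest rate at which both flavours train
  stably from the calibrated init.  Gradients are hand-written reverse-mode
  passes (the package is pure NumPy/SciPy; no deep-learning framework): the
  Jacobian of the gradient step is the self-adjoint normal operator AᵀA, and
  the basis expansion back-propagates by orthonormal projection.
* **Padding.**  Default zeros.  Equivariance is checked with circular padding
  and circular translations, where translation equivariance is exact;
  with zero padding, boundary effects would contaminate the 1e−5 residual
  checks without saying anything about the operator's interior behaviour.
* **TV proximal operator.**  Isotropic TV with forward differences and
  Neumann boundary; `prox_tv` runs projected gradient ascent on the dual with
  fixed step 1/8 and stops at relative duality gap 1e−8 (certifying a
  relative solution error of about √gap).  The forward-difference stencil is
  not exactly 90°-invariant, so a symmetrised variant — the average of the
  forward-difference TV over the four rotated stencils, exactly Z₄-invariant
  on square grids — is provided; its prox commutes with quarter turns to
  solver accuracy, realising the invariance ⇒ prox-equivariance theorem at
  the discrete level.  Tikhonov shrinkage u/(1 + τλ) commutes exactly.
* **Alg. 1 step sizes** default to 1/‖A‖² via power iteration.
* **Metrics.**  PSNR uses the ground-truth peak (not a bit-depth range) and
  an `inf` sentinel for identical images.  SSIM uses a uniform 7×7 window,
  c₁ = (0.01L)², c₂ = (0.03L)² with L the data range, and sample-normalised
  covariances, matching the scikit-image defaults (the tests cross-check to
  1e−6).  Region-restricted SSIM reflection-pads by 3, computes the aligned
  SSIM map, and averages over the mask.  MRI metrics act on magnitudes.

## Synthetic data

The generators replace clinical datasets at desk scale.  Phantoms are
overlays of random anti-aliased ellipses, deliberately elongated
(eccentricity 0.6–0.95) so rotation generalisation is non-trivial —
isotropic blobs would hide the difference between the flavours.  Ellipse
orientations are drawn from a configurable range: the default is the full
isotropic [0, π), while a narrow range emulates the global orientation of
clinical images (chests are scanned upright), which is precisely what makes
a rotated test image out-of-distribution.  Every generator is a pure
function of its seed.  What the
phantoms do *not* emulate: anatomical texture, correlated backgrounds,
scanner artefacts; passing tests therefore demonstrate the symmetry
machinery and the optimisation, not clinical reconstruction quality.

Two experiments probe rotation generalisation:

* **Single-pair denoising:** ordinary and Z₄-equivariant linear filters
  (9×9, circular padding) are Adam-trained on one strongly oriented
  image with additive Gaussian noise (σ = 0.3, a standard non-trivial
  denoising regime).  On the 90°-rotated test copy the equivariant filter's
  PSNR is unchanged (the rotation is an exact permutation the filter
  commutes with), while the ordinary filter, having specialised to the
  training orientation, loses several dB.
* **Small-training-set CT:** width-matched nets (width 32, it 8) trained on
  N = 20 phantoms at 64×64 whose ellipse axes lie in a common 60° band
  (the orientation-concentrated ensemble standing in for globally oriented
  anatomy), evaluated on held-out phantoms from the same ensemble, upright
  and rotated by 90° (with freshly simulated measurements).  Medians are
  taken over ≥3 training seeds.  The comparison is directional and
  stochastic: the equivariant net's rotated-test PSNR should not fall below
  the ordinary net's.  With a fully isotropic ensemble the rotated test
  would be in-distribution and neither flavour would be penalised — the
  out-of-distribution structure is what the experiment is about.  Rotated test images built with on-grid angles incur
  no interpolation loss; off-grid angles smooth away high frequencies (the
  tests verify TV strictly drops under a 20° rotation of a checkerboard) and
  would make the rotated problem artificially easier.

## Known limitations

* Exactness claims hold for m ∈ {1, 2, 4}; other orders rely on bilinear
  resampling in both the field action and the kernel constraint, and the
  resulting equivariance is approximate by construction.
* Reflections (dihedral groups), continuous-SO(2) irreducible
  representations, 3-D groups, multi-coil MRI and fan-beam CT are out of
  scope.
* The full reconstruction operator is *not* equivariant end-to-end — the
  measured data break the symmetry through ∇E_y — and the package makes no
  such claim; only each prox-net is equivariant.  A test documents the
  corresponding failure of the classical variational solution map under
  incomplete measurements.
* Desk-scale training (hundreds of Adam iterations, 64×64 phantoms) is far
  from the converged reference regime; the experiments establish directions
  and invariances, not absolute reconstruction quality.
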