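# Methods

## Conventions

**Real basis.** All tensors are real. Real spherical harmonics are the
standard recombination of the complex ones (Condon–Shortley phase folded into
the conversion), ordered m = −ℓ…ℓ: Y_{ℓm} = √2(−1)^m Re Y_ℓ^m for m > 0 and
√2(−1)^m Im Y_ℓ^{|m|} for m < 0. They are orthonormal on the unit sphere.
Rotations are intrinsic ZYZ Euler triples, R = R_z(α)R_y(β)R_z(γ);
quaternions are scalar-last.

**Wigner-D.** D^ℓ(R) is *defined* by Y_ℓ(R·x̂) = D^ℓ(R)·Y_ℓ(x̂) on the real
harmonic vector. It is computed from Wigner's factorial formula for the
small-d matrix (exact integer prefactors, float trigonometry) and conjugated
into the real basis with the unitary change-of-basis matrix. With this
convention D¹(R) = P·R·Pᵀ where P is the fixed permutation (x, y, z) →
(y, z, x); steerable blocks of shape (channels, 2ℓ+1) are rotated by
right-multiplication with D^ℓ(R)ᵀ.

**Clebsch–Gordan coefficients.** Complex coefficients are evaluated exactly
with Python `Fraction` arithmetic via Racah's closed form (a single float
square root at the end), then conjugated into the real basis. The conjugated
tensor is purely real when ℓ₁+ℓ₂+ℓ₃ is even and purely imaginary when odd; a
global unit phase per triple makes every block real. This preserves both the
orthogonality relation Σ_{m₁m₂} C^{(ℓ₃)} C^{(ℓ₃′)} = δ and exact
equivariance, which the test suite verifies against sympy's symbolic values.
Tables are built once per maximum degree (default cap 14), cached, and
serializable to a single `.npz` archive.

**Zernike radial polynomials.** The closed form used is

    R_nℓ(r) = √(2n+3) · r^ℓ · P_k^{(0, ℓ+1/2)}(2r² − 1),  k = (n−ℓ)/2,

orthonormal on [0, 1] under weight r², identically zero (bitwise 0.0) when
n < ℓ or n−ℓ is odd. Radii are divided by r_max before evaluation; points
exactly at r = r_max are included (closed ball). Any orthonormal radial
convention spans the same space; this one is the standard Jacobi-polynomial
form. Each point contributes unit weight to the transform; per-point weights
are a constructor option.

**Spherical grids.** Images live on the 2bw × 2bw equiangular Driscoll–Healy
grid, θ_j = π(2j+1)/(4bw), φ_k = πk/bw. The quadrature weights are the
sampling-theorem weights (azimuthal factor π/bw folded in); their exactness
for band-limited integrands below the bandwidth is asserted by a test, not
assumed. Image transforms use a constant radial function (one radial index
per degree).

## Architecture

A Clebsch–Gordan block applies, in order, Lin → ETP → BN → SN (the order is
configurable; the alternative BN → ETP → SN → Lin is also tested for
equivariance):

* **Lin** — per-degree weight matrices W_ℓ mixing channels, never orders;
  initialization N(0, 1/C_in) per degree, from the model's seeded generator.
* **ETP** — channel-wise Clebsch–Gordan products along a restricted path
  set. The default connectivity couples each degree with itself into every
  allowed output degree up to the block's cap, and (when an ℓ = 1 feature
  exists) each degree with ℓ = 1 into its neighboring degrees; the inputs
  pass through alongside the products. This guarantees information paths
  from every degree down to ℓ = 0 and back up, while keeping the product
  count linear in the number of degrees. The path set is fully overridable.
* **BN** — divides each (degree, channel) feature by the batch-averaged
  feature norm (momentum 0.1, ε = 1e−6); evaluation always uses running
  statistics, and a batch of one falls back to them with a warning.
* **SN** — divides the whole tensor by the square root of its total norm and
  applies a learned scalar per degree. The total norm is the sum of
  *inner-product* (squared L2) feature norms, so with unit affine factors
  the output's total norm is exactly 1; with plain L2 norms that unit-norm
  property would not hold, which fixed the convention.

The encoder's degree caps descend one per block from L−1 to 1; the decoder's
ascend from 2 back to L (single-block edge cases for L ≤ 1). The invariant
code is a linear read-out of the final ℓ = 0 channels (2× width for the
variational mean/log-variance); the frame head maps the final ℓ = 1 channels
to exactly two 3-vectors for Gram–Schmidt. The decoder sees the frame as two
ℓ = 1 channels (rows converted by the permutation P), which is what makes
the composition equivariant end to end; the KL term touches only the
invariant part, and the frame is always deterministic. During training a
fixed orthogonal pair scaled by 1e−6 is added to the two learned vectors
before Gram–Schmidt so that gradients remain finite near collinearity; at
evaluation, degenerate inputs (residual norm < 1e−8) raise instead.

Since no GPU tensor framework is a dependency, layers run on a small
reverse-mode autodiff core over float64 numpy arrays (`hvae.autodiff`),
providing exactly the primitives the layers need (broadcast arithmetic,
einsum, reductions, concatenation); every primitive's gradient is tested
against central finite differences.

## Training

The loss is α·MSE + β·KL with MSE the *mean* over all coefficients (keeping
α comparable across signatures) and the closed-form diagonal-Gaussian KL.
α defaults to 1; β to 0 (plain autoencoder) with an optional linear warm-up
over the first 25% of epochs when nonzero. Optimization is Adam
(lr 1e−3 … 2e−3 in the bundled experiments), seeded and deterministic in
single-threaded numpy; training aborts with a diagnostic on a non-finite
loss. Optional early stopping monitors held-out cosine loss with patience
20. Input tensors are normalized to unit global norm at encoding time: the
cosine evaluation metric is scale-free and unit-norm inputs keep per-sample
MSE magnitudes comparable.

Latent-space evaluation follows the standard recipe: K-means (k = number of
classes, 10 restarts, fixed seed) scored by purity and V-measure, and a
standardize-then-fit linear or K-nearest-neighbor classifier on the
invariant codes only. Pocket-style embeddings are plain sums of residue
embeddings (permutation-invariant, extensive).

## Synthetic data

The generators are pure functions of (spec, seed). The cloud generator
emulates residue-centered atomic neighborhoods: three shape classes — an
8-point ring with two axial oxygens, a helical arc with two terminal
nitrogens, a tetrahedral carbon cluster with a central sulfur — across the
four heavy-atom channels, positional noise σ = 0.05 (template units),
Haar-uniform rotations via normalized Gaussian quaternions, scaled into the
10 Å ball. The image generator sums von-Mises–Fisher-like bumps
(exp κ(n̂·ĉ − 1), κ = 10) at rotated class-specific center patterns on the
DH grid. Ground-truth rotations are stored with every sample, which is what
lets tests verify the transforms' equivariance against the generator
directly.

What passing tests on these data do **not** show: realistic protein
geometry or chemistry (bond lengths, radial density profiles, class overlap
between residue types), image textures beyond smooth bumps, class
imbalance, or measurement noise structure. The synthetic classes are
well-separated by design — the reference experiment's purity of ~1.0 is a
property of the benchmark, not a claim about real structural data.

## Reference experiment

The toy experiment (`hvae.experiments.toy_cloud_experiment`) trains a
deterministic model with latent size 8 and width 12 on 600 encoded clouds
(L = 4, N = 4, 140 coefficients), Adam lr 2e−3 for 100 epochs plus 25
epochs at lr/4, evaluated on a rotated held-out quarter. The
orientation-augmentation comparison trains at reduced scale (50 samples per
class, 40 + 10 epochs, several seeds per condition): by exact equivariance,
training on non-rotated data and evaluating on rotated data should match
rotated-training performance up to seed noise, and the experiment measures
exactly that gap. Problem sizes were chosen so the whole reference pipeline
runs in minutes on one CPU core.

## Limitations

* Parity is not handled: the group is SO(3), not O(3); reflections are out
  of scope, as are spin-weighted harmonics and SU(2) double covers.
* The ETP default path set is a documented design choice, not a tuned
  optimum; ablations over path sets are out of scope.
* Reconstruction quality degrades for higher degrees ℓ at small latent
  sizes (all degrees compete for the same invariant bottleneck); the
  multiscale variants that might relieve this are not implemented.
* The autodiff core is deliberately minimal (no GPU, no JIT); it is sized
  for the desk-scale experiments shipped here, not for large-corpus
  training.
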