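# Methods

## Problem setting

Diffusion-weighted MRI measures, in every voxel, signal attenuation along N
gradient directions (b-vectors) on the sphere; a scan is a discretization of
a function f: R^3 x S^2 -> R.  Rigidly moving the subject transforms this
function by the action of SE(3): the voxel grid rotates *and* every voxel's
spherical signal rotates with it.  This package implements convolutional
networks whose layers are equivariant to (discretizations of) that action,
in direct regular-representation form — group elements index feature
channels, and convolutions are weighted sums over group translates — rather
than through spectral (irreducible-representation / steerable) machinery.
The benchmark task is voxel-wise classification of four tissue classes:
cerebrospinal fluid (CSF), subcortical gray matter, white matter (WM) and
cortical gray matter (GM).

## Discretization

**Sphere and rotation group.** S^2 is discretized by the 12 vertices of a
regular icosahedron, SO(3) by the icosahedron's 60 proper rotational
symmetries.  Every group element factors uniquely as (coset representative
of a vertex) x (one of the five stabilizer rotations 2k*pi/5 about the
reference vertex v0): 12 fibers x 5 spins.  Elements are ordered
lexicographically by (vertex, spin), so element `5*v + s` has fiber `(v, s)`
and the identity is element 0.  Coset representatives are chosen
deterministically (maximal trace, then lexicographic on the matrix entries),
which makes the identity the representative of v0's own coset.

**Embedding.** Vertices sit at the normalized cyclic coordinate permutations
of (0, +-1, +-phi).  In this embedding the three 180-degree rotations about
the coordinate axes are exact group elements *and* exact permutations of any
cubic voxel grid, so end-to-end equivariance can be asserted without any
interpolation error.  The orientation of the icosahedron relative to the
voxel grid is otherwise arbitrary; this choice trades nothing and buys exact
tests.

**Signals.** Two views of the data coexist: Type 1, the raw N-vector of
measurements per voxel (used by the classical CNN, directions as input
channels); and Type 2, a proper spherical function obtained by
Nadaraya-Watson smoothing with the antipodally symmetric Watson kernel
`exp(kappa (mu.v)^2)`, kappa = 10 (used by all group networks).  Weights are
row-normalized, so interpolated values are convex combinations of
measurements, the kappa -> 0 limit is the uniform mean, and interpolation
commutes exactly with joint rotation of queries and samples.  One
interpolation matrix is precomputed per (gradient table, query set) pair.

## Operators

All operators act on group feature maps indexed by (voxel, group element in
60, channel); every convolutional sublayer carries one bias per output
channel, and ReLU follows conv -> bias.

* **Lifting (S^2 -> group).** A star-shaped kernel with 11 sample points —
  the reference vertex, the five arc-midpoints of its incident edges and its
  five one-ring neighbours — is transported by each group element and
  correlated with the signal, discretizing the lifting integral with
  counting measure on the 11 samples.  The kernel support is pinned to 11
  points by the published capacity of every architecture variant; the radial
  placement (midpoints + vertices) is this package's choice.  The union of
  all rotated sample points (the orbit: 12 vertices + 30 edge midpoints = 42
  directions) is closed under the group, so lifting a rotated signal is an
  exact index permutation of lifting the original — equivariance holds to
  machine precision, and tests assert it at 1e-6.
* **Group convolution (fiber kernel).** The kernel is supported on exactly
  one fiber (the five stabilizer spins).  With the (vertex, spin) ordering
  the layer is a cyclic correlation over the five spins inside each coset,
  looked up through the Cayley table:
  `out(g) = bias + sum_k F(g sigma_k^-1) W_k`.  Pure table lookups; exactly
  left-equivariant.
* **Spatial convolution.** A valid (no padding, stride 1) 3x3x3 correlation
  applied per group slot.  Three modes tie the kernel to the slot: `none`
  uses the unrotated kernel everywhere (the direct product T^3 x SO(3));
  `partial` rotates by the fiber's coset representative (SE(3)*); `full`
  rotates by the slot's own rotation (SE(3)).  Kernel rotation is trilinear
  on the 3^3 offset grid with zero outside the cube (corners rotate
  partially out of support; this is the acknowledged interpolation error of
  the direct approach).  For the grid-exact 180-degree rotations the rotated
  kernel is an exact index flip, hence the exact end-to-end tests.  A
  rotated central *delta* kernel is no longer a delta for non-grid
  rotations — trilinear resampling spreads small weights to neighbouring
  offsets — so "delta kernel = central crop" holds exactly only on
  identity-rotation slots.
* **Projection.** Channel-wise max over group coordinates: over the five
  spins of each fiber (back to the 12 sphere vertices; used by the
  SO(3)-only network) or over all 60 elements (back to the voxel grid;
  used by the spatial variants).  No learned weights; confers invariance.

## Architectures and parameter accounting

Variants, in increasing group structure: `classical` (plain 3D CNN on the
Type-1 volume), `baseline_so3` (single-voxel lift-gconv-project),
`decoupled`/`partial_se3`/`full_se3` (interleaved S^2 and R^3 sublayers,
three spatial sublayers shrinking 7^3 -> 1^3, final S^2 sublayer, projection
over all 60, FC head), and `rotavg_classical` (the classical stack
replicated over 12 or 60 rotated kernel copies with shared weights, logits
averaged).  Channel-width lists alternate S^2/R^3 sublayer widths for the
spatial variants; a list of even length ends on a spatial sublayer (the
configuration used for the external comparison network).

Under the bias conventions above the counts reproduce the published
capacities exactly: classical 90-5-5-5 = 13,539 and 90-120-120-90 = 972,694;
baseline 1-5 = 286 and 10-20 = 2,104; decoupled/partial/full 5x7 = 2,514 and
10-20-20-40-40-20-10 = 59,914; the comparison configuration
10-10-20-40-20-10 = 34,964; rotation-averaged classical = 13,539 (shared
copies counted once).  `count_parameters` computes these analytically; an
independent enumeration walks the built layer stack, and the two are
asserted equal for every preset.

## Training

The numerical stack (forward, backward, Adam) is implemented in numpy with
hand-written gradients; activations use layout (group, batch, x, y, z,
channel) so the inner loops are large BLAS matrix products (the lift is a
single combined gather-weight GEMM; the fiber convolution is one GEMM with a
block-circulant matrix; the spatial convolution is an im2col GEMM with a
transposed-convolution backward, chunked over group slots to bound memory).
Training arrays are float32; gradient-check tests run the same layers in
float64 against central differences.

Hyperparameters follow the published protocol: focal loss
`-alpha_y (1 - p_y)^gamma log p_y` with gamma = 2 and alpha = (0.35, 0.35,
0.15, 0.15) for (CSF, subcortical, WM, GM); batch size 100; Adam at learning
rate 0.001 (the protocol fixes only batch size and learning rate; Adam is
this package's choice, seedable).  Epoch budgets are exposed in
configuration rather than replicating a convergence-based stopping rule.
p_y is clamped at 1e-8 before the log.  Inputs are b0-normalized attenuations passed
through a fixed affine standardization ((x - 0.4) * 4, i.e. approximately
centered and unit-variance at b = 1000); this conditions the optimization
and is applied identically across variants.

**Augmentation.** On-the-fly rotations are drawn from the 24-element
octahedral group so the voxel grid permutes exactly; per-voxel signals are
re-expressed at the original b-vectors by Watson interpolation from the
rotated gradient scheme.  The rotated test set applies one independent
octahedral element per patch, seeded.

## Metrics

Per-class accuracy is recall (#correct / #class samples), Dice is
2TP/(2TP+FP+FN), overall accuracy is #correct / #all; with multiple scans,
metrics aggregate as mean +- sd over scan-level values, and scans lacking a
class are excluded from that class's mean (flagged if absent everywhere).
The performance-drop map takes x = C_reference / C_perturbed and returns
either `exp(-alpha x)` (default; the closest literal reading of the
published formula) or a logistic `1/(1+exp(-alpha (x-1)))`; both are
provided because the published formula is typographically ambiguous, and any
reported number should name the formula used.

## Synthetic phantom

The generator emulates the statistical structure the networks assume, not
brain anatomy: four concentric tissue shells on a 32^3 grid (CSF core,
subcortical ring, WM interior, GM shell; radii fractions 0.32/0.46/0.78/1.0
of the mask radius), per-voxel signals from the mono-exponential tensor
model S(v) = S0 exp(-b v^T D v) with literature-typical diffusivities
(mm^2/s): CSF (3.0, 3.0, 3.0)e-3, WM (1.7, 0.3, 0.3)e-3, GM (0.9, 0.7,
0.7)e-3, subcortical a 50/50 WM/GM two-tensor mixture.  The WM principal
direction is the azimuthal tangent of the voxel position, giving spatially
coherent, smoothly rotating anisotropy for the spatial layers to exploit.
Acquisition: 90 repulsion-spread directions (seeded Coulomb descent, 500
iterations) at b = 1000 s/mm^2 plus 3 b0 volumes; Rician noise sigma = 0.02
relative to S0 by default.  The gradient table has its own seed (default
2025), independent of the per-scan seed, because an acquisition protocol is
shared across the scans of a study — two phantoms with different scan seeds
differ in noise realization only.

What the phantom does *not* model: crossing fibers, multi-shell acquisition,
partial-volume mixing at boundaries beyond the subcortical mixture, eddy
currents, motion, or anatomical geometry.  Passing the end-to-end tests
therefore shows that the implementation learns and that the equivariance
machinery behaves as designed — not that the architectures would reach any
particular accuracy on clinical data.

## Desk-scale study

The end-to-end suite trains on patches of one phantom and evaluates on a
second phantom (same gradient table, different noise), mirroring the
train-on-one-scan protocol at desk scale.  Training uses the scan's natural
class proportions (about 3% CSF, 6% subcortical, 38% WM, 53% GM inside the
mask) — the focal loss exists precisely to weight the rare classes — with
1,200 training patches, 400 test patches, and epoch budgets of 25
(classical), 15 (decoupled) and 10 (full SE(3)); these sizes are the
package's chosen study conditions.  On this phantom the two easy contrasts
(mean attenuation and directional spread) already separate CSF/WM/GM almost
perfectly, while the subcortical mixture is genuinely hard — matching the
qualitative difficulty ordering of the real task.  Robustness is probed by
the octahedral rotated test set; the expected qualitative ordering is that
the classical CNN loses the most accuracy and the SE(3) network the least.

## Numerical choices and edge cases

- Group closure deduplicates at 1e-6 Frobenius and re-verifies all tables at
  1e-9; closure failing to terminate at exactly 60 elements raises.
- Orbit deduplication tolerance 1e-9; lift inputs with a wrong orbit size
  are rejected rather than re-interpolated.
- b0 normalization guards with epsilon = 1e-6; voxels with mean b0 below it
  are masked out and zero-filled.
- Ties in projection maxima route the gradient to the first argmax (numpy
  argmax convention); ReLU's subgradient at 0 is 0.
- Rotation of sampling schemes rejects matrices that are not proper
  rotations (|det - 1| > 1e-6).
- Training aborts with a diagnostic on non-finite loss.

## Known limitations

- The training stack is CPU-bound numpy; it is sized for desk-scale
  experiments (thousands of patches), not full scans.
- Only single-shell acquisitions are modeled; b-values enter solely through
  b0 separation and the phantom's attenuation model.
- The partial (SE(3)*) variant is only fully equivariant for kernels with
  SO(2) symmetry, which is not imposed; it is included as an ablation, not
  as an equivariance guarantee.
- The rotation-averaged classical CNN averages logits across branches;
  averaging post-softmax probabilities is the other defensible reading of
  the published description.
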