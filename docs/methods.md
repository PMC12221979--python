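# Methods

## Overview

`habitspace` analyses the external shape (habit) of crystal-like particles
given as 3-D surface point clouds. The pipeline is:

1. **Habit generation** (`synthetic_habits`) — labelled convex polyhedra
   standing in for the output of kinetic Monte Carlo crystal-growth
   simulations, whose equilibrium shapes are simple convex polyhedra.
2. **Geometric featurization** (`geometry`, `zingg`) — PCA axis lengths,
   S:M and M:L aspect ratios, Zingg class, convex-hull area/volume.
3. **Spherical-harmonic descriptors** (`shsd`) — a 66-dimensional
   frequency-space shape description at truncation degree 10.
4. **Voxelization** (`voxelize`) — aligned, normalized 32×32×32 occupancy
   grids for model input.
5. **Disentangling autoencoder** (`dae`) — a 3-D convolutional
   autoencoder whose 6-D latent space passes through an exactly
   orthogonal learned map.
6. **Latent analysis** (`latent_analysis`) — latent–feature correlations,
   2-D projections, class centroids, and decoded shape-morphing
   trajectories.

## Synthetic habit generator

A habit is the bounded intersection of facet halfspaces
{x : n_f · x ≤ d_f} (a Wulff-style construction) with the origin
interior. Boundedness is checked exactly: the set is bounded iff the
origin lies strictly inside the convex hull of the outward normals.
Vertices come from `scipy.spatial.HalfspaceIntersection`.

Three crystal systems are modelled through the symmetry constraints they
impose on facet families:

- **monoclinic** — parallelepiped habits; the unique angle β is drawn
  uniformly from [95°, 125°] per habit (real monoclinic cells cluster in
  this range); all three facet-pair distances are free, so all four Zingg
  classes occur.
- **tetragonal** (γ = 90°) — square prisms; the four in-plane facets share
  one distance.
- **hexagonal** (γ = 120°) — hexagonal prisms; the six-member in-plane
  family shares one distance.

Because the prism cross-sections have an isotropic in-plane second
moment, two principal extents coincide and laths (both aspect ratios
below threshold) are geometrically impossible in the tetragonal and
hexagonal systems; requesting them is a configuration error.

**Ground-truth labels.** Aspect ratios of a habit are defined on the
uniform *solid*, via the exact second-moment tensor computed by Delaunay
tetrahedral decomposition (for a tetrahedron with vertices v₁..v₄ and sum
s, ∫ x xᵀ dV = (V/20)(Σᵢ vᵢvᵢᵀ + s sᵀ)). The square roots of the
covariance eigenvalues, sorted, give S ≤ M ≤ L. This is the
infinite-sample limit of the dense-sampling covariance oracle, and tests
verify the two agree.

**Aspect-ratio targets** are drawn log-uniformly in [0.15, 1.0] within
the requested class's quadrant, with a 0.04 margin off the 0.66 threshold
so that surface sampling and jitter rarely flip labels (measured
agreement between the generator label and classification of the sampled
cloud: ≈98%). Monoclinic skew perturbs realized ratios, so each habit is
re-checked against the oracle and resampled on a class mismatch.

**Surface sampling** picks hull triangles with probability proportional
to area and uniform barycentric coordinates, so points lie exactly on
facet planes and per-facet counts are area-proportional. An isotropic
Gaussian jitter of σ = 0.3% of the maximum extent (configurable) emulates
growth-front roughness; it is applied after sampling, so the on-plane
guarantee holds for `sample_surface` itself.

What the generator does **not** emulate: growth kinetics (no site
energies, no supersaturation schedule), surface topography beyond
isotropic jitter, concave or re-entrant shapes, and the skewed class
abundances of real parameter sweeps (classes are balanced by
construction). Passing tests therefore demonstrate that the analytics
recover geometry-driven structure from convex, cleanly labelled data —
not robustness to kinetic roughening or label noise.

## Geometric features

Clouds are centered at their centroid and scaled by the maximum Euclidean
norm (idempotent). Axis lengths are the singular values of the centered
N×3 coordinate matrix divided by √N — RMS extents, which makes them
independent of sampling density; only the ratios S:M and M:L are used
downstream, so the √N convention is immaterial to classification. A
rank-deficient cloud yields S = 0 with a `degenerate` flag rather than an
exception, so batch runs never abort.

Zingg classification uses the printed threshold 0.66 (not the exact
fraction 2/3): block iff both ratios exceed it, equality assigned to the
"≤" branch because a block is defined by ratios *greater than* the
threshold. The threshold is a parameter.

Hull surface area and volume come from Qhull (`scipy.spatial.ConvexHull`).

## Spherical-harmonic shape descriptors

A convex particle is star-shaped about its volume centroid (computed by
fan decomposition of the hull), so its surface is a radial function
r(θ, φ): the radius along direction u is min over facets of
d_f / (n_f · u) restricted to n_f · u > 0. Coefficients

  c_{l,m} = ∮ r(θ, φ) conj(Y_l^m) dΩ

are computed with orthonormal complex harmonics on a Gauss–Legendre (in
cos θ) × uniform (in φ) product rule. Defaults n_θ = 24, n_φ = 48
integrate band-limited integrands of degree min(2n_θ−1, n_φ−1) = 47 ≥ 20
exactly; `sh_expand` refuses quadratures below the 2·l_max exactness
contract. For real r, c_{l,−m} is determined by conjugation, so the
m ≥ 0 magnitudes carry all information: at l_max = 10 that is
(11·12)/2 = 66 values, ordered lexicographically by (l, m) so that
Mag_0..Mag_5 are Y00, Y10, Y11, Y20, Y21, Y22. The "real, m ≥ 0"
convention is realized as magnitudes of complex m ≥ 0 coefficients; a
real-basis convention restricted to cosine terms would give the same
66-count and closely related magnitudes.

Descriptors are computed in the fixed Cartesian frame of the cloud; no
rotational invariance is applied, so descriptor comparisons are
frame-dependent by design.

**Truncation quality.** At l_max = 10 the synthesis error of compact
(block) habits stays below 10% of the local radius. For high-aspect
habits the pointwise *relative* error at the thin waist is dominated by
Gibbs overshoot against a small radius and can approach the aspect ratio
itself; across the generator family the RMS error stays below 40% of the
mean radius. Tests assert exactly these two bounds.

## Voxelization

Aligned model input: the cloud is rotated into its principal frame
(L → z, M → y, S → x; axis signs fixed by non-negative third moments),
normalized to max norm 1, rasterized on a [−1, 1]³ grid at a working
resolution of 64, then block-max downsampled (non-overlapping 2³ max,
`skimage.measure.block_reduce`) to the 32³ model input. The working
resolution is twice the final side so exactly one factor-2 pooling is
applied; the pre-pool resolution is a package choice (the 32³ target is
the stated model-input size).

`convex_solid` fill (default, suited to convex habits and stabler
autoencoder targets than thin shells) marks voxels whose center is inside
the hull, unioned with voxels containing a sample point — the union keeps
surface occupancy a subset of solid occupancy where a face plane passes
between a point and its voxel center. `surface` fill marks only
point-containing voxels. Occupancy is binary at source resolution; no
partial-volume anti-aliasing. Decoded volumes are binarized at 0.5 when
converted back to point sets (`voxels_to_points` returns occupied-voxel
centers in physical coordinates).

Center-in counting carries a ±1 voxel-layer phase error per axis, so
voxelized volume agrees with hull volume only to within area × spacing
(the shell bound); this is the bound tests assert.

## Disentangling autoencoder

**Architecture.** Encoder: four stride-2, kernel-2 3-D convolutions
(channels 8/16/32/64) with ReLU, 32³ → 16³ → 8³ → 4³ → 2³, a linear head
to the 6-D latent, then the orthogonal map. Decoder mirrors with
transposed convolutions and a sigmoid output in [0, 1]. A stride-2
kernel-2 convolution partitions the grid into disjoint 2×2×2 blocks and
applies one linear map per block, so all layers are exact blockwise
matrix products; the network (forward and hand-derived backward) runs on
BLAS in NumPy with no deep-learning framework. Gradients are verified
against central differences in the test suite.

**Orthogonal latent map.** R = Π G(i,j,θ_{ij}) over all 15 index pairs of
the 6-D latent — an Euler-angle factorization of SO(6) by Givens plane
rotations. Orthogonality holds *by construction* at every step (RᵀR = I
to round-off, measured ≤ 5·10⁻¹⁶ throughout training); gradients flow
through the angles via the product rule over prefix/suffix partial
products. The map is placed after the encoder's linear head (the decoder
consumes the rotated latent directly); applying it at the decoder input
instead would be an equivalent reparameterization of this architecture.

**Training.** Adam (β₁ = 0.9, β₂ = 0.999), default learning rate 2·10⁻³,
batch 32, 30 epochs, per-voxel binary cross-entropy on [0, 1] targets
(squared error available). Defaults were chosen for stable convergence
of the blockwise architecture at the 10³-sample scale; the memorization
sanity check (50 copies of one shape) uses a higher rate (10⁻²) and more
epochs, appropriate for its tiny, redundant dataset. Inputs must be
PCA-aligned (see Voxelization) because the convolutional layers are not
rotation equivariant.

**Metrics.** 3-D SSIM (uniform 7³ window, stabilization constants
(0.01·range)² and (0.03·range)², range 1, via scikit-image) and NCC
(Pearson correlation of flattened volumes; undefined and raised for
constant input).

## Latent-space analysis

The latent–feature matrix is the Pearson correlation between each latent
dimension and {S:M, M:L, area, volume, SA:V} (correlation, not raw
covariance: the quantities of interest are scale-free and comparable
across features). Constant variables yield flagged NaN entries.
The 2-D latent view either selects the two dimensions with the largest
|r| against S:M and M:L (forced distinct; pure column selection, no
fitting) or embeds all six dimensions with UMAP (15 neighbours, min_dist
0.1, fixed seed). Class centroids are arithmetic means. Trajectories
interpolate linearly between centroids (8 steps by default, matching the
granularity at which shape morphing is usually displayed), decode each
step, and measure aspect ratios on the binarized decode; a step decoding
to an empty volume is flagged, not fatal.

## Scaled-down study conditions

The acceptance study generates 1,320 balanced habits (330 per class,
spread over the crystal systems that allow each class), trains on 1,200
with 120 held out, at 32³ voxels for 30 epochs — sized so the full study
runs in minutes on one CPU. On these conditions the trained model shows
two distinct latent dimensions with |r| ≈ 0.85–0.90 against S:M and M:L,
held-out reconstruction SSIM ≈ 0.8 against a mean-volume baseline of
≈ 0.26, and lath↔block / plate↔needle trajectory endpoints that decode to
their own classes. These are recovery properties of the method at this
scale, not reproductions of any particular full-scale figure.

## Numerical choices and degenerate inputs

- Halfspace systems that are unbounded raise; sliver solids below a
  10⁻¹² volume tolerance (or that break Qhull) raise a degenerate-habit
  error.
- Vertex deduplication and the brute-force vertex oracle match to 10⁻⁶.
- Ray–facet division guards against near-parallel facets (denominators
  below 10⁻¹² are treated as misses).
- Rank-2 clouds classify (S = 0 ⇒ s_m = 0) instead of raising.
- The Zingg boundary itself is assigned to the "≤" side; the threshold,
  binarization level (0.5), and SSIM window are all parameters.

## Known limitations

- The generator's habit family is convex prisms/parallelepipeds; habits
  with many facet families, curvature, or concavities are out of scope.
- SHSD assumes star-shapedness; it holds for convex input but the module
  does not detect non-star input fed to it directly.
- The DAE is not rotation-equivariant; inputs must be aligned, and the
  learned latent axes are only defined up to the training run (signs and
  assignment of aspect-ratio dimensions vary with the seed).
- UMAP determinism is guaranteed per-platform only (numba parallelism is
  disabled by the fixed random_state).
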