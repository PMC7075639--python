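# Methods

This note records the models, algorithms, parameter choices and known
limitations of `zlinekit`, in the order the pipeline runs.

## Conventions

All orientations are **nematic** (θ ≡ θ + π) and canonicalized to [0, π),
measured counter-clockwise from the +x (column) axis in a y-up mathematical
frame; raster row-down coordinates are converted wherever gradients or step
vectors are formed. Vertical image structures therefore have θ = π/2.
Invalid orientations carry NaN plus an explicit validity mask and are never
consumed downstream. Missing metrics are NaN, never 0 — a blank field must
not drag a coverslip average toward zero.

## Skeleton extraction

**Coherence-enhancing diffusion.** ∂u/∂t = div(D ∇u), with D built each
step from the ρ-smoothed structure tensor of the σ-smoothed image:
diffusivity α across the locally coherent direction and
α + (1 − α)·exp(−C/κ) along it, where κ = (μ₁ − μ₂)² is the squared
eigenvalue gap. The explicit scheme on a unit grid is stable for
dt ≤ 1/(2·ndim) = 0.25; the bound is enforced, default dt = 0.2. The image
is normalized to unit maximum internally so the contrast constant C is
independent of bit depth. Defaults (time 5, σ 1 px, ρ 4 px, C 10⁻⁶,
α 10⁻³) were chosen for ~6 px/μm micrographs where z-lines are 2–3 px wide
and ~10 px long: ρ of the order of the ridge length measures coherence
along whole striations. All values ship as configuration and are the
intended target of the tuning module rather than constants.

**Top-hat, background, threshold.** White top-hat with a disk of radius
3 px (just above the ridge half-width) removes structures wider than the
striations. The residual background surface is a bivariate spline through
per-block 10th percentiles (32 px blocks); low percentiles track the
background under sparse bright foreground. Binarization is adaptive mean
thresholding (pixel > local mean + offset) with a 49 px window, roughly
four sarcomere spacings, so the window always mixes foreground and
background; the offset defaults to 0 because the background has already
been flattened.

**Thinning and trimming.** Topology-preserving thinning (Guo–Hall) to one
pixel width. Spur branches shorter than 4 px that terminate at a branch
point are deleted iteratively; free-standing lines are never shortened.
Connected components under 4 px are dropped. Both floors are configurable.
Closed loops are left intact: trimming removes only endpoint-terminated
branches, since the underlying anatomy (a ring of staining) is not ours to
erase.

**Orientation.** The least-mean-square gradient estimator: windowed
averages of the double-angle gradient products give the dominant gradient
direction φ = ½·atan2(2⟨gₓg_y⟩, ⟨gₓ²⟩ − ⟨g_y²⟩); the structure direction is
φ + π/2. The window defaults to 9 px (≈ one z-line length); larger windows
bleed orientation across neighboring structures and measurably bias
segmentation where off-target staining abuts z-line tracks. Validity floor:
windowed gradient energy above 1 % of the image maximum. The actin channel
is Gaussian-blurred (σ 2 px) and standardized to zero mean, unit variance
before estimation.

## Actin-guided segmentation

The director per non-overlapping 5 μm tile (30 px at 6 px/μm, anchored at
the image origin, partial edge tiles used as-is) is the maximum-eigenvalue
eigenvector of T = ⟨2 r rᵀ − I⟩ over the tile's valid actin unit vectors.
γ = |cos(θ_actin − θ_pixel)|; the absolute value removes the
pseudo-vector sign ambiguity, so operand order and θ → θ + π flips cannot
change the score. γ ≥ 0.7 (boundary inclusive) classifies a pixel
off-target. Pixels in tiles with no valid actin, in tiles whose tensor
cancels to numerical zero (balanced orthogonal orientations — no meaningful
director), or without a valid own orientation are *unassigned*: excluded
from both N_α and N_z, since counting them in N_α alone would bias the
fraction downward without evidence.

## Continuity grouping

Candidate neighbors: of the 8 neighbors, the two compass directions nearest
θ ± π/2 are excluded (midway ties round to the next counter-clockwise
direction). Remaining candidates split into half-planes along ±θ; per half
the occupied candidate maximizing |cos Δθ| is preferred, ties broken by the
straighter geometric continuation, then the lexicographically smaller
coordinate. Links are kept only when **mutual** (reciprocal best), which
caps the degree at two and guarantees simple paths with deterministic
output; branches at true 3-way junctions lose to the better-aligned
competitor and are logged implicitly as separate lines. Cycles — possible
only through orientation artifacts — are broken at the weakest link
(smallest |cos Δθ|) and logged. No angular floor is applied to linking
beyond candidate exclusion (`--link-min-cos` exists for exploration,
default 0).

Both the pixel count and the Euclidean path length of each line are
first-class: pixel counts for lattice-level validation, μm (Euclidean /
resolution) for biology. The median over lines of ≥ 2 pixels summarizes a
field; coverslip medians pool all lines across fields.

## Metrics

* OOP: maximum eigenvalue of T over an angle set; invariant under global
  rotation and nematic flips; pooled OOPs are recomputed from concatenated
  angle lists because eigenvalues do not average.
* σ̃ₓ = Σ cos²(θᵢ + π/2)/N_T with the major axis along x by convention;
  `major_axis_deg` rotates angles first for unaligned inputs. Bounds
  0 ≤ σ̃ₓ ≤ N_z/N_T with equality at all-perpendicular / all-parallel.
* Sarcomere spacing: per usable director tile, z-line pixels are projected
  onto the director; the pairwise-separation histogram (1 px bins) of the
  projections peaks at lattice multiples, and the first peak ≥ 3 px with
  prominence ≥ 0.3·max and height ≥ 3× the median bin is the tile's
  spacing. Tiles with < 8 pixels or no qualifying peak are skipped. The
  algorithm behind this named output was an open design choice; an
  autocorrelation of projections is equivalent to the pairwise histogram
  and the latter is simpler to make robust.
* Nuclei: Gaussian blur → Otsu → hole filling → watershed seeded at
  distance-transform maxima → components ≥ 20 px. Density is Σ counts /
  Σ areas over the coverslip, not a mean of per-field densities.

## Parameter tuning

Skeleton similarity is a tolerance-F1: pixels of the two skeletons are
paired one-to-one within Chebyshev distance 1 px by **maximum bipartite
matching** and S = 2m/(|a| + |b|). Exact matching was chosen over greedy
row-major pairing because greedy order-dependence can violate the required
symmetry S(a,b) = S(b,a); the exact matching is symmetric by construction
and S = 1 iff the skeletons coincide under the tolerance. The grid search
minimizes E_p = (1/n)Σᵢ(S_{i,p} − S_{i,max})², deterministic in grid
order; multiple hand traces per image are averaged at the S level.

## Synthetic data

**Segment fixtures** encode the continuity rule by construction: n vertical
segments of 7 px, consecutive lateral shifts of ≤ 1 px yield a single truth
line, ≥ 2 px separate lines; rotations rotate the whole polyline and keep
the truth grouping. Fixtures are generated, never stored.

**Tissue phantoms** emulate the targeted imaging regime: 6 px/μm, 2 μm
sarcomere spacing, 1.5 μm z-lines laterally registered across myofibril
tracks, actin fibrils as 3 px-spaced streamlines along a constant or
smoothly varying direction field, off-target α-actinin as segments parallel
to the fibrils. The requested off-target pixel fraction is realized by
greedily flipping whole tracks, then single segments, until the drawn
fraction matches (typically within 0.01). Both channels get a Gaussian PSF
(σ 1 px), Poisson shot noise (200 photons per unit intensity) and Gaussian
read noise (σ 0.01); truth masks stay unblurred. Phantoms are
bit-reproducible under their mandatory seed.

What phantoms do *not* emulate: non-myocyte actin layers (fibroblasts above
or below the monolayer), intensity inhomogeneity across a field,
anisotropic PSFs, variable sarcomere maturity within one cell, and
realistic off-target morphology (curved stress fibers, punctate
pre-myofibrils). Passing phantom tests therefore demonstrates the
correctness of the measurement chain under the stated image model, not
robustness to every pathology of real micrographs.

Test problem sizes — 192×256 phantoms, ≤ 64×64 oracle grids — keep the full
suite around half a minute while every tile-level structure (director
grids, sarcomere lattices, multiple myofibril tracks) appears at full
scale.

## Numerical and degenerate-input choices

* Diffusion of a constant image is the identity; time 0 returns the input
  bit-for-bit.
* Degenerate (constant) images: background removal returns zeros with a
  warning; orientation fields are all-invalid; empty masks yield empty
  skeletons with warnings; empty angle sets yield NaN metrics.
* z-line fraction with N_α = 0 is NaN with a warning — never 0.
* Two empty skeletons compare as similarity 1 (with a warning), so a
  parameter set that correctly produces nothing on an empty reference is
  not penalized.

## Known limitations

* The thinned skeleton is not bit-exact under 90° image rotation: every
  stage through binarization and the orientation field is exactly
  equivariant, but directional thinning sub-iterations are not
  90°-symmetric; skeletons of rotated inputs agree at IoU ≈ 0.9.
* Continuity is measured, not lateral *registration*: registered z-lines
  separated by gaps are reported as separate lines.
* Segmentation assumes the actin in a tile belongs to the myocyte layer;
  mixed cell layers corrupt the director.
* Single-frame analysis only; video manifests are processed frame by frame
  with no temporal linking.
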