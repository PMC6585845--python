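# Methods

## Problem and scope

`paveshape` quantifies the shape of leaf epidermal pavement cells from traced
outlines, aggregates per-species statistics across leaf sides and clades, and
tests whether shape traits carry phylogenetic signal. The pipeline mirrors a
broad comparative survey design: per species, ~30 cell outlines per leaf side
(adaxial/abaxial), one leaf outline, a clade assignment, and a rooted
phylogeny with branch lengths over the sampled species. Segmentation of raw
micrographs is out of scope: inputs are binary masks or outline CSVs.

## Outlines and geometric kernels

An outline is an ordered, implicitly closed, simple polygon in micrometres.
On construction it is canonicalized: consecutive duplicate vertices dropped,
orientation corrected to counter-clockwise, self-intersection rejected via a
polygon-validity scan. Area is the shoelace sum; the convex hull comes from
the vertex set, so hull vertices are a subset of outline vertices.

Mask ingestion traces the pixel-edge ("crack") contour: the polygon is the
union of the unit squares of a 4-connected foreground component, so a k×k
pixel square yields area exactly k², giving unbiased areas for small objects.
4-connectivity guarantees the exterior ring of each component is a simple
polygon; interior holes are ignored. Components touching the image border are
extracted but flagged, and the pipeline's extraction stage excludes them by
default. Components below `min_area` (default 50 px²) are dropped as
segmentation speckle. Masks must contain exactly two pixel values (foreground
is the greater unless inverted); a uniform image is treated as all-background.

Resampling places n vertices at equal arc-length spacing along the boundary,
starting at the original first vertex; all measurement is performed on
300-point resampled outlines so that hand-tracing vertex density is not a
nuisance variable.

### Principal-axis extents

Length and width are the coordinate extents of the outline after rotating its
principal axis onto x. The principal axis is taken from the second *area*
moments of the filled polygon (the covariance of the uniform measure over the
interior), not from the covariance of boundary vertices. Boundary-vertex
covariance is biased on pixel-edge contours: a staircase running at 45° is
√2 longer per unit of true boundary than an axis-aligned run, so equal
arc-length resampling concentrates vertices direction-dependently and can
shift the inferred axis enough to move the aspect ratio by ~0.03 on rasters.
Area moments are insensitive to this and give identical answers on smooth
outlines (a 2×1 rectangle has aspect ratio exactly 0.5 in either convention).
A maximum-Feret-chord axis is available behind `method="feret"`. When the two
eigenvalues tie within 1e-9 relative (isotropic shapes), the angle is fixed
at 0 and the result flagged.

## Shape descriptors

For one outline with area A, perimeter P, hull area A_h, aligned extents
L ≥ W:

- solidity S = A / A_h ∈ (0, 1]; 1 for convex shapes, decreasing with margin
  undulation (and, unavoidably, with whole-cell curvature — banana-shaped
  cells with smooth margins also score low; no correction is applied);
- aspect ratio AR = W / L ∈ (0, 1]; 1 isotropic, → 0 elongate;
- circularity C = P² / (4πA) ≥ 1; 1 only for a circle, inflated by both
  undulation and elongation (it is deliberately redundant with S and AR);
- area in μm² for cells, mm² for leaves.

Quartile classes for a batch of values use type-7 (linear interpolation)
quantiles at 0.25/0.5/0.75; intervals are right-closed so boundary ties fall
in the lower class; an all-equal batch degenerates to class 1 with a warning.

Dataset medians and ranges are computed over species means by default (one
row per species), with an all-cells variant behind `over="cells"`.

## Elliptic Fourier analysis

The forward transform uses the closed-form coefficient sums over the
polyline, parameterized by cumulative chord length (equal to arc length after
resampling). Normalization follows the first-harmonic ellipse: a start-point
rotation θ from the standard arctangent formula (taking the candidate with
the larger first-harmonic magnitude, i.e. the semi-major axis), a spatial
rotation ψ putting that axis on +x, and division by the first-harmonic
magnitude, leaving a₁ = 1, b₁ = c₁ = 0. The residual half-period ambiguity in
θ is resolved by choosing the coefficient-wise larger of the two canonical
forms, so equal shapes yield coefficient sets equal to ~1e-15 regardless of
input rotation, scale, or starting vertex. Reflection is deliberately not
quotiented away. The pipeline default is 20 harmonics; `select_harmonics`
returns the smallest count whose cumulative power fraction exceeds a
threshold (0.999 default).

Two numerical facts worth knowing:

- Under chord-length parameterization an eccentric ellipse is *not* exactly
  one harmonic: a 2:1 ellipse keeps ~0.57% of its power in odd harmonics ≥ 3
  (the non-uniform angular speed appears as phase modulation). The ≥99.9%
  single-harmonic collapse holds for circles and mild ellipses (AR ≳ 0.85).
- A radial lobe modulation sin(kθ) appears in the Cartesian coordinates as
  sidebands at harmonics k−1 and k+1, not at k (angle-sum identities), with
  the k−1 band dominant.

Reconstruction error is the mean distance from reconstructed vertices to the
source boundary polyline, relative to the source's mean centroid radius; it
is non-increasing in the harmonic count. Power totals are preserved under
re-transformation of a reconstruction only when the re-forward uses the
reconstruction's own uniform parameter (`parameterization="index"`); the
chord-length re-parameterization shifts ~0.5% of power between harmonics.

EFA is retained as a comparison utility rather than the primary morphospace:
across a panel in which margin undulation and aspect ratio vary
independently, distances between normalized coefficient vectors track AR
differences far better than solidity differences (this limitation is pinned
by a regression test).

## Dataset statistics

PCA operates on the four-descriptor table (AR, A, C, S) over all cells,
centered and by default standardized to unit variance, since area (μm²) and
the dimensionless ratios are incommensurate; an unstandardized variant is one
flag away. Components are an SVD eigendecomposition with the sign convention
that each component's largest-magnitude loading is positive.

Spearman's rho is the Pearson correlation of average-rank vectors; the
two-sided p-value uses t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of freedom. The
small-sample Edgeworth-series refinement is not implemented; for the n ≥ 30
species-level correlations this pipeline targets, the two differ negligibly,
and the t form is exact enough for the worked examples (ρ = 0.8, p ≈ 0.104
at n = 5).

Species aggregation caps each species-side at 30 cells via a seeded
subsample (default seed 20181003) whose random stream is derived from the
species and side names, so results are independent of input row order.
The adaxial-minus-abaxial solidity difference is reported per species
(positive = abaxial more undulate) together with the count and fraction of
positive species. Leaf-AR versus cell-AR correlations use the side-pooled
species mean cell AR and can be restricted to clade subsets.

## Phylogenetic signal

Proximity weights are inverse patristic distances, row-normalized (each
row sums to 1); other weightings exist in the literature, so the method tag
is carried in the output and results are comparable only within-method.
With centred traits z and m₂ = Σz²/n, local Moran's I is
I_i = (z_i/m₂)·Σ_j w_ij z_j; under row normalization Σ I_i = n·I_global
(asserted internally). Significance uses conditional permutation: tip i's
value is held fixed, the remaining n−1 values are shuffled (999 draws by
default), and p = (1 + #{I_perm ≥ I_obs}) / (1 + n_perm), never exactly
zero. The default test is one-sided for positive autocorrelation
("hotspots", p < α = 0.05 and I_i > 0); a two-sided variant and an exact
(n−1)!-enumeration mode for small trees are available. Raw p-values are
reported alongside Benjamini–Hochberg-adjusted ones, and hotspot counts
under both, since no single correction convention is canonical for this
test. Global Moran's I uses the cross-product form with null expectation
−1/(n−1).

Brownian-motion simulation (independent N(0, σ²·branch length) increments
accumulated root-to-tip) provides the positive control: on unit-height Yule
trees, Brownian traits yield a hotspot fraction exceeding the iid type-I
rate by a wide margin (~0.3–0.5 at n = 60), while iid traits stay at the
nominal ~5%.

## Synthetic data generator

Cells are radially lobed ellipses r(θ) = 1 + amp·sin(kθ + φ) scaled by
semi-axes (a, b): star-shaped by construction, hence always simple, while
spanning solidity down to ~0.58 within the amp ≤ 0.4 ceiling. This emulates
the undulation continuum of real pavement cells but not true jigsaw
interdigitation, tessellation constraints between neighbours, or imaging
artefacts — so passing recovery tests demonstrates the *pipeline's*
correctness, not robustness to real segmentation noise.

Species-level target solidity and AR are Beta draws per clade
(parameterized by mean and concentration κ). The lobe amplitude realizing a
solidity target is obtained by inverting a numerically precomputed
amp→solidity curve per (k, AR) stratum (21 amp knots, cached); the curve is
non-increasing everywhere and strictly decreasing once the outline becomes
concave. Lobe count k is drawn uniformly among counts 4–10 whose calibration
range reaches the target; targets below the 0.60 floor attainable at amp 0.4
are clamped there (rare tail draws, logged), while direct calibration calls
outside the range raise.

The shipped default survey is 3 clades × 30 species × 2 sides × 30 cells:
ferns (S mean 0.68, AR 0.60), monocots (S 0.88, AR 0.35), eudicots (S 0.78,
AR 0.65), κ = 80–120; within-species noise is amp sd 0.02, AR sd 0.04, and
1% radial vertex jitter; cell mean radius is log-normal around 30 μm. These
values are synthetic choices reproducing the qualitative clade ordering seen
across vascular plants (ferns most undulate, monocots least undulate and
most elongate), not estimates from any particular dataset. Abaxial cells
receive a +0.06 lobe-amplitude offset, making abaxial solidity lower.
Leaves are superellipses (exponent 2.5, length 30–150 mm); in ferns and
monocots leaf AR follows the species' cell AR through a monotone link plus
noise (coupled), in eudicots it is independent.

Trees are unit-height Yule trees (pure birth, terminal branches extended by
the waiting time to the next unrealized event so no zero-length cherries
occur). A clade-mapped variant plants one Yule subtree per clade on a common
root (stem fraction 0.3) so clade-structured traits are phylogenetically
clustered.

Rasterization fills the polygon on a uint8 grid where pixel (r, c) covers
[c, c+1)×[r, r+1); an axis-aligned k×k square maps to exactly k×k foreground
pixels, closing the loop with the crack-contour tracer.

## Problem sizes and reproducibility

Default analysis sizes: 300-point resampling, 20 harmonics, 999 Moran
permutations. Validation sizes: raster round trips at ≥ 200 px cell
diameter (solidity recovered within 0.005, AR within 0.002); full-survey
recovery at 90 species (clade means within 0.03 with ordering preserved;
abaxial offset detected in > 80% of species); Moran calibration with 500
null draws for the global mean, 200 seeds × 199 permutations for the local
type-I rate, and 100 seeds for the Brownian-vs-iid power ordering. All
randomness flows from explicit seeds; the CLI derives named substreams from
one config seed, and repeated runs are byte-identical.

## Known limitations

- Solidity conflates margin undulation with whole-cell curvature; no
  correction is attempted.
- The t-based Spearman p-value is approximate below n ≈ 10.
- The generator's radial lobes cannot produce re-entrant (interdigitated)
  margins; solidity below ~0.55 is out of its reach even at the amp ceiling.
- Crack contours inflate perimeter-dependent quantities (circularity) on
  rasters by construction (staircase length); solidity, AR and area are
  unaffected. No sub-pixel smoothing is applied.
- Hole-bearing cells (e.g. around stomata in a mask) are filled, not
  annular.
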