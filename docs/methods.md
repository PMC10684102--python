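# Methods

## The analysis chain

The pipeline operates on per-vertex maps of the six isocortical layer
thicknesses over a triangulated cortical sheet and proceeds in a fixed
order: exclude agranular/dysgranular parcels (no clear 6-layer
structure), smooth each *absolute* layer-thickness map with a uniform
moving disk on the inflated surface, normalize by total thickness to
relative profiles, aggregate to parcels by the median, build the
covariance matrix, and embed its principal axes. Smoothing precedes
normalization deliberately — the disk average is a statement about
measured thickness, not about composition — and the driver rejects a
configuration requesting the swapped order.

**Covariance.** The laminar thickness covariance between two parcels is
the first-order partial correlation of their 6-layer relative profiles
controlling for the cortex-average profile, Fisher z-transformed.
Controlling for the average isolates *greater-than-average* covariance:
two parcels are similar only to the extent that their deviations from
the average laminar composition align. The covariate is the unweighted
mean profile over included parcels, computed after parcellation (the
alternative — a vertex-level average — differs only by parcel-size
weighting; the parcel-level choice keeps the covariate on the same scale
as the profiles it controls). Fisher z is applied element-wise, so its
order relative to any edge exclusion is immaterial. The matrix diagonal
is undefined (arctanh(1) diverges); every consumer works on the
lower-triangle off-diagonal entries. Plain Pearson (+ Fisher z) and
negated Euclidean distance are available as robustness metrics — the
negation keeps "larger = more similar" true for every kind. The same
machinery builds MPC from 50-point depth-intensity profiles and LIC from
per-layer mean intensities (10 interior interpolation points per layer,
averaged). LTC and LIC can be fused by ranking each matrix's defined
entries, min–max rescaling the second onto the first's rank range, and
concatenating horizontally.

**Gradients.** Each row of the covariance matrix keeps only its top
(1 − p) fraction of entries (p = 0.9 by default; ties broken toward the
lower column index so results are reproducible), rows are compared with
the normalized-angle kernel `1 − arccos(cosine)/π`, and PCA of the
column-centered affinity yields the gradients. Cosines within 1e−12 of
±1 are snapped to ±1 before arccos — the inverse cosine loses half its
significant digits at the poles, and exactly parallel rows must map to
affinity exactly 1. Explained variance is reported on the centered
affinity. Diffusion maps (α = 0.5 anisotropic normalization) and
Laplacian eigenmaps are selectable alternatives; component signs are
arbitrary, so a reference map may be supplied and each component is
flipped to correlate positively with it. The discrete alternative is
k-means over profiles for k = 2…10 with the elbow chosen by the
maximum-distance-to-chord rule on the min–max–normalized distortion
curve (distortion = mean within-cluster squared distance), which is
parameter-free.

**Hierarchy and connectivity models.** Asymmetry-based hierarchy is the
weighted unsigned out-degree minus in-degree of a directed connectivity
matrix (diagonal excluded); the scores sum to zero by construction.
Edge-level models run over the lower triangle with undefined edges
dropped: exponential distance fits `y = a·e^(−d/λ) + c` by nonlinear
least squares (initialized at a = range(y), λ = median(d), c = min(y),
with jittered restarts; R² = 1 − SS_res/SS_tot on the original scale),
logistic models of binarized structural connectivity by maximum
likelihood with internally standardized predictors (McFadden pseudo-R²
by default, Cox–Snell selectable; single-predictor models are the
default presentation, a joint fit is a call away since predictors are
just columns). Windowed probability curves sort edges by a predictor
into near-equal windows (sizes differ by ≤ 1). "Long-range" edges
default to the upper geodesic-distance tercile — the cutoff is
explicitly configurable because no principled constant exists.

**Surface operators.** Disk smoothing takes the unweighted mean of valid
vertices within a Euclidean radius (default 10 mm) of each vertex in
*inflated* coordinates; invalid vertices join no disk and stay invalid.
Mean curvature uses the cotangent Laplace–Beltrami operator with
mixed-Voronoi vertex areas (barycentric areas leave ~15% error at the
twelve valence-5 vertices of an icosphere; the mixed rule is exact to
< 0.1% at subdivision 4). Sign convention: positive = convex outward
(gyral). Parcel centroids are exact Euclidean medoids (ties to the
lowest vertex index). Geodesic parcel distances are graph shortest paths
with chord-length weights over a neighbourhood graph; the default
includes up to 3-ring connections because the pure edge graph of a
triangulation overestimates geodesics by up to 2/√3 − 1 ≈ 15% in the
worst direction, while the 3-ring graph measures within 1.9% of analytic
great-circle distances on a subdivision-5 sphere. Exact polyhedral
geodesics are deliberately out of scope.

## Null models

Correlations between spatially autocorrelated maps need nulls that
preserve that autocorrelation. Two are provided.

*Spin permutations* draw uniform random rotations (QR of a Gaussian
matrix, determinant forced +1), rotate the parcel-centroid cloud on the
sphere, and map each parcel to its nearest rotated centroid. The default
mapping allows repeats (surjective), matching standard parcel-spin
practice; a bijective optimal-assignment variant is available. Applied
to matrices, a spin permutes rows and columns jointly, preserving
symmetry.

*Variogram surrogates* permute the map, smooth the permutation with
exponentially-weighted k-nearest-neighbour averaging for each candidate
neighbourhood size (10%…90% of parcels), regress the empirical variogram
on each candidate's (γ_emp ≈ α·γ + β over 25 distance bins up to the
40th percentile of pairwise distances), keep the best k, and return
√|α|·smoothed + √|β|·white noise. The marginal distribution is not
resampled by default (a rank-remap flag pins it to the original
values). The distance cap was fixed by requiring the surrogate
correlation test to reject independent smooth null maps at close to the
nominal 5% — capping much shorter leaves the test mildly conservative
(~3.5%), much longer drifts liberal — and is configurable.

All tests use p = (1 + #{null ≥ observed}) / (n_perm + 1) (two-sided on
|r| for correlations, one-sided for F and within-type differences), so p
is never zero and is exact under exchangeability. Null procedures are
seed-deterministic.

## The synthetic cortex

The generator's job is to produce inputs with exactly the statistical
structure the analyses assume, with every planted parameter recoverable.

*Geometry.* An icosphere (default subdivision 5, 10,242 vertices) of
radius 70 mm — the surface area (~62,000 mm²) is of one-hemisphere
order — with unit-sphere and inflated companions. Parcels (default 500)
are contiguous Voronoi patches from farthest-point seeding on mesh
geodesics.

*Laminar field.* A planted axis a(v) ∈ [0, 1] is the rescaled projection
of each vertex on a fixed direction. Each layer's relative thickness
follows a logistic transition along a with its own amplitude and
midpoint (layers II–IV rise monotonically, V–VI fall, layer I near
flat), with the across-layer mean subtracted at every a so the fractions
stay on the simplex. The staggered midpoints matter: if all layers
trended *linearly*, every profile would lie on one affine line in layer
space, the partial correlation against the mean profile would collapse
to a ±1 two-block sign pattern, and no embedding could recover the
ordering (zero-noise recovery saturates near ρ ≈ 0.8). Real laminar
profiles trace a curved trajectory — different layers transition at
different cortical loci — and the staggered construction reproduces
that, making the axis recoverable (ρ ≈ 1 at zero noise, ~0.90–0.94 at
default noise).

*Curvature.* A fixed-seed band-limited spherical-harmonic field (degrees
18 and 24; angular wavelength 18–24 mm on the 70 mm sphere),
standardized. Superficial relative thickness is decremented by
`coupling × curvature` with the mass credited to infragranular layers.
The default coupling 0.015 and fraction-space noise sd 0.02 were solved
analytically so that corr(curvature, superficial fraction) ≈ −0.3 on the
unsmoothed field — the magnitude reported for real folded cortex — and
the harmonic degrees sit below the 10 mm disk diameter scale so that
smoothing attenuates the coupling (to ≈ −0.05) while preserving the
axis. A degree ≤ 6 field would survive smoothing and the attenuation
phenomenon could not be emulated.

*Noise.* Spatially correlated noise is disk-smoothed white noise
(radius = the 10 mm spatial_smoothness default) rescaled to the stated
marginal sd, added in fraction space; total thickness is 2.5 mm with a
0.15 mm smooth variation; fractions are clipped at 0.01 before scaling,
keeping thicknesses positive.

*Intensity profiles.* Piecewise-constant in depth with one level per
layer (boundaries at cumulative relative thickness) sampled at 50
equispaced depth fractions; levels vary linearly along the axis with
layer IV strongest, emulating density variation in cell-body-stained
tissue. Equivolumetric depth surfaces are approximated by depth-fraction
sampling throughout — the synthetic profiles live in fraction space, and
real-data mode accepts externally computed profiles.

*Connectivity.* Directed weights are `0.5 + e^(−d/40 mm)` plus an
asymmetric term proportional to the planted hierarchy difference
(h ~ N(0, 1)) plus noise; the 0.5 floor keeps weights mostly positive so
the unsigned degree difference stays linear in the planted hierarchy.
Binary SC is Bernoulli in a logistic model with standardized LTC and
distance (β₀ = −1, β_LTC = 2, β_GD = −2); FC is `e^(−d/30 mm)` plus
0.3·z(LTC) plus N(0, 0.05²) noise, symmetrized. Cortical types are axis
sextiles with 5% label noise, placing a-/dysgranular labels at one pole
so exclusion removes a contiguous band.

All randomness flows from one integer seed through hashed
`SeedSequence` spawn keys, so any module can be rerun in isolation and
reproduce what the full pipeline would have produced; identical configs
give bit-identical outputs.

### What the generator does not emulate

Realistic gyrification and the folding-thickness mechanics behind it
(curvature is an analytic field, not folded geometry); vertex-level
atlas resolutions (~164k) and mesh decimation; inter-individual
variability; vascular and staining artifacts; the geometry of real
functional parcellation atlases. Passing tests therefore show that the *pipeline* recovers
planted structure of the assumed form at realistic noise; they do not
validate the biological assumptions themselves on real atlases.

## Study sizes and numerical choices

- End-to-end recovery runs use the default 500-parcel,
  subdivision-5 cortex; determinism and smoke checks use 80–100 parcels
  at subdivision 4.
- Null-model calibration uses 120 quasi-uniform (Fibonacci) centroids,
  200 repetitions × 500 permutations; spin permutations depend only on
  centroid geometry, so one set of 500 spins is shared across
  repetitions, while variogram surrogates are data-dependent and
  regenerated per repetition. With a true rejection rate near 5%, a
  200-repetition estimate has a binomial sd of ±1.5 percentage points.
- Surrogate fidelity (variogram SSE vs naive shuffles) is summarized by
  the median over 30 map realizations on a denser 300-centroid cloud
  with a 40 mm correlation length that the sampling clearly resolves:
  the per-map ratio is heavy-tailed, since a single smooth map can
  realize a variogram that a value-preserving shuffle already matches
  well, and the ratio is meaningful only for maps whose autocorrelation
  is substantial at the sampling scale.
- Elbow selection is evaluated over 40 seeds of 4 planted clusters at
  10× separation.
- Exponential fits bound λ > 0 and restart from jittered initial values;
  correlations snap at the ±1 poles where inverse transforms are
  ill-conditioned; p-values use the +1 convention; undefined matrix
  entries are NaN end to end and never silently zero.

## Known limitations

- Graph geodesics carry a small systematic positive bias (≤ ~2% at the
  default 3-ring graph) relative to exact surface geodesics.
- The partial-correlation covariance is intrinsically unstable for
  parcels whose profiles sit very close to the cortex-average profile
  (small residual norm); this is a property of the statistic, visible as
  mid-axis ordering noise in recovery runs.
- The variogram surrogate test is approximately, not exactly, calibrated;
  its rejection rate on smooth nulls is within about a percentage point
  of nominal under the defaults and drifts conservative for very
  sparsely sampled or extremely smooth maps.
- File-based (real-data) mode validates inputs and feeds the same stage
  functions, but no real-atlas end-to-end run is included — the paper's
  sources require external downloads.
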