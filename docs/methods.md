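# Methods

This note records the models, numerical conventions and design choices
behind morphokit, in the order the workflow runs them.

## Shape representations

Landmark configurations are `(k, m)` arrays, `m ∈ {2, 3}`; sets of
configurations are `(n, k, m)` with specimen ids. Closed outlines are
represented by elliptic Fourier coefficients, `(n, h, 4)` per-harmonic
quadruples `(a_j, b_j, c_j, d_j)` plus optional `(A0, C0)` center terms.
Both flatten to an `(n, p)` `ShapeMatrix` — the common currency of every
ordination — with `p = k·m` (landmark-major, coordinate-minor order:
`x1, y1[, z1], x2, …`) or `p = 4h` (harmonic-major: `a1, b1, c1, d1, a2,
…`). The flattening order is stored in the matrix so ordination loadings
un-flatten unambiguously; flatten/unflatten is an exact bijection.

## Generalized Procrustes analysis

Full Procrustes: each configuration is centered, scaled to unit centroid
size (`CS = sqrt(Σ‖x_i − x̄‖²)`), and rotated onto an iteratively updated
consensus. Rotations come from the SVD of the cross-product matrix with a
determinant correction that forbids reflections. The consensus is
initialised with the first specimen, re-centered and re-scaled to unit
size each iteration, and iterated until its change drops below 1e-10 (or
100 iterations). The summed squared distance of aligned shapes to the
consensus is non-increasing across iterations (tested). A configuration
with zero centroid size raises an error naming the specimen. No partial
Procrustes option and no semilandmark sliding: input curves/surfaces are
assumed to have been slid upstream.

## Thin-plate splines

Kernel `U(r) = r² log r²` with `U(0) = 0` in 2D and `U(r) = r` in 3D (the
convention matters only up to a scale of the weights; the 3D choice is
recorded here because published software differs). The map solves the
standard bordered system `[[K, P], [Pᵀ, 0]] [W; A] = [target; 0]`, giving
exact interpolation at the source landmarks and exact reproduction of
affine targets with zero non-affine weights. The bending energy is
`trace(Wᵀ K W)` with the sign flipped in 3D (where the kernel is
conditionally negative definite on the constraint subspace), so it is
non-negative and zero exactly when the target is an affine image of the
source. Targets may have any number of columns: `d = m` for shape warps,
`d = 1` for scalar fields (performance landscapes). Repeated or
collinear/coplanar source landmarks are rejected with the offending
indices.

## Elliptic Fourier analysis

Kuhl–Giardina coefficients under cumulative chord-length
parameterisation, computed as exact integrals of the piecewise-linear
outline; `(A0, C0)` is the exact arc-length centroid. Reconstruction is
`x(t) = A0 + Σ_j a_j cos(jt) + b_j sin(jt)` (and likewise `y`) on
`t ∈ [0, 2π]`. **No starting-point, rotation or size normalisation is
applied**: inputs are assumed pre-normalised upstream, which matches how
coefficient tables are usually exported; analyses mixing un-normalised
outlines will conflate orientation with shape. Reconstruction error on a
fixed smooth outline decreases monotonically with the harmonic count. For
reference, the h=20 round trip of a unit square has a maximum deviation
of 0.010124 from the input polyline — the L∞ truncation error of the
square's Fourier series, dominated by the corners; smooth biological
outlines converge much faster (a 2:1 ellipse recovers its semi-axes to
1e-3 at h=20).

## Linear shape models and detrending

`fit_shape_regression` is ordinary least squares of each shape variable on
a shared design matrix (QR-based); `fitted + residuals` reconstructs the
data exactly and residuals are orthogonal to the design. Detrending
returns `residuals + anchor` where the anchor is the grand mean shape by
default or the model prediction at a supplied design row (e.g. the shape
predicted at maximum size, the natural choice when tracking "static" adult
morphology in a growth-contaminated sample). Formulas like
`"~ log_size + locality"` build designs from covariate tables: numeric
columns enter as-is, categorical columns are dummy-coded against their
first level (in order of appearance) — the coding determines what design
rows mean for `expected_shapes`, hence it is fixed and documented.
Grouped detrending loops the same formula over groups and re-anchors each
group at **its own** mean (or its own displacement target); the
alternative of re-anchoring globally would re-introduce between-group
offsets into the residual variation.

Burnaby filtering projects the centered data with
`P = I − F(FᵀF)⁻¹Fᵀ` and adds the mean back; the projector is verified
idempotent and the output has exactly zero variance along every removed
direction. When nuisance covariates (rather than directions) are given to
the Burnaby ordination, `F` is the matrix of multivariate regression
coefficient directions of shapes on the centered covariates.

## Ordinations

All methods return the same structure (center, unit-norm loading columns,
scores, per-axis variances or singular values) and satisfy
`scores = (X − 1·centerᵀ)·V`, so projections of new shapes are a single
affine map. Axis signs follow a fixed convention — each loading column is
flipped so its largest-magnitude entry is positive — making repeated runs
bit-identical.

- **PCA**: SVD of the centered data; eigenvalues sum to the total
  variance.
- **bgPCA**: PCA of the `g × p` matrix of group means (unweighted: each
  group counts once; frequency weighting is an option), all `n`
  observations projected; at most `g − 1` axes. With `loocv=True` each
  observation's scores come from axes recomputed with that observation
  removed from its own group mean — the standard guard against the
  spurious separation bgPCA produces when `p ≫ n`. On isotropic noise
  with arbitrary labels, the between-group variance share of LOOCV scores
  sits inside its permutation null (tested against a 999-replicate null).
- **two-block PLS**: SVD of `XcᵀYc/(n−1)`; paired singular vectors with a
  joint sign convention, `min(p, p_y, n−1)` axes; a zero cross-covariance
  matrix degrades to a warning with zero singular values.
- **Burnaby ordination**: PCA of the data projected into the orthogonal
  complement of the nuisance directions; retained axes lie in that
  complement, so scores along the removed directions are exactly zero and
  the retained variance equals total variance minus variance along
  span(F).
- **pPCA** (covariance mode): GLS root `a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X`,
  evolutionary covariance `R = (X−1a)ᵀC⁻¹(X−1a)/(s−1)`, eigenvectors of
  `R`, tip scores `(X−1a)V`. Because `V` is a full orthonormal basis, the
  full-rank score space preserves the original inter-specimen geometry —
  distances and angles are rotated, not re-weighted — so disparity or
  separation statistics still require phylogenetic correction downstream.
  Internal-node scores are obtained by estimating ancestral shapes first
  and projecting them (see below), never by ordinating node estimates.
- **PACA**: with alignment matrix `A = C` (the BM tip covariance), axes
  are the eigenvectors of `Xcᵀ A Xc`; by the Rayleigh-quotient property
  axis 1 maximises the phylogenetically weighted score covariation among
  all unit shape directions (verified against 1000 random directions on
  simulated BM data). The loadings are an orthonormal rotation, so
  full-rank distances are preserved here too.

Axis-retention criteria (parallel analysis, likelihood tests) are out of
scope; all axes are returned and the caller truncates.

## Phylogenetic machinery

Trees are rooted dendropy trees with branch lengths on every non-root
edge. The BM tip covariance is `C[i,j] =` shared root-to-MRCA path
length; its diagonal holds root-to-tip depths. Ancestral states are
maximum-likelihood Brownian-motion estimates: with `C_nt` the
internal-node×tip matrix of shared path lengths,
`nodes = a + C_nt C⁻¹ (X − 1a)` per variable — the root row reduces to
the GLS estimate `a`. Only BM is supported; OU/EB and multi-rate models
are out of scope. Because both the ancestral estimator and the score
projection are affine, estimating shapes then projecting equals
projecting tip scores then estimating (tested) — phylomorphospaces are
therefore consistent no matter which order a user composes.

## Canvas and projections

A canvas is an ordination axis pair with an `r × c` grid of background
shape models, evenly spaced over the observed score range padded by 5%
per side (defaults `6 × 5`). Background shapes are
`center + s_i v_i + s_j v_j` with **all non-plotted axes held at zero**:
the models visualise the plotted plane's variation only (holding other
axes at data-conditional means would entangle planes). Rendering
dispatches on the shape kind — Fourier rows become silhouettes via
inverse EFA, landmark rows become points/wireframes, and an optional
template polyline is TPS-warped from the consensus to each model.

Group overlays are convex hulls (exact vertex set of the group's scores)
or data ellipses at the χ²₂ quantile of the requested level; a
`mean_ellipse` flag divides the score covariance by the group size,
giving a confidence region for the mean instead of the spread. Coverage
of the 0.95 data ellipse is verified by Monte Carlo (20,000 draws:
fraction inside ∈ [0.945, 0.955]).

Landscapes interpolate performance values over the plane with a 2D TPS
(exact at supports, reproduces planar fields exactly); inverse-distance
weighting is the fallback for near-singular support sets, and collinear
supports are rejected outright since they cannot pin down a surface.
"Empirical" landscapes use specimen scores as supports; "theoretical"
landscapes use `extract_shapes` grid positions whose performance was
measured externally. Pareto fronts are the non-dominated subset under a
per-metric max/min orientation; ranks come from iterative front peeling
and the normalised rank `1 − (rank−1)/max_rank` is the interpolable
optimality surface. The front construction is pinned by an O(q²)
domination oracle rather than by a closed form.

Phenograms plot node height (root-to-node path length) against an axis
score with straight parent-child segments; internal values default to BM
ancestral estimates. Hybrid views pair one axis with an external
variable (scatter for continuous, box/violin summaries per level for
categorical) and can carry margin shape models identical to
`extract_shapes` along that single axis. Projections never mutate the
canvas's ordination, so layer order is irrelevant to the data.

## Synthetic fixtures

The generators are pure functions of their spec (including the seed) and
define the conditions every end-to-end test runs under:

- **Outlines** (`OutlineFixtureSpec`): 137 specimens in four congeneric
  species, seven harmonics. Species means sit on a shared morphocline
  direction at positions −1, −1/3, +1/3, +1 times the separation 0.3,
  plus a 0.35-weight idiosyncratic direction each — between-species
  variation is quasi-1D, as in an anagenetic series. Allometry drifts
  coefficients by 0.08 per unit log-size along a fixed direction; iid
  coefficient noise sd 0.02; lognormal sizes with group-shifted means;
  ages uniform on 127–132. The injected truth is attached to the
  covariate table (`DataFrame.attrs`) so recovery tests compare
  estimates against it directly.
- **Landmarks** (`LandmarkFixtureSpec`): 7 species × 10 individuals × 4
  size-ordered measurements (280 shapes, 9 landmarks, 2D). The
  allometric coefficient 0.25 per unit log-size makes ontogeny the
  dominant within-individual signal — the defining feature of a growth
  series — against landmark noise sd 0.01, individual deviations sd
  0.02, and locality/age nuisance shifts (0.03/0.02). Configurations are
  randomly rotated, translated and size-scaled so Procrustes alignment
  is genuinely exercised (`jitter_pose=False` disables this for tests
  that need raw coordinates).
- **BM tips**: independent Brownian traits accumulated edge by edge;
  across replicates the tip covariance converges to `rate · C`
  (Monte-Carlo verified to <10% relative Frobenius error at 2000
  replicates).

What the fixtures deliberately do not model: real shell or tail
anatomies, semilandmark sliding noise, measurement covariance between
landmarks, asymmetry, and non-BM evolution. Passing tests therefore
demonstrate that the estimators recover structure **of the kind they
assume**, not that real data satisfy those assumptions.

## Statistical conventions in the tests

Effect-recovery checks compare estimates to the injected truth in OLS
standard-error units. Where a single coefficient matrix is checked, each
entry must lie within 3 SE. Where many hundreds of comparisons are
pooled (slopes and group means across species), the literal per-entry
3 SE rule fails by chance alone, so the suite asserts the calibrated
reading: the fraction of |z| > 3 stays at the binomial chance level
(≤ 2.5%) and no |z| exceeds 6.

## Problem sizes

The test suite and the acceptance script run at the fixtures' native
sizes (137 outlines, 280 landmark shapes, 5–13-tip trees), with 999
permutation replicates, 1000 random-direction oracles, 2000 Brownian
replicates and 20,000 Monte-Carlo draws; the whole suite completes in
well under a minute on one CPU.

## Known limitations

- EFA offers no starting-point/rotation normalisation; un-normalised
  coefficient sets will mix orientation into shape variation.
- GPA is full-Procrustes only (unit centroid size); no partial
  Procrustes, no symmetric/asymmetric or uniform/non-uniform
  decomposition.
- 3D shapes are warped as point/curve templates; mesh (OBJ/PLY)
  deformation is out of scope, and canvas rendering of 3D models draws
  their xy-projection.
- Ancestral estimation and phylogenetic ordinations assume Brownian
  motion with a single rate.
- LOOCV bgPCA recomputes axes per observation; it is O(n) SVDs of the
  group-mean matrix, fine for thousands of observations but not for
  millions.
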