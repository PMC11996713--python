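# Methods

This note records the model, the numerical choices, and what the synthetic
validation does and does not establish.

## The alignment model

A specimen surface is a triangulated point set; only translation, uniform
scale and rotation are treated as non-shape. Superimposition of one
surface onto another minimizes the **symmetric** 1/(2m)-weighted squared
nearest-neighbor cost — exactly the squared Procrustes Surface Metric
(PSM) — over similarity transforms, by alternating nearest-neighbor
pairing (both directions, k-d tree, exact-tie break to the lowest index)
with a closed-form weighted least-squares similarity fit (SVD/Umeyama).
Making the ICP objective identical to the reported metric is a deliberate
choice: "symmetric ICP" alone does not pin down a cost, and any other
choice would mean optimizing one functional while reporting another.

The recorded per-iteration cost is non-increasing by construction:
re-pairing can only shorten nearest-neighbor distances at a fixed
transform, and the refit minimizes the cost at a fixed pairing.

**Initialization.** ICP converges only locally. Surfaces are first
translated to a common centroid and matched in centroid size, and a
pre-rotation aligning the principal axes of the two clouds is considered
alongside the identity: the four proper sign assignments of the axes plus
the identity are scored by initial symmetric cost and the best kept.
Keeping the identity in the candidate set matters for near-spherical
shapes, whose principal axes are noise-driven and would otherwise scramble
an already-reasonable pose. With this initializer, recovery of applied
transforms is exact (rotation error ≪ 0.1°) for rotations at least up to
30°, versus roughly 15° with centroid-only initialization. Note that
shapes with discrete symmetries (e.g. an exact tri-axial ellipsoid sampled
symmetrically) admit flipped alignments that are genuinely
indistinguishable by any shape metric; recovery is then defined only up to
that symmetry group.

**Scale** is re-estimated every iteration (a flag disables it). Defaults:
at most 100 iterations, stop at relative cost change below 1e-7.

## The generalized (multi-surface) loop

The prototype is either supplied (e.g. a baseline-round mean reused across
rounds) or selected as the cohort medoid under pairwise post-alignment
PSM. Each outer iteration registers every specimen to the current
prototype, then moves each prototype point to the arithmetic mean of the
specimen vertices whose nearest prototype point it is (inbound pairings);
points attracting no vertex fall back to the mean of their own nearest
neighbors per specimen. Points closer than `duplicate_merge_radius`
(default 0.25 × mean edge length) are merged to the centroid of their
within-radius connected component, ascending-index deterministic; faces
are reindexed and collapsed faces dropped. The loop stops when the RMS
prototype displacement falls below the ICP tolerance × prototype diameter
(default cap: 10 outer iterations).

The PSM is computed in RMS form (with the square root); the squared form
is exposed separately. In the special case of equal counts and identity
mutual pairing, D = P/√m with P the ordinary Procrustes distance — an
identity verified by test. PSM is symmetric and non-negative but not
proven to satisfy the triangle inequality; it is treated as a
dissimilarity throughout, which is also why ordination reports negative
eigenvalue mass rather than assuming Euclidean input.

## Variance fields and heatmaps

For each prototype point, the paired set holds the point's nearest
neighbor on every superimposed specimen (one per specimen). The field
value is the trace of the 3×3 sample covariance (n−1 denominator) of that
set — total variance, invariant to rigid motion of the whole superimposed
cohort — with a largest-eigenvalue option for dominant-direction
variation. Colors interpolate a 5-stop blue→cyan→green→yellow→red
palette after min–max normalization (a percentile(2, 98) mode guards
against single-vertex outliers); a constant field maps entirely to blue.
Hot-spots are connected components (mesh-edge connectivity) of the top
fraction of vertices by value, ranked by peak value.

With this pairing rule every prototype point receives exactly one partner
per specimen, so no point is ever under-sampled; the trade-off is that a
prototype point in a region a specimen fails to cover borrows its nearest
available vertex, inflating local variance — visible when specimens have
strongly differing vertex sets (see limitations).

## Ordination

Classical Gower PCoA: double-center the squared distances, eigendecompose,
scale eigenvectors by the square roots of positive eigenvalues. Variance
proportions use positive eigenvalues only; negative eigenvalue mass is
reported, never embedded. Axis signs are fixed by making the
largest-magnitude loading positive, so output is reproducible
run-to-run. Shape modes are per-point, per-coordinate ordinary least
squares of homologized vertex coordinates on the retained axis scores
jointly (with intercept); a single-axis mode is available through
`n_axes=1`. The intended use — ordination of subset *mean* surfaces —
is the default workflow; all-specimen ordination is supported but
individual variation then dilutes group contrasts.

## The synthetic generator as study design

Real inputs would be dense (≈170k-triangle) cortical surfaces from
segmented MRI; none are distributable, so cohorts are generated:

* **Base shapes** — icosphere-subdivision spheres and ellipsoids
  (near-uniform vertex density, as decimated scan meshes are), plus a
  `perturbed_ellipsoid` whose fixed low-order harmonic
  (2xy + 0.7yz + z² − 1/3 radial modulation, amplitude 0.08) breaks all
  flip symmetries — the default "brain-like" shape, since brains are
  globally asymmetric.
* **Similarity transforms** per specimen: rotations up to 20°,
  translations up to 10% of size, scale 0.9–1.1 by default — typical
  head-pose and brain-size variation between scan sessions.
* **Bumps** — radial deformations with Gaussian angular falloff
  (amplitude · exp(−(θ/ρ)²)); a scalar amplitude displaces every selected
  specimen identically (useful for exact-displacement checks), while a
  per-specimen distribution (e.g. normal with sd A) produces *variance*
  at the bump, which is what a heatmap can detect. Selectors restrict
  bumps to label strata (e.g. only the trained group), emulating a
  training-induced regional effect.
* **Noise** — isotropic Gaussian vertex jitter, default sd 0.5% of the
  shape diameter, a generous bound on surface-extraction noise.
* **Vertex-count jitter** — each specimen loses a random 1–5% of
  vertices (surface re-triangulated through the convex hull of its
  direction set), so no stage can assume shared indexing. Default on.

All draws come from one seeded generator in a fixed per-specimen order, so
cohorts are bitwise reproducible and extending a cohort never shifts
earlier specimens.

Validation conditions used by the test suite and `scripts/acceptance.py`
(cohort sizes chosen to exercise each property at desk scale):

* *Metric oracle*: 50 random point-set pairs (n ≤ 300) against an
  exhaustive O(n²) brute force, plus hand-computed cases.
* *Recovery*: 20 random similarity transforms (rotation ≤ 30°, scale
  0.8–1.25) of a ~10k-vertex asymmetric surface, inverted to < 0.1°
  rotation and < 1e-3 scale error.
* *Null cohorts*: 10 specimens differing only by similarity transforms
  align to machine precision — PSM and variance ≪ 1e-6 × diameter — the
  analogue of an untrained group showing a flat heatmap.
* *Hot-spots*: single-bump cohorts (N = 10, amplitude sd = 5× absolute
  noise, fixed vertex counts) put the top-1% variance vertices inside the
  true support (1.5× angular radius), pooled over 5 seeds; doubling the
  amplitude multiplies peak variance by ≈4 (quadratic regime; the small
  noise floor keeps the measured ratio slightly below 4).
* *Calibration*: 200-specimen isotropic-jitter cohorts recover a mean
  trace of 3σ² within 10%.

Passing these shows the machinery is correct and calibrated on smooth,
noise-controlled, single-effect surfaces. It does **not** show that
gyrified cortical geometry, segmentation artifacts, partial coverage, or
multi-factor biological variation are handled — no synthetic cohort here
imitates those.

## Known limitations

* Nearest-neighbor homology is vertex-to-vertex; tangential sliding along
  the surface is invisible to it, and correspondence quality degrades when
  vertex density differs strongly between specimens. At the test meshes'
  coarse resolution (≈640 vertices), the 1–5% vertex-removal option
  produces correspondence-gap variance comparable to a 5×-noise bump,
  which is why the variance-localization conditions fix vertex counts;
  at realistic densities the same gaps are orders of magnitude smaller.
* PSM is not a metric in the mathematical sense; ordination of PSM
  matrices can produce negative eigenvalues (reported, not embedded).
* The variance field conflates amplitude and direction of variation;
  the largest-eigenvalue estimator partially separates them.
* Heavy mesh repair (self-intersections, holes, non-manifold edges) is
  out of scope; the validator only reports basic defects and inputs are
  expected clean.
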