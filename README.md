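# gpsa — landmark-free generalized Procrustes surface analysis

`gpsa` superimposes cohorts of closed triangulated 3D surfaces (e.g.
MRI-segmented cortical surfaces) **without landmarks**, estimates a mean
surface, quantifies shape differences, localizes regions of high shape
variation as heatmaps, and ordinates specimens or subset means in a few
shape axes. It is aimed at geometric morphometricians and neuroimaging
researchers working with structures — like the cerebral cortex — whose
morphology is too complex for reliable homologous landmarking.

## Method

Classical generalized Procrustes analysis removes translation, uniform
scale and rotation from landmark configurations. `gpsa` extends the same
paradigm to whole surfaces:

1. **Prototype selection.** The reference surface is either supplied (e.g.
   a previously computed mean) or chosen as the cohort *medoid* — the
   least morphometrically atypical specimen, minimizing summed shape
   distance to all others.
2. **Symmetric ICP superimposition.** Each specimen is registered to the
   prototype by iterative closest point: vertices are paired to nearest
   neighbors *in both directions*, and one similarity transform
   (translation + uniform scale + rotation) is fitted per iteration from
   the pooled bidirectional pairings by closed-form (SVD) least squares.
3. **Mean surface estimation.** Prototype points are moved to the average
   of the specimen points paired to them, near-duplicate points are
   merged, and the loop repeats until the prototype stabilizes.
4. **Shape distance.** Differences between superimposed surfaces A and B
   are summarized by the Procrustes Surface Metric

   ```
   D(A,B) = sqrt( 1/(2 m_A) Σᵢ ‖p_{A,i} − q_{B,i}‖²
                + 1/(2 m_B) Σⱼ ‖p_{B,j} − q_{A,j}‖² )
   ```

   where q is the nearest neighbor of p on the other surface and m the
   vertex count: a symmetric RMS-type distance in which both surfaces
   contribute equally regardless of vertex count. With equal counts and
   identity pairing it reduces to the Procrustes distance divided by √m.
5. **Variance heatmaps.** Each prototype point collects one paired point
   per specimen; the trace (or largest eigenvalue) of the 3×3 sample
   covariance of that set is painted blue (low) → red (high) on the mean
   surface, exposing "hot-spots" of localized shape variation.
6. **Ordination.** Pairwise PSM matrices (typically between subset mean
   surfaces) are embedded by classical principal coordinate analysis with
   per-axis variance proportions; homologized vertex coordinates can be
   regressed on axis scores to visualize each axis as a deformation field.

Because no public cohort accompanies the method, the package ships a
first-class synthetic generator: cohorts of smooth closed surfaces sharing
a base shape and differing by known similarity transforms, localized
Gaussian-falloff "bump" deformations, vertex jitter and per-specimen
vertex counts — so every claim above is testable against ground truth.

## Worked example

```python
import numpy as np
from gpsa import (DistanceMatrix, GPSAParams, hotspot_report, pcoa,
                  run_gpsa, variance_field)
from gpsa.synthetic import Bump, CohortSpec, generate_cohort

bump = Bump(center=(0, 0, 1), angular_radius_deg=25.0,
            amplitude=("normal", 0.0, 0.1))      # regional variation, sd 0.1
spec = CohortSpec(n_specimens=10, seed=42, base_shape="perturbed_ellipsoid",
                  noise_sigma=0.005, bumps=[bump], max_rotation_deg=15.0,
                  vertex_count_jitter=False)
meshes, truth = generate_cohort(spec)

result = run_gpsa(meshes, "auto", GPSAParams())
print("PSM to mean:", np.array2string(result.psm_to_mean, precision=4))
fld = variance_field(result)
clusters = hotspot_report(fld, result.prototype, 0.01)
print("hot-spots:", len(clusters))
res = pcoa(DistanceMatrix(result.names, result.pairwise_psm), n_axes=2)
print(f"PCoA: {100*res.proportions[0]:.0f}% / {100*res.proportions[1]:.0f}%")
```

prints

```
PSM to mean: [0.026  0.0373 0.0262 0.0273 0.0278 0.0263 0.0257 0.0291 0.0353 0.0256]
hot-spots: 1
PCoA: 29% / 10%
```

Each specimen sits ~0.03 length units (PSM) from the mean surface —
the residual left by the injected bump and noise after pose and size are
removed. The top-1% variance vertices form a single connected cluster at
the true bump location, and the first two ordination axes carry 29% and
10% of the shape variance among specimens.

The same pipeline is available from the shell:

```sh
gpsa synth --n 12 --seed 7 --out cohort/ --bump 0,0,1,25,0.1,group=practice
gpsa run --manifest cohort/manifest.tsv --subset group=practice --out out_MB/
gpsa pcoord --mean out_MB/mean_surface.ply --mean out_CTR/mean_surface.ply --out po/
gpsa heatmap --run-dir out_MB/ --colormap percentile
```

`out_MB/heatmap.ply` is a vertex-colored PLY that any standard mesh viewer
displays as the variance heatmap.

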