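# Methods

`canaliz` implements two automated procedures for locating dental root
canals and extracting their medial line: a slice-by-slice procedure for
high-resolution micro-CT records, and a volumetric procedure for
low-resolution cone-beam CT (CBCT). Since no clinical volumes ship with
the package, both procedures are developed and validated against synthetic
tooth phantoms with exactly known geometry. This note describes the models,
the parameters that matter, the numerical choices, and what the phantom
results do and do not establish.

## Coordinate and unit conventions

All geometry is expressed in voxel units, voxel-center, 0-based `(x, y, z)`
with `z` the stacking axis; grids are stored `[z, row(y), col(x)]`. Voxel
spacing in millimetres is carried alongside every exported volume so
lengths convert trivially. Micro-CT phantoms use a 16 µm isotropic spacing
tag; CBCT phantoms default to 0.2 mm isotropic (the clinically typical
range is 0.1–0.3 mm; requesting a spacing outside it is allowed with a
warning).

## The synthetic phantoms

A canal is a set of branches, each a natural cubic spline through control
points with a per-point radius profile, arc-length resampled at 0.25 voxel.
Child branches must start on their parent's curve; control polygons must be
simple. Four presets cover the shapes that matter clinically: `straight`
and `curved` single canals (rendered running through the whole recorded
stack, as a real micro-CT record cuts the canal at both ends), a
`y-bifurcation`, and a `molar3` with a wide pulp chamber and two staged
bifurcations yielding three apical branches. Randomized batteries jitter
the interior control points.

The micro-CT renderer draws, per slice, a dentin disk (gray ~160/255) with
an enamel rim (~205) and a thin lighter cementum band, the canal
cross-sections dark (~25) on a dark background (~12), then adds Gaussian
granular noise (default sd 5), a low-amplitude sinusoid in polar radius on
the hard tissues (the ring artifact; amplitude 3, period 6 voxels), and
optionally burned-in bright glyph blocks near the top-left corner to
exercise text removal. The CBCT renderer rasterizes the same tissue
geometry at 4× resolution, maps it to Hounsfield-like anchors (air −1000,
canal 0, dentin +1500, enamel +2500 — only the ordering matters
downstream), block-averages down (this *is* the partial-volume model: wall
voxels take intermediate HU, and a 0.4 mm canal at 0.2 mm spacing is two
voxels wide), and adds Gaussian noise (default sd 60 HU).

Ground truth — canal mask, tooth mask, per-slice cross-section centers and
the centerline graph — is computed from the geometry only, so changing the
noise level never changes the truth. Rendering is bit-reproducible from
`(spec, intensity model, seed)`.

What the phantoms do **not** emulate: beam hardening, scatter, detector
afterglow, anatomical texture inside dentin, metal artifacts, or oblique
tooth orientation. Passing the battery therefore shows the pipelines are
correct and stable under the artifact classes modeled (granular noise,
ring artifact, burned-in text, partial volume at clinical voxel sizes),
not that they would reach the same rates on arbitrary clinical data.

## Micro-CT procedure

1. **Preprocessing.** Median filter (disk radius 1); removal of burned-in
   text (high-contrast connected components confined to a corner margin,
   replaced by the border background level); trimming to the bounding box
   of content above background, with the ROI offset recorded so all later
   geometry returns to original coordinates. A slice with no content above
   background (absolute floor 5 gray levels) is skipped.
2. **Double partitioning.** The *local* partition clusters the slice's own
   gray-level histogram with a 4-class EnFCM — fuzzy c-means where each
   gray level is weighted by its count, which is exactly equivalent to
   per-pixel FCM but linear in the number of occupied levels. The binary
   threshold is placed at the midpoint of the widest gap between adjacent
   prototypes. The *global* partition thresholds at tau_global, the
   midpoint of a 2-class EnFCM run on histograms pooled from 2% of the
   slices taken at linearly spaced z positions (endpoints included).
   Fuzzifier m = 2, convergence 1e-4, deterministic initialization at
   weighted quantiles; prototypes are returned strictly ascending.
3. **Decision making.** A binary entropy-minimizing decision tree over the
   four threshold features (tau_global and the three inter-prototype
   half-gaps) picks local vs global per slice. Training grows greedy
   information-gain splits at midpoint candidates until every leaf is
   homogeneous; contradictory duplicate feature vectors are rejected.
   When no trained tree is supplied, a shipped heuristic keeps the
   partition whose interior dark fraction (dark pixels not connected to
   the ROI border) lies in a plausible band (0.1%–15%), preferring local.
4. **Spots.** Dark 8-connected components; components touching the ROI
   border are outer space and discarded. Centers by area centroid
   (flagged when it falls outside a concave spot) or by morphological
   thinning (residue point farthest from the boundary). Selection
   protocols: P1 keeps the largest spot only (incisor prior), P2k keeps
   up to k spots above a size threshold, P3 keeps all spots above an
   absolute area floor and an area ratio to the largest. A spot's
   `min_radius` is its center-to-boundary distance with the convention
   EDT(center) − 1, which yields r for a rasterized disk of radius r and
   0 for a single pixel.
5. **Regularization.** Hole filling, then opening and closing with a disk
   (radius 2), plus a merge closing that unifies spots closer than the
   merge distance; the loop runs to a fixed point so the operation is
   idempotent. Opening precedes closing deliberately: closing first welds
   pixels at the base of thin peninsulas which the opening then cannot
   remove.
6. **Consistency checking.** Spot centers of adjacent slices are linked by
   greedy nearest matching. A boundary is flagged when the largest link
   jump exceeds a threshold (default: 3× the record's median link
   distance, floor 5 px — deliberately conservative, advising more slices
   than strictly necessary) or when the spot count changes. A count
   change persisting ≥ 2 slices whose new spots keep correlating with the
   next neighbor is a bifurcation; everything else is advised for
   intervention. Overrides arrive as data: M1 overrules the local/global
   decision, M2 re-thresholds a slice at an explicit value, M3 discards a
   named spot; conflicting overrides on one slice are rejected so
   application order cannot matter. The interactive snake-based
   unification (M4) is out of scope.
7. **Assembly and ending correction.** Selected spots are stacked into a
   3D mask in original coordinates. Each open ending is virtually
   lengthened with copies of its peripheral plane — as many as the
   shortest radius of the peripheral spot (minimum 1) — because every
   skeletonization shortens open tube ends; the appended planes are
   cropped from all outputs.
8. **Potential-field skeleton.** Unit charges on boundary voxels; the
   interior force is the sum of `1/r^order` repulsions, evaluated exactly
   on demand and with a 15-voxel interaction cutoff inside the tracer
   (cutoff error < 1% on tubes, verified against exact summation). The
   skeleton is traced hierarchically: interior voxels form a graph whose
   medially weighted shortest paths (edge cost divided by the squared
   boundary distance) connect the two geodesically farthest tips; further
   tips are appended while their Euclidean geodesic reach exceeds
   `divergence ×` the local tube radius, which discards the short
   branches that grow toward surface bumps (the role of the divergence
   parameter; raising it can only remove branches). Every traced point is
   then re-centered at sub-voxel precision by annealed force descent in
   the plane normal to the local tangent; moves that would leave the
   object are rejected, which guarantees containment. The last few points
   of each free ending are replaced by a straight extrapolation of the
   adjacent centered segment, because the voxel path runs diagonally
   inside the rounded ending cap and biases the tangent projection there.
   Defaults: charge order 4 (at order 2 the long-range field of a curved
   tube displaces the equilibrium visibly off the medial axis; order 4
   localizes it, measured mean axis error < 0.1 voxel), step 0.5 voxel,
   divergence 2.5. A non-tubular object (a sphere's worth of mask)
   collapses to a single locus near its center. Disconnected masks yield
   one skeleton per component with a warning.

## CBCT procedure

1. **Context-sensitive filtering.** Each voxel becomes the weighted mean
   of its 3³ window with weights `delta·sigma`, where
   `delta = 1/(1 + κ_δ d)` decays with distance and
   `sigma = 1/(1 + κ_σ |log(v_i/v_j)|)` with the log-intensity ratio, so
   averaging happens along homogeneous tissue and edges survive. The
   filter's intensity trade-off defaults to 10 — deliberately stronger
   than the chain's — because a canal only 2–3 voxels wide otherwise
   bleeds toward dentin through its mostly-dentin window.
2. **Fuzzy-chain segmentation.** Voxel pairs are fuzzy-linked when
   `mu_Psi = delta·sigma ≥ alpha`; two voxels share a segment when an
   alpha-chain of linked face neighbors connects them, computed as
   connected components of the link graph. Raw HU can be non-positive, so
   intensities are shifted affinely to map the volume minimum to 1 before
   any log (order-preserving; the choice of anchor only rescales κ_σ).
   With face-neighbor chains every edge has unit length, so κ_δ acts as a
   constant and the intensity term does the discriminating; an optional
   long-range neighborhood (config-gated, off by default) admits hops up
   to a Euclidean radius, where low κ_δ lets physically disconnected
   same-intensity regions join and, conversely, a piecewise-constant
   high-κ_σ limit reproduces classical connectivity labeling. Defaults
   κ_δ = 0.25, κ_σ = 8, alpha = 0.5, set on the phantom battery: the
   binding constraints are that noisy within-canal links must survive
   (ratio ≈ 1.06 after filtering) while two-step partial-volume ramps
   from canal to dentin must break (each step ≈ 1.15).
3. **Tooth and canal selection.** The single interaction is a seed voxel
   on the tooth. The seeded region must be radiodense (≥ 800 HU, else
   "seed not on a tooth"); adjacent regions at or above that floor
   (dentin, enamel, cementum, dense partial-volume shells) are absorbed.
   Canal candidates are the sub-threshold regions enclosed by the tooth
   (iteratively: all outside face-neighbors in the tooth or in other
   candidates, never on the volume border). Voxels inside the tooth
   region darker than 500 HU are also reclaimed as canal: a chain that
   stepped across a partial-volume ramp can occasionally swallow the
   canal tunnel into the tooth region, and such voxels are canal by the
   definition used here (dark matter enclosed by the tooth). An optional
   `merge_regions` intervention absorbs nearby regions whose mean is
   within 15% of the seeded region's, for records whose dentin fragments.
4. **Surfaces.** Topologically consistent (Lewiner) marching cubes at the
   0.5 isosurface of each mask, padded by one voxel so surfaces close (a
   mask touching the border is capped there with a warning). Canal
   components are unioned and one-voxel gaps bridged by a closing before
   meshing.
5. **Mesh-contraction skeleton.** Constrained Laplacian contraction: per
   iteration, solve least-squares for positions balancing `W_L·L` (cotangent
   Laplacian pull) against `W_H·I` anchoring to the current positions,
   with `W_L` starting at `3·sqrt(mean face area)` and growing ×2.5 per
   iteration, and per-vertex `W_H = sqrt(A_i^0/A_i^t)` strengthening as
   the local one-ring area collapses. Iterations stop when the mean
   one-ring area falls below 1e-4 of its start (or stalls at a comparable
   level; 20-iteration hard cap); the mean one-ring area is non-increasing
   across accepted iterations. Because canals rarely exceed 10 voxels in
   width, convergence takes 6–8 iterations at these defaults. The
   collapsed near-1D cloud is reduced by shortest-edge-first cluster
   collapse in which two clusters merge only while their centroids stay
   within the collapse length (1 voxel) — bounding cluster extent, so a
   chain of short edges along the curve stays a chain — and the skeleton
   is read off the cluster graph by the same farthest-tip shortest-path
   strategy as the potential-field tracer, with offshoots under 8 voxels
   treated as contraction residue. All tie-breaks (edge order, tip
   selection) are by index, so the reduction is deterministic.

The potential-field method is not applied to CBCT: at 100–300 µm the canal
is too few voxels wide for a useful interior field. Conversely the
micro-CT path never needs meshes.

## Known limitations

* The molar geometry is the fragile case, exactly as clinical experience
  suggests: at CBCT resolution the two closely spaced junctions are
  occasionally merged into one, or a thin apical limb is lost, in roughly
  1 noise realization in 15. The apical-endpoint check therefore reports
  the median over five seeded phantoms.
* Skeleton accuracy close to a bifurcation is intrinsically limited by
  geometry: below the true branching point the two child tubes still
  overlap into one cross-section, so the extracted junction sits where the
  lumina actually separate, which can be many voxels apical of the
  centerline branching. Endpoint positions at apices sit at the end of the
  canal *cavity*, up to one local radius beyond the end of the geometric
  medial curve.
* Natural-spline interpolation slightly flattens curve ends (about a third
  of a voxel on a radius-10 arc through three control points).
* The fuzzy-chain defaults are calibrated for HU-like dynamic range; data
  on a different intensity scale needs κ_σ rescaled (the log-ratio term is
  scale-free but the shift anchor is not).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on phantoms sized so
the complete battery executes in a few minutes on one CPU: micro-CT stacks
of 90–200 slices at 56²–64² (the straight-cylinder accuracy check keeps
the full 200 × 64² record, radius 4), CBCT volumes of 64 × 48², and a
30-phantom mixed battery (presets cycled, two noise levels per modality,
jittered control points) for the end-to-end success rate. Oracle checks
(per-pixel FCM, exhaustive split search, brute-force field summation,
transitive-closure labeling) use the small sizes where the oracle itself
is exact and fast.
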