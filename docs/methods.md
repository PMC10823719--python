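# Methods

`mandisym` implements a landmark-based screening procedure for the
mandibular midsagittal plane (MMSP), together with the algorithmic
original–mirror reference plane it is judged against. This note records
the model, the numerical choices, and what the synthetic test substrate
does and does not establish.

## The screening model

A mandible is represented by a closed, outward-oriented triangle surface
mesh in mm, plus named anatomical landmarks. Seven *midline points* are
derived: the five central landmarks B, Pog, Gn, Me, G and the midpoints of
the bilateral mandibular-foramen (F) and mental-foramen (MF) pairs. Every
unordered triplet of midline points spans one candidate plane —
C(7,3) = 35 candidates, labelled by their landmark names (e.g. `B-Gn-F`).

Each candidate plane Π is scored by the **asymmetry index**

    AI(Π) = sqrt( mean_i  d(R_Π(x_i), S)^2 )

where S is the surface, x_i are n area-weighted uniform surface samples
("quasi-landmarks", default n = 17,415), R_Π is the reflection across Π,
and d(·, S) is the exact Euclidean distance to the surface. AI is the RMS
of the pointwise original-to-mirror deviations in mm; the mean absolute
deviation is reported as a secondary column. Deliberately, **no rigid
re-alignment follows the mirroring**: a free alignment after reflection
would make every candidate plane equivalent up to the shape's intrinsic
asymmetry, erasing exactly the between-plane differences the screening
ranks. The reflection across the *candidate plane itself* is the map being
evaluated.

Candidates are ranked by AI (ascending; near-collinear triplets are
flagged degenerate via the dimensionless condition number
area/longest-edge², kept in the report with no AI, and ranked last). The
`top_k` (default 4) lowest-AI planes are adjudicated against a reference
plane by three clinical-style indices:

* **landmark distance difference** — per bilateral pair, ||d_L| − |d_R||
  of the unsigned perpendicular distances to the plane (a pair whose
  midpoint lies on the plane scores exactly 0, which is why every plane
  built through the F̄ midpoint has a zero F row);
* **side-volume difference** — |V_A − V_B| of the two capped halves, with
  V_A + V_B equal to the total enclosed volume to ≤ 1e−6 relative;
* **similarity index** — SI = 2·V(A ∩ B′)/(V(A) + V(B′)), where B′ is
  side B mirrored across the plane and the intersection volume is computed
  by voxel overlap on a shared grid; SI ∈ [0, 1], 1 = perfect symmetry.

Across a cohort, candidate-vs-reference differences are compared with
two-sided paired-sample t tests (t = mean(d)/(sd(d)/√n), df = n−1),
starred at 0.05/0.01. No multiple-testing correction is applied in the
primary columns; a Holm-adjusted column is emitted alongside, clearly
labelled as an extension.

## The reference symmetry plane

The reference plane is estimated from the surface alone by
original–mirror alignment:

1. seed with the best of the three centroid-anchored principal planes
   (smallest coarse mirrored-sample residual);
2. mirror the mesh across the current plane;
3. rigidly register the mirror back onto the original with robust ICP;
4. the composite map M = T ∘ Reflect(Π) is an improper isometry; its
   linear part has an eigenvalue −1 whose eigenvector is the new plane
   normal m, and the invariant-plane offset is m·b/2 with b the
   translation part; if no eigenvalue lies within 1e−6 of −1 the
   alignment has collapsed and a degenerate-symmetry error is raised;
5. repeat from 2 until the plane moves by < 0.01° and < 1e−3 mm.

The inner registration is point-to-point ICP: closest-point
correspondences from 5,000 source samples to the target surface, Tukey
biweight weights, and a weighted Kabsch solve (SVD with a det = +1 guard).
The robust scale is 1.4826 × MAD of the residuals, with cutoff
c = 4.685 × scale. The scale is held **fixed while the transform
converges, then re-estimated and the registration resumed** (up to 3
phases): the first phase sees residuals dominated by the initial
misalignment, so only a converged residual distribution lets the MAD
reflect the inlier spread and the cutoff reject deformed regions. Within
a phase the mean Tukey loss is provably non-increasing (each weighted
Kabsch step is a majorise–minimise update of the loss at fixed scale, and
re-matching to the closest point can only shrink residuals); the recorded
objective trace is the final phase's. Convergence is measured as the
largest displacement of the source bounding-box corners between
successive transforms, tolerance 1e−4 mm; with that tolerance,
point-to-point ICP on smooth surfaces needs a couple of hundred
iterations, so the per-phase cap is 300. Non-convergence is reported in
the result flags, never raised.

Correspondence is closest-point-on-surface rather than a nonrigidly
mapped template. This is the package's one deliberate methodological
surrogate: dense template mapping establishes homologous point pairs,
which shifts absolute AI values, but on the synthetic substrate it does
not change plane *orderings*, which is what every test asserts.

## Geometry kernel

* **Planes** are stored in Hesse normal form (unit normal, offset mm)
  with the normal sign canonicalised — largest-magnitude component
  positive, ties broken x, y, z — so planes compare reproducibly.
  Triplets whose triangle area is below 1e−6 mm² are refused as
  degenerate.
* **Closest-point queries** are exact: candidates are pruned with a k-d
  tree over triangle centroids using the bound that any triangle nearer
  than the current best upper bound u must have a centroid within
  u + R_max (R_max = largest centroid-to-vertex distance); oversized
  triangles are split 1→4 inside the query structure only, which leaves
  every distance identical but shrinks R_max. Per-pair distances use the
  projection/edge-clamp closest-point construction.
* **Plane splitting** clips each crossing triangle, chains the directed
  boundary edges of each half into closed planar polygons, and caps them
  by ear clipping (with a fan fallback for numerically degenerate rings —
  the fan still has the exact signed area, hence exact volume).
  On-plane vertices are nudged to the positive side by 1e−9 × the mesh
  diagonal so edge cases vanish; the induced volume error is far below
  the 1e−6 conservation tolerance.
* **Voxelization** is solid occupancy at voxel centers by column parity
  counting: a +z ray per (x, y) grid column, crossings collected per
  triangle, interior filled between crossing pairs. Query columns carry a
  deterministic sub-voxel jitter (~1e−7 × pitch) so exactly grid-aligned
  geometry (e.g. unit cubes) cannot produce double-counted edge hits.
  The occupancy volume approximates the enclosed volume to within the
  surface-shell bound 3 × area × pitch. Default pitch 0.5 mm.
* **Volumes** come from the divergence theorem (signed tetrahedra);
  open meshes are refused with their boundary-edge count.

## Synthetic substrate

The generator produces a stylized mandible: an elliptical tube swept
along a clamped cubic-spline centerline (dental-arch body of arc radius
45 mm turning up into a 45 mm ramus), with rotation-minimising frames,
smooth body→ramus width/height blending, condylar and coronoid
protuberances as parametric radial bulges, and a fan-capped condylar end.
The right half (x ≥ 0) is built first and welded to its own mirror image
at the midline ring, so the mesh is *exactly* symmetric about x = 0 and
every bilateral landmark pair mirrors exactly. Landmarks sit on grid
nodes of the parametric surface at fixed sweep/angle loci. Default
resolution 64 rings × 32 around (≈ 4.1k vertices, 8.1k faces,
volume ≈ 5.2e4 mm³, extents ≈ 123 × 78 × 57 mm).

Perturbations, each seeded and with amplitude 0 an exact identity:

* `gaussian_bump` — outward normal displacement a·exp(−d²/2r²) on one
  side (default r = 8 mm); landmarks move with the field; a warning is
  issued if the support reaches the midline (contaminated ground truth);
* `unilateral_scale` — smooth one-sided scaling of x with a 5 mm
  sigmoidal blend at the midline;
* `condyle_shift` — anterior displacement of one condylar region with
  gaussian falloff;
* rigid pose — one random rotation (≤ 15° by default) and translation
  (≤ 20 mm) applied consistently to mesh, landmarks and plane;
* landmark noise — iid isotropic gaussian jitter, default
  σ = 1.04·√(π/8) ≈ 0.652 mm per axis so the mean 3D displacement is
  1.04 mm, matching the reported accuracy of automated mandibular
  landmark localization.

The default study cohort is 20 independent subjects (seeds
base + index) with bump amplitude ~ Uniform(0, 1) mm on a random side,
default landmark noise, and random pose. Screening inside cohort runs
uses 2,000 quasi-landmarks per plane: on this substrate the AI ranking is
stable well below that count (the 17,415-sample AI differs from a
70,000-sample AI by < 2 × 10⁻² relative), and it keeps a 20-subject,
35-plane screen to a few minutes on one core.

What passing tests show — and what they do not: the synthetic shape has
clean geometry, a single dominant symmetry, and landmark noise that is
isotropic and independent. Real CBCT-derived mandibles have segmentation
noise, non-manifold artifacts, anatomically correlated landmark errors,
and genuine biological asymmetry with no ground-truth plane; absolute AI
or SI values from this substrate therefore do not transfer to clinical
data. What does transfer is the *contract*: exactness of the geometric
primitives, invariance of every metric under rigid motion, monotone
response to injected asymmetry, and the relative instability of planes
built from tightly clustered (symphysis-only) landmark triplets versus
triplets that reach back to the foramen midpoints.

## Design choices on genuinely open points

* Intersection volumes for SI use voxel overlap (image-style), not an
  exact mesh boolean; resolution is the configurable pitch.
* Table-style distance differences use *unsigned* distances (the d1/d2
  construction treats them as lengths); midpoint-on-plane pairs are zero
  either way.
* Side labels: A is the side with the smaller x-centroid ("left" in the
  canonical frame); SI is symmetric in the sides, so the choice is
  cosmetic.
* Cohort aggregation is per-subject screening followed by quantile
  summaries (median, IQR with linear interpolation, min–max); quantiles
  are computed, never transcribed, so they are always ordered.
* p-values are reported to 3 significant digits with the */** convention
  at 0.05/0.01.

## Known limitations

* Closest-point correspondence (not template homology) biases absolute
  AI slightly downward for large deformations.
* Voxel-based SI carries an O(area × pitch) shell error; SI comparisons
  across meshes should use a shared pitch.
* Point-to-point ICP converges slowly near the optimum; the bounding-box
  displacement tolerance (1e−4 mm) is deliberately strict and dominates
  runtime.
* The ear-clipping capper assumes simple (non-self-intersecting) cut
  polygons, which closed manifold meshes guarantee; the fan fallback
  preserves volumes but not necessarily watertightness in pathological
  rings.
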