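# Methods

## The measurement model

All quantities are derived from a labeled voxel volume of a left
ventricle — background (0), blood pool (1), normal myocardium (2),
heterogeneous tissue (HT, 3), dense scar (4) — on an axis-aligned lattice
with 1.2 mm isotropic spacing by default. Scar and HT are geometric
subsets of the myocardium, so every wall computation masks on the union
{2, 3, 4}. World coordinates are voxel centers in millimetres.

### Tissue classification

Scar and HT are defined relative to the maximum signal intensity M within
the myocardial segmentation: SI ≥ 0.60·M is scar, 0.40·M ≤ SI < 0.60·M is
HT. Boundaries are inclusive at the lower edge of each class, which makes
the degenerate all-equal-intensity volume "all scar" rather than an
error. The reference maximum is taken over the mask only, so the
classification is invariant under positive rescaling of intensities. No
smoothing or connected-component clean-up is applied by default; an
optional minimum-component-size filter exists but is off.

### Transmural Laplace field

The transmural coordinate u solves ∇²u = 0 on the myocardium with u = 0 on
the endocardial surface and u = 1 on the epicardial surface.
Discretization is 7-point finite differences. Boundary conditions are
imposed *between* voxel centers: for each myocardium→blood or
myocardium→background lattice edge, the interface position is estimated at
sub-voxel precision and the Dirichlet value is attached there through a
one-sided ghost coefficient (Gibou–Fedkiw). The sub-voxel position is the
0.5-level crossing of a Gaussian-smoothed binary indicator of the far
phase, evaluated at two smoothing scales (σ and √2·σ, σ = 1 voxel) and
extrapolated linearly in σ² — the extrapolation cancels the curvature
bias of the smoothed level-set. On a flat interface the estimate reduces
exactly to the face midpoint. Untagged wall edges (the cut base of a
truncated ventricle, the lattice boundary) get mirror (zero-flux)
conditions. The system is symmetric positive definite; small systems
(≤ 20k unknowns) are solved directly, larger ones by conjugate gradients,
and the max-norm residual is checked against the 1e-6 tolerance.

Accuracy on the analytic spherical-shell benchmark (R = 20/30 mm at
1.2 mm): mean |u − analytic| ≈ 0.003, maximum ≈ 0.033. The maximum is a
*geometric* floor, not a solver property: where the sphere runs tangent to
a lattice plane, every labeling is identical for any surface position
within a one-voxel slab across an ~8 mm facet, so no method working from
labels alone can localize the surface there better than about half a
voxel; multiplied by the boundary gradient u′(R₁) = 0.15/mm this is ~0.03
in u. Away from tangent facets the sub-voxel treatment keeps errors an
order of magnitude smaller. A solver consuming the underlying intensity
(partial-volume) data could do better; that input is outside this
module's contract.

### Streamline thickness and transmurality

One streamline is traced per endocardial node (myocardial voxels
face-adjacent to blood; 6-connectivity; a voxel adjacent to both blood and
background is assigned by majority face count, tie → endocardium, with a
thin-wall warning). The tracer integrates the normalized gradient of u
with fixed-step RK4 at half a voxel; the per-voxel gradient uses central
differences with ghost values at wall faces and is extended past the wall
by nearest-neighbor so trilinear interpolation stays valid at the
surfaces. A trace ends when its next position's nearest voxel is no
longer myocardial; traces whose gradient magnitude falls below 1e-8 are
flagged undefined rather than assigned a fabricated thickness.

Because voxel centers sit half a voxel inside each physical surface, both
path ends are clamped onto the voxelized tissue boundary by bisection on
nearest-voxel membership along the local streamline direction. On the
slab phantom this makes the measured thickness exactly the face-to-face
extent of the voxelized wall (9.6 mm for a 10 mm wall that quantizes to 8
layers), within half a voxel of truth. Tissue labels are sampled
nearest-neighbor at the midpoints of consecutive path points — a uniform
arc-length sampling at half-voxel intervals strictly interior to the
wall — and scar/HT transmurality is the percentage of samples in each
class. With this sampling, recovered transmurality on slab patches with
requested fractions 0.25/0.5/0.75/1.0 matches the voxelized truth
exactly at the patch core. A node is non-transmural when combined scar+HT
transmurality is below 95%.

### Surface metrics

The endocardial mesh is the marching-cubes 0.5-isosurface of the blood
mask after Gaussian smoothing at σ = 1 voxel (raw binary marching cubes
overestimates the area of a smooth surface by ~8%; smoothed, the shell
benchmark area is within ~1%). Node thickness is transferred to mesh
vertices as the mean over a 2.4 mm (2-voxel) neighborhood: streamline
thickness carries half-voxel quantization jitter, and differentiating
un-smoothed values marks thousands of scattered vertices as "steep". The
thickness field is then interpolated with a thin-plate-spline RBF in
ambient 3D coordinates (smoothing 1.0; ≥ 2000-vertex meshes use a seeded
random subset of centers, as the dense solve scales cubically), the
gradient is taken by central differences of the interpolant (step 0.01 mm)
and projected onto each vertex's tangent plane. Steep-gradient regions
are vertices with tangential magnitude ≥ 0.5 mm/mm by default — no
published value exists for "steep", so this is a package choice; a
90th-percentile data-driven alternative is reported alongside, and both
are configurable. Distances (to HT voxels anywhere in the wall depth, and
to steep vertices) are Euclidean 3D in world mm via KD-tree; the geodesic
variant is deliberately not implemented.

### Registration

Landmark alignment is Kabsch/Procrustes without scaling (reflections
excluded); ICP refinement uses point-to-closest-point-on-triangle
correspondences (candidate triangles via a centroid KD-tree, exact
point-triangle projection), drops the worst 10% of correspondences per
iteration, and stops when the trimmed RMS improves by less than 1e-4 mm.
An update that would raise the RMS is rejected, so the reported sequence
is non-increasing by construction. Transforms are rigid (6-DOF): both
geometries come from the same ventricle, so scale is fixed at 1 (a
similarity variant was considered and rejected for that reason).
Registered points are assigned to the nearest mesh node within 1 mm,
ties to the lowest node id; farther points stay unassigned.

### Activation analysis

Conduction block is operationalized from the >15 ms adjacent-point rule:
points within a 5 mm neighbor radius (the scale of EAM point spacing) are
adjacent; edges with |Δt| > 15 ms are block-crossing; midpoints of
crossing edges are grouped into connected chains, and each chain's
polyline runs through centroids of bins along its principal axis (raw
midpoint traversal zigzags and inflates arc length; binning at half the
neighbor radius suppresses this). Total block length is the summed chain
arc length; the region count is the number of chains. The visual criteria
used alongside the time rule in practice (opposing wavefront directions,
double potentials) are not part of the detector. Diastolic times are
classified into equal tertiles of the diastolic window [QRS end, cycle
end) with half-open boundaries.

### Statistics

Mann–Whitney U is exact by full enumeration of all C(n₁+n₂, n₁) group
assignments (mid-ranks, valid under ties) for combined samples up to 16,
and uses the tie-corrected normal approximation with continuity correction
above that; the two-tailed p doubles the smaller tail. Kruskal–Wallis uses
the tie-corrected H with the χ² approximation; Dunn's (1964) pairwise z
on mean ranks with pooled tie-corrected variance is Bonferroni-adjusted
(p × number of pairs, capped at 1). The paired t-test reports the 95% CI
of the mean difference from the t distribution, and raises on
zero-variance differences (a literally identical pair of samples has no
defined t). Under the null at n = 30/group the measured type-I rates are
≈ 0.045 for both nonparametric tests (the continuity correction makes
them slightly conservative).

## The phantom: what it emulates and what it does not

The default study phantom is a spherical shell (endocardial radius 20 mm,
healthy wall 8.4 mm) with one 30° infarct patch: scar grows from the
endocardium to 40% of local wall depth, is ringed by a 2.4 mm HT rim, and
the wall thins with a cosine ramp from healthy thickness at the patch
border to 60% of it over the patch interior — placing the steep thickness
gradient at the scar border zone, as observed around healed infarcts.
Intensities are class means (normal 20, HT 50, scar 100, arbitrary units)
plus Gaussian noise (sd 3); the means are chosen so the 40%/60%-of-max
thresholds bracket the HT mean symmetrically and recover the true classes
exactly on a noiseless phantom. EAM exports seed 100 diastolic points in
a ±10° band around the scar border (≈ 40% landing inside scar, ≈ 20% in
tissue with no scar/HT — mirroring the observed ~20% of diastolic sites
without enhancement) and 100 normal points ≥ 25° beyond the patch, all on
the true endocardial surface, displaced by a known rigid transform (15°
rotation + (5, −3, 2) mm) with 0.5 mm position noise, alongside apex and
three ostial fiducials. Activation maps are kinematic: planar wavefronts
on a 30 × 30 mm patch at 2 mm spacing, either uniform or colliding along a
full-width line with a 40 ms offset.

The generator reproduces the *geometry* of the measurement problem, not
its physics: no MRI artifacts or partial-volume intensity profiles, no
electrogram morphology (activation times are assigned, not simulated), no
coupling between diastolic timing and local structure (per-tertile
distance orderings are therefore not expected to reproduce), and rigid —
not deformable — frame displacement. Passing tests therefore demonstrate
that the measurement chain recovers known structure at realistic
resolution and noise; they say nothing about biological variability or
acquisition artifacts in real data.

## Problem sizes and numerical choices

Default runs use the 55³–59³ lattices the 1.2 mm shells naturally occupy
(~35–46k wall voxels; the full-lattice validation pads to 96³); a full
pipeline run takes a few seconds on one CPU. Laplace tolerance 1e-6
(max-norm residual); streamline step 0.6 mm; RBF centers capped at 2000;
ICP capped at 100 iterations. All randomness flows through
`numpy.random.default_rng` seeded from the configuration; identical
configuration and seed reproduce outputs bit-for-bit.

## Known limitations

- Wall thickness is isotropic-Laplace thickness; fiber-aware or
  2D-slice-based measures are out of scope.
- The Laplace max-error floor at tangent facets (above) is inherent to
  label-only input at 1.2 mm.
- The block detector assumes locally line-like block; crossing or
  branching block lines would be merged into single chains by the
  principal-axis binning.
- `distance_to_set` is ambient Euclidean; through-wall shortcuts are
  possible in strongly folded geometries (irrelevant on the phantoms
  used here).
- The truncated-ellipsoid phantom approximates wall depth radially from
  the chamber center, which is exact for the shell and slightly biased
  for eccentric ellipsoids.
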