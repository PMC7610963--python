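# Methods

This note documents the models, numerical choices and limitations behind
each pipeline, in the order the package exposes them. Conventions
throughout: all geometry in world millimetres, voxel indices 0-based, the
affine maps index → mm (NIfTI convention).

## Segmentation and surface extraction

`region_grow` labels the connected component, under 6- or 26-connectivity
(default 6, the conservative choice against leakage), of voxels whose
intensity lies in a closed range containing the seed. It is deterministic
and invariant to the choice of seed within a component.

`mesh_from_labels` runs marching cubes at iso-level 0.5. The binary mask is
first anti-aliased with a Gaussian of σ = 1 voxel (zero-padded boundary):
the 0.5 level of the smoothed indicator tracks the true boundary to a small
fraction of a voxel, whereas the raw binary iso-surface is a 45°-faceted
staircase that overestimates area by ~8% (measured on a digitised 10 mm
sphere at 0.5 mm spacing; <1% after anti-aliasing). Structures smaller than
the kernel (where the smoothed maximum falls below 0.6) fall back to the
raw mask so single-voxel labels still produce a closed cuboid. Optional
uniform Laplacian smoothing uses a conservative relaxation factor (0.15)
chosen so that ten iterations change the enclosed volume of the digitised
sphere by well under 2%.

Landmark measurements: ring area is the polygon area after projecting the
points onto their best-fit (least-squares) plane; the perimeter is the true
3-D closed-loop length, so a non-planar ring keeps its physical perimeter.
A collinear ring yields area zero with a warning rather than an error.

## B-spline FFD registration and strain

The deformation h(x) = x + Σₖ cₖ B³((x − origin)/s − k) is a tensor product
of cubic B-splines over a lattice of control displacements cₖ with spacing
s; the basis is a positive partition of unity, so displacements are bounded
by the largest control vector. Points must lie in the fully-supported
interior of the lattice; the lattice constructor pads one node beyond the
registered domain on every side.

Registration minimises SSD between the fixed image and the warped moving
image by gradient descent on the control displacements, with the analytic
gradient through linear image interpolation (chain rule). The step is a
maximum control-point move in mm (gradient normalised by its ∞-norm);
on a non-decrease the step halves, so SSD is strictly decreasing over
accepted steps. The multi-level scheme starts at 2^(levels−1) × the finest
spacing and halves per level (default 4 levels, finest 10 mm); each finer
lattice is seeded with the coarser displacement sampled at the new control
nodes, then re-optimised, and coarser levels subsample the fixed image
(stride up to 4) as an image pyramid. Frames of a sequence are registered
independently frame-0 → frame-t; no temporal regularisation is applied.
On the parameter-recovery harness (smooth random 64³ texture warped by a
known 2 mm / 10 mm-lattice deformation) the recovered field agrees with
the truth to ~0.03 voxel RMS, comfortably sub-voxel.

Strain uses the surface-deformation convention: per triangle, **F** is the
unique linear map sending the two reference edges to the deformed edges and
the reference unit normal to the deformed unit normal. The normal direction
therefore carries no strain claim; rigid motions give **F** ∈ SO(3) and
**E** = ½(**F**ᵀ**F** − **I**) = 0 to machine precision. Circumferential and
longitudinal directions are intrinsic per triangle: longitudinal is the
long-axis component tangent to the triangle plane, circumferential is
normal × longitudinal; triangles orthogonal to the axis (apex caps) get NaN
directional strains and are excluded from aggregation. The 16-segment model
splits the base→apex axis fraction λ into basal (λ < 1/3, six 60° sectors),
mid (six sectors) and apical (λ ≥ 2/3, four 90° sectors), angles measured
from a caller-supplied reference direction; boundary values tie-break to
the lower-index segment. Segment curves are area-weighted means per frame.

## LGE scar quantification

`project_mip` samples the LGE volume by trilinear interpolation along each
triangle's outward normal from −1 mm (inward) to +3 mm (outward) in
0.25 mm steps and keeps the maximum. Projection is at triangle centroids so
scores, labels and areas live on the same elements; meshes are re-oriented
outward (signed volume > 0) before projection so "outward" is well defined.
Scores are normalised by the blood-pool mean (image intensity ratio); the
default thresholds exposed in configuration are 1.2 and 1.32, and labelling
is strict (score > threshold). Burden is the labelled area percentage.

Corridor gap analysis is one-dimensional on the rim: corridor triangles
(geodesic distance to the rim ≤ width via edge-graph Dijkstra; rim-incident
triangles always included) project to their nearest rim vertex; a rim
vertex is covered when any of its triangles is scar, and gaps are maximal
circular runs of uncovered vertices, each vertex owning half of each
adjacent loop segment. A fully uncovered ring is one gap of fraction 1.
This matches the encirclement question of pulmonary vein isolation rather
than 2-D patch topology. Pre/post comparison is area-weighted Dice plus
new/regressed area fractions with the 0/0 → 0 convention; cross-scan
correspondence (by triangle index) is the caller's responsibility.

## Laplace-equation wall thickness

The potential solves Δu = 0 on wall voxels with u = 0/1 on the endo/epi
marker layers, by red-black successive over-relaxation (ω = 1.8, 6-point
stencil scaled per-axis by 1/h², default tolerance 1e-5 on the max update).
The Dirichlet value is imposed at the *face* between a wall voxel and a
marker voxel — the neighbour weight doubles to 2/h², placing the boundary
half a voxel out — so the discrete solution is consistent with the
continuum surfaces: the slab potential is exactly z/d, and the shell
potential matches the harmonic (1/r_in − 1/r)/(1/r_in − 1/r_out) to ~0.006
RMS at 0.5 mm spacing (per-voxel errors up to ~0.04 survive in the first
voxel layer where the staircase boundary ripples; they decay inward).
Wall components not connected to both boundaries get NaN and a warning.

Thickness integrates one streamline of ∇u/‖∇u‖ up to the epicardium and
one down to the endocardium from every wall voxel (Euler steps, default
0.25 × min spacing; trilinear gradient interpolation; only the gradient
*direction* is used, which immunises the trace against the one-sided
gradient bias at boundaries). Streamlines terminate on the 0.5 iso-level of
the σ = 1 voxel Gaussian-smoothed wall indicator — a sub-voxel estimate of
the wall face — refined by bisection; termination on the raw voxel mask
would carry ±h/2 quantisation per end. A path exceeding 10× the domain
diagonal is reported as diverged (NaN). Measured accuracy at 0.5 mm
spacing: slab 10 mm recovered within 2 Euler steps at every interior voxel
(away from the phantom's open lateral sides, where the finite slab stops
being a parallel-plate geometry); shell 5 mm within 3% at every interior
voxel. The solve is on the voxel grid rather than a tetrahedral mesh —
thickness is a field property, and mesh association is preserved by
trilinear sampling with a one-voxel nearest-valid fallback.

## Vessel clipping

The medial radius field is the Euclidean distance transform of the blood
pool (maximal-inscribed-sphere radius, the volumetric analogue of the
embedded Voronoi radius). Centerlines are Dijkstra shortest paths on the
26-connected interior voxel graph with edge cost step/(medial radius)²,
which pulls the path onto the medial axis; a window-5 moving average
smooths the voxel staircase. Per-point cross-sectional area is the proxy
π·(medial radius)² — monotone-equivalent to a true orthogonal section for
opening detection and far cheaper; it is a proxy, not a measurement.

Opening detection walks from the distal seed toward the chamber centre and
triggers where the forward moving-median of the area (odd window, default
4× the sample step) exceeds rise_factor (default 1.5) × the running median
of the traversed segment. Because the forward median leads the rise by
about half a window, the trigger is then refined to the rise onset: back
off while the forward median is still >5% above baseline, then advance on
the raw profile while it stays within 2% of baseline. The tight advance
gate deliberately keeps the opening on the *vessel* side of the junction,
where the calibre still equals the vessel's — on the tube–sphere phantom
the chamber cross-section grows by ~120 mm²/mm past the junction, so
overshooting is far more damaging than stopping a voxel short. Detection
lands within ~1 voxel of the analytic junction on axis-aligned and oblique
phantoms. With rise_factor = 1.0 the rule degenerates to triggering on the
first positive fluctuation, as documented.

Clipping uses finite disks (origin on the centerline, normal the local
tangent, radius 1.5× the local medial radius by default) so one vein's
clip cannot cut the far wall: only discard-side material edge-connected to
the cut is severed. Mesh clipping re-triangulates crossing triangles at the
plane; cut points that coincide with existing vertices snap to them, so rim
loops are always edge loops of the output mesh and feed corridor analysis
directly. Volume clipping removes severed voxel components; it returns no
rim (a mesh concept). The reported opening area is the planar polygon area
of the rim loop: on a straight vessel it matches πr² within a few percent,
while at a chamber ostium it additionally carries the anti-aliased
extraction's corner blend between vessel and chamber (measured +13% at
1 mm voxels, decaying with distance from the junction).

## Phantoms: what they emulate and what they do not

Every generator is a pure function of its parameters and seed and returns
ground truth in world mm. The slab/shell wall phantoms place their endo and
epi marker layers immediately outside the exact-thickness wall so the
wall/marker faces coincide with the continuum surfaces the solver pins.
The chamber phantom is a sphere with cylindrical veins; its truth is the
analytic sphere–cylinder junction √(R² − r²) along each axis. The LGE
phantom fills the mesh interior with the blood-pool mean, plants a
scar_ratio × band (2 mm thick, straddling the surface) over patch triangles
selected by mesh geodesics, and adds seeded Gaussian noise; near-surface
voxels are attributed by exact closest-point-on-triangle queries so the
band edge matches the per-triangle truth. Motion phantoms are smoothed
white-noise control lattices scaled to a displacement amplitude, with a
half-sine temporal envelope and an identity first frame.

None of this emulates MR physics: no bias fields, no surface-coil
intensity falloff, no motion artefacts, no partial-volume beyond the
voxelisation itself, and Gaussian rather than Rician noise. Passing tests
therefore demonstrate correctness of the geometry and numerics under
idealised intensities, not robustness to scanner artefacts. Two measured
discretisation limits worth knowing: (i) scar-burden recovery of a planted
patch overshoots by ~0.5–1 percentage point because trilinear sampling
partial-volumes a half-voxel ring at the patch edge across the threshold —
the acceptance check bounds the error by the patch-boundary ring area, the
quantisation floor of a triangle-quantised patch; (ii) edge-graph geodesics
exceed true surface geodesics by a few percent, so geodesically-defined
patches are slightly smaller than their nominal radius suggests.

## Problem sizes

Default study conditions: 0.5 mm phantoms for thickness (shell 10/15 mm,
slab 10 mm), 1 mm chamber phantoms (R = 20 mm) for clipping and the
pipeline, a 64³ image with 10 mm finest lattice for registration recovery
(unit tests use a 32³ version of the same harness), and 0.5–1 mm LGE
volumes. The registration descent runs up to 100 accepted steps per level
with relative-SSD tolerance 1e-6.

## Known limitations

- Registration is SSD-only (mono-modal) with no diffeomorphism guarantee;
  the motion phantom's amplitude < spacing/2 margin keeps its warps benign.
- Strain lives on whichever surface is supplied; no claim about
  endocardial vs epicardial layers is made.
- The area proxy π·r² along centerlines is not a true orthogonal
  cross-section; openings, not calibres, are its purpose.
- Gap analysis treats rim vertices without assigned corridor triangles as
  uncovered; extremely coarse corridors could over-count gaps.
- 4-D NIfTI is not read; time series are file sequences.
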