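# Methods

## Volume conduction model

The head is modelled as four nested homogeneous, isotropic compartments
bounded by closed triangulated surfaces ordered outside-in: scalp,
outer skull, inner skull, brain.  Compartment conductivities default to
σ_scalp = 0.33, σ_skull = 0.0132, σ_CSF = 1.79, σ_brain = 0.33 S/m and
are overridable on the `HeadModel`.  Geometry is expressed in mm in a
right-handed frame (+X toward the right pre-auricular point, +Y toward
the nasion, +Z up, origin midway between the pre-auricular points) and
converted to metres inside the solver, so potentials are volts per A·m
of dipole moment.

## BEM discretization

The surface potential solves the Geselowitz integral equation; we
discretize by vertex collocation with linear shape functions, using de
Munck's analytic formula for the potential integral of a linearly
varying source density over a triangle.  Singular self-triangle terms
are skipped and restored by the auto-element correction: each vertex row
of the self-surface block must total the interior solid angle 2π; half
the missing angle is assigned to the vertex, the rest spread over its
triangle ring.  The free additive constant of the potential is removed
by rank-one deflation (adding `1/n` to every matrix entry), and the
dense system is LU-factorized.  Electrode potentials come from
barycentric interpolation over the scalp triangle nearest each
electrode; electrodes farther than 10 mm from the surface are rejected.

### Isolated problem approach

With σ_skull ≈ σ_CSF/136 the potential drops by more than an order of
magnitude across the skull, and the discretization error of the large
intracranial potential leaks into the small scalp values.  The isolated
problem approach splits the solution as `v = u + A·v0`, where `v0`
solves the *isolated* problem — the volume bounded by the inner skull
with zero conductivity outside — and `u` is a smooth correction.  The
term that couples `v0` to the outer surfaces through the discrete
operator is replaced by its exact continuous value (the exterior
representation identity of the isolated conductor), which is what
removes the conductivity-jump error; the residual source for `u` is
algebraic in `v0`: with μ = σ_skull/σ_CSF, `u` solves the full system
with right-hand side `μ·b − (2μ/(1+μ))·v0` on the isolation surface
(and `μ·b` elsewhere), and `A` equals 1 on the inner skull and `1 − μ`
on surfaces inside it.  This generalizes the classical three-surface
formulation to the four-surface model, with the isolated sub-problem
spanning the inner-skull *and* brain surfaces.  The isolation surface is
chosen automatically as the surface with the strongest outward
conductivity drop.  When the jump is absent (σ_skull equal to its
neighbours) the correction provably reduces to the plain solve up to the
free constant.

On concentric four-shell spheres (radii 78/80/86/92 mm, the default
conductivities, 2,500 faces per shell) the solver agrees with the
analytic series solution with RDM < 0.05 and MAG within [0.85, 1.15]
for random dipoles up to 0.8 eccentricity, and the IPA solve is at
least as accurate as the plain solve for essentially every source —
both re-measured by `tests/test_acceptance.py` on every run.  RDM and
MAG are computed after average-referencing both vectors, since the BEM
potential carries an arbitrary constant fixed only by the deflation.

### Analytic oracle

`analytic_sphere_potential` implements the Legendre-series solution for
a dipole in N concentric isotropic shells: for each degree n, a small
linear system expresses potential and radial-current continuity at each
interface plus zero current at the outer boundary.  Basis functions are
rescaled per layer (`(r/R_j)^n`, `(R_{j-1}/r)^{n+1}`) so the system
stays well conditioned to high degree.  The one-shell limit is verified
to 1e-10 against an independent closed form obtained by summing the
homogeneous-sphere series with generating functions — the two
derivations share no code path.

## Mesh machinery

No exact boolean/CSG or decimation backend is assumed.  The package
carries its own primitives, each validated against brute-force oracles
in the test suite:

* **Signed distance** via exact point-triangle queries (KD-tree pruned,
  with a provably safe re-query fallback) and angle-weighted
  pseudonormal signs — exact for watertight meshes.
* **Boolean carving** (`carve_ears`) as signed-distance CSG: the
  difference `max(sdf_scalp, −sdf_impression)` is sampled on a lattice
  (default 1.5–2 mm) and re-triangulated with marching cubes, which is
  watertight by construction; marching-cubes slivers are removed by
  edge collapse, never by face deletion.  A sphere-minus-sphere test
  reproduces the closed-form lens volume within 2% (measured ≈ 0.3%).
  Carved faces are labelled `"ear"` and protected during decimation.
* **Remeshing** by midpoint subdivision up and quadric edge-collapse
  (QEM) down, with link-condition and normal-flip guards so closed
  2-manifolds stay closed; enclosed volume is preserved within 1%.
  A labelled dense region is kept at a requested area-density ratio by
  subdividing globally and protecting the region from collapses.
* **Containment** via the generalized winding number (the same solid
  angle primitive the BEM uses), with lattice flood fill for bulk
  queries.

### Minimum-distance enforcement

After carving, surfaces are processed outside-in (the spec order: scalp
first, brain last); the outer surface of each pair stays fixed.  Gap
violations are detected at vertices, edge midpoints and face centroids
of the inner surface *and* from the outer surface's vertices against
the inner faces — a coarse inner face can violate the 1 mm rule between
its own sample points when a thin feature such as the carved ear canal
passes by.  Offending vertices move along the local gap direction (away
from the fixed surface) rather than the vertex normal, which would
fail to clear lateral features like canal walls; the displacement field
is diffused into the surrounding ring so patches move coherently, and
the loop aims slightly past the target gap so it terminates.  The
procedure is idempotent and leaves already-satisfying models untouched.

## Synthetic ear head

The generator emulates the study conditions: a four-shell head with a
parametric ear carve on both sides (revolved concha bowl, default
radius 10 mm / depth 5 mm, plus canal cylinder, radius 4 mm / depth
6 mm), 15 in-ear electrodes per ear placed as two canal rings plus a
concha ring (so they span a volume — the property a planar scalp patch
lacks), 10 periauricular electrodes ringing each carve, and 128
quasi-uniform scalp electrodes (golden-angle spiral, ear regions and
neck excluded).  All randomness (ring phases, 0.3 mm placement jitter
emulating digitization noise) flows from a single seed; electrodes are
snapped exactly onto the carved surface.  The carve is not anatomically
faithful — there is no pinna, no canal curvature, no tissue detail —
so passing tests demonstrate the *mechanics* of the pipeline and the
qualitative electrode-configuration physics, not clinical realism.
`simulate_sources` projects seeded dipole time courses through a
computed lead field and adds white sensor noise; the ground-truth
inverse mixing matrix is returned so evaluation metrics can be checked
against construction.

Default problem sizes are chosen for desk-scale work: 2,000–2,500 faces
per shell for accuracy benchmarks, 1,500 for the ear head, a 4 mm
source grid (~31,000 nodes inside a 78 mm brain), and a carve lattice
of 2 mm.

## Dipole fitting and metrics

`fit_dipole` scans all source-grid nodes (the moment is linear and
solved per node by batched normal equations on mean-centred data — the
objective is exactly the residual variance), then refines the location
with Nelder–Mead using trilinear interpolation of the lead field over
the eight enclosing nodes.  Positions outside the lattice hull are
flagged and fall back to the best node.  Because the paper's
correlation metric is scale-invariant but RV is not, the predicted map
uses the least-squares moment, which makes RV = 0 attainable for a
perfect shape match.  Quantization snaps to the nearest node with ties
broken toward the lower index; component selection keeps the k = 12
lowest-RV components among those fitted inside the brain volume.

## Preprocessing

Rate ratios between amplifiers follow from the sample counts between
the first and last shared trigger; streams are cropped at the first
trigger, polyphase-resampled to 500 Hz and referenced to the common
electrode (FPz by convention).  The filter chain applies average
reference, per-channel demeaning (so DC is removed exactly and IIR edge
transients stay small), a 1 Hz Butterworth high-pass and 50/100/150/200
Hz band-stop filters, all forward-backward (zero phase); the
"4th-order" notch is realized as an order-2 Butterworth band-stop whose
zero-phase application has a 4th-order magnitude response.  Saturation
flags channels dwelling ≥ `dwell` consecutive samples within 1% of the
rails.  The ASSR detector averages epochs of 8 trigger periods (1 s at
an 8 Hz trigger) and compares the 40 Hz power of the average against
the mean of 12 neighbouring 1 Hz bins (nearest bin each side excluded
as a leakage guard) via F(2, 24); a channel survives when any bipolar
pair within its group is significant at α = 0.05, with no
multiple-comparison correction — a deliberately liberal criterion, so
a noise-only group occasionally survives by chance (the tests pin the
seed).  Channels shared between groups survive if significant in any.

## Known limitations

* The ear carve is a solid of revolution; real concha/canal geometry is
  markedly asymmetric and individual.
* Linear collocation accuracy is certified only up to 0.8 eccentricity;
  sources within ~4 mm of the brain surface are kept in the grid but
  flagged `near_boundary`.
* The sequential minimum-distance enforcement can locally thin the
  skull below its anatomical thickness under deep carves — intended
  behaviour, but worth knowing when interpreting sensitivity near the
  canal tip.
* ICA itself is out of scope: the inverse mixing matrix is an input
  (or synthetic ground truth), never estimated here.
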