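# Methods

`pelviflow` performs an in-silico analogue of the Whitaker pressure-flow
study: it imposes physiological urine production rates on a luminal model
of the renal pelvis, ureteropelvic junction (UPJ) and proximal ureter,
computes the steady flow field, and reads off the pelvis-to-outlet pressure
difference ΔP as a function of flow rate Q.  The severity call is the
dichotomy used clinically for hydronephrosis: an obstructed system shows a
pelvic pressure that rises with urine flow; an unobstructed (or
compensated) system does not.

## Governing model and assumptions

The urine flow is modeled as steady, laminar, incompressible and Newtonian
in a rigid lumen:

    div U = 0
    rho (U . grad) U = -grad P + mu lap U

with density rho = 1050 kg/m³ and dynamic viscosity mu = 0.001 Pa·s.
Reynolds numbers over the physiological band (0.25–1.0 mL/min through a
millimetre-scale duct) are O(1)–O(10), so a creeping-flow (Stokes)
approximation is also exposed; in that regime ΔP is exactly linear in Q and
the solver exploits this (one solve per sweep, rescaled).  Boundary
conditions:

* **Papillary inflow** — a plug (uniform) velocity profile normal to the
  inlet patch, scaled so the *discrete* influx equals Q exactly; multiple
  patches split Q area-weighted.  The pelvis chamber dissipates any
  profile detail long before the UPJ (see the uniformity property below),
  so the plug choice is immaterial to ΔP.
* **Ureteral outlet** — zero traction with reference (gauge) pressure
  0 Pa; all reported pressures are relative to this datum.
* **Walls** — homogeneous no-slip on a rigid wall.  Peristalsis, wall
  compliance and unsteadiness are out of scope.
* No body force: reported ΔP excludes hydrostatic (posture) effects.

## Discretization and solvers

Taylor–Hood mixed finite elements on tetrahedra — continuous P2 velocity,
P1 pressure — which satisfy the inf-sup condition, so no pressure
stabilization is used and checkerboard modes cannot appear.  Viscous and
divergence terms are integrated exactly (degree-2 Keast rule); the
convective term uses a degree-3 rule.  Dirichlet data are eliminated from
the algebraic system; the plug-inflow speed is calibrated against the
discrete surface integral of the P2 trace (edge-midpoint rule, exact for
quadratics) after no-slip has zeroed the patch rim, which is why mass
balance between inlet and outlet holds to machine precision on every
converged solution, independent of mesh quality.

The linearized saddle system has the same scalar operator acting on each
velocity component, so one scalar sparse LU (SuperLU) serves all three.
The coupled system is solved by preconditioned GMRES with a block
upper-triangular preconditioner: exact velocity block via the scalar LU,
and the pressure Schur complement approximated by the lumped P1 mass
matrix divided by mu (spectrally equivalent for Stokes flow).  GMRES is
run to a relative tolerance of 1e-10 (restart 300).  Because the Krylov
iteration is exactly scale-invariant in the right-hand side, Stokes
solutions scale bit-for-bit linearly with Q.

Navier–Stokes is solved by Picard iteration on the convective field,
initialized from the Stokes solution (or from a rescaled neighbouring-rate
solution during sweeps), with inexact inner solves whose tolerance tracks
the nonlinear residual.  Convergence is declared at a relative momentum
residual of 1e-8; after 50 iterations the solver raises an error that
reports the last residual and the Reynolds number, since failure at high
Re signals a violation of the steady-laminar assumption.  Picard (rather
than Newton) keeps the velocity operator component-scalar and is robust at
these Reynolds numbers.

## Meshing

Two tetrahedralization paths:

* **Swept (structured)** — used for the axisymmetric synthetic geometries,
  which carry their radius profile r(z) as metadata.  A single disk
  triangulation (rings with counts proportional to radius, geometric
  radial grading toward the wall by the `near_wall_refine` factor) is
  scaled to r(z) at graded axial stations and swept; the prisms between
  layers are split into tetrahedra with the minimum-global-index diagonal
  rule, which is consistent across neighbouring prisms and provably avoids
  the two unsplittable (cyclic) diagonal configurations.  Axial station
  spacing is tied to the local radius (aspect ≈ 3) with a floor of 1/12 of
  the edge target, so narrow throats keep near-isotropic cells.
* **Delaunay-carve (generic)** — for arbitrary watertight surfaces
  (e.g. CT-segmentation STL): Delaunay tetrahedralization of the surface
  vertices plus a graded interior point cloud (inward vertex-normal offset
  layers and a coarse lattice), carved to the interior by the generalized
  winding number, keeping the largest face-connected component.

Boundary facets inherit surface tags by nearest-facet matching with a 30°
normal tolerance, tie-breaking to WALL.  Point containment and
nearest-triangle queries are computed natively (solid-angle winding
numbers; KD-tree candidate search with exact point-triangle distances).
Volume conservation between surface and tet mesh is held to 2%.

## Synthetic phantoms — what they emulate and what they do not

The phantom generator stands in for CT-extracted patient geometry: a
spheroidal pelvis chamber (anteroposterior diameter and length 30 mm by
default — a grade 3–4 hydronephrotic pelvis), truncated at the dome by a
planar papillary inflow disk carrying `inlet_patch_fraction` (default
0.15) of the dome area; a C1 cubic-Hermite convergence to the UPJ; a
cylindrical throat waist (`upj_throat_diameter`, default 1.5 mm, half of
the 8 mm junction length) whose R⁻⁴ lubrication resistance dominates ΔP; a
smoothstep divergence into a mildly dilated 6 mm proximal ureter stub of
15 mm (the extracted segment ends well above the bladder).  An optional
seeded radial roughness (2% of local radius) emulates segmentation noise;
roughened surfaces are no longer axisymmetric and are volume-meshed through
the generic path.

The phantoms deliberately do *not* reproduce calyceal anatomy, asymmetric
pelvis shapes, distributed papillary openings, wall compliance or
peristaltic transport.  Passing tests therefore demonstrate that the
pipeline solves the stated flow model correctly on pelvis-like geometry
and that the ΔP(Q) severity logic behaves as designed — not that any
particular patient's pelvic pressure is predicted accurately.

## Probes, ΔP and classification

Three probe points are placed automatically at the 25/50/75% stations of
the pelvis region (the half of the domain, along the principal axis, with
the larger mean cross-section), snapped to interior cell centroids; a
geometry without an enlarged region falls back to whole-domain stations
with a warning flag.  ΔP is the mean of the three probe pressures relative
to the outlet datum; because the chamber pressure is uniform (max pairwise
probe spread is bounded by 5% of ΔP in the acceptance suite, and measures
~10⁻⁴ of ΔP in practice), the choice of probe statistic is immaterial.

A sweep over the physiological band (default 360/720/1440 mL/day, i.e.
0.25/0.5/1.0 mL/min; the band is configurable for patient size) yields
ΔP(Q).  Classification: **flow-dependent obstructive** iff ΔP at the
maximum swept rate reaches the threshold *and* ΔP increases strictly
across the sweep; otherwise **flow-independent**.  The default threshold
of 0.015 Pa is the lower edge of the elevated-pressure band reported for a
single clinical case and is exposed as a parameter — it is not a validated
clinical cutoff, and the package makes no claim about absolute intrapelvic
pressure.

## Numerical choices and problem sizes

* Default desk-scale meshes: ~5k cells (validation cylinder), ~9k cells
  (default phantom), up to ~37k on the refined cylinder — far below the
  ~10⁶ cells a commercial polyhedral mesher would produce.  The
  grid-convergence study (three levels, 6/4.5/3 mm edge targets on the
  stenotic phantom) holds the ΔP change between the two finest levels
  under 2%, which justifies the desk-scale default.
* The inscribed-polygon representation of circular cross-sections biases
  ΔP up by ≈ (2π/n_theta)²/3 (about 1–3% at defaults); it is the dominant
  discretization error and vanishes quadratically under refinement.
* Tag tie-breaks go to WALL; overlapping inlet/outlet tagging rules and
  empty selections are hard errors.
* Degenerate inputs (non-watertight surfaces after vertex-merge repair,
  empty or multi-component voxel masks, specs violating their invariants,
  meshes without an outlet group) raise typed errors naming the condition.
* All stages are deterministic given (spec, seed); sweeps, meshes and CSV
  outputs reproduce bit-for-bit.

## Known limitations

* The computed ΔP is an estimate of the viscous pressure difference under
  an imposed steady inflow — not the physiologic intrapelvic pressure,
  which includes compliance, peristalsis and outlet conditions not
  modeled here.
* The obstruction threshold derives from one case; on other geometries it
  is only a configurable default.
* The Delaunay-carve path favours robustness over cell quality; strongly
  concave CT geometries may need a finer edge target than the default.
* Solver cost grows quickly below ~0.3 mm throats at default grading; the
  acceptance family stops at 0.5 mm.
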