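# Methods

`rootpatch` implements two loosely coupled models of root hair initiation in
*Arabidopsis* root epidermal cells: a reaction–diffusion model that positions
a patch of activated ROP GTPase on the cell surface, and a nonlinear
thin-shell model of a pressurized cell-wall patch whose stress pattern around
a locally modified region is classified as radial or circumferential. This
note records the models, the numerical choices, and the points where the
design was genuinely open.

## 1. ROP patterning model

### 1.1 Equations

The 2D cell surface is discretized into polygonal compartments. Auxin A
follows a source–sink transport balance,

    dA/dt = D_a ΔA + t + s_in·[source] − s_out·A·[sink] − q·A,

with production in a basal strip (influx proxy) and first-order removal in an
apical strip (efflux proxy). ROP cycles between a fast-diffusing cytosolic
inactive form R_i and a slow, membrane-bound active form R_a:

    dR_a/dt = D_1 ΔR_a + a + R_i (k_1 + k_2 R_a² A) − c R_a − (r + p·[boundary]) R_a
    dR_i/dt = D_2 ΔR_i + b − e R_i − R_i (k_1 + k_2 R_a² A) + c R_a

The cubic, auxin-dependent autoactivation plus the D_2 ≫ D_1 contrast make
this an activator–substrate patterning system; the extra decay p in
compartments bordering the cell outline models active ROP lost to the
anticlinal faces. Default rate constants are the reference table values
(gradient mode: D_a = 5.0, s_in = 0.25, s_out = 0.31, q = 2·10⁻⁵, t = 0;
ROP: D_1 = 0.01, D_2 = 1.0, a = 0, b = 0.01, c = 0.1, e = 0, r = 0.01,
p = 0.01, k_1 = 0.01, k_2 = 0.015). Constant-auxin regimes set
s_in = s_out = 0 and q = 0.1, so the uniform steady level is t/q.

### 1.2 Units and default geometry

The rate table is written in arbitrary length/concentration units. The
default cell is **10 × 2 length units** (286 compartments); with one unit ≙
10 μm this is a 100 × 20 μm epidermal cell. The length is fixed by the model
itself: with the table's diffusivity and source/sink rates, a 10-unit-long
cell yields a basal-to-apical auxin drop of ≈ 22%, matching the ~20%
regime the model was built around, whereas reading the table in μm on a
100 μm cell would produce a ~95% drop. Source and sink strips each cover 5%
of the cell length.

### 1.3 Spatial operator

Transport between compartments i, j is proportional to the concentration
difference with geometric weights: (D/area_i)·Σ_j (L_ij/d_ij)(f_j − f_i),
where L_ij is the shared edge length and d_ij the centroid distance. The
outer boundary is zero-flux; the only boundary loss is the explicit p term.
This operator conserves area-weighted mass to rounding error for any field.

### 1.4 Tessellation and lateral symmetry

Compartments are Lloyd-relaxed (centroidal) Voronoi cells of seeded random
points — polygonal, with controlled size variation. A subtlety discovered
during development drives two design choices:

* **Mirror-symmetric tessellation (default).** The steady patch of this
  model is only a few compartments wide, so on an arbitrary tessellation its
  lateral position is selected by compartment-size noise (lattice pinning),
  not by the model. The default tessellation is therefore exactly mirror
  symmetric about the long midline (cells generated on the half strip and
  reflected, with edge weights copied bitwise).
* **Symmetry-reduced gradient run.** Even on a symmetric tessellation,
  floating-point asymmetries of order 10⁻¹⁶ are amplified to O(1) by the
  patterning instability. The gradient-mode simulation is therefore computed
  on the half cell — no-flux at the midline (the exact symmetric subspace),
  boundary degradation only on true membrane edges — and reflected onto the
  full tessellation. Within this subspace the patch settles against the
  midline, i.e. laterally centered in the full cell, reproducing the
  centered basal patch; off-center pinned states do exist in the full system
  and are selected if the symmetry reduction is not used.

### 1.5 Time integration and initial conditions

Fixed-step classical RK4, with the step chosen at half the explicit
diffusive stability bound (2.785/λ_max estimated from the conductance sums);
integration stops when max |d·/dt| < 10⁻⁸ over all species (a direct sparse
solve of the linear auxin balance provides an independent oracle for the
auxin stage). The auxin field is equilibrated first and held fixed during
the ROP stage.

Initial conditions differ by mode, and the difference matters:

* **Gradient mode**: A = 0 and a cold ROP start (R_a = 0, R_i small). The
  auxin gradient provides the positional bias; the run converges to a single
  basal patch.
* **Constant-auxin modes**: the run starts at the uniform reaction
  equilibrium (R_a = b/r, R_i balancing activation) with 1% multiplicative
  noise (seeded). This is the standard protocol for probing instability of
  the homogeneous state and lets several peaks nucleate simultaneously. A
  cold start instead funnels all substrate into whichever peak fires first,
  which then overshoots and collapses in a birth–death cycle rather than
  reaching equilibrium.

Two linear-analysis facts organize the constant-auxin behavior. First, the
well-mixed reaction system crosses a Hopf bifurcation at A ≈ 1.09, so all
three study levels (1.1, 1.2, 1.3) sit in the oscillatory regime of the
homogeneous mode. Second, the dispersion relation of the uniform state has
its fastest-growing *stationary* mode at wavelength ≈ 11.5 length units.
Consequences, verified numerically:

* On the default 10-unit cell (shorter than that wavelength) constant-auxin
  runs never reach a steady state: single peaks fire, overload their
  substrate supply and collapse in a relaxation cycle. These runs return
  their final state flagged `converged=False`.
* On an elongated 20 × 2 cell the stationary patterned branch exists and
  the runs converge: level 1.1 relaxes to a uniform low-activation state
  (no patch — the boundary degradation pulls the background below the Hopf
  point), and levels 1.2 and 1.3 lock a single interior peak. This
  20 × 2 cell is the geometry used for the constant-auxin regime tests.
* A state with *several* coexisting peaks could not be stabilized at any
  auxin level: the inactive-ROP screening length √(D₂/uptake) ≈ 9 units is
  comparable to the selected peak spacing, so substrate competition always
  coarsens the pattern to one peak (checked with seeded two- and three-peak
  initial conditions and noise up to 20%, on cells up to 40 units). The
  multi-peak regime reported for high constant auxin is therefore outside
  what this implementation of the reference rates reproduces; a cell long
  enough to decouple several peaks would be far too long to also reproduce
  the ~20% auxin gradient.

Peak *positions* in constant-auxin runs depend on the noise seed; only
counts and coarse position are meaningful.

### 1.6 Patch detection

Compartments with R_a ≥ 0.5·max(R_a) are clustered by adjacency. A cluster
counts as a patch only if max(R_a) ≥ 2× the area-weighted mean — a
near-uniform field has no patch, which distinguishes the low-activation
1.1 regime from true patterning. The dominant peak (largest integrated
R_a) defines the basal offset (centroid x / length) and the signed lateral
offset ((centroid y − midline)/width).

## 2. Wall-patch mechanics

### 2.1 Model

A 20 × 20 μm, 0.5 μm thick, initially flat wall patch with fully fixed
edges, loaded by turgor minus 1 atm (0.101325 MPa exactly) applied as a
follower pressure (always normal to the deformed surface). A central
circular region (default radius 2 μm) can differ in Young's modulus
(70/100/130 MPa; ν = 0.2 throughout) and turgor (0.2 vs 0.4 MPa). The
material is Saint Venant–Kirchhoff: S = λ tr(E) I + 2μ E with Green–Lagrange
strain E and second Piola–Kirchhoff stress S; E_Y = μ(2μ+3λ)/(λ+μ),
ν = λ/(2(λ+μ)).

### 2.2 Discretization

Geometrically nonlinear membrane kinematics on bilinear quadrilaterals
(2×2 Gauss) or linear triangles (1-point): the mid-surface deformation
gradient is a 3×2 map, E = ½(FᵀF − I) in the reference plane, and the
through-thickness response is plane stress (λ → 2λμ/(λ+2μ)). The membrane
alone has zero out-of-plane stiffness in the flat state, so a linear
Reissner–Mindlin bending term at the physical thickness (selective reduced
integration on the shear, correction factor 5/6) is added about the flat
reference. It regularizes the load onset, supplies the correct
small-load clamped-plate limit, and contributes little at working loads
(h/L = 0.025; deflections ≈ 2 μm are membrane-dominated). Reported stresses
are mid-surface membrane stresses; Cauchy stress is the push-forward
σ = (1/J) F S Fᵀ on the deformed tangent plane.

The default mesh is a structured 40 × 40 quad grid with region labels by
centroid; an optional conforming mode splits circle-crossing quads into
triangles. Quadrupling the element count changes the maximum deflection and
the stress ratio by under 2%.

### 2.3 Solver

Ten equal load increments with full Newton iterations (relative residual
10⁻⁸, nonsymmetric tangent including the follower-pressure term, sparse LU);
on divergence the increment is halved. Deterministic for a fixed mesh. Two
independent identities check the assembly: internal forces equal the
finite-difference gradient of the total strain energy, and the total
follower force equals the pressure times the surface vector area — which,
with a clamped boundary, is fixed at p·A·ẑ for any deformation.

### 2.4 Stress-pattern classifier

At sample points outside the modified region, the Cauchy tensors of
elements within one element size of the point are averaged; the radial
direction from the patch center is projected onto each element's deformed
tangent plane (the circumferential direction is horizontal by construction),
giving σ_rr/σ_θθ. Ratio > 1 ⇒ radial (star-like) pattern, < 1 ⇒
circumferential. Using the flat radial direction instead would
underestimate σ_rr by the surface tilt and bias the classifier.

Two sample points are used — on the +x axis and the +45° diagonal, at
patch_radius + 1.0 μm — and their mean is the classifier. The square domain
is not axisymmetric: σ_rr/σ_θθ of the *homogeneous* patch reads ≈ 1.1 on the
axes and ≈ 0.95 on the diagonals at this distance, so a single point
inherits that background anisotropy while the axis/diagonal mean sits near
1.07. The offset of 1.0 μm was chosen (radius and sampling location are
free parameters of the analysis) because the resulting classifier reproduces
the full qualitative scenario matrix: soft → circumferential (0.93),
stiff → radial (1.17), doubled inner pressure → radial (1.17), doubled
pressure + soft → radial (1.03, the threshold case), doubled pressure +
stiff → strongest anisotropy (1.28). Absolute ratio values depend on these
sampling conventions and are not comparable across implementations; only the
sign structure and the monotonic trends are.

### 2.5 Sweeps

The modulus sweep varies the inner-region stiffness at fixed 0.2 MPa turgor
(default grid 60–140 MPa); the pressure sweep varies inner turgor from 0.2
to 0.4 MPa with a softened (70 MPa) center. Both ratio curves are
monotonically non-decreasing and cross 1 exactly once: near E_inner ≈ 85–90
MPa (slightly below the 100 MPa background because of the residual square-
domain anisotropy noted above), and within the 0.2–0.4 MPa pressure range.

## 3. What the synthetic geometry does and does not emulate

The generators produce the study's two idealized domains: a flat rectangular
cell surface with polygonal compartments, and a flat square wall patch. They
emulate compartment-size heterogeneity, basal/apical source–sink zoning, and
a circular modified region with region-wise material/load contrast. They do
not emulate root curvature (a cylindrical shell would add a baseline
circumferential bias at tissue scale), real cell outlines, wall-thickness
variation, anisotropic (fiber-reinforced) wall material, or any coupling of
the ROP field into the mechanical patch. Passing tests therefore support
the internal consistency of the models and the reproducibility of the
reported regimes, not quantitative predictions for real walls.

## 4. Problem sizes and tolerances used in the shipped tests

The test suite integrates chemistry on the default 286-compartment cell
(and a 60-compartment cell for operator-level checks), solves mechanics on
40×40 meshes for scenario classification and on 24×24 meshes for the
7-point sweeps, and verifies mesh convergence against a 20×20 solve. These
sizes keep a full run to a few minutes while leaving every assertion's
tolerance (gradient ±5 percentage points; classification against the ratio-1
threshold; conservation to 10⁻¹⁰; energy consistency to 10⁻⁴; plate limit to
5%) comfortably away from discretization error.

## 5. Known limitations

* The bending regularization is linear about the flat reference, so bending
  boundary layers near the stiffness discontinuity are only approximate;
  membrane stresses, which the conclusions rest on, are insensitive to this.
* SVK is the stated material model; at ~5–8% strain it differs from
  hypoelastic formulations used by general-purpose FE codes at the few-
  percent level, which shifts the absolute threshold locations but not the
  qualitative matrix.
* Constant-auxin peak layouts are noise-seeded; only counts are stable.
* The discrete patch is 1–3 compartments wide at the reference rates, so
  within-lattice patch positions are pinned; the symmetry reduction (not a
  finer lattice) is what fixes the lateral position. The basal offset of the
  gradient patch similarly reflects lattice-scale equilibrium between the
  auxin bias and boundary degradation.
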