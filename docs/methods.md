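# Methods

## Physical model

A microdrop of culture medium under oil is treated as a bounded 2D Stokes
domain: a circular no-slip wall of radius `R` (the water/oil contact line)
containing rigid bodies — disks for microcolonies, capsules (rectangles
with semicircular caps) for rod-shaped bacteria. Because the Reynolds
number of the system is ~1e−6, inertia is dropped entirely and every body's
propulsion force is balanced by hydrodynamic drag at all times; computing
drag at a measured speed therefore *is* computing the propulsion force.
The governing equations are

    ∇p/ρ − ν ∇²u = f,   ∇·u = 0   in the fluid,
    u = 0 on the drop wall,  u = V_n + ω_n × r on body n.

Assumptions inherited from the experimental setting: the flow is
two-dimensional (all motion is surface-associated); the drop wall is a
rigid no-slip boundary (no oil-phase coupling); body rotation is
negligible and mobility solves release translations only; bodies never
touch (finite separation). Fluid defaults are a dilute aqueous buffer,
ν = 1e−6 m²/s and ρ = 1000 kg/m³; since Stokes drag is linear in the
dynamic viscosity μ = ρν, any correction is a single multiplicative
factor.

**2D force normalization.** A 2D solver produces force per unit depth.
Reported newtons multiply by a configurable slab depth `depth_scale_um`
(default 1 µm). Absolute published forces for this system depend on an
unstated depth convention, so the package treats per-depth values as
primary, refuses to mix chains computed under different depths, and
documents that absolute forces are reproducible only up to this
normalization. The net force percentage is a ratio of two forces computed
under the same normalization and is exactly invariant to it (and to
viscosity).

## GMLS discretization

The fluid is discretized by scattered collocation nodes. Around node `i`,
a field ψ sampled at neighbors `j` (all nodes with `r_ij < ε_i`,
`ε_i = 3 h_i` by default with `h_i` the local spacing) is approximated by
the polynomial of total order `r` (default 4) minimising
`Σ_j (ψ_j − P(x_j)ᵀc)² W_ij` with `W(r) = 1 − (r/ε)⁴`. Derivatives of the
reconstruction at the node give consistent stencils of order
`r + 1 − |α|`. Local problems are shifted to the node and scaled by ε
before solving — raw monomials at physical coordinates would be
catastrophically ill-conditioned — and solved by Cholesky factorization of
the Gram matrix, with degenerate neighbor geometries (e.g. collinear
clouds) reported together with the condition number.

Velocity uses a **divergence-free vector polynomial basis**, built as
curls of scalar stream monomials of degree 1..r+1. In 2D every
solenoidal polynomial field is such a curl, so the construction spans the
complete space (dimension 9 at order 2, 20 at order 4) and every element
is exactly divergence-free — the package's discrete incompressibility is
the identically-zero divergence of these local reconstructions, reported
alongside an independent scalar-stencil divergence of the nodal field
(which converges at O(h^{r−1}) like any derivative of the error and is a
diagnostic, not an identity).

### Discrete system

Unknowns are nodal velocities and the kinematic pressure `q = p/μ`.
A sparse weighted least-squares system collects, at every node:

* the two momentum components (divergence-free velocity Laplacian stencils
  plus scalar pressure-gradient stencils), scaled by `h²`;
* a continuity row from independent scalar stencils, scaled by `h`;
* a **pressure-Poisson row** `∇²q = ∇·f` — the divergence of the momentum
  equation under incompressibility. This is an exact consequence of the
  PDE, not a stabilizer in the consistency sense; without it the pressure
  modes that the momentum rows control only weakly grow under refinement,
  with it both velocity and pressure converge at ≈4th order;
* Dirichlet rows on boundary nodes; a single pressure pin (re-centered to
  zero mean afterwards) keeps the normal equations sparse.

The normal equations are factorized once per geometry (SuperLU) and reused
for every boundary-condition set — resistance-matrix columns, linearity
sweeps and mobility solves are additional triangular solves only. One
step of iterative refinement recovers the digits the squared conditioning
of normal equations costs. Mobility mode solves unit-velocity resistance
problems for each free body, assembles the translational resistance
matrix, and solves for the force-free velocities (torque balance is not
imposed; rotation is frozen by assumption).

### Node generation

Interior nodes come from a quadtree driven by a spacing field: a base
spacing (snapped to the dyadic cell ladder) refined inside circular
patches with linear grading 0.2 away from each patch. Narrow gaps between
bodies or between a body and the wall automatically receive patches with
local spacing at most half the gap, sized to cover the lubrication zone
(~√(r·gap) along the surfaces). Boundaries are sampled at the requested
arc spacing — uniformly in angle (even counts) where the spacing field is
constant, so mirror-symmetric scenes discretize mirror-symmetrically — and
two rings of boundary-fitted fluid nodes at offsets 0.8h and 1.6h line
every wall; these rings give boundary-adjacent stencils locally structured
support and reduce off-center force errors by roughly an order of
magnitude at fixed spacing. Per-node supports grow individually until the
neighborhood floor (1.5× the basis dimension) is met.

### Forces and adaptivity

Tractions integrate `σ·n`, `σ = −qμI + μ(∇u + ∇uᵀ)`, over the body
outline with the trapezoid rule on quadrature points whose fields come
from local reconstructions; the point count doubles until the force
changes by <0.1%. The adaptive loop marks nodes by a recovered-gradient
jump indicator (Dörfler fraction 0.3), spawns half-spacing patches at
marked nodes, regenerates the node set and re-solves; exhausting the
iteration budget raises an error carrying the last estimate.

### Validation surface

* **Eccentric rotating cylinders.** The analytic oracle represents the
  stream function in Goursat form `ψ = Re(z̄φ + χ)` with Laurent series in
  the coaxal Möbius variable (the conformal image in which the two circles
  are concentric) plus the paired Stokeslet logarithms; coefficients are
  fixed by least squares on boundary points placed uniformly in the image
  plane, with the mode count raised until the boundary residual is
  ~1e−12. Because the true solution lies in the basis span, this is the
  exact classical solution evaluated through a convergent series, coded
  entirely independently of the solver. The numeric drag matches it to
  ≤0.7% for minimum gaps from r₁/2 down to r₁/20 at the default benchmark
  resolution.
* **Manufactured solutions.** A smooth divergence-free field with
  manufactured forcing on the unit disk gives observed convergence order
  ≈4.1 for the order-4 basis. (Low-order configurations superconverge
  past their nominal estimates on quasi-uniform clouds — order ≈3 for the
  order-2 basis — as symmetric stencils cancel the leading error term.)
* **Reciprocity.** The two-disk translational resistance matrix assembled
  column-by-column from tractions is symmetric to ~4e−5 on a graded node
  set (base spacing R/64, near-body patches at half that).

## Force-balance chain (NFP)

`F_Stroking = F_Gliding · πW/(4L)` assumes force generation proportional
to the substrate contact area carrying the motility adhesins; no drag
anisotropy correction is applied. The canonical cell is L = 6.7 µm with
W = 0.716 µm, the width back-solved so the contact ratio reproduces the
published stroking/gliding force pair. Base-cell counts come from one of
three models: the measured power law `N = 0.2 D^1.36`, constant areal
density `N = nπ(0.48·D/2)²` (n = 0.25 cells/µm², i.e. 4 µm² per base
cell, resolved from the fitted curve at D = 10 µm), or constant linear
density `N = 0.25 D` — the last predicts size-independent colony speed
(`v ∝ N/D`) and is ruled out by the observed positive size–velocity
correlation. Uncertainty propagation is deliberately minimal: only the
colony-speed sd enters (linearly, via the drag law); `F_Stroking` and
`F_Max` are treated as exact. Printed-precision comparisons use half-up
rounding. The published force spread (±4.79 fN) is slightly below exact
linear scaling of the speed sd (±5.0 fN); when it is supplied directly
the chain reproduces the published ±25.4% on the NFP.

## Image quantification

Segmentation builds two masks per frame — gamma 0.7 → invert → rolling-ball
background subtraction → Gaussian (σ = 2 px) then 3×3 mean filter → Otsu
threshold, and the same without gamma with subtraction in light-background
mode — and ORs them, which makes the component count robust to contrast
polarity; the thresholded foreground is taken as the minority class.
Rolling-ball subtraction operates on a 0–255 intensity scale (the radius
convention couples intensity and pixel units) and uses the classic
downscale approximation for large radii. Components below D = 10 µm
(single cells, not colonies) and centroids outside the circular ROI are
dropped. Tracking is frame-to-frame linear assignment under a gating
distance; a colony that disappears while overlapping a linked colony is a
merge parent (splits are the converse), and event steps are excluded from
displacement statistics rather than zero-filled, which removes the
center-of-mass jumps merges would otherwise inject. Merge/split detection
uses centroid/diameter disk overlap with a 30% area-consistency slack.
Weighted time series use equivalent sphere volumes as weights; empty
frames report missing values, never zeros. The uncoupler-experiment table
keeps components strictly above 1000 px² (≈ D > 37 µm at 1.04 µm/px).
Base-cell counting follows rolling-ball subtraction → contrast stretch
saturating 3% of pixels → h-maxima at a user-supplied prominence (it is
image-specific by design) restricted to the base region (inner circle of
diameter 0.48·D); spots closer than the suppression distance merge into
one maximum. Power-law fits are OLS on log-log axes (the spreadsheet
convention), with a nonlinear least-squares variant for comparison.
Orientation statistics weight neighbors within 9.8 µm by
`1 − distance/radius` and average the acute relative angle (0–90°).

## Synthetic data

The generators are pure functions of (spec, seed), bit-reproducible, and
emulate: dark colony disks (sigmoid edges, Gaussian noise, default
SNR 8) that grow linearly, drift in persistent random directions with
speed `v = c·D^0.5` anchored at (50 µm, 0.031 µm/s) times multiplicative
noise, and merge on schedule (partners are initialized nearby and steered
to stay just separated until the merge frame, so the merge is the only
discontinuity); bright base-cell spots (Gaussian, σ 0.6 µm, ≥3 µm apart at
0.25 µm/px) with Poisson or exact counts from a scaling law, confined to
the 0.48·D base circle; colony speeds as normal draws clipped at zero
(clipping keeps the sample mean within 0.001 µm/s of 0.031, which
rejection sampling would not); and rod-cell fields with aligned, uniform
or von Mises-clustered orientations around a mean length of 6.7 µm.
The speed–size exponent and image-noise model are fixture choices, not
measurements; what closure tests demonstrate is parameter recovery from
data with the assumed structure — uneven illumination, focus drift and
cell-scale texture of real movies are out of scope.

## Problem sizes and numerical defaults

Tests and the benchmark run at deliberately moderate sizes chosen to sit
well inside the asymptotic regime while staying desk-scale: the
convergence study uses unit-disk spacings 0.2/0.1/0.05; the benchmark
uses base spacing 0.0156 (in units of the outer radius 0.5) with gap
patches at one fifth of the gap; the reciprocity check uses ~18k nodes;
the gliding scene (8 capsules, 18-µm drop) uses 0.56-µm spacing (~5k
nodes). The stochastic exponent-recovery check uses the 100-colony,
uniform-diameter design throughout. Linear-solver tolerance is the
SuperLU factorization plus one refinement step, rejected if the relative
normal-equation residual exceeds 1e−6.

## Known limitations

* Collocation least squares is not variational: reciprocity and
  symmetry hold only to discretization accuracy, and the quoted symmetry
  requires the graded configuration above.
* The narrow-gap benchmark error (~0.6%) is dominated by the lubrication
  pressure; spacing-field grading steeper than ~0.2 degrades it markedly.
* Mobility mode balances forces only (rotation frozen), per the
  negligible-rotation assumption.
* The time-lapse generator's merge kinematics are scripted, not physical;
  merge detection is validated against that script, not against real
  coalescence dynamics.
* Absolute forces in newtons depend on the 2D depth normalization; only
  per-depth values and normalization-invariant ratios (NFP) are
  quantitative.
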