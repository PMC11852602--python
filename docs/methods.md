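# Methods

## Scope and state variables

`osteostim` evolves, per tetrahedral element of an implanted proximal femur,
the coupled state (porosity P, apparent density ρ, Young's modulus E) under
daily mechanical loading, with an optional electro-stimulation layer. The
couplings ρ = (1 − P)·ρ₀ and E = 3790·ρ³ (MPa, ρ in g/cm³) are enforced
simultaneously on every bone element after every update; implant elements
carry a fixed modulus (default 110 GPa, titanium-alloy class) and no density
state. Units throughout: mm, N, MPa, g/cm³, days, volts.

## Material mapping

CT numbers map linearly to density between configurable bounds,
ρ = ρ_a + (ρ_b − ρ_a)(HU − HU_min)/(HU_max − HU_min). The bounds are not
physical constants of the model; the defaults ρ_a = 0.1, ρ_b = ρ₀ = 1.8 g/cm³
over HU ∈ [0, 1700] span the usual apparent-density range of femoral bone and
keep the cubic modulus law in its calibrated regime. Densities are quantized
once, at initialization, to 50 equal-width levels (the "material gradient");
binning is not re-applied during remodeling. Elements at or above
1.3 g/cm³ are classed cortical, below it cancellous; the class selects the
BMU timing constants and is frozen at initialization. Porosity is clamped to
[0.01, 0.99] so stiffness and specific surface stay strictly positive.

## Static elasticity

Small-strain isotropic elasticity on 4-node (default) or 10-node tetrahedra;
quadratic elements use a 4-point Gauss rule, which integrates their
stiffness exactly for straight-sided elements, and are sub-parametric
(Jacobian from the corner nodes). The distal cut plane ("base") is fully
fixed; joint and muscle forces are applied as uniform tractions over named
boundary patches so that the resultant equals the prescribed force vector —
point loads would put stress singularities into the element-wise remodeling
stimulus. Angles are measured from the proximal shaft axis in the coronal
plane; the joint force is compressive, the muscle force tensile, and
negative angles flip to the opposite side. Element stress is the
volume-averaged tensor; sorted eigenvalues give principal stresses and the
von Mises equivalent σ̄ = sqrt(((σ₁−σ₂)² + (σ₂−σ₃)² + (σ₃−σ₁)²)/2).
Systems are solved by direct sparse LU with a relative-residual guard of
1e-8; the base reactions balance the applied loads to the same tolerance.
Verification: constant-stress patch test (exact to solver tolerance on tet4
and tet10), slender-cantilever tip deflection within 0.2% of
P·L³/(3EI) at the shipped refinement (asserted at 5%), monotone strain-energy
convergence under refinement.

## Daily stimulus and BMU kinetics

The three load cases enter the daily stimulus as a cycle-weighted power
mean, Φ = (Σⱼ nⱼ σ̄ⱼᵐ)^{1/m}, m = 4, n = (6000, 2000, 2000). The reference
stimulus Φ₀ is computed element-wise from the *intact* femur solved under
the same three cases, transferred to the implanted mesh by nearest-centroid
matching (exact on the shared-grid fixtures) and floored at 1e-6 MPa;
unmatched bone elements fall back to their own implanted-model stimulus, so
they sit at equilibrium rather than in spurious disuse. Disuse raises the
BMU activation frequency through the sigmoid
f_a = f_a,max / (1 + exp((Φ/Φ₀ − κ_D1)/κ_D2)), κ_D1 = 0.5, κ_D2 = 0.1,
f_a,max = 0.1 BMU/(mm³·day): at equilibrium f_a = f_a,max/(1+e⁵) ≈ 6.69e-4,
under total disuse f_a → f_a,max/(1+e⁻⁵) ≈ 9.93e-2. The exponent is clipped
at ±700 and saturates cleanly to the limits.

BMUs initiate on internal surfaces, so the daily activation density is
f_a·S_r(P) with the quintic specific surface
S_r = 32.1P − 93.9P² + 134P³ − 101P⁴ + 28.8P⁵ (mm²/mm³, zero at P = 0 and
P = 1). Each element keeps a ring buffer of daily f_a·S_r values of length
T_R + T_I + T_F for its bone class (cortical 24/8/64, cancellous 60/57/197
days). The resorbing population N_R is the sum over the most recent T_R
entries, the refilling population N_F the sum over entries aged
(T_R+T_I, T_R+T_I+T_F]; both are plain windowed sums with Δt = 1 day, and
the gathered windows are summed in chronological order on C-contiguous
copies so the result is bit-identical to a brute-force sliding-window
oracle. The porosity rate is dP/dt = Q_R·N_R − Q_F·N_F (positive = bone
loss), integrated by forward Euler with Δt = 1 day — the natural step given
day-valued stage durations. Q_R follows the simplified BMU geometries:
cortical cylinder Q_R = π d_o² v/4 ≈ 3.1416e-4 mm³/day (d_o = 0.2 mm), and
cancellous semi-elliptic groove Q_R = π d_e d_BMU v/4 ≈ 2.5525e-4 mm³/day
(d_e = 0.05, d_BMU = 0.65 mm), with v = 0.01 mm/day. The refilling rate is
closed by the equilibrium balance Q_F = Q_R·T_R/T_F, so a constant history
gives dP/dt = 0 exactly. Histories are pre-filled with the equilibrium value
f_a(Φ₀)·S_r(P(0)): the skeleton is assumed at remodeling equilibrium before
surgery, and a run driven at Φ = Φ₀ holds every density to machine
precision for 300 days.

The stress field is re-solved on the current modulus field every
`fe_update_interval` days (1 by default; the shipped scenario runs use 5,
which changes neck-mean trajectories by well under the day-to-day rate
scale while cutting cost fivefold).

## Electro-stimulation layer

Bone is treated as an anisotropic dielectric, ∇·(β∇φ) = 0 with
β = diag(β₁₁, β₁₁, β₃₃) in a frame whose third axis is the shaft axis
(β₁₁ = 88.54e-12 F/m, β₃₃ = 106.248e-12 F/m). A 32 V electrode band on the
lateral neck surface and ground on the distal cut are Dirichlet conditions;
everything else is zero-flux. This is a permittivity boundary-value problem,
not a conduction problem — the formulation is kept exactly as stated, and
the physical ambiguity is noted rather than resolved. The implant is given
the bone dielectric by default since its electrical role is unspecified.
One static solve per configuration is reused for all days: the dielectric
does not depend on the remodeling state. The element-mean potential is
rescaled to φ̂ ∈ [0, 1] (highest potential → influence 1, lowest → 0), and
inside the stimulation window the activation frequency becomes
f_a,eff = f_a·(1 − A·φ̂), A ∈ [0, 1]. This single-channel reduction —
stimulation suppresses BMU *activation*, entering resorption and refilling
through the shared history — reproduces the reported qualitative behavior:
the density rate rises as soon as the window opens (resorption responds
within T_R days, refilling only T_R + T_I days later), the density can
transiently *increase* at high amplitude, and the rate returns negative
after cessation. Whether stimulation should act asymmetrically on resorption
versus refilling is unknown; the symmetric choice is a documented model
decision, not a claim about mechanism.

Verification: 1-D slab gives the linear profile exactly; a two-layer slab
reproduces the closed-form voltage divider with gradient ratio β₃₃/β₁₁;
rotating mesh and material axis together leaves the solution unchanged; the
discrete solution respects the maximum principle on all fixtures.

## Fixtures

Patient geometry is unavailable, so the femur is parametric: a shaft
(outer radius 14 mm, marrow canal radius 7 mm, length 80 mm), a neck of
radius 11 mm and length 40 mm at 55° from the shaft axis, and a spherical
head of radius 17 mm. Implicit solids are sampled on one structured
tetrahedral background grid (6 tets per cell, Kuhn split); an element is
kept if its centroid is inside the solid, and the largest *face-connected*
component is retained — voxel sampling otherwise leaves element islands and
single-node hinges that would make the stiffness singular. The implanted
variant removes the head and fills the canal and neck core with a stem
(radius 6 mm, length 60 mm) ending in a 10 mm ball that receives the joint
load. Because both variants are carved from the same grid, their common bone
elements coincide exactly; nearest-centroid matching (capped at 25% of the
local element size, unmatched elements excluded from ratio statistics) is
therefore exact on fixtures while remaining well defined for independently
meshed models. The synthetic HU field has three plateaus — cortical shell
(elements within 4 mm of the outer surface), cancellous interior, marrow
canal — with optional clipped Gaussian noise; it emulates the gross density
architecture of a CT-derived femur but none of its anatomical detail
(trabecular orientation, cortical thinning, metaphyseal gradients), so tests
passing on it validate the *machinery and the model's qualitative dynamics*,
not patient-level predictions. The shipped scenario runs use a
~6000-element target (5990 elements implanted), the package's default desk
scale; results at 3000 and 6000 targets agree qualitatively.

## Shielding analysis

Per matched bone element and load case, r = σ̄_implanted/σ̄_intact; elements
with intact stress below 1e-6 MPa are excluded and counted separately.
Histograms use width-0.1 bins on [0, 2] plus an overflow bin; bins are
(lo, hi] with the first bin closed at zero, so the "shielded fraction"
r ∈ [0, 1] is exactly the sum of the first ten bins and a ratio of exactly 1
counts as shielded. On the fixture pair the neck is strongly shielded (mean
ratio far below the shaft mean, and a clear majority of neck elements below
1) while distal shaft elements often exceed 1 — the stem hands its load back
to the shaft. The printed fractions depend on the parametric geometry and
are not comparable to patient-specific values.

## Known limitations

- Forward Euler with Δt = 1 day is first-order; the BMU stage durations set
  the time scale, and halving Δt changes 300-day trajectories only in the
  third decimal, but stiff parameter choices (very large f_a,max·S_r) would
  need a smaller step.
- The disuse sigmoid uses the printed numeric constants; the unit of
  f_a,max (BMU/(mm³·day)) is dimensionally awkward next to the surface
  factor S_r (mm²/mm³) — the product f_a·S_r is treated as a BMU activation
  density per day, and the values are used as printed rather than rescaled.
- Bonded bone–implant interface (shared nodes); no contact, micromotion, or
  fatigue.
- Isotropic elasticity and a scalar density state; no anisotropy, no
  mineralization dynamics, no strain-rate effects.
- The stimulation coupling is phenomenological; amplitudes are dimensionless
  fractions of full activation suppression, not electrode currents.
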