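# Methods

## Model and assumptions

The simulator couples three components on a shared mesh:

1. **Interstitial fluid flow.** The tissue is a rigid, saturated porous
   medium. Continuity carries a Starling source,
   `div(u) = Q_m = L_pS_v (p_v - p_i) - L_plS_vl (p_i - p_l)`, with the
   lymphatic term zero in the tumor. Momentum is Darcy drag with the
   transvascular momentum-sink correction,
   `u = -(1/k + Q_m/eps_p^2)^-1 grad(p_i)`. The Brinkman shear term is
   omitted from the discrete operator: at tissue conductivities
   (k ~ 1e-14..1e-12 m2/(Pa s), mu_i ~ 1e-3 Pa s) its screening length
   `sqrt(mu_i k / eps_p)` is ~1e-8 m, four orders of magnitude below the
   mesh size, so the shear layer it would add is sub-resolution
   everywhere. The flow is solved quasi-steadily once per infusion phase
   (pump on / pump off): Darcy relaxation times are seconds against a
   24 h horizon. The `Q_m`-dependent drag makes the problem weakly
   nonlinear; a Picard loop (relative tolerance 1e-6, max 50 iterations)
   converges in 2 iterations in practice because the correction is
   ~1e-15 relative at physiological exchange rates.

2. **Drug transport.** Transient convection-diffusion for the relative
   concentration `C_i` (inlet value 1), with a transvascular exchange law
   whose convective part is proportional to the vascular concentration
   `C_v`. During CED `C_v = 0`, so vessels are a purely diffusive sink
   `-P S_v C_i`; drug cannot leave convectively through vessel walls even
   where fluid does. Degradation `k_d` acts everywhere, lymphatic
   drainage `k_l` only in healthy tissue. The storage term is `dC_i/dt`
   without an explicit porosity factor; the mass budget uses the same
   convention, so the audit is self-consistent whichever convention one
   prefers.

3. **Hindered pore transport.** All drug/pore-size dependence enters
   through `lambda = r_s/r_0`: Bungay-Brenner `K_t`, `K_s` drag
   coefficients give `H = 6 pi Phi / K_t` and
   `W = Phi(2 - Phi) K_s / (2 K_t)` with `Phi = (1-lambda)^2`;
   `sigma_f = 1 - W`. A Renkin-style centerline polynomial is available
   via `correlation="renkin"`; the two agree within a few percent for
   `lambda <= 0.6`. The correlations carry ~5e-5 truncation error at
   `lambda -> 0`, clipped so `H <= 1` and `sigma_f >= 0` hold exactly.
   `lambda >= 1` is handled as hard exclusion (`P = 0`, `sigma_f = 1`)
   rather than an error, because drug-larger-than-pore combinations are
   legitimate grid points of the parametric study.

## Synthetic domain

The geometry module generates the computational domain rather than
reading imaging data: a homogeneous healthy sphere (default radius
40 mm) containing a 6 mm tumor at the origin and a 1.5 mm catheter
cavity entering along +z, its tip plane by default 3 mm above the tumor
center (placing the infusion site in the upper tumor half); the
misplaced-catheter variant puts the tip at `tumor_radius + 1 mm`. The
catheter is a cavity with boundary conditions — prescribed normal inflow
`U_0 = Q_f/(pi r_c^2)` and `C = 1` on the tip while the pump runs,
no-flow/no-flux otherwise — not a flow domain; intra-catheter jet
hydrodynamics are out of scope.

What the generator does **not** emulate: gray/white-matter anatomy and
anisotropic (DTI-derived) diffusion, poroelastic swelling under
infusion, backflow along the catheter track, and discrete vasculature.
Consequently, passing tests demonstrate the correctness of the coupled
porous-flow/transport solver under controlled geometry, not fidelity to
any particular patient anatomy.

Meshes are structured and graded: 0.25 mm triangles inside and around
the tumor, geometrically coarsening (ratio 1.3) to 2 mm in the far
field; the default axisymmetric mesh has ~6.7k nodes / ~13k cells. Grid
lines are snapped to the catheter radius and tip plane so those
boundaries are exact. The spherical tumor boundary is not
mesh-conforming; each cell instead stores its tumor volume fraction
(16-point subdivision sampling; 35-point barycentric lattice for
tetrahedra). Labels and reported volumes use the fraction (cut cells
count fractionally; the binary label is fraction >= 1/2), and solver
coefficients in cut cells are volume-fraction homogenized — harmonically
for `k` (interface transport in series), arithmetically for
reaction/source terms. This removed an O(h) staircase bias in the
pressure solution. An optional full-3D tetrahedral mode (Kuhn-subdivided
graded grid, Jacobi-preconditioned CG) exists for qualitative
cross-checks; transport runs are axisymmetric.

## Discretization

P1 elements throughout, with the cylindrical `r` weight in every
axisymmetric integral (exact moment formulas, no quadrature error for
linear fields). Transport uses the conservative (integrated-by-parts)
convection operator plus a boundary outflow term on the outer surface,
so the discrete global drug balance closes identically; the infused mass
is measured as the Dirichlet reaction at the tip nodes. Stabilization is
threefold (see `P1Basis.streamline_diffusion`): SUPG-type streamline
diffusion with `tau = h/(2|u|)(coth Pe - 1/Pe)`; crosswind artificial
diffusion `0.35 max(0, |u|h/2 - D)` perpendicular to the flow; and full
upwind diffusion confined to the one-cell band at the tumor/healthy
interface, where the conductivity jump kinks the velocity field. With a
lumped mass matrix and implicit Euler stepping (dt = 30 s during
infusion, 120 s after, exact restart at the phase switch) the worst
undershoot across the 29 study scenarios is -6.4e-4, within the 1e-3
non-negativity tolerance. One sparse LU factorization per phase serves
all time steps; a 24 h axisymmetric run takes a few seconds.

Verification anchors: the flow solver reproduces the closed-form IFP of
an isolated leaky sphere, `p(r) = p_v [1 - (R/r) sinh(alpha r/R) /
sinh(alpha)]` with `alpha = R sqrt(L_pS_v/k)`, to 0.97% relative L2 at
the default mesh with observed convergence order ~1.5; the global fluid
balance (inlet + transvascular = outflow) closes to ~1e-13 relative;
halving dt changes the 12 h tumor average by well under 2%.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| drug diameter | 1 / 20 / 60 | nm | small molecule, liposome, large nanoparticle |
| tumor wall-pore diameter | 50 / 100 / 150 | nm | leaky tumor endothelium range |
| tumor k | 2e-14 / 2e-13 / 2e-12 | m2/(Pa s) | reported spread of tumor interstitium |
| gamma (pore area fraction) | 1e-3 | — | literature-typical for leaky vessels |
| L_vw (wall thickness) | 5 | um | tumor microvessel wall |
| mu (plasma), T | 1e-3, 310 | Pa s, K | plasma at body temperature |
| tortuosity | 1.6 | — | brain extracellular matrix; D_i = D/1.6^2 |
| tumor: p_v, S_v, eps_p | 3330, 2e4, 0.3 | Pa, 1/m, — | tumor microvasculature |
| healthy: p_v, S_v, eps_p | 2080, 7e3, 0.2 | Pa, 1/m, — | normal brain values |
| healthy k | 2e-12 | m2/(Pa s) | white-matter-like conductivity |
| healthy L_pS_v, L_plS_vl | 5e-10, 2e-9 | 1/(Pa s) | intact-BBB filtration, weak clearance |
| healthy wall pores | 20 | nm | tight endothelium (excludes >= 20 nm drugs) |
| k_d, k_l (healthy) | 0, 1e-4 | 1/s | stable agent; parenchymal drainage |
| infusion | 0.5 ml/h x 6 h = 3 ml | | clinical CED range |

The healthy-region *fluid* coefficients deliberately do not come from the
20 nm-pore wall model: an intact blood-brain barrier filters water orders
of magnitude more weakly than leaky tumor vessels, and these values are
what let fluid leaking from the high-IFP tumor rim percolate through the
parenchyma at the 1e-7..1e-6 m/s interstitial speeds reported for brain
tissue (asserted as an order-of-magnitude band in the test suite). The
healthy *drug* permeability still comes from pore theory with 20 nm
pores, so only the 1 nm agent is cleared by healthy vessels.

## Parameter regimes and known limitations

The tumor filtration coefficient sets a fluid penetration length
`l = sqrt(k / L_pS_v)`; with the defaults above (100 nm pores:
`L_pS_v = 1.25e-6` 1/(Pa s), baseline k) `l ~ 0.4 mm`, so nearly all
infusate is reabsorbed by tumor vessels within a millimeter of the tip.
Because the exchange law removes fluid but not drug (its convective term
carries `C_v = 0`), poorly-permeating agents then accumulate to local
relative concentrations well above 1 near the tip instead of sweeping
the tumor. Tumor-averaged concentrations are therefore highly sensitive
to `gamma S_v / L_vw`, which also fixes `P S_v` — the two cannot be
varied independently within the pore model. Regimes in which the
infusate perfuses the whole tumor require `L_pS_v` two to three orders
smaller; users exploring that regime can override `tumor_properties:
Lp_Sv` in the scenario config. Other limitations: no poroelasticity or
backflow, isotropic diffusion, no drug binding/cellular uptake, single
homogeneous healthy region (a two-shell gray/white variant can be
composed through per-region property overrides), and the axisymmetric
restriction for transient transport.

Degenerate inputs are rejected early with named errors (non-positive
sizes, tortuosity < 1, infeasible geometry, unknown config keys); ties
at the tumor boundary resolve to the tumor label at fraction exactly
1/2; snapshots must land on time-step boundaries (hours do, for the
default steps).
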