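# Methods

`mechangio` simulates vascular tumour growth as four coupled sub-models on a
shared 3D domain: reaction–diffusion biochemistry, quasi-static growth
mechanics, a discrete sprouting vascular network, and a coupled
blood/interstitial flow solve. This note records the model equations as
implemented, the parameter choices and their provenance, the numerical
decisions, and what the bundled synthetic scenarios can and cannot show.

## Domain and discretisation

The tissue is a cube of edge `L` (default 12 mm) meshed with trilinear
hexahedra, split into a tumour region Ω^T (elements whose centroid lies in a
centred sphere, default 1 mm diameter) and host Ω^H. Two opposite faces
carry the vascular inlets/outlets (Γ^V); all fields live in the reference
(Lagrangian) frame, so diffusion operators and the network's embedding are
built once on the undeformed mesh. The default grid is centre-refined
(finest edge `h_centre`, geometric coarsening outward) because the tumour
and its oxygen boundary layer (≈ 0.3 mm, see below) must be resolved by
several elements; with a one-element tumour the element-wise vascular
density ρ_v smears vessel-supplied oxygen onto the tumour boundary nodes
and growth starts far too fast. The minimum element edge must not be
smaller than the maximum tip elongation per vascular step
(v_max·Δt_v = 0.0625 mm), so that a new vascular segment never crosses an
entire element; the configuration validator enforces this.

The vascular network is a 1D graph of nodes and straight segments embedded
non-conformingly: each node stores its host element and local coordinates,
and everything exchanged between the continuum and the network (species
values, gradients, stresses, interstitial pressure) is interpolated with
trilinear weights. The initial condition is a square lattice of straight,
parallel, unbranched capillaries (spacing 0.6 mm) spanning the inlet →
outlet planes; lines that would enter the tumour are pushed radially in the
cross-section plane just outside it, so the tumour starts avascular.
Pre-existing nodes carry birth time t_g = 0 and never remodel.

## Biochemistry

Four normalised species: TAF τ (tumour angiogenic factor, a homogenised
VEGF-like signal), oxygen ξ, MMP μ (matrix metalloproteinase) and ECM
density ε. τ, ξ, μ obey reaction–diffusion equations with zero-flux
boundaries,

    dτ/dt = D_τ ∆τ + Q(ξ) − δ_τ τ,   Q = λ_τ exp(−2ξ/ξ̄) in Ω^T, 0 outside
    dξ/dt = D_ξ ∆ξ + λ_ξ ρ_v − δ_ξ ξ
    dμ/dt = D_μ ∆μ + F − δ_μ μ,      F = λ_μ-c·[X∈Ω^T] + λ_μ-v ρ_t
    dε/dt = −δ_ε μ ε   on host nodes only, floored at ε = 0.05

ρ_v ∈ {0,1} flags elements containing at least one well-perfused functional
vascular node (mean blood velocity ≥ 0.1 mm/s); ρ_t counts tip nodes per
element. TAF production is evaluated nodally (it depends on nodal ξ);
the element-valued sources λ_ξ ρ_v and F are distributed to nodes with
consistent FE weights.

Time integration is forward Euler with a row-sum lumped mass matrix. The
stiffness operator is reduced to its low-order M-matrix form (positive
off-diagonal trilinear corner couplings dropped, diagonal restored to keep
zero row sums): this keeps the explicit update conservative *and*
positivity-preserving under the step bound, at the cost of slightly more
numerical diffusion — on a regular grid it coincides with the 7-point
finite-difference Laplacian, still second order. The step size is
`min(safety·h_min²/(6·D_max), safety/δ_max, Δt_solid)` with safety 0.5; any
residual negative undershoot is clipped to zero and the run aborts if the
clipped mass ever exceeds 10⁻⁶ of the total.

Parameter defaults (all `[assumed]`, chosen once from literature scales):
D_τ = D_ξ = 8.64 mm²/day (≈10⁻⁶ cm²/s), D_μ = 0.86 mm²/day;
δ_ξ = λ_ξ = 100/day so that fully perfused tissue relaxes to the
normalisation fixed point ξ* = λ_ξ/δ_ξ = 1 and the oxygen penetration depth
is √(D_ξ/δ_ξ) ≈ 0.29 mm (the classical ~0.2–0.3 mm hypoxia length);
λ_τ = 10/day, δ_τ = 1/day gives a TAF halo of decay length ≈ 3 mm around
the tumour, reaching the sprouting threshold τ* = 0.02 at the nearest
vessels within the first day.

## Solid mechanics and growth

Deformation follows the multiplicative split F = F_e·F_g. The volumetric
growth strain is a Gompertz-type function of oxygen,

    ϑ_g(ξ) = α_g exp(−β_g exp(−γ_g ξ)) − α_g exp(−β_g),   λ_g = √(2ϑ_g+1),

and the growth tensor adds directional stretches along the *unit-normalised*
oxygen and ECM gradients:

    F_g = λ_g I + (λ_g-ξ − λ_g) n̂_ξ⊗n̂_ξ + (λ_g-ε − λ_g) n̂_ε⊗n̂_ε.

The gradients are normalised before the dyadic products because the dyad
must be a pure direction — an unnormalised gradient would make growth scale
with the squared gradient magnitude and carry the wrong units.

Two deliberate regularisations of the growth update:

* **Ratcheting.** ϑ is updated per quadrature point as
  ϑ ← max(ϑ, ϑ(ξ)) — growth is irreversible, so tumour volume never
  decreases when the hypoxic core's oxygen later falls.
* **Rate limiting.** λ_g may rise by at most `growth_rate_per_day`·Δt per
  update (default 0.16/day, i.e. ≈160 μm/day of diameter gain on a 1 mm
  seed, the tissue-interface speed the model is designed around). Without
  this cap a coarse mesh lets ξ jump at the tumour boundary and produces a
  non-physical growth shock in the first hours.

The stored-energy function is the generalised polynomial
W̄ = ζ·[c10(Ī1−3) + c20(Ī1−3)² + c01(Ī2−3) + c02(Ī2−3)² + c11(Ī1−3)(Ī2−3)]
+ κ(J−1)²/2 in the deviatoric invariants of the elastic right Cauchy–Green
tensor; only the isochoric part is scaled by the ECM integrity factor
ζ ∈ (0,1], which is identified with the ECM density ε. Defaults
(`[assumed]`, mammary-tissue scale): host c10 = 1 kPa, κ = 50 kPa; tumour
c10 = 3 kPa, κ = 150 kPa. Growth triplets: α_g = 25 (asymptotic volume gain
≈ ×150 at ξ = 1, consistent with a ~×270 volume gain over 40 days once
directional growth is added), β_g = 12, γ_g = 3 — β sets the oxygen
threshold character so growth is negligible below ξ ≈ 0.3; the directional
triplets use α = 5 with the same β, γ.

Equilibrium ∂/∂X·(F·S_ref) = 0 (no body force, quasi-static) is solved by
Newton–Raphson with a backtracking line search and automatic load stepping
on F_g. S(C_e) is the analytic derivative 2∂W̄/∂C_e; the material tangent
is built by central finite differences of the pulled-back stress wrt the
total Green–Lagrange strain (batched over all quadrature points), which
costs 12 extra vectorised stress evaluations per iteration and avoids a
long closed-form fourth-order tangent. Convergence: residual < 10⁻⁸ of its
initial scale or increment < 10⁻¹⁰. Boundary conditions: zero displacement
on the two inlet/outlet faces, traction-free elsewhere. (The source
description assigns these two conditions to inconsistently-labelled face
sets in different sections; pinning the inlet/outlet planes is the reading
implemented.)

Derived quantities for the vascular coupling: the tissue hydrostatic
pressure THP = −tr(σ)/3 with σ the Cauchy stress (positive in compression),
quadrature-averaged per element, projected to mesh nodes by volume
weighting and interpolated trilinearly at vascular nodes; the kPa → mm-Hg
conversion (×7.50062) is applied once at this interface. A configuration
flag (`cauchy_pressure=False`) selects the literal −tr(S)/3 on the second
Piola–Kirchhoff stress instead. The mechanotaxis direction t is the unit
eigenvector of the algebraically smallest eigenvalue of S, signed so that
−k_m t never opposes the tip's previous direction; an isotropic
(degenerate) stress falls back to the previous direction.

## Vascular network dynamics

Every vascular step Δt_v = 6 h:

1. **Tip extension.** Active tips (not frozen at the boundary, not
   collapsed, local τ ≥ τ*, pressure ratio p̄ < p_c) advance by
   d = v_v(R)·Δt_v·ê with ê = ℓ/‖ℓ‖, ℓ = k_τ∇τ + k_ε∇ε − k_m t; the tip
   speed v_v = v_0 + v_1 exp(−R/R̃) is clamped to v_max = 0.25 mm/day below
   R = 2 μm and capped at v_max everywhere. New nodes start at R_min,
   h_min, r_p^max. A node whose proposed position leaves the domain is
   clamped to the boundary and permanently frozen. Default weights
   k_τ = 1, k_ε = 0.2, k_m = 0.1 (`chemo_only` mode zeroes the last two).
2. **Branching.** Each eligible node draws one uniform number (consumed in
   node-id order from a single PCG64 stream, so runs are bit-reproducible)
   against P = w_A·G(age; m_A, s_A) + w_D·G(dist; m_D, s_D), where G is a
   Gaussian scaled by its mode (each component ∈ [0,1]) and dist is the
   network geodesic to the nearest degree-≥3 node (falling back to the
   nearest inlet/outlet when no branch exists). Hypo-perfused vessels use
   larger weights than well-perfused ones (0.03/0.03 vs 0.01/0.01,
   validated as an ordering constraint), making poorly perfused vessels
   bifurcate more readily. m_A = 2 d, s_A = 1.5 d, m_D = 400 μm,
   s_D = 150 μm were chosen so that simulated inter-capillary distances
   stay in the 0.1–0.8 mm range observed in tumours. A new branch takes
   the taxis direction, rotated in-plane to at least 30° from the parent
   direction, and immediately performs its first extension (a zero-length
   segment would break the flow solve).
3. **Anastomosis.** A tip within 40 μm of a functional node outside its
   own 2-hop neighbourhood fuses to the nearest such node; both ends stop
   being tips.
4. **Wall remodelling.** Post-natal nodes age on the WSS-dependent clock
   t_m(τ_f): t_m-T = 10 d at/above the threshold τ̄_f = 2.4×10⁻⁸/R mm-Hg
   (R in metres; 4×10⁻⁴ mm-Hg at R = 60 μm), rising smoothly to
   t_m-0 = 100 d at zero WSS. With t̄ = (t − t_g)/t_m: lumen
   R = R_min + (R_max−R_min)·exp(−11 exp(−4.4 t̄)) (tips stay at R_min);
   thickness rises linearly h_min → h_max over t̄ ∈ [0,1] (the monotone
   reading of the thickness law — the printed form would start at
   h_max+h_min, contradicting the stated initialisation at h_min); pore
   radius decays cubically r_p^max → r_p^min with a continuous junction at
   t̄ = 1 and stays at r_p^min beyond.
5. **Compression and collapse.** With p̄ = (p_int + p_h)/p_vsc: in
   1 < p̄ < p_c the radial strain follows the smaller root of the quadratic
   wall law p̄ = 1 + (2p_c−2)(e/e_c) − (p_c−1)(e/e_c)², and the effective
   radius is R/(1+e_r) (reversible by default; a flag makes it plastic).
   At p̄ ≥ p_c the node collapses permanently: R is scaled down by 10³,
   p_vsc pinned to 0, and the node leaves the flow system and all
   sprouting/branching. The per-node critical pressure derives from the
   wall stiffness E_w = 2(p_c−1)/e_c, interpolated linearly in the
   remodelling level between 1.3 (nascent) and 5.22 (pre-existing parents),
   i.e. p_c ∈ [1.6, 3.4] at e_c = 0.92. After every collapse pass,
   functional components that lost all paths to an inlet or outlet are
   pruned (collapsed) too — unless an anastomosis provides a second path.

## Flow

One symmetric sparse system couples all pressure unknowns. Vascular
segments carry Poiseuille conductance πR⁴/(8 μ_B L) (μ_B = 3×10⁻⁵ mm-Hg·s,
calibrated so that 8 μ_B·v/R at the 0.1 mm/s perfusion threshold equals the
τ̄_f coefficient — WSS is computed in the model's convention
τ_f = R|Δp|/L, twice the conventional Poiseuille value, and the threshold
coefficient is calibrated to that same convention, so the two are mutually
consistent). Tissue nodes connect along element edges with Darcy
conductance K_int·A_int/L, A_int = 2πR̄/S_vsc from the per-element vascular
surface density (defaults for vessel-free elements). Each functional
vascular node exchanges Starling flux K_vsc·A_vsc·(p_eff − p_int) with its
host element's vertices through a trilinear-weighted conductance star
(A_vsc = Σ 2πR·L/2 over attached segments;
K_vsc = γ_p r_p²/(8 μ_B h); p_eff = p_vsc − σ_o(π_vsc − π_int) with
σ_o = 0.82, π_vsc = 20, π_int = 15 mm-Hg). Dirichlet anchors: inlets
25 mm-Hg, outlets 10 mm-Hg, collapsed nodes 0, tissue nodes on the
inlet/outlet planes 0.1 mm-Hg. Deformed segment and edge lengths are used.
The system is solved directly (sparse LU); the residual is verified to
10⁻⁸ relative. These defaults give nascent-wall conductivities of
~3×10⁻⁴ mm/(mm-Hg·s) (hyper-permeable sprouts) and parent-wall values of
~4×10⁻⁸, bracketing measured tumour/normal Starling conductivities.

## Coupling loop and time scales

Per vascular step (6 h): the biochemistry is advanced in CFL-limited
sub-steps, with a solid equilibrium solve every hour (warm-started from the
previous displacement, so later solves typically converge in 1–2 Newton
iterations); then the network update, the flow solve, a collapse
re-assessment with the fresh pressures, and a flow re-solve if the topology
changed. Checkpoints capture every state array plus the RNG state, and a
restarted run reproduces the uninterrupted trajectory bit-exactly.

## Synthetic scenarios, problem sizes, and what they show

All inputs are generated programmatically; there are no external data. The
full study configuration (12 mm cube, centre-refined to ~0.07 mm, 40
simulated days) is expressible in the configuration system but is a
multi-hour computation; the bundled tests and examples use two reduced
scenarios chosen as the package's own validation scale:

* a **tiny scenario** (4 mm cube, 0.5 mm central resolution, 0.8 mm vessel
  spacing, 1 day) exercising the full coupled loop, determinism and
  checkpointing;
* a **reference scenario** (6 mm cube, 0.4 mm central resolution, 0.6 mm
  spacing, 8 days, three seeds) for the emergent behaviours: the
  intratumoural interstitial-pressure plateau with its steep peritumoural
  fall, monotone vascular-density growth and its dependence on the taxis
  mode, peritumoural vessel orientation, and the response to vascular wall
  stiffening.

At this scale the model reproduces the *shape* and *ordering* of the
emergent behaviours, not end-point magnitudes that depend on the 40-day
horizon and the full domain (normalised density reaches only ~1.1–1.2 by
day 8 rather than ~3 by day 40; the interstitial plateau overshoots its long-run
value while the network is maximally leaky and immature). The generator
also idealises real tissue: a regular initial lattice rather than measured
vascular geometry, uniform material constants per tissue type, one
homogenised growth factor, no haematocrit-dependent rheology and no
lymphatics — so passing tests demonstrate internal consistency and
qualitative fidelity of the mechanisms, not patient- or tumour-specific
prediction.

## Known limitations

* Advection of solutes by interstitial flow is deliberately absent.
* Diffusion operators live in the reference frame; severe growth distortion
  is not reflected in effective diffusivities.
* The low-order transport operator slightly over-smooths sharp species
  fronts (the price of guaranteed positivity).
* Collapse is binary and permanent; no regression/re-opening of vessels.
* On strongly reduced domains the fixed Lagrangian mesh eventually
  degenerates: past roughly day 9 on the 6 mm reference domain the host
  elements crushed between the growing tumour and the pinned faces approach
  zero volume and the equilibrium solve becomes intractable.  The full
  12 mm domain postpones this far beyond the 40-day horizon.
* The branching mixture's haemodynamic dependence is reduced to the
  two-class (hypo/well-perfused) parameter split.
* Inter-capillary distance uses the centreline convention and labels
  vessels as branch-free chains; samples adjacent to junctions slightly
  bias the mean downward.
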