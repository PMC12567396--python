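# Methods

## Model

`dermafem` simulates passive drug permeation through skin mounted in a
Franz diffusion cell as one-dimensional Fickian diffusion through four
stacked layers — donor compartment (DC), stratum corneum (SC), rest of skin
(RS: viable epidermis + dermis, lumped), receptor compartment (RC):

    dC_i/dt = d/dx ( D_i dC_i/dx )            in each layer i,

with no flux through the outer donor and receptor walls and, at the
interface between layers i and i+1,

    -D_i dC_i/dx |_left  =  -D_{i+1} dC_{i+1}/dx |_right
                         =  K_i ( C_i(x_i) - C_{i+1}(x_i) / P_i ).

`P_i` is the dimensionless partition coefficient, defined as the
downstream/upstream concentration ratio at equilibrium, so concentration
may jump at an interface; `K_i` (cm/h) is the interfacial mass-transfer
conductance.  `K_i -> inf` collapses the kinetic condition to the pure
partition condition `C_{i+1} = P_i C_i`; the DC–SC and SC–RS interfaces use
this equilibrium limit by default, while the RS–RC interface keeps a finite
`K_3`.  Initially all drug sits in the donor at concentration `C_0`.

The donor and receptor are physical fluid volumes, not boundary
conditions: they are modelled as layers of thickness `volume / area` with a
large artificial diffusivity so they stay spatially uniform (well mixed).
This makes donor depletion (finite dose) and receptor accumulation exact
consequences of mass conservation.

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| area | exposure area | 0.64 cm² | study cell |
| V_DC, V_RC | chamber volumes | 1, 12 mL | study cell |
| C_0 | donor load | 5 mg/cm³ | study protocol (5 mg in 1 mL) |
| L_SC | SC thickness | 0.002 cm | typical dermatomed porcine ear SC (20 µm); not measured in the study, configurable |
| L_RS | RS thickness | 0.098 cm | membrane ≈ 1 mm total minus SC |
| D_RS | RS diffusivity | 1.80e-3 cm²/h | measured value, held fixed in fits |
| D_SC, P_1, P_2, P_3, K_3 | permeation parameters | Case 2 estimates (1.49e-4 cm²/h, 4.84, 0.96, 0.111, 0.043 cm/h) | the full four-layer fit; the Case 1 set (P_2 = 1) ships alongside |
| well-mixed D | DC/RC diffusivity | 1e4 cm²/h | receptor homogenization time L²/D ≈ 0.035 h, far below the 2 h sampling interval; a ×10 change moves the receiver curve < 0.1% (tested) |
| elements | per layer | (4, 40, 60, 8) | SC and RS host the gradients; convergence-tested |
| dt | implicit step | 0.01 h | temporal error far below the observation scale; first-order convergence verified |

## Discretization

Linear finite elements per layer with *duplicated* nodes at the three
interfaces, so the concentration jump is representable.  The semi-discrete
system is `M dc/dt + A c = 0` with a consistent mass matrix `M`
(block-diagonal per layer, scaled by the exposure area, so `1ᵀ M c` is drug
mass in mg; a lumped option exists but the consistent form preserves the
second-order spatial accuracy the convergence suite checks).  Finite
interfaces contribute the Robin-type coupling
`+K, -K/P; -K, +K/P` (area-scaled) to the rows of the two coincident
nodes; each coupling column sums to zero, which is discrete mass
conservation.

Equilibrium interfaces are eliminated exactly rather than penalized: the
downstream node is a slave equal to `P_i` times its master, and the slave's
residual row is *added* to the master's row, cancelling the internal
interface flux (a Lagrange multiplier).  The reduction is Petrov–Galerkin —
prolongation carries the factor `P_i`, restriction does not — deliberately:
a symmetric reduction would scale the slave equation by `P_i` and break
exact conservation for `P_i ≠ 1`, while the row-sum form conserves
`1ᵀ M c` identically.  The large-K penalty route is retained as an option
and agrees with elimination to < 0.1% at K = 1e4 cm/h (tested).

Time integration is backward Euler, `(S M T + dt S A T) c_r = S M c_old`,
unconditionally stable and first-order; the right-hand side uses the full
previous state, so the discontinuous initial condition needs no special
projection and the conserved total is exactly the initial donor load.
Factorizations (sparse LU) are cached per distinct dt.  Output times are
hit exactly by shortening the final substeps of each interval — never by
interpolation — so fitted residuals carry no interpolation bias.

## Verification oracles

Independent of the FEM assembly path:

1. **Analytic slab series** — cosine eigenfunction solution for a single
   homogeneous layer with no-flux walls (the P = 1, equal-D continuity
   limit).  Observed spatial convergence order of the FEM is ≈ 2 against
   it; the series is truncated by a uniform coefficient bound (individual
   coefficients can vanish by symmetry, so per-term tests are unsafe).
2. **Closed-form equilibrium** — uniform per layer with jump `P_i` and
   total mass `M`: `C_DC = M / (V_1 + V_2 P_1 + V_3 P_1 P_2 + V_4 P_1 P_2 P_3)`.
   Reached by the solver in the long-time limit and, thanks to A-stability,
   by a single huge implicit step.
3. **Steady-state series resistance** — exact piecewise-linear profile and
   flux across SC + RS between fixed boundary concentrations:
   `J = (P_1 P_2 c_L - c_R / P_3) / (P_1 P_2 / K_1 + P_2 L_SC / D_SC + P_2 / K_2 + L_RS / D_RS + 1 / K_3)`.
4. **Finite-volume reference** — cell-centered discretization with
   interface flux matching by eliminating the face concentrations
   (`F = A (c_L - c_R/P) / (1/K + h_L/2D_L + h_R/2PD_R)`), implicit in
   time, sharing no assembly code; agrees with the FEM receiver mass to
   well under 0.5%.

## Inverse problem

Weighted nonlinear least squares over any subset of
{D_SC, P_1, P_2, P_3, K_3} (D_RS fixed at its measured value unless
explicitly freed).  Residuals concatenate (a) cumulative receiver mass in
mg at each sampling time and (b) endpoint DC/SC/RS residuals in
concentration units: model median nodal concentration minus observed
mass / layer volume.  The median summary keeps units commensurate across
compartments whose volumes span four orders of magnitude and damps local
peaks.  Optional late-time weighting (factor 4 on the last 25% of receiver
points, the preset default) emphasises the tail of the receiver curve;
weighted and uniform fits agree to < 0.5% on clean data (tested).

Optimization runs in log10 parameter space — parameters are positive and
span orders of magnitude, so bounds become boxes and scaling is uniform —
with `scipy.optimize.least_squares` (trust-region reflective), step and
function tolerances 1e-5, and default bounds D_SC ∈ [1e-7, 1e-1] cm²/h,
P ∈ [1e-3, 1e3], K_3 ∈ [1e-4, 1e2] cm/h.  The fit is deterministic;
non-convergence is reported in the result, not raised.

## Synthetic experiments

`generate_observations` forward-simulates a configuration, reads cumulative
receiver mass every 2 h from 2 h to 50 h plus the 51.5 h endpoint, and
reads donor/SC/RS content at the endpoint, mimicking receptor sampling and
endpoint tape-strip / residual-skin analysis.  Noise, when enabled, is
multiplicative Gaussian (default CV 5%, seeded, clipped at zero) applied
independently to every observed value.

Two conventions matter:

* **Endpoint observation operator.**  The reported endpoint "mass" is the
  layer's median concentration × volume — the same summary the residuals
  use — rather than the integrated mass.  At 51.5 h the skin profiles are
  nearly linear so the two differ by only ~1e-3 relative, but using one
  operator on both sides makes noise-free self-consistency fits exactly
  unbiased (the residual at the generating parameters is identically
  zero).  Consequence: the generated endpoint masses close the total mass
  budget to ~1e-3 relative, not to machine precision; the solver-level
  mass budget (`mass_in_layer`) still closes to 1e-8.
* **No withdrawal simulation.**  The model does not simulate the 200 µL
  sample withdrawals; `sampling_correction` exists to convert raw sampled
  concentrations into cumulative mass when round-tripping external data.

What the generator does *not* emulate: biological variability between skin
samples, analytical (HPLC) detection limits, strip-by-strip SC depth
profiles, drug binding or metabolism.  Passing self-consistency tests
therefore demonstrates correctness of the simulator + estimator loop, not
that real skin obeys the model.

## Identifiability, honestly

Noise-free self-consistency fits recover all parameters to optimizer
precision (~1e-9 relative) in both the Case 2 and the Case 1 (P_2 = 1)
protocols.  Under 5% multiplicative noise the picture changes: with a
20 µm SC the term `P_2 L_SC / D_SC` is only ~14% of the total transport
resistance, so D_SC trades off almost freely against P_3 and K_3 along a
flat likelihood ridge (linearized error propagation gives a standard
deviation of ±2.2 decades on log10 D_SC; P_1 and P_2 remain identifiable
at the few-percent level).  Replicate noisy fits reflect exactly that:
P_1/P_2 recover well, D_SC/P_3/K_3 scatter widely while reaching *lower*
residual norms than the generating point — an information limit of the
observation design, not an optimizer failure.  A thicker SC, lower noise,
or SC-resolved (depth-profile) data would restore identifiability.

## Numerical choices and edge cases

* Validation returns all violations as messages (no exceptions) so tools
  can report every problem at once.
* `validate_config` enforces the well-mixed convention (DC/RC diffusivity
  equals the configured well-mixed value; layer thickness × area equals
  chamber volume to 1e-12 relative).
* Backward-Euler states may undershoot near the initial discontinuity;
  at output times the study run stays above −1e-9 × C_0 (tested).
* Median of an even node count uses the midpoint-average convention.
* Degenerate fits (guesses on bounds, empty series, non-monotone times)
  are rejected up front with named messages.

## Problem sizes

Default runs use 115 degrees of freedom (elements 4/40/60/8 with
duplicated interface nodes) and 5 150 implicit steps for a 51.5 h
simulation (~0.25 s).  The convergence suite uses a unit slab at 4×/8×/16×
refinement with dt ∝ h²; replicate-fit studies reuse one forward solve and
re-noise it.  Where many fits run in one test, a coarser 46-DOF mesh with
dt = 0.05 h is used — self-consistency is unaffected because observations
and fits share the same forward discretization.

## Known limitations

One spatial dimension (no radial edge effects at the orifice); constant
diffusivities (no concentration dependence, binding, or metabolism); no
donor saturation/precipitation; withdrawal not simulated; aggregate SC
content only.  The equilibrium-interface reduction assumes the partition
coefficients are time-independent.
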