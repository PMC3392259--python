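# Methods

## The procedure

`feaspace` implements feasibility analysis of kinetic metabolic models: a
forward, sampling-based exploration of which enzyme-level configurations a
cell can assume while remaining physically viable and close to optimal on a
set of quantitative cellular objectives.

Given a kinetic model (stoichiometry `N`, per-reaction rate laws
`v_i = f(e_i, x, c, p)` and a reference steady state `x0, c0, J0, e0`),
the pipeline runs:

1. **Sample** — draw relative enzyme-level vectors `r = e/e0` from a
   configured distribution (the enzyme space).
2. **Map** — solve each sample's steady state `N v(r, x) = 0`
   (the physiological space).
3. **Constrain** — keep samples passing the hard constraints
   (thermodynamics, total-enzyme budget, optional capacity caps, local
   stability): the *viable* space.
4. **Score** — evaluate the three objectives (function, robustness /
   homeostasis, temporal responsiveness) on every viable state and label
   feasibility per objective: the *feasible* space.
5. **Regulate** — decompose every reference-to-sample flux change into
   hierarchical (enzyme-level) and metabolic (metabolite-mediated)
   contributions.

Inversion of the kinetic model (which enzyme levels produce a desired
physiology?) is replaced by Monte-Carlo sampling because general non-linear
kinetic models cannot be inverted explicitly.

## Steady states

Two routes are implemented and used as mutual oracles.

**Closed form (linlog models).** For linlog kinetics,
`v_i = r_i J0_i (1 + Σ_j Ex_ij ln(x_j/x0_j) + Σ_k Ec_ik ln(c_k/c0_k))`,
mass balance is linear in `z = ln(x/x0)`:
`N diag(r∘J0)(k + Ex z) = 0` with `k = 1 + Ec ln(c/c0)`, solved directly.
A singular system ("no unique steady state") marks the sample non-viable
rather than raising, so batches never abort. Systems with condition number
above 1e12 are treated as singular.

**ODE integration (any model).** `dx/dt = N v(r, x, c)` is integrated
(LSODA, rtol 1e-9/atol 1e-12) over geometrically growing horizons until the
relative rate of change `max_i |dx_i/dt| / max(x_i, 1e-12)` falls below
1e-8, with a horizon of 1e6 time units. The endpoint is then polished by a
damped Newton iteration on `N v(x) = 0`: the rate criterion alone can
trigger while slow modes (large pools with small drains) still carry a
visible flux imbalance, and the Newton refinement removes it. If the
horizon is reached first, the same refinement is attempted and accepted
only when it lands on a genuinely balanced root (relative flux imbalance
below 1e-9). Divergence, loss of positivity and integrator failures are
reported per sample through flags, never exceptions.

**Stability.** A state is stable when every eigenvalue of the Jacobian
`A = N ∂v/∂x` (analytic for linlog, central differences otherwise) has real
part below −1e-10. Marginal eigenvalues are conservatively labelled
non-stable; on the small pathway this affects extreme samples whose drain
enzyme is nearly absent and whose end-product pool grows so large that its
relaxation is numerically indistinguishable from neutral.

## Constraints

* **Thermodynamic** (per state): converged, `x_ss > 0`, `J ≥ 0` on the
  irreversible set; with supplied Gibbs energies additionally
  `sign(J_i)·ΔG_i ≤ 0`.
* **Total enzyme budget**: `|Σ w_i r_i / Σ w_i − 1| ≤ δ` — the cell may
  re-allocate enzymes freely but the (cost-weighted) total may move at most
  a fraction δ from the reference. Default δ = 0.5 for the small-pathway
  scenario; 0.1 is the conventional tight setting.
* **Capacity** (optional, off by default): `J_i ≤ v_max,i`.
* **Stability** as above.

Kinetic consistency and mass balance are enforced by construction:
physiological states are only ever produced through the rate laws, and the
solvers only flag convergence below the residual tolerance.

With the default uniform sampling on [0, 2]³ and δ = 0.5, the coordinate-sum
(Irwin–Hall) distribution gives a budget acceptance of
`1 − 2·(0.75³/6) = 0.8594`; the Monte-Carlo fraction reproduces this within
its standard error (~0.25% at n = 2·10⁴).

## Objectives

* **Function**: `F = J_target / J_max`, with `J_max` the empirical maximum
  of the target flux over the viable sample set (an optional grid search can
  refine it; empirically the sampler covers the optimum well at the default
  sample sizes). Feasible when `F ≥ 1 − θ_flux`; θ_flux = 0.25 keeps the
  top quartile of fluxes.
* **Robustness / homeostasis**: quantified by co-response coefficients.
  Locally, `O^{a,b}_{e_i} = C^a_{e_i} / C^b_{e_i}` with
  `C^y_{e_i} = ∂ln y / ∂ln e_i` the scaled control coefficients; for the
  default finite-change mode the reference→sample transition is scored by
  `Ô_j = ln(x_j/x0_j) / ln(J/J0)` per metabolite. The aggregate
  `H = Σ_j |Ô_j|` (sum by default; mean via a flag) is read twice:
  homeostasis-feasible when `H ≤ θ_homeo` (the state is maintained),
  robustness-feasible when the same number `R ≥ θ_robust` (the function is
  buffered by metabolite adjustment). A transition that leaves the flux
  unchanged while metabolites move scores `R = +∞` (perfectly robust,
  maximally non-homeostatic); the identity transition scores `H = 0` by
  convention. Divisions use a 1e-9 cutoff.
* **Temporal responsiveness**: turnover time
  `τ_j = x_j / Σ_i max(−N_ji J_i, 0)`; feasible when every monitored
  metabolite has `τ_j ≤ θ_tau` (default 0.5 time units). Zero consumption
  leaves τ infinite.

Control coefficients are computed analytically for linlog models
(`C_x = −M⁻¹ N diag(J_ss)`, `C_J = I + diag(r∘J0/J_ss) Ex C_x` with
`M = N diag(r∘J0) Ex`, from implicit differentiation of the steady-state
system), under which the summation theorems — flux rows sum to 1,
concentration rows to 0 — hold to machine precision. The generic path
re-solves the steady state at multiplicative enzyme perturbations
`e^(±h)` (default h = 1e-4) and takes central differences.

θ_homeo = 0.5 and θ_robust = 2.0 are package defaults chosen so that
"homeostatic" means the summed metabolite co-response stays below half the
flux response and "robust" means metabolite adjustments absorb at least
twice the flux response; both are ordinary knobs in the configuration.

With the shipped reference state (τ = 1 at reference for both
intermediates) the three-way conjunction of function, homeostasis and
responsiveness at the default cut-offs is a very small — at default
sampling, empty — corner of the viable space: responsiveness requires
pushing the drain enzyme well above the flux-optimal allocation that the
enzyme budget allows. The reported conjunction counts should be read with
that trade-off in mind.

## Regulation analysis

Because all shipped rate laws factor as `v = e·g(x, c)`, the log flux
change of each reaction splits exactly as `Δln v = Δln e + Δln g`, giving
`ρ_h = Δln e / Δln v` (hierarchical) and `ρ_m = 1 − ρ_h` (metabolic).
Reactions with `|Δln v| ≤ 1e-9` or a flux sign reversal are left undefined.
Classification uses a band of 0.05 around 1 ("hierarchical") and around 0
("metabolic"), "mixed" otherwise.

Exclusively hierarchical states (ρ_h ≈ 1 for every reaction) are
necessarily homeostatic: the enzymes carry the whole flux change, so the
metabolites did not move. The test-suite and acceptance script verify this
link quantitatively (ρ_h within 1e-3 of 1 ⇒ H < 1e-2).

## The small-pathway fixture

A linear chain `S → M1 → M2 → P` with three reactions, linlog kinetics and
reference `x0 = (1,1)`, `J0 = (1,1,1)`, `e0 = (1,1,1)`. Default
elasticities: reaction 1 is product-inhibited by M1 (−0.5) and driven by
external S (+1); reaction 2 is driven by M1 (+0.5); reaction 3 by M2
(+0.5). M2 is kinetically inert on the upstream reactions, so the pathway
flux is the harmonic mean of the two upstream enzyme levels,
`J = 2 r1 r2/(r1+r2)`, independent of the drain enzyme, while the M2 pool
absorbs the imbalance (`ln x2 = 2(J/r3 − 1)`) — the closed forms the
test-suite uses as independent oracles. Two optional regulatory links are
scannable: end-product feedback inhibition of reaction 1 by M2 (elasticity
0 to −5) and feedforward activation of reaction 3 by M1. These elasticity
values are package defaults engineered to the qualitative structure above,
not measured quantities, and every one can be overridden in the model
options.

Because the flux is independent of the drain enzyme, the flux optimum under
the budget is a ridge at `r1 = r2` rather than an isolated point on the
`r1 = r2 = r3` diagonal; the diagonal structure appears instead in the
homeostasis labels, which require all enzymes to move in concert.

## Chemostat, competition, redesign

* **Chemostat coupling** turns the clamped external substrate into a state
  variable `dS/dt = D(S_in − S) − q_upt·X`; when `S_in` is not given it is
  derived so the model's reference remains a steady state of the coupled
  system.
* **Competition** integrates `dX_k/dt = (μ_k − D) X_k` for strains sharing
  the substrate pool, with Monod growth scaled by the strain's relative
  uptake enzyme and a linear proteome-cost penalty:
  `μ_k = μ_max u_k S/(K_s+S) · (1 − c·(Σe_k/Σe0 − 1))`, `c = 0.1` by
  default. The linear cost form is a modelling assumption of this package.
  The shipped four-strain scenario (wild type; economy-only, all enzymes
  down; competition-only, uptake up at full proteome cost; trade-off,
  uptake up with the rest down) illustrates that the trade-off strain has
  the lowest break-even substrate concentration and takes over the
  culture.
* **Storage-branch redesign** adds a T6P-like intermediate fed from the
  kinase product by first-order mass-action reactions and multiplies the
  kinase rate by a non-competitive factor `1/(1 + T6P/K_i)` (the inhibition
  form is an assumption); rate constants and a kinase rescale are chosen on
  construction so the extended reference state is exactly preserved, and
  that invariance is verified at build time.

## Synthetic data and what the tests show

All inputs are generated programmatically: the small pathway and its
scan variants, the Monte-Carlo enzyme samples (default 2·10⁴ triplets,
uniform on [0, 2], clipped below at 0.01 to avoid dead reactions; seeds
make every run bitwise reproducible) and the competition scenario. The
generator emulates the study conditions — relative enzyme levels around a
reference steady state under a total-proteome budget — and deliberately
omits features of real data: measurement noise, enzyme covariation,
thermodynamically derived elasticity bounds and the full yeast glycolysis
kinetics. Passing tests therefore demonstrate the correctness of the
machinery (solvers, constraint logic, control-analysis identities,
regulation algebra) and the qualitative phenomena that follow from the
pathway structure, not quantitative agreement with any organism.

The yeast-glycolysis extension requires an externally supplied kinetic
parameterization (internal YAML model format); without one the feature
disables itself with a clear message. Test and acceptance problem sizes
(2 000-sample mapped sets, 4 000-sample scans, 20 000-sample budget check)
were chosen as the smallest sizes at which the Monte-Carlo statistics are
stable to well within the asserted tolerances.

## Known limitations

* Linlog rate laws lose physical meaning far from the reference state
  (rates can turn negative at very low substrate); the starvation limit of
  the chemostat illustrates this artifact.
* The empirical `J_max` under-estimates the true optimum when sampling is
  sparse; feasibility labels for function are relative to the sampled
  optimum.
* No DAE or spatial models; no symbolic manipulation of arbitrary rate
  laws; adaptive/sequential sampling is out of scope.
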