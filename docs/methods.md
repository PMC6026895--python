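# Methods

This note documents the model, the numerical choices, and the limits of
what the simulations show. It complements the README, which gives the
user-facing overview.

## Batch model

A single well-mixed, constant-volume vessel holds substrate `S` (µg/mL),
susceptible bacteria `X_S` (cells/mL), infected bacteria and free phage `P`
(particles/mL). Growth follows Monod kinetics,
`mu(S) = mu_max·S/(Km + S)`, with yield accounting through `e`, the
substrate consumed per cell produced; infection follows mass action,
`Ki·X_S·P`. Endogenous bacterial decay `dX` and phage decay `dP` are
first-order sinks.

The three infection parameters are functions of the host's specific growth
rate, reflecting the experimental observation that fast-growing hosts
adsorb phage faster, support larger bursts and lyse sooner:

* adsorption rate `Ki(mu)`: log-linear from `Ki(0) = 1e-9` to
  `Ki(mu_max) = 1e-7` mL/h — i.e. `Ki = 1e-9 · 100^(mu/mu_max)`;
* latent period `T(mu)`: linear from 0.8 h down to 0.4 h;
* burst size `b(mu)`: linear from 0 up to 90 phages/cell.

The default bacterial parameterization (`mu_max = 0.7726`/h,
`Km = 0.0727` µg/mL, `e = 1e-6` µg/cell) is a literature-based *E. coli*
profile. All curve endpoints are configurable; the curves for any other
host/phage pairing must be measured (chemostat cultures at several dilution
rates, infection parameters assayed at each steady state).

### Delay removal (linear chain)

Lysis lags adsorption by `T`, so the natural formulation is a delay
differential equation. Delays compose badly across multiple vessels with
discrete transfer events, so the production model replaces the delayed
infected pool with `M × N` compartments `X_I[m, n]`: `m` indexes a
parameter bin (the infection parameters frozen at infection time), `n` an
age class. Each age class drains into the next at ageing rate
`D_m = N / T_m`, so the chain's mean residence time is exactly `T_m` (the
residence-time distribution is Erlang-`N`; larger `N` sharpens it toward
the deterministic delay). The oldest class lyses into the phage pool with
burst `b_m`. A dispatch function
`sigma(mu) = min(M, floor(M·mu/mu_max) + 1)` routes new infections into the
bin whose representative growth rate brackets the instantaneous `mu(S)`.

Bin `m` carries the response curves evaluated at the bin midpoint
`mu_m = (m − ½)·mu_max/M`. Midpoints are the unbiased within-bin
representative and preserve strict monotonicity of the discretized arrays
(`Ki` and `b` increasing, `T` decreasing). Evaluating at bin edges instead
shifts the effective top-bin burst from 85.5 to 81 or 90 — a visible but
secondary effect.

Defaults are `M = 10`, `N = 50`. The test suite includes a convergence
study against the method-of-steps DDE solver: with constant parameters the
ODE solution's phage-titre error at a fixed horizon falls monotonically
over `N = 5, 25, 125` (8.7% → 1.8% → 0.4% on the standard fixture), so
`N = 50` keeps the discretization error in the low percent range at ~500
state variables per vessel.

`dX` and `dP` default to zero: no reference values are available for the
default pairing, and cycle times of a few hours are short against typical
decay timescales. Both are plain configuration fields.

### Numerics

* Stiff-capable integration (`scipy.integrate.solve_ivp`, BDF) with the
  structural Jacobian sparsity supplied, so finite-difference Jacobians
  cost O(bandwidth) rather than O(dimension) right-hand-side evaluations.
  The lysis terms make the system stiff once titres are high.
* Default tolerances `rtol = 1e-8`, `atol = 1e-2` (absolute tolerance in
  concentration units, negligible against the 1e6–1e11 /mL range of
  interest).
* A vessel containing neither phage nor infected cells can never start an
  infection; that case integrates the exact reduced substrate/biomass
  system (LSODA, 2 states), which keeps the phage-free growth vessel cheap.
* Solver output is clipped: magnitudes below 1e-30 become exactly 0, and
  tiny negative excursions (solver artifacts) are clamped to 0. The
  right-hand side evaluates `mu` and infection terms on non-negativized
  states, so clipping never feeds back spurious dynamics.
* `sigma(mu)` makes the right-hand side piecewise-smooth in `S`; the bin
  switches are handled by the adaptive step control, and in practice the
  infection phase of a cycle sits deep inside the top bin.

### DDE reference solver

`phagecycle.dde.simulate_batch_dde` integrates the fixed-parameter delayed
model by the method of steps: segments of length `T` are solved as plain
IVPs, with the delayed terms read from the dense interpolant of earlier
segments. The default pre-history is phage-free (`P = 0` for `t < 0`), so
no lysis occurs before one latent period has elapsed — the standard
convention for phage added at `t = 0`. The solver is an oracle and a
case-study engine, not the production path.

## Two-stage process

The growth vessel (SCF) and infection vessel (SCI) are simulated as
independent batches between cycling events; events are instantaneous, in
the order: (1) harvest SCI to its LLS, (2) drain SCF to its LLS,
(3) transfer the drained broth into the SCI up to at most its MLS,
discarding excess, (4) fresh medium into the SCI up to its HLS, (5) fresh
medium into the SCF up to its HLS. If the drained broth does not reach the
MLS (the optimized geometry drains 38.4 L against a 39 L span), all of it
is transferred and the top-up starts from the actual level — both vessels
always return exactly to their HLS, and every species amount is conserved
across the streams (asserted to 1e-10 relative in the tests). Withdrawal
does not change concentrations; additions mix ideally.

Start-up defaults: SCF full at its HLS with fresh medium and a 1e6
cells/mL inoculum; SCI at its LLS with a 1e8 /mL phage solution and no
bacteria. The cyclic steady state after tens of cycles is insensitive to
these values; they are configurable. The SCI is harvested every cycle —
one production period per cycle — which is also what the per-cycle cost
arithmetic of the reference scenario implies.

Steady state is declared when the relative spread of the harvested-phage
count over the last 5 cycles falls below 1e-3; the optimized scenario
converges long before its 45th cycle.

## Economics

`cost/cycle = operation_rate·cycle_time + medium_cost·V_fresh +
substrate_cost·m_substrate`, with default rates $40/h, $15/L and $0.1/g.
Substrate is charged on top of the per-litre medium preparation cost — they
are separate line items, and together they reproduce the reference
scenario's ≈$849/cycle and ≈$309/h. Harvested and discarded streams carry
no credit or disposal cost. Degenerate cycles (no phage harvested) report
infinite cost per phage with a warning instead of raising, so optimization
sweeps rank them last.

## Experiment layer

* **Semi-exhaustive search**: full 4-level factorial over the five
  operational parameters (1024 runs), then a second 1024-run factorial over
  a range one third of the original, centred per-parameter on the incumbent
  and clipped to the original bounds — 2048 scheduled evaluations. The two
  substrate axes use log-spaced levels (their 1–1000 µg/mL range spans
  three decades); volumes and cycle time are linear.
* **Local sensitivity**: elasticity `S = (ΔC/C)/(ΔV/V)` at ±1%, averaging
  the two one-sided estimates against the shared mid-point (10 perturbed
  runs for 5 parameters). At the optimized point the implementation
  reproduces the expected elasticity pattern: cost per phage is dominated
  by the SCF feed concentration (≈ −0.99) and SCF low-level setting
  (≈ +0.30), with exactly zero sensitivity to the SCI mid-level sensor,
  which the transferred volume never reaches.
* **Interaction scan**: 5-level full factorial of ±2% perturbations
  (3125 runs), z-score normalization of predictors and response, OLS with
  all 5 main effects and 10 pairwise products, t-based p-values multiplied
  by 10 (Bonferroni over the pairwise terms, capped at 1), significance at
  adjusted p < 0.05. When the model fits the response essentially exactly,
  residual variance collapses to rounding error and t-statistics on
  machine-epsilon coefficients become meaningless; `significant()`
  therefore also requires the normalized coefficient to exceed 1e-8.
* **Dosing case study**: the fixed-parameter DDE model, dosed at `t = 0`
  against a target population of 1e6 cells/mL with `Ki = 1e-7` mL/h and
  `T = 0.5` h. Eradication counts infected cells as dead:
  `1 − X_S(t)/X_S(0)`, clamped at 0. Two defaults were genuinely open and
  are package choices: the burst size is 67.5 (the reference burst curve
  evaluated at the growth rate whose latent period is 0.5 h), and the
  ambient substrate is 0 — the intended application is nutrient-exhausted
  pipeline water, where the hosts are static targets. Under these defaults
  a dose of 1e7 /mL eradicates ≈81% within an hour, and the smallest
  power-of-ten dose exceeding 90% is 1e7–1e8 depending on the assumed
  burst; the dose–response is reported as an order-of-magnitude result.

## What the reference scenario does and does not show

The bundled `optimal_50L` fixture reproduces the reference process
economics closely (cost per cycle within 0.1%, all sensitivity elasticities
to two significant figures). Its absolute phage output (3.3e15/cycle at
6.7e10/mL) is a factor ≈1.7 above the reference value of ≈1.9e15/cycle;
the gap corresponds to an effective burst size near 50 rather than the
top-bin 85.5 that the stated response curves imply, and is attributable to
constants of the original study that were never published (`dX`, `dP`, `M`,
`N`, bin placement). The package reports what its own stated
parameterization produces rather than calibrating hidden constants to match
— downstream figures that divide by productivity (e.g. the ~140 h estimate
to produce 1e17 particles) shift by the same factor, to ≈84 h.

## Known limitations

* No bacterial resistance or phage co-evolution: valid for the
  strictly one-way two-stage process, not for continuous co-culture.
* Adsorption is independent of host density; very dense cultures
  (>1e9/mL) may saturate in reality.
* Infection parameters depend on growth rate only through the current
  substrate level; lag phases and stress physiology are not modelled.
* Ideal instantaneous mixing and instantaneous cycling events; pump
  rates, sensor hysteresis and fouling are out of scope, as are
  downstream processing costs and capital expenditure.
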