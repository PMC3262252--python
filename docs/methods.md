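# Methods

## Model class and standing assumptions

`clockbalance` analyses forced ODE models dx/dt = f(x, k, θ(t)) where x is a
vector of mRNA/protein concentrations (nM), k > 0 a parameter vector (time
unit: hours), and θ(t) the periodic light signal (forcing period τ, 24 h by
default). The standing assumption is that the forced system has a unique
attracting periodic solution g(t, k): everything downstream — sensitivities,
the SVD structure, balance equations — is first-order perturbation theory
around that orbit. Models are declared in YAML: states, parameters, one rate
expression per state over a restricted grammar (arithmetic, powers, `exp`,
`log`, `sqrt`, `sin`, `cos`, and the reserved symbol `theta`), a subset of
*light parameters* that must appear only in products with `theta`, and a
subset of *temperature parameters* eligible for Arrhenius dependence.
Expressions are compiled with sympy, which also supplies exact Jacobians
∂f/∂x and ∂f/∂k for the variational equations; malformed expressions fail at
model construction.

Light fluctuations scale the drive: k_j θ → k_j α θ with daily intensity α.
Regulation weights turn this into k_j (c_j α + d_j) θ with c_j + d_j = 1,
implemented by scaling the light parameter itself — valid precisely because
light parameters are confined to θ-products (this confinement is validated
symbolically at compile time). At α = 1 the regulated and original models
coincide exactly.

## Light protocol

θ is a square wave, 1 on [dawn, dusk) and 0 otherwise (defaults 6 h/18 h), or
optionally a smoothed version built from logistic ramps of width w (default
0.05 h) when a differentiable signal is preferred. All integrations split
each forcing cycle at dawn/dusk so that, in square mode, every segment is an
autonomous ODE — the discontinuity never crosses an integrator step.

## Entrained orbit

The orbit is converged by iterating the period map: integrate one forcing
cycle (LSODA, rtol 1e−9, atol 1e−12) and stop when ‖x(nτ) − x((n−1)τ)‖∞ <
1e−8 (default; max 200 cycles, error with the residual trace otherwise).
A further cycle is sampled on a uniform grid of 2400 intervals per 24 h
(0.01 h), backed by dense output and wrapped in a periodic cubic spline.
This avoids boundary-value machinery entirely and is robust for any
asymptotically stable entrained orbit; the convergence rate is the largest
Floquet multiplier.

Peak and trough phases are located on the grid and refined by a local
quadratic fit (~0.001 h accuracy). One subtlety is deliberate: with square
light, a component whose derivative is positive just before a switch and
negative just after has its maximum *exactly at the switch* (a corner, not a
smooth peak). Such extrema are snapped to the switch time, and their phase
sensitivity is reported as exactly zero — the peak is pinned to the switch
under small parameter changes, so the implicit-function formula (which
assumes smooth curvature) does not apply. The bundled demo's nuclear protein
peaks at dusk in precisely this way. Multiple local maxima are all reported,
with the global maximum defining the component's phase and a multi-peak flag
(relevant for components whose near-equal local peaks can exchange the
global-maximum role under perturbations, making the "phase" jump
discontinuously; the per-peak report is the stable object in that case).

Free-running periods clamp θ to 0 (DD) or 1 (LL), integrate 200 days, and
read the period from upward crossings of the component's mean level (a
Poincaré section) over a 480 h window; a model is declared arrhythmic when
the peak-to-trough amplitude falls below 1e−4 of the mean level.

## Sensitivities and their principal components

The default method integrates the forward variational equations
dZ_j/dt = J_x(t) Z_j + ∂f/∂k_j along the orbit over repeated cycles until Z
is τ-periodic (same fixed-point argument as the orbit itself). The
cross-check re-converges the orbit at k_j(1 ± h) (relative step h = 1e−4,
central differences); the two agree to ~1e−8 relative on the demo model,
far inside the 1% contract. A parameter perturbs its day and night effective
values together, i.e. S_j is the response to a sustained parameter change.

The Hilbert-space inner product is ⟨u, v⟩ = Σ_m ∫₀^τ u_m v_m dt with unit
state weights, evaluated by the trapezoidal rule on the orbit grid. Unit
weights treat a nanomolar of each species as equally important; this is a
modelling choice, exposed as a configurable `state_weights` vector. Note
that per-state weighting (equivalently, changing a state's units) changes
the inner product and therefore the eigenstructure and parameter rankings —
only a *uniform* rescaling is an exact invariance. The Gram matrix
G_ij = ⟨S_i, S_j⟩ is diagonalised (`eigh`); σ_i = √eigenvalues descending
(ties broken by a stable sort and flagged as degenerate, since U_i within a
degenerate block are not unique), V the orthonormal eigenvectors, W = Vᵀ,
U_i = M V_i / σ_i.

Relative (log-parameter) mode keeps σ and U from the absolute decomposition
and rescales the weight matrix to W̃_ij = k_j W_ij (and Ṽ = diag(k) V). This
is the convenient convention for balance equations over parameters whose
magnitudes span decades; it is *not* the SVD of M·diag(k) — a deliberate
design choice, documented here because the distinction matters if one
interprets σ̃ as singular values of the rescaled operator.

Phase sensitivities use the implicit-function formula at the peak condition
ġ_m(φ_m) = 0:

    dφ_m/dk_j = −(dS_mj/dt)(φ_m) / g̈_m(φ_m),

with dS/dt evaluated from the variational right-hand side and g̈ = J_x f on
the orbit (both analytic, no numerical differentiation). An equivalent route
through the principal-component expansion is provided and agrees to
algebraic precision; both are validated against re-converged
finite-difference peak shifts to < 2%.

The power sensitivity spectrum ranks parameters by max_{i≤4} |σ_i W̃_ij|
with an optional relative-threshold filter (e.g. 30% of the maximum), the
standard device for selecting the parameters worth making
temperature-sensitive.

## Balance equations and solvers

Balance sums B_i = Σ_{j∈S} W_ij dk_j/dp are evaluated for any subset and
derivative vector; the implied first-order response norm is
(Σ_i σ_i² B_i²)^½. The sign condition — equation i is solvable with
positive summands only if the W_ij over the subset carry mixed signs — is
checked explicitly and raised as a structured infeasibility error.

**Light weights.** With fixed entries moved to the right-hand side, the
first r balance equations Σ_free W̃_ij c_j = −Σ_fixed W̃_ij c_j form an
r × r linear system (error if its condition number exceeds 1e10, which
signals a poor fixed/free split). The demo configuration fixes c_q2 = 1 and
solves r = 2 for (c_q1, c_q3): with the demo's W̃ this split yields moderate
weights (0.26, 1, 0.29) and a 78% realized response reduction, whereas
fixing c_q1 produces a large compensating weight on q2 that inflates the
third balance sum and forfeits most of the benefit. Which weights to fix is
genuinely a user decision; the solver takes the split as explicit input.

**Activation energies.** The temperature balance sums Σ_j W_ij k_j E_j are
linear in E, but the bounds 1 ≤ E_j ≤ 150 kJ/mol may preclude exact zeros,
so the solver minimises Σ_{i≤r} (σ_i B_i)² by bound-constrained linear
least squares (`lsq_linear`, BVLS), recovering exact zeroing whenever it is
feasible. Because the sums are linear in E, rescaling an exact solution
keeps it exact; an optional `target_mean` lifts solved energies toward a
physiological mean (default ~30 kJ/mol in the examples) within bounds. An
iterative mode re-derives the orbit and W at the parameterization implied
by the solved energies (through a user-supplied refresh callable) and
re-solves until the energies move by < 1e−3 kJ/mol or 20 iterations.
Day-temperature and night-temperature sums are treated as two independent
constraint blocks that may be stacked.

## Arrhenius layer

k_j(T) = A_j exp(−E_j/RT) with R = 8.314472 × 10⁻³ kJ mol⁻¹ K⁻¹, specified
by a reference pair (k_ref, T_ref). The first-order Taylor coefficient about
T is dk/dT = +k₀E/RT² under this law (rates increase with temperature).
Some published day/night parameter tables follow the opposite direction
convention — rates increasing toward the colder night, equivalent to a
Taylor coefficient −k₀E/RT² — so the direction is a per-parameter flag
(`increasing_with_temperature`, default True); the bundled consistency
fixtures exercise both conventions. Temperature fluctuations are applied to
the exact law (kelvin offsets added to T_day/T_night), never to the Taylor
linearization; the Taylor coefficients exist for balance-sum analysis,
where the quadratic remainder is O(1e−3) for a parameter of order 0.1 at
E ≈ 50 kJ/mol and kelvin-scale offsets. Day/night forcing splits each
temperature-sensitive parameter as k_j = k_j^D θ + k_j^N (1 − θ).

## Monte-Carlo fluctuation ensembles

Each simulated day draws either α ~ 𝒩(1, 0.2) (light; truncated below at 0,
a negligible correction at these settings) or independent kelvin offsets
ε, η ~ 𝒩(0, 1) for the day and night temperature. A draw applies from dawn
to the next dawn — the natural alignment for day-to-day fluctuations, whose
switch time the problem does not otherwise pin down — with ε active during
the lit interval and η during the dark one. The model is integrated
*continuously* through the noisy days (no per-day reset) after a 10-day
deterministic transient from the converged orbit, so carry-over between
days is retained. Defaults are 200 days per ensemble. Per day and component
the global maximum is located on 0.02 h samples and refined quadratically
(corner maxima at light switches keep the sampled value; see above).
Summary statistics are the mean, SD and CV of daily peak levels and the
circular mean/SD of daily peak phases; the SD is the population SD by
default with a sample-SD flag, a definitional ambiguity made explicit.
Integration failures mid-ensemble preserve completed days and are logged.

## The demo models

The damped demo clock is a three-state negative-feedback loop — Hill-
repressed transcription (exponent 2), reversible nuclear transport, linear
degradation — with three light entry points: additive light-activated
transcription (q1), light-enhanced cytoplasmic degradation (q2) and
light-enhanced nuclear import (q3). With exponent 2 the dark system has a
unique stable equilibrium, so the forced system has a unique attracting
24 h orbit for every perturbation the tests apply; this removes
entrainment-range edge cases from the analysis and is the reason the demo
is damped rather than self-oscillating. Its σ spectrum spans three orders
of magnitude, so low-order balancing is effective.

The oscillatory variant raises the Hill exponent to 16 and lowers all
degradation rates to 0.1 h⁻¹, past the Hopf bifurcation of the dark system:
it carries a sustained DD limit cycle of period ≈ 19.6 h and exists solely
to exercise free-running-period analysis (the damped variant correctly
reports arrhythmic in constant conditions). These values were chosen
because milder settings leave the loop a slowly decaying focus rather than
a limit cycle.

The random-instance generator builds damped production chains with
diagonally dominant degradation, Hill feedback of exponent 2 from the last
state onto the first, and light entering a configurable number of terms
(alternating additive and proportional). It is seed-deterministic and used
for the cross-method sensitivity sweeps.

## What the synthetic conditions do and do not show

The demo emulates the structural features the theory needs — multiple light
entry points, a forced attracting orbit, fast σ decay, mixed-sign W columns
— with none of the biological detail of a multi-loop plant or animal clock
model (no interlocked loops, no dual-peaked components by construction, no
saturating degradation). Passing tests therefore demonstrate the
correctness of the machinery and the reality of balance-based buffering in
a genuine nonlinear forced system, not quantitative agreement with any
published organism-specific model; CV reductions and phase drifts are
properties of the demo, and their magnitudes will differ in other models.
Peak-phase drift of components with near-equal multiple peaks can jump when
the global maximum changes identity across a temperature range — the
per-peak tables, not the scalar phase, are the robust output there.

## Numerical choices (summary)

| choice | value | note |
|---|---|---|
| integrator | LSODA, rtol 1e−9, atol 1e−12 | stiff-capable; sensitivities difference nearby orbits |
| orbit tolerance | 1e−8 (∞-norm period-map residual) | max 200 cycles |
| orbit grid | 2400 samples / 24 h | phase refinement to ~0.001 h |
| variational periodicity | 1e−9 | geometric convergence |
| FD sensitivity step | 1e−4 relative, central | truncation vs cancellation at stated tolerances |
| balance r | 2 for the 3-light-parameter demo | "first few components"; 3 is natural for larger subsets |
| energy bounds | [1, 150] kJ/mol | solver is least-squares, not exact zeroing |
| ensemble | 200 days, 10-day transient | SDs stable to a few % |
| arrhythmicity floor | amplitude < 1e−4 × mean | after 200 forcing-free days |
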