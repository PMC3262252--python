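# clockbalance

Balance equations for buffering circadian clocks against environmental
fluctuations.

Circadian oscillators are entrained by daily light and temperature cycles,
yet both cycles fluctuate substantially from day to day (measured daily
irradiance has a coefficient of variation of roughly 36%). `clockbalance`
implements, for light-forced limit-cycle ODE models, the analysis that
explains how a clock network can stay firmly entrained to the *periodicity*
of its environment while filtering out the *noise*: principal-component
global sensitivity analysis of the entrained orbit, the balance equations it
induces, solvers that tune light-input weights and Arrhenius activation
energies to satisfy those equations, and Monte-Carlo simulation of daily
light/temperature noise to verify the buffering. The same machinery
addresses temperature compensation of the *entrained phase* — arguably the
physiologically relevant setting — rather than of the free-running period.

## The mathematics in brief

For a forced model dx/dt = f(x, k, θ(t)) with an attracting periodic
solution g(t, k), the first-order response to a parameter change δk is
δg = M δk, where M maps parameter space into the Hilbert space of periodic
time series with inner product ⟨u, v⟩ = Σ_m ∫₀^τ u_m v_m dt. Writing the
SVD structure of M as M V_i = σ_i U_i (σ₁ ≥ σ₂ ≥ …, V_i orthonormal in
parameter space, U_i orthonormal time series, W = V⁻¹):

    δg = Σ_i σ_i (Σ_j W_ij δk_j) U_i.

If a subset S of parameters depends on an environmental variable p, then

    dg/dp = Σ_i σ_i B_i U_i,   B_i = Σ_{j∈S} W_ij dk_j/dp,

and the **balance equations** B_i = 0 for the leading i make the orbit (and,
by an implicit-function argument, every component's peak phase) insensitive
to p at first order. Because the σ_i typically decay fast, zeroing only the
first few sums removes most of the response. Concretely:

* **light**: each light input k_j θ(t) is regulated into
  k_j (c_j α + d_j) θ(t) with c_j + d_j = 1, where α is the daily light
  intensity; the c_j solve the leading balance equations
  Σ_j W̃_ij c_j = 0 in log-parameter (relative) mode.
* **temperature**: parameters follow Arrhenius laws k_j = A_j exp(−E_j/RT),
  so dk_j/dT = k_j E_j/RT² and the balance sums are Σ_j W_ij k_j E_j. Since
  k_j E_j > 0, equation i is solvable only if the W_ij of the subset carry
  mixed signs — a structural constraint on which networks can be balanced.

## Worked example

A bundled three-state demo clock (mRNA, cytoplasmic protein, nuclear
protein; Hill-repressed transcription; three light entry points) exercises
the full pipeline. Solving the first two light balance equations with the
drive on q2 held unregulated:

```python
import clockbalance as cb

model = cb.build_demo("damped")
orbit = cb.find_entrained_orbit(model)
sens  = cb.compute_sensitivities(orbit)           # variational equations
pc    = cb.principal_components(sens, mode="relative")
mod   = cb.solve_light_balance(pc, model.light_params, fixed_c={"q2": 1.0}, r=2)
```

Running `python examples/03_light_balance.py` prints

```
solved light weights c_j: {'q1': 0.2588, 'q2': 1.0, 'q3': 0.2889}
balance sums before: [-0.1022 -0.1059 -0.1488]
balance sums after:  [ 1.7347e-18  2.7105e-18 -8.1605e-02]
realized |dg| ratio under a 5% light step: 0.222 (78% reduction)
```

The two targeted balance sums drop to solver precision and the *nonlinear*
response to a sustained 5% light-amplitude step shrinks by 78%. Under daily
noise α ~ 𝒩(1, 0.2) over 200 days (`examples/05_fluctuation_buffering.py`)
the balanced model's daily peak-level CV is smaller for every component —
by a factor 3 for the transcript and over 100 for the nuclear protein —
with identical noise realisations hitting both models.

The other examples cover the entrained orbit and peak phases (`01`), the
singular-value spectrum and the power sensitivity spectrum used to pick
temperature-sensitive parameters (`02`), activation-energy balancing (`04`)
and temperature compensation of entrained phases plus free-running periods
(`06`). A thin CLI wraps the same stages:

```bash
clockbalance spectrum --model demo --out out/
clockbalance balance-light --model demo --r 2 --out out/
clockbalance fluctuate --model demo --kind light --sigma 0.2 --days 200 --seed 7 --out out/
```

Models are plain YAML (states, parameters, rate expressions over the states
and the light symbol `theta`, light/temperature parameter subsets), so the
framework applies to any forced clock model written in that dialect.

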