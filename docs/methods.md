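# Methods

## Model family

All shipped models are deterministic compartmental ODE systems with
frequency-dependent incidence βIS/N, recruitment Ω into the susceptible
class, natural mortality μ from every compartment, and disease-induced
mortality σ from the infectious class. The reference system is the SEIR
model

    dS/dt = Ω − βIS/N − μS
    dE/dt = βIS/N − (α + μ)E
    dI/dt = αE − (γ + σ + μ)I
    dR/dt = γI − μR

whose defining property tests exploit two exact identities: the bookkeeping
identity dS+dE+dI+dR = Ω − μ(S+E+I+R) − σI at every state, and invariance of
the disease-free set (E=I=0 ⇒ dE=dI=0).

SI, SIS, SIR and SIRV are the conventional textbook forms of the same
family, declared as flow specifications; they add no mechanism beyond the
SEIR terms except SIRV's vaccination flow S→V at an extra rate ν. These
forms are this package's choice of convention (the family is usually named
without fixing demography); we put recruitment and natural death on every
model so that the SEIR limits (α→∞ collapses E, γ=0 removes recovery, …)
stay consistent across the family.

### The incidence denominator N

The model equations leave the time-dependence of N open, and the two
reference implementations this package mirrors both freeze it before
integrating (one computes N=S+E+I+R once from the initial state, the other
hard-codes N=1001). The default is therefore `fixed_at_initial`; a
`dynamic` mode (N recomputed as ΣX at each evaluation) is available via
`ModelSpec.incidence_n_mode` or the `--dynamic-n` CLI flag. With the
default parameter sets the two differ visibly over 120 days because
recruitment (20/day) is large relative to the initial population of 1001.

### Parameter sets

Two inconsistent parameterizations appear in the source material: the
tabulated values (Ω=29.08, β=0.9) and the script defaults (Ω=20, β=0.3),
with μ=4.252912·10⁻⁵, α=0.3, γ=0.1, σ=0.003286 shared. Both ship as named
sets (`table1`, `code_default`); `code_default` is the default because the
scripts are what produced the published trajectories. Nothing is silently
merged.

### Negative states

No clamping: components may undershoot zero by at most 1e-9 (rounding
slack); anything beyond raises. Clamping would mask integrator defects that
the tests are designed to catch.

## Flow compiler

`ModelSpec` declares compartments, parameter names, and flows whose rates
are arithmetic expressions over declared symbols plus `N` and `t`.
Expressions are parsed with the `ast` module and restricted to names,
numbers and `+ - * / **`; any other syntax (calls, attributes, subscripts)
is rejected at specification time, as is any undeclared symbol — so a
`ModelSpec` cannot execute arbitrary code. `compile_model` assembles one
Python function per model (sum of in-flows minus out-flows per compartment)
via code generation, which keeps the integrator's inner loop free of
per-flow interpretation overhead. Equivalence of the compiled SEIR model
with the hand-coded right-hand side is a randomized property test (1e-12
relative).

## Integrator

The adaptive solver is the embedded Dormand–Prince 4(5) pair: seven stages,
the 5th-order solution propagates, the 4th-order embedded solution supplies
the error estimate, and the first-same-as-last property gives the endpoint
derivative of an accepted step for free. Choices the classic solver
interface leaves implicit are pinned down as follows:

- **Error norm**: weighted max-norm, weights `abs_tol + rel_tol ·
  max(|y_n|, |y_high|)` per component; a step is accepted when the norm is
  ≤ 1.
- **Tolerances**: `rel_tol` defaults to 1e-5 (the reference setting);
  `abs_tol` defaults to 1e-6, which for populations of order 10³ makes the
  relative term dominate except when a compartment sits near zero.
- **Step controller**: elementary controller `h ← h · clamp(0.9 ·
  err^(−1/5), [0.2, 5])`; the clamp prevents both step collapse after one
  bad estimate and overconfident growth.
- **Initial step**: the standard ‖y‖/‖f‖ heuristic (two derivative
  evaluations), overridable via `SolverConfig.initial_step`.
- **Termination**: the last step is truncated to land exactly on `t_max`;
  floating-point snap tolerance is 1e-12 relative to the horizon.
- **Failure modes**: step-size underflow below `min_step` and exceeding
  `max_accepted_steps` (default 10⁶) raise `IntegrationError` carrying the
  time reached; a non-finite stage value rejects the step and shrinks h
  first.

The solver is deterministic throughout; there is no randomness anywhere in
the integration path.

### Dense output

Accepted steps retain endpoint states and derivatives; sampling on a user
grid (default: daily, matching the reference output convention) evaluates
the cubic Hermite interpolant on each step. Its interpolation error is
O(h⁴) locally — lower order than the 5th-order solution, but at the default
tolerance the accepted steps are short enough that the daily-grid test
bounds the total error at ≤ 10·rel_tol on the scalar decay problem, and the
end-to-end SEIR comparison against the fixed-step oracle shows ~2·10⁻⁵
relative agreement. Grid points coinciding with accepted-step times
reproduce stored states exactly. Trajectories returned at solver steps and
trajectories sampled on a grid are both first-class, mirroring the two
output conventions of the reference implementations.

### Fixed-step reference

`rk4_reference` is the classical 4th-order Runge–Kutta method at a fixed
step. It shares nothing with the adaptive path except the right-hand side
and exists as an independent oracle: regression fixtures are generated from
it at h=10⁻³ (its own step-halving self-consistency on the reference run is
below 10⁻⁸ relative), and the adaptive solver is required to stay within
10⁻³ relative of it. scipy's RK45 serves as a second, external cross-check
in the test suite only; it is never the shipped integrator.

### "Relative deviation" between trajectories

Pointwise relative error is ill-defined where a compartment passes through
zero (E(0)=R(0)=0 exactly), so trajectory comparisons use a scaled maximum
deviation: per compartment, max|a−b| divided by max(1, max|b|). Measured
deviations (~10⁻⁵ at the default tolerance) sit far below the 10⁻³
regression bound, so the normalization choice is not load-bearing.

## Epidemiological analysis

The analytical layer is derived from the model equations with the standard
next-generation construction (the simulator's source material presents no
analytical epidemiology; these are documented extensions):

- `next_generation_matrix`: F = [[0, β], [0, 0]], V = [[α+μ, 0],
  [−α, γ+σ+μ]] over (E, I) at the disease-free equilibrium.
- `basic_reproduction_number`: the closed form αβ/((α+μ)(γ+σ+μ)), tested to
  equal the spectral radius of FV⁻¹ to 1e-10 relative on random draws.
- `disease_free_equilibrium`: (Ω/μ, 0, 0, 0); undefined at μ=0 (raises).
- `summarize`: peak prevalence, earliest time attaining it (deterministic
  tie-break), final state, attack fraction (S₀−S_end)/S₀.
- `final_size_residual`: ln(S∞/S₀) + R₀(1 − S∞/N), the closed-epidemic
  final-size identity used as an end-to-end test statistic coupling the
  integrator to the theory (|residual| < 10⁻² required; measured ~5·10⁻⁹).

## I/O and reproducibility

Run configurations are JSON with a closed key set (unknown keys rejected,
validation errors name the offending key); defaults reproduce the reference
setup exactly: SEIR, `code_default`, (S,E,I,R)=(1000,0,1,0), 120 days,
daily grid, rel_tol 1e-5. CSV output (`time,S,E,I,R`, column order matching
the model's state ordering) uses shortest-round-trip float formatting, so a
write is byte-deterministic and a read-back is lossless. Figures are PNG
with metadata stripped, making repeated runs byte-identical end to end —
the determinism contract is tested on both CSV and figure bytes.

Regression fixtures (`make_fixture`) pair a config with the RK4-oracle
trajectory for three cases: the reference SEIR run under each parameter
set, and a closed SIR epidemic (Ω=μ=σ=0, β=0.3, γ=0.1, S₀=999, I₀=1) whose
fixture additionally certifies population conservation. Fixtures are
regenerated programmatically at test time, never stored.

## Problem sizes used in checks

The oracle comparisons integrate the full 120-day reference horizon with
RK4 at h=10⁻³ (1.2·10⁵ steps) — small enough to run in seconds while
leaving the oracle's own error (~h⁴) orders of magnitude below the bounds
it polices. The final-size run uses a 400-day horizon so the closed
epidemic is effectively over (I(400) ≈ 10⁻⁷). Randomized consistency checks
use 100 parameter draws.

## Known limitations

- Explicit solver only: no stiff variant, no event detection, no backward
  integration. The reference parameter sets are non-stiff over the horizons
  of interest.
- Deterministic ODE dynamics only: no demographic stochasticity (CTMC/SDE),
  age or spatial structure, or parameter fitting.
- The Hermite interpolant is 4th-order; at tolerances much tighter than
  ~1e-9 the interpolation error, not the integration error, dominates
  sampled output.
- The flow-expression language is arithmetic only (no time-varying forcing
  functions beyond explicit use of `t` in expressions).
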