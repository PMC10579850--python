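# seirkit

Deterministic compartmental epidemic models — SI, SIS, SIR, SIRV and SEIR —
with an embedded Dormand–Prince 4(5) adaptive integrator, dense output on a
daily grid, and basic epidemiological analysis (basic reproduction number,
disease-free equilibrium, epidemic summaries, final-size checks).

`seirkit` is aimed at researchers and students who simulate
ordinary-differential-equation transmission models and want a small,
fully-tested toolkit whose solver behaviour is explicit rather than hidden
behind a black-box call: the step controller, error norm, tolerances and
interpolation are all documented and testable (see `docs/methods.md`).

## The model

The core system is the SEIR model with recruitment and mortality under
frequency-dependent incidence:

```
dS/dt = Ω − βIS/N − μS
dE/dt = βIS/N − (α + μ)E
dI/dt = αE − (γ + σ + μ)I
dR/dt = γI − μR
```

with S susceptible, E exposed (infected, not yet infectious), I infectious,
R recovered; Ω recruitment (individuals/day), β transmission, μ natural
death, α progression E→I, γ recovery, and σ disease-induced death (all
1/day). N is the population size in the incidence denominator, frozen by
default at its initial value (a `dynamic` mode recomputes it each
evaluation). Two named parameter sets ship — `code_default`
(Ω=20, β=0.3, μ=4.252912·10⁻⁵, α=0.3, γ=0.1, σ=0.003286) and `table1`
(Ω=29.08, β=0.9, other rates equal) — because the source material states
both; `code_default` is the default.

The basic reproduction number follows from the next-generation matrix over
the infected subsystem (E, I):

```
R0 = αβ / ((α + μ)(γ + σ + μ))
```

Other compartmental structures are declared as lists of flows
(`ModelSpec`/`compile_model`), so variants like SEIRS with waning are a few
lines of specification, not new derivative code (`examples/custom_model.py`).

## Worked example

```python
import seirkit as sk

config = sk.RunConfig()          # SEIR, code_default, (S,E,I,R)=(1000,0,1,0), 120 days
traj = sk.simulate(config)       # adaptive integration, sampled daily
s = sk.summarize(traj)
print(len(traj), round(s.peak_infected, 1), s.t_peak, round(s.attack_fraction, 3))
```

prints

```
121 692.5 53.0 0.595
```

— 121 daily rows (t = 0…120), a peak of ≈692.5 infectious individuals on
day 53, and 59.5 % of the initial susceptibles leaving S by day 120. The
reproduction numbers of the shipped parameter sets are

```python
sk.basic_reproduction_number(sk.get_parameter_set("code_default"))  # 2.903
sk.basic_reproduction_number(sk.get_parameter_set("table1"))        # 8.709
```

The same run from a shell:

```sh
seirkit run --config config.json --out run.csv --fig-dir figures/
seirkit summary run.csv
seirkit r0 --params code_default
```

where `config.json` can be as small as `{"model": "seir"}` (all defaults
applied). `run` writes a `time,S,E,I,R` CSV and five figures (one per
compartment plus a combined plot). Short narrative scripts for each
capability live in `examples/`.

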