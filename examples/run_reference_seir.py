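"""Simulate the reference SEIR setup and summarize the epidemic.

The defaults are the published reference run: 1000 susceptibles, one
infectious case, the `code_default` rates, relative tolerance 1e-5, and a
120-day horizon sampled daily.
"""

import seirkit as sk

config = sk.RunConfig()  # seir / code_default / (1000, 0, 1, 0) / 120 days
traj = sk.simulate(config)
s = sk.summarize(traj)

print(f"rows on the daily grid : {len(traj)}")
print(f"peak infected          : {s.peak_infected:.1f} individuals")
print(f"time of peak           : {s.t_peak:.0f} days")
print(f"attack fraction        : {s.attack_fraction:.3f}")
print(f"final state (S,E,I,R)  : {[round(float(v), 1) for v in s.final_state]}")

# The peak is the largest prevalence of infectious individuals on the daily
# grid; the attack fraction is the share of the initial susceptibles who
# left S by day 120.
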