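"""Detecting the onset of flocking order without knowing the order parameter.

Runs one Vicsek-model simulation in which the coupling radius ramps from a
value too small for order (r = 0.0065) to one well above the transition
(r = 0.06), and compares the map alignment statistic Z_10(p, v) before and
after the ramp with the classic polarization order parameter.
"""

import numpy as np

from mapalign import FlockConfig, Schedule
from mapalign.flocking import run_experiment

schedule = Schedule.ramp(0.0065, 0.06, t_start=160, t_end=240)
config = FlockConfig(
    n_agents=150, speed=1 / 320, noise=np.pi / 5, schedule=schedule,
    n_steps=400, seed=3,
)

early = list(range(10, 80))
late = list(range(330, 401))
run = run_experiment(config, measure_steps=early + late)

z_early = np.nanmean(run.z[10:80])
z_late = np.nanmean(run.z[330:401])
o_early = run.order[10:80].mean()
o_late = run.order[330:401].mean()

print(f"{config.n_agents} agents, radius ramp 0.0065 -> 0.06 over steps 160-240")
print(f"before ramp: Z_10(p, v) = {z_early:6.2f}   polarization = {o_early:.3f}")
print(f"after ramp:  Z_10(p, v) = {z_late:6.2f}   polarization = {o_late:.3f}")
print(
    "Z_10 is built only from the two inter-agent distance time series, yet\n"
    "it jumps by tens of null standard deviations exactly when the flock\n"
    "orders, tracking the hand-picked polarization order parameter."
)
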