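"""Endemic equilibria of the good and bad contagion for one sociality level.

A population interacting at a rate that gives the good contagion a
reproduction number R_g also gives the bad contagion R_b = c * R_g.  Each
contagion settles at the classic SIS equilibrium 1 - 1/R when R > 1 and
dies out otherwise.
"""

import numpy as np

from sociality import ContagionParams, mono_equilibrium, reproduction_numbers, \
    simulate_mono

# from raw rates: interactions at rate 7/day, transmission probabilities
# 0.5 (good) and 0.25 (bad), recovery in one day for both
params = reproduction_numbers(sigma=7, p_g=0.5, p_b=0.25, gamma_g=1, gamma_b=1)
print(f"R_g = {params.R_g:g}, c = {params.c:g}, R_b = {params.R_b:g}")

eq = mono_equilibrium(params)
print(f"equilibrium: I_g = {eq.I_g:.6f}, I_b = {eq.I_b:.6f}, S_b = {eq.S_b:.6f}")
# -> 71.4% of individuals carry the useful contagion at any time; 42.9%
#    carry the harmful one (c R_g = 1.75 > 1, so it is endemic too).

traj = simulate_mono(params, init=(0.01, 0.01), t_grid=np.linspace(0, 40, 81))
print(f"after t = 40 recovery times from 1% seeding: "
      f"I_g = {traj.I_g[-1]:.6f}, I_b = {traj.I_b[-1]:.6f}")
# -> the trajectory has converged to the closed-form equilibrium above.
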