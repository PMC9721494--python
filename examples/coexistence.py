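"""Stable coexistence of two sociality strategies.

When resident and mutant strategies straddle the social optimum (here
R_r = 7 and R_m = 3 around R_opt = 4, with alpha = 0.25 and c = 0.25), the
rarer-is-fitter structure of the utility difference produces a globally
stable interior equilibrium of the replicator equation: both strategies
persist.
"""

from sociality import CobbDouglasUtility, classify_pairwise, \
    find_interior_equilibrium, simulate_replicator

model = CobbDouglasUtility(alpha=0.25)
R_r, R_m, c = 7.0, 3.0, 0.25

out = classify_pairwise(model, R_r, R_m, c)
print("outcome:", out.kind.value, "| endpoint signs of U_m - U_r:",
      out.endpoint_signs)
# -> mutants gain when rare (+) and lose when common (-): coexistence.

f_eq = find_interior_equilibrium(model, R_r, R_m, c)
print(f"interior equilibrium f_eq = {f_eq:.4f}")

for f0 in (0.1, 0.95):
    traj = simulate_replicator(model, R_r, R_m, c, f0=f0)
    print(f"from f0 = {f0:4.2f}: terminal f = {traj.terminal_f:.4f} "
          f"({traj.terminal_classification})")
# -> both initial conditions converge to the same mixed composition.
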