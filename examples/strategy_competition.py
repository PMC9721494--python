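"""Replicator competition: a more-social mutant invades the social optimum.

With Cobb-Douglas weight alpha = 0.75 and a bad contagion four times less
transmissible than the good (c = 0.25), the socially optimal strategy is
R_opt = 4.  A mutant with R_m = 5 nevertheless obtains higher utility at
every population composition, so the replicator equation drives it to
fixation: the collective optimum is not evolutionarily stable.
"""

from sociality import CobbDouglasUtility, DimorphicParams, classify_pairwise, \
    simulate_replicator, strategy_utilities

model = CobbDouglasUtility(alpha=0.75)
R_r, R_m, c = 4.0, 5.0, 0.25

for f in (0.1, 0.5, 0.9):
    U_r, U_m = strategy_utilities(model, DimorphicParams(R_r=R_r, R_m=R_m,
                                                         f=f, c=c))
    print(f"f = {f:.1f}:  U_r = {U_r:.4f}  U_m = {U_m:.4f}  (gap {U_m-U_r:+.4f})")
# -> the mutant is ahead at every mutant fraction f.

outcome = classify_pairwise(model, R_r, R_m, c)
print("pairwise outcome:", outcome.kind.value)

traj = simulate_replicator(model, R_r, R_m, c, f0=0.05)
print(f"replicator from f0 = 0.05: terminal f = {traj.terminal_f:g} "
      f"({traj.terminal_classification}) after t = {traj.times[-1]:.0f}")
# -> f = 1: the population abandons the social optimum for over-sociality.
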