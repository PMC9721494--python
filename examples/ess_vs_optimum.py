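"""The social dilemma of sociality: ESS vs social optimum.

Long-run adaptive dynamics push the sociality level to the strategy where
the local selection gradient vanishes (the ESS).  Whenever the two
contagions differ in transmissibility (c != 1), the ESS disagrees with the
level a benevolent planner would pick: too much interaction when the good
contagion spreads more readily (c < 1), too little when the bad does
(c > 1) — down to total collapse of sociality.
"""

from sociality import CobbDouglasUtility, pip_grid, social_dilemma_report, \
    sociality_rates

for alpha, c in [(0.75, 0.25), (0.75, 1.0), (0.75, 4.0), (0.25, 4.0)]:
    rep = social_dilemma_report(CobbDouglasUtility(alpha), c)
    print(f"alpha={alpha:4.2f} c={c:4.2f}:  R_ESS={rep.R_ESS:5.2f}  "
          f"R_opt={rep.R_opt:5.2f}  {rep.dilemma_direction.value:12s} "
          f"{rep.regime.value}")
# -> c=0.25: over-sociality (ESS 7 > opt 4); c=1: no dilemma; c=4: under-
#    sociality (3.25 < 4); alpha=0.25, c=4: sociality collapses to R=1,
#    the utility-minimizing state where the good contagion cannot spread.

# the same strategies expressed as interaction rates (p_g = 0.5, gamma_g = 1)
rep = social_dilemma_report(CobbDouglasUtility(0.75), 0.25)
print(f"sigma_ESS = {sociality_rates(rep.R_ESS, 0.5, 1.0):g} contacts/"
      f"recovery vs sigma_opt = {sociality_rates(rep.R_opt, 0.5, 1.0):g}")

# pairwise-invasibility structure around the ESS
grid = pip_grid(CobbDouglasUtility(0.75), 0.25, (2.0, 10.0), 41)
n_mutual = int(grid.mutual_matrix.sum())
print(f"PIP 41x41: {n_mutual} mutually-invasible cells "
      f"(dimorphism-compatible region near the ESS)")
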