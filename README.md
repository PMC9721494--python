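# sociality

**Evolution of social-interaction rates under a beneficial and a costly
contagion.**

Social contact spreads useful things (information, innovations) and harmful
ones (infectious disease) at the same time. `sociality` implements a
three-timescale model of how the level of social interaction itself evolves
under that tension, for theoretical ecologists and evolutionary
epidemiologists:

1. **Contagion (fast).** Two independent SIS contagions — a good one *g* and
   a bad one *b* — spread through contacts made at rate σ. A sociality
   strategy is summarised by the good contagion's basic reproduction number
   R⁽ᵍ⁾ = σp_g/γ_g; the bad contagion then has R⁽ᵇ⁾ = cR⁽ᵍ⁾, where
   c = p_bγ_g/(p_gγ_b) is its relative transmissibility. Each contagion
   settles at the endemic equilibrium Î = 1 − 1/R (when R > 1, else 0), also
   in populations mixing two strategies (resident R_r, mutant R_m at
   fraction f), where both groups share a contact-weighted infectious pool.
2. **Competition (intermediate).** An individual's payoff is a utility
   U(Î⁽ᵍ⁾, Ŝ⁽ᵇ⁾), increasing in time spent carrying the good contagion and
   in time spent free of the bad one — by default the Cobb-Douglas family
   U = (Î⁽ᵍ⁾)^α (Ŝ⁽ᵇ⁾)^{1−α} (linear and CES utilities are also provided).
   The mutant fraction follows the replicator equation
   df/dt = f(1−f)[U_m(f) − U_r(f)] with utilities evaluated at the
   quasi-static contagion equilibrium. For Cobb-Douglas utility the
   log-utility gap is strictly decreasing in f, so competition ends in
   mutant fixation, resident fixation, or a unique stable coexistence.
3. **Trait evolution (slow).** Adaptive dynamics of R⁽ᵍ⁾: invasion fitness
   s_{R_r}(R_m) = log U[R_m, R_r] − log U[R_r, R_r], its selection gradient,
   singular strategies and pairwise-invasibility plots. For Cobb-Douglas,

       R_ESS = max(1, 1/c + α/(1−α)),   R_opt = max(1/c, 1/(1−α)),

   and the two disagree whenever c ≠ 1 — a **social dilemma**: evolution
   oversocializes when the good contagion spreads more readily (c < 1) and
   undersocializes when the bad one does (c > 1), down to total collapse of
   sociality (R_ESS = 1) for small α and large c.

## Worked example

```python
from sociality import CobbDouglasUtility, social_dilemma_report, \
    simulate_replicator

model = CobbDouglasUtility(alpha=0.75)   # 3:1 weight on the good contagion

rep = social_dilemma_report(model, c=0.25)
print(rep.R_ESS, rep.R_opt, rep.dilemma_direction.value)
# 7.0 4.0 ESS_greater

traj = simulate_replicator(model, R_r=4.0, R_m=5.0, c=0.25, f0=0.05)
print(traj.terminal_f, traj.terminal_classification)
# 1.0 mutant_fixed
```

With the bad contagion four times *less* transmissible than the good
(c = 0.25), the socially optimal strategy R_opt = 4 just barely eliminates
the bad contagion — but it is not evolutionarily stable: a slightly more
social mutant (R_m = 5) obtains higher utility at every population
composition and fixes, and gradual evolution carries the population all the
way to R_ESS = 7, where the bad contagion is endemic and everyone is worse
off than at the optimum.

The `examples/` directory contains one short narrative script per
capability (`contagion_equilibria.py`, `strategy_competition.py`,
`coexistence.py`, `ess_vs_optimum.py`); each prints the numbers it computes
with a line on what they mean. A thin CLI exposes the same operations:

```sh
sociality ess --alpha 0.75 --c 0.25
# {"R_ESS": 7.0, "feasible": true, "is_ESS": true, ...}
sociality scenario --name fig5 --outdir out/
```

Scenario presets (`fig1` … `fig6`, `table1`) regenerate the model's
reference analyses as CSV tables, optionally with quick-look plots.

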