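# Methods

## Model

Two contagions spread independently through the same social contacts in a
well-mixed population: a beneficial one *g* (e.g. useful information) and a
harmful one *b* (e.g. an infectious disease). Both follow
susceptible–infectious–susceptible (SIS) dynamics: susceptibles are infected
on contact with an infectious partner (probabilities p_g, p_b) and recover
spontaneously (rates γ_g, γ_b) with no immunity. Individuals interact at
rate σ; a sociality *strategy* is the choice of σ, summarised throughout by
the good contagion's basic reproduction number R⁽ᵍ⁾ = σp_g/γ_g. The bad
contagion then has R⁽ᵇ⁾ = cR⁽ᵍ⁾ with c = p_bγ_g/(p_gγ_b) its relative
transmissibility. Because every quantity of interest is monotone in σ
through R⁽ᵍ⁾ alone (derivatives with respect to the two are proportional),
optima and evolutionarily stable strategies are computed in R⁽ᵍ⁾ and
converted back to σ = γ_gR/p_g on demand (`sociality_rates`).

Demography (births/deaths), interaction between the two contagions, network
structure and stochasticity are all outside the model's assumptions; see
Limitations.

### Timescale separation

Three nested timescales, each assumed fast relative to the next:

1. **Contagion.** For fixed strategies, prevalences relax to globally
   stable equilibria: Î = 1 − 1/R for R > 1, extinction otherwise. All ODEs
   are integrated in units of the respective recovery times (the γ's only
   matter when converting σ). With two strategies present (resident R_r,
   mutant R_m at fraction f) the force of infection is shared through the
   contact-weighted probability that a random contact is infectious,
   B = [R_r(1−f)I_r + R_mfI_m]/[R_r(1−f) + R_mf], and the mixed population
   has net reproduction number
   R_net = (fR_m² + (1−f)R_r²)/(fR_m + (1−f)R_r); the two-group SIS
   threshold theorem guarantees a unique endemic equilibrium iff R_net > 1.
2. **Competition.** Utilities are evaluated at those equilibria and the
   mutant fraction follows the replicator equation
   df/dt = f(1−f)[U_m(f) − U_r(f)]. Utilities are *never* co-integrated
   with the contagion ODEs: each replicator step re-solves the contagion
   equilibrium for the current f (quasi-static coupling), which both
   respects the model's timescale assumption and makes trajectories exactly
   reproducible.
3. **Trait evolution.** Rare mutants appear against a monomorphic resident
   at equilibrium. Their exposure has closed forms
   (Î_m⁽ᵍ⁾ = R_m(R_r−1)/(R_m(R_r−1)+R_r); Ŝ_m⁽ᵇ⁾ = R_r/(R_m(cR_r−1)+R_r)
   when cR_r > 1, else 1), giving the invasion fitness
   s_{R_r}(R_m) = log U[R_m,R_r] − log U[R_r,R_r] and, by differentiation,
   the local selection gradient. Note the partial ∂Ŝ_m⁽ᵇ⁾/∂R_m is
   *negative* when the bad contagion is endemic — a more social mutant is
   more exposed to both contagions; the implementation carries this sign
   explicitly and validates it against central finite differences.

### Utility models

A utility U(Î⁽ᵍ⁾, Ŝ⁽ᵇ⁾) must be strictly increasing in both arguments on
the open unit square (checked numerically before optimization; violations
raise `UtilityContractError`). Built in:

* **Cobb-Douglas** U = I^α S^{1−α}, α ∈ [0, 1] the weight on acquiring the
  good contagion. The primary model: the social optimum
  R_opt = max(1/c, 1/(1−α)), the singular strategy 1/c + α/(1−α), the ESS
  R_ESS = max(1, 1/c + α/(1−α)) and the selection gradient
  (α − (1−α)(R−1/c))/R² above the bad-contagion threshold (α/R² below it)
  are all closed-form, and the log-utility gap between two strategies is
  strictly decreasing in f, which excludes bistable fixation. The
  convention 0⁰ := 1 lets α ∈ {0, 1} degenerate to single-objective
  utilities. The interior singular strategy is infeasible (< 1) exactly
  when α < 1/2 and c > (1−α)/(1−2α); the boundary R = 1 is then returned
  as the (convergence-stable) ESS.
* **Linear** U = αI + (1−α)S. Not strictly concave: the monomorphic social
  utility can increase without bound in R (whenever αc > 1−α), reported as
  an `unbounded_above` sentinel status rather than a number.
* **CES** U = (αI^ρ + (1−α)S^ρ)^{1/ρ}, ρ < 1, ρ ≠ 0, recovering
  Cobb-Douglas as ρ → 0 (verified to 1e-4 at ρ = ±1e-6). The convention is
  the standard two-good CES; linear/CES evolutionary bistability is exposed
  only through exploratory diagnostics (multiple-root warnings), not as
  asserted results.

## Numerical choices

* **Thresholds.** At R = 1 (or cR = 1) exactly, the contagion-free branch
  is returned — "endemic" requires strictly R > 1. This matters in the
  reference scenario c = 0.25, R = 4, which sits exactly at cR = 1.
* **Dimorphic equilibria.** The per-contagion two-group fixed-point system
  reduces exactly to one scalar equation in the shared contact probability
  B (each group's prevalence is a_xB/(1 + a_xB)); its left side is strictly
  decreasing in B with a guaranteed sign change on (0, 1] iff R_net > 1, so
  bracketed `brentq` (xtol 1e-14) is unconditionally convergent. Residuals
  are checked against the full 4-dimensional right-hand side
  (tolerance 1e-10); a stiff ODE integration to t = 10⁴ recovery times
  remains as a fallback and serves as the independent oracle in tests
  (componentwise agreement 1e-6 on random parameter sets). Solver outputs
  are clipped to [0, 1].
* **Replicator integration.** Adaptive LSODA with terminal events: within
  1e-6 of a boundary (fixation), |df/dt| < 1e-10 (interior equilibrium), or
  t_max = 10⁵ in utility-scale time units. The default tolerances resolve
  the slow near-fixation regime of the c = 4 reference scenario, where the
  utility gap shrinks to ≈ 5·10⁻⁴.
* **Endpoint evaluation.** Utilities at f = 0 and f = 1 use the rare-type
  closed forms (with resident/mutant roles swapped at f = 1), not the
  dimorphic solver at the exact boundary, removing a 0/0 ambiguity.
  Endpoint utility differences below 1e-12 are reported as degenerate
  (selective neutrality), never silently classified.
* **Interior replicator equilibria.** A 41-point scan of U_m − U_r
  followed by `brentq` on each sign-change interval; for Cobb-Douglas the
  root is unique by monotonicity of the log-gap.
* **Social optima.** The monomorphic utility is piecewise smooth with kinks
  at R = 1 and R = 1/c, which generic optimizers miss; each smooth branch
  is maximized separately (bounded Brent, xatol 1e-10) and compared against
  the kink/boundary candidates, including the contagion-free candidate
  R = 1/c < 1 when c > 1. A positive derivative at the right search edge
  yields the `unbounded_above` status.
* **ESS classification.** Evolutionary stability from the sign of the
  invasion-fitness curvature in R_m (central second difference, step
  1e-4·R*, |curvature| < 1e-8 reported as neutral/degenerate); convergence
  stability from the +/− sign change of the gradient through R*. These are
  the standard adaptive-dynamics second-order criteria. For non-closed-form
  models the singular strategy is bracketed by doubling from
  max(1, 1/c)(1 + 1e-9) up to R_max = 10³ — generous enough for the c ≪ 1
  regime where R_ESS is large.
* **c = 1.** Structurally unstable; treated as exact equality only when
  |c − 1| < 1e-12, otherwise strictly compared.

## Reference scenarios and reported quantities

The scenario presets use the study parameterizations directly (no free
knobs): Cobb-Douglas α ∈ {0.25, 0.75}, c ∈ {0.25, 1, 4} (plus {0.5, 2} for
the ESS/optimum curves), resident R_r = 4 with mutants R_m ∈ {3, 5, 7}, and
the coexistence case (α, c, R_r, R_m) = (0.25, 0.25, 7, 3). The body text
and the figure caption of the mutant-dominance scenario disagree on R_m
(7 vs 5); both are provided (`fig2A_alt` vs `fig2A`) and both end in mutant
fixation. Pairwise-invasibility grids default to 81 points per axis
(closed-form invasion fitness, so grids are cheap); regime maps use a
41×41 (c, α) grid.

One reported quantity deviates from its published description: for the
coexistence scenario the interior equilibrium computed from the model as
specified is f_eq = 0.8187 (confirmed independently by root-finding on the
scalar-reduced fixed point, by long-time integration of the full
two-strategy ODE system, and by the endpoint utility gaps, which are
+0.167 at f = 0 but only −0.049 at f = 1 and therefore place the crossing
well above 0.5), whereas the original description quotes "around 0.6". A
uniformly-mixed (non-contact-weighted) infection pool would move the value
to 0.66 but contradicts both the stated two-strategy dynamics and the net
reproduction number above. The package reports the computed value.

## What the tests do and do not show

All inputs are model parameters; there is no data generator beyond the
parameter grids of the scenario presets, and the pipeline is fully
deterministic. The tests verify internal consistency (closed forms vs
independent numerical routes: ODE integration vs equilibrium solver,
finite differences vs analytic gradients, dynamics vs endpoint
classification) and the study's qualitative laws (threshold behaviour,
monotonicity, the dilemma-direction law sign(R_ESS − R_opt) = sign(1 − c)).
They say nothing about how well the idealized model describes any real
social system.

## Limitations

* Both contagions are simple (bilinear-incidence) SIS processes spreading
  independently; no superinfection, awareness coupling, complex contagion,
  or virulence coevolution.
* The population is well-mixed and effectively infinite: no network
  structure, no demographic turnover, no finite-population drift
  (replicator and adaptive dynamics are deterministic).
* At most two strategies compete at once; the adaptive dynamics assume
  rare, small-effect mutations.
* Utilities depend only on equilibrium exposure, so transient epidemics
  carry no payoff consequences.
* The assortative-interaction extension and expected-payoff derivations of
  the utility families are out of scope.
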