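"""Replicator competition between two fixed sociality strategies.

On the intermediate evolutionary timescale the mutant fraction f obeys

    df/dt = f (1 - f) [U_m(f) - U_r(f)],

where the utilities are evaluated at the *equilibrium* of the two-strategy
contagion system for the current f (quasi-static timescale separation:
contagion dynamics are assumed much faster than strategy competition, so
Eq-level co-integration is never performed).

For Cobb-Douglas utility the log-utility difference log U_m - log U_r is
strictly decreasing in f, which yields exactly three outcomes — mutant
fixation, resident fixation, or a unique globally-stable interior
coexistence — determined by the utility comparison at the endpoints f = 0
and f = 1 (evaluated via the rare-type closed forms, avoiding a 0/0 solver
ambiguity at the exact boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .contagion import DimorphicParams, mono_equilibrium, ContagionParams, \
    mutant_rare_equilibrium
from .utility import UtilityModel, strategy_utilities

__all__ = [
    "OutcomeKind",
    "PairwiseOutcome",
    "ReplicatorTrajectory",
    "DegenerateCompetitionError",
    "replicator_rhs",
    "simulate_replicator",
    "find_interior_equilibrium",
    "classify_pairwise",
]

_BOUNDARY_TOL = 1e-6
_NEUTRAL_TOL = 1e-12


class DegenerateCompetitionError(ValueError):
    """Both endpoint utility differences are numerically zero."""


class OutcomeKind(str, Enum):
    MUTANT_DOMINATES = "MUTANT_DOMINATES"
    RESIDENT_DOMINATES = "RESIDENT_DOMINATES"
    COEXISTENCE = "COEXISTENCE"
    BISTABILITY = "BISTABILITY"  # impossible for Cobb-Douglas (see Prop. below)


@dataclass(frozen=True)
class PairwiseOutcome:
    """Long-run outcome of pairwise strategy competition."""

    kind: OutcomeKind
    endpoint_signs: tuple[int, int]  # sign of U_m - U_r at f=0 and f=1
    f_eq: float | None = None  # interior equilibrium, COEXISTENCE only


@dataclass(frozen=True)
class ReplicatorTrajectory:
    """Integrated mutant-fraction trajectory with per-step utilities."""

    times: np.ndarray
    f_values: np.ndarray
    U_r: np.ndarray
    U_m: np.ndarray
    terminal_f: float
    terminal_classification: str  # mutant_fixed | resident_fixed | interior | max_time

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "f": self.f_values,
                             "U_r": self.U_r, "U_m": self.U_m})


def _utilities_at(model: UtilityModel, R_r: float, R_m: float, c: float,
                  f: float) -> tuple[float, float]:
    """(U_r, U_m) from the quasi-static dimorphic contagion equilibrium."""
    return strategy_utilities(model, DimorphicParams(R_r=R_r, R_m=R_m, f=f, c=c))


def replicator_rhs(f: float, model: UtilityModel, R_r: float, R_m: float,
                   c: float) -> float:
    """df/dt = f(1-f)[U_m(f) - U_r(f)] at the contagion equilibrium for f."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"f must be in [0, 1], got {f}")
    if f == 0.0 or f == 1.0:
        return 0.0
    U_r, U_m = _utilities_at(model, R_r, R_m, c, f)
    return f * (1.0 - f) * (U_m - U_r)


def simulate_replicator(model: UtilityModel, R_r: float, R_m: float, c: float,
                        f0: float, t_max: float = 1e5,
                        tol: float = 1e-10) -> ReplicatorTrajectory:
    """Integrate the replicator equation from f0 until (near-)convergence.

    Stops when f comes within 1e-6 of a boundary (fixation), when |df/dt|
    drops below ``tol`` (interior equilibrium), or at ``t_max``.  Time is in
    units where utilities are O(1).
    """
    if not (0.0 < f0 < 1.0):
        raise ValueError(f"f0 must be in (0, 1), got {f0}")

    def rhs(_t, y):
        f = float(np.clip(y[0], 0.0, 1.0))
        return [replicator_rhs(f, model, R_r, R_m, c)]

    def hit_lower(_t, y):
        return y[0] - _BOUNDARY_TOL

    def hit_upper(_t, y):
        return (1.0 - _BOUNDARY_TOL) - y[0]

    def stalled(t, y):
        if t == 0.0:
            return 1.0
        return abs(rhs(t, y)[0]) - tol

    hit_lower.terminal = hit_upper.terminal = stalled.terminal = True
    sol = solve_ivp(rhs, (0.0, t_max), [f0], method="LSODA",
                    events=[hit_lower, hit_upper, stalled],
                    rtol=1e-9, atol=1e-12, max_step=t_max / 50)
    if not sol.success:
        raise RuntimeError(f"replicator integration failed: {sol.message}")

    times = sol.t
    f_values = np.clip(sol.y[0], 0.0, 1.0)
    terminal_f = float(f_values[-1])
    if terminal_f >= 1.0 - 2 * _BOUNDARY_TOL:
        classification = "mutant_fixed"
        terminal_f = 1.0
    elif terminal_f <= 2 * _BOUNDARY_TOL:
        classification = "resident_fixed"
        terminal_f = 0.0
    elif sol.status == 1:  # stalled interior
        classification = "interior"
    else:
        classification = "max_time"

    U_r = np.empty_like(f_values)
    U_m = np.empty_like(f_values)
    for i, f in enumerate(f_values):
        fc = float(np.clip(f, _BOUNDARY_TOL, 1.0 - _BOUNDARY_TOL))
        U_r[i], U_m[i] = _utilities_at(model, R_r, R_m, c, fc)
    return ReplicatorTrajectory(times=times, f_values=f_values, U_r=U_r,
                                U_m=U_m, terminal_f=terminal_f,
                                terminal_classification=classification)


def _utility_gap(model: UtilityModel, R_r: float, R_m: float, c: float,
                 f: float) -> float:
    U_r, U_m = _utilities_at(model, R_r, R_m, c, f)
    return U_m - U_r


def find_interior_equilibrium(model: UtilityModel, R_r: float, R_m: float,
                              c: float, scan_points: int = 41):
    """Interior root(s) of U_m(f) - U_r(f) on (0, 1).

    Bisection (brentq) on each sign-change interval of a coarse scan of the
    utility gap.  For Cobb-Douglas the gap's log-form is strictly decreasing
    in f, so at most one root exists and a float (or None) is returned;
    should a non-Cobb-Douglas model produce several sign changes, all roots
    are returned with a multiplicity warning.
    """
    if R_r == R_m:
        raise ValueError("interior equilibrium requires distinct strategies")
    lo, hi = _BOUNDARY_TOL, 1.0 - _BOUNDARY_TOL
    grid = np.linspace(lo, hi, scan_points)
    gaps = np.array([_utility_gap(model, R_r, R_m, c, f) for f in grid])
    roots: list[float] = []
    for a, b, ga, gb in zip(grid[:-1], grid[1:], gaps[:-1], gaps[1:]):
        if ga == 0.0:
            roots.append(float(a))
        elif ga * gb < 0.0:
            roots.append(float(brentq(
                lambda f: _utility_gap(model, R_r, R_m, c, f), a, b,
                xtol=1e-12)))
    if gaps[-1] == 0.0:
        roots.append(float(grid[-1]))
    if not roots:
        return None
    if len(roots) > 1:
        warnings.warn(f"multiple interior equilibria found ({len(roots)}); "
                      "returning all", RuntimeWarning)
        return roots
    return roots[0]


def endpoint_utility_gaps(model: UtilityModel, R_r: float, R_m: float,
                          c: float) -> tuple[float, float]:
    """U_m - U_r in the rare-mutant (f=0) and rare-resident (f=1) limits,
    via the closed-form rare-type equilibria."""
    # f -> 0: residents monomorphic, mutant rare
    res_eq = mono_equilibrium(ContagionParams(R_g=R_r, c=c))
    I_m_g, S_m_b = mutant_rare_equilibrium(R_m, R_r, c)
    gap0 = model.value(I_m_g, S_m_b) - model.value(res_eq.I_g, res_eq.S_b)
    # f -> 1: mutants monomorphic, resident rare (roles swapped)
    mut_eq = mono_equilibrium(ContagionParams(R_g=R_m, c=c))
    I_r_g, S_r_b = mutant_rare_equilibrium(R_r, R_m, c)
    gap1 = model.value(mut_eq.I_g, mut_eq.S_b) - model.value(I_r_g, S_r_b)
    return gap0, gap1


def classify_pairwise(model: UtilityModel, R_r: float, R_m: float,
                      c: float) -> PairwiseOutcome:
    """Classify pairwise competition from the endpoint utility comparison.

    For Cobb-Douglas with R_r, R_m >= 1 (at least one > 1) the log-utility
    gap is strictly decreasing in f, so the endpoint signs fully determine
    the outcome: (+,+) mutant fixes, (-,-) resident fixes, (+,-) unique
    stable coexistence.  The (-,+) bistable pattern cannot occur under
    Cobb-Douglas; if a non-Cobb-Douglas model produces it, it is reported as
    BISTABILITY with a warning.
    """
    if min(R_r, R_m) < 1.0:
        warnings.warn("classification outside the R >= 1 hypotheses; "
                      "falling back to endpoint signs + scan", RuntimeWarning)
    gap0, gap1 = endpoint_utility_gaps(model, R_r, R_m, c)
    if abs(gap0) < _NEUTRAL_TOL and abs(gap1) < _NEUTRAL_TOL:
        raise DegenerateCompetitionError(
            "utility difference vanishes at both endpoints; strategies are "
            "selectively neutral at this tolerance")
    s0 = 1 if gap0 > 0 else -1
    s1 = 1 if gap1 > 0 else -1
    if s0 > 0 and s1 > 0:
        return PairwiseOutcome(OutcomeKind.MUTANT_DOMINATES, (s0, s1))
    if s0 < 0 and s1 < 0:
        return PairwiseOutcome(OutcomeKind.RESIDENT_DOMINATES, (s0, s1))
    if s0 > 0 and s1 < 0:
        f_eq = find_interior_equilibrium(model, R_r, R_m, c)
        if isinstance(f_eq, list):  # pragma: no cover - non-CD multiplicity
            f_eq = f_eq[0]
        return PairwiseOutcome(OutcomeKind.COEXISTENCE, (s0, s1), f_eq=f_eq)
    warnings.warn("endpoint signs indicate bistability, which is impossible "
                  "under Cobb-Douglas utility", RuntimeWarning)
    return PairwiseOutcome(OutcomeKind.BISTABILITY, (s0, s1))
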