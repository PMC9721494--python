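"""Adaptive dynamics of the sociality level: invasion analysis, singular
strategies/ESS, pairwise-invasibility plots, and the social-dilemma report.

On the slowest timescale the population is essentially monomorphic at a
resident strategy R_r and rare mutants with nearby strategies R_m arise.
The invasion fitness is the log-utility advantage of a rare mutant at the
resident's contagion equilibrium,

    s_{R_r}(R_m) = log U[R_m, R_r] - log U[R_r, R_r],

its derivative at R_m = R_r is the local selection gradient, and zeros of
the gradient are singular strategies.  For Cobb-Douglas utility everything
is closed-form: the gradient is alpha/R_r^2 below the bad-contagion
threshold R_r = 1/c and [alpha - (1-alpha)(R_r - 1/c)]/R_r^2 above it,
giving the ESS

    R_ESS = max(1, 1/c + alpha/(1-alpha)),

to be compared with the social optimum R_opt = max(1/c, 1/(1-alpha)).  The
two disagree whenever c != 1 — the social dilemma — with sign(R_ESS - R_opt)
= sign(1 - c).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .contagion import (
    ContagionParams,
    mono_equilibrium,
    mutant_rare_equilibrium,
    mutant_rare_sensitivities,
)
from .utility import CobbDouglasUtility, UtilityModel, social_optimum

__all__ = [
    "SingularStrategyResult",
    "PIPGrid",
    "RegimeClassification",
    "DilemmaDirection",
    "Regime",
    "invasion_fitness",
    "selection_gradient",
    "singular_strategy",
    "social_dilemma_report",
    "pip_grid",
    "sociality_rates",
]

_C_EQUALITY_TOL = 1e-12
_CURVATURE_NEUTRAL_TOL = 1e-8


def _mutant_utility(model: UtilityModel, R_m: float, R_r: float, c: float) -> float:
    I_m_g, S_m_b = mutant_rare_equilibrium(R_m, R_r, c)
    return model.value(I_m_g, S_m_b)


def invasion_fitness(R_m: float, R_r: float, model: UtilityModel,
                     c: float) -> float:
    """Invasion fitness s_{R_r}(R_m) = log U[R_m,R_r] - log U[R_r,R_r].

    Requires a resident that sustains the good contagion (R_r > 1 for
    Cobb-Douglas, whose utility vanishes otherwise).  A zero utility on
    either side is mapped to a signed infinity with a diagnostic warning
    rather than a silent NaN; s(R_r, R_r) = 0 exactly.
    """
    if R_m == R_r:
        return 0.0
    U_res = _mutant_utility(model, R_r, R_r, c)
    U_mut = _mutant_utility(model, R_m, R_r, c)
    if U_res == 0.0 and U_mut == 0.0:
        warnings.warn("both utilities vanish; invasion fitness undefined "
                      "(returning 0: selectively neutral)", RuntimeWarning)
        return 0.0
    if U_res == 0.0:
        warnings.warn("resident utility is 0 (R_r <= 1 under Cobb-Douglas); "
                      "any mutant with positive utility invades",
                      RuntimeWarning)
        return math.inf
    if U_mut == 0.0:
        warnings.warn("mutant utility is 0; invasion impossible",
                      RuntimeWarning)
        return -math.inf
    return math.log(U_mut) - math.log(U_res)


def selection_gradient(R_r: float, model: UtilityModel, c: float) -> float:
    """Local selection gradient d s_{R_r}(R_m)/d R_m at R_m = R_r.

    Cobb-Douglas: exact piecewise closed form (always positive below the
    bad-contagion threshold, decreasing in R_r).  General models: assembled
    from the model's partial derivatives and the rare-mutant equilibrium
    sensitivities, on the log-utility scale, i.e.
    (U_I dI/dR_m + U_S dS/dR_m) / U evaluated at the monomorphic equilibrium.
    """
    if not (R_r > 1.0):
        raise ValueError(f"selection gradient requires R_r > 1, got {R_r}")
    if not (c > 0):
        raise ValueError(f"c must be > 0, got {c}")
    if isinstance(model, CobbDouglasUtility):
        a = model.alpha
        if c * R_r <= 1.0:
            return a / R_r**2
        return (a - (1.0 - a) * (R_r - 1.0 / c)) / R_r**2
    eq = mono_equilibrium(ContagionParams(R_g=R_r, c=c))
    U = model.value(eq.I_g, eq.S_b)
    if U <= 0.0:
        raise ValueError("selection gradient undefined at zero utility")
    dI, dS = mutant_rare_sensitivities(R_r, R_r, c)
    dU = model.partial_I_g(eq.I_g, eq.S_b) * dI \
        + model.partial_S_b(eq.I_g, eq.S_b) * dS
    return dU / U


@dataclass(frozen=True)
class SingularStrategyResult:
    """Singular strategy of the adaptive dynamics with stability labels."""

    R_star: float
    feasible: bool  # interior singular strategy exceeds 1
    is_ESS: bool
    is_convergence_stable: bool
    boundary: bool  # R_star = 1 returned via the infeasibility condition
    curvature: float = float("nan")  # d2 s / d R_m^2 at the singular point
    degenerate: bool = False  # |curvature| below the neutrality tolerance


def _invasion_curvature(model: UtilityModel, c: float, R_star: float) -> float:
    h = 1e-4 * R_star
    s_plus = invasion_fitness(R_star + h, R_star, model, c)
    s_minus = invasion_fitness(R_star - h, R_star, model, c)
    return (s_plus + s_minus) / h**2  # s(R_star, R_star) = 0


def _convergence_stable(model: UtilityModel, c: float, R_star: float) -> bool:
    h = max(1e-6, 1e-4 * R_star)
    below = selection_gradient(max(R_star - h, 1.0 + 1e-9), model, c)
    above = selection_gradient(R_star + h, model, c)
    return below > 0.0 and above < 0.0


def singular_strategy(model: UtilityModel, c: float,
                      R_max: float = 1e3) -> SingularStrategyResult:
    """Singular strategy / ESS of the sociality adaptive dynamics.

    Cobb-Douglas uses the closed form max(1, 1/c + alpha/(1-alpha)); the
    interior point is infeasible (boundary R=1 returned) when alpha < 1/2
    and c > (1-alpha)/(1-2alpha).  Other models: bracketed root-finding on
    the selection gradient over (max(1, 1/c)(1+eps), R_max], expanding the
    bracket by doubling; no sign change returns the boundary with a
    diagnostic.  Evolutionary stability is the negative curvature of the
    invasion fitness in R_m at the singular point (central second
    difference); convergence stability is the +/- sign change of the
    gradient through it.
    """
    if not (c > 0):
        raise ValueError(f"c must be > 0, got {c}")
    if isinstance(model, CobbDouglasUtility):
        a = model.alpha
        if a >= 1.0:
            raise ValueError("alpha = 1 puts no weight on the bad contagion; "
                             "sociality increases without bound")
        interior = 1.0 / c + a / (1.0 - a)
        feasible = interior > 1.0
        if not feasible:
            # gradient negative for all R_r > 1; boundary ESS at R = 1
            return SingularStrategyResult(
                R_star=1.0, feasible=False, is_ESS=True,
                is_convergence_stable=True, boundary=True)
        R_star = interior
    else:
        lo = max(1.0, 1.0 / c) * (1.0 + 1e-9)
        g_lo = selection_gradient(lo, model, c)
        if g_lo <= 0.0:
            return SingularStrategyResult(
                R_star=1.0, feasible=False, is_ESS=True,
                is_convergence_stable=True, boundary=True)
        hi = 2.0 * lo
        while hi <= R_max and selection_gradient(hi, model, c) > 0.0:
            hi *= 2.0
        if hi > R_max:
            warnings.warn("selection gradient positive up to R_max; "
                          "returning R_max as a censored singular strategy",
                          RuntimeWarning)
            return SingularStrategyResult(
                R_star=R_max, feasible=True, is_ESS=False,
                is_convergence_stable=False, boundary=True)
        R_star = brentq(lambda R: selection_gradient(R, model, c), lo, hi,
                        xtol=1e-12)

    curv = _invasion_curvature(model, c, R_star)
    degenerate = abs(curv) < _CURVATURE_NEUTRAL_TOL
    if degenerate:
        warnings.warn("invasion-fitness curvature at the singular strategy "
                      "is numerically zero; ESS status is neutral/degenerate",
                      RuntimeWarning)
    return SingularStrategyResult(
        R_star=R_star, feasible=True, is_ESS=(curv < 0.0) and not degenerate,
        is_convergence_stable=_convergence_stable(model, c, R_star),
        boundary=False, curvature=curv, degenerate=degenerate)


class DilemmaDirection(str, Enum):
    ESS_GREATER = "ESS_greater"
    EQUAL = "equal"
    ESS_SMALLER = "ESS_smaller"


class Regime(str, Enum):
    """Qualitative regimes of the ESS vs social-optimum comparison."""

    ESS_EXCEEDS_OPT_BAD_ELIMINATED_AT_OPT = "ESS_exceeds_opt_bad_eliminated_at_opt"
    ESS_EXCEEDS_OPT_BAD_ENDEMIC = "ESS_exceeds_opt_bad_endemic"
    ESS_BELOW_OPT_INTERIOR = "ESS_below_opt_interior"
    ESS_COLLAPSE_NO_SOCIALITY = "ESS_collapse_no_sociality"


@dataclass(frozen=True)
class RegimeClassification:
    """ESS vs social optimum, with the dilemma direction and regime label."""

    regime: Regime
    R_opt: float
    R_ESS: float
    dilemma_direction: DilemmaDirection
    details: dict = field(default_factory=dict, compare=False)


def social_dilemma_report(model: UtilityModel, c: float) -> RegimeClassification:
    """Compare the evolutionarily-stable and socially-optimal strategies.

    The dilemma direction follows sign(1 - c) for any utility meeting the
    monotone contract: the ESS oversocializes when the good contagion
    spreads more readily (c < 1) and undersocializes when c > 1; the two
    coincide only at the structurally-unstable point c = 1.  The four
    qualitative regimes (Cobb-Douglas case conditions: c vs 1 - alpha and
    alpha c vs (1-alpha)(c-1)) distinguish the two extreme dilemmas — bad
    contagion endemic at the ESS though eliminated at the optimum, and total
    collapse of sociality (R_ESS = 1, the good contagion cannot spread).
    """
    sing = singular_strategy(model, c)
    R_ESS = sing.R_star
    if isinstance(model, CobbDouglasUtility):
        R_opt = model.social_optimum_closed_form(c)
        details: dict = {"alpha": model.alpha}
    else:
        opt = social_optimum(model, c)
        R_opt = opt.R_opt
        details = {"optimum_status": opt.status}
    details["singular"] = sing

    if abs(c - 1.0) < _C_EQUALITY_TOL:
        direction = DilemmaDirection.EQUAL
    elif c < 1.0:
        direction = DilemmaDirection.ESS_GREATER
    else:
        direction = DilemmaDirection.ESS_SMALLER

    if R_ESS <= 1.0:
        regime = Regime.ESS_COLLAPSE_NO_SOCIALITY
    elif direction is DilemmaDirection.ESS_SMALLER:
        regime = Regime.ESS_BELOW_OPT_INTERIOR
    elif R_opt <= 1.0 / c + 1e-12 and c < 1.0:
        regime = Regime.ESS_EXCEEDS_OPT_BAD_ELIMINATED_AT_OPT
    else:
        regime = Regime.ESS_EXCEEDS_OPT_BAD_ENDEMIC
    return RegimeClassification(regime=regime, R_opt=R_opt, R_ESS=R_ESS,
                                dilemma_direction=direction, details=details)


@dataclass(frozen=True)
class PIPGrid:
    """Sign of invasion fitness over a resident x mutant strategy grid."""

    resident_axis: np.ndarray
    mutant_axis: np.ndarray
    sign_matrix: np.ndarray  # entry [i, j]: sign of s_{R_r=res[j]}(R_m=mut[i])
    mutual_matrix: np.ndarray  # True where each strategy invades the other

    def to_frame(self):
        import pandas as pd

        rr, mm = np.meshgrid(self.resident_axis, self.mutant_axis)
        return pd.DataFrame({
            "R_r": rr.ravel(), "R_m": mm.ravel(),
            "sign": self.sign_matrix.ravel().astype(int),
            "mutual": self.mutual_matrix.ravel(),
        })


def pip_grid(model: UtilityModel, c: float,
             R_range: tuple[float, float], n: int) -> PIPGrid:
    """Pairwise-invasibility plot data on an n x n grid.

    Diagonal entries are exactly 0 (self-invasion is neutral); the companion
    boolean matrix marks mutual invasibility, s(R_m; R_r) > 0 together with
    s(R_r; R_m) > 0, the dimorphism-compatible region.
    """
    lo, hi = R_range
    if not (hi > lo > 1.0):
        raise ValueError("R_range must lie strictly above 1")
    if n < 3:
        raise ValueError("need n >= 3 grid points")
    axis = np.linspace(lo, hi, n)
    s = np.zeros((n, n))
    for j, R_r in enumerate(axis):
        for i, R_m in enumerate(axis):
            s[i, j] = invasion_fitness(R_m, R_r, model, c)
    sign = np.sign(s).astype(int)
    mutual = (sign > 0) & (sign.T > 0)
    return PIPGrid(resident_axis=axis, mutant_axis=axis,
                   sign_matrix=sign, mutual_matrix=mutual)


def sociality_rates(R: float, p_g: float, gamma_g: float) -> float:
    """Convert a good-contagion reproduction number back to the underlying
    social-interaction rate: sigma = gamma_g * R / p_g."""
    if not (0.0 < p_g <= 1.0):
        raise ValueError(f"p_g must be in (0, 1], got {p_g}")
    if not (gamma_g > 0):
        raise ValueError(f"gamma_g must be > 0, got {gamma_g}")
    if R < 0:
        raise ValueError("R must be >= 0")
    return gamma_g * R / p_g
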