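"""Utility (fitness) functions over equilibrium contagion exposure.

A sociality strategy is evaluated through the equilibrium fraction of time
spent carrying the good contagion, I_g, and the fraction of time free of the
bad contagion, S_b.  Every model must be strictly increasing in both
arguments on the open unit square: individuals always prefer more of the
good contagion and less of the bad.

Built-in families:

* Cobb-Douglas  U = I_g^alpha * S_b^(1-alpha)  (the primary model; admits
  closed-form optima throughout the analysis),
* linear        U = alpha * I_g + (1-alpha) * S_b,
* CES           U = (alpha * I_g^rho + (1-alpha) * S_b^rho)^(1/rho), rho < 1,
  rho != 0, recovering Cobb-Douglas as rho -> 0.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .contagion import (
    ContagionParams,
    DimorphicParams,
    dimorphic_equilibrium,
    mono_equilibrium,
)

__all__ = [
    "UtilityModel",
    "CobbDouglasUtility",
    "LinearUtility",
    "CESUtility",
    "UtilityContractError",
    "OptimumResult",
    "evaluate_utility",
    "monomorphic_utility",
    "social_optimum",
    "strategy_utilities",
    "make_utility",
]

_FD_STEP = 1e-7


class UtilityContractError(ValueError):
    """A utility model violated the positive-partial-derivative contract."""


def _check_unit(name: str, x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {x}")


class UtilityModel(ABC):
    """Interface: utility of an exposure pair with signed partials."""

    @abstractmethod
    def value(self, I_g: float, S_b: float) -> float:
        """Utility at exposure (I_g, S_b); nonnegative on the unit square."""

    def partial_I_g(self, I_g: float, S_b: float) -> float:
        """dU/dI_g; central finite difference unless overridden analytically."""
        h = _FD_STEP
        lo, hi = max(I_g - h, 0.0), min(I_g + h, 1.0)
        return (self.value(hi, S_b) - self.value(lo, S_b)) / (hi - lo)

    def partial_S_b(self, I_g: float, S_b: float) -> float:
        h = _FD_STEP
        lo, hi = max(S_b - h, 0.0), min(S_b + h, 1.0)
        return (self.value(I_g, hi) - self.value(I_g, lo)) / (hi - lo)


def _check_alpha(alpha: float) -> None:
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")


@dataclass(frozen=True)
class CobbDouglasUtility(UtilityModel):
    """U = I_g^alpha * S_b^(1-alpha), with the 0^0 := 1 convention so the
    degenerate weights alpha in {0, 1} reduce to single-argument utilities."""

    alpha: float

    def __post_init__(self) -> None:
        _check_alpha(self.alpha)

    @staticmethod
    def _pow(base: float, exp: float) -> float:
        if exp == 0.0:
            return 1.0
        return base ** exp

    def value(self, I_g: float, S_b: float) -> float:
        _check_unit("I_g", I_g)
        _check_unit("S_b", S_b)
        return self._pow(I_g, self.alpha) * self._pow(S_b, 1.0 - self.alpha)

    def partial_I_g(self, I_g: float, S_b: float) -> float:
        a = self.alpha
        if a == 0.0:
            return 0.0
        return a * self._pow(I_g, a - 1.0) * self._pow(S_b, 1.0 - a)

    def partial_S_b(self, I_g: float, S_b: float) -> float:
        a = self.alpha
        if a == 1.0:
            return 0.0
        return (1.0 - a) * self._pow(I_g, a) * self._pow(S_b, -a)

    def social_optimum_closed_form(self, c: float) -> float:
        """R_opt = max(1/c, 1/(1-alpha)); infinite for alpha = 1."""
        if self.alpha >= 1.0:
            return math.inf
        return max(1.0 / c, 1.0 / (1.0 - self.alpha))

    def ess_closed_form(self, c: float) -> float:
        """R_ESS = max(1, 1/c + alpha/(1-alpha)); infinite for alpha = 1."""
        if self.alpha >= 1.0:
            return math.inf
        return max(1.0, 1.0 / c + self.alpha / (1.0 - self.alpha))


@dataclass(frozen=True)
class LinearUtility(UtilityModel):
    """U = alpha * I_g + (1-alpha) * S_b.  Not strictly concave: the social
    optimum can be unbounded above for some (alpha, c)."""

    alpha: float

    def __post_init__(self) -> None:
        _check_alpha(self.alpha)

    def value(self, I_g: float, S_b: float) -> float:
        _check_unit("I_g", I_g)
        _check_unit("S_b", S_b)
        return self.alpha * I_g + (1.0 - self.alpha) * S_b

    def partial_I_g(self, I_g: float, S_b: float) -> float:
        return self.alpha

    def partial_S_b(self, I_g: float, S_b: float) -> float:
        return 1.0 - self.alpha


@dataclass(frozen=True)
class CESUtility(UtilityModel):
    """Constant-elasticity-of-substitution utility.

    U = (alpha * I_g^rho + (1-alpha) * S_b^rho)^(1/rho) with rho < 1 and
    rho != 0; strictly concave, and the rho -> 0 limit is Cobb-Douglas.
    For rho < 0 a zero argument sends the utility to its limit 0.
    """

    alpha: float
    rho: float

    def __post_init__(self) -> None:
        _check_alpha(self.alpha)
        if self.rho == 0.0 or self.rho >= 1.0:
            raise ValueError(f"rho must be < 1 and != 0, got {self.rho}")

    def value(self, I_g: float, S_b: float) -> float:
        _check_unit("I_g", I_g)
        _check_unit("S_b", S_b)
        a, r = self.alpha, self.rho
        if r < 0.0 and (I_g == 0.0 or S_b == 0.0):
            return 0.0
        inner = a * I_g ** r + (1.0 - a) * S_b ** r
        if inner <= 0.0:
            return 0.0
        return inner ** (1.0 / r)

    def partial_I_g(self, I_g: float, S_b: float) -> float:
        v = self.value(I_g, S_b)
        if v == 0.0 or I_g == 0.0:
            return self._limit_partial()
        return self.alpha * (v / I_g) ** (1.0 - self.rho)

    def partial_S_b(self, I_g: float, S_b: float) -> float:
        v = self.value(I_g, S_b)
        if v == 0.0 or S_b == 0.0:
            return self._limit_partial()
        return (1.0 - self.alpha) * (v / S_b) ** (1.0 - self.rho)

    def _limit_partial(self) -> float:
        # boundary limit: derivative diverges for rho in (0,1), vanishes rho<0
        return 0.0 if self.rho < 0.0 else math.inf


def evaluate_utility(model: UtilityModel, I_g: float, S_b: float) -> float:
    """Utility of an exposure pair; validates the unit-square domain."""
    return model.value(I_g, S_b)


def monomorphic_utility(model: UtilityModel, R: float, c: float) -> float:
    """Utility of strategy R adopted population-wide, at contagion equilibrium.

    Composes the monomorphic endemic equilibria into the model; for
    Cobb-Douglas this reproduces the three-branch piecewise social utility
    (0 for R <= 1; (1-1/R)^alpha while the bad contagion cannot spread;
    (1-1/R)^alpha (1/(cR))^(1-alpha) once it can).
    """
    eq = mono_equilibrium(ContagionParams(R_g=R, c=c))
    return model.value(eq.I_g, eq.S_b)


@dataclass(frozen=True)
class OptimumResult:
    """Outcome of the social-utility maximization over strategies R."""

    R_opt: float
    utility: float
    status: str  # 'interior' | 'boundary' | 'unbounded_above'
    branch: str  # which piecewise branch/boundary produced the maximizer
    candidates: dict = field(default_factory=dict, compare=False)


def _contract_check(model: UtilityModel) -> None:
    rng = np.random.default_rng(0)
    for I_g, S_b in rng.uniform(0.05, 0.95, size=(8, 2)):
        if model.partial_I_g(I_g, S_b) < -1e-12 or model.partial_S_b(I_g, S_b) < -1e-12:
            raise UtilityContractError(
                "utility model must be nondecreasing in both exposures "
                f"(negative partial at I_g={I_g:.3f}, S_b={S_b:.3f})")


def social_optimum(model: UtilityModel, c: float,
                   search_interval: tuple[float, float] = (1.0, 1e3)
                   ) -> OptimumResult:
    """Global maximizer of the monomorphic social utility U(R).

    The utility is piecewise smooth with kinks at the epidemic thresholds
    R = 1 (good contagion) and R = 1/c (bad contagion), so each smooth branch
    is maximized separately (bounded Brent) and compared against the boundary
    candidates, including R = 1/c < 1 (neither contagion spreads) when c > 1.
    If the utility is still rising at the right edge of the interval the
    result is flagged ``unbounded_above`` (possible for linear utility).
    """
    if not (c > 0):
        raise ValueError(f"c must be > 0, got {c}")
    lo, hi = search_interval
    if not (hi > lo >= 0):
        raise ValueError(f"invalid search interval {search_interval}")
    _contract_check(model)

    U = lambda R: monomorphic_utility(model, R, c)

    # breakpoints of the piecewise structure inside [lo, hi]
    kinks = sorted({lo, hi} | {x for x in (1.0, 1.0 / c) if lo < x < hi})
    candidates: dict[str, tuple[float, float]] = {}
    for x in kinks:
        candidates[f"boundary R={x:g}"] = (x, U(x))
    if c > 1.0 and lo <= 1.0 / c:
        # contagion-free candidate below the good-contagion threshold
        candidates["boundary R=1/c (contagion-free)"] = (1.0 / c, U(1.0 / c))
    eps = 1e-9
    for a, b in zip(kinks[:-1], kinks[1:]):
        if b - a < 4 * eps:
            continue
        res = minimize_scalar(lambda R: -U(R), bounds=(a + eps, b - eps),
                              method="bounded",
                              options={"xatol": 1e-10})
        candidates[f"interior ({a:g}, {b:g})"] = (float(res.x), U(float(res.x)))

    branch, (R_opt, best) = max(candidates.items(), key=lambda kv: kv[1][1])
    # snap to an adjacent kink when the interior optimizer stalls at a bound
    for x in kinks:
        if abs(R_opt - x) < 1e-6 and U(x) >= best - 1e-12:
            R_opt, best = x, U(x)
            branch = f"boundary R={x:g}"

    h = 1e-6 * hi
    rising_at_edge = U(hi) - U(hi - h) > 1e-12 * max(1.0, abs(U(hi)))
    if rising_at_edge and U(hi) >= best - 1e-12:
        return OptimumResult(R_opt=math.inf, utility=U(hi),
                             status="unbounded_above", branch="right edge",
                             candidates=candidates)
    status = "interior" if branch.startswith("interior") else "boundary"
    return OptimumResult(R_opt=R_opt, utility=best, status=status,
                         branch=branch, candidates=candidates)


def strategy_utilities(model: UtilityModel,
                       dparams: DimorphicParams) -> tuple[float, float]:
    """(U_r, U_m): utilities of the two strategies at the dimorphic
    contagion equilibrium for the current mutant fraction."""
    eq = dimorphic_equilibrium(dparams)
    U_r = model.value(eq.I_r_g, eq.S_r_b)
    U_m = model.value(eq.I_m_g, eq.S_m_b)
    return U_r, U_m


def make_utility(model: str, alpha: float, rho: float | None = None) -> UtilityModel:
    """Construct a built-in utility model from config-style keys."""
    model = model.lower()
    if model in ("cobb_douglas", "cd"):
        return CobbDouglasUtility(alpha=alpha)
    if model == "linear":
        return LinearUtility(alpha=alpha)
    if model == "ces":
        if rho is None:
            raise ValueError("CES utility requires rho")
        return CESUtility(alpha=alpha, rho=rho)
    raise ValueError(f"unknown utility model {model!r}")
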