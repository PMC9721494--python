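"""Coupled good/bad SIS contagion dynamics and their endemic equilibria.

Two contagions spread independently through the same social contacts: a
beneficial one ("good", e.g. useful information) and a harmful one ("bad",
e.g. an infectious disease).  An individual's sociality strategy is summarised
by the good contagion's basic reproduction number ``R_g = sigma * p_g / gamma_g``;
the bad contagion then has ``R_b = c * R_g`` where ``c`` is its relative
transmissibility.  Time is measured in units of the respective recovery times,
so the per-contagion dynamics take the logistic form
``dI/dt = R (1 - I) I - I``.

The module covers the monomorphic case (one strategy population-wide), the
dimorphic case (a resident strategy ``R_r`` and a mutant strategy ``R_m``
present at fraction ``f``), and the rare-mutant limit used by the adaptive
dynamics analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ContagionParams",
    "MonoEquilibrium",
    "MonoTrajectory",
    "DimorphicParams",
    "DimorphicEquilibrium",
    "reproduction_numbers",
    "mono_rhs",
    "mono_equilibrium",
    "simulate_mono",
    "net_reproduction_number",
    "dimorphic_rhs",
    "dimorphic_equilibrium",
    "mutant_rare_equilibrium",
    "mutant_rare_sensitivities",
]

_RATE_CONSISTENCY_RTOL = 1e-9
_CLIP_SLACK = 1e-12


def _endemic_prevalence(R: float) -> float:
    """Endemic SIS prevalence 1 - 1/R, zero at and below threshold R <= 1."""
    return 1.0 - 1.0 / R if R > 1.0 else 0.0


@dataclass(frozen=True)
class ContagionParams:
    """Reproduction numbers of the two contagions.

    Parameters
    ----------
    R_g : float
        Basic reproduction number of the good contagion, >= 0.  The canonical
        sociality coordinate.
    c : float
        Relative transmissibility of the bad contagion, > 0, so R_b = c * R_g.
    sigma, p_g, p_b, gamma_g, gamma_b : float, optional
        Underlying rates: social-interaction rate, per-contact transmission
        probabilities and recovery rates.  When supplied they must be
        consistent with (R_g, c) to relative tolerance 1e-9.
    """

    R_g: float
    c: float
    sigma: float | None = None
    p_g: float | None = None
    p_b: float | None = None
    gamma_g: float | None = None
    gamma_b: float | None = None

    def __post_init__(self) -> None:
        if not (self.R_g >= 0.0):
            raise ValueError(f"R_g must be >= 0, got {self.R_g}")
        if not (self.c > 0.0):
            raise ValueError(f"c must be > 0, got {self.c}")
        raw = (self.sigma, self.p_g, self.p_b, self.gamma_g, self.gamma_b)
        if any(v is not None for v in raw):
            if any(v is None for v in raw):
                raise ValueError("either supply all raw rates or none")
            R_g = self.sigma * self.p_g / self.gamma_g
            c = (self.p_b * self.gamma_g) / (self.p_g * self.gamma_b)
            for name, want, got in (("R_g", R_g, self.R_g), ("c", c, self.c)):
                if not math.isclose(want, got, rel_tol=_RATE_CONSISTENCY_RTOL,
                                    abs_tol=_RATE_CONSISTENCY_RTOL):
                    raise ValueError(
                        f"{name}={got} inconsistent with raw rates (expected {want})"
                    )

    @property
    def R_b(self) -> float:
        """Bad-contagion reproduction number c * R_g."""
        return self.c * self.R_g


def reproduction_numbers(sigma: float, p_g: float, p_b: float,
                         gamma_g: float, gamma_b: float) -> ContagionParams:
    """Convert raw interaction/transmission/recovery rates to (R_g, c).

    R_g = sigma * p_g / gamma_g and c = (p_b * gamma_g) / (p_g * gamma_b).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    for name, p in (("p_g", p_g), ("p_b", p_b)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    for name, g in (("gamma_g", gamma_g), ("gamma_b", gamma_b)):
        if not (g > 0.0):
            raise ValueError(f"{name} must be > 0, got {g}")
    if p_g == 0.0:
        raise ValueError("p_g = 0 leaves the relative transmissibility c undefined")
    R_g = sigma * p_g / gamma_g
    c = (p_b * gamma_g) / (p_g * gamma_b)
    return ContagionParams(R_g=R_g, c=c, sigma=sigma, p_g=p_g, p_b=p_b,
                           gamma_g=gamma_g, gamma_b=gamma_b)


@dataclass(frozen=True)
class MonoEquilibrium:
    """Endemic equilibrium prevalences for a monomorphic population."""

    I_g: float
    I_b: float

    @property
    def S_b(self) -> float:
        return 1.0 - self.I_b


def mono_equilibrium(params: ContagionParams) -> MonoEquilibrium:
    """Globally-stable equilibrium of the decoupled SIS pair.

    I_g = 1 - 1/R_g when R_g > 1 (else 0); I_b = 1 - 1/(c R_g) when
    c R_g > 1 (else 0).  At threshold exactly (R = 1) the contagion-free
    branch is returned.
    """
    return MonoEquilibrium(I_g=_endemic_prevalence(params.R_g),
                           I_b=_endemic_prevalence(params.R_b))


def mono_rhs(I_g: float, I_b: float, params: ContagionParams) -> tuple[float, float]:
    """Time derivatives of the two prevalences, in recovery-time units."""
    for name, I in (("I_g", I_g), ("I_b", I_b)):
        if not (0.0 <= I <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {I}")
    dI_g = params.R_g * (1.0 - I_g) * I_g - I_g
    dI_b = params.R_b * (1.0 - I_b) * I_b - I_b
    return dI_g, dI_b


@dataclass(frozen=True)
class MonoTrajectory:
    """Integrated monomorphic prevalences on a time grid."""

    t: np.ndarray
    I_g: np.ndarray
    I_b: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "I_g": self.I_g, "I_b": self.I_b})


def simulate_mono(params: ContagionParams, init: tuple[float, float],
                  t_grid: np.ndarray) -> MonoTrajectory:
    """Integrate the monomorphic SIS pair over ``t_grid`` (recovery units)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a 1-D strictly increasing array")
    I_g0, I_b0 = init
    for name, I in (("I_g(0)", I_g0), ("I_b(0)", I_b0)):
        if not (0.0 <= I <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {I}")

    def rhs(_t, y):
        I_g, I_b = np.clip(y, 0.0, 1.0)
        return mono_rhs(I_g, I_b, params)

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [I_g0, I_b0],
                    t_eval=t_grid, method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"SIS integration failed: {sol.message}")
    I_g, I_b = np.clip(sol.y, 0.0, 1.0)
    return MonoTrajectory(t=sol.t, I_g=I_g, I_b=I_b)


@dataclass(frozen=True)
class DimorphicParams:
    """Resident + mutant strategy pair with mutant fraction f."""

    R_r: float
    R_m: float
    f: float
    c: float

    def __post_init__(self) -> None:
        if not (self.R_r >= 0.0):
            raise ValueError(f"R_r must be >= 0, got {self.R_r}")
        if not (self.R_m >= 0.0):
            raise ValueError(f"R_m must be >= 0, got {self.R_m}")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if not (self.c > 0.0):
            raise ValueError(f"c must be > 0, got {self.c}")


def net_reproduction_number(R_r: float, R_m: float, f: float) -> float:
    """Basic reproduction number of a contagion in the mixed population.

    R_net = (f R_m^2 + (1-f) R_r^2) / (f R_m + (1-f) R_r); the population's
    contact-weighted mean strategy, weighted again by contact rate.
    """
    denom = f * R_m + (1.0 - f) * R_r
    if denom <= 0.0:
        raise ValueError("f*R_m + (1-f)*R_r must be positive")
    return (f * R_m**2 + (1.0 - f) * R_r**2) / denom


@dataclass(frozen=True)
class DimorphicEquilibrium:
    """Equilibrium prevalences for resident/mutant under good/bad contagion."""

    I_r_g: float
    I_m_g: float
    I_r_b: float
    I_m_b: float

    @property
    def S_r_b(self) -> float:
        return 1.0 - self.I_r_b

    @property
    def S_m_b(self) -> float:
        return 1.0 - self.I_m_b


def dimorphic_rhs(state, dparams: DimorphicParams) -> np.ndarray:
    """Right-hand side of the two-strategy SIS system (recovery-time units).

    Both contagions share the same mean-field contact term
    ``B = [R_r (1-f) I_r + R_m f I_m] / [R_r (1-f) + R_m f]`` — the
    probability that a random contact is with an infectious individual —
    evaluated with that contagion's own prevalences.
    """
    I_r_g, I_m_g, I_r_b, I_m_b = state
    for name, I in (("I_r_g", I_r_g), ("I_m_g", I_m_g),
                    ("I_r_b", I_r_b), ("I_m_b", I_m_b)):
        if not (0.0 <= I <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {I}")
    R_r, R_m, f = dparams.R_r, dparams.R_m, dparams.f
    D = R_r * (1.0 - f) + R_m * f
    if D <= 0.0:
        raise ValueError("degenerate contact pool: R_r*(1-f) + R_m*f must be > 0")

    def pair(a_r: float, a_m: float, I_r: float, I_m: float) -> tuple[float, float]:
        B = (R_r * (1.0 - f) * I_r + R_m * f * I_m) / D
        return (a_r * B * (1.0 - I_r) - I_r, a_m * B * (1.0 - I_m) - I_m)

    dI_r_g, dI_m_g = pair(R_r, R_m, I_r_g, I_m_g)
    dI_r_b, dI_m_b = pair(dparams.c * R_r, dparams.c * R_m, I_r_b, I_m_b)
    return np.array([dI_r_g, dI_m_g, dI_r_b, dI_m_b])


def _pair_equilibrium(R_r: float, R_m: float, f: float, c_scale: float,
                      tol: float = 1e-14) -> tuple[float, float]:
    """Endemic equilibrium (I_r, I_m) of one contagion in the mixed population.

    ``c_scale`` rescales both reproduction numbers (1 for the good contagion,
    c for the bad).  The 2-D fixed-point system reduces exactly to a scalar
    equation in the shared infectious-contact probability B: at equilibrium
    I_x = a_x B / (1 + a_x B), and B solves
    ``a_r^2 (1-f) / (1 + a_r B) + a_m^2 f / (1 + a_m B) = a_r (1-f) + a_m f``.
    The left side is strictly decreasing in B, equals D * R_net at B = 0 and
    is below D at B = 1, so a positive root exists iff R_net > 1 and brentq
    on (0, 1] is unconditionally convergent (uniqueness per the two-group SIS
    threshold theorem of Hethcote & Yorke).
    """
    a_r, a_m = c_scale * R_r, c_scale * R_m
    D = a_r * (1.0 - f) + a_m * f
    if D <= 0.0:
        return 0.0, 0.0
    R_net = (a_r**2 * (1.0 - f) + a_m**2 * f) / D
    if R_net <= 1.0:
        return 0.0, 0.0

    def g(B: float) -> float:
        return (a_r**2 * (1.0 - f) / (1.0 + a_r * B)
                + a_m**2 * f / (1.0 + a_m * B) - D)

    lo = 1e-16
    if g(lo) <= 0.0:  # root below floating resolution of the bracket
        return 0.0, 0.0
    B = brentq(g, lo, 1.0, xtol=tol, rtol=8.9e-16)
    I_r = a_r * B / (1.0 + a_r * B)
    I_m = a_m * B / (1.0 + a_m * B)
    return I_r, I_m


def _dimorphic_ode_equilibrium(dparams: DimorphicParams,
                               t_final: float = 1e4) -> np.ndarray:
    """Fallback/oracle: integrate the dimorphic system to its attractor."""
    R_net_g = net_reproduction_number(dparams.R_r, dparams.R_m, dparams.f) \
        if dparams.R_r * (1 - dparams.f) + dparams.R_m * dparams.f > 0 else 0.0
    y0 = np.full(4, 0.01)
    if R_net_g <= 1.0:
        y0[:2] = 0.0
    if dparams.c * R_net_g <= 1.0:
        y0[2:] = 0.0

    def rhs(_t, y):
        return dimorphic_rhs(np.clip(y, 0.0, 1.0), dparams)

    sol = solve_ivp(rhs, (0.0, t_final), y0, method="LSODA",
                    rtol=1e-12, atol=1e-13)
    if not sol.success:
        raise RuntimeError(f"dimorphic ODE fallback failed: {sol.message}")
    return np.clip(sol.y[:, -1], 0.0, 1.0)


def dimorphic_equilibrium(dparams: DimorphicParams,
                          residual_tol: float = 1e-10) -> DimorphicEquilibrium:
    """Unique globally-attracting equilibrium of the two-strategy system.

    Solved per contagion by bracketed scalar root-finding on the shared
    contact probability (see ``_pair_equilibrium``); zeros are returned for a
    contagion whose net reproduction number is <= 1.  Falls back to long-time
    ODE integration if the root-finder result fails the residual check.
    """
    I_r_g, I_m_g = _pair_equilibrium(dparams.R_r, dparams.R_m, dparams.f, 1.0)
    I_r_b, I_m_b = _pair_equilibrium(dparams.R_r, dparams.R_m, dparams.f, dparams.c)
    state = np.clip([I_r_g, I_m_g, I_r_b, I_m_b], 0.0, 1.0)
    resid = np.max(np.abs(dimorphic_rhs(state, dparams)))
    if resid > residual_tol:
        warnings.warn(
            f"dimorphic root-finder residual {resid:.2e} > {residual_tol:.0e}; "
            "falling back to ODE integration", RuntimeWarning)
        state = _dimorphic_ode_equilibrium(dparams)
        resid = np.max(np.abs(dimorphic_rhs(state, dparams)))
        if resid > 1e-8:
            raise RuntimeError(
                f"dimorphic equilibrium did not converge (residual {resid:.2e})")
    return DimorphicEquilibrium(*state)


def mutant_rare_equilibrium(R_m: float, R_r: float, c: float) -> tuple[float, float]:
    """Rare-mutant (f -> 0) equilibrium exposure (I_m_g, S_m_b).

    With the resident at its monomorphic equilibrium, a vanishing mutant
    cohort with strategy R_m equilibrates at

        I_m_g = R_m (R_r - 1) / (R_m (R_r - 1) + R_r)      if R_r > 1, else 0
        S_m_b = R_r / (R_m (c R_r - 1) + R_r)              if c R_r > 1, else 1
    """
    if R_m < 0 or R_r < 0:
        raise ValueError("reproduction numbers must be >= 0")
    if not (c > 0):
        raise ValueError(f"c must be > 0, got {c}")
    I_m_g = (R_m * (R_r - 1.0) / (R_m * (R_r - 1.0) + R_r)
             if R_r > 1.0 else 0.0)
    S_m_b = (R_r / (R_m * (c * R_r - 1.0) + R_r)
             if c * R_r > 1.0 else 1.0)
    return I_m_g, S_m_b


def mutant_rare_sensitivities(R_m: float, R_r: float, c: float) -> tuple[float, float]:
    """Partial derivatives of the rare-mutant exposure w.r.t. R_m.

    dI_m_g/dR_m = R_r (R_r - 1) / (R_m R_r + R_r - R_m)^2 > 0;
    dS_m_b/dR_m = -R_r (c R_r - 1) / (c R_m R_r + R_r - R_m)^2 < 0 when
    c R_r > 1 (else 0): a more social mutant is more exposed to both
    contagions.  At R_m = R_r these reduce to (R_r-1)/R_r^3 and
    -(c R_r - 1)/(c^2 R_r^3).
    """
    if not (R_r > 1.0):
        raise ValueError(f"sensitivities require R_r > 1, got {R_r}")
    if R_m < 0:
        raise ValueError("R_m must be >= 0")
    dI = R_r * (R_r - 1.0) / (R_m * R_r + R_r - R_m) ** 2
    if c * R_r > 1.0:
        dS = -R_r * (c * R_r - 1.0) / (c * R_m * R_r + R_r - R_m) ** 2
    else:
        dS = 0.0
    return dI, dS
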