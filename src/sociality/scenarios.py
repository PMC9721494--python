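"""Scenario presets, configuration handling and tabular output.

Each preset reproduces one of the study's illustrative parameterizations:
utility/equilibrium sweeps (``fig1``), pairwise strategy competition with
mutant dominance (``fig2A``/``fig2A_alt``/``fig2C``), stable coexistence
(``fig3``), pairwise-invasibility plots (``fig4``), the (c, alpha) regime
map (``fig5``), ESS and optimum curves vs alpha (``fig6``), and a numeric
check of the regime case conditions (``table1``).  All outputs are CSV
(floats at 12 significant digits); plotting is optional so the numeric
pipeline carries no rendering dependency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adaptive import pip_grid, social_dilemma_report
from .contagion import ContagionParams, DimorphicParams, dimorphic_equilibrium, \
    mono_equilibrium
from .replicator import classify_pairwise, find_interior_equilibrium
from .utility import CobbDouglasUtility, make_utility, strategy_utilities

__all__ = ["ScenarioConfig", "load_config", "dump_config", "run_scenario",
           "export_table", "PRESETS"]

logger = logging.getLogger("sociality")

_FLOAT_FMT = "%.12g"

# Preset parameterizations (fig2A follows the figure caption R_m = 5; the
# body text uses R_m = 7, provided as fig2A_alt — both give mutant fixation).
PRESETS: dict[str, dict] = {
    "fig1": {},
    "fig2A": {"alpha": 0.75, "c": 0.25, "R_r": 4.0, "R_m": 5.0},
    "fig2A_alt": {"alpha": 0.75, "c": 0.25, "R_r": 4.0, "R_m": 7.0},
    "fig2C": {"alpha": 0.75, "c": 4.0, "R_r": 4.0, "R_m": 3.0},
    "fig3": {"alpha": 0.25, "c": 0.25, "R_r": 7.0, "R_m": 3.0},
    "fig4": {},
    "fig5": {},
    "fig6": {},
    "table1": {},
}
# panel aliases: {scenario: fig2, panel: A} etc.
_PANELS = {("fig2", "A"): "fig2A", ("fig2", "A-alt"): "fig2A_alt",
           ("fig2", "C"): "fig2C"}

_KNOWN_KEYS = {"scenario", "panel", "utility", "alpha", "rho", "c",
               "sigma", "p_g", "p_b", "gamma_g", "gamma_b",
               "R_r", "R_m", "f0", "grid_min", "grid_max", "grid_n",
               "t_max", "tol", "outdir", "seed", "plot"}


@dataclass
class ScenarioConfig:
    """Validated scenario configuration with defaults filled.

    The random seed is reserved for future stochastic extensions; the
    current pipeline is deterministic.
    """

    scenario: str
    panel: str | None = None
    utility: str = "cobb_douglas"
    alpha: float = 0.75
    rho: float | None = None
    c: float = 0.25
    R_r: float | None = None
    R_m: float | None = None
    f0: float = 0.5
    grid_min: float = 1.05
    grid_max: float = 12.0
    grid_n: int = 61
    t_max: float = 1e5
    tol: float = 1e-10
    outdir: str = "."
    seed: int = 0
    plot: bool = False

    def __post_init__(self) -> None:
        name = self.scenario
        if name == "fig2" and self.panel is None:
            self.panel = "A"  # caption parameterization by default
        if self.panel is not None:
            key = (name, self.panel)
            if key not in _PANELS:
                raise ValueError(f"unknown panel {self.panel!r} for {name!r}")
            name = _PANELS[key]
        if name not in PRESETS:
            raise ValueError(
                f"unknown scenario {name!r}; known: {sorted(PRESETS)}")
        self._resolved = name
        for k, v in PRESETS[name].items():
            if getattr(self, k) is None or k not in self._explicit:
                setattr(self, k, v)
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (self.c > 0):
            raise ValueError(f"c must be > 0, got {self.c}")
        if not (0.0 < self.f0 < 1.0):
            raise ValueError(f"f0 must be in (0, 1), got {self.f0}")
        for k in ("R_r", "R_m"):
            v = getattr(self, k)
            if v is not None and v < 0:
                raise ValueError(f"{k} must be >= 0, got {v}")
        if self.grid_n < 3 or not (self.grid_max > self.grid_min):
            raise ValueError("invalid strategy grid specification")
        if self.t_max <= 0 or self.tol <= 0:
            raise ValueError("t_max and tol must be positive")

    # set of keys the user supplied explicitly (filled by load_config)
    _explicit: frozenset = field(default=frozenset(), repr=False, compare=False)

    @property
    def resolved_scenario(self) -> str:
        return self._resolved

    def model(self):
        return make_utility(self.utility, self.alpha, self.rho)

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if not k.startswith("_") and v is not None}
        return d


def _from_mapping(data: dict) -> ScenarioConfig:
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "scenario" not in data:
        raise ValueError("config must name a scenario")
    cfg = ScenarioConfig(**data, _explicit=frozenset(data))
    return cfg


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML or JSON scenario configuration."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return _from_mapping(data)


def dump_config(cfg: ScenarioConfig, path: str | Path) -> None:
    """Write a config back out (YAML); load(dump(x)) round-trips."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def export_table(results, path: str | Path) -> Path:
    """Write a DataFrame (or object exposing ``to_frame``) as CSV with
    floats at 12 significant digits; deterministic byte-for-byte."""
    if hasattr(results, "to_frame") and not isinstance(results, pd.DataFrame):
        results = results.to_frame()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def _strategy_sweep(cfg: ScenarioConfig, f_grid: np.ndarray) -> pd.DataFrame:
    model = cfg.model()
    rows = []
    for f in f_grid:
        dp = DimorphicParams(R_r=cfg.R_r, R_m=cfg.R_m, f=float(f), c=cfg.c)
        eq = dimorphic_equilibrium(dp)
        U_r, U_m = strategy_utilities(model, dp)
        rows.append({"f": f, "I_r_g": eq.I_r_g, "I_m_g": eq.I_m_g,
                     "I_r_b": eq.I_r_b, "I_m_b": eq.I_m_b,
                     "U_r": U_r, "U_m": U_m})
    return pd.DataFrame(rows)


def _run_fig1(cfg: ScenarioConfig, outdir: Path) -> dict:
    R_grid = np.linspace(0.0, 12.0, 241)
    rows = []
    for c in (0.25, 1.0, 4.0):
        for alpha in (0.25, 0.5, 0.75):
            model = CobbDouglasUtility(alpha=alpha)
            for R in R_grid:
                eq = mono_equilibrium(ContagionParams(R_g=max(R, 0.0), c=c))
                rows.append({"c": c, "alpha": alpha, "R": R, "I_g": eq.I_g,
                             "S_b": eq.S_b,
                             "U": model.value(eq.I_g, eq.S_b)})
    df = pd.DataFrame(rows)
    export_table(df, outdir / "fig1_utility_curves.csv")
    return {"rows": len(df)}


def _run_fig2(cfg: ScenarioConfig, outdir: Path) -> dict:
    name = cfg.resolved_scenario
    df = _strategy_sweep(cfg, np.linspace(0.01, 0.99, 50))
    export_table(df, outdir / f"{name}_competition.csv")
    outcome = classify_pairwise(cfg.model(), cfg.R_r, cfg.R_m, cfg.c)
    min_gap = float(np.min(df.U_m - df.U_r))
    return {"outcome": outcome.kind.value, "min_utility_gap": min_gap}


def _run_fig3(cfg: ScenarioConfig, outdir: Path) -> dict:
    df = _strategy_sweep(cfg, np.linspace(0.01, 0.99, 50))
    export_table(df, outdir / "fig3_coexistence.csv")
    f_eq = find_interior_equilibrium(cfg.model(), cfg.R_r, cfg.R_m, cfg.c)
    return {"f_eq": f_eq}


def _run_fig4(cfg: ScenarioConfig, outdir: Path) -> dict:
    summaries = {}
    frames = []
    for c in (0.25, 1.0, 4.0):
        for alpha in (0.25, 0.75):
            model = CobbDouglasUtility(alpha=alpha)
            hi = max(2.0 / c + alpha / (1 - alpha), 10.0)
            grid = pip_grid(model, c, (1.05, hi), cfg.grid_n)
            df = grid.to_frame()
            df.insert(0, "alpha", alpha)
            df.insert(0, "c", c)
            frames.append(df)
            summaries[f"c={c:g},alpha={alpha:g}"] = \
                model.ess_closed_form(c)
    export_table(pd.concat(frames, ignore_index=True),
                 outdir / "fig4_pip.csv")
    return {"ess_markers": summaries}


def _run_fig5(cfg: ScenarioConfig, outdir: Path) -> dict:
    rows = []
    for c in np.geomspace(0.1, 10.0, 41):
        for alpha in np.linspace(0.02, 0.98, 41):
            rep = social_dilemma_report(CobbDouglasUtility(alpha=alpha), c)
            rows.append({"c": c, "alpha": alpha, "R_opt": rep.R_opt,
                         "R_ESS": rep.R_ESS, "regime": rep.regime.value,
                         "direction": rep.dilemma_direction.value})
    df = pd.DataFrame(rows)
    export_table(df, outdir / "fig5_regimes.csv")
    return {"regimes": sorted(df.regime.unique())}


def _run_fig6(cfg: ScenarioConfig, outdir: Path) -> dict:
    rows = []
    for c in (2.0, 0.5):
        for alpha in np.linspace(0.01, 0.95, 95):
            model = CobbDouglasUtility(alpha=alpha)
            rows.append({"c": c, "alpha": alpha,
                         "R_ESS": model.ess_closed_form(c),
                         "R_opt": model.social_optimum_closed_form(c)})
    df = pd.DataFrame(rows)
    export_table(df, outdir / "fig6_ess_vs_opt.csv")
    gap_c2 = df[df.c == 2.0].eval("R_ESS - R_opt")
    return {"max_gap_at_c2": float(gap_c2.max())}


def _run_table1(cfg: ScenarioConfig, outdir: Path) -> dict:
    rows = []
    mismatches = 0
    for c in np.geomspace(0.2, 5.0, 13):
        for alpha in np.linspace(0.05, 0.95, 13):
            model = CobbDouglasUtility(alpha=alpha)
            R_ESS = model.ess_closed_form(c)
            R_opt = model.social_optimum_closed_form(c)
            # printed case conditions
            if alpha * c > (1 - alpha) * (c - 1):
                want_ess = 1.0 / c + alpha / (1 - alpha)
            else:
                want_ess = 1.0
            want_opt = 1.0 / c if c < 1 - alpha else 1.0 / (1 - alpha)
            ok = (abs(R_ESS - max(1.0, want_ess)) < 1e-12
                  and abs(R_opt - want_opt) < 1e-12)
            mismatches += not ok
            rows.append({"c": c, "alpha": alpha, "R_ESS": R_ESS,
                         "R_opt": R_opt, "case_consistent": ok})
    export_table(pd.DataFrame(rows), outdir / "table1_cases.csv")
    return {"mismatches": mismatches}


def run_scenario(cfg: ScenarioConfig) -> dict:
    """Run a scenario preset; writes CSV tables, returns a summary dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = cfg.resolved_scenario
    logger.info("running scenario %s", name)
    runners = {"fig1": _run_fig1, "fig2A": _run_fig2, "fig2A_alt": _run_fig2,
               "fig2C": _run_fig2, "fig3": _run_fig3, "fig4": _run_fig4,
               "fig5": _run_fig5, "fig6": _run_fig6, "table1": _run_table1}
    try:
        summary = runners[name](cfg, outdir)
    except Exception:
        logger.exception("scenario %s failed", name)
        raise
    summary["scenario"] = name
    if cfg.plot:
        _render(name, outdir)
    logger.info("scenario %s done: %s", name, summary)
    (outdir / f"{name}_summary.json").write_text(
        json.dumps(summary, indent=2, default=str))
    return summary


def _render(name: str, outdir: Path) -> None:
    """Optional quick-look plots for scenario CSV output (headless Agg)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for csv in sorted(outdir.glob(f"{name}*.csv")):
        df = pd.read_csv(csv)
        fig, ax = plt.subplots(figsize=(5, 4))
        num = df.select_dtypes("number")
        x = num.columns[0]
        for col in num.columns[1:6]:
            ax.plot(num[x], num[col], label=col, lw=1)
        ax.set_xlabel(x)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(csv.with_suffix(".png"), dpi=110)
        plt.close(fig)
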