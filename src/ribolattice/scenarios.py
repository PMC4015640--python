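"""Named scenario presets mirroring the study's worked example and figures.

Every preset is runnable with no further input and fixed seeds; simulation
presets default to reduced step counts suitable for tests (``full=True``
restores figure-scale run lengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import meanfield, pbn, petri, simulate
from .lattice import LatticeConfig
from .regulation import (FeedbackSpec, PrematureStopSpec, feedback_fixed_point,
                         make_slow_profile)

__all__ = ["Scenario", "scenario_presets", "run_scenario", "compare_backends"]


@dataclass(frozen=True)
class Scenario:
    """A runnable preset: base rates, optional sweep and regulation."""

    name: str
    note: str
    n: int
    r: int
    alpha: float
    beta: float
    gamma: float
    sweep_param: str | None = None          # "alpha" | "slow_rate" | "mu" | "k_I" | "d_I"
    sweep_values: tuple[float, ...] = ()
    slow_positions: tuple[int, ...] = ()
    stop_position: int | None = None
    feedback: FeedbackSpec | None = None
    backends: tuple[str, ...] = ("pbn", "sim-rs", "sim-par", "petri", "heinrich")
    seed: int = 20140227
    steps: int = 20000
    full_steps: int = 400000

    def config(self) -> LatticeConfig:
        return LatticeConfig(self.n, self.r, self.alpha, self.beta, self.gamma)


def scenario_presets() -> dict[str, Scenario]:
    """All named presets keyed by name."""
    presets = [
        Scenario(
            name="toy-pbn", n=2, r=1, alpha=0.6, beta=0.4, gamma=1.0,
            note="worked 2-codon example: exact state density, codon density "
                 "and translation rate", backends=("pbn", "sim-rs"),
            steps=100000, full_steps=100000),
        Scenario(
            name="fig2", n=50, r=12, alpha=0.1, beta=0.5, gamma=0.5,
            sweep_param="alpha",
            sweep_values=(0.05, 0.2, 0.5),
            note="model comparison sweep over the initiation rate, "
                 "beta = gamma = 0.5",
            backends=("sim-rs", "petri", "heinrich")),
        Scenario(
            name="fig3", n=50, r=12, alpha=0.1, beta=0.5, gamma=1.0,
            sweep_param="alpha", sweep_values=(0.05, 0.2, 0.5),
            note="update-rule comparison sweep over the initiation rate, "
                 "beta = 0.5, gamma = 1",
            backends=("sim-rs", "sim-par")),
        Scenario(
            name="fig4-single", n=50, r=12, alpha=1.0, beta=1.0, gamma=1.0,
            sweep_param="slow_rate", sweep_values=(0.2, 0.5, 1.0),
            slow_positions=(25,),
            note="single slow codon at codon 25, alpha = beta = 1",
            backends=("pbn", "sim-rs", "sim-par", "petri")),
        Scenario(
            name="fig4-double", n=50, r=12, alpha=1.0, beta=1.0, gamma=1.0,
            sweep_param="slow_rate", sweep_values=(0.2, 0.5, 1.0),
            slow_positions=(25, 26),
            note="two consecutive equally-slow codons at 25-26, alpha = beta = 1",
            backends=("pbn", "sim-rs", "sim-par", "petri")),
        Scenario(
            name="fig5", n=50, r=12, alpha=1.0, beta=0.1, gamma=1.0,
            sweep_param="mu", sweep_values=(0.2, 0.5, 0.8),
            stop_position=25,
            note="premature stop codon at codon 25 with readthrough sweep, "
                 "alpha = 1, beta = 0.1",
            backends=("pbn", "sim-rs", "sim-par")),
        Scenario(
            name="fig6-k", n=50, r=12, alpha=1.0, beta=1.0, gamma=1.0,
            sweep_param="k_I", sweep_values=(0.0, 1.0, 4.0),
            feedback=FeedbackSpec(alpha_I=1.0, k_I=1.0, d_I=1.0, rho_m=1.0),
            note="initiation autoregulation, sweep over feedback strength k_I "
                 "(alpha_I = 1 is this package's choice; not stated in the study)",
            backends=("feedback",)),
        Scenario(
            name="fig6-d", n=50, r=12, alpha=1.0, beta=1.0, gamma=1.0,
            sweep_param="d_I", sweep_values=(0.5, 1.0, 2.0),
            feedback=FeedbackSpec(alpha_I=1.0, k_I=1.0, d_I=1.0, rho_m=1.0),
            note="initiation autoregulation, sweep over degradation rate d_I",
            backends=("feedback",)),
    ]
    return {s.name: s for s in presets}


def compare_backends(config: LatticeConfig, backends, stop=None,
                     steps: int = 20000, seed: int = 0) -> dict[str, float]:
    """Translation rate from each requested backend on one configuration."""
    out: dict[str, float] = {}
    for b in backends:
        if b == "pbn":
            out["c_pbn"] = pbn.solve(config, stop=stop).c
        elif b == "sim-rs":
            s = simulate.run(config, simulate.SimulationConfig(
                "efficient-varying", steps=steps, seed=seed), stop=stop)
            out["c_sim_rs"] = s.c
        elif b == "sim-par":
            s = simulate.run(config, simulate.SimulationConfig(
                "parallel", steps=steps, seed=seed + 1), stop=stop)
            out["c_sim_par"] = s.c
        elif b == "petri":
            out["c_petri"] = petri.pn_translation_rate(config, stop=stop)
        elif b == "heinrich":
            out["c_heinrich"] = meanfield.mf_steady_state(
                meanfield.MeanFieldParams(config)).c
        else:
            raise ValueError(f"unknown backend {b!r}")
    return out


def run_scenario(scenario: Scenario, full: bool = False,
                 solver_steps: int | None = None) -> pd.DataFrame:
    """Run one preset end to end; one row per sweep value (or a single row)."""
    steps = solver_steps or (scenario.full_steps if full else scenario.steps)
    values = scenario.sweep_values or (None,)
    rows = []
    for v in values:
        cfg = scenario.config()
        stop = None
        fb = scenario.feedback
        if scenario.sweep_param == "alpha" and v is not None:
            cfg = LatticeConfig(cfg.n, cfg.r, v, cfg.beta, cfg.gamma)
        elif scenario.sweep_param == "slow_rate" and v is not None:
            cfg = make_slow_profile(cfg, scenario.slow_positions, v)
        elif scenario.sweep_param == "mu" and v is not None:
            stop = PrematureStopSpec(scenario.stop_position, v)
        elif scenario.sweep_param == "k_I" and v is not None:
            fb = FeedbackSpec(fb.alpha_I, v, fb.d_I, fb.rho_m)
        elif scenario.sweep_param == "d_I" and v is not None:
            fb = FeedbackSpec(fb.alpha_I, fb.k_I, v, fb.rho_m)
        if scenario.stop_position is not None and stop is None:
            stop = PrematureStopSpec(scenario.stop_position, 1.0)

        row: dict = {}
        if scenario.sweep_param:
            row[scenario.sweep_param] = v
        if "feedback" in scenario.backends:
            alpha_star, c_star, rho_star = feedback_fixed_point(fb, cfg)
            row.update(alpha_star=alpha_star, c_star=c_star, rho_I_star=rho_star)
        else:
            row.update(compare_backends(cfg, scenario.backends, stop=stop,
                                        steps=steps, seed=scenario.seed))
        rows.append(row)
    return pd.DataFrame(rows)
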