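"""Reproducible experiment protocols for the headline analyses.

Each protocol maps (configuration, master seed) deterministically to a set
of CSV/JSON outputs and returns a manifest with content hashes. Desk scale
shrinks Monte-Carlo breadth (path and schedule counts) but never alters
dynamics settings (dt, horizons, densities).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_PARAMETERS,
    IN_VITRO_DENSITY,
    IN_VIVO_DENSITY,
    ModelParameters,
    apc_constants,
    load_parameters,
    save_parameters,
)
from .deterministic import (
    integrate_ode,
    mixed_equilibrium,
    quorum_density,
    reversal_window,
    scale_decomposition,
    secretion_bifurcation_scan,
    _leading_eig,
)
from .discernment import performance_grid
from .schedule import APCSchedule
from .sensitivity import effect_sizes, regime_scan
from .stochastic import balance_distribution, ensemble_summary, run_ensemble

__all__ = ["ExperimentConfig", "run_experiment", "make_fixtures", "EXPERIMENTS"]

NAIVE = np.array([0.1, 0.1, 0.0, 0.0])
WEEK = 168.0

EXPERIMENTS = ("fig2", "fig3", "fig4", "fig5", "fig6", "s2fig", "sensitivity")


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str
    outdir: Path
    master_seed: int = 0
    scale: str = "desk"  # desk | paper
    parameter_file: Path | None = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if self.scale not in ("desk", "paper"):
            raise ValueError("scale must be 'desk' or 'paper'")
        object.__setattr__(self, "outdir", Path(self.outdir))

    def params(self) -> ModelParameters:
        p = (
            load_parameters(self.parameter_file)
            if self.parameter_file
            else DEFAULT_PARAMETERS
        )
        if self.overrides:
            p = p.replace(**self.overrides)
        return p

    @property
    def n_sde_paths(self) -> int:
        return 1000 if self.scale == "paper" else 100

    @property
    def n_timecourses(self) -> int:
        return 200 if self.scale == "paper" else 20

    @property
    def n_tracking_paths(self) -> int:
        return 100 if self.scale == "paper" else 20

    @property
    def n_sensitivity(self) -> int:
        return 500 if self.scale == "paper" else 200


def _write(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _write_json(obj, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
    return path


def _fig2(cfg: ExperimentConfig, p: ModelParameters) -> list[Path]:
    out = []
    for tag, scale in (("secretion_on", 1.0), ("secretion_off", 0.0)):
        ens = run_ensemble(
            cfg.n_sde_paths, NAIVE, p, IN_VITRO_DENSITY,
            secretion_scale=scale, t_span=(0.0, WEEK),
            master_seed=cfg.master_seed,
        )
        dist = balance_distribution(ens, WEEK)
        df = dist.to_frame()
        df["shape"] = dist.shape
        df["central_mass"] = dist.central_mass()
        df["extreme_mass"] = dist.extreme_mass()
        out.append(_write(df, cfg.outdir / f"fig2_theta_hist_{tag}.csv"))
    scan = secretion_bifurcation_scan(p, IN_VITRO_DENSITY)
    tab = scan["table"].copy()
    tab["critical_scale"] = scan["critical_scale"]
    out.append(_write(tab, cfg.outdir / "fig2_secretion_bifurcation.csv"))
    return out


def _fig3(cfg: ExperimentConfig, p: ModelParameters) -> list[Path]:
    traj = integrate_ode(NAIVE, p, IN_VITRO_DENSITY, t_span=(0.0, WEEK))
    ens = run_ensemble(
        cfg.n_sde_paths, NAIVE, p, IN_VITRO_DENSITY,
        t_span=(0.0, WEEK), master_seed=cfg.master_seed,
    )
    return [
        _write(traj.to_frame(), cfg.outdir / "fig3_ode_dynamics.csv"),
        _write(ensemble_summary(ens), cfg.outdir / "fig3_sde_summary.csv"),
    ]


def _fig4(cfg: ExperimentConfig, p: ModelParameters) -> list[Path]:
    rhos = np.geomspace(1e6, 1e9, 25)
    rows = []
    guess = None
    for rho in rhos:
        x = mixed_equilibrium(p, rho, guess=guess)
        guess = x
        lead = _leading_eig(p, rho, x)
        dec = scale_decomposition(p, rho, x)
        rows.append(
            {
                "rho": rho,
                "mixed_TF": x[0],
                "mixed_CY": x[2],
                "leading_eig": lead,
                "within_effect": dec.within_effect,
                "cross_effect": dec.cross_effect,
                "verdict": dec.verdict,
                "eig_verdict": "mixed-stable" if lead < 0 else "polarizing",
            }
        )
    q = quorum_density(p)
    summary = {
        "quorum_density_cells_per_ml": q["critical_density"],
        "production_removal_ratio": q["production_removal_ratio"],
        "cy_tf_ratio": q["cy_tf_ratio"],
    }
    return [
        _write(pd.DataFrame(rows), cfg.outdir / "fig4_density_scan.csv"),
        _write_json(summary, cfg.outdir / "fig4_quorum.json"),
    ]


def _fig5(cfg: ExperimentConfig, p: ModelParameters) -> list[Path]:
    apc_64 = apc_constants(6, 4, p)
    apc_1k = apc_constants(0, 1000, p)
    base = reversal_window(p, IN_VIVO_DENSITY, apc_64, apc_1k)
    rows = []
    for bias in (0.6, 0.7, 0.8, 0.9):
        w = reversal_window(
            p, IN_VIVO_DENSITY,
            apc_constants(10 * bias, 10 * (1 - bias), p), apc_1k,
        )["window"]
        rows.append({"scan": "bias", "bias": bias, "n_apcs": 10, "window_h": w})
    for n_apc in (10, 30, 100):
        w = reversal_window(
            p, IN_VIVO_DENSITY,
            apc_constants(0.9 * n_apc, 0.1 * n_apc, p), apc_1k,
        )["window"]
        rows.append({"scan": "count", "bias": 0.9, "n_apcs": n_apc, "window_h": w})
    return [
        _write_json(
            {"window_h_6v4": base["window"]}, cfg.outdir / "fig5_window.json"
        ),
        _write(pd.DataFrame(rows), cfg.outdir / "fig5_window_grid.csv"),
    ]


def _fig6(cfg: ExperimentConfig, p: ModelParameters) -> list[Path]:
    grid = performance_grid(
        p,
        n_timecourses=cfg.n_timecourses,
        n_paths=cfg.n_tracking_paths,
        master_seed=cfg.master_seed,
    )
    return [_write(grid.table, cfg.outdir / "fig6_performance_grid.csv")]


def _s2fig(cfg: ExperimentConfig, p: ModelParameters) -> list[Path]:
    # exogenous stimulation: initial cytokine pulses tune the 1-week state
    rows = []
    for stim in np.linspace(0.0, 1.0, 9):
        x0 = np.array([0.1, 0.1, 2.0 * stim, 2.0 * (1.0 - stim)])
        traj = integrate_ode(x0, p, IN_VITRO_DENSITY, t_span=(0.0, 1680.0))
        for t in (WEEK, 1680.0):
            y = traj.y[np.searchsorted(traj.t, t)]
            rows.append(
                {
                    "stim_th1_fraction": stim,
                    "time_h": t,
                    "TF1": y[0],
                    "TF2": y[1],
                }
            )
    return [_write(pd.DataFrame(rows), cfg.outdir / "s2fig_tunable_transients.csv")]


def _sensitivity(cfg: ExperimentConfig, p: ModelParameters) -> list[Path]:
    out = []
    for tag, rho in (("low", IN_VITRO_DENSITY), ("high", IN_VIVO_DENSITY)):
        scan = regime_scan(
            p, rho, amps=(0.1, 0.2, 0.3, 0.5), n_per_amp=cfg.n_sensitivity,
            seed=cfg.master_seed,
        )
        tab = scan["table"].copy()
        tab["first_mismatch_amp"] = scan["first_mismatch_amp"]
        tab["base_count"] = scan["base_count"]
        out.append(_write(tab, cfg.outdir / f"sensitivity_regimes_{tag}.csv"))
    eff = effect_sizes(
        p, IN_VITRO_DENSITY, amp=0.1, n=max(2 * cfg.n_sensitivity, 500),
        seed=cfg.master_seed,
    )
    out.append(_write(eff, cfg.outdir / "sensitivity_effect_sizes_low.csv"))
    return out


_RUNNERS = {
    "fig2": _fig2,
    "fig3": _fig3,
    "fig4": _fig4,
    "fig5": _fig5,
    "fig6": _fig6,
    "s2fig": _s2fig,
    "sensitivity": _sensitivity,
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one protocol; returns a manifest of outputs with content hashes."""
    p = config.params()
    files = _RUNNERS[config.experiment](config, p)
    manifest = {
        "experiment": config.experiment,
        "scale": config.scale,
        "master_seed": config.master_seed,
        "parameters": p.as_dict(),
        "outputs": {
            str(f.relative_to(config.outdir)): hashlib.sha256(
                f.read_bytes()
            ).hexdigest()
            for f in files
        },
    }
    _write_json(manifest, config.outdir / f"{config.experiment}_manifest.json")
    return manifest


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict:
    """Write small seeded inputs used by the test suite and examples.

    A symmetric parameter file, three APC schedules (constant, transient
    switch, sustained switch), and a 10-path mini-ensemble summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = DEFAULT_PARAMETERS
    save_parameters(p, outdir / "parameters.json")
    save_parameters(p, outdir / "parameters.toml")
    horizon = 500.0
    apc_th1 = apc_constants(30, 0, p)
    apc_th2 = apc_constants(0, 30, p)
    scheds = {
        "schedule_constant.csv": APCSchedule.constant(apc_th1, horizon),
        "schedule_transient.csv": APCSchedule(
            [0.0, 200.0, 212.0], [200.0, 212.0, horizon],
            [apc_th1.APC1, apc_th2.APC1, apc_th1.APC1],
            [apc_th1.APC2, apc_th2.APC2, apc_th1.APC2],
        ),
        "schedule_sustained.csv": APCSchedule.switch(
            apc_th1, apc_th2, 200.0, horizon
        ),
    }
    for name, s in scheds.items():
        s.to_csv(outdir / name)
    ens = run_ensemble(
        10, NAIVE, p, IN_VITRO_DENSITY, t_span=(0.0, 24.0), master_seed=seed,
        record_every=4.0,
    )
    ensemble_summary(ens).to_csv(outdir / "mini_ensemble_summary.csv", index=False)
    files = ["parameters.json", "parameters.toml", "mini_ensemble_summary.csv"] + list(
        scheds
    )
    return {
        "outdir": str(outdir),
        "seed": seed,
        "files": {
            f: hashlib.sha256((outdir / f).read_bytes()).hexdigest() for f in files
        },
    }
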