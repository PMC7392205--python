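"""Discernment of changing APC instruction by stochastic Th quora.

A committed Th quorum ought to ignore transient or incomplete changes in
APC instruction (possible parasitic manipulation) but obey complete changes
sustained for at least a sensitivity duration tau (a legitimate new
infection). This module generates random instruction time-courses, derives
the theoretically optimal response for a given tau, scores how well SDE
sample paths track it, and scans tracking performance over grids of
molecular volatility (Fig-6-style experiments), all at in-vivo density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ModelParameters
from .deterministic import TH1, TH2
from .schedule import APCSchedule
from .stochastic import _em_batch

__all__ = [
    "ScheduleConfig",
    "OptimalResponse",
    "PerformanceGrid",
    "random_apc_timecourse",
    "optimal_response",
    "tracking_performance",
    "performance_grid",
    "VOLATILITY_GRID",
    "TAU_GRID",
]

#: Default volatility grid for Fig-6-style scans (dimensionless, per sqrt-h).
VOLATILITY_GRID = (0.02, 0.1, 0.3, 0.5, 1.0)
#: Default sensitivity durations (hours).
TAU_GRID = (24.0, 48.0, 96.0)

IN_VIVO = 1e9
_NAIVE = (0.1, 0.1, 0.0, 0.0)


@dataclass(frozen=True)
class ScheduleConfig:
    """Generator settings for random APC instruction time-courses.

    The first segment carries complete instruction (bias 0 or 1, a clear
    initial infection signal); later segments draw from complete and
    incomplete biases so that both obey-worthy and ignore-worthy changes
    occur. Durations are log-uniform; the final segment is extended to the
    horizon.
    """

    horizon: float = 500.0
    n_segments_range: tuple[int, int] = (1, 6)
    duration_range: tuple[float, float] = (10.0, 250.0)
    bias_choices: tuple[float, ...] = (0.0, 0.25, 0.75, 1.0)
    initial_bias_choices: tuple[float, ...] = (0.0, 1.0)
    total_apcs: float = 30.0


DEFAULT_SCHEDULE_CONFIG = ScheduleConfig()


def random_apc_timecourse(
    rng_seed: int | np.random.Generator,
    params: ModelParameters,
    config: ScheduleConfig = DEFAULT_SCHEDULE_CONFIG,
) -> APCSchedule:
    """Draw a random piecewise-constant instruction schedule."""
    if config.horizon <= 0:
        raise ValueError("schedule horizon must be positive")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lo, hi = config.n_segments_range
    n_seg = int(rng.integers(lo, hi + 1))
    breaks = [0.0]
    biases = []
    for i in range(n_seg):
        dur = float(
            np.exp(
                rng.uniform(*np.log(config.duration_range))
            )
        )
        b = float(
            rng.choice(config.initial_bias_choices if i == 0 else config.bias_choices)
        )
        end = min(breaks[-1] + dur, config.horizon)
        if i == n_seg - 1:
            end = config.horizon
        breaks.append(end)
        biases.append(b)
        if end >= config.horizon:
            break
    breaks[-1] = config.horizon
    return APCSchedule.from_biases(
        np.array(breaks), np.array(biases), config.total_apcs, params
    )


@dataclass(frozen=True)
class OptimalResponse:
    """Piecewise-constant target effector label for a schedule.

    The target starts on the side of the initial majority bias and switches
    only when the schedule holds complete (100%) opposite instruction for at
    least ``tau`` hours continuously; the switch takes effect at the moment
    the criterion is met.
    """

    initial_label: str
    switches: tuple[tuple[float, str], ...]  # (time, new label)
    tau: float

    def labels_at(self, times: np.ndarray) -> np.ndarray:
        lab = np.full(len(times), self.initial_label, dtype=object)
        for t_sw, new in self.switches:
            lab[np.asarray(times) >= t_sw] = new
        return lab


def optimal_response(schedule: APCSchedule, tau: float) -> OptimalResponse:
    """Derive the theoretically optimal response for a schedule."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    tot = schedule.apc1 + schedule.apc2
    if np.all(tot == 0):
        raise ValueError("schedule has zero APC instruction everywhere")
    with np.errstate(invalid="ignore"):
        bias = np.where(tot > 0, schedule.apc1 / np.where(tot > 0, tot, 1.0), 0.5)
    current = TH1 if bias[0] >= 0.5 else TH2
    switches: list[tuple[float, str]] = []
    run_side: str | None = None
    run_start = 0.0
    for t0, t1, b, tt in zip(schedule.t_start, schedule.t_end, bias, tot):
        side = TH1 if (b == 1.0 and tt > 0) else (TH2 if (b == 0.0 and tt > 0) else None)
        if side is None or side == current:
            run_side = None
            continue
        if run_side != side:
            run_side, run_start = side, t0
        if t1 - run_start >= tau:
            current = side
            switches.append((run_start + tau, side))
            run_side = None
    return OptimalResponse(TH1 if bias[0] >= 0.5 else TH2, tuple(switches), tau)


def tracking_performance(
    theta: np.ndarray,
    times: np.ndarray,
    optimal: OptimalResponse,
    lo: float = 0.2,
    hi: float = 0.8,
) -> dict:
    """Time-fraction agreement between path labels and the optimal target.

    ``theta`` has shape (n_paths, n_times). A path agrees at an evaluation
    time iff its attractor label (balance index against the lo/hi cutoffs)
    equals the target label; mixed counts as disagreement with any target.
    Returns per-path scores and their mean, all in [0, 1].
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.size == 0:
        raise ValueError("empty ensemble")
    target = optimal.labels_at(times)
    want_th1 = target == TH1
    agree = np.where(want_th1[None, :], theta > hi, theta < lo)
    per_path = agree.mean(axis=1)
    return {"per_path": per_path, "pooled": float(per_path.mean())}


@dataclass(frozen=True)
class PerformanceGrid:
    """Mean and relative tracking performance over a volatility grid."""

    table: pd.DataFrame  # n_tf, n_cy, tau_h, mean_performance, relative_performance
    master_seed: int
    n_timecourses: int
    n_paths: int
    meta: dict = field(default_factory=dict, compare=False)

    def for_tau(self, tau: float) -> pd.DataFrame:
        return self.table[self.table["tau_h"] == tau].reset_index(drop=True)

    def best_cell(self, tau: float) -> tuple[float, float]:
        sub = self.for_tau(tau)
        row = sub.loc[sub["mean_performance"].idxmax()]
        return float(row["n_tf"]), float(row["n_cy"])

    def diagonal(self, tau: float) -> pd.DataFrame:
        sub = self.for_tau(tau)
        return sub[sub["n_tf"] == sub["n_cy"]].reset_index(drop=True)


def _score_cell(
    n_tf: float,
    n_cy: float,
    schedules: list[APCSchedule],
    params: ModelParameters,
    taus: tuple[float, ...],
    n_paths: int,
    seed_seq: np.random.SeedSequence,
    dt: float,
    record_every: float,
    rho: float,
) -> dict[float, float]:
    """Mean tracking performance of one volatility cell, per tau."""
    P = params.with_noise(n_tf, n_cy)
    horizon = schedules[0].horizon
    n_sched = len(schedules)
    n_tot = n_sched * n_paths
    gens = [np.random.default_rng(c) for c in seed_seq.spawn(n_tot)]
    sched_idx = np.repeat(np.arange(n_sched), n_paths)
    x0 = np.tile(np.array(_NAIVE), (n_tot, 1))
    t, xs = _em_batch(
        x0, P, rho, schedules, sched_idx, 1.0, (0.0, horizon), dt, gens,
        record_every,
    )
    theta = xs[:, :, 0] / np.maximum(xs[:, :, 0] + xs[:, :, 1], 1e-300)
    theta = theta.T  # (n_tot, n_rec)
    out = {}
    for tau in taus:
        scores = []
        for j, sched in enumerate(schedules):
            opt = optimal_response(sched, tau)
            rows = sched_idx == j
            scores.append(
                tracking_performance(theta[rows], t, opt)["pooled"]
            )
        out[tau] = float(np.mean(scores))
    return out


def performance_grid(
    params: ModelParameters,
    tf_volatilities: tuple[float, ...] = VOLATILITY_GRID,
    cy_volatilities: tuple[float, ...] | None = None,
    taus: tuple[float, ...] = TAU_GRID,
    n_timecourses: int = 20,
    n_paths: int = 20,
    master_seed: int = 0,
    config: ScheduleConfig = DEFAULT_SCHEDULE_CONFIG,
    rho: float = IN_VIVO,
    dt: float = 0.02,
    record_every: float = 2.0,
    diagonal_only: bool = False,
) -> PerformanceGrid:
    """Scan tracking performance over volatility settings (Fig 6e/6f).

    The same ``n_timecourses`` random schedules and the same per-cell path
    seeds are reused for every grid cell, so cells differ only in the noise
    magnitudes. ``diagonal_only=True`` restricts to n_TF = n_CY (the 1-D
    scan); the full grid's diagonal reproduces it exactly. Relative
    performance divides by the best cell mean within each tau.
    """
    if n_timecourses < 1 or n_paths < 1:
        raise ValueError("counts must be >= 1")
    if cy_volatilities is None:
        cy_volatilities = tuple(tf_volatilities)
    sched_rng = np.random.default_rng(np.random.SeedSequence((master_seed, 0)))
    schedules = [
        random_apc_timecourse(sched_rng, params, config)
        for _ in range(n_timecourses)
    ]
    cells = (
        [(v, v) for v in tf_volatilities]
        if diagonal_only
        else [(a, b) for a in tf_volatilities for b in cy_volatilities]
    )
    rows = []
    for n_tf, n_cy in cells:
        # identical path seeds in every cell: cells differ only in volatility
        res = _score_cell(
            n_tf, n_cy, schedules, params, tuple(taus), n_paths,
            np.random.SeedSequence((master_seed, 1)), dt, record_every, rho,
        )
        for tau, perf in res.items():
            rows.append(
                {"n_tf": n_tf, "n_cy": n_cy, "tau_h": tau, "mean_performance": perf}
            )
    table = pd.DataFrame(rows)
    table["relative_performance"] = table.groupby("tau_h")[
        "mean_performance"
    ].transform(lambda s: s / s.max())
    table["n_timecourses"] = n_timecourses
    table["n_paths"] = n_paths
    table["master_seed"] = master_seed
    return PerformanceGrid(table, master_seed, n_timecourses, n_paths)
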