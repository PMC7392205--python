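"""Stochastic (SDE) simulation: sample paths, ensembles, balance statistics.

The stochastic model adds independent multiplicative (geometric) Brownian
terms to each of the four molecular species, capturing the heavy-tailed,
lognormal-like cell-to-cell variability of transcription-factor and
cytokine expression. Paths are integrated with the Euler–Maruyama scheme in
natural coordinates with clamping at zero (the multiplicative noise itself
vanishes at zero, so clamping only absorbs discretization overshoot).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .core import APCInstruction, ModelParameters, ZERO_APC, apply_density, drift
from .deterministic import Trajectory, balance_index
from .schedule import APCSchedule

__all__ = [
    "Ensemble",
    "BalanceDistribution",
    "simulate_sde",
    "run_ensemble",
    "balance_distribution",
    "ensemble_summary",
]

_CHUNK = 2000  # steps of pre-generated noise per path (memory/speed tradeoff)


class StepSizeError(RuntimeError):
    pass


def _path_generators(master_seed: int, n_paths: int) -> list[np.random.Generator]:
    """Independent, reproducible per-path generators from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_paths)]


def _em_batch(
    x0: np.ndarray,
    params: ModelParameters,
    rho: float,
    schedules: list[APCSchedule],
    sched_idx: np.ndarray,
    secretion_scale: float,
    t_span: tuple[float, float],
    dt: float,
    generators: list[np.random.Generator],
    record_every: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Euler–Maruyama over a batch of paths.

    ``sched_idx[i]`` selects the APC schedule of path ``i``; instruction is
    evaluated on the step grid. Noise is drawn per path from its own
    generator (in chunks), so each path depends only on its own seed.
    Returns ``(times, states)`` with states of shape (n_rec, n_paths, 4).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ctx_rates = apply_density(params, rho)
    stiffest = max(params.dTF1, params.dTF2, ctx_rates.dCY1, ctx_rates.dCY2)
    if dt * stiffest > 2.0:
        raise StepSizeError(
            f"dt={dt} exceeds the Euler stability bound {2.0 / stiffest:.3g} h "
            "for the fastest decay rate; reduce dt"
        )
    t0, t1 = t_span
    steps = int(round((t1 - t0) / dt))
    rec_stride = max(int(round(record_every / dt)), 1)
    n = len(x0)
    nvec = params.noise
    ctx = apply_density(params, rho)
    sq = np.sqrt(dt)

    # per-schedule instruction on the step grid
    t_steps = t0 + dt * np.arange(steps)
    apc_tab = np.empty((len(schedules), steps, 2))
    for j, s in enumerate(schedules):
        a1, a2 = s.values_at(np.minimum(t_steps, s.horizon - 1e-9))
        apc_tab[j, :, 0] = a1
        apc_tab[j, :, 1] = a2

    x = np.array(x0, dtype=float)
    rec_t = [t0]
    rec_x = [x.copy()]
    noise_buf = None
    buf_base = 0
    explode = 1e12
    for k in range(steps):
        if noise_buf is None or k - buf_base >= noise_buf.shape[1]:
            m = min(_CHUNK, steps - k)
            noise_buf = np.empty((n, m, 4))
            for i, g in enumerate(generators):
                noise_buf[i] = g.standard_normal((m, 4))
            buf_base = k
        xi = noise_buf[:, k - buf_base, :]
        a = apc_tab[sched_idx, k, :]
        apc = SimpleNamespace(APC1=a[:, 0], APC2=a[:, 1])
        f = drift(x, ctx, params, apc, secretion_scale)
        x = x + f * dt + (x * nvec) * sq * xi
        np.clip(x, 0.0, None, out=x)
        if not np.all(np.isfinite(x)) or np.max(x) > explode:
            raise StepSizeError(
                f"state norm exploded at t={t0 + (k + 1) * dt:.3f} h; "
                f"reduce dt (currently {dt})"
            )
        if (k + 1) % rec_stride == 0:
            rec_t.append(t0 + (k + 1) * dt)
            rec_x.append(x.copy())
    return np.array(rec_t), np.stack(rec_x)


@dataclass(frozen=True)
class Ensemble:
    """A collection of SDE sample paths on a common time grid."""

    t: np.ndarray                 # (n_rec,)
    paths: np.ndarray             # (n_paths, n_rec, 4)
    master_seed: int
    path_seeds: np.ndarray        # (n_paths,) spawn keys (informational)
    noise: np.ndarray             # the four volatilities used
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def n_paths(self) -> int:
        return self.paths.shape[0]

    def trajectory(self, i: int) -> Trajectory:
        return Trajectory(self.t, self.paths[i], dict(self.meta, path=i))

    def balance(self) -> np.ndarray:
        """Balance index per path per time, shape (n_paths, n_rec)."""
        return balance_index(self.paths)

    def to_frame(self) -> pd.DataFrame:
        n_p, n_t, _ = self.paths.shape
        return pd.DataFrame(
            {
                "path_id": np.repeat(np.arange(n_p), n_t),
                "time_h": np.tile(self.t, n_p),
                "TF1": self.paths[:, :, 0].ravel(),
                "TF2": self.paths[:, :, 1].ravel(),
                "CY1": self.paths[:, :, 2].ravel(),
                "CY2": self.paths[:, :, 3].ravel(),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_sde(
    initial: np.ndarray,
    params: ModelParameters,
    rho: float,
    apc_schedule: APCSchedule | APCInstruction | None = None,
    secretion_scale: float = 1.0,
    t_span: tuple[float, float] = (0.0, 168.0),
    dt: float = 0.01,
    seed: int | np.random.SeedSequence = 0,
    record_every: float = 1.0,
) -> Trajectory:
    """Single Euler–Maruyama sample path; identical seed, identical path."""
    x0 = np.asarray(initial, dtype=float)
    if x0.shape != (4,) or np.any(x0 < 0):
        raise ValueError("initial state must be a non-negative 4-vector")
    horizon = t_span[1]
    if apc_schedule is None or isinstance(apc_schedule, APCInstruction):
        apc_schedule = APCSchedule.constant(
            apc_schedule or ZERO_APC, horizon
        )
    gen = np.random.default_rng(seed)
    t, xs = _em_batch(
        x0[None, :], params, rho, [apc_schedule], np.zeros(1, int),
        secretion_scale, t_span, dt, [gen], record_every,
    )
    meta = {"rho": rho, "secretion_scale": secretion_scale, "dt": dt}
    return Trajectory(t, xs[:, 0, :], meta)


def run_ensemble(
    n_paths: int,
    initial: np.ndarray,
    params: ModelParameters,
    rho: float,
    apc_schedule: APCSchedule | APCInstruction | None = None,
    secretion_scale: float = 1.0,
    t_span: tuple[float, float] = (0.0, 168.0),
    dt: float = 0.01,
    master_seed: int = 0,
    record_every: float = 1.0,
) -> Ensemble:
    """Ensemble of independent paths with seeds spawned from a master seed.

    Path ``i`` is bitwise-identical to ``simulate_sde`` run with the ``i``-th
    spawned seed, so sub-ensembles are reproducible slices.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    x0 = np.tile(np.asarray(initial, dtype=float), (n_paths, 1))
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    horizon = t_span[1]
    if apc_schedule is None or isinstance(apc_schedule, APCInstruction):
        apc_schedule = APCSchedule.constant(apc_schedule or ZERO_APC, horizon)
    gens = _path_generators(master_seed, n_paths)
    t, xs = _em_batch(
        x0, params, rho, [apc_schedule], np.zeros(n_paths, int),
        secretion_scale, t_span, dt, gens, record_every,
    )
    meta = {
        "rho": rho,
        "secretion_scale": secretion_scale,
        "dt": dt,
        "initial": list(map(float, np.asarray(initial, float))),
    }
    return Ensemble(
        t, xs.transpose(1, 0, 2), master_seed,
        np.arange(n_paths), params.noise, meta,
    )


# ---------------------------------------------------------------------------
# Balance distributions (Fig 2-style summaries)


@dataclass(frozen=True)
class BalanceDistribution:
    """Distribution of the balance index across an ensemble at one time."""

    t_eval: float
    theta: np.ndarray
    counts: np.ndarray
    bin_edges: np.ndarray
    shape: str  # uniform | U-shaped | unimodal-central | other

    def central_mass(self, lo: float = 0.3, hi: float = 0.7) -> float:
        return float(np.mean((self.theta > lo) & (self.theta < hi)))

    def extreme_mass(self, lo: float = 0.2, hi: float = 0.8) -> float:
        return float(np.mean((self.theta < lo) | (self.theta > hi)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def _shape_label(counts: np.ndarray) -> str:
    """Classify a 10-bin balance histogram.

    uniform: max/min bin mass < 3. U-shaped: both outer bins exceed twice
    the mean inner-bin mass and the two middle bins are below half of it.
    unimodal-central: the modal bin is one of the middle two. Else other.
    """
    c = counts.astype(float)
    inner = c[1:-1]
    inner_mean = inner.mean() if inner.size else 0.0
    if c.min() > 0 and c.max() / c.min() < 3:
        return "uniform"
    if (
        c[0] > 2 * inner_mean
        and c[-1] > 2 * inner_mean
        and c[4] <= 0.5 * inner_mean
        and c[5] <= 0.5 * inner_mean
    ):
        return "U-shaped"
    if np.argmax(c) in (4, 5):
        return "unimodal-central"
    return "other"


def balance_distribution(
    ensemble: Ensemble, t_eval: float, n_bins: int = 10
) -> BalanceDistribution:
    """Histogram of the balance index theta across paths at ``t_eval``."""
    match = np.isclose(ensemble.t, t_eval, rtol=0, atol=1e-9)
    if not match.any():
        raise ValueError(f"t_eval={t_eval} is not on the ensemble time grid")
    k = int(np.argmax(match))
    theta = balance_index(ensemble.paths[:, k, :])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(theta, bins=edges)
    label = _shape_label(
        counts if n_bins == 10 else np.histogram(theta, bins=10, range=(0, 1))[0]
    )
    return BalanceDistribution(t_eval, theta, counts, edges, label)


def ensemble_summary(ensemble: Ensemble) -> pd.DataFrame:
    """Per-time mean, median, and interquartile range of each variable."""
    if ensemble.n_paths == 0:
        raise ValueError("empty ensemble")
    cols = {}
    names = ["TF1", "TF2", "CY1", "CY2"]
    cols["time_h"] = ensemble.t
    for i, nm in enumerate(names):
        v = ensemble.paths[:, :, i]
        cols[f"{nm}_mean"] = v.mean(axis=0)
        cols[f"{nm}_median"] = np.median(v, axis=0)
        q75, q25 = np.percentile(v, [75, 25], axis=0)
        cols[f"{nm}_iqr"] = q75 - q25
    return pd.DataFrame(cols)
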