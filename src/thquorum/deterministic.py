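"""Deterministic (ODE) analysis: trajectories, equilibria, bifurcations.

This module locates and classifies the fixed points of the mean-field model,
scans the two bifurcation parameters of interest — the permitted fraction of
cytokine secretion (antibody blocking) and the cell density (quorum
sensing) — and computes the two derived quantities built on them: the
within/cross-scale stability decomposition of the mixed equilibrium and the
APC reversal window at in-vivo density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .core import (
    APCInstruction,
    DensityContext,
    ModelParameters,
    ZERO_APC,
    apply_density,
    drift,
    jacobian,
)
from .schedule import APCSchedule

__all__ = [
    "Trajectory",
    "EquilibriumSet",
    "ScaleDecomposition",
    "integrate_ode",
    "find_equilibria",
    "mixed_equilibrium",
    "secretion_bifurcation_scan",
    "quorum_density",
    "scale_decomposition",
    "reversal_window",
    "balance_index",
    "classify_attractor",
]

#: Root-acceptance tolerance on the drift (max-norm, model units/h).
DRIFT_TOL = 1e-8
#: Relative deduplication tolerance between equilibria.
DEDUP_RTOL = 1e-6

TH1, TH2, MIXED = "Th1", "Th2", "mixed"


def balance_index(state: np.ndarray) -> np.ndarray:
    """Balance of Th1 vs Th2 commitment, theta = TF1/(TF1+TF2) in [0,1].

    The symmetric undecided state (0,0,...) maps to 0.5.
    """
    state = np.asarray(state, dtype=float)
    tot = state[..., 0] + state[..., 1]
    with np.errstate(invalid="ignore"):
        th = np.where(tot > 0, state[..., 0] / np.where(tot > 0, tot, 1.0), 0.5)
    return th


def classify_attractor(state: np.ndarray, lo: float = 0.2, hi: float = 0.8) -> str:
    """Classify a terminal state by balance index (Th1 / Th2 / mixed)."""
    th = float(balance_index(state))
    if th > hi:
        return TH1
    if th < lo:
        return TH2
    return MIXED


@dataclass(frozen=True)
class Trajectory:
    """Time-gridded solution of the deterministic or stochastic system."""

    t: np.ndarray
    y: np.ndarray  # (n_times, 4): TF1, TF2, CY1, CY2
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.t.ndim != 1 or self.y.shape != (len(self.t), 4):
            raise ValueError("trajectory needs t (n,) and y (n, 4)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.y < 0):
            raise ValueError("states must be non-negative")

    @property
    def final(self) -> np.ndarray:
        return self.y[-1]

    def balance(self) -> np.ndarray:
        return balance_index(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.t,
                "TF1": self.y[:, 0],
                "TF2": self.y[:, 1],
                "CY1": self.y[:, 2],
                "CY2": self.y[:, 3],
            }
        )

    def write(self, path: str | Path) -> None:
        """CSV plus a JSON sidecar of run metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        side = path.with_suffix(".meta.json")
        side.write_text(json.dumps(self.meta, indent=2, default=float) + "\n")


class SolverError(RuntimeError):
    """ODE solver failure, carrying the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time: {last_time:.3f} h)")
        self.last_time = last_time


def _as_schedule(apc, horizon: float) -> APCSchedule:
    if apc is None:
        apc = ZERO_APC
    if isinstance(apc, APCInstruction):
        return APCSchedule.constant(apc, horizon)
    return apc


def integrate_ode(
    initial: np.ndarray,
    params: ModelParameters,
    rho: float,
    apc_schedule: APCSchedule | APCInstruction | None = None,
    secretion_scale: float = 1.0,
    t_span: tuple[float, float] = (0.0, 500.0),
    reporting_step: float = 1.0,
    rtol: float = 1e-8,
) -> Trajectory:
    """Integrate the deterministic system over ``t_span``.

    The integration is split at schedule breakpoints so the piecewise-
    constant APC instruction is handled exactly. A stiff-capable solver
    (LSODA) is used; states are clipped to zero at the solver tolerance.
    """
    t0, t1 = map(float, t_span)
    if not t1 > t0:
        raise ValueError("t_span must be increasing")
    sched = _as_schedule(apc_schedule, t1)
    if sched.horizon < t1 - 1e-9:
        raise ValueError("APC schedule does not cover the requested span")
    ctx = apply_density(params, rho)
    x = np.asarray(initial, dtype=float)
    if x.shape != (4,) or np.any(x < 0):
        raise ValueError("initial state must be a non-negative 4-vector")

    cuts = sched.breakpoints
    cuts = cuts[(cuts > t0) & (cuts < t1)]
    edges = np.concatenate([[t0], cuts, [t1]])
    ts_all = [np.array([t0])]
    ys_all = [x[None, :]]
    for a, b in zip(edges[:-1], edges[1:]):
        apc = sched.at(0.5 * (a + b))
        t_eval = np.arange(a, b, reporting_step)[1:]
        t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(
            lambda t, y: drift(np.clip(y, 0.0, None), ctx, params, apc, secretion_scale),
            (a, b),
            np.clip(x, 0.0, None),
            method="LSODA",
            rtol=rtol,
            atol=1e-12,
            t_eval=t_eval,
        )
        if not sol.success:
            raise SolverError(sol.message, sol.t[-1] if len(sol.t) else a)
        x = sol.y[:, -1]
        ts_all.append(sol.t)
        ys_all.append(np.clip(sol.y.T, 0.0, None))
    t = np.concatenate(ts_all)
    y = np.concatenate(ys_all, axis=0)
    keep = np.concatenate([[True], np.diff(t) > 0])
    meta = {
        "rho": rho,
        "secretion_scale": secretion_scale,
        "schedule": sched.to_frame().to_dict("list"),
    }
    return Trajectory(t[keep], y[keep], meta)


# ---------------------------------------------------------------------------
# Equilibria


@dataclass(frozen=True)
class EquilibriumSet:
    """Located fixed points with eigenvalues and stability labels."""

    states: np.ndarray        # (m, 4)
    eigenvalues: np.ndarray   # (m, 4) complex
    stable: np.ndarray        # (m,) bool
    rho: float
    secretion_scale: float
    apc: APCInstruction

    def __len__(self) -> int:
        return len(self.states)

    @property
    def stable_states(self) -> np.ndarray:
        return self.states[self.stable]

    @property
    def n_stable(self) -> int:
        return int(np.sum(self.stable))

    def leading(self, i: int) -> float:
        return float(np.max(self.eigenvalues[i].real))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "TF1": self.states[:, 0],
                "TF2": self.states[:, 1],
                "CY1": self.states[:, 2],
                "CY2": self.states[:, 3],
                "leading_eig_real": [self.leading(i) for i in range(len(self))],
                "stable": self.stable,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _drift_extended(x, ctx, params, apc, scale):
    """Drift evaluated through |x|: smooth extension for root finding."""
    return drift(np.abs(x), ctx, params, apc, scale)


def _polish_root(x0, ctx, params, apc, scale):
    for method, opts in (
        ("hybr", {"xtol": 1e-12, "maxfev": 400}),
        ("lm", {"xtol": 1e-14, "maxiter": 2000}),
    ):
        sol = root(
            _drift_extended, x0, args=(ctx, params, apc, scale), method=method,
            options=opts,
        )
        x = np.abs(sol.x)
        x[x < 1e-14] = 0.0
        d = drift(x, ctx, params, apc, scale)
        if np.max(np.abs(d)) < DRIFT_TOL * (1.0 + np.max(np.abs(x))):
            return x
    return None


def _start_points(params: ModelParameters, ctx, apc, scale, n_tf: int = 6):
    """TF grid spanning the Hill-threshold range, cytokines slaved."""
    lo = 0.01 * min(params.X1, params.X2, params.P1, params.P2)
    hi = 100.0 * max(params.X1, params.X2, params.P1, params.P2)
    tf_vals = np.geomspace(max(lo, 1e-3), hi, n_tf)
    starts = []
    for T1 in tf_vals:
        for T2 in tf_vals:
            x = np.array([T1, T2, 0.0, 0.0])
            # slave cytokines to the TF guess (two sweeps for the U coupling)
            for _ in range(2):
                d = drift(x, ctx, params, apc, scale)
                c1 = max(x[2] + d[2] / max(ctx.dCY1, 1e-12), 0.0)
                c2 = max(x[3] + d[3] / max(ctx.dCY2, 1e-12), 0.0)
                x = np.array([T1, T2, c1, c2])
            starts.append(x)
    return starts


def find_equilibria(
    params: ModelParameters,
    rho: float,
    apc: APCInstruction = ZERO_APC,
    secretion_scale: float = 1.0,
    n_tf: int = 6,
    extra_starts: list | None = None,
) -> EquilibriumSet:
    """Multi-start root search for all equilibria, stability-classified.

    Starts on a log-spaced TF grid spanning 0.01-100x the Hill thresholds
    with cytokines initialized at secretion balance; roots are verified
    against the drift tolerance, deduplicated, and classified by the
    eigenvalues of the numerically evaluated Jacobian.
    """
    ctx = apply_density(params, rho)
    starts = _start_points(params, ctx, apc, secretion_scale, n_tf)
    if extra_starts:
        starts = list(extra_starts) + starts
    found: list[np.ndarray] = []
    for x0 in starts:
        x = _polish_root(x0, ctx, params, apc, secretion_scale)
        if x is None:
            continue
        scale_x = 1.0 + np.max(np.abs(x))
        if any(np.max(np.abs(x - y)) < DEDUP_RTOL * scale_x for y in found):
            continue
        found.append(x)
    if not found:
        import warnings

        warnings.warn("no equilibria found; check parameters", RuntimeWarning)
        return EquilibriumSet(
            np.empty((0, 4)), np.empty((0, 4), complex), np.empty(0, bool),
            rho, secretion_scale, apc,
        )
    states = np.array(found)
    eigs = np.array(
        [
            np.linalg.eigvals(jacobian(x, ctx, params, apc, secretion_scale))
            for x in states
        ]
    )
    stable = np.max(eigs.real, axis=1) < 0
    # order: descending balance-index asymmetry then TF1 for reproducibility
    order = np.lexsort((states[:, 0], np.round(balance_index(states), 6)))
    return EquilibriumSet(
        states[order], eigs[order], stable[order], rho, secretion_scale, apc
    )


def mixed_equilibrium(
    params: ModelParameters,
    rho: float,
    secretion_scale: float = 1.0,
    apc: APCInstruction = ZERO_APC,
    guess: np.ndarray | None = None,
) -> np.ndarray:
    """Track the mixed (symmetric-branch) equilibrium.

    For symmetric parameters with unbiased instruction this solves the
    two-variable problem on the symmetric manifold; otherwise it polishes a
    full four-variable root from the supplied continuation guess.
    """
    ctx = apply_density(params, rho)
    symmetric = params.symmetric and apc.APC1 == apc.APC2
    if symmetric:
        Tg, cg = (10.0, 0.5) if guess is None else (guess[0], max(guess[2], 1e-9))

        def f2(v):
            T, c = v
            d = drift(np.abs([T, T, c, c]), ctx, params, apc, secretion_scale)
            return [d[0], d[2]]

        sol = root(f2, [Tg, cg], method="hybr", options={"xtol": 1e-13})
        T, c = np.abs(sol.x)
        x = np.array([T, T, c, c])
    else:
        x0 = np.array([10.0, 10.0, 0.5, 0.5]) if guess is None else np.asarray(guess)
        x = _polish_root(x0, ctx, params, apc, secretion_scale)
        if x is None:
            raise RuntimeError("mixed-branch continuation failed from the given guess")
    d = drift(x, ctx, params, apc, secretion_scale)
    if np.max(np.abs(d)) > DRIFT_TOL * (1.0 + np.max(np.abs(x))):
        raise RuntimeError("mixed-branch equilibrium did not converge")
    return x


def _leading_eig(params, rho, x, apc=ZERO_APC, scale=1.0):
    ctx = apply_density(params, rho)
    return float(np.max(np.linalg.eigvals(jacobian(x, ctx, params, apc, scale)).real))


# ---------------------------------------------------------------------------
# Bifurcation scans


def secretion_bifurcation_scan(
    params: ModelParameters,
    rho: float,
    scales: np.ndarray | None = None,
) -> dict:
    """Stability of the mixed branch as cytokine secretion is removed.

    Returns per-scale summaries of the located equilibria and the critical
    secretion scale where the mixed branch loses stability (bracketed by a
    sign change of its leading eigenvalue, refined by Brent's method).
    """
    if scales is None:
        scales = np.linspace(1.0, 0.0, 21)
    scales = np.asarray(scales, dtype=float)
    rows = []
    guess = None
    mixed_lead = {}
    for s in np.sort(scales)[::-1]:
        x = mixed_equilibrium(params, rho, s, guess=guess)
        guess = x
        lead = _leading_eig(params, rho, x, scale=s)
        mixed_lead[s] = lead
        eq = find_equilibria(params, rho, secretion_scale=s, n_tf=5)
        rows.append(
            {
                "secretion_scale": s,
                "mixed_TF": x[0],
                "mixed_CY": x[2],
                "mixed_leading_eig": lead,
                "mixed_stable": lead < 0,
                "n_equilibria": len(eq),
                "n_stable": eq.n_stable,
            }
        )
    table = pd.DataFrame(rows)

    critical = None
    st = table.sort_values("secretion_scale")
    sign = np.sign(st["mixed_leading_eig"].to_numpy())
    flips = np.nonzero(np.diff(sign))[0]
    if len(flips):
        lo = st["secretion_scale"].to_numpy()[flips[0]]
        hi = st["secretion_scale"].to_numpy()[flips[0] + 1]

        def lead_at(s):
            x = mixed_equilibrium(params, rho, s, guess=None)
            return _leading_eig(params, rho, x, scale=s)

        critical = brentq(lead_at, lo, hi, xtol=1e-4)
    return {"table": table, "critical_scale": critical}


def quorum_density(
    params: ModelParameters,
    bracket: tuple[float, float] = (2e6, 1e9),
    xtol_log10: float = 1e-3,
) -> dict:
    """Critical cell density where the mixed equilibrium loses stability.

    Bisects (in log-density) on the sign of the mixed-branch leading
    eigenvalue and reports, at the crossing, the cytokine
    production:removal ratio and the CY:TF expression ratio of the mixed
    equilibrium — the two quantities that mechanistically pin the quorum.
    """
    lo, hi = bracket

    def lead_at_logrho(lr):
        rho = 10.0**lr
        x = mixed_equilibrium(params, rho)
        return _leading_eig(params, rho, x)

    f_lo, f_hi = lead_at_logrho(np.log10(lo)), lead_at_logrho(np.log10(hi))
    if not (f_lo < 0 < f_hi):
        raise ValueError(
            "invalid bracket: mixed branch must be stable at the low end and "
            f"unstable at the high end (got {f_lo:.3g}, {f_hi:.3g}); widen the bracket"
        )
    lr = brentq(lead_at_logrho, np.log10(lo), np.log10(hi), xtol=xtol_log10)
    rho_c = 10.0**lr
    ctx = apply_density(params, rho_c)
    x = mixed_equilibrium(params, rho_c)
    prod_removal = (ctx.a1 / ctx.dCY1 + ctx.a2 / ctx.dCY2) / 2.0
    cy_tf = (x[2] + x[3]) / (x[0] + x[1])
    return {
        "critical_density": rho_c,
        "production_removal_ratio": prod_removal,
        "cy_tf_ratio": cy_tf,
        "mixed_state": x,
    }


# ---------------------------------------------------------------------------
# Within/cross-scale decomposition


@dataclass(frozen=True)
class ScaleDecomposition:
    """Within-scale vs cross-scale contributions to mixed-state stability.

    The polarization mode of the mixed equilibrium lives in the difference
    coordinates (TF1-TF2, CY1-CY2). Projecting the Jacobian onto them gives
    a 2x2 matrix whose diagonal entries are the within-scale feedbacks (the
    TF block: toggle cross-inhibition and self-activation against decay; the
    CY block: cytokine mutual inhibition against removal) and whose
    off-diagonal entries are the two cross-scale gains (CY->TF induction and
    TF->CY secretion asymmetries). The mixed state is stable iff both
    within-scale feedbacks are restoring and their product — the
    within-scale stabilizing margin — exceeds the product of the
    cross-scale gains (the standard trace/determinant criterion).
    """

    within_effect: float   # product of within-scale relaxation rates (signed)
    cross_effect: float    # product of the two cross-scale gains
    w_tf: float            # TF-block within-scale feedback (diagonal entry)
    w_cy: float            # CY-block within-scale feedback (diagonal entry)
    verdict: str           # "mixed-stable" | "polarizing"

    @property
    def mixed_stable(self) -> bool:
        return self.verdict == "mixed-stable"


def _polarization_generator(J: np.ndarray) -> np.ndarray:
    """Exact 2x2 generator of the polarization (difference) coordinates.

    The two eigenmodes of ``J`` whose eigenvectors carry the most
    difference-space energy span an invariant subspace; restricting ``J`` to
    it and expressing the restriction in the (TF1-TF2, CY1-CY2) chart gives
    the exact dynamics of the polarization coordinates on that manifold. For
    a symmetric equilibrium this reduces to the plain block projection.
    """
    P = np.array(
        [[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]]
    ) / np.sqrt(2)
    vals, vecs = np.linalg.eig(J)
    energy = np.abs(P @ vecs) ** 2
    score = energy.sum(axis=0) / (np.abs(vecs) ** 2).sum(axis=0)
    order = np.argsort(score)[::-1]
    picked = []
    for i in order:
        if any(np.isclose(vals[i], np.conj(vals[j])) and i != j for j in picked):
            continue  # conjugate partner handled via real/imag split
        picked.append(i)
        if np.iscomplex(vals[i]) and abs(vals[i].imag) > 1e-12:
            break  # complex pair spans a 2-D real subspace by itself
        if len(picked) == 2:
            break
    if len(picked) == 1 and abs(vals[picked[0]].imag) > 1e-12:
        v = vecs[:, picked[0]]
        Vd = np.column_stack([v.real, v.imag])
    else:
        Vd = np.column_stack([vecs[:, i].real for i in picked[:2]])
    D = P @ Vd
    if abs(np.linalg.det(D)) < 1e-10 * np.linalg.norm(Vd):
        # degenerate chart; fall back to the orthogonal projection
        return P @ J @ P.T
    return (P @ J @ Vd) @ np.linalg.inv(D)


def scale_decomposition(
    params: ModelParameters,
    rho: float,
    equilibrium: np.ndarray,
    apc: APCInstruction = ZERO_APC,
    secretion_scale: float = 1.0,
) -> ScaleDecomposition:
    """Decompose the stability of a mixed equilibrium by interaction scale."""
    ctx = apply_density(params, rho)
    x = np.asarray(equilibrium, dtype=float)
    d = drift(x, ctx, params, apc, secretion_scale)
    if np.max(np.abs(d)) > DRIFT_TOL * (1.0 + np.max(np.abs(x))):
        raise ValueError(
            f"supplied state is not an equilibrium (max |drift| = {np.max(np.abs(d)):.3g})"
        )
    J = jacobian(x, ctx, params, apc, secretion_scale)
    M = _polarization_generator(J)
    w_tf = float(M[0, 0])
    w_cy = float(M[1, 1])
    cross = float(M[0, 1] * M[1, 0])
    both_restoring = (w_tf < 0) and (w_cy < 0)
    within = (1.0 if both_restoring else -1.0) * abs(w_tf * w_cy)
    verdict = "mixed-stable" if (both_restoring and within >= cross) else "polarizing"
    return ScaleDecomposition(within, cross, w_tf, w_cy, verdict)


# ---------------------------------------------------------------------------
# APC reversal window


def reversal_window(
    params: ModelParameters,
    rho: float,
    apc_initial: APCInstruction,
    apc_switch: APCInstruction,
    switch_times: np.ndarray | None = None,
    horizon: float = 500.0,
    initial: np.ndarray = (0.1, 0.1, 0.0, 0.0),
    refine_tol: float = 0.05,
) -> dict:
    """Largest switch time at which opposing instruction still reverses.

    Integrates the deterministic system under ``apc_initial`` until each
    candidate switch time, then under ``apc_switch`` for the remaining
    horizon, classifying the terminal attractor by balance index. The
    boundary between the last reversing and first non-reversing grid point
    is refined by bisection to ``refine_tol`` hours.
    """
    b0 = apc_initial.APC1 / max(apc_initial.APC1 + apc_initial.APC2, 1e-30)
    b1 = apc_switch.APC1 / max(apc_switch.APC1 + apc_switch.APC2, 1e-30)
    if (b0 - 0.5) * (b1 - 0.5) >= 0:
        raise ValueError("apc_initial must be biased opposite to apc_switch")
    initial_side = TH1 if b0 > 0.5 else TH2
    switch_side = TH1 if b1 > 0.5 else TH2

    def terminal_label(ts: float) -> str:
        sched = APCSchedule.switch(apc_initial, apc_switch, ts, ts + horizon)
        traj = integrate_ode(
            np.asarray(initial, float), params, rho, sched,
            t_span=(0.0, ts + horizon), reporting_step=max(horizon / 50, 1.0),
        )
        lab = classify_attractor(traj.final)
        if lab == MIXED:
            raise RuntimeError(
                f"terminal state unclassifiable (balance "
                f"{balance_index(traj.final):.3f}) at switch time {ts:.2f} h"
            )
        return lab

    if switch_times is None:
        switch_times = np.array([0.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0])
    switch_times = np.sort(np.asarray(switch_times, dtype=float))
    labels = {ts: terminal_label(ts) for ts in switch_times}
    if labels[switch_times[0]] != switch_side:
        return {"window": -1.0, "labels": labels}  # even immediate switch fails
    reversing = [ts for ts in switch_times if labels[ts] == switch_side]
    holding = [ts for ts in switch_times if labels[ts] == initial_side]
    if not holding:
        return {"window": np.inf, "labels": labels}  # never becomes irreversible
    lo, hi = max(reversing), min(holding)
    while hi - lo > refine_tol:
        mid = 0.5 * (lo + hi)
        if terminal_label(mid) == switch_side:
            lo = mid
        else:
            hi = mid
    return {"window": 0.5 * (lo + hi), "labels": labels}
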