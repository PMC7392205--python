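"""Monte-Carlo parameter perturbation studies.

Two analyses around the calibrated operating points: (i) regime robustness —
how often the number of stable equilibria changes when all rate and
threshold parameters vary simultaneously by up to +/- a given amplitude;
(ii) per-parameter effect sizes on the position of a tracked equilibrium,
estimated by a main-effects linear regression across the Monte-Carlo
sample (parameter effects near the operating points are close to linear
and non-interacting, which the regression diagnoses rather than assumes).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ModelParameters, ZERO_APC, apply_density, drift
from .deterministic import (
    DRIFT_TOL,
    _polish_root,
    balance_index,
    find_equilibria,
    mixed_equilibrium,
)

__all__ = [
    "ParameterSample",
    "sample_parameters",
    "regime_scan",
    "effect_sizes",
    "PERTURBABLE_FIELDS",
]

#: Rate/threshold parameters perturbed by default. Hill exponents are held
#: fixed: scaling an exponent changes the interaction's functional class,
#: not just its strength. Noise magnitudes and the reference density are
#: likewise structural settings, not kinetic rates.
PERTURBABLE_FIELDS = (
    "b", "p1", "p2", "P1", "P2", "X1", "X2", "s1", "s2", "S1", "S2",
    "Z1", "Z2", "a1_base", "a2_base", "A1", "A2", "R1", "R2", "U1", "U2",
    "dTF1", "dTF2", "dCY_consume", "dCY_free",
)


@dataclass(frozen=True)
class ParameterSample:
    """Monte-Carlo sample of perturbed parameter sets."""

    base: ModelParameters
    amplitude: float
    multipliers: pd.DataFrame          # (n, len(fields)), columns = fields
    sets: tuple[ModelParameters, ...] = field(compare=False, default=())
    seed: int = 0

    def __len__(self) -> int:
        return len(self.sets)


def sample_parameters(
    base: ModelParameters,
    amp: float,
    n: int,
    seed: int = 0,
    fields: tuple[str, ...] = PERTURBABLE_FIELDS,
) -> ParameterSample:
    """Draw ``n`` parameter sets, each field scaled by U(1-amp, 1+amp)."""
    if not 0.0 <= amp <= 0.9:
        raise ValueError("amplitude must lie in [0, 0.9] (>=1 gives negative rates)")
    rng = np.random.default_rng(seed)
    mult = rng.uniform(1.0 - amp, 1.0 + amp, size=(n, len(fields)))
    sets = []
    for row in mult:
        kwargs = {f: getattr(base, f) * m for f, m in zip(fields, row)}
        sets.append(base.replace(**kwargs))
    return ParameterSample(
        base, amp, pd.DataFrame(mult, columns=list(fields)), tuple(sets), seed
    )


def _count_stable(params: ModelParameters, rho: float, n_tf: int = 5) -> int | None:
    """Stable-equilibrium count; None if the search fails outright."""
    try:
        eq = find_equilibria(params, rho, n_tf=n_tf)
    except Exception:
        return None
    if len(eq) == 0:
        return None
    return eq.n_stable


def regime_scan(
    base: ModelParameters,
    rho: float,
    amps: np.ndarray = (0.1, 0.2, 0.3, 0.5, 0.7, 0.9),
    n_per_amp: int = 500,
    seed: int = 0,
    n_tf: int = 5,
) -> dict:
    """Fraction of perturbed sets preserving the base regime, per amplitude.

    The regime label is the number of stable equilibria at the operating
    density. Returns the per-amplitude table, the smallest amplitude with
    any mismatch, and the overall fraction matching across the sweep.
    Search failures are excluded and counted.
    """
    base_count = _count_stable(base, rho, n_tf=n_tf)
    if base_count is None:
        raise RuntimeError("equilibrium search failed on the base parameter set")
    rows = []
    first_mismatch = None
    for i, amp in enumerate(np.sort(np.asarray(amps, dtype=float))):
        sample = sample_parameters(base, amp, n_per_amp, seed=seed + i)
        counts = [_count_stable(p, rho, n_tf=n_tf) for p in sample.sets]
        failed = sum(c is None for c in counts)
        ok = [c for c in counts if c is not None]
        matching = sum(c == base_count for c in ok)
        frac = matching / len(ok) if ok else np.nan
        rows.append(
            {
                "amp": amp,
                "n": n_per_amp,
                "n_failed": failed,
                "n_matching": matching,
                "fraction_matching": frac,
            }
        )
        if first_mismatch is None and matching < len(ok):
            first_mismatch = amp
    table = pd.DataFrame(rows)
    total_match = table["n_matching"].sum()
    total_ok = (table["n"] - table["n_failed"]).sum()
    return {
        "base_count": base_count,
        "table": table,
        "first_mismatch_amp": first_mismatch,
        "overall_fraction_matching": total_match / total_ok,
    }


def _tracked_equilibrium(
    params: ModelParameters, rho: float, guess: np.ndarray
) -> np.ndarray | None:
    """Continue the tracked equilibrium of a perturbed set from ``guess``."""
    ctx = apply_density(params, rho)
    x = _polish_root(np.asarray(guess, dtype=float), ctx, params, ZERO_APC, 1.0)
    return x


def effect_sizes(
    base: ModelParameters,
    rho: float,
    amp: float = 0.1,
    n: int = 1000,
    seed: int = 0,
    branch: str = "mixed",
    fields: tuple[str, ...] = PERTURBABLE_FIELDS,
) -> pd.DataFrame:
    """Per-parameter net effect on equilibrium position.

    Fits one main-effects linear model per response (balance index theta and
    total TF level of the tracked equilibrium) on the parameter multipliers,
    then reports each parameter's predicted change across its sampled range
    with all others held at base, as a percentage (percentage points of
    theta; percent of the base level for total TF).
    """
    if branch == "mixed":
        guess = mixed_equilibrium(base, rho)
    else:  # polarized branch: settle from a Th1-leaning start
        eq = find_equilibria(base, rho)
        stable = eq.stable_states
        if len(stable) == 0:
            raise RuntimeError("no stable equilibrium to track")
        guess = stable[np.argmax(balance_index(stable))]
    if n < 2 * len(fields):
        raise ValueError(
            f"n={n} too small for {len(fields)} main effects; need >= {2 * len(fields)}"
        )
    sample = sample_parameters(base, amp, n, seed=seed, fields=fields)
    theta = np.full(n, np.nan)
    tf_tot = np.full(n, np.nan)
    for i, p in enumerate(sample.sets):
        x = _tracked_equilibrium(p, rho, guess)
        if x is None:
            continue
        theta[i] = balance_index(x)
        tf_tot[i] = x[0] + x[1]
    ok = np.isfinite(theta)
    if ok.sum() < 2 * len(fields):
        raise RuntimeError("too many tracking failures for a stable regression")
    M = sample.multipliers.to_numpy()[ok]
    X = np.column_stack([np.ones(ok.sum()), M - 1.0])
    base_tf = float(tf_tot[ok].mean())
    rows = []
    for resp_name, resp, scale in (
        ("theta", theta[ok], 1.0),          # percentage points
        ("total_TF", tf_tot[ok], base_tf),  # percent of base level
    ):
        coef, *_ = np.linalg.lstsq(X, resp, rcond=None)
        # predicted change across the sampled multiplier range [1-amp, 1+amp]
        net = coef[1:] * (2.0 * amp)
        for f, v in zip(fields, net):
            rows.append(
                {
                    "parameter": f,
                    "response": resp_name,
                    "net_effect_percent": 100.0 * v / scale,
                }
            )
    return pd.DataFrame(rows)
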