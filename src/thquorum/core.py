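"""Core model definitions for Th1/Th2 effector choice with dynamic cytokines.

The model tracks four state variables describing a well-mixed group of CD4+
helper T cells: the master transcription factors TF1 (T-bet, Th1) and TF2
(GATA3, Th2), measured in molecules per cell, and the master cytokines CY1
(IFN-gamma) and CY2 (IL-4), measured as extracellular concentrations. Each
transcription factor self-activates and cross-inhibits its partner; each
cytokine induces its own transcription factor, is secreted under control of
both transcription factors, and cross-inhibits the opposing cytokine. All
regulatory interactions are saturating Hill functions.

Cell density enters through the cytokine kinetics only: secretion scales
linearly with density, while removal is the sum of a density-scaled
consumption term and a density-independent free-decay term. The
production:removal ratio therefore increases monotonically with density,
which is what ultimately drives the quorum-sensing bifurcation.

Antigen-presenting cells (APCs) instruct differentiation by targeted
cytokine delivery; they are modeled as additive constants that augment every
appearance of CY1/CY2 in the equations except the decay terms.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ModelParameters",
    "DensityContext",
    "APCInstruction",
    "DEFAULT_PARAMETERS",
    "IN_VITRO_DENSITY",
    "IN_VIVO_DENSITY",
    "apply_density",
    "apc_constants",
    "drift",
    "diffusion",
    "jacobian",
    "load_parameters",
    "save_parameters",
]

#: Typical Th culture density (cells/mL); the in-vitro operating point.
IN_VITRO_DENSITY = 2e6
#: Typical lymph-node density (cells/mL); the in-vivo operating point.
IN_VIVO_DENSITY = 1e9

_POSITIVE_FIELDS = (
    "b", "p1", "p2", "P1", "P2", "X1", "X2", "s1", "s2", "S1", "S2",
    "Z1", "Z2", "a1_base", "a2_base", "A1", "A2", "R1", "R2", "U1", "U2",
    "dTF1", "dTF2", "dCY_consume", "dCY_free", "rho_ref", "kappa_apc",
    "apc_nhalf",
)
_HILL_FIELDS = ("hp", "hx", "hs", "hz", "ha", "hr", "hu")
_NOISE_FIELDS = ("n_TF1", "n_TF2", "n_CY1", "n_CY2")

# Index-1 <-> index-2 partner fields, used by the symmetry predicate and by
# the state-swap helpers in the test suite.
_PAIRED_FIELDS = (
    ("p1", "p2"), ("P1", "P2"), ("X1", "X2"), ("s1", "s2"), ("S1", "S2"),
    ("Z1", "Z2"), ("a1_base", "a2_base"), ("A1", "A2"), ("R1", "R2"),
    ("U1", "U2"), ("dTF1", "dTF2"), ("n_TF1", "n_TF2"), ("n_CY1", "n_CY2"),
)


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, Hill thresholds/exponents and noise magnitudes.

    Units: transcription factors in molecules/cell, cytokines in
    concentration units, time in hours, density in cells/mL. Secretion rates
    ``a1_base``/``a2_base`` and the consumption coefficient ``dCY_consume``
    are quoted at the reference density ``rho_ref``.
    """

    # basal and self-activated TF production
    b: float = 1.0
    p1: float = 1.6
    p2: float = 1.6
    P1: float = 8.0
    P2: float = 8.0
    hp: float = 2.0
    # TF cross-inhibition
    X1: float = 10.0
    X2: float = 10.0
    hx: float = 3.0
    # cytokine-driven TF induction
    s1: float = 1.4
    s2: float = 1.4
    S1: float = 0.025
    S2: float = 0.025
    hs: float = 2.0
    # cytokine cross-inhibition of TF induction
    Z1: float = 5.0
    Z2: float = 5.0
    hz: float = 2.0
    # cytokine secretion (at reference density)
    a1_base: float = 0.05
    a2_base: float = 0.05
    A1: float = 2.0
    A2: float = 2.0
    ha: float = 2.0
    # TF repression of the opposing cytokine
    R1: float = 60.0
    R2: float = 60.0
    hr: float = 2.0
    # cytokine cross-inhibition of the opposing cytokine
    U1: float = 3.0
    U2: float = 3.0
    hu: float = 2.0
    # decay
    dTF1: float = 0.1
    dTF2: float = 0.1
    dCY_consume: float = 0.0001
    dCY_free: float = 0.1
    # noise volatilities (per sqrt-hour)
    n_TF1: float = 0.1
    n_TF2: float = 0.1
    n_CY1: float = 0.1
    n_CY2: float = 0.1
    # reference density and per-APC instruction strength
    rho_ref: float = IN_VITRO_DENSITY
    kappa_apc: float = 0.2
    apc_nhalf: float = 30.0

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        for name in _HILL_FIELDS:
            if not getattr(self, name) >= 1:
                raise ValueError(f"Hill exponent {name!r} must be >= 1")
        for name in _NOISE_FIELDS:
            if not getattr(self, name) >= 0:
                raise ValueError(f"noise magnitude {name!r} must be >= 0")

    @property
    def symmetric(self) -> bool:
        """True iff every index-1 value equals its index-2 partner."""
        return all(
            getattr(self, f1) == getattr(self, f2) for f1, f2 in _PAIRED_FIELDS
        )

    @property
    def noise(self) -> np.ndarray:
        return np.array([self.n_TF1, self.n_TF2, self.n_CY1, self.n_CY2])

    def replace(self, **kwargs: float) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    def with_noise(self, n_TF: float, n_CY: float | None = None) -> "ModelParameters":
        """Convenience: set all four volatilities (TF pair, CY pair)."""
        if n_CY is None:
            n_CY = n_TF
        return self.replace(n_TF1=n_TF, n_TF2=n_TF, n_CY1=n_CY, n_CY2=n_CY)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


#: Calibrated symmetric default parameter set (see docs/methods.md).
DEFAULT_PARAMETERS = ModelParameters()


@dataclass(frozen=True)
class DensityContext:
    """Density-resolved cytokine kinetics at a given cell density.

    ``a1``/``a2`` are the realized secretion maxima and ``dCY1``/``dCY2`` the
    realized removal rates at density ``rho``.
    """

    rho: float
    a1: float
    a2: float
    dCY1: float
    dCY2: float


@dataclass(frozen=True)
class APCInstruction:
    """Additive instruction constants, in cytokine-concentration units."""

    APC1: float = 0.0
    APC2: float = 0.0

    def __post_init__(self) -> None:
        if self.APC1 < 0 or self.APC2 < 0:
            raise ValueError("APC instruction constants must be >= 0")


ZERO_APC = APCInstruction(0.0, 0.0)


def apply_density(params: ModelParameters, rho: float) -> DensityContext:
    """Resolve cytokine secretion and removal rates at cell density ``rho``.

    Secretion into the extracellular volume scales with cell number,
    ``a_i(rho) = a_i_base * rho / rho_ref``; removal is cellular consumption
    (density-scaled) plus free decay (density-independent),
    ``dCY_i(rho) = dCY_consume * rho / rho_ref + dCY_free``. Because the
    free-decay floor is constant, the production:removal ratio increases
    strictly with density.
    """
    if not rho > 0:
        raise ValueError(f"cell density must be strictly positive, got {rho!r}")
    scale = rho / params.rho_ref
    d = params.dCY_consume * scale + params.dCY_free
    return DensityContext(
        rho=rho,
        a1=params.a1_base * scale,
        a2=params.a2_base * scale,
        dCY1=d,
        dCY2=d,
    )


def apc_constants(
    n_type1: float, n_type2: float, params: ModelParameters
) -> APCInstruction:
    """Instruction constants for given counts of Type-1 and Type-2 APCs.

    Instruction strength saturates with the total APC count,
    ``APC_i = kappa_apc * n_i * N_half / (N_half + N)`` with ``N = n1 + n2``:
    each APC contributes ``kappa_apc`` concentration units at low counts,
    while the total instruction is bounded by ``kappa_apc * N_half``
    (limited Th-APC contact capacity). The APC1:APC2 ratio always equals
    the count ratio, so instruction *bias* is the count frequency.
    """
    if n_type1 < 0 or n_type2 < 0:
        raise ValueError("APC counts must be >= 0")
    total = n_type1 + n_type2
    gain = params.kappa_apc * params.apc_nhalf / (params.apc_nhalf + total)
    return APCInstruction(gain * n_type1, gain * n_type2)


def _act(x: np.ndarray, K: float, h: float) -> np.ndarray:
    """Activating Hill term x^h / (K^h + x^h)."""
    xh = np.power(x, h)
    return xh / (K**h + xh)


def _rep(x: np.ndarray, K: float, h: float) -> np.ndarray:
    """Repressing Hill term K^h / (K^h + x^h)."""
    Kh = K**h
    return Kh / (Kh + np.power(x, h))


def drift(
    state: np.ndarray,
    ctx: DensityContext,
    params: ModelParameters,
    apc: APCInstruction = ZERO_APC,
    secretion_scale: float = 1.0,
) -> np.ndarray:
    """Deterministic rate of change of ``(TF1, TF2, CY1, CY2)``.

    ``state`` may carry leading batch axes; the last axis has length 4.
    Every appearance of CY_i except its decay term is augmented to
    ``CY_i + APC_i``. ``secretion_scale`` multiplies the cytokine secretion
    maxima only, modeling antibody blocking of secreted cytokine.

    The field is positivity-preserving: at any state with a zero component,
    the corresponding rate is non-negative.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("state components must be non-negative")
    if not 0.0 <= secretion_scale <= 1.0:
        raise ValueError("secretion_scale must lie in [0, 1]")
    p = params
    T1, T2, C1, C2 = (state[..., i] for i in range(4))
    E1 = C1 + apc.APC1  # effective instruction-augmented cytokine signals
    E2 = C2 + apc.APC2

    dT1 = (
        (p.b + p.p1 * _act(T1, p.P1, p.hp)) * _rep(T2, p.X2, p.hx)
        + p.s1 * _act(E1, p.S1, p.hs) * _rep(E2, p.Z2, p.hz)
        - p.dTF1 * T1
    )
    dT2 = (
        (p.b + p.p2 * _act(T2, p.P2, p.hp)) * _rep(T1, p.X1, p.hx)
        + p.s2 * _act(E2, p.S2, p.hs) * _rep(E1, p.Z1, p.hz)
        - p.dTF2 * T2
    )
    dC1 = (
        secretion_scale * ctx.a1
        * _act(T1, p.A1, p.ha) * _rep(T2, p.R2, p.hr) * _rep(E2, p.U2, p.hu)
        - ctx.dCY1 * C1
    )
    dC2 = (
        secretion_scale * ctx.a2
        * _act(T2, p.A2, p.ha) * _rep(T1, p.R1, p.hr) * _rep(E1, p.U1, p.hu)
        - ctx.dCY2 * C2
    )
    return np.stack([dT1, dT2, dC1, dC2], axis=-1)


def diffusion(state: np.ndarray, params: ModelParameters) -> np.ndarray:
    """State-proportional (geometric) noise amplitudes.

    Returns ``(n_TF1*TF1, n_TF2*TF2, n_CY1*CY1, n_CY2*CY2)``, the amplitudes
    of independent Brownian differentials. The multiplicative form yields
    lognormal-type fluctuations and vanishes at zero, so the origin is never
    crossed by noise.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("state components must be non-negative")
    return state * params.noise


def jacobian(
    state: np.ndarray,
    ctx: DensityContext,
    params: ModelParameters,
    apc: APCInstruction = ZERO_APC,
    secretion_scale: float = 1.0,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Jacobian of the drift field at ``state`` (central finite differences).

    Steps are taken relative to the component magnitude (floored at 1e-6 in
    model units) and clipped so that perturbed states stay non-negative.
    """
    x = np.asarray(state, dtype=float)
    J = np.empty((4, 4))
    for j in range(4):
        h = rel_step * abs(x[j]) + 1e-8
        lo = x.copy()
        hi = x.copy()
        hi[j] += h
        lo[j] = max(lo[j] - h, 0.0)
        span = hi[j] - lo[j]
        f_hi = drift(hi, ctx, params, apc, secretion_scale)
        f_lo = drift(lo, ctx, params, apc, secretion_scale)
        J[:, j] = (f_hi - f_lo) / span
    return J


# ---------------------------------------------------------------------------
# Parameter file I/O (flat key -> value; TOML or JSON)

def load_parameters(path: str | Path) -> ModelParameters:
    """Load a flat key->value parameter file (TOML or JSON by suffix).

    Unknown keys and invariant violations raise ``ValueError`` naming the
    offending key.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    known = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
    for key, value in data.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool) or not math.isfinite(value):
            raise ValueError(f"parameter {key!r} must be a finite number")
    return ModelParameters(**{k: float(v) for k, v in data.items()})


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a flat parameter file (TOML or JSON by suffix)."""
    path = Path(path)
    data = params.as_dict()
    if path.suffix.lower() == ".toml":
        lines = [f"{k} = {v!r}" for k, v in data.items()]
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")
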