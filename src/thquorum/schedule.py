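"""Piecewise-constant time courses of APC instruction."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import APCInstruction, ModelParameters, apc_constants

__all__ = ["APCSchedule"]


@dataclass(frozen=True)
class APCSchedule:
    """Piecewise-constant (APC1, APC2) instruction over a time horizon.

    Segments are stored as parallel arrays ``t_start < t_end`` (hours) with
    instruction constants per segment. Segments must tile the horizon
    contiguously from ``t_start[0]``.
    """

    t_start: np.ndarray
    t_end: np.ndarray
    apc1: np.ndarray
    apc2: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("t_start", "t_end", "apc1", "apc2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t_start)
        if not (len(self.t_end) == len(self.apc1) == len(self.apc2) == n) or n == 0:
            raise ValueError("schedule arrays must be non-empty and equal length")
        if np.any(self.t_end <= self.t_start):
            raise ValueError("segment ends must exceed starts")
        if n > 1 and not np.allclose(self.t_start[1:], self.t_end[:-1]):
            raise ValueError("segments must be contiguous")
        if np.any(self.apc1 < 0) or np.any(self.apc2 < 0):
            raise ValueError("instruction constants must be >= 0")

    # -- constructors -----------------------------------------------------
    @classmethod
    def constant(cls, apc: APCInstruction, horizon: float) -> "APCSchedule":
        return cls([0.0], [horizon], [apc.APC1], [apc.APC2])

    @classmethod
    def switch(
        cls,
        apc_before: APCInstruction,
        apc_after: APCInstruction,
        t_switch: float,
        horizon: float,
    ) -> "APCSchedule":
        """Single instruction switch at ``t_switch``."""
        if t_switch <= 0:
            return cls.constant(apc_after, horizon)
        if t_switch >= horizon:
            return cls.constant(apc_before, horizon)
        return cls(
            [0.0, t_switch],
            [t_switch, horizon],
            [apc_before.APC1, apc_after.APC1],
            [apc_before.APC2, apc_after.APC2],
        )

    @classmethod
    def from_biases(
        cls,
        breaks: np.ndarray,
        biases: np.ndarray,
        total_apcs: float,
        params: ModelParameters,
    ) -> "APCSchedule":
        """Build from Th1-bias fractions per segment and a total APC count."""
        breaks = np.asarray(breaks, dtype=float)
        biases = np.asarray(biases, dtype=float)
        pairs = [
            apc_constants(total_apcs * b, total_apcs * (1.0 - b), params)
            for b in biases
        ]
        return cls(
            breaks[:-1], breaks[1:],
            [p.APC1 for p in pairs], [p.APC2 for p in pairs],
            meta={"biases": biases.tolist(), "total_apcs": total_apcs},
        )

    # -- accessors --------------------------------------------------------
    @property
    def horizon(self) -> float:
        return float(self.t_end[-1])

    @property
    def breakpoints(self) -> np.ndarray:
        return np.concatenate([self.t_start[:1], self.t_end])

    def segment_index(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.t_end, np.asarray(t, dtype=float), side="right")
        return np.clip(idx, 0, len(self.t_start) - 1)

    def at(self, t: float) -> APCInstruction:
        i = int(self.segment_index(t))
        return APCInstruction(float(self.apc1[i]), float(self.apc2[i]))

    def values_at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = self.segment_index(t)
        return self.apc1[idx], self.apc2[idx]

    def bias(self, t: float) -> float:
        """Th1 bias fraction APC1/(APC1+APC2); 0.5 when no instruction."""
        a = self.at(t)
        tot = a.APC1 + a.APC2
        return a.APC1 / tot if tot > 0 else 0.5

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_start_h": self.t_start,
                "t_end_h": self.t_end,
                "apc1": self.apc1,
                "apc2": self.apc2,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "APCSchedule":
        df = pd.read_csv(path)
        return cls(
            df["t_start_h"].to_numpy(),
            df["t_end_h"].to_numpy(),
            df["apc1"].to_numpy(),
            df["apc2"].to_numpy(),
        )
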