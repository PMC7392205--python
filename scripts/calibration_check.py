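"""Verify the calibrated default parameter set against its design targets.

The shipped defaults are a symmetric calibrated set (see docs/methods.md).
This script recomputes the regime diagnostics the calibration targeted:

  1. with secretion blocked, the transcription-factor toggle is bistable;
  2. at culture density (1-2e6 cells/mL) the mixed state is the unique
     stable equilibrium, with a healthy stability margin;
  3. at lymph-node density (1e9 cells/mL) the mixed state is unstable and
     the two polarized quorum states are stable;
  4. the quorum density lies strictly between the two;
  5. the secretion-bifurcation critical scale lies inside (0, 1);
  6. the APC reversal window for the 10-APC 6:4 scenario is on the
     hours-to-tens-of-hours scale.

Usage: python scripts/calibration_check.py
"""

from __future__ import annotations

import numpy as np

from thquorum import (
    DEFAULT_PARAMETERS,
    apc_constants,
    balance_index,
    find_equilibria,
    mixed_equilibrium,
    quorum_density,
    reversal_window,
    secretion_bifurcation_scan,
)
from thquorum.deterministic import _leading_eig


def main() -> None:
    p = DEFAULT_PARAMETERS
    print("calibrated default parameter set — regime diagnostics\n")

    eq0 = find_equilibria(p, 2e6, secretion_scale=0.0)
    theta0 = balance_index(eq0.stable_states)
    print(f"1. toggle (secretion off): {len(eq0)} equilibria, "
          f"{eq0.n_stable} stable at theta = {np.round(np.sort(theta0), 3)}")

    for rho in (1e6, 2e6):
        x = mixed_equilibrium(p, rho)
        lead = _leading_eig(p, rho, x)
        n_stable = find_equilibria(p, rho).n_stable
        print(f"2. rho={rho:.0e}: mixed TF={x[0]:.2f} CY={x[2]:.3f} "
              f"leading eig {lead:+.4f}/h, stable equilibria: {n_stable}")

    eq9 = find_equilibria(p, 1e9)
    x9 = mixed_equilibrium(p, 1e9)
    print(f"3. rho=1e9: mixed leading eig {_leading_eig(p, 1e9, x9):+.4f}/h, "
          f"{eq9.n_stable} stable polarized states at theta = "
          f"{np.round(np.sort(balance_index(eq9.stable_states)), 3)}")

    q = quorum_density(p)
    print(f"4. quorum density: {q['critical_density']:.3g} cells/mL "
          f"(production:removal ratio {q['production_removal_ratio']:.2f})")

    scan = secretion_bifurcation_scan(p, 2e6, scales=np.linspace(1, 0, 11))
    print(f"5. critical secretion scale at 2e6: {scan['critical_scale']:.4f}")

    w = reversal_window(
        p, 1e9, apc_constants(6, 4, p), apc_constants(0, 1000, p)
    )
    print(f"6. reversal window (10 APCs at 6:4 vs 1000 opposing): "
          f"{w['window']:.1f} h")


if __name__ == "__main__":
    main()
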