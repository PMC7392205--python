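# thquorum

Quorum sensing in CD4+ T helper (Th) effector choice, as a simulatable
dynamical model.

When naive helper T cells decide between the Th1 and Th2 effector programs,
experiments disagree: cultured cells (~10⁶ cells/mL) form stable mixtures
of Th1, Th2 and hybrid phenotypes, while in lymph nodes (~10⁹ cells/mL)
whole cell groups commit to a single effector type — even under conflicting
instruction from antigen-presenting cells (APCs). `thquorum` implements a
four-variable model that reconciles both: the master transcription factors
T-bet (TF1) and GATA3 (TF2) form a self-activating, cross-inhibiting
toggle inside cells, while the master cytokines IFN-γ (CY1) and IL-4 (CY2)
couple cells through the shared extracellular volume,

    dTF1 = [(b + p1·TF1ʰ/(P1ʰ+TF1ʰ))·X2ʰ/(X2ʰ+TF2ʰ)
            + s1·CY1ʰ/(S1ʰ+CY1ʰ)·Z2ʰ/(Z2ʰ+CY2ʰ) − dTF1·TF1] dt + n·TF1 dW
    dCY1 = [a1(ρ)·TF1ʰ/(A1ʰ+TF1ʰ)·R2ʰ/(R2ʰ+TF2ʰ)·U2ʰ/(U2ʰ+CY2ʰ)
            − dCY1(ρ)·CY1] dt + n·CY1 dW      (index 2 mirrored)

with cytokine secretion and removal scaling with cell density ρ, APC
instruction entering as additive constants on every cytokine term except
decay, and multiplicative noise capturing the heavy-tailed cell-to-cell
variability of molecular expression.

The package provides, as library functions and a `thquorum` CLI:

* deterministic integration, equilibrium location and stability analysis;
* the secretion-blocking bifurcation (mixed phenotypes are only stable in
  the presence of cytokine signaling) and the density-driven quorum
  bifurcation, with the within-scale vs cross-scale stability
  decomposition of the mixed state;
* APC "sparking" of quorum commitment and the reversal window after which
  opposing mass instruction can no longer flip the decision;
* stochastic (Euler–Maruyama) ensembles, balance-index distributions, and
  discernment scoring — how well noisy quora track time-varying APC
  instruction, scanned over molecular-volatility grids;
* Monte-Carlo parameter sensitivity: regime robustness and per-parameter
  effect sizes.

The shipped parameter set is a symmetric calibrated default that
reproduces the qualitative regime structure above; see `docs/methods.md`
for its construction, all numerical choices, and known limitations.

## Worked example

```python
import numpy as np
from thquorum import (DEFAULT_PARAMETERS, apc_constants, find_equilibria,
                      quorum_density, reversal_window)

p = DEFAULT_PARAMETERS

eq = find_equilibria(p, rho=2e6)            # culture density
print(len(eq), eq.n_stable)                 # -> 1 1  (a single stable mixed state)

eq = find_equilibria(p, rho=1e9)            # lymph-node density
print(len(eq), eq.n_stable)                 # -> 5 2  (mixed + two saddles unstable,
                                            #         two polarized states stable)
q = quorum_density(p)
print(f"{q['critical_density']:.3g}")       # -> 1.83e+07  (cells/mL)

w = reversal_window(p, 1e9, apc_constants(6, 4, p), apc_constants(0, 1000, p))
print(f"{w['window']:.1f} h")               # -> 11.6 h
```

Ten APCs with a slight 6:4 Th1 majority commit the whole quorum to Th1;
after ~12 hours, even a thousand all-Th2 APCs can no longer reverse that
commitment. The quorum density (1.8×10⁷ cells/mL) falls squarely between
culture and lymph-node densities, which is why polarized group decisions
are an in-vivo phenomenon.

The same protocols are scriptable, e.g.

```
thquorum equilibria --rho 1e9 --out eq.csv
thquorum experiment fig2 --outdir out/ --seed 1
thquorum discern --seed 0 --out grid.csv
```

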