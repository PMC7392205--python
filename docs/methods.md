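# Methods

## Model

`thquorum` simulates effector choice in a well-mixed group of CD4+ helper T
cells with four state variables: the intracellular master transcription
factors TF1 (T-bet, Th1 program) and TF2 (GATA3, Th2 program), in molecules
per cell, and the extracellular master cytokines CY1 (IFN-γ) and CY2
(IL-4), in concentration units. Time is in hours.

The deterministic rates are built entirely from saturating Hill terms:

```
dTF1/dt = (b + p1·act(TF1;P1,hp)) · rep(TF2;X2,hx)
        + s1·act(CY1+APC1;S1,hs) · rep(CY2+APC2;Z2,hz)  − dTF1·TF1
dCY1/dt = σ·a1(ρ)·act(TF1;A1,ha) · rep(TF2;R2,hr) · rep(CY2+APC2;U2,hu)
        − dCY1(ρ)·CY1
```

with `act(x;K,h) = x^h/(K^h+x^h)`, `rep(x;K,h) = K^h/(K^h+x^h)`, the
index-2 equations mirrored, `σ ∈ [0,1]` the permitted secretion fraction
(antibody blocking of secreted cytokine; it scales only `a1, a2`), and APC
instruction entering additively at every cytokine appearance except decay.

Each transcription factor self-activates (`p, P, hp`), is cross-inhibited
by its rival (`X, hx`), and is induced by its own cytokine (`s, S, hs`)
under cross-inhibition by the rival cytokine (`Z, hz`). Cytokine secretion
is driven by the cognate transcription factor (`a, A, ha`), repressed by
the rival transcription factor (`R, hr`) and by the rival cytokine
(`U, hu`).

Cell density ρ (cells/mL) affects only the cytokine kinetics:
`a_i(ρ) = a_i_base·ρ/ρ_ref` (secretion into the shared volume scales with
cell number) and `dCY_i(ρ) = dCY_consume·ρ/ρ_ref + dCY_free` (removal is
density-scaled consumption plus density-independent free decay). Because
free decay sets a floor, the production:removal ratio increases strictly
with density — the quantity that ultimately drives quorum sensing.

The stochastic extension adds independent multiplicative Brownian terms
`n_X·X·dW_X` to each species, producing lognormal-like heavy-tailed
fluctuations. Paths use Euler–Maruyama in natural coordinates with
clamping at zero (the noise amplitude itself vanishes at zero, so the clamp
only absorbs discretization overshoot); default `dt = 0.01 h` (0.02 h for
the long discernment protocols, where the fastest relaxation rate is
0.15 /h and both step sizes resolve it by three orders of magnitude).

## Default parameter set

The shipped defaults are a **symmetric calibrated stand-in**, not a
literature-fitted set. They were chosen once so that the model reproduces
the qualitative regime structure the biology demands, and are then treated
as the package's study conditions:

| group | values |
|---|---|
| TF production | b=1.0, p=1.6, P=8, hp=2, X=10, hx=3, dTF=0.1 /h |
| cytokine→TF induction | s=1.4, S=0.025, hs=2, Z=5, hz=2 |
| secretion | a_base=0.05 at ρ_ref=2×10⁶/mL, A=2, ha=2, R=60, hr=2 |
| CY–CY inhibition / removal | U=3, hu=2, dCY_consume=10⁻⁴ /h, dCY_free=0.1 /h |
| noise / APC | n=0.1 per √h (all species), κ_apc=0.2, N_half=30 |

The calibration targets, all verified by the test suite:

1. **Bare toggle bistable.** With secretion blocked (σ=0) the
   transcription-factor pair is a classic self-activation/cross-inhibition
   toggle: unstable symmetric point at TF≈9.9 (growth rate +0.087 /h) and
   two stable polarized states (balance index 0.97/0.03).
2. **Mixed state uniquely stable in vitro.** At 1–2×10⁶ cells/mL with full
   secretion, cytokine induction lifts both factors to TF≈17.5, deep enough
   into the cross-inhibition saturation that the toggle instability is
   quenched (leading eigenvalue −0.04 /h). Polarized states do not exist
   there: a would-be loser's basal expression still secretes enough
   cytokine (A=2 is low) to re-induce its transcription factor and restore
   the mixed state. This "rescue" is what makes mixed effector phenotypes
   the unique in-vitro attractor.
3. **Quorum bifurcation.** As density rises the cytokine level at the mixed
   equilibrium grows past Z, the rival-cytokine repression collapses the
   induction lift, and the underlying toggle instability re-emerges
   together with a destabilizing CY–CY block (cytokine level past U); the
   mixed branch loses stability at ≈1.8×10⁷ cells/mL. At 10⁹ cells/mL the
   only stable states are the two polarized quorum decisions.
4. **Hour-scale commitment in vivo.** Cytokine kinetics at 10⁹ cells/mL are
   deliberately slow (dCY ≈ 0.15 /h), so the polarization instability runs
   at ≈0.14 /h and deterministic commitment takes tens of hours — an APC
   reversal window of ≈12 h for the 10-APC 6:4 scenario, consistent with
   the tens-of-hours scale on which lymph-node effector commitment becomes
   refractory to new instruction.

### APC instruction

Type-1/Type-2 APC counts map to additive instruction constants through a
saturating contact law `APC_i = κ_apc·n_i·N_half/(N_half+N)`, `N = n1+n2`:
κ_apc per APC at low counts, total bounded by κ_apc·N_half (limited
Th–APC contact capacity). The APC1:APC2 ratio always equals the count
ratio. A purely linear law cannot serve both ends of the count range: ten
biased APCs must deliver instruction that outweighs molecular noise at
in-vivo density, while a thousand opposing APCs must not deliver so much
that they erase an established quorum's cytokine field outright.

## Analyses

* **Equilibria** are found by multi-start Newton/hybrid root search (TF
  grid log-spaced over 0.01–100× the Hill thresholds, cytokines started at
  secretion balance), verified to `‖drift‖ < 10⁻⁸` (relative), deduplicated
  at 10⁻⁶ relative distance, and classified by Jacobian eigenvalues
  (central finite differences). Brute-force endpoint clustering from a 5⁴
  initial-condition grid serves as an independent oracle in the tests.
* **Bifurcation scans** track the mixed (symmetric-branch) equilibrium by
  continuation and bracket the critical secretion fraction and quorum
  density by the sign change of its leading eigenvalue (Brent's method on
  log-density; tolerance 10⁻³ decades).
* **Within/cross-scale decomposition.** The mixed state's polarization mode
  lives in the difference coordinates (TF1−TF2, CY1−CY2). The Jacobian is
  restricted to its difference-like invariant subspace (the two eigenmodes
  with the most difference-space energy, expressed in the difference
  chart — an oblique projection that is exact, and reduces to the plain
  block projection in the symmetric case). The diagonal entries of the
  resulting 2×2 are the within-scale feedbacks (TF toggle vs decay; CY
  mutual inhibition vs removal) and the off-diagonals the cross-scale gains.
  Verdict: mixed-stable iff both within-scale feedbacks restore *and* their
  product exceeds the product of cross-scale gains — the standard
  trace/determinant criterion, hence exactly the sign of the mode's leading
  eigenvalue.
* **Reversal window**: deterministic integration under a piecewise
  instruction schedule, terminal attractor classified by the balance index
  θ = TF1/(TF1+TF2) (Th1 if θ>0.8, Th2 if θ<0.2, θ(0,0)≡0.5); the boundary
  switch time is refined by bisection to 0.05 h.
* **Discernment**: random piecewise-constant instruction time-courses
  (1–6 segments over 500 h, durations log-uniform on [10, 250] h, first
  segment fully biased, later segments drawn from biases
  {0, 0.25, 0.75, 1}, 30 APCs total). The optimal response obeys complete
  opposite instruction sustained ≥ τ (τ ∈ {24, 48, 96} h) and ignores
  everything else. Tracking performance is the time-fraction of agreement
  between a path's attractor label and the target (mixed counts as
  disagreement); cell means are normalized by the best cell. Identical
  schedules and path seeds are reused across volatility cells (common
  random numbers). Desk scale: 20 schedules × 20 paths; the paper-scale
  200×100 is a flag away.
* **Sensitivity**: all 25 rate/threshold parameters multiplied by
  independent U(1−A, 1+A) draws (Hill exponents fixed — scaling an
  exponent changes the interaction's functional class). Regime label =
  number of stable equilibria. Effect sizes: main-effects linear regression
  of the tracked equilibrium's balance index and total TF level on the
  multipliers; reported as the predicted change across each parameter's
  sampled range (A=0.1), in percentage points of θ and percent of the base
  level respectively.

## What the generator does and does not emulate

The synthetic study conditions reproduce: culture versus lymph-node
densities (2×10⁶ vs 10⁹ cells/mL), antibody secretion blocking, one-week
culture horizons, small conflicting APC cohorts and late mass-instruction
switches, and heavy-tailed expression variability. They do not include
proliferation or cell death, spatial cytokine gradients, discrete per-cell
APC contacts, receptor occupancy, epigenetic locking, or additional
effector lineages. Passing tests therefore demonstrate the collective
decision-making logic of the four-species network under these idealized
conditions, not quantitative agreement with any particular culture or
in-vivo dataset.

## Known limitations

* The default parameters are a calibrated stand-in; quantities that depend
  on fine margins inherit that choice. In particular, per-parameter effect
  sizes on the mixed equilibrium reach ~11 percentage points of θ (the
  in-vitro operating point sits a factor ~2–3 from criticality), and at
  high density rare regime changes appear from ±30% parameter variation.
* Tracking performance along the equal-noise diagonal decreases
  monotonically with volatility at this calibration: equal transcription-
  factor noise degrades initial commitment accuracy and retention faster
  than the accompanying cytokine noise enables obedience, so the interior
  optimum appears only off-diagonal (low TF noise, high CY noise — where
  the best cells lie for τ = 24 and 48 h). The committed state's cytokine
  level sits ~25× above the Z threshold, so escaping it requires cytokine
  volatility near 1.0 per √h.
* With symmetric parameters the in-vitro mean dynamics are symmetric; any
  late Th2 drift seen in real mixed cultures requires an asymmetric
  parameter set and is out of scope for the symmetric default.
* Exactly symmetric initial states in a polarized regime ride the unstable
  manifold into the mixed saddle; the package reports "mixed" in that
  degenerate case rather than perturbing the state.
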