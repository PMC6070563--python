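# Methods

## The model

`pflswitch` models the core gene circuit of fibroblast activation: the
transcription factor Twist1 induces Prrx1, Prrx1 induces the matricellular
protein tenascin-C (TNC), and secreted TNC feeds back to sustain Twist1
production — a three-gene positive feedback loop (PFL). The circuit is
reduced to three state variables (Tw, P, T — the cellular levels of
Twist1, Prrx1 and TNC, in arbitrary units) with Hill-activation production
and first-order decay:

    dTw/dt = b_Tw + V_dox · h(D; K_dox, n_dox)
                  + V_fb · h(T_sensed; K_fb, n_fb) − k_Tw · Tw
    dP/dt  = b_P + V_TwP · h(Tw; K_TwP, n_TwP) − k_P · P
    dT/dt  = b_T + V_PT  · h(P; K_PT, n_PT)  − k_T · T

with `h(x; K, n) = xⁿ / (Kⁿ + xⁿ)`. Two input modes cover the two
experimental settings:

* **dox mode** — the stimulus D is the doxycycline level of a Tet-ON
  Twist1 induction; the feedback senses the endogenous TNC (T_sensed = T).
* **tnc_injection mode** — D = 0 and the feedback senses endogenous plus
  exogenous TNC (T_sensed = T + stimulus), modelling recombinant-protein
  treatment.

This is deliberately a minimal model: no intermediate species, no
transport, no explicit secretion. Its purpose is the qualitative switch
behaviour — ultrasensitivity, bistability, hysteresis, and irreversibility
— not quantitative proteome kinetics.

### Assumptions

- Production terms are independent and additive; degradation is linear.
- The feedback operates through a single saturable activation with
  half-saturation constant K_fb (K_m1 in the phase-diagram axes).
- Exogenous and endogenous TNC are interchangeable for the receptor-level
  feedback (tnc_injection mode).
- Concentrations are arbitrary units; time is days, which is the natural
  scale of the induction experiments being emulated.

## Switch analysis

**Fixed points.** At equilibrium P and T are explicit functions of Tw, so
the 3-D equilibrium problem collapses to one scalar self-consistency
equation in Tw. That equation is scanned on a dense bracketed grid (2000
log-spaced points up to the production bound ΣV/k, an a-priori bound on
any equilibrium), sign changes are polished by Brent's method, and
stability is read from the eigenvalues of the full 3×3 Jacobian. The scan
is exhaustive by construction — unlike Newton iterations from random
starts, it cannot silently miss a branch. The model has 1–3 equilibria;
when there are three, the pattern is stable/saddle/stable (a bistable
window).

**Quasi-static sweeps.** The stimulus–response branches are traced by
stepping the stimulus and solving to steady state at each step, seeded
with the previous step's state. Two interchangeable back-ends exist:

- `method="relax"` — literal ODE relaxation (LSODA with the analytic
  Jacobian) until ‖dx/dt‖∞ < 10⁻⁸ a.u./day; the faithful but slower
  protocol.
- `method="continuation"` — pick the stable fixed point nearest the
  previous state. Equivalent in the quasi-static limit and orders of
  magnitude faster; used for 40×40 phase diagrams.

The acceptance suite cross-checks the two back-ends against each other and
against a third independent oracle, an explicit slow up-then-down ramp
(ramp time ≫ all relaxation times).

**Switching metrics.** θ_on (θ_off) is the stimulus at the discontinuous
jump of the up (down) branch, located by an adjacent-grid-point ratio
test (> 5×, configurable) and reported as the midpoint of the bracketing
interval — grid resolution is the quoted uncertainty. The irreversibility
measure ΔTNC is TNC(final) − TNC(initial) at zero stimulus after an
up-then-down sweep: ΔTNC ≤ ε_rev = 10⁻³ a.u. is reversible (phase I),
larger is irreversible (phase II). The hysteresis width is θ_on − θ_off,
defined as 0 for a monostable (jump-free) response and undefined
(open-ended) when the loop never switches off.

**Ultrasensitivity.** The effective Hill exponent
n_eff = log 81 / log(EC90/EC10) of the up-sweep TNC branch, compared with
the feedback-ablated control (V_fb = 0). When EC10 and EC90 collapse into
one grid interval the response is all-or-none and n_eff is reported
infinite, flagged.

## Reference parameterizations

Four presets are shipped as versioned JSON (regenerable with
`scripts/tune_presets.py`); they were tuned once against their anchors and
then frozen.

**`dox_reference`** — the Tet-ON induction model. Feedback is
Michaelis–Menten (n_fb = 1, matching the description of K_m1 as a
Michaelis–Menten constant) with a deliberately sub-saturated downstream
cascade (K_TwP = 15, K_PT = 8 against maximal levels of ~10), so the high
branch keeps depending on dox. That choice produces a wide reversible
regime: at the default V_fb = 35 the loop is bistable with θ_on ≈ 0.69 and
θ_off ≈ 0.28; the hysteresis width grows with V_fb (≈0.12 at V_fb = 28 to
≈0.56 at 40) while θ_on moves by < 20%; beyond V_fb ≈ 42 the loop latches
(ΔTNC > 0), and at V_fb = 80 it is deeply irreversible (ΔTNC ≈ 5.5).
Basal rates are tiny (10⁻³ a.u./day) so the OFF state sits near the
origin and the feedback is negligible before switching. Defaults for
convergence and integration: rtol 10⁻⁸, atol 10⁻¹⁰, steady-state
threshold 10⁻⁸ a.u./day.

**`mrc5` and `imr90`** — the dox_reference with every rate-dimension
parameter multiplied by a single factor (0.2343 and 0.4685). A global
time rescale leaves every equilibrium, threshold and phase boundary
exactly unchanged and only stretches the kinetics, so it is the clean way
to encode "same circuit, slower cells": under a dox step of level 1.0 the
TNC level first exceeds 2-fold over baseline at 8.0 days (MRC5-like) and
4.0 days (IMR90-like, inside the reported 3–5-day range), with the
activation order Twist1 → Prrx1 → TNC.

**`dermal_injection`** — the exogenous-TNC model. Here the anchors are
printed operating points, not curves: irreversible at
(K_m1, V) = (5, 30) with a pulse of amplitude 3, reversible at (10, 15)
for any amplitude, and dose–response activation (> 2-fold in Twist1 and
endogenous TNC) only at 5 µg among {0, 0.1, 1, 2, 5} µg with a single
dose→stimulus scale (1 µg = 1 a.u.). Meeting the fold-change constraints
requires an appreciable Twist1 baseline (b_Tw = 2) and cooperative
feedback (n_fb = 4): with n_fb = 1 any parameterization that switches
below 3 a.u. already shows > 2-fold Twist1 induction at 2 µg. The
cooperativity is a preset-level design choice, not a claim about the
underlying biochemistry.

Preset conventions: n_dox = 1 and n_TwP = n_PT in all presets, leaving 16
free kinetic constants; both ties are conventions of the preset files,
not code constraints.

## Synthetic data

The generators stand in for the study's measurements; they are pure
functions of (parameters, protocol, seed).

* **Induction time courses** — simulate the preset under a dox step,
  convert to log2 fold change over the pre-stimulus steady state (the
  western-blot normalisation), add i.i.d. Gaussian noise on the log2
  scale (default σ = 0.2, a conventional stand-in for densitometry
  error; the source data state no noise model). Default sampling days
  {0, 1, 3, 5, 8, 11, 15}, 3 replicates.
* **Dose–response tables** — each dose applied independently from the
  resting state (separate dishes), relaxed to steady state; linear fold
  changes with log-normal noise; the zero-dose lane is each replicate's
  own normalisation reference, so its fold change is exactly 1.
* **Single-cell snapshots** — at a stimulus inside the bistable window,
  each cell is ON with probability `fraction_on`; intensities are the
  corresponding stable fixed point times per-gene log-normal factors
  (median 1, CV 0.2 by default). All three genes are concordant within a
  cell by construction. The saddle's TNC level is the natural ON/OFF
  classification threshold.

What a green test on synthetic data does **not** establish: the generators
share the model family with the analysis, so they validate the pipeline's
internal consistency (estimators recover generating parameters, metrics
detect built-in switches), not the biological fidelity of the model form.
Real blots have saturation, loading artefacts and correlated errors; real
single-cell data have segmentation noise and continuous intermediate
states; none of these are emulated.

## Parameter estimation

Maximum likelihood with homoscedastic Gaussian noise on log2 fold changes:
NLL = Σ (y_obs − y_sim)²/(2σ²) + n·log(σ√2π). The global search is a
real-coded genetic algorithm in log10 parameter space (rate constants live
on ratio scales): tournament selection (size 3), uniform crossover (rate
0.8), Gaussian mutation (rate 0.1, σ = 0.15 decades), elitism (2), default
population 100 × 200 generations (tests and the acceptance suite use
scaled-down populations, stated inline), log-uniform initialisation within
bounds (default ±2 decades around the reference), followed by a
Nelder-Mead polish of the best individual. Everything is driven by one
seed; fits are bit-reproducible.

**Identifiability.** The feedback pair (V_fb, K_fb) is structurally
compensating in this model: V·T/(K+T) is nearly scale-invariant under
(V, K) → (cV, cK) whenever K is not far below the visited TNC range, so
joint recovery of both from a single induction course runs along a ridge
to the bounds at any realistic noise (a washout protocol does not break
the ridge either). `recovery_experiment` flags such parameters (median
relative error above 100%); the shipped recovery benchmark therefore frees
the identifiable set (V_fb, k_Tw, V_dox, V_PT), recovered to 2–6% median
error at σ = 0.2 with the scaled-down GA.

## Numerical choices and degenerate inputs

- Stiff-safe integration: LSODA with the analytic Jacobian, restarted at
  protocol breakpoints so step discontinuities never cross a solver step.
- States are clipped at 0 on output (solver undershoot ≤ atol); negative
  inputs to the vector field raise.
- Root de-duplication within 10⁻⁶ relative; root residual 10⁻⁹.
- Zero baselines in fold-change computations fall back to an absolute
  floor of 10⁻⁶ a.u.
- Non-convergent relaxations return a flagged result (sweeps continue);
  solver failures raise with the failing time.
- Ties in activation order are broken upstream-first (Twist1, Prrx1, TNC).

## Known limitations

- The ΔTNC fast path for phase diagrams assumes branches are monotone in
  the stimulus (true for this activation-only cascade; it would need
  revisiting for models with repression).
- θ_on/θ_off inherit the stimulus-grid resolution; phase boundaries in
  40×40 diagrams inherit both grid resolutions.
- The GA is single-threaded; a 10-seed 4-parameter recovery takes a few
  minutes on one CPU.
- Hill coefficients are constrained to ≥ 1; sub-linear activation is out
  of scope.
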