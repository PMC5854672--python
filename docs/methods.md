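# Methods

## Scope and model

`bkfit` analyzes macroscopic patch-clamp recordings of large-conductance
Ca²⁺- and voltage-activated K⁺ (BK) channels and of their block by pore-
occluding peptide toxins such as charybdotoxin (ChTX). Four quantities are
extracted:

1. **Voltage dependence of activation.** Steady-state currents from a
   voltage-step family are converted to chord conductance
   `G(V) = I_ss / (V − E_rev)` and fitted with the Boltzmann function

       G / G_max = 1 / (1 + exp((V − V_half) / κ)),

   yielding the half-activation voltage `V_half` and steepness `κ`. The
   functional form is kept exactly as above, so an *activating* curve has
   `κ < 0`; the conventional positive slope factor `k = −κ` is exposed as
   `BoltzmannFit.slope_k` to avoid sign confusion.

2. **Relaxation kinetics.** Activation (step phase) and deactivation (tail
   phase) are fitted with a single exponential
   `I(t) = baseline + amplitude · exp(−t/τ)`, one τ per phase, assembled
   into τ–V relationships. Biexponential or sigmoidally delayed (Cole–Moore)
   kinetics are out of scope.

3. **Toxin-block kinetics.** Peak currents sampled around a timed toxin
   application are fitted to a first-order bimolecular scheme in two
   regimes: onset `I(t) = (I₀ − I_ss)·exp(−t/τ_on) + I_ss` for
   t₀ < t < t₁ and recovery `I(t) = I_r − (I_r − I_ss)·exp(−(t − t₁)/τ_off)`
   for t > t₁, where t₀/t₁ are the application/washout times. The
   equilibrium dissociation constant follows from
   `K_D = [Tx] / (τ_off/τ_on − 1)`, and percent inhibition is
   `100·(1 − I_ss/I₀)`. When τ_off ≤ τ_on the scheme cannot assign an
   affinity (block too weak); `K_D` is then reported as a status
   (`undefined_weak_block`), never a number.

4. **Double-mutant cycle coupling.** With the gating free energy taken
   proportional to `V_half`, the non-additivity of the four cycle corners
   (wild-type complex, two single mutants, double mutant)

       ΔΔV = V_half(βmut) + V_half(αmut) − V_half(double) − V_half(wt)

   measures the residue-pair coupling on the voltage axis. Any common
   reference cancels algebraically, so raw `V_half` values are used
   directly (asserted by a reference-shift invariance test). Energy
   conversion uses the fixed equivalence 20 mV ≡ 1 kcal/mol; no zΔV·F
   conversion is attempted because the effective gating charge is not an
   input. The coupling verdict is |ΔΔV| ≥ 20 mV, inclusive. The ΔΔV
   standard error is propagated by quadrature from the four fit SEs
   (independent patches).

## Synthetic data generator

Because no raw recordings ship with the package, every fit is validated
against a generator with analytic ground truth:

* **Gating sweeps.** Two-state gating: the open fraction rests at its
  Boltzmann steady state during the prepulse and relaxes mono-exponentially
  toward the steady state of each commanded voltage with time constant
  τ(V); current is ohmic, `I = g_max · p(t) · (V − E_rev)`, with `g_max` in
  nS, voltages in mV and currents in pA. `E_rev = 0 mV` by default
  (symmetrical K⁺ recording solutions). τ(V) defaults to a log-bell peaked
  at `V_half` (floor 0.5 ms, peak +12 ms, width 60 mV) — a smooth stand-in
  with the qualitatively correct shape, *not* an inference about BK
  biophysics; any constant or callable can be substituted.

* **Block time courses.** The unblocked fraction obeys
  `du/dt = −k_on[Tx]u + k_off(1−u)` during application and
  `du/dt = k_off(1−u)` after washout, evaluated in closed form, so
  `1/τ_on = k_on[Tx] + k_off`, `τ_off = 1/k_off` and
  `I_ss/I₀ = K_D/(K_D + [Tx])` hold exactly in the noiseless limit.

* **Noise.** Additive i.i.d. Gaussian noise on current samples, one named
  `numpy.random.default_rng(seed)` per dataset (default seed 0). A fixed
  seed fixes every output byte; the noiseless component never depends on
  the seed. Real recordings differ: their noise is band-limited (not white
  per sample), they carry capacitive/leak artifacts, gating is multi-state
  and Ca²⁺-dependent, and rundown/drift perturbs block time courses. A
  passing recovery test therefore shows estimator correctness under the
  stated statistical model, not robustness to every artifact of real data.

## Default parameters

| parameter | default | why |
|---|---|---|
| step family | −140…+140 mV, 20 mV increments | standard BK activation protocol |
| prepulse | −180 mV, 10 ms | holds channels closed before the step |
| step / tail duration | 50 ms / 25 ms | covers activation and tail relaxation |
| sampling interval | 0.01 ms (100 kHz) | typical digitization rate for these recordings |
| tail (deactivation) voltage | −100 mV | strong deactivating driving force |
| `g_max` | 10 nS | macroscopic patch with ~40 pS channels, a few hundred open |
| `κ` | −16 mV | typical BK steepness at 10 μM Ca²⁺ |
| steady-state window | last 10 % of the step | plateau average; configurable `tail_fraction` |
| relaxation blanking | first 5 % of the phase | emulates capacitive-transient blanking |
| block sampling interval | 10 s | one test depolarization per 10 s |
| toxin concentration | caller-supplied, nM | 1 μM ≡ 1000 nM in the worked examples |

## Numerical choices

* All nonlinear fits use Levenberg–Marquardt (`scipy.optimize.least_squares`)
  with tight tolerances. The Boltzmann fit uses an analytic Jacobian and is
  performed on conductances normalized internally by `max(g)`, which makes
  the shape parameters exactly invariant under binary-exact rescaling of
  the data. Initialization: `V_half` from the interpolated half-max
  crossing, `κ` from the 25–75 % rise span divided by 2·ln 3 (sign
  automatic), `g_max` free by default (option to pin to `max(g)`); on
  non-convergence the start is jittered ×5 and the best solution returned
  with `converged=False` — a flagged fit, never silent garbage.
* Exponential fits are parameterized in log τ to keep time constants
  positive. A fitted amplitude below 3× the residual SD is flagged
  `no_relaxation` (or no-block) rather than reported as a τ.
* `I₀` is the pre-application mean, not a fit parameter; `I_ss` is fitted
  in the onset phase and held fixed in the recovery phase; `I_r` is free.
  Application and washout times are experiment metadata — a change-point
  helper (`suggest_application_window`) exists as a diagnostic but is never
  applied silently.
* The steady-state conductance is a window mean, so noiseless round trips
  are exact only when the relaxation completes within the step (τ ≪ step
  duration) — exactness tests use a fast constant τ. Likewise the recovery
  equation assumes the onset reached steady state by washout, so exact
  τ_off round trips need an application window of ≳16 τ_on.
* Sweeps at `V = E_rev` carry no conductance information and are dropped
  with a warning. Degenerate inputs (flat G-V data, one-sided curves,
  empty groups, τ_off ≤ τ_on, I₀ = 0) raise or set explicit statuses.
* Voltage-axis K_D cancellation: `K_D = [Tx]/(τ_off/τ_on − 1)` loses
  floating-point precision as τ_off/τ_on → 1; that regime is reported as
  `undefined_weak_block` anyway.
* The t-test is the classic pooled-variance Student's test (two-tailed,
  unpaired), with Welch's form behind a flag; two zero-variance groups with
  equal means report t = 0, p = 1 by convention. Dispersion is labeled
  explicitly (`sd` vs `se`) in every summary rather than assuming one.
* Display rounding is centralized (2 decimals for voltages, 1 for τ and
  K_D); JSON outputs keep full precision.

## Problem sizes used in validation

Monte Carlo recovery checks use 100 seeded replicates per condition at 1–2 %
of-peak Gaussian current noise on a 0.1 ms grid (0.01 ms for the end-to-end
cycle pipeline), and block recovery uses mSlo1-like rates sampled at 0.5 s
(the 10 s default undersamples a 3.5 s onset; the sampling interval is an
explicit model field). `scripts/acceptance.py` reruns all of these from
scratch with seeds derived from `--seed`.

## Known limitations

* Two-state gating only: no Markov multi-state models, Ca²⁺-dependence,
  inactivation, or single-channel stochastics.
* Single-exponential kinetics only; one-site reversible block only (no
  Hill/concentration-response fitting).
* The τ(V) default is a placeholder shape; τ–V conclusions from synthetic
  data reflect that choice.
* Fractional V_half shifts are reported as Δ/|V_half,ref| alongside the
  absolute shift; other normalizations exist and the choice is explicit in
  `VHalfShift`.
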