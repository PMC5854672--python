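# bkfit

Analysis of BK-channel patch-clamp experiments: Boltzmann conductance-voltage
(G-V) fitting, single-exponential relaxation kinetics, first-order
bimolecular toxin-block kinetics with dissociation-constant (K_D)
derivation, and thermodynamic double-mutant cycle coupling analysis — plus a
synthetic voltage-clamp data generator so every stage can be validated
against known ground truth.

## Who this is for

Electrophysiologists quantifying how auxiliary subunits (e.g. the β4
subunit) or point mutations change BK-channel gating and blocker
pharmacology. The package takes episodic voltage-step sweep sets and
peak-current block time courses (plain TSV + JSON sidecar) and produces the
standard result tables: V_half ± SE per construct, τ_on/τ_off/K_D per
blocker experiment, and coupling verdicts for residue pairs.

## The quantities it computes

* **G-V / Boltzmann:** `G/G_max = (1 + exp((V − V_half)/κ))⁻¹`, fitted by
  least squares from steady-state currents converted to chord conductance.
* **Relaxation:** `I(t) = baseline + amplitude·e^(−t/τ)` per phase
  (activation at the step, deactivation on the tail), assembled into τ–V
  curves.
* **Toxin block:** onset `I(t) = (I₀ − I_ss)e^(−t/τ_on) + I_ss`, recovery
  `I(t) = I_r − (I_r − I_ss)e^(−(t−t₁)/τ_off)`, and
  `K_D = [Tx]/((τ_off/τ_on) − 1)`; percent inhibition `100(1 − I_ss/I₀)`.
* **Double-mutant cycle:** `ΔΔV = V_half(αβ*) + V_half(α*β) −
  V_half(α*β*) − V_half(αβ)`, converted to energy at 20 mV ≡ 1 kcal/mol,
  with the inclusive coupling criterion |ΔΔV| ≥ 20 mV.

See `docs/methods.md` for model assumptions, defaults and limitations.

## Worked example

```python
import bkfit as bk

# simulate an mSlo1-like patch: V_half = 30.39 mV, activating kappa
model = bk.GatingModel(v_half=30.39, kappa=-16.0, g_max=10.0,
                       tau_params=5.0, noise_sd=0.0)
sweeps = bk.make_gating_sweeps(model, bk.StepProtocol())
gv = bk.steady_state_conductance(sweeps, e_rev=0.0)   # warns: 0 mV dropped
fit = bk.fit_boltzmann(gv)
print(f"V_half = {fit.v_half:.2f} mV, kappa = {fit.kappa:.2f} mV")

# charybdotoxin block with mSlo1-like rates at 1 uM toxin
m = bk.BlockModel(k_on=(1/3.5 - 1/21.6)/1000, k_off=1/21.6, toxin_nm=1000.0,
                  i0_pa=1000.0, t_apply_s=30.0, t_washout_s=90.0,
                  interval_s=0.5, total_s=200.0)
bf = bk.fit_block(bk.make_block_timecourse(m))
print(f"tau_on = {bf.tau_on_s:.1f} s, tau_off = {bf.tau_off_s:.1f} s, "
      f"KD = {bf.kd_nm:.1f} nM, inhibition = {bf.inhibition_pct:.1f}%")

# double-mutant cycle on four measured half-activation voltages
panel = bk.analyze_cycle(38.89, 18.64, -2.53, 19.58)
print(f"ddV = {panel.ddv_mv:.2f} mV, ddG = {panel.ddg_kcal:.3f} kcal/mol, "
      f"coupled = {panel.coupled}")
```

prints

```
V_half = 30.39 mV, kappa = -16.00 mV
tau_on = 3.5 s, tau_off = 21.6 s, KD = 193.4 nM, inhibition = 83.8%
ddV = -42.36 mV, ddG = -2.118 kcal/mol, coupled = True
```

The fitted V_half and κ equal the generator truth (noiseless round trip);
the block fit recovers the onset and washout time constants and hence
K_D = k_off/k_on ≈ 193 nM, with the equilibrium inhibition
100·[Tx]/(K_D + [Tx]); the cycle's −42.36 mV non-additivity (≈ −2.1
kcal/mol) far exceeds the 20 mV criterion, so the two mutated residues are
energetically coupled.

A CLI mirrors the library:
`bkfit simulate gating|block`, `bkfit gv`, `bkfit kinetics`, `bkfit block`,
`bkfit cycle`, `bkfit report` (see `bkfit --help`).

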