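"""Synthetic voltage-clamp data with known ground truth.

Generates episodic voltage-step sweep sets from a two-state Boltzmann gating
model and peak-current block time courses from a first-order bimolecular
blocker scheme, so every downstream fit (G-V, relaxation, block kinetics,
mutant cycle) can be validated against analytic truth.

Model conventions
-----------------
* Steady-state open probability ``P(V) = 1 / (1 + exp((V - v_half)/kappa))``.
  With this form an *activating* channel (conductance rising with
  depolarization) has ``kappa < 0``.
* Macroscopic current is ohmic: ``I = g_max * p(t) * (V - e_rev)`` with
  ``g_max`` in nS, voltages in mV, currents in pA (nS * mV = pA).
* Relaxation to the steady state at each commanded voltage is
  mono-exponential with a voltage-dependent time constant ``tau(V)``.
* Block: the unblocked fraction ``u(t)`` obeys
  ``du/dt = -k_on*[Tx]*u + k_off*(1 - u)`` while toxin is applied and
  ``du/dt = k_off*(1 - u)`` after washout, giving onset rate
  ``1/tau_on = k_on*[Tx] + k_off``, recovery rate ``1/tau_off = k_off`` and
  equilibrium ``I_ss/I_0 = K_D/(K_D + [Tx])`` with ``K_D = k_off/k_on``.

Noise is additive i.i.d. Gaussian on current samples, drawn from a named
``numpy.random.default_rng(seed)`` per dataset; a fixed seed fixes every
output byte and the noiseless component never depends on the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "GatingModel",
    "StepProtocol",
    "BlockModel",
    "Sweep",
    "SweepSet",
    "BlockTimecourse",
    "LogBellTau",
    "boltzmann_popen",
    "make_gating_sweeps",
    "make_block_timecourse",
    "make_cycle_dataset",
    "CYCLE_LABELS",
]

# Canonical double-mutant-cycle corner labels: wild-type complex, pore-subunit
# single mutant, auxiliary-subunit single mutant, double mutant.
CYCLE_LABELS = ("wt", "alpha_mut", "beta_mut", "double")


def boltzmann_popen(v_mv, v_half: float, kappa: float):
    """Steady-state open fraction ``1 / (1 + exp((V - v_half)/kappa))``."""
    v_mv = np.asarray(v_mv, dtype=float)
    return 1.0 / (1.0 + np.exp((v_mv - v_half) / kappa))


@dataclass(frozen=True)
class LogBellTau:
    """Log-bell voltage dependence of the relaxation time constant.

    ``log tau(V)`` is a Gaussian bell in voltage peaking at ``v_center``:
    ``tau(V) = tau_floor + tau_peak * exp(-((V - v_center)/width)**2)``.

    The real voltage dependence of BK relaxation is not specified by the
    two-state model; this is a smooth stand-in with the qualitatively right
    shape (slow near the half-activation voltage, fast at extremes).
    """

    tau_peak_ms: float = 12.0
    v_center_mv: float = 0.0
    width_mv: float = 60.0
    tau_floor_ms: float = 0.5

    def __call__(self, v_mv: float) -> float:
        return self.tau_floor_ms + self.tau_peak_ms * math.exp(
            -(((v_mv - self.v_center_mv) / self.width_mv) ** 2)
        )


TauSpec = Union[float, Callable[[float], float], None]


@dataclass
class GatingModel:
    """Ground-truth Boltzmann gating model for one channel construct.

    Parameters
    ----------
    v_half : half-activation voltage (mV).
    kappa : Boltzmann steepness (mV); negative for activating channels under
        the ``1/(1 + exp((V - v_half)/kappa))`` convention.
    g_max : maximal macroscopic conductance (nS).
    e_rev : reversal potential (mV); 0 in symmetrical K+.
    tau_params : relaxation time constant tau(V) in ms — a constant, a
        callable ``V -> tau``, or None for a log-bell peaked at ``v_half``.
    noise_sd : additive Gaussian current noise SD (pA).
    seed : RNG seed for the noise stream.
    """

    v_half: float
    kappa: float = -16.0
    g_max: float = 10.0
    e_rev: float = 0.0
    tau_params: TauSpec = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("v_half", "kappa", "g_max", "e_rev", "noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.kappa == 0:
            raise ValueError("kappa must be nonzero")
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def popen(self, v_mv):
        return boltzmann_popen(v_mv, self.v_half, self.kappa)

    def tau_ms(self, v_mv: float) -> float:
        if self.tau_params is None:
            tau = LogBellTau(v_center_mv=self.v_half)(v_mv)
        elif callable(self.tau_params):
            tau = float(self.tau_params(v_mv))
        else:
            tau = float(self.tau_params)
        if not (math.isfinite(tau) and tau > 0):
            raise ValueError(f"tau({v_mv} mV) = {tau!r} is not a positive number")
        return tau

    def steady_current_pa(self, v_mv: float) -> float:
        return self.g_max * float(self.popen(v_mv)) * (v_mv - self.e_rev)


@dataclass
class StepProtocol:
    """Episodic voltage-step protocol: prepulse -> step family -> tail."""

    prepulse_mv: float = -180.0
    prepulse_ms: float = 10.0
    step_voltages: Sequence[float] = tuple(range(-140, 141, 20))
    step_ms: float = 50.0
    tail_mv: float = -100.0
    tail_ms: float = 25.0
    sample_interval_ms: float = 0.01  # 100 kHz digitization

    def __post_init__(self) -> None:
        self.step_voltages = tuple(float(v) for v in self.step_voltages)
        if len(self.step_voltages) == 0:
            raise ValueError("step_voltages must be non-empty")
        if any(b <= a for a, b in zip(self.step_voltages, self.step_voltages[1:])):
            raise ValueError("step_voltages must be strictly increasing")
        for name in ("prepulse_ms", "step_ms", "tail_ms", "sample_interval_ms"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")
        if self.sample_interval_ms >= min(self.prepulse_ms, self.step_ms, self.tail_ms):
            raise ValueError("sample_interval_ms must be shorter than every phase")

    @property
    def t_step_start_ms(self) -> float:
        return self.prepulse_ms

    @property
    def t_tail_start_ms(self) -> float:
        return self.prepulse_ms + self.step_ms

    @property
    def t_total_ms(self) -> float:
        return self.prepulse_ms + self.step_ms + self.tail_ms

    def time_grid_ms(self) -> np.ndarray:
        n = int(round(self.t_total_ms / self.sample_interval_ms)) + 1
        return np.arange(n) * self.sample_interval_ms

    def phase_window_ms(self, phase: str) -> tuple[float, float]:
        """(start, end) of 'prepulse' | 'activation' (step) | 'deactivation' (tail)."""
        if phase == "prepulse":
            return 0.0, self.t_step_start_ms
        if phase == "activation":
            return self.t_step_start_ms, self.t_tail_start_ms
        if phase == "deactivation":
            return self.t_tail_start_ms, self.t_total_ms
        raise ValueError(f"unknown phase {phase!r}")

    def to_dict(self) -> dict:
        return {
            "prepulse_mv": self.prepulse_mv,
            "prepulse_ms": self.prepulse_ms,
            "step_voltages": list(self.step_voltages),
            "step_ms": self.step_ms,
            "tail_mv": self.tail_mv,
            "tail_ms": self.tail_ms,
            "sample_interval_ms": self.sample_interval_ms,
        }


@dataclass
class Sweep:
    """One episodic sweep: commanded step voltage plus the sampled trace."""

    voltage_mv: float
    t_ms: np.ndarray
    i_pa: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.i_pa = np.asarray(self.i_pa, dtype=float)
        if self.t_ms.shape != self.i_pa.shape:
            raise ValueError("time and current arrays must have equal length")


@dataclass
class SweepSet:
    """A family of sweeps sharing one protocol and sampling grid."""

    sweeps: list[Sweep]
    protocol: StepProtocol
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sweeps) != len(self.protocol.step_voltages):
            raise ValueError("one sweep per protocol step voltage is required")
        grid = self.sweeps[0].t_ms
        for sw in self.sweeps[1:]:
            if sw.t_ms.shape != grid.shape or not np.array_equal(sw.t_ms, grid):
                raise ValueError("all sweeps must share one sampling grid")

    def sweep_at(self, voltage_mv: float) -> Sweep:
        for sw in self.sweeps:
            if sw.voltage_mv == voltage_mv:
                return sw
        raise KeyError(f"no sweep at {voltage_mv} mV")

    @property
    def voltages(self) -> np.ndarray:
        return np.array([sw.voltage_mv for sw in self.sweeps])


@dataclass
class BlockTimecourse:
    """Peak current vs elapsed time around a timed toxin application."""

    t_s: np.ndarray
    i_peak_pa: np.ndarray
    toxin_nm: float
    t_apply_s: float
    t_washout_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.i_peak_pa = np.asarray(self.i_peak_pa, dtype=float)
        if self.t_s.shape != self.i_peak_pa.shape:
            raise ValueError("time and current arrays must have equal length")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t_s must be strictly increasing")
        if not (self.t_apply_s < self.t_washout_s):
            raise ValueError("t_apply_s must precede t_washout_s")
        if self.t_apply_s < self.t_s[0] or self.t_washout_s > self.t_s[-1]:
            raise ValueError("application window must lie inside the recording")


@dataclass
class BlockModel:
    """Ground truth for a reversible first-order bimolecular blocker.

    ``k_on`` in nM^-1 s^-1, ``k_off`` in s^-1; the implied dissociation
    constant is ``kd_nm = k_off / k_on``. The toxin is applied at
    ``t_apply_s`` and washed out at ``t_washout_s``; peak currents are
    sampled every ``interval_s`` (10 s default, one voltage step per sample).
    """

    k_on: float
    k_off: float
    toxin_nm: float
    i0_pa: float = 1000.0
    t_apply_s: float = 100.0
    t_washout_s: float = 300.0
    interval_s: float = 10.0
    total_s: float = 600.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "toxin_nm", "i0_pa", "t_apply_s",
                     "t_washout_s", "interval_s", "total_s", "noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("k_on and k_off must be positive")
        if self.toxin_nm < 0:
            raise ValueError("toxin_nm must be >= 0")
        if not (0 <= self.t_apply_s < self.t_washout_s <= self.total_s):
            raise ValueError("require 0 <= t_apply_s < t_washout_s <= total_s")
        if self.interval_s <= 0:
            raise ValueError("interval_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def kd_nm(self) -> float:
        return self.k_off / self.k_on

    @property
    def tau_on_s(self) -> float:
        """Onset time constant 1/(k_on*[Tx] + k_off)."""
        return 1.0 / (self.k_on * self.toxin_nm + self.k_off)

    @property
    def tau_off_s(self) -> float:
        """Recovery time constant 1/k_off."""
        return 1.0 / self.k_off

    @property
    def u_ss(self) -> float:
        """Equilibrium unblocked fraction K_D/(K_D + [Tx])."""
        return self.kd_nm / (self.kd_nm + self.toxin_nm)


def _command_voltage(protocol: StepProtocol, step_mv: float, t_ms: np.ndarray) -> np.ndarray:
    v = np.full_like(t_ms, protocol.prepulse_mv)
    v[t_ms >= protocol.t_step_start_ms] = step_mv
    v[t_ms >= protocol.t_tail_start_ms] = protocol.tail_mv
    return v


def noiseless_sweep_current(model: GatingModel, protocol: StepProtocol,
                            step_mv: float, t_ms: np.ndarray) -> np.ndarray:
    """Analytic open-fraction relaxation evaluated on the sample grid.

    The patch is held equilibrated at the prepulse voltage; at each phase
    transition the open fraction relaxes mono-exponentially from its value at
    the transition toward the new steady state with tau(V_phase).
    """
    p = np.empty_like(t_ms)
    p_pre = float(model.popen(protocol.prepulse_mv))
    t0, t1 = protocol.t_step_start_ms, protocol.t_tail_start_ms

    pre = t_ms < t0
    p[pre] = p_pre

    step = (t_ms >= t0) & (t_ms < t1)
    p_inf = float(model.popen(step_mv))
    tau_v = model.tau_ms(step_mv)
    p[step] = p_inf + (p_pre - p_inf) * np.exp(-(t_ms[step] - t0) / tau_v)
    p_step_end = p_inf + (p_pre - p_inf) * math.exp(-(t1 - t0) / tau_v)

    tail = t_ms >= t1
    p_tail = float(model.popen(protocol.tail_mv))
    tau_t = model.tau_ms(protocol.tail_mv)
    p[tail] = p_tail + (p_step_end - p_tail) * np.exp(-(t_ms[tail] - t1) / tau_t)

    v_cmd = _command_voltage(protocol, step_mv, t_ms)
    return model.g_max * p * (v_cmd - model.e_rev)


def make_gating_sweeps(model: GatingModel, protocol: StepProtocol) -> SweepSet:
    """Simulate one sweep per protocol step voltage.

    With ``noise_sd = 0`` the output equals the analytic relaxation at every
    sample; with noise, a single ``default_rng(model.seed)`` stream makes the
    run bit-reproducible and the noiseless component seed-independent.
    """
    t_ms = protocol.time_grid_ms()
    rng = np.random.default_rng(model.seed)
    sweeps = []
    for v_step in protocol.step_voltages:
        i = noiseless_sweep_current(model, protocol, v_step, t_ms)
        if model.noise_sd > 0:
            i = i + rng.normal(0.0, model.noise_sd, size=i.shape)
        sweeps.append(Sweep(voltage_mv=v_step, t_ms=t_ms.copy(), i_pa=i))
    meta = {
        "kind": "synthetic_gating",
        "seed": model.seed,
        "truth": {
            "v_half": model.v_half, "kappa": model.kappa, "g_max": model.g_max,
            "e_rev": model.e_rev, "noise_sd": model.noise_sd,
        },
    }
    return SweepSet(sweeps=sweeps, protocol=protocol, metadata=meta)


def noiseless_block_fraction(model: BlockModel, t_s: np.ndarray) -> np.ndarray:
    """Closed-form unblocked fraction u(t) of the bimolecular scheme."""
    u = np.ones_like(t_s)
    on = (t_s >= model.t_apply_s) & (t_s < model.t_washout_s)
    off = t_s >= model.t_washout_s
    if model.toxin_nm == 0:
        return u
    rate_on = model.k_on * model.toxin_nm + model.k_off
    u_ss = model.u_ss
    u[on] = u_ss + (1.0 - u_ss) * np.exp(-(t_s[on] - model.t_apply_s) * rate_on)
    u_wash = u_ss + (1.0 - u_ss) * math.exp(
        -(model.t_washout_s - model.t_apply_s) * rate_on
    )
    u[off] = 1.0 - (1.0 - u_wash) * np.exp(-(t_s[off] - model.t_washout_s) * model.k_off)
    return u


def make_block_timecourse(model: BlockModel) -> BlockTimecourse:
    """Simulate a peak-current block/washout time course."""
    n = int(math.floor(model.total_s / model.interval_s)) + 1
    t_s = np.arange(n) * model.interval_s
    i = model.i0_pa * noiseless_block_fraction(model, t_s)
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        i = i + rng.normal(0.0, model.noise_sd, size=i.shape)
    meta = {
        "kind": "synthetic_block",
        "seed": model.seed,
        "truth": {
            "k_on": model.k_on, "k_off": model.k_off, "kd_nm": model.kd_nm,
            "tau_on_s": model.tau_on_s, "tau_off_s": model.tau_off_s,
            "i0_pa": model.i0_pa, "noise_sd": model.noise_sd,
        },
    }
    return BlockTimecourse(
        t_s=t_s, i_peak_pa=i, toxin_nm=model.toxin_nm,
        t_apply_s=model.t_apply_s, t_washout_s=model.t_washout_s, metadata=meta,
    )


def make_cycle_dataset(models: Mapping[str, GatingModel],
                       protocol: StepProtocol) -> dict[str, SweepSet]:
    """Simulate the four corners of a double-mutant cycle.

    ``models`` must carry exactly the labels ``wt``, ``alpha_mut``,
    ``beta_mut`` and ``double`` (wild-type complex, the two single mutants,
    and the double mutant). Deterministic given each model's seed.
    """
    got = set(models)
    want = set(CYCLE_LABELS)
    if got != want:
        missing, extra = sorted(want - got), sorted(got - want)
        raise ValueError(
            f"cycle needs labels {CYCLE_LABELS}; missing {missing}, extra {extra}"
        )
    out = {}
    for label in CYCLE_LABELS:
        ss = make_gating_sweeps(models[label], protocol)
        ss.metadata["cycle_label"] = label
        out[label] = ss
    return out
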