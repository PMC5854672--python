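"""Single-exponential relaxation fits and tau-V relationships.

Activation kinetics are fitted on the step phase of each sweep and
deactivation kinetics on the tail phase, both with

    I(t) = baseline + amplitude * exp(-t / tau)

where t is measured from the phase onset. The first ``skip_fraction`` of the
phase is excluded to emulate capacitive-transient blanking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synthetic import StepProtocol, Sweep, SweepSet

__all__ = ["RelaxFit", "fit_relaxation", "tau_voltage_curve", "TauVoltageCurve"]

# fitted |amplitude| below this multiple of the residual SD is flagged as
# "no relaxation" rather than reported as a time constant
_AMP_SNR_MIN = 3.0


@dataclass
class RelaxFit:
    """One exponential relaxation fit.

    ``no_relaxation`` is set (and ``converged`` cleared) when the fitted
    amplitude is indistinguishable from the residual noise.
    """

    tau_ms: float
    amplitude_pa: float
    baseline_pa: float
    window_ms: tuple[float, float]
    rss: float
    converged: bool
    kind: str  # "activation" | "deactivation"
    no_relaxation: bool = False
    se_tau_ms: float = float("nan")


def _phase_samples(sweep: Sweep, protocol: StepProtocol, phase: str,
                   skip_fraction: float) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    t0, t1 = protocol.phase_window_ms(phase)
    w_start = t0 + skip_fraction * (t1 - t0)
    sel = (sweep.t_ms >= w_start) & (sweep.t_ms < t1)
    t = sweep.t_ms[sel] - t0  # re-zero to phase onset
    return t, sweep.i_pa[sel], (w_start, t1)


def fit_relaxation(sweep: Sweep, protocol: StepProtocol, phase: str,
                   skip_fraction: float = 0.05) -> RelaxFit:
    """Fit a single exponential to one phase of one sweep.

    Parameters
    ----------
    phase : "activation" (step phase) or "deactivation" (tail phase).
    skip_fraction : fraction of the phase dropped at its start, in [0, 0.5).
    """
    if phase not in ("activation", "deactivation"):
        raise ValueError("phase must be 'activation' or 'deactivation'")
    if not (0.0 <= skip_fraction < 0.5):
        raise ValueError("skip_fraction must be in [0, 0.5)")
    t, i, window = _phase_samples(sweep, protocol, phase, skip_fraction)
    if len(t) < 10:
        raise ValueError(f"need >= 10 samples in the {phase} phase after skipping")

    if float(np.ptp(i)) == 0.0:
        return RelaxFit(tau_ms=float("nan"), amplitude_pa=0.0,
                        baseline_pa=float(i[0]), window_ms=window, rss=0.0,
                        converged=False, kind=phase, no_relaxation=True)

    base0 = float(np.mean(i[-max(3, len(i) // 10):]))
    amp0 = float(i[0] - base0)
    span = float(t[-1] - t[0])
    # time at which |I - baseline| first drops to amp/e, as a tau guess
    dev = np.abs(i - base0)
    below = dev <= abs(amp0) / math.e
    tau0 = float(t[np.argmax(below)] - t[0]) if below.any() and abs(amp0) > 0 else span / 3.0
    if tau0 <= 0:
        tau0 = span / 3.0

    def resid(p):
        log_tau, amp, base = p
        return base + amp * np.exp(-(t - t[0]) / math.exp(log_tau)) - i

    sol = least_squares(resid, np.array([math.log(tau0), amp0, base0]),
                        method="lm", xtol=1e-14, ftol=1e-14, max_nfev=10000)
    log_tau, amp, base = sol.x
    tau = math.exp(log_tau)
    rss = float(2.0 * sol.cost)
    resid_sd = math.sqrt(rss / max(len(t) - 3, 1))

    se_tau = float("nan")
    if len(t) > 3:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / (len(t) - 3)
            se_tau = tau * math.sqrt(max(cov[0, 0], 0.0))  # delta method on log tau
        except np.linalg.LinAlgError:
            pass

    no_relax = abs(amp) < _AMP_SNR_MIN * resid_sd
    return RelaxFit(
        tau_ms=tau, amplitude_pa=float(amp), baseline_pa=float(base),
        window_ms=window, rss=rss,
        converged=bool(sol.success) and not no_relax,
        kind=phase, no_relaxation=bool(no_relax), se_tau_ms=se_tau,
    )


@dataclass
class TauVoltageCurve:
    """Tau-V relationship: converged fits plus the rejected sweeps."""

    table: pd.DataFrame            # columns: v_mv, tau_ms, se_tau_ms
    rejects: pd.DataFrame          # columns: v_mv, reason
    phase: str


def tau_voltage_curve(sweeps: SweepSet, phase: str,
                      skip_fraction: float = 0.05) -> TauVoltageCurve:
    """Fit every sweep and assemble the tau-V table, ordered by voltage.

    Sweeps whose fit does not converge (or shows no relaxation) go to the
    rejects table. Raises if no sweep yields a converged fit.
    """
    rows, rejects = [], []
    for sw in sweeps.sweeps:
        try:
            fit = fit_relaxation(sw, sweeps.protocol, phase, skip_fraction)
        except ValueError as err:
            rejects.append({"v_mv": sw.voltage_mv, "reason": str(err)})
            continue
        if fit.converged:
            rows.append({"v_mv": sw.voltage_mv, "tau_ms": fit.tau_ms,
                         "se_tau_ms": fit.se_tau_ms})
        else:
            reason = "no relaxation" if fit.no_relaxation else "fit did not converge"
            rejects.append({"v_mv": sw.voltage_mv, "reason": reason})
    if not rows:
        raise ValueError(f"no sweep produced a converged {phase} fit")
    table = pd.DataFrame(rows).sort_values("v_mv").reset_index(drop=True)
    rej = pd.DataFrame(rejects, columns=["v_mv", "reason"])
    return TauVoltageCurve(table=table, rejects=rej, phase=phase)
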