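"""Charybdotoxin block kinetics: onset/washout fits, K_D, percent inhibition.

Peak-current time courses around a timed toxin application are fitted to a
first-order bimolecular reaction scheme, in two time regimes relative to the
application time t0 and the washout time t1:

* onset (t0 < t < t1):   I(t) = (I0 - Iss) * exp(-t/tau_on) + Iss,
  with I0 fixed to the mean control current before application;
* recovery (t > t1):     I(t) = Ir - (Ir - Iss) * exp(-(t - t1)/tau_off),
  with Iss carried over from the onset fit and Ir (the recovered current)
  free.

The equilibrium dissociation constant follows from the two time constants:

    K_D = [Tx] / (tau_off/tau_on - 1)

which is undefined when tau_off <= tau_on — block too weak to resolve — and
is then reported as a status, never a number. Percent inhibition is
100 * (1 - Iss/I0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .synthetic import BlockTimecourse

__all__ = [
    "BlockFit",
    "fit_on_phase",
    "fit_off_phase",
    "fit_block",
    "dissociation_constant",
    "percent_inhibition",
    "suggest_application_window",
]

# fitted block/recovery amplitude below this multiple of the pre-application
# noise SD is treated as "no signal"
_AMP_SNR_MIN = 3.0

#: noise allowance on reported inhibition percentages outside [0, 100]
INHIBITION_EPS_PCT = 5.0


@dataclass
class BlockFit:
    """Block time-course fit results.

    ``kd_status`` is ``"ok"`` (kd_nm set), ``"undefined_weak_block"``
    (tau_off <= tau_on, mirroring blank K_D table cells for weak blockers)
    or ``"not_fit"``.
    """

    tau_on_s: float = float("nan")
    tau_off_s: float = float("nan")
    i0_pa: float = float("nan")
    iss_pa: float = float("nan")
    ir_pa: float = float("nan")
    kd_nm: Optional[float] = None
    inhibition_pct: float = float("nan")
    inhibition_clipped: bool = False
    converged_on: bool = False
    converged_off: bool = False
    kd_status: str = "not_fit"
    se_tau_on_s: float = float("nan")
    se_tau_off_s: float = float("nan")


def _exp_relax_fit(t: np.ndarray, y: np.ndarray, y_inf_free: bool,
                   y0_fixed: float, tau0: float, y_inf0: float):
    """Least squares for y(t) = y_inf + (y0 - y_inf) * exp(-t/tau).

    y0 is fixed; returns (tau, y_inf, rss, se_tau, success). Parameterized in
    log(tau) to keep the time constant positive.
    """
    def resid(p):
        tau = math.exp(p[0])
        y_inf = p[1] if y_inf_free else y_inf0
        return y_inf + (y0_fixed - y_inf) * np.exp(-t / tau) - y

    p0 = [math.log(tau0)] + ([y_inf0] if y_inf_free else [])
    sol = least_squares(resid, np.array(p0), method="lm", xtol=1e-14,
                        ftol=1e-14, max_nfev=10000)
    tau = math.exp(sol.x[0])
    y_inf = float(sol.x[1]) if y_inf_free else y_inf0
    rss = float(2.0 * sol.cost)
    npar = len(p0)
    se_tau = float("nan")
    if len(t) > npar:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / (len(t) - npar)
            se_tau = tau * math.sqrt(max(cov[0, 0], 0.0))
        except np.linalg.LinAlgError:
            pass
    return tau, y_inf, rss, se_tau, bool(sol.success)


def fit_on_phase(tc: BlockTimecourse) -> BlockFit:
    """Fit the block-onset regime; returns a partial BlockFit.

    I0 is the mean control current before application (not a fit parameter);
    time is re-zeroed so t = 0 at application. Needs >= 5 samples in
    [t_apply, t_washout) and >= 1 pre-application sample. If the block
    amplitude does not rise above the pre-application noise the fit is
    flagged (``converged_on`` False, ``kd_status`` "not_fit").
    """
    pre = tc.t_s < tc.t_apply_s
    on = (tc.t_s >= tc.t_apply_s) & (tc.t_s < tc.t_washout_s)
    if int(np.sum(pre)) < 1:
        raise ValueError("no pre-application samples to estimate I0")
    if int(np.sum(on)) < 5:
        raise ValueError("need >= 5 samples in the application window")

    i0 = float(np.mean(tc.i_peak_pa[pre]))
    noise_sd = float(np.std(tc.i_peak_pa[pre], ddof=1)) if int(np.sum(pre)) > 1 else 0.0

    t = tc.t_s[on] - tc.t_apply_s
    y = tc.i_peak_pa[on]
    if tc.toxin_nm == 0 or float(np.ptp(y)) == 0.0 and abs(float(np.mean(y)) - i0) < 1e-12:
        return BlockFit(i0_pa=i0, converged_on=False, kd_status="not_fit")

    span = float(t[-1] - t[0]) if len(t) > 1 else 1.0
    iss0 = float(y[-1])
    tau0 = max(span / 5.0, float(t[1] - t[0]) if len(t) > 1 else 1.0)
    tau_on, iss, rss, se_tau, success = _exp_relax_fit(
        t, y, y_inf_free=True, y0_fixed=i0, tau0=tau0, y_inf0=iss0
    )
    amp = abs(i0 - iss)
    resid_sd = math.sqrt(rss / max(len(t) - 2, 1))
    if amp < _AMP_SNR_MIN * max(noise_sd, resid_sd, 1e-12):
        return BlockFit(i0_pa=i0, iss_pa=iss, converged_on=False,
                        kd_status="not_fit")

    inhib = percent_inhibition(i0, iss)
    return BlockFit(
        tau_on_s=tau_on, i0_pa=i0, iss_pa=iss,
        inhibition_pct=inhib.pct, inhibition_clipped=inhib.clipped,
        converged_on=success, kd_status="not_fit", se_tau_on_s=se_tau,
    )


def fit_off_phase(tc: BlockTimecourse, on_fit: BlockFit) -> BlockFit:
    """Fit the washout-recovery regime, completing an on-phase BlockFit.

    Iss is carried from the on-phase fit (fixed); the recovered current Ir is
    free. Needs >= 5 samples at t >= t_washout. Derives K_D and its status
    from the two time constants when both phases converged.
    """
    off = tc.t_s >= tc.t_washout_s
    if int(np.sum(off)) < 5:
        raise ValueError("need >= 5 samples after washout")
    if not math.isfinite(on_fit.iss_pa):
        raise ValueError("on-phase fit with a finite Iss is required first")

    t = tc.t_s[off] - tc.t_washout_s
    y = tc.i_peak_pa[off]
    iss = on_fit.iss_pa

    span = float(t[-1] - t[0]) if len(t) > 1 else 1.0
    tau0 = max(span / 5.0, float(t[1] - t[0]) if len(t) > 1 else 1.0)

    def resid(p):
        tau = math.exp(p[0])
        ir = p[1]
        return ir - (ir - iss) * np.exp(-t / tau) - y

    sol = least_squares(resid, np.array([math.log(tau0), float(y[-1])]),
                        method="lm", xtol=1e-14, ftol=1e-14, max_nfev=10000)
    tau_off = math.exp(sol.x[0])
    ir = float(sol.x[1])
    rss = float(2.0 * sol.cost)
    resid_sd = math.sqrt(rss / max(len(t) - 2, 1))
    se_tau = float("nan")
    if len(t) > 2:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / (len(t) - 2)
            se_tau = tau_off * math.sqrt(max(cov[0, 0], 0.0))
        except np.linalg.LinAlgError:
            pass

    converged_off = bool(sol.success) and abs(ir - iss) >= _AMP_SNR_MIN * max(resid_sd, 1e-12)
    out = replace(on_fit, tau_off_s=tau_off, ir_pa=ir,
                  converged_off=converged_off, se_tau_off_s=se_tau)
    if out.converged_on and out.converged_off:
        kd, status = dissociation_constant(out.tau_on_s, out.tau_off_s, tc.toxin_nm)
        out = replace(out, kd_nm=kd, kd_status=status)
    return out


def fit_block(tc: BlockTimecourse) -> BlockFit:
    """Convenience: onset fit, then washout fit, then K_D and inhibition."""
    on = fit_on_phase(tc)
    if not on.converged_on:
        return on
    return fit_off_phase(tc, on)


def dissociation_constant(tau_on_s: float, tau_off_s: float,
                          toxin_nm: float) -> tuple[Optional[float], str]:
    """K_D = [Tx] / (tau_off/tau_on - 1), in nM.

    Returns ``(kd_nm, "ok")`` when tau_off > tau_on, else
    ``(None, "undefined_weak_block")`` — the first-order scheme cannot assign
    an affinity when recovery is no slower than onset.
    """
    if not (tau_on_s > 0 and tau_off_s > 0):
        raise ValueError("time constants must be positive")
    if not toxin_nm > 0:
        raise ValueError("toxin concentration must be positive")
    if tau_off_s <= tau_on_s:
        return None, "undefined_weak_block"
    return toxin_nm / (tau_off_s / tau_on_s - 1.0), "ok"


@dataclass
class Inhibition:
    pct: float
    clipped: bool  # True when the raw value fell outside [0, 100]


def percent_inhibition(i0_pa: float, iss_pa: float) -> Inhibition:
    """Fractional current inhibition 100 * (1 - Iss/I0), in percent.

    Values outside [0, 100] (possible under noise) are reported as-is with
    ``clipped`` set, so downstream tables can flag them.
    """
    if i0_pa == 0:
        raise ValueError("I0 = 0: inhibition undefined")
    pct = 100.0 * (1.0 - iss_pa / i0_pa)
    return Inhibition(pct=pct, clipped=not (0.0 <= pct <= 100.0))


def suggest_application_window(tc_t_s: np.ndarray, i_peak_pa: np.ndarray
                               ) -> tuple[float, float]:
    """Change-point helper: guess (t_apply, t_washout) from the trace.

    Scans all split pairs for the two-change-point piecewise-mean model with
    the lowest squared error. Offered as a diagnostic only — application and
    washout times are experiment metadata and are never inferred silently.
    """
    t = np.asarray(tc_t_s, dtype=float)
    y = np.asarray(i_peak_pa, dtype=float)
    n = len(t)
    if n < 6:
        raise ValueError("too few samples for change-point detection")
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(a: int, b: int) -> float:  # segment [a, b)
        m = b - a
        s = csum[b] - csum[a]
        s2 = csum2[b] - csum2[a]
        return s2 - s * s / m

    best = (math.inf, 1, 2)
    for i in range(2, n - 3):
        for j in range(i + 2, n - 1):
            total = sse(0, i) + sse(i, j) + sse(j, n)
            if total < best[0]:
                best = (total, i, j)
    _, i, j = best
    return float(t[i]), float(t[j])
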