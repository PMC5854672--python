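"""Conductance-voltage curves and Boltzmann activation fits.

Steady-state currents from a voltage-step family are converted to chord
conductance ``G(V) = I_ss / (V - E_rev)`` and fitted with the Boltzmann
function

    G / G_max = 1 / (1 + exp((V - V_half) / kappa))

where ``V_half`` is the half-activation voltage and ``kappa`` the steepness
factor. Under this sign convention an activating curve has ``kappa < 0``;
the conventional positive slope factor is ``k = -kappa`` and is exposed as
``BoltzmannFit.slope_k``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .synthetic import SweepSet, boltzmann_popen

__all__ = [
    "GVCurve",
    "BoltzmannFit",
    "VHalfShift",
    "steady_state_conductance",
    "fit_boltzmann",
    "v_half_shift",
]

#: allowance above 1.0 for normalized conductance under noise
GNORM_NOISE_EPS = 0.05


@dataclass
class GVCurve:
    """Conductance-voltage points from one patch (or averaged patches)."""

    v: np.ndarray          # mV, strictly increasing
    g: np.ndarray          # nS
    g_norm: np.ndarray     # g / max(g)
    n_sweeps: int = 1
    se: Optional[np.ndarray] = None  # per-point SE of g, same units

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.g_norm = np.asarray(self.g_norm, dtype=float)
        if not (self.v.shape == self.g.shape == self.g_norm.shape):
            raise ValueError("v, g, g_norm must have equal length")
        if np.any(np.diff(self.v) <= 0):
            raise ValueError("v must be strictly increasing")
        if np.any(self.g_norm < -GNORM_NOISE_EPS) or np.any(
            self.g_norm > 1.0 + GNORM_NOISE_EPS
        ):
            warnings.warn(
                "g_norm outside [0, 1] beyond the noise allowance "
                f"({GNORM_NOISE_EPS}); check E_rev and the steady-state window",
                stacklevel=2,
            )


@dataclass
class BoltzmannFit:
    """Least-squares Boltzmann parameters with convergence diagnostics."""

    v_half: float
    kappa: float
    g_max: float
    se_v_half: float
    se_kappa: float
    rss: float
    n_iter: int
    converged: bool

    @property
    def slope_k(self) -> float:
        """Conventional positive steepness for activating curves (= -kappa)."""
        return -self.kappa

    def predict(self, v_mv) -> np.ndarray:
        return self.g_max * boltzmann_popen(v_mv, self.v_half, self.kappa)


@dataclass
class VHalfShift:
    """Shift of V_half relative to a reference construct.

    ``delta_mv < 0`` is a leftward (activating) shift. ``fractional`` is
    ``delta_mv / |ref_v_half|`` and is None when the reference V_half is 0.
    """

    delta_mv: float
    fractional: Optional[float]
    v_half_mv: float
    ref_v_half_mv: float


def steady_state_conductance(sweeps: SweepSet, e_rev: float = 0.0,
                             tail_fraction: float = 0.1) -> GVCurve:
    """Convert step-phase steady-state currents to a normalized G-V curve.

    The steady-state current at each step voltage is the mean over the last
    ``tail_fraction`` of the step phase; chord conductance divides by the
    driving force ``V - e_rev``. Points at ``V == e_rev`` carry no conductance
    information and are dropped with a warning.
    """
    if not (0.0 < tail_fraction <= 0.5):
        raise ValueError("tail_fraction must be in (0, 0.5]")
    proto = sweeps.protocol
    t0, t1 = proto.phase_window_ms("activation")
    w_start = t1 - tail_fraction * (t1 - t0)

    v_list, g_list = [], []
    for sw in sweeps.sweeps:
        if np.any(np.diff(sw.t_ms) <= 0):
            raise ValueError("non-monotone time grid")
        if sw.voltage_mv == e_rev:
            warnings.warn(
                f"dropping sweep at {sw.voltage_mv} mV: zero driving force "
                "(V == E_rev)", stacklevel=2,
            )
            continue
        sel = (sw.t_ms >= w_start) & (sw.t_ms < t1)
        if not np.any(sel):
            raise ValueError("steady-state window contains no samples")
        i_ss = float(np.mean(sw.i_pa[sel]))
        v_list.append(sw.voltage_mv)
        g_list.append(i_ss / (sw.voltage_mv - e_rev))
    if not v_list:
        raise ValueError("all G-V points dropped (every step voltage == e_rev)")

    v = np.array(v_list)
    g = np.array(g_list)
    g_max = float(np.max(g))
    if g_max <= 0:
        raise ValueError("maximal conductance is non-positive; cannot normalize")
    return GVCurve(v=v, g=g, g_norm=g / g_max, n_sweeps=1)


def _boltzmann_init(v: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """Initial (v_half, kappa, g_max) from the half-max crossing and the
    25-75% rise span (span = 2*kappa*ln 3 under the fitted form)."""
    g_max0 = float(np.max(g))
    gn = g / g_max0

    def crossing(level: float) -> float:
        # first crossing of `level`, linearly interpolated; data may be noisy
        above = gn >= level
        if above.all():
            return float(v[0])
        if not above.any():
            return float(v[-1])
        idx = int(np.argmax(above)) if not above[0] else int(np.argmax(~above))
        i0 = max(idx - 1, 0)
        x0, x1 = v[i0], v[min(i0 + 1, len(v) - 1)]
        y0, y1 = gn[i0], gn[min(i0 + 1, len(v) - 1)]
        if y1 == y0:
            return float(x0)
        return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))

    v50 = crossing(0.5)
    v25, v75 = crossing(0.25), crossing(0.75)
    kappa0 = (v25 - v75) / (2.0 * math.log(3.0))
    if kappa0 == 0 or not math.isfinite(kappa0):
        kappa0 = -(v[-1] - v[0]) / 8.0 if gn[-1] >= gn[0] else (v[-1] - v[0]) / 8.0
    return v50, kappa0, g_max0


def fit_boltzmann(gv: GVCurve, fix_gmax: bool = False,
                  n_restarts: int = 5) -> BoltzmannFit:
    """Fit ``G(V) = G_max / (1 + exp((V - V_half)/kappa))`` by least squares.

    Requires at least four distinct voltages with data on both sides of the
    half-maximal conductance. ``G_max`` is a free parameter by default; with
    ``fix_gmax=True`` it is pinned to ``max(g)``. On non-convergence the
    initial guess is jittered ``n_restarts`` times and the best solution is
    returned with ``converged`` reflecting the optimizer's status — a flagged
    fit, never silent garbage.

    Per-point standard errors weight the residuals only when the curve
    aggregates multiple sweeps (``n_sweeps > 1``).
    """
    v = gv.v
    if len(np.unique(v)) < 4:
        raise ValueError("need >= 4 distinct voltages to fit a Boltzmann")
    if float(np.ptp(gv.g)) == 0.0:
        raise ValueError("degenerate flat G-V data: no voltage dependence to fit")
    # fit in units of max(g): makes the solution exactly scale-invariant
    scale = float(np.max(np.abs(gv.g)))
    g = gv.g / scale
    if not (np.min(g) < 0.5 * np.max(g)):
        raise ValueError("data do not span both sides of the half-max")

    w = None
    if gv.se is not None and gv.n_sweeps > 1:
        se = np.asarray(gv.se, dtype=float) / scale
        w = np.where(se > 0, 1.0 / se, 1.0 / np.max(se[se > 0]))

    v50, kappa0, gmax0 = _boltzmann_init(v, g)

    # analytic Jacobian: with E = exp((V - vh)/kappa) and P = 1/(1 + E),
    # d(gmax*P)/dvh = gmax*E*P^2/kappa, d/dkappa = gmax*E*P^2*(V - vh)/kappa^2
    def _parts(vh, kappa):
        e = np.exp((v - vh) / kappa)
        p_open = 1.0 / (1.0 + e)
        return e, p_open

    if fix_gmax:
        def resid(p):
            r = gmax0 * boltzmann_popen(v, p[0], p[1]) - g
            return r * w if w is not None else r

        def jac(p):
            vh, kappa = p
            e, po = _parts(vh, kappa)
            core = gmax0 * e * po * po
            cols = np.column_stack([core / kappa, core * (v - vh) / kappa ** 2])
            return cols * w[:, None] if w is not None else cols
        p0 = np.array([v50, kappa0])
    else:
        def resid(p):
            r = p[2] * boltzmann_popen(v, p[0], p[1]) - g
            return r * w if w is not None else r

        def jac(p):
            vh, kappa, gmax = p
            e, po = _parts(vh, kappa)
            core = gmax * e * po * po
            cols = np.column_stack([core / kappa,
                                    core * (v - vh) / kappa ** 2, po])
            return cols * w[:, None] if w is not None else cols
        p0 = np.array([v50, kappa0, gmax0])

    rng = np.random.default_rng(0)
    best = None
    n_iter_total = 0
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            start = p0.copy()
        else:
            start = p0 * rng.normal(1.0, 0.2, size=p0.shape) + rng.normal(
                0.0, 5.0, size=p0.shape
            )
        if start[1] == 0:
            start[1] = kappa0 if kappa0 != 0 else -1.0
        try:
            sol = least_squares(resid, start, jac=jac, method="lm",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                max_nfev=10000)
        except Exception:
            continue
        n_iter_total += int(sol.nfev)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success:
            break
    if best is None:
        raise RuntimeError("Boltzmann optimizer failed to evaluate")

    p = best.x
    rss = float(2.0 * best.cost)  # in scaled units until the final rescale
    n, npar = len(v), len(p)
    # covariance from the Jacobian at the solution
    se_v_half = se_kappa = float("nan")
    if n > npar:
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.inv(jtj) * rss / (n - npar)
            se_v_half = float(math.sqrt(max(cov[0, 0], 0.0)))
            se_kappa = float(math.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            pass
    # optimizer success == its ftol/xtol/gtol criteria met at the solution
    converged = bool(best.success)
    return BoltzmannFit(
        v_half=float(p[0]), kappa=float(p[1]),
        g_max=(gmax0 if fix_gmax else float(p[2])) * scale,
        se_v_half=se_v_half, se_kappa=se_kappa,
        rss=rss * scale * scale, n_iter=n_iter_total, converged=converged,
    )


def v_half_shift(fit: BoltzmannFit, ref: BoltzmannFit) -> VHalfShift:
    """Absolute and fractional shift of V_half against a reference fit.

    Negative shifts are leftward (activating). The fractional shift
    normalizes by ``|ref.v_half|`` and is undefined (None) when the
    reference V_half is zero.
    """
    if not (fit.converged and ref.converged):
        raise ValueError("both fits must have converged")
    delta = fit.v_half - ref.v_half
    frac = delta / abs(ref.v_half) if ref.v_half != 0 else None
    return VHalfShift(delta_mv=delta, fractional=frac,
                      v_half_mv=fit.v_half, ref_v_half_mv=ref.v_half)
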