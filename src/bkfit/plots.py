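"""Convenience plots: G-V curve, tau-V relationship, block time course."""

from __future__ import annotations

from typing import Optional

import matplotlib
import numpy as np

matplotlib.use("Agg")  # headless backend; these are file-output plots
import matplotlib.pyplot as plt

from .block import BlockFit
from .gv import BoltzmannFit, GVCurve
from .kinetics import TauVoltageCurve
from .synthetic import BlockTimecourse

__all__ = ["plot_gv", "plot_tau_v", "plot_block"]


def plot_gv(gv: GVCurve, fit: Optional[BoltzmannFit] = None, ax=None):
    """Normalized G-V points with the fitted Boltzmann curve."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(gv.v, gv.g_norm, "o", label="data")
    if fit is not None:
        vv = np.linspace(gv.v[0], gv.v[-1], 200)
        ax.plot(vv, fit.predict(vv) / fit.g_max, "-",
                label=f"V1/2 = {fit.v_half:.2f} mV")
        ax.legend()
    ax.set_xlabel("V (mV)")
    ax.set_ylabel("G / Gmax")
    return ax


def plot_tau_v(curve: TauVoltageCurve, ax=None):
    """Tau-V relationship with SE bars where available."""
    if ax is None:
        _, ax = plt.subplots()
    tbl = curve.table
    yerr = tbl["se_tau_ms"].to_numpy()
    yerr = np.where(np.isfinite(yerr), yerr, 0.0)
    ax.errorbar(tbl["v_mv"], tbl["tau_ms"], yerr=yerr, fmt="o-")
    ax.set_xlabel("V (mV)")
    ax.set_ylabel(f"tau {curve.phase} (ms)")
    return ax


def plot_block(tc: BlockTimecourse, fit: Optional[BlockFit] = None, ax=None):
    """Peak currents vs time with the application window and fitted phases."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(tc.t_s, tc.i_peak_pa, "o", ms=3, label="peak current")
    ax.axvspan(tc.t_apply_s, tc.t_washout_s, alpha=0.15, label="toxin")
    if fit is not None and fit.converged_on:
        on = (tc.t_s >= tc.t_apply_s) & (tc.t_s < tc.t_washout_s)
        t = tc.t_s[on]
        ax.plot(t, fit.iss_pa + (fit.i0_pa - fit.iss_pa)
                * np.exp(-(t - tc.t_apply_s) / fit.tau_on_s), "-")
        if fit.converged_off:
            off = tc.t_s >= tc.t_washout_s
            t = tc.t_s[off]
            ax.plot(t, fit.ir_pa - (fit.ir_pa - fit.iss_pa)
                    * np.exp(-(t - tc.t_washout_s) / fit.tau_off_s), "-")
    ax.set_xlabel("t (s)")
    ax.set_ylabel("I peak (pA)")
    ax.legend()
    return ax
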