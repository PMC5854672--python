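"""Group summaries, significance annotation, and result tables.

Replicate estimates (per-patch V_half values, time constants, inhibition
percentages) are summarized as mean with SD/SE, compared with a two-tailed
unpaired Student's t-test (pooled variance; Welch available behind a flag),
and assembled into the standard result tables: a V_half table per construct,
a kinetics/K_D table with blank K_D cells for constructs whose block is too
weak to resolve, and a cycle-verdict table.

Display rounding is centralized here (2 decimals for voltages, 1 for time
constants and K_D); JSON outputs keep full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .block import BlockFit
from .cycle import CyclePanel
from .gv import BoltzmannFit

__all__ = [
    "GroupSummary",
    "summarize",
    "t_test_unpaired_two_tailed",
    "TTestResult",
    "significance_stars",
    "render_tables",
    "fmt_voltage",
    "fmt_tau",
    "fmt_kd",
]


def fmt_voltage(x: float) -> str:
    """Voltages print with 2 decimals."""
    return f"{x:.2f}"


def fmt_tau(x: float) -> str:
    """Time constants print with 1 decimal."""
    return f"{x:.1f}"


def fmt_kd(x: float) -> str:
    """K_D prints with 1 decimal (nM)."""
    return f"{x:.1f}"


@dataclass
class GroupSummary:
    """Sample statistics for one labeled group of replicate estimates."""

    label: str
    n: int
    mean: float
    sd: float
    se: Optional[float]       # sd / sqrt(n); None for n = 1
    dispersion_kind: str = "se"   # which dispersion the table prints


def summarize(values: Sequence[float], label: str,
              dispersion_kind: str = "se") -> GroupSummary:
    """Exact sample mean/SD/SE of replicate estimates; SE omitted at n = 1."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty group")
    if dispersion_kind not in ("sd", "se"):
        raise ValueError("dispersion_kind must be 'sd' or 'se'")
    n = int(vals.size)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    se = sd / math.sqrt(n) if n > 1 else None
    return GroupSummary(label=label, n=n, mean=mean, sd=sd, se=se,
                        dispersion_kind=dispersion_kind)


def significance_stars(p: float) -> str:
    """Conventional star annotation: *** < 0.001, ** < 0.01, * < 0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    stars: str


def t_test_unpaired_two_tailed(a: Sequence[float], b: Sequence[float],
                               welch: bool = False) -> TTestResult:
    """Two-tailed unpaired Student's t-test (pooled variance).

    ``welch=True`` switches to the unequal-variance form. When both groups
    have zero variance and equal means the statistic is 0/0; by convention
    this reports t = 0, p = 1 (no evidence of a difference).
    """
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    na, nb = xa.size, xb.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 replicates")
    va = float(np.var(xa, ddof=1))
    vb = float(np.var(xb, ddof=1))
    diff = float(np.mean(xa) - np.mean(xb))

    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            df = float(na + nb - 2)
            return TTestResult(t=0.0, df=df, p=1.0, stars="ns")
        t = math.copysign(math.inf, diff)
        return TTestResult(t=t, df=float(na + nb - 2), p=0.0, stars="***")

    if welch:
        sem2 = va / na + vb / nb
        t = diff / math.sqrt(sem2)
        df = sem2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p, stars=significance_stars(p))


def _gv_table(fits: Mapping[str, BoltzmannFit]) -> pd.DataFrame:
    rows = []
    for label in fits:
        f = fits[label]
        rows.append({
            "label": label,
            "v_half_mv": fmt_voltage(f.v_half),
            "se_v_half_mv": fmt_voltage(f.se_v_half) if math.isfinite(f.se_v_half) else "",
            "kappa_mv": fmt_voltage(f.kappa),
            "slope_k_mv": fmt_voltage(f.slope_k),
            "g_max_ns": f"{f.g_max:.3f}",
            "converged": f.converged,
        })
    return pd.DataFrame(rows)


def _block_table(blockfits: Mapping[str, BlockFit]) -> pd.DataFrame:
    rows = []
    for label in blockfits:
        f = blockfits[label]
        kd = fmt_kd(f.kd_nm) if f.kd_status == "ok" and f.kd_nm is not None else ""
        rows.append({
            "label": label,
            "tau_on_s": fmt_tau(f.tau_on_s) if math.isfinite(f.tau_on_s) else "",
            "tau_off_s": fmt_tau(f.tau_off_s) if math.isfinite(f.tau_off_s) else "",
            "kd_nm": kd,
            "kd_status": f.kd_status,
            "inhibition_pct": fmt_tau(f.inhibition_pct)
            if math.isfinite(f.inhibition_pct) else "",
        })
    return pd.DataFrame(rows)


def _cycle_table(cycles: Mapping[str, CyclePanel]) -> pd.DataFrame:
    rows = []
    for name in cycles:
        c = cycles[name]
        rows.append({
            "cycle": name,
            "v_wt_mv": fmt_voltage(c.v_wt),
            "v_alpha_mut_mv": fmt_voltage(c.v_alpha_mut),
            "v_beta_mut_mv": fmt_voltage(c.v_beta_mut),
            "v_double_mv": fmt_voltage(c.v_double),
            "ddv_mv": fmt_voltage(c.ddv_mv),
            "ddg_kcal_mol": f"{c.ddg_kcal:.3f}",
            "coupled": c.coupled,
        })
    return pd.DataFrame(rows)


def render_tables(fits: Optional[Mapping[str, BoltzmannFit]] = None,
                  blockfits: Optional[Mapping[str, BlockFit]] = None,
                  cycles: Optional[Mapping[str, CyclePanel]] = None,
                  outdir: Optional[str | Path] = None) -> dict[str, pd.DataFrame]:
    """Assemble the report bundle; optionally write TSV + JSON files.

    At least one result mapping is required. Output is deterministic given
    the inputs: mappings are rendered in insertion order and all formatting
    goes through the centralized format helpers.
    """
    if not (fits or blockfits or cycles):
        raise ValueError("at least one result object is required")
    bundle: dict[str, pd.DataFrame] = {}
    if fits:
        bundle["gv"] = _gv_table(fits)
    if blockfits:
        bundle["block"] = _block_table(blockfits)
    if cycles:
        bundle["cycle"] = _cycle_table(cycles)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
            (outdir / f"{name}.json").write_text(
                json.dumps(df.to_dict(orient="records"), indent=2) + "\n"
            )
    return bundle
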