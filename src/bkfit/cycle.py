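"""Thermodynamic double-mutant cycle analysis on half-activation voltages.

A cycle consists of the wild-type channel complex (alpha-beta), the two
single mutants and the double mutant. Because the gating free energy is
taken to be proportional to V_half, the coupling free energy between the two
mutated residues can be measured on the voltage axis:

    ddV = V_half(beta_mut) + V_half(alpha_mut) - V_half(double) - V_half(wt)

Any common reference voltage cancels in this combination, so raw V_half
values are used directly. The conversion to energy uses the fixed
equivalence 20 mV = 1 kcal/mol, and |ddV| >= 20 mV (1 kcal/mol, inclusive)
is the coupling criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

from .gv import BoltzmannFit

__all__ = [
    "CyclePanel",
    "coupling_voltage",
    "coupling_energy",
    "is_coupled",
    "analyze_cycle",
    "cycle_from_fits",
    "MV_PER_KCAL",
    "COUPLING_THRESHOLD_MV",
]

#: voltage shift equivalent to 1 kcal/mol of gating free energy
MV_PER_KCAL = 20.0
#: default coupling criterion (inclusive)
COUPLING_THRESHOLD_MV = 20.0


@dataclass
class CyclePanel:
    """The four V_half corners of a double-mutant cycle plus derived coupling."""

    v_wt: float
    v_alpha_mut: float
    v_beta_mut: float
    v_double: float
    ddv_mv: float
    ddg_kcal: float
    threshold_mv: float
    coupled: bool
    se_ddv_mv: Optional[float] = None  # quadrature of the four V_half SEs


def coupling_voltage(v_wt: float, v_alpha_mut: float, v_beta_mut: float,
                     v_double: float) -> float:
    """Non-additivity of the four half-activation voltages (mV).

    Invariant to adding any constant to all four inputs: the implicit
    reference of each delta-V term cancels.
    """
    vals = (v_wt, v_alpha_mut, v_beta_mut, v_double)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("all four V_half values must be finite")
    return v_beta_mut + v_alpha_mut - v_double - v_wt


def coupling_energy(ddv_mv: float) -> float:
    """Convert a coupling voltage to kcal/mol via 20 mV = 1 kcal/mol."""
    if not math.isfinite(ddv_mv):
        raise ValueError("ddv_mv must be finite")
    return ddv_mv / MV_PER_KCAL


def is_coupled(ddv_mv: float, threshold_mv: float = COUPLING_THRESHOLD_MV) -> bool:
    """Coupling verdict: |ddV| >= threshold (inclusive)."""
    if not math.isfinite(ddv_mv):
        raise ValueError("ddv_mv must be finite")
    if not threshold_mv > 0:
        raise ValueError("threshold_mv must be positive")
    return abs(ddv_mv) >= threshold_mv


def analyze_cycle(v_wt: float, v_alpha_mut: float, v_beta_mut: float,
                  v_double: float, threshold_mv: float = COUPLING_THRESHOLD_MV,
                  se: Optional[tuple[float, float, float, float]] = None
                  ) -> CyclePanel:
    """Assemble a CyclePanel with derived coupling voltage, energy, verdict.

    ``se``, if given, holds the standard errors of the four V_half values in
    the same order as the positional arguments; the SE of ddV follows by
    quadrature (the four estimates are independent patches).
    """
    ddv = coupling_voltage(v_wt, v_alpha_mut, v_beta_mut, v_double)
    se_ddv = None
    if se is not None:
        if len(se) != 4:
            raise ValueError("se must hold four values")
        se_ddv = math.sqrt(sum(s * s for s in se))
    return CyclePanel(
        v_wt=v_wt, v_alpha_mut=v_alpha_mut, v_beta_mut=v_beta_mut,
        v_double=v_double, ddv_mv=ddv, ddg_kcal=coupling_energy(ddv),
        threshold_mv=threshold_mv, coupled=is_coupled(ddv, threshold_mv),
        se_ddv_mv=se_ddv,
    )


def cycle_from_fits(fits: Mapping[str, BoltzmannFit],
                    threshold_mv: float = COUPLING_THRESHOLD_MV) -> CyclePanel:
    """Build a cycle from four labeled Boltzmann fits.

    ``fits`` must carry the labels ``wt``, ``alpha_mut``, ``beta_mut`` and
    ``double``; fit standard errors propagate to the ddV SE when all four
    are finite.
    """
    want = ("wt", "alpha_mut", "beta_mut", "double")
    if set(fits) != set(want):
        raise ValueError(f"cycle needs fits labeled {want}, got {sorted(fits)}")
    v = {k: fits[k].v_half for k in want}
    ses = tuple(fits[k].se_v_half for k in want)
    se = ses if all(math.isfinite(s) for s in ses) else None
    return analyze_cycle(v["wt"], v["alpha_mut"], v["beta_mut"], v["double"],
                         threshold_mv=threshold_mv, se=se)
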