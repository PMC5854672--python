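"""Plain-text interchange formats for sweep sets and block time courses.

A sweep set is written as one TSV (column ``time_ms`` followed by one
current column per step voltage, headers = the voltages in mV) plus a JSON
sidecar carrying the protocol, any ground-truth model parameters and the
seed. A block time course is a two-column TSV (``t_s``, ``i_peak_pA``) plus
a sidecar with the toxin concentration and the application window.

The sidecar lives next to the TSV with the suffix ``.json`` replacing
``.tsv``; both readers accept either path.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import BlockTimecourse, StepProtocol, Sweep, SweepSet

__all__ = [
    "write_sweepset",
    "read_sweepset",
    "write_block_timecourse",
    "read_block_timecourse",
]


def _paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".json":
        return p.with_suffix(".tsv"), p
    if p.suffix == ".tsv":
        return p, p.with_suffix(".json")
    return p.with_suffix(".tsv"), p.with_suffix(".json")


def write_sweepset(sweeps: SweepSet, path: str | Path) -> tuple[Path, Path]:
    """Write a sweep set as TSV + JSON sidecar; returns the two paths."""
    tsv, sidecar = _paths(path)
    data = {"time_ms": sweeps.sweeps[0].t_ms}
    for sw in sweeps.sweeps:
        data[f"{sw.voltage_mv:g}"] = sw.i_pa
    pd.DataFrame(data).to_csv(tsv, sep="\t", index=False)
    meta = {
        "format": "bkfit.sweepset.v1",
        "protocol": sweeps.protocol.to_dict(),
        "metadata": sweeps.metadata,
    }
    sidecar.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return tsv, sidecar


def read_sweepset(path: str | Path) -> SweepSet:
    """Read a sweep set written by :func:`write_sweepset`."""
    tsv, sidecar = _paths(path)
    meta = json.loads(sidecar.read_text())
    if meta.get("format") != "bkfit.sweepset.v1":
        raise ValueError(f"{sidecar} is not a bkfit sweep-set sidecar")
    protocol = StepProtocol(**meta["protocol"])
    df = pd.read_csv(tsv, sep="\t", float_precision="round_trip")
    if df.columns[0] != "time_ms":
        raise ValueError(f"{tsv}: first column must be time_ms")
    t = df["time_ms"].to_numpy(dtype=float)
    sweeps = [
        Sweep(voltage_mv=float(col), t_ms=t.copy(),
              i_pa=df[col].to_numpy(dtype=float))
        for col in df.columns[1:]
    ]
    return SweepSet(sweeps=sweeps, protocol=protocol,
                    metadata=meta.get("metadata", {}))


def write_block_timecourse(tc: BlockTimecourse, path: str | Path) -> tuple[Path, Path]:
    """Write a block time course as TSV + JSON sidecar; returns the paths."""
    tsv, sidecar = _paths(path)
    pd.DataFrame({"t_s": tc.t_s, "i_peak_pA": tc.i_peak_pa}).to_csv(
        tsv, sep="\t", index=False
    )
    meta = {
        "format": "bkfit.blocktimecourse.v1",
        "toxin_nM": tc.toxin_nm,
        "t_apply_s": tc.t_apply_s,
        "t_washout_s": tc.t_washout_s,
        "metadata": tc.metadata,
    }
    sidecar.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return tsv, sidecar


def read_block_timecourse(path: str | Path) -> BlockTimecourse:
    """Read a block time course written by :func:`write_block_timecourse`."""
    tsv, sidecar = _paths(path)
    meta = json.loads(sidecar.read_text())
    if meta.get("format") != "bkfit.blocktimecourse.v1":
        raise ValueError(f"{sidecar} is not a bkfit block-time-course sidecar")
    df = pd.read_csv(tsv, sep="\t", float_precision="round_trip")
    return BlockTimecourse(
        t_s=df["t_s"].to_numpy(dtype=float),
        i_peak_pa=df["i_peak_pA"].to_numpy(dtype=float),
        toxin_nm=float(meta["toxin_nM"]),
        t_apply_s=float(meta["t_apply_s"]),
        t_washout_s=float(meta["t_washout_s"]),
        metadata=meta.get("metadata", {}),
    )
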