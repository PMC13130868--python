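"""Persistence: raw-ensemble store (HDF5), columnar summaries, extended-XYZ
snapshots, mother checkpoints and run manifests.

The raw store keeps one matrix per experiment (rows = daughters, columns =
steps) with the metadata needed to re-run the analysis without re-simulating;
series produced by external engines can be ingested by writing the same
layout.  Summaries are plain columnar text with '#' header comments, so they
are engine- and tool-agnostic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import h5py
import numpy as np
import pandas as pd

from .model import BoxSpec, PhasePoint
from .ttcf import StressSeriesEnsemble, TTCFEstimate

__all__ = [
    "save_ensemble", "load_ensemble",
    "summary_table", "write_summary", "read_summary",
    "write_daughter_series", "read_daughter_series",
    "write_xyz", "read_xyz",
    "save_checkpoint", "load_checkpoint",
    "write_manifest",
]

_REQUIRED_ATTRS = ("shear_rate", "volume", "kbt")


def save_ensemble(path, ens: StressSeriesEnsemble,
                  extra: Optional[Dict] = None) -> None:
    """Write the raw per-daughter stress store with its metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("pyx", data=ens.values)
        f.create_dataset("time_grid", data=ens.time_grid)
        if ens.mapped_groups is not None:
            f.create_dataset("mapped_groups", data=ens.mapped_groups)
        f.attrs["shear_rate"] = ens.shear_rate
        f.attrs["volume"] = ens.volume
        f.attrs["kbt"] = ens.kbt
        for k, v in (extra or {}).items():
            f.attrs[k] = v


def load_ensemble(path) -> StressSeriesEnsemble:
    """Read a raw store; refuses files with incomplete metadata."""
    with h5py.File(path, "r") as f:
        missing = [k for k in _REQUIRED_ATTRS if k not in f.attrs]
        if missing:
            raise ValueError(
                f"ensemble store {path} is missing metadata fields {missing}")
        groups = f["mapped_groups"][...] if "mapped_groups" in f else None
        return StressSeriesEnsemble(f["pyx"][...], f["time_grid"][...],
                                    float(f.attrs["shear_rate"]),
                                    float(f.attrs["volume"]),
                                    float(f.attrs["kbt"]),
                                    mapped_groups=groups)


def summary_table(ens: StressSeriesEnsemble,
                  estimates: Dict[str, TTCFEstimate]) -> pd.DataFrame:
    """Per-step summary: means, SEs, CIs and the -P_yx/gammadot columns."""
    n_steps = len(ens.time_grid)
    out = {"step": np.arange(n_steps), "time": ens.time_grid}
    g = ens.shear_rate
    for name, est in estimates.items():
        tag = name.lower()
        out[f"{tag}_mean"] = est.mean_response
        out[f"{tag}_se"] = (est.se if est.se is not None
                            else np.full(n_steps, np.nan))
        out[f"{tag}_ci_low"] = (est.ci95_low if est.ci95_low is not None
                                else np.full(n_steps, np.nan))
        out[f"{tag}_ci_high"] = (est.ci95_high if est.ci95_high is not None
                                 else np.full(n_steps, np.nan))
        if g != 0:
            out[f"{tag}_visc"] = -est.mean_response / g
    return pd.DataFrame(out)


def write_summary(path, df: pd.DataFrame,
                  header: Optional[Dict] = None) -> None:
    with open(path, "w") as f:
        for k, v in (header or {}).items():
            f.write(f"# {k}: {v}\n")
        df.to_csv(f, index=False)


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_daughter_series(path, series, kbt: float = 1.0) -> None:
    """Columnar per-daughter record: step, time, P_yx, T_kin, Omega."""
    from .observables import dissipation_function

    omega = np.array([
        dissipation_function(p, series.shear_rate, series.volume, 1.0, kbt)
        for p in series.pyx])
    df = pd.DataFrame({"step": np.arange(len(series.time)),
                       "time": series.time, "pyx": series.pyx,
                       "tkin": series.tkin, "omega": omega})
    write_summary(path, df, header={"shear_rate": series.shear_rate,
                                    "volume": series.volume, "kbt": kbt})


def read_daughter_series(path) -> pd.DataFrame:
    return read_summary(path)


# --------------------------------------------------------------------------
# extended XYZ

def write_xyz(path, state: PhasePoint, comment: str = "") -> None:
    """Extended-XYZ snapshot: positions + velocities + tilted lattice."""
    lx, ly, lz = state.box.edge_lengths
    t = state.box.tilt_xy
    lattice = f"{lx} 0.0 0.0 {t} {ly} 0.0 0.0 0.0 {lz}"
    vel = state.momenta / state.masses[:, None]
    with open(path, "w") as f:
        f.write(f"{state.n_particles}\n")
        f.write(f'Lattice="{lattice}" '
                f'Properties=species:S:1:pos:R:3:vel:R:3 '
                f'Time={state.time} {comment}\n'.rstrip() + "\n")
        for p, v in zip(state.positions, vel):
            f.write(f"X {p[0]:.17g} {p[1]:.17g} {p[2]:.17g} "
                    f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")


def read_xyz(path) -> PhasePoint:
    with open(path) as f:
        n = int(f.readline())
        header = f.readline()
        lat = header.split('Lattice="')[1].split('"')[0].split()
        cell = np.array([float(x) for x in lat]).reshape(3, 3)
        time = 0.0
        for tok in header.split():
            if tok.startswith("Time="):
                time = float(tok[5:])
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        for i in range(n):
            parts = f.readline().split()
            pos[i] = [float(x) for x in parts[1:4]]
            vel[i] = [float(x) for x in parts[4:7]]
    box = BoxSpec(np.array([cell[0, 0], cell[1, 1], cell[2, 2]]),
                  tilt_xy=cell[1, 0])
    return PhasePoint(pos, vel, np.ones(n), box, time)


# --------------------------------------------------------------------------
# checkpoints and manifests

def save_checkpoint(path, state: PhasePoint, rng_seed: int,
                    rng_step: int, alpha: float = 0.0) -> None:
    """Binary mother checkpoint: full state plus noise-stream counters."""
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=state.positions)
        f.create_dataset("momenta", data=state.momenta)
        f.create_dataset("masses", data=state.masses)
        f.attrs["edge_lengths"] = state.box.edge_lengths
        f.attrs["tilt_xy"] = state.box.tilt_xy
        f.attrs["time"] = state.time
        f.attrs["rng_seed"] = rng_seed
        f.attrs["rng_step"] = rng_step
        f.attrs["alpha"] = alpha


def load_checkpoint(path):
    with h5py.File(path, "r") as f:
        box = BoxSpec(np.asarray(f.attrs["edge_lengths"]),
                      float(f.attrs["tilt_xy"]))
        state = PhasePoint(f["positions"][...], f["momenta"][...],
                           f["masses"][...], box, float(f.attrs["time"]))
        return (state, int(f.attrs["rng_seed"]), int(f.attrs["rng_step"]),
                float(f.attrs["alpha"]))


def write_manifest(path, payload: Dict) -> None:
    """Machine-readable provenance record; suffices to regenerate the run."""
    from . import __version__

    doc = {"package": "lowshear", "version": __version__}
    doc.update(payload)
    Path(path).write_text(json.dumps(doc, indent=2, default=str))
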