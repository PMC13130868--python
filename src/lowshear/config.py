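"""Experiment configuration: structured text (YAML) with lossless round-trip.

Defaults reproduce the two reference protocols:

* ``dpd`` — standard DPD fluid, a=25, gamma=4.5, sigma=3, rc=1, rho=3, T=1,
  L=5 (N=375), dt=0.01, 1500 equilibration steps, mother sampled every 100
  steps, 1e5 daughters of 420 steps, unmapped covariance-corrected TTCF with
  the zero initial value imposed.
* ``lj`` — WCA fluid at the triple point (rho*=0.8442, T*=0.722), N=256,
  dt=2.5e-3, 10000 equilibration steps, mother sampled every 1000 steps,
  4e4 daughters of 600 steps, mapped (4 mappings), Nose-Hoover thermostat.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .dynamics import ThermostatState, default_nose_hoover_q
from .model import BoxSpec, ForceFieldSpec, SimulationParams, Variant

__all__ = ["ExperimentConfig", "default_config"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one TTCF experiment."""

    force_field: ForceFieldSpec
    simulation: SimulationParams
    density: float
    box_edge: float
    lattice: str = "sc"
    corrected: bool = True
    n_resamples: int = 1200
    ci_level: float = 0.95
    output_dir: str = "lowshear_run"
    system: str = "custom"

    @property
    def box(self) -> BoxSpec:
        return BoxSpec.cubic(self.box_edge)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        ff = asdict(self.force_field)
        ff["variant"] = self.force_field.variant.value
        sim = asdict(self.simulation)
        thermo = self.simulation.thermostat
        sim["thermostat"] = (None if thermo is None
                             else {"q": thermo.q, "alpha": thermo.alpha})
        return {
            "system": self.system,
            "force_field": ff,
            "simulation": sim,
            "box": {"edge": self.box_edge, "density": self.density,
                    "lattice": self.lattice},
            "ttcf": {"corrected": self.corrected},
            "stats": {"n_resamples": self.n_resamples,
                      "ci_level": self.ci_level},
            "output": {"directory": self.output_dir},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        ffd = dict(d["force_field"])
        ffd["variant"] = Variant(ffd["variant"])
        simd = dict(d["simulation"])
        thermo = simd.get("thermostat")
        simd["thermostat"] = (None if thermo is None
                              else ThermostatState(thermo["q"],
                                                   thermo.get("alpha", 0.0)))
        return cls(force_field=ForceFieldSpec(**ffd),
                   simulation=SimulationParams(**simd),
                   density=d["box"]["density"], box_edge=d["box"]["edge"],
                   lattice=d["box"].get("lattice", "sc"),
                   corrected=d["ttcf"]["corrected"],
                   n_resamples=d["stats"]["n_resamples"],
                   ci_level=d["stats"].get("ci_level", 0.95),
                   output_dir=d["output"]["directory"],
                   system=d.get("system", "custom"))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        return cls.from_dict(yaml.safe_load(text))


def default_config(system: str = "dpd", shear_rate: float = 1e-2,
                   **overrides) -> ExperimentConfig:
    """Reference protocol for the DPD or LJ (WCA) system.

    Keyword overrides apply to the simulation block (e.g. ``n_daughters=500``).
    """
    if system == "dpd":
        ff = ForceFieldSpec.dpd_fluid()
        sim = SimulationParams(timestep=0.01, shear_rate=shear_rate,
                               n_equilibration_steps=1500,
                               mother_sampling_interval=100,
                               n_daughters=100_000, daughter_length=420,
                               use_mappings=False, impose_zero_initial=True)
        density, edge, lattice = 3.0, 5.0, "sc"
    elif system == "lj":
        ff = ForceFieldSpec.wca_fluid()
        n, density = 256, 0.8442
        edge = (n / density) ** (1.0 / 3.0)
        dt = 2.5e-3
        thermo = ThermostatState(
            default_nose_hoover_q(n, ff.kB, ff.temperature, dt))
        sim = SimulationParams(timestep=dt, shear_rate=shear_rate,
                               n_equilibration_steps=10_000,
                               mother_sampling_interval=1000,
                               n_daughters=40_000, daughter_length=600,
                               use_mappings=True, impose_zero_initial=False,
                               thermostat=thermo)
        lattice = "fcc"
    else:
        raise ValueError("system must be 'dpd' or 'lj'")
    for k, v in overrides.items():
        setattr(sim, k, v)
    sim.__post_init__()
    return ExperimentConfig(force_field=ff, simulation=sim, density=density,
                            box_edge=edge, lattice=lattice, system=system)
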