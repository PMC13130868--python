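"""Time integration: equilibrium dynamics, SLLOD shear with a deforming box.

Homogeneous planar shear in the xy plane (velocity along x, gradient along
y) via the SLLOD equations of motion,

    dr_i/dt = p_i/m_i + x_hat * gammadot * y_i
    dp_i/dt = F_i     - x_hat * gammadot * p_y,i   [- alpha p_i, thermostatted]

with peculiar momenta p and Lagrangian-rhomboid (tilting-box) boundary
conditions: the xy tilt advances by gammadot*Ly*dt per step and flips back by
Lx when it exceeds Lx/2.  At zero shear the equations reduce to plain
velocity-Verlet NVE (or Nose-Hoover NVT); the DPD dissipative+random pair
forces act as their own thermostat, so DPD runs use no explicit one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from . import _kernels
from .forces import RandomStreamSpec, _kernel_ff_args
from .model import ForceFieldSpec, PhasePoint, SimulationParams

__all__ = [
    "ThermostatState",
    "IntegratorSpec",
    "StressSeries",
    "default_nose_hoover_q",
    "step",
    "advance",
    "run_mother",
    "run_daughter",
]

#: default Verlet-list skin, in units of the interaction range
DEFAULT_SKIN = 0.3

_MODES = ("equilibrium", "sllod_nve", "sllod_nvt")


@dataclass
class ThermostatState:
    """Nose-Hoover multiplier alpha and damping parameter Q.

    d(alpha)/dt = (sum_i p_i^2/m_i - 3*N*kB*T) / Q.  The multiplier is
    mutated in place as integration proceeds.
    """

    q: float
    alpha: float = 0.0

    def __post_init__(self):
        if self.q <= 0:
            raise ValueError("damping parameter Q must be positive")
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")


def default_nose_hoover_q(n_particles: int, kB: float, temperature: float,
                          dt: float, tau_steps: float = 100.0) -> float:
    """Q = 3*N*kB*T*tau^2 with relaxation time tau = tau_steps*dt."""
    return 3.0 * n_particles * kB * temperature * (tau_steps * dt) ** 2


@dataclass
class IntegratorSpec:
    """Mode, timestep, shear rate and optional thermostat.

    sllod_nvt requires a thermostat; sllod_nve forbids one; equilibrium mode
    accepts an optional one (needed to thermalize WCA, redundant for DPD).
    """

    mode: str
    timestep: float
    shear_rate: float = 0.0
    thermostat: Optional[ThermostatState] = None

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.mode == "sllod_nvt" and self.thermostat is None:
            raise ValueError("sllod_nvt requires a thermostat")
        if self.mode == "sllod_nve" and self.thermostat is not None:
            raise ValueError("sllod_nve forbids a thermostat")
        if self.mode == "equilibrium" and self.shear_rate != 0.0:
            raise ValueError("equilibrium mode requires zero shear rate")


@dataclass
class StressSeries:
    """Per-step P_yx (and kinetic temperature) along one daughter."""

    time: np.ndarray
    pyx: np.ndarray
    tkin: np.ndarray
    shear_rate: float
    volume: float


def advance(state: PhasePoint, ff: ForceFieldSpec, integ: IntegratorSpec,
            rng: RandomStreamSpec, n_steps: int, *,
            skin: float = DEFAULT_SKIN) -> tuple:
    """Integrate n_steps and return (new_state, pyx, tkin) arrays.

    The returned series have n_steps+1 entries; index 0 is the entry state
    (with forces freshly evaluated there).  The noise stream is consumed one
    step-counter per step; the thermostat multiplier, if any, is updated in
    place.  Raises on trajectory blow-up (non-finite coordinates).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    new = state.copy()
    lx, ly, lz = (float(e) for e in new.box.edge_lengths)
    sllod = integ.mode != "equilibrium"
    thermo = integ.thermostat
    (is_wca, eps, sig, a, gam, sigr, rcut,
     hd, hr, xif, xival, vdu) = _kernel_ff_args(ff)
    xif = xif or rng.xi_mode == "fixed_constant"
    pyx, tkin, tilt, alpha, _pe = _kernels.run_trajectory(
        new.positions, new.momenta, new.masses,
        lx, ly, lz, float(new.box.tilt_xy),
        is_wca, eps, sig, a, gam, sigr, rcut,
        hd, hr, xif, xival, vdu,
        float(integ.shear_rate), sllod, float(integ.timestep), int(n_steps),
        np.uint64(rng.seed), np.uint64(rng.step_counter),
        thermo is not None, 0.0 if thermo is None else float(thermo.alpha),
        1.0 if thermo is None else float(thermo.q),
        float(ff.kB), float(ff.temperature),
        float(skin))
    if not np.all(np.isfinite(new.positions)):
        raise ValueError("trajectory blow-up: non-finite coordinates")
    new.box.tilt_xy = float(tilt)
    new.time = state.time + n_steps * integ.timestep
    if thermo is not None:
        thermo.alpha = float(alpha)
    return new, pyx, tkin


def step(state: PhasePoint, ff: ForceFieldSpec, integ: IntegratorSpec,
         rng: RandomStreamSpec) -> PhasePoint:
    """One velocity-Verlet step of the selected equations of motion."""
    new, _pyx, _tkin = advance(state, ff, integ, rng, 1)
    return new


def run_mother(state0: PhasePoint, ff: ForceFieldSpec,
               params: SimulationParams,
               rng: RandomStreamSpec) -> Iterator[PhasePoint]:
    """Equilibrium mother trajectory yielding decorrelated snapshots.

    Advances ``n_equilibration_steps`` first, then yields a deep snapshot
    every ``mother_sampling_interval`` steps until n_daughters (or
    n_daughters/4 with mappings, each snapshot then seeding a quadruplet)
    snapshots have been produced.
    """
    integ = IntegratorSpec("equilibrium", params.timestep,
                           thermostat=params.thermostat)
    n_snap = params.n_daughters // 4 if params.use_mappings \
        else params.n_daughters
    state = state0
    stream = rng
    state, _, _ = advance(state, ff, integ, stream,
                          params.n_equilibration_steps)
    stream = stream.advanced(params.n_equilibration_steps)
    for _ in range(n_snap):
        state, _, _ = advance(state, ff, integ, stream,
                              params.mother_sampling_interval)
        stream = stream.advanced(params.mother_sampling_interval)
        yield state.copy()


def run_daughter(gamma0: PhasePoint, ff: ForceFieldSpec,
                 params: SimulationParams,
                 rng: RandomStreamSpec) -> StressSeries:
    """Nonequilibrium transient: field switched on at t=0.

    Records P_yx at every step including step 0 (momenta reinterpreted as
    peculiar, valid because the streaming velocity vanishes at t=0) for
    ``daughter_length`` steps, giving daughter_length+1 points.
    """
    thermo = None
    if params.thermostat is not None:
        # fresh multiplier per daughter
        thermo = ThermostatState(params.thermostat.q, 0.0)
        mode = "sllod_nvt"
    else:
        mode = "sllod_nve"
    integ = IntegratorSpec(mode, params.timestep, params.shear_rate, thermo)
    start = gamma0.copy()
    start.time = 0.0
    start.box.tilt_xy = 0.0
    _, pyx, tkin = advance(start, ff, integ, rng, params.daughter_length)
    t = params.timestep * np.arange(params.daughter_length + 1)
    return StressSeries(t, pyx, tkin, params.shear_rate,
                        gamma0.box.volume)
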