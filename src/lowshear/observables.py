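"""Instantaneous measurements on a phase point.

Virial pressure tensor P_ab = (1/V) * sum_i [ m_i c_ia c_ib
+ (1/2) sum_{j!=i} r_ij,a F_ij,b ] with c = p/m the peculiar velocity,
kinetic temperature, the SLLOD dissipation function and Newton's-law
viscosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forces import PairForceResult
from .model import PhasePoint

__all__ = [
    "PressureTensor",
    "pressure_tensor",
    "kinetic_temperature",
    "dissipation_function",
    "viscosity",
]


@dataclass
class PressureTensor:
    """Kinetic + configurational pressure tensor (reduced units)."""

    kinetic_part: np.ndarray
    configurational_part: np.ndarray

    @property
    def components(self) -> np.ndarray:
        return self.kinetic_part + self.configurational_part

    @property
    def p_yx(self) -> float:
        return float(self.components[1, 0])


def pressure_tensor(state: PhasePoint, forces: PairForceResult) -> PressureTensor:
    """Virial pressure from a state and its pair-force evaluation.

    The kinetic part uses peculiar velocities c = p/m; the configurational
    part is the per-pair accumulated virial divided by the volume.
    """
    v = state.box.volume
    c = state.momenta / state.masses[:, None]
    kin = np.einsum("i,ia,ib->ab", state.masses, c, c) / v
    conf = forces.pair_virial_tensor / v
    return PressureTensor(kin, conf)


def kinetic_temperature(state: PhasePoint) -> float:
    """T_kin = sum p^2/m / (3*N*kB), with kB = 1 in reduced units.

    Uses 3N degrees of freedom (no constraint subtraction), matching the
    Nose-Hoover target sum_i p_i^2 - 3*N*kB*T.
    """
    n = state.n_particles
    if n < 1:
        raise ValueError("need at least one particle")
    return float(np.sum(state.momenta ** 2 / state.masses[:, None]) / (3.0 * n))


def dissipation_function(p_yx: float, shear_rate: float, volume: float,
                         kB: float, temperature: float) -> float:
    """SLLOD dissipation function Omega = -gammadot * V * P_yx / (kB*T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -shear_rate * volume * p_yx / (kB * temperature)


def viscosity(mean_p_yx: float, shear_rate: float) -> float:
    """Newton's law of viscosity, mu = -<P_yx> / gammadot.

    Raises at zero shear rate; the zero-shear limit is the province of
    equilibrium (Green-Kubo) estimators, which this package does not provide.
    """
    if shear_rate == 0:
        raise ZeroDivisionError(
            "viscosity undefined at zero shear rate; use an equilibrium "
            "(Green-Kubo) estimator instead")
    return -mean_p_yx / shear_rate
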