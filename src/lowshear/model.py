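"""Domain types, parameter validation, initial configurations and geometry.

Reduced units throughout: lengths in units of the interaction range, energies
in units of kB*T (DPD) or the well depth epsilon (WCA), unit bead mass.  The
simulation cell is periodic in all three directions and may carry an ``xy``
tilt that encodes the accumulated shear strain of the deforming (Lagrangian
rhomboid) boundary conditions; volume is invariant under the tilt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Variant",
    "BoxSpec",
    "PhasePoint",
    "ForceFieldSpec",
    "SimulationParams",
    "validate_fdt",
    "fdt_holds",
    "init_configuration",
    "minimum_image",
    "wrap_positions",
]


class Variant(str, Enum):
    """Force-field families understood by the engine.

    ``WCA``
        Truncated-and-shifted Lennard-Jones (Weeks-Chandler-Andersen).
    ``DPD_FULL``
        Standard DPD: conservative + dissipative + random force, with the
        fluctuation-dissipation constraint sigma^2 = 2*gamma*kB*T enforced.
    ``DPD_C``
        Conservative force only (diagnostic probe).
    ``DPD_C_RFIXED``
        Conservative + random force with a single constant xi for every pair
        (diagnostic probe).
    ``DPD_CDR_XIFIXED``
        All three forces with constant xi (diagnostic probe).
    """

    WCA = "wca"
    DPD_FULL = "dpd_full"
    DPD_C = "dpd_c"
    DPD_C_RFIXED = "dpd_c_rfixed"
    DPD_CDR_XIFIXED = "dpd_cdr_xifixed"

    @property
    def is_dpd(self) -> bool:
        return self is not Variant.WCA

    @property
    def has_dissipative(self) -> bool:
        return self in (Variant.DPD_FULL, Variant.DPD_CDR_XIFIXED)

    @property
    def has_random(self) -> bool:
        return self in (Variant.DPD_FULL, Variant.DPD_C_RFIXED,
                        Variant.DPD_CDR_XIFIXED)

    @property
    def xi_is_fixed(self) -> bool:
        return self in (Variant.DPD_C_RFIXED, Variant.DPD_CDR_XIFIXED)


@dataclass
class BoxSpec:
    """Periodic, shear-deformable (xy-tilted) orthogonal cell.

    ``tilt_xy`` is the accumulated shear displacement of the upper y face in
    the x direction; it is remapped into [-Lx/2, Lx/2] on construction (the
    box is periodic in the tilt with period Lx).
    """

    edge_lengths: np.ndarray
    tilt_xy: float = 0.0

    def __post_init__(self):
        self.edge_lengths = np.asarray(self.edge_lengths, dtype=float).reshape(3)
        if not np.all(self.edge_lengths > 0):
            raise ValueError("box edge lengths must be positive")
        lx = self.edge_lengths[0]
        self.tilt_xy = float(self.tilt_xy - np.rint(self.tilt_xy / lx) * lx)

    @classmethod
    def cubic(cls, edge: float, tilt_xy: float = 0.0) -> "BoxSpec":
        return cls(np.array([edge, edge, edge], dtype=float), tilt_xy)

    @property
    def volume(self) -> float:
        return float(np.prod(self.edge_lengths))

    def copy(self) -> "BoxSpec":
        return BoxSpec(self.edge_lengths.copy(), self.tilt_xy)


def minimum_image(box: BoxSpec, displacement) -> np.ndarray:
    """Shortest periodic image of a displacement in the tilted cell.

    Convention: wrap y first, shifting x by the tilt for every crossed y
    image, then wrap x, then z.  Works for displacements of any magnitude.
    """
    d = np.array(displacement, dtype=float, copy=True)
    lx, ly, lz = box.edge_lengths
    ny = np.rint(d[..., 1] / ly)
    d[..., 1] -= ny * ly
    d[..., 0] -= ny * box.tilt_xy
    d[..., 0] -= np.rint(d[..., 0] / lx) * lx
    d[..., 2] -= np.rint(d[..., 2] / lz) * lz
    return d


def wrap_positions(pos, box: BoxSpec) -> np.ndarray:
    """Wrap positions into the primary (possibly tilted) cell.

    The primary cell is { (u + t*y/Ly, y, z) : u in [0,Lx), y in [0,Ly),
    z in [0,Lz) } with t the tilt.
    """
    p = np.array(pos, dtype=float, copy=True).reshape(-1, 3)
    lx, ly, lz = box.edge_lengths
    t = box.tilt_xy
    ky = np.floor(p[:, 1] / ly)
    p[:, 1] -= ky * ly
    p[:, 0] -= ky * t
    u = p[:, 0] - t * p[:, 1] / ly
    p[:, 0] -= np.floor(u / lx) * lx
    p[:, 2] -= np.floor(p[:, 2] / lz) * lz
    return p


@dataclass
class PhasePoint:
    """Full microscopic state: positions, peculiar momenta, masses, box, time.

    Momenta are peculiar (streaming-subtracted) at all times; at equilibrium
    the streaming velocity is zero so peculiar and laboratory momenta agree.
    """

    positions: np.ndarray
    momenta: np.ndarray
    masses: np.ndarray
    box: BoxSpec
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.momenta = np.ascontiguousarray(self.momenta, dtype=float)
        self.masses = np.ascontiguousarray(self.masses, dtype=float).reshape(-1)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3) or self.momenta.shape != (n, 3):
            raise ValueError("positions and momenta must both be (N, 3)")
        if self.masses.shape[0] != n:
            raise ValueError("masses length must match particle count")
        if not np.all(self.masses > 0):
            raise ValueError("masses must be positive")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "PhasePoint":
        return PhasePoint(self.positions.copy(), self.momenta.copy(),
                          self.masses.copy(), self.box.copy(), self.time)

    def wrapped(self) -> "PhasePoint":
        return PhasePoint(wrap_positions(self.positions, self.box),
                          self.momenta.copy(), self.masses.copy(),
                          self.box.copy(), self.time)


@dataclass
class ForceFieldSpec:
    """Parameters of the WCA or DPD interaction.

    For WCA the cutoff is pinned to 2^(1/6)*sigma_lj (the potential minimum),
    which makes energy and force vanish continuously at the cutoff with shift
    constant +epsilon.  For DPD_FULL the fluctuation-dissipation constraint
    sigma_rand^2 = 2*gamma_diss*kB*T is validated at construction and the
    spec is rejected on violation, since only then do the dissipative and
    random forces form a canonical-ensemble thermostat.

    ``vd_unit_vector`` selects the projection used in the dissipative force:
    True (default) for -gamma*wD*(rhat.v)*rhat, False for the full-vector
    form -gamma*wD*(r.v)*rhat.
    """

    variant: Variant
    epsilon: float = 1.0
    sigma_lj: float = 1.0
    a: float = 25.0
    gamma_diss: float = 4.5
    sigma_rand: float = 3.0
    r_cut: Optional[float] = None
    temperature: float = 1.0
    kB: float = 1.0
    vd_unit_vector: bool = True
    xi_fixed_value: float = 1.0

    def __post_init__(self):
        self.variant = Variant(self.variant)
        if self.variant is Variant.WCA:
            wca_rc = 2.0 ** (1.0 / 6.0) * self.sigma_lj
            if self.r_cut is None:
                self.r_cut = wca_rc
            elif not math.isclose(self.r_cut, wca_rc, rel_tol=1e-12):
                raise ValueError(
                    f"WCA cutoff must be 2^(1/6)*sigma = {wca_rc!r}")
        else:
            if self.r_cut is None:
                self.r_cut = 1.0
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.variant is Variant.DPD_FULL and not validate_fdt(self):
            raise ValueError(
                "DPD_FULL violates the fluctuation-dissipation constraint "
                "sigma_rand^2 = 2*gamma_diss*kB*T")

    # -- convenience constructors -------------------------------------------

    @classmethod
    def dpd_fluid(cls, a: float = 25.0, gamma_diss: float = 4.5,
                  sigma_rand: float = 3.0, r_cut: float = 1.0,
                  temperature: float = 1.0, kB: float = 1.0,
                  **kw) -> "ForceFieldSpec":
        """Standard DPD simple fluid (a=25, gamma=4.5, sigma=3, rc=1, T=1)."""
        return cls(Variant.DPD_FULL, a=a, gamma_diss=gamma_diss,
                   sigma_rand=sigma_rand, r_cut=r_cut,
                   temperature=temperature, kB=kB, **kw)

    @classmethod
    def wca_fluid(cls, epsilon: float = 1.0, sigma_lj: float = 1.0,
                  temperature: float = 0.722, kB: float = 1.0,
                  **kw) -> "ForceFieldSpec":
        """WCA fluid at the Lennard-Jones triple-point temperature T*=0.722."""
        return cls(Variant.WCA, epsilon=epsilon, sigma_lj=sigma_lj,
                   temperature=temperature, kB=kB, **kw)

    @property
    def shift_constant(self) -> float:
        """WCA energy shift ensuring continuity at the cutoff (= +epsilon)."""
        if self.variant is not Variant.WCA:
            raise TypeError("shift constant applies to the WCA branch only")
        return self.epsilon


def fdt_holds(gamma_diss: float, sigma_rand: float, kB: float,
              temperature: float, rel_tol: float = 1e-12) -> bool:
    """Fluctuation-dissipation constraint sigma^2 = 2*gamma*kB*T."""
    return math.isclose(sigma_rand ** 2, 2.0 * gamma_diss * kB * temperature,
                        rel_tol=rel_tol)


def validate_fdt(spec: ForceFieldSpec) -> bool:
    """True iff the DPD spec satisfies sigma_rand^2 = 2*gamma_diss*kB*T.

    Raises TypeError for a WCA spec: the constraint links the random and
    dissipative amplitudes and is meaningless without them.
    """
    if spec.variant is Variant.WCA:
        raise TypeError("FDT constraint does not apply to WCA")
    return fdt_holds(spec.gamma_diss, spec.sigma_rand, spec.kB,
                     spec.temperature)


@dataclass
class SimulationParams:
    """Protocol parameters for a mother/daughter TTCF experiment.

    Defaults follow the standard DPD protocol: dt=0.01, 1500 equilibration
    steps, mother sampled every 100 steps, 1e5 daughters of 420 steps.
    ``thermostat`` is None (DPD thermostats itself) or a
    ``dynamics.ThermostatState`` for Nose-Hoover (required for WCA).
    """

    timestep: float = 0.01
    shear_rate: float = 0.0
    n_equilibration_steps: int = 1500
    mother_sampling_interval: int = 100
    n_daughters: int = 100_000
    daughter_length: int = 420
    rng_seed: int = 0
    use_mappings: bool = False
    impose_zero_initial: bool = True
    thermostat: object = None

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.daughter_length < 1:
            raise ValueError("daughter_length must be >= 1")
        if self.mother_sampling_interval < 1:
            raise ValueError("mother_sampling_interval must be >= 1")
        if self.use_mappings and self.n_daughters % 4 != 0:
            raise ValueError(
                "with mappings on, n_daughters must be divisible by 4 "
                "(no partial quadruplets)")


def _sc_lattice(n_sites: int, box: BoxSpec) -> np.ndarray:
    """First n_sites points of a simple-cubic grid filling the box."""
    n = 1
    while n ** 3 < n_sites:
        n += 1
    lx, ly, lz = box.edge_lengths
    ax, ay, az = lx / n, ly / n, lz / n
    pts = np.empty((n_sites, 3))
    m = 0
    for ix in range(n):
        for iy in range(n):
            for iz in range(n):
                if m == n_sites:
                    return pts
                pts[m, 0] = (ix + 0.5) * ax
                pts[m, 1] = (iy + 0.5) * ay
                pts[m, 2] = (iz + 0.5) * az
                m += 1
    return pts


_FCC_BASIS = np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.0],
                       [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]])


def _fcc_lattice(n_sites: int, box: BoxSpec) -> np.ndarray:
    """First n_sites points of an FCC lattice (4 basis atoms per cell)."""
    n = 1
    while 4 * n ** 3 < n_sites:
        n += 1
    cell = box.edge_lengths / n
    pts = np.empty((n_sites, 3))
    m = 0
    for ix in range(n):
        for iy in range(n):
            for iz in range(n):
                for b in range(4):
                    if m == n_sites:
                        return pts
                    pts[m, 0] = (ix + _FCC_BASIS[b, 0] + 0.25) * cell[0]
                    pts[m, 1] = (iy + _FCC_BASIS[b, 1] + 0.25) * cell[1]
                    pts[m, 2] = (iz + _FCC_BASIS[b, 2] + 0.25) * cell[2]
                    m += 1
    return pts


def init_configuration(density: float, box: BoxSpec, temperature: float,
                       seed: int, *, lattice: str = "sc", mass: float = 1.0,
                       kB: float = 1.0) -> PhasePoint:
    """Lattice placement plus Maxwell-Boltzmann momenta.

    N = density * V must round to an integer (within 1e-9).  Momenta are
    drawn at temperature T, shifted so the total momentum vanishes, then
    rescaled so the kinetic temperature (3N degrees of freedom) matches T
    exactly.  Deterministic for a given seed.

    ``lattice`` is "sc" (simple cubic; adequate for the soft DPD potential)
    or "fcc" (overlap-free start for dense WCA fluids).
    """
    n_real = density * box.volume
    n = int(round(n_real))
    if abs(n_real - n) > 1e-9:
        raise ValueError(
            f"density*volume = {n_real!r} is not within 1e-9 of an integer")
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    if lattice == "sc":
        pos = _sc_lattice(n, box)
    elif lattice == "fcc":
        pos = _fcc_lattice(n, box)
    else:
        raise ValueError(f"unknown lattice {lattice!r}")
    masses = np.full(n, float(mass))
    rng = np.random.default_rng(seed)
    if temperature == 0.0:
        mom = np.zeros((n, 3))
    else:
        mom = rng.normal(0.0, np.sqrt(mass * kB * temperature), size=(n, 3))
        if n > 1:
            mom -= mom.mean(axis=0)
        tkin = np.sum(mom ** 2 / masses[:, None]) / (3.0 * n * kB)
        if tkin > 0:
            mom *= np.sqrt(temperature / tkin)
    return PhasePoint(pos, mom, masses, box.copy(), 0.0)
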