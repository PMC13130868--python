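"""Shared fixtures and independent reference implementations.

The brute-force oracle here is a deliberately naive pure-Python/numpy
re-derivation of the pair forces (double loop, explicit minimum image,
its own splitmix64 implementation) kept independent of the compiled kernels
it checks.
"""

import math

import numpy as np
import pytest

import lowshear as ls

# --------------------------------------------------------------------------
# pure-python counter-based noise (independent re-implementation)

_M64 = (1 << 64) - 1


def _mix(z):
    z = (z + 0x9E3779B97F4A7C15) & _M64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return z ^ (z >> 31)


def python_pair_normal(seed, step, i, j):
    a, b = (i, j) if i < j else (j, i)
    h = _mix(seed ^ _mix(step))
    h = _mix(h ^ ((a * 0x100000001B3 + b) & _M64))
    u1 = ((h >> 11) + 1) * 2.0 ** -53
    u2 = (_mix(h) >> 11) * 2.0 ** -53
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)


def brute_forces(state, ff, shear_rate, seed, step, dt):
    """O(N^2) double-loop force/virial oracle, formulas written out."""
    n = state.n_particles
    pos, mom, mass = state.positions, state.momenta, state.masses
    lx, ly, lz = state.box.edge_lengths
    tilt = state.box.tilt_xy
    forces = np.zeros((n, 3))
    virial = np.zeros((3, 3))
    pe = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            ny = round(d[1] / ly)
            d = d - np.array([ny * tilt, ny * ly, 0.0])
            d[0] -= round(d[0] / lx) * lx
            d[2] -= round(d[2] / lz) * lz
            r = math.sqrt(d @ d)
            if r >= ff.r_cut or r == 0.0:
                continue
            if ff.variant is ls.Variant.WCA:
                s6 = (ff.sigma_lj / r) ** 6
                pe += 4 * ff.epsilon * (s6 * s6 - s6) + ff.epsilon
                f = 24 * ff.epsilon * (2 * s6 * s6 - s6) / r * (d / r)
            else:
                w = 1 - r / ff.r_cut
                pe += 0.5 * ff.a * ff.r_cut * w * w
                f = ff.a * w * (d / r)
                if ff.variant.has_dissipative:
                    v = mom[i] / mass[i] - mom[j] / mass[j]
                    v = v + np.array([shear_rate * d[1], 0.0, 0.0])
                    proj = (d @ v) / r if ff.vd_unit_vector else (d @ v)
                    f = f - ff.gamma_diss * w * w * proj * (d / r)
                if ff.variant.has_random:
                    xi = (ff.xi_fixed_value if ff.variant.xi_is_fixed
                          else python_pair_normal(seed, step, i, j))
                    f = f + ff.sigma_rand * w * xi / math.sqrt(dt) * (d / r)
            forces[i] += f
            forces[j] -= f
            virial += np.outer(d, f)
    return forces, virial, pe


# --------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def dpd_ff():
    return ls.ForceFieldSpec.dpd_fluid()


@pytest.fixture(scope="session")
def wca_ff():
    return ls.ForceFieldSpec.wca_fluid()


@pytest.fixture(scope="session")
def dpd_box():
    return ls.BoxSpec.cubic(5.0)


@pytest.fixture(scope="session")
def dpd_thermal_state(dpd_ff, dpd_box):
    """Standard DPD fluid (N=375) equilibrated from the lattice start."""
    state = ls.init_configuration(3.0, dpd_box, 1.0, seed=101, lattice="sc")
    integ = ls.IntegratorSpec("equilibrium", 0.01)
    state, _, _ = ls.advance(state, dpd_ff, integ, ls.RandomStreamSpec(102),
                             1500)
    return state


@pytest.fixture(scope="session")
def dpd_temp_series(dpd_ff, dpd_thermal_state):
    """Kinetic-temperature series over 10^4 equilibrium DPD steps."""
    integ = ls.IntegratorSpec("equilibrium", 0.01)
    _, _, tkin = ls.advance(dpd_thermal_state, dpd_ff, integ,
                            ls.RandomStreamSpec(103, 1500), 10_000)
    return tkin


@pytest.fixture(scope="session")
def wca_thermal_state(wca_ff):
    """Small WCA fluid (N=108, rho*=0.8442) thermalized at T*=0.722."""
    n, rho = 108, 0.8442
    box = ls.BoxSpec.cubic((n / rho) ** (1 / 3))
    state = ls.init_configuration(rho, box, wca_ff.temperature, seed=104,
                                  lattice="fcc")
    dt = 2.5e-3
    thermo = ls.ThermostatState(
        ls.default_nose_hoover_q(n, 1.0, wca_ff.temperature, dt))
    integ = ls.IntegratorSpec("equilibrium", dt, thermostat=thermo)
    state, _, _ = ls.advance(state, wca_ff, integ, ls.RandomStreamSpec(105),
                             3000)
    return state


@pytest.fixture()
def tiny_dpd_state(dpd_ff):
    """N=24 DPD beads in an L=2 box (cutoff exactly half the edge)."""
    box = ls.BoxSpec.cubic(2.0)
    return ls.init_configuration(3.0, box, 1.0, seed=7, lattice="sc")
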