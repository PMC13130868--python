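"""Pairwise force and energy evaluation with per-pair virial accumulation.

The scalar/one-pair operations here are the reference formulation of the
force fields; `compute_all_forces` assembles them over all minimum-image
pairs through the compiled kernels.  The per-pair virial is accumulated
during force evaluation, so the configurational pressure term
(1/2) sum_i sum_{j!=i} r_ij,a F_ij,b is reproduced exactly as written.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from . import _kernels
from .model import BoxSpec, ForceFieldSpec, PhasePoint, Variant

__all__ = [
    "PairForceResult",
    "RandomStreamSpec",
    "pair_noise",
    "wca_energy_force",
    "dpd_weights",
    "dpd_pair_forces",
    "compute_all_forces",
]


@dataclass
class PairForceResult:
    """Total force per particle, pair virial tensor and conservative energy.

    ``pair_virial_tensor[a, b] = sum_pairs d_a * F_b`` over unordered
    minimum-image pairs (equal to the half-sum over ordered pairs).  The
    potential energy covers the conservative part only.
    """

    total_force_per_particle: np.ndarray
    pair_virial_tensor: np.ndarray
    potential_energy: float


@dataclass
class RandomStreamSpec:
    """Replayable noise stream: counter-based, keyed on (seed, step, pair).

    ``xi_mode`` is "per_pair_gaussian" (a fresh standard-normal draw per
    unordered pair per step, shared by both members so xi_ij == xi_ji) or
    "fixed_constant" (one constant for every pair; diagnostic variants).
    """

    seed: int
    step_counter: int = 0
    xi_mode: str = "per_pair_gaussian"

    def advanced(self, n_steps: int) -> "RandomStreamSpec":
        return RandomStreamSpec(self.seed, self.step_counter + n_steps,
                                self.xi_mode)


def pair_noise(seed: int, step: int, i: int, j: int) -> float:
    """The Gaussian draw xi_ij used at a given step; xi_ij == xi_ji."""
    return float(_kernels.pair_gaussian(np.uint64(seed), np.uint64(step),
                                        np.uint64(i), np.uint64(j)))


def wca_energy_force(r: float, spec: ForceFieldSpec) -> Tuple[float, float]:
    """WCA energy and force magnitude at separation r.

    phi(r) = 4*eps*[(sigma/r)^12 - (sigma/r)^6] + eps for r <= rc, else 0;
    force magnitude is -dphi/dr (positive = repulsive).  Both go to zero
    continuously at rc = 2^(1/6)*sigma.
    """
    if spec.variant is not Variant.WCA:
        raise TypeError("wca_energy_force requires a WCA spec")
    if r <= 0:
        raise ValueError("separation must be positive")
    if r > spec.r_cut:
        return 0.0, 0.0
    s6 = (spec.sigma_lj / r) ** 6
    energy = 4.0 * spec.epsilon * (s6 * s6 - s6) + spec.epsilon
    force = 24.0 * spec.epsilon * (2.0 * s6 * s6 - s6) / r
    return energy, force


def dpd_weights(r: float, r_cut: float) -> Tuple[float, float]:
    """DPD weight functions (wD, wR) with wR = 1 - r/rc and wD = wR^2."""
    if r < 0:
        raise ValueError("separation must be non-negative")
    if r > r_cut:
        return 0.0, 0.0
    wr = 1.0 - r / r_cut
    return wr * wr, wr


def dpd_pair_forces(r_ij, v_ij, xi_ij: float, spec: ForceFieldSpec,
                    dt: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conservative, dissipative and random force on bead i from bead j.

    F_C = a*(1 - r/rc)*rhat;  F_D = -gamma*wD*(rhat.v_ij)*rhat (unit-vector
    projection by default, full-vector (r.v_ij) if the spec says so);
    F_R = sigma*wR*xi_ij*dt^(-1/2)*rhat.  All three vanish beyond rc.
    Variants zero out the components they exclude.
    """
    if spec.variant is Variant.WCA:
        raise TypeError("dpd_pair_forces requires a DPD-family spec")
    d = np.asarray(r_ij, dtype=float)
    v = np.asarray(v_ij, dtype=float)
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ValueError("zero separation between beads")
    zero = np.zeros(3)
    if r > spec.r_cut:
        return zero, zero.copy(), zero.copy()
    rhat = d / r
    wd, wr = dpd_weights(r, spec.r_cut)
    f_c = spec.a * wr * rhat
    if spec.variant.has_dissipative:
        proj = float(rhat @ v) if spec.vd_unit_vector else float(d @ v)
        f_d = -spec.gamma_diss * wd * proj * rhat
    else:
        f_d = zero.copy()
    if spec.variant.has_random:
        f_r = spec.sigma_rand * wr * xi_ij / np.sqrt(dt) * rhat
    else:
        f_r = zero.copy()
    return f_c, f_d, f_r


def _kernel_ff_args(spec: ForceFieldSpec):
    v = spec.variant
    return (v is Variant.WCA, spec.epsilon, spec.sigma_lj, spec.a,
            spec.gamma_diss, spec.sigma_rand, spec.r_cut,
            v.has_dissipative, v.has_random, v.xi_is_fixed,
            spec.xi_fixed_value, spec.vd_unit_vector)


def compute_all_forces(state: PhasePoint, spec: ForceFieldSpec,
                       shear_rate: float, rng: RandomStreamSpec,
                       dt: float) -> PairForceResult:
    """Sum pair forces over all minimum-image neighbours.

    The relative velocity entering F_D is the laboratory one: peculiar
    velocity difference plus the streaming correction shear_rate*dy
    (minimum-image dy) in x; it vanishes at zero shear.  Net force is zero
    to machine precision for every variant because xi_ij == xi_ji.
    """
    box = state.box
    if spec.r_cut > 0.5 * float(np.min(box.edge_lengths)):
        raise ValueError("cutoff exceeds half the smallest box edge")
    n = state.n_particles
    pos = np.ascontiguousarray(state.positions)
    mom = np.ascontiguousarray(state.momenta)
    lx, ly, lz = (float(e) for e in box.edge_lengths)
    tilt = float(box.tilt_xy)
    npmax = max(n * (n - 1) // 2, 1)
    pi_arr = np.empty(npmax, np.int64)
    pj_arr = np.empty(npmax, np.int64)
    n_pairs = _kernels.build_pairs(pos, lx, ly, lz, tilt, spec.r_cut,
                                   pi_arr, pj_arr)
    forces = np.empty((n, 3))
    virial = np.empty((3, 3))
    xi_fixed = rng.xi_mode == "fixed_constant" or spec.variant.xi_is_fixed
    is_wca, eps, sig, a, gam, sigr, rcut, hd, hr, _, xival, vdu = \
        _kernel_ff_args(spec)
    pe = _kernels.compute_forces(
        pos, mom, state.masses, lx, ly, lz, tilt,
        pi_arr, pj_arr, n_pairs,
        is_wca, eps, sig, a, gam, sigr, rcut,
        hd, hr, xi_fixed, xival, vdu,
        float(shear_rate), 1.0 / np.sqrt(dt),
        np.uint64(rng.seed), np.uint64(rng.step_counter),
        forces, virial)
    return PairForceResult(forces, virial, float(pe))
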