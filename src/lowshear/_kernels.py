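"""Numba hot loops: pair interactions, neighbour bookkeeping, time stepping.

Everything in this module operates on plain float64 arrays so the inner loops
stay allocation-free; the public modules wrap these in the domain types.

Randomness is counter-based: every Gaussian pair noise ``xi_ij`` is a hash of
``(seed, step, i, j)`` with the pair taken unordered.  A trajectory is
therefore bit-reproducible from its seed alone, independent of how the pair
loop is ordered (brute force vs. neighbour list) or how a run is split into
segments, and ``xi_ij == xi_ji`` holds by construction, which is what makes
the random force conserve momentum exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_SM_GAMMA = U64(0x9E3779B97F4A7C15)
_SM_MUL1 = U64(0xBF58476D1CE4E5B9)
_SM_MUL2 = U64(0x94D049BB133111EB)
_PAIR_MUL = U64(0x100000001B3)
_TWO_PI = 2.0 * np.pi
_INV_2_53 = 2.0 ** -53


@njit(cache=True, inline="always")
def _splitmix64(z):
    z = z + _SM_GAMMA
    z = (z ^ (z >> U64(30))) * _SM_MUL1
    z = (z ^ (z >> U64(27))) * _SM_MUL2
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def pair_gaussian(seed, step, i, j):
    """Standard-normal draw for the unordered pair (i, j) at a given step."""
    a = i if i < j else j
    b = j if i < j else i
    h = _splitmix64(U64(seed) ^ _splitmix64(U64(step)))
    h = _splitmix64(h ^ (U64(a) * _PAIR_MUL + U64(b)))
    # Box-Muller on two 53-bit uniforms; u1 offset away from zero.
    u1 = (np.float64(h >> U64(11)) + 1.0) * _INV_2_53
    u2 = np.float64(_splitmix64(h) >> U64(11)) * _INV_2_53
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(_TWO_PI * u2)


@njit(cache=True, fastmath=True)
def build_pairs(pos, lx, ly, lz, tilt, rlist, pi_arr, pj_arr):
    """Verlet pair list by brute-force sweep; returns the number of pairs.

    Minimum image in the tilted cell: wrap y first (shifting x by the tilt),
    then x, then z.  Positions need not lie in the primary cell.  fastmath
    is safe here: the list is a candidate superset (skin-padded), the exact
    cutoff decision happens in the force evaluation.
    """
    n = pos.shape[0]
    rl2 = rlist * rlist
    inv_lx = 1.0 / lx
    inv_ly = 1.0 / ly
    inv_lz = 1.0 / lz
    x = np.empty(n)
    y = np.empty(n)
    z = np.empty(n)
    for i in range(n):
        x[i] = pos[i, 0]
        y[i] = pos[i, 1]
        z[i] = pos[i, 2]
    r2 = np.empty(n)
    m = 0
    for i in range(n - 1):
        xi = x[i]
        yi = y[i]
        zi = z[i]
        # branchless distance pass (SIMD-friendly), then a scalar scan
        for j in range(i + 1, n):
            dz = zi - z[j]
            dz -= np.rint(dz * inv_lz) * lz
            dy = yi - y[j]
            ny = np.rint(dy * inv_ly)
            dy -= ny * ly
            dx = xi - x[j] - ny * tilt
            dx -= np.rint(dx * inv_lx) * lx
            r2[j] = dx * dx + dy * dy + dz * dz
        for j in range(i + 1, n):
            if r2[j] < rl2:
                pi_arr[m] = i
                pj_arr[m] = j
                m += 1
    return m


@njit(cache=True)
def compute_forces(pos, mom, mass, lx, ly, lz, tilt,
                   pi_arr, pj_arr, n_pairs,
                   is_wca, eps, sig, a_rep, gam, sig_r, rcut,
                   has_diss, has_rand, xi_fixed, xi_value, vd_unit,
                   shear_rate, inv_sqrt_dt, seed, step,
                   forces, virial):
    """Accumulate pair forces and the pair virial into the output buffers.

    ``virial[alpha, beta] = sum_pairs d_alpha * F_beta`` with d = r_i - r_j
    (minimum image) and F the total pair force on particle i, i.e. the
    configurational term of the virial pressure before division by V.

    The dissipative force uses the laboratory relative velocity: peculiar
    velocity difference plus the streaming correction shear_rate * dy in x.
    Returns the conservative potential energy.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for r_ in range(3):
        for c_ in range(3):
            virial[r_, c_] = 0.0
    pe = 0.0
    rc2 = rcut * rcut
    inv_lx = 1.0 / lx
    inv_ly = 1.0 / ly
    inv_lz = 1.0 / lz
    for k in range(n_pairs):
        i = pi_arr[k]
        j = pj_arr[k]
        dz = pos[i, 2] - pos[j, 2]
        dz -= np.rint(dz * inv_lz) * lz
        if dz * dz >= rc2:
            continue
        dy = pos[i, 1] - pos[j, 1]
        ny = np.rint(dy * inv_ly)
        dy -= ny * ly
        dx = pos[i, 0] - pos[j, 0]
        dx -= ny * tilt
        dx -= np.rint(dx * inv_lx) * lx
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2 or r2 <= 0.0:
            continue
        r = np.sqrt(r2)
        if is_wca:
            s2 = (sig * sig) / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            pe += 4.0 * eps * (s12 - s6) + eps
            coef = 24.0 * eps * (2.0 * s12 - s6) / r2
        else:
            w = 1.0 - r / rcut
            pe += 0.5 * a_rep * rcut * w * w
            coef = a_rep * w / r
            if has_diss:
                dvx = mom[i, 0] / mass[i] - mom[j, 0] / mass[j] + shear_rate * dy
                dvy = mom[i, 1] / mass[i] - mom[j, 1] / mass[j]
                dvz = mom[i, 2] / mass[i] - mom[j, 2] / mass[j]
                proj = dx * dvx + dy * dvy + dz * dvz
                if vd_unit:
                    proj /= r
                coef -= gam * w * w * proj / r
            if has_rand:
                if xi_fixed:
                    xi = xi_value
                else:
                    xi = pair_gaussian(seed, step, i, j)
                coef += sig_r * w * xi * inv_sqrt_dt / r
        fx = coef * dx
        fy = coef * dy
        fz = coef * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += dx * fx
        virial[0, 1] += dx * fy
        virial[0, 2] += dx * fz
        virial[1, 0] += dy * fx
        virial[1, 1] += dy * fy
        virial[1, 2] += dy * fz
        virial[2, 0] += dz * fx
        virial[2, 1] += dz * fy
        virial[2, 2] += dz * fz
    return pe


@njit(cache=True)
def run_trajectory(pos, mom, mass,
                   lx, ly, lz, tilt0,
                   is_wca, eps, sig, a_rep, gam, sig_r, rcut,
                   has_diss, has_rand, xi_fixed, xi_value, vd_unit,
                   shear_rate, sllod, dt, n_steps,
                   seed, step0,
                   thermo_on, alpha0, q_damp, kb, t_target,
                   skin):
    """Velocity-Verlet integration of n_steps, mutating pos/mom in place.

    Operator splitting (frozen): half-kick (force, minus the shear coupling
    -gammadot*p_y in x, minus alpha*p when thermostatted), drift (p/m plus the
    streaming term +gammadot*y in x, box tilt advance, position rewrap),
    thermostat-multiplier update, force recomputation, half-kick.

    Momenta are peculiar throughout.  The box tilt at step k is recomputed
    from the step counter (tilt0 + k*gammadot*Ly*dt, remapped into
    [-Lx/2, Lx/2]) rather than accumulated, so total strain is exact in the
    integer-step sense regardless of flips.

    Returns (pyx, tkin, tilt, alpha, pe): per-step shear pressure P_yx and
    kinetic temperature (index 0 = entry state), final tilt, final thermostat
    multiplier and last conservative potential energy.  P_yx at step k uses
    the kinetic term from the step-k momenta and the configurational virial
    from the step-k force evaluation.
    """
    n = pos.shape[0]
    npmax = n * (n - 1) // 2
    pi_arr = np.empty(npmax, np.int64)
    pj_arr = np.empty(npmax, np.int64)
    forces = np.empty((n, 3))
    virial = np.empty((3, 3))
    disp = np.zeros((n, 3))
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    vol = lx * ly * lz
    dtilt = shear_rate * ly * dt if sllod else 0.0
    tilt = tilt0
    tilt_build = tilt
    rlist = rcut + skin
    n_pairs = build_pairs(pos, lx, ly, lz, tilt, rlist, pi_arr, pj_arr)
    pe = compute_forces(pos, mom, mass, lx, ly, lz, tilt,
                        pi_arr, pj_arr, n_pairs,
                        is_wca, eps, sig, a_rep, gam, sig_r, rcut,
                        has_diss, has_rand, xi_fixed, xi_value, vd_unit,
                        shear_rate, inv_sqrt_dt, seed, step0,
                        forces, virial)
    pyx = np.empty(n_steps + 1)
    tkin = np.empty(n_steps + 1)
    kxy = 0.0
    ks = 0.0
    for i in range(n):
        kxy += mom[i, 1] * mom[i, 0] / mass[i]
        ks += (mom[i, 0] ** 2 + mom[i, 1] ** 2 + mom[i, 2] ** 2) / mass[i]
    pyx[0] = (kxy + virial[1, 0]) / vol
    tkin[0] = ks / (3.0 * n * kb)
    alpha = alpha0
    half = 0.5 * dt
    for s in range(1, n_steps + 1):
        # first half-kick
        for i in range(n):
            px = mom[i, 0]
            py = mom[i, 1]
            pz = mom[i, 2]
            gx = forces[i, 0]
            gy = forces[i, 1]
            gz = forces[i, 2]
            if sllod:
                gx -= shear_rate * py
            if thermo_on:
                gx -= alpha * px
                gy -= alpha * py
                gz -= alpha * pz
            mom[i, 0] = px + half * gx
            mom[i, 1] = py + half * gy
            mom[i, 2] = pz + half * gz
        # drift
        for i in range(n):
            vx = mom[i, 0] / mass[i]
            if sllod:
                vx += shear_rate * pos[i, 1]
            vy = mom[i, 1] / mass[i]
            vz = mom[i, 2] / mass[i]
            ddx = dt * vx
            ddy = dt * vy
            ddz = dt * vz
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz
            disp[i, 0] += ddx
            disp[i, 1] += ddy
            disp[i, 2] += ddz
        if sllod:
            traw = tilt0 + s * dtilt
            tilt = traw - np.rint(traw / lx) * lx
        # rewrap into the (possibly tilted) primary cell
        for i in range(n):
            ky = np.floor(pos[i, 1] / ly)
            if ky != 0.0:
                pos[i, 1] -= ky * ly
                pos[i, 0] -= ky * tilt
            u = pos[i, 0] - tilt * pos[i, 1] / ly
            kx = np.floor(u / lx)
            if kx != 0.0:
                pos[i, 0] -= kx * lx
            kz = np.floor(pos[i, 2] / lz)
            if kz != 0.0:
                pos[i, 2] -= kz * lz
        if thermo_on:
            ks = 0.0
            for i in range(n):
                ks += (mom[i, 0] ** 2 + mom[i, 1] ** 2 + mom[i, 2] ** 2) / mass[i]
            alpha += dt * (ks - 3.0 * n * kb * t_target) / q_damp
        # neighbour-list refresh when the two largest displacements could
        # have closed a gap of the skin width
        d2max1 = 0.0
        d2max2 = 0.0
        for i in range(n):
            d2 = disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2
            if d2 > d2max1:
                d2max2 = d2max1
                d2max1 = d2
            elif d2 > d2max2:
                d2max2 = d2
        need = np.sqrt(d2max1) + np.sqrt(d2max2) > skin
        if (not need) and np.abs(tilt - tilt_build) > 0.1 * skin:
            need = True
        if need:
            n_pairs = build_pairs(pos, lx, ly, lz, tilt, rlist, pi_arr, pj_arr)
            tilt_build = tilt
            for i in range(n):
                disp[i, 0] = 0.0
                disp[i, 1] = 0.0
                disp[i, 2] = 0.0
        pe = compute_forces(pos, mom, mass, lx, ly, lz, tilt,
                            pi_arr, pj_arr, n_pairs,
                            is_wca, eps, sig, a_rep, gam, sig_r, rcut,
                            has_diss, has_rand, xi_fixed, xi_value, vd_unit,
                            shear_rate, inv_sqrt_dt, seed, step0 + s,
                            forces, virial)
        # second half-kick
        for i in range(n):
            px = mom[i, 0]
            py = mom[i, 1]
            pz = mom[i, 2]
            gx = forces[i, 0]
            gy = forces[i, 1]
            gz = forces[i, 2]
            if sllod:
                gx -= shear_rate * py
            if thermo_on:
                gx -= alpha * px
                gy -= alpha * py
                gz -= alpha * pz
            mom[i, 0] = px + half * gx
            mom[i, 1] = py + half * gy
            mom[i, 2] = pz + half * gz
        kxy = 0.0
        ks = 0.0
        for i in range(n):
            kxy += mom[i, 1] * mom[i, 0] / mass[i]
            ks += (mom[i, 0] ** 2 + mom[i, 1] ** 2 + mom[i, 2] ** 2) / mass[i]
        if not np.isfinite(ks):
            raise ValueError("trajectory blow-up: non-finite momenta")
        pyx[s] = (kxy + virial[1, 0]) / vol
        tkin[s] = ks / (3.0 * n * kb)
    return pyx, tkin, tilt, alpha, pe
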