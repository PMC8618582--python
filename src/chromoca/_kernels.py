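"""Numba kernels: pair forces, Langevin (BAOAB) integration, contact counting.

All kernels work in internal units (length d = 1, energy kT = 1, time ps).
Randomness enters only through pre-generated Gaussian noise arrays so that
trajectories are bit-reproducible for a fixed numpy seed.
"""

import numpy as np
from numba import njit

WCA_CUT2 = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2


@njit(cache=True)
def compute_forces(pos, f, d, bond_k, u0_ev, u0_attr, r_cut, cage_r, cage_k):
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    rc2 = r_cut * r_cut
    wca2 = d * d * WCA_CUT2
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            r2 = dx * dx + dy * dy + dz * dz
            if j == i + 1:
                # harmonic bond, rest length d
                r = np.sqrt(r2)
                fb = bond_k * (r - d) / r
                f[i, 0] += fb * dx
                f[i, 1] += fb * dy
                f[i, 2] += fb * dz
                f[j, 0] -= fb * dx
                f[j, 1] -= fb * dy
                f[j, 2] -= fb * dz
                continue
            if r2 >= rc2:
                continue
            inv2 = d * d / r2
            inv6 = inv2 * inv2 * inv2
            inv12 = inv6 * inv6
            if r2 <= wca2:
                if u0_ev > 0.0:
                    fp = 24.0 * u0_ev * (2.0 * inv12 - inv6) / r2
                    # force on i points away from j (repulsion)
                    f[i, 0] -= fp * dx
                    f[i, 1] -= fp * dy
                    f[i, 2] -= fp * dz
                    f[j, 0] += fp * dx
                    f[j, 1] += fp * dy
                    f[j, 2] += fp * dz
            else:
                ua = u0_attr[i, j]
                if ua > 0.0:
                    fp = 24.0 * ua * (2.0 * inv12 - inv6) / r2
                    f[i, 0] -= fp * dx
                    f[i, 1] -= fp * dy
                    f[i, 2] -= fp * dz
                    f[j, 0] += fp * dx
                    f[j, 1] += fp * dy
                    f[j, 2] += fp * dz
        if cage_r > 0.0:
            ri = np.sqrt(xi * xi + yi * yi + zi * zi)
            if ri > cage_r:
                fc = -cage_k * (ri - cage_r) / ri
                f[i, 0] += fc * xi
                f[i, 1] += fc * yi
                f[i, 2] += fc * zi


@njit(cache=True)
def baoab_chunk(pos, vel, f, noise, dt, gamma, mass, kT,
                d, bond_k, u0_ev, u0_attr, r_cut, cage_r, cage_k):
    """Integrate len(noise) BAOAB steps in place; forces must be current."""
    n = pos.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1) / mass)
    half = 0.5 * dt
    for s in range(noise.shape[0]):
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * f[i, k] / mass
                pos[i, k] += half * vel[i, k]
                vel[i, k] = c1 * vel[i, k] + c2 * noise[s, i, k]
                pos[i, k] += half * vel[i, k]
        compute_forces(pos, f, d, bond_k, u0_ev, u0_attr, r_cut, cage_r, cage_k)
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * f[i, k] / mass


@njit(cache=True)
def count_contacts(pos, r_cont, out):
    """Add 1 to out[i, j] (both triangles) for every pair within r_cont."""
    n = pos.shape[0]
    rc2 = r_cont * r_cont
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz <= rc2:
                out[i, j] += 1
                out[j, i] += 1


@njit(cache=True)
def pair_distances(pos, ii, jj, out):
    for k in range(ii.shape[0]):
        i = ii[k]
        j = jj[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        out[k] = np.sqrt(dx * dx + dy * dy + dz * dz)
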