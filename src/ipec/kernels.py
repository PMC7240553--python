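"""Numba force/energy kernels.

Pairwise terms accumulate forces symmetrically (Newton's third law holds
pairwise to round-off).  The short-range kernel walks a Verlet pair list
built by an O(n²) sweep with a skin; at desk scale (n <= a few thousand)
the brute rebuild, triggered by a displacement criterion, is cheaper than
maintaining cell lists.  Coulomb is a direct non-periodic sum over charged
beads (the complex is dilute: no periodic images).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "build_dual_pair_list",
    "wca_forces",
    "yukawa_forces",
    "bond_forces",
    "coulomb_forces",
]


@njit(cache=True)
def build_dual_pair_list(pos, cutoff_lj, cutoff_yk, is_h, partner1, partner2,
                         cap):
    """One sweep, two Verlet lists: WCA pairs and H-H Yukawa pairs.

    The WCA list holds every non-bonded pair inside ``cutoff_lj``; the
    Yukawa list holds H-H non-bonded pairs inside ``cutoff_yk`` (pass
    cutoff_yk = 0 to skip it when ε_HH = 0).  Returns
    (lj_i, lj_j, n_lj, yk_i, yk_j, n_yk); n_lj == -1 flags buffer overflow.
    """
    n = pos.shape[0]
    c2l = cutoff_lj * cutoff_lj
    c2y = cutoff_yk * cutoff_yk
    li = np.empty(cap, dtype=np.int64)
    lj = np.empty(cap, dtype=np.int64)
    yi = np.empty(cap, dtype=np.int64)
    yj = np.empty(cap, dtype=np.int64)
    kl = 0
    ky = 0
    for i in range(n - 1):
        xi, yi_, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        b1, b2 = partner1[i], partner2[i]
        hi = is_h[i]
        for j in range(i + 1, n):
            if j == b1 or j == b2:
                continue
            dx = xi - pos[j, 0]
            dy = yi_ - pos[j, 1]
            dz = zi - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < c2l:
                if kl >= cap:
                    return li, lj, -1, yi, yj, ky
                li[kl] = i
                lj[kl] = j
                kl += 1
            if hi == 1 and is_h[j] == 1 and r2 < c2y:
                if ky >= cap:
                    return li, lj, -1, yi, yj, ky
                yi[ky] = i
                yj[ky] = j
                ky += 1
    return li, lj, kl, yi, yj, ky


@njit(cache=True, fastmath=True)
def wca_forces(pos, pi, pj, npairs, eps_lj, sigma, forces):
    """WCA repulsion over a pair list. Returns (energy, min pair r²)."""
    rc2 = (2.0 ** (1.0 / 3.0)) * sigma * sigma
    sig2 = sigma * sigma
    e = 0.0
    min_r2 = 1.0e300
    for k in range(npairs):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < min_r2:
            min_r2 = r2
        if r2 < rc2:
            inv2 = sig2 / r2
            s6 = inv2 * inv2 * inv2
            e += 4.0 * eps_lj * (s6 * s6 - s6 + 0.25)
            g = 4.0 * eps_lj * (12.0 * s6 * s6 - 6.0 * s6) / r2
            fx = g * dx
            fy = g * dy
            fz = g * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return e, min_r2


@njit(cache=True, fastmath=True)
def yukawa_forces(pos, pi, pj, npairs, eps, sigma, forces):
    """Yukawa attraction ε (σ/r)(1-(r/4σ)²)² over an H-H pair list."""
    rcy = 4.0 * sigma
    rcy2 = rcy * rcy
    e = 0.0
    for k in range(npairs):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rcy2:
            r = np.sqrt(r2)
            u = 1.0 - r2 / rcy2
            e += eps * (sigma / r) * u * u
            g = eps * sigma * (u * u / (r2 * r) + 4.0 * u / (rcy2 * r))
            fx = g * dx
            fy = g * dy
            fz = g * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return e


@njit(cache=True, fastmath=True)
def bond_forces(pos, bonds, K, b, forces):
    """Harmonic bonds E = K (r - b)². Returns (energy, max |r-b|/b)."""
    e = 0.0
    max_dev = 0.0
    for k in range(bonds.shape[0]):
        i = bonds[k, 0]
        j = bonds[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dev = r - b
        e += K * dev * dev
        ad = abs(dev) / b
        if ad > max_dev:
            max_dev = ad
        fscal = -2.0 * K * dev / r
        fx = fscal * dx
        fy = fscal * dy
        fz = fscal * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return e, max_dev


@njit(cache=True, fastmath=True)
def coulomb_forces(pos, q, charged_idx, l_b, forces):
    """Direct non-periodic Coulomb over the charged beads. Returns energy."""
    n = charged_idx.shape[0]
    e = 0.0
    for a in range(n - 1):
        i = charged_idx[a]
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        qi = q[i]
        fx = fy = fz = 0.0
        for c in range(a + 1, n):
            j = charged_idx[c]
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            inv = 1.0 / np.sqrt(r2)
            epair = l_b * qi * q[j] * inv
            e += epair
            g = epair * inv * inv
            fx += g * dx
            fy += g * dy
            fz += g * dz
            forces[j, 0] -= g * dx
            forces[j, 1] -= g * dy
            forces[j, 2] -= g * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
    return e
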