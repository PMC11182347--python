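"""Optional numba-compiled inner loops for the bead-peptide and LJ models.

The numpy implementations in :mod:`ktntools.models` are the reference;
these kernels compute the identical quantities with explicit loops and are
cross-checked against the numpy path by the test suite.  If numba is not
importable the package silently falls back to numpy.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=False)
def lj_energy_gradient(pos):
    n = pos.shape[0]
    e = 0.0
    g = np.zeros((n, 3))
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            inv12 = inv6 * inv6
            e += 4.0 * (inv12 - inv6)
            c = 4.0 * (-12.0 * inv12 + 6.0 * inv6) * inv2
            g[i, 0] += c * dx
            g[i, 1] += c * dy
            g[i, 2] += c * dz
            g[j, 0] -= c * dx
            g[j, 1] -= c * dy
            g[j, 2] -= c * dz
    return e, g


@njit(cache=True, fastmath=False)
def peptide_energy_gradient(pos, qq_scaled, pair_i, pair_j, lambda_d,
                            bond_r0, bond_k, theta0, angle_k,
                            lj_eps, lj_sigma,
                            dc1, ds1, dc2, ds2,
                            helix_center, strand_center,
                            coop_h, coop_s, coop_power):
    n = pos.shape[0]
    e = 0.0
    g = np.zeros((n, 3))
    # bonds
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0
        e += bond_k * dr * dr
        c = 2.0 * bond_k * dr / r
        g[i + 1, 0] += c * dx
        g[i + 1, 1] += c * dy
        g[i + 1, 2] += c * dz
        g[i, 0] -= c * dx
        g[i, 1] -= c * dy
        g[i, 2] -= c * dz
    # angles
    for i in range(n - 2):
        u = pos[i] - pos[i + 1]
        v = pos[i + 2] - pos[i + 1]
        nu = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
        nv = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        uh = u / nu
        vh = v / nv
        cos = uh[0] * vh[0] + uh[1] * vh[1] + uh[2] * vh[2]
        if cos > 1.0:
            cos = 1.0
        if cos < -1.0:
            cos = -1.0
        theta = np.arccos(cos)
        sin2 = 1.0 - cos * cos
        if sin2 < 1e-12:
            sin2 = 1e-12
        sin = np.sqrt(sin2)
        dt = theta - theta0
        e += angle_k * dt * dt
        dEdt = 2.0 * angle_k * dt
        for c3 in range(3):
            gi = dEdt * (cos * uh[c3] - vh[c3]) / (nu * sin)
            gk = dEdt * (cos * vh[c3] - uh[c3]) / (nv * sin)
            g[i, c3] += gi
            g[i + 2, c3] += gk
            g[i + 1, c3] -= gi + gk
    # dihedrals: pass 1 computes angles and dphi/dx, pass 2 adds the base
    # two-well term plus the cooperative neighbour coupling
    n_dih = n - 3
    phis = np.empty(n_dih)
    dphi = np.empty((n_dih, 4, 3))
    for i in range(n_dih):
        b1 = pos[i + 1] - pos[i]
        b2 = pos[i + 2] - pos[i + 1]
        b3 = pos[i + 3] - pos[i + 2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        cr = np.cross(n1, n2)
        y = (cr[0] * b2[0] + cr[1] * b2[1] + cr[2] * b2[2]) / nb2
        phis[i] = np.arctan2(y, x)
        n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        f1 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (nb2 * nb2)
        f3 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (nb2 * nb2)
        for c3 in range(3):
            di = -nb2 / n1sq * n1[c3]
            dl = nb2 / n2sq * n2[c3]
            dphi[i, 0, c3] = di
            dphi[i, 1, c3] = -(1.0 + f1) * di + f3 * dl
            dphi[i, 2, c3] = f1 * di - (1.0 + f3) * dl
            dphi[i, 3, c3] = dl
    wh = np.empty(n_dih)
    dwh = np.empty(n_dih)
    ws = np.empty(n_dih)
    dws = np.empty(n_dih)
    for i in range(n_dih):
        dh = phis[i] - helix_center
        bhm = (1.0 + np.cos(dh)) / 2.0
        wh[i] = bhm ** coop_power
        dwh[i] = coop_power * bhm ** (coop_power - 1.0) * (-np.sin(dh) / 2.0)
        dsm = phis[i] - strand_center
        bsm = (1.0 + np.cos(dsm)) / 2.0
        ws[i] = bsm ** coop_power
        dws[i] = coop_power * bsm ** (coop_power - 1.0) * (-np.sin(dsm) / 2.0)
    for i in range(n_dih - 1):
        e += -coop_h * wh[i] * wh[i + 1] - coop_s * ws[i] * ws[i + 1]
    for i in range(n_dih):
        phi = phis[i]
        e += (dc1 * np.cos(phi) + ds1 * np.sin(phi)
              + dc2 * np.cos(2.0 * phi) + ds2 * np.sin(2.0 * phi))
        dEdphi = (-dc1 * np.sin(phi) + ds1 * np.cos(phi)
                  - 2.0 * dc2 * np.sin(2.0 * phi)
                  + 2.0 * ds2 * np.cos(2.0 * phi))
        nb_h = 0.0
        nb_s = 0.0
        if i > 0:
            nb_h += wh[i - 1]
            nb_s += ws[i - 1]
        if i < n_dih - 1:
            nb_h += wh[i + 1]
            nb_s += ws[i + 1]
        dEdphi += -coop_h * dwh[i] * nb_h - coop_s * dws[i] * nb_s
        for c3 in range(3):
            g[i, c3] += dEdphi * dphi[i, 0, c3]
            g[i + 1, c3] += dEdphi * dphi[i, 1, c3]
            g[i + 2, c3] += dEdphi * dphi[i, 2, c3]
            g[i + 3, c3] += dEdphi * dphi[i, 3, c3]
    # nonbonded
    sig2 = lj_sigma * lj_sigma
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        s6 = (sig2 / r2) ** 3
        e += 4.0 * lj_eps * (s6 * s6 - s6)
        dEdr = 4.0 * lj_eps * (-12.0 * s6 * s6 + 6.0 * s6) / r
        qq = qq_scaled[p]
        if qq != 0.0:
            if lambda_d > 0.0:
                screen = np.exp(-r / lambda_d)
                dscreen = -screen / lambda_d
            else:
                screen = 1.0
                dscreen = 0.0
            e += qq * screen / r
            dEdr += qq * (dscreen / r - screen / r2)
        c = dEdr / r
        g[i, 0] += c * dx
        g[i, 1] += c * dy
        g[i, 2] += c * dz
        g[j, 0] -= c * dx
        g[j, 1] -= c * dy
        g[j, 2] -= c * dz
    return e, g
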