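"""Numba-compiled inner loops for bonded and non-bonded force evaluation.

All kernels accumulate forces in-place into a pre-zeroed (N, 2) array and
return the potential-energy contribution.  FENE overextension is signalled
by returning the offending bond index (−1 when all bonds are valid) so the
caller can raise a typed error outside compiled code.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# non-bonded pair kinds
KIND_NONE = 0
KIND_LJ = 1
KIND_WCA = 2


@njit(cache=True)
def bonded_forces(pos, bond_i, bond_j, bond_kf, bond_r0, bond_dr,
                  ang_i, ang_j, ang_k, ang_kb, ang_cos0, forces):
    """FENE bonds + cosine-form bend triples.  Returns (energy, bad_bond)."""
    energy = 0.0
    for n in range(bond_i.shape[0]):
        i = bond_i[n]
        j = bond_j[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        r = np.sqrt(dx * dx + dy * dy)
        x = (r - bond_r0[n]) / bond_dr[n]
        x2 = x * x
        if x2 >= 1.0:
            return np.nan, n
        energy += -0.5 * bond_kf[n] * bond_dr[n] * bond_dr[n] * np.log(1.0 - x2)
        # F_i = -dU/dr * rhat_ij ; dU/dr = kF (r - r0) / (1 - x^2)
        fmag = -bond_kf[n] * (r - bond_r0[n]) / (1.0 - x2)
        if r > 0.0:
            fx = fmag * dx / r
            fy = fmag * dy / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[j, 0] -= fx
            forces[j, 1] -= fy
    for n in range(ang_i.shape[0]):
        i = ang_i[n]
        j = ang_j[n]  # central bead
        k = ang_k[n]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        lu = np.sqrt(ux * ux + uy * uy)
        lv = np.sqrt(vx * vx + vy * vy)
        c = (ux * vx + uy * vy) / (lu * lv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        d = c - ang_cos0[n]
        energy += 0.5 * ang_kb[n] * d * d
        g = ang_kb[n] * d  # dU/dcos
        inv_uv = 1.0 / (lu * lv)
        inv_u2 = 1.0 / (lu * lu)
        inv_v2 = 1.0 / (lv * lv)
        # dcos/dr_i and dcos/dr_k
        gix = g * (vx * inv_uv - c * ux * inv_u2)
        giy = g * (vy * inv_uv - c * uy * inv_u2)
        gkx = g * (ux * inv_uv - c * vx * inv_v2)
        gky = g * (uy * inv_uv - c * vy * inv_v2)
        forces[i, 0] -= gix
        forces[i, 1] -= giy
        forces[k, 0] -= gkx
        forces[k, 1] -= gky
        forces[j, 0] += gix + gkx
        forces[j, 1] += giy + gky
    return energy, -1


@njit(cache=True)
def pair_forces(pos, pair_i, pair_j, kind, eps, sigma, cutoff, shift, forces):
    """LJ (min at sigma, shifted at cutoff) and WCA over a candidate pair list."""
    energy = 0.0
    for n in range(pair_i.shape[0]):
        kd = kind[n]
        if kd == KIND_NONE:
            continue
        i = pair_i[n]
        j = pair_j[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        r2 = dx * dx + dy * dy
        rc = cutoff[n]
        if r2 >= rc * rc:
            continue
        r = np.sqrt(r2)
        s = sigma[n] / r
        s6 = s * s * s * s * s * s
        s12 = s6 * s6
        u = eps[n] * (s12 - 2.0 * s6)
        if kd == KIND_WCA:
            u += eps[n]
        else:
            u -= shift[n]
        energy += u
        # dU/dr = -12 eps (s12 - s6) / r ;  F_i = -dU/dr * rhat
        fmag = 12.0 * eps[n] * (s12 - s6) / r
        fx = fmag * dx / r
        fy = fmag * dy / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[j, 0] -= fx
        forces[j, 1] -= fy
    return energy
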