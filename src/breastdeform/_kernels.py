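"""Numba kernels for the explicit dynamic-relaxation loop.

The vectorized numpy assembly in :mod:`breastdeform.fem` is the readable
reference; these kernels run the identical arithmetic element-by-element
inside one compiled loop so a full relaxation block costs no Python
overhead. The equivalence of the two force routes is asserted in tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def element_forces(x, tets, Bm, V0, mu, K, f):
    """Accumulate neo-Hookean internal forces into ``f``; returns the
    index of the first inverted element, or -1."""
    f[:] = 0.0
    m = tets.shape[0]
    for e in range(m):
        n0, n1, n2, n3 = tets[e, 0], tets[e, 1], tets[e, 2], tets[e, 3]
        # columns of Ds = current edge vectors
        a00 = x[n1, 0] - x[n0, 0]; a01 = x[n2, 0] - x[n0, 0]; a02 = x[n3, 0] - x[n0, 0]
        a10 = x[n1, 1] - x[n0, 1]; a11 = x[n2, 1] - x[n0, 1]; a12 = x[n3, 1] - x[n0, 1]
        a20 = x[n1, 2] - x[n0, 2]; a21 = x[n2, 2] - x[n0, 2]; a22 = x[n3, 2] - x[n0, 2]
        B = Bm[e]
        # F = Ds @ B
        F00 = a00 * B[0, 0] + a01 * B[1, 0] + a02 * B[2, 0]
        F01 = a00 * B[0, 1] + a01 * B[1, 1] + a02 * B[2, 1]
        F02 = a00 * B[0, 2] + a01 * B[1, 2] + a02 * B[2, 2]
        F10 = a10 * B[0, 0] + a11 * B[1, 0] + a12 * B[2, 0]
        F11 = a10 * B[0, 1] + a11 * B[1, 1] + a12 * B[2, 1]
        F12 = a10 * B[0, 2] + a11 * B[1, 2] + a12 * B[2, 2]
        F20 = a20 * B[0, 0] + a21 * B[1, 0] + a22 * B[2, 0]
        F21 = a20 * B[0, 1] + a21 * B[1, 1] + a22 * B[2, 1]
        F22 = a20 * B[0, 2] + a21 * B[1, 2] + a22 * B[2, 2]
        J = (F00 * (F11 * F22 - F12 * F21)
             - F01 * (F10 * F22 - F12 * F20)
             + F02 * (F10 * F21 - F11 * F20))
        if J <= 0.0:
            return e
        # C = F^T F (symmetric)
        C00 = F00 * F00 + F10 * F10 + F20 * F20
        C01 = F00 * F01 + F10 * F11 + F20 * F21
        C02 = F00 * F02 + F10 * F12 + F20 * F22
        C11 = F01 * F01 + F11 * F11 + F21 * F21
        C12 = F01 * F02 + F11 * F12 + F21 * F22
        C22 = F02 * F02 + F12 * F12 + F22 * F22
        detC = J * J
        # inverse of C via adjugate
        i00 = (C11 * C22 - C12 * C12) / detC
        i01 = (C02 * C12 - C01 * C22) / detC
        i02 = (C01 * C12 - C02 * C11) / detC
        i11 = (C00 * C22 - C02 * C02) / detC
        i12 = (C01 * C02 - C00 * C12) / detC
        i22 = (C00 * C11 - C01 * C01) / detC
        I1 = C00 + C11 + C22
        Jm23 = J ** (-2.0 / 3.0)
        cdev = mu[e] * Jm23
        cvol = -cdev * I1 / 3.0 + K[e] * J * (J - 1.0)
        S00 = cdev + cvol * i00
        S01 = cvol * i01
        S02 = cvol * i02
        S11 = cdev + cvol * i11
        S12 = cvol * i12
        S22 = cdev + cvol * i22
        # P = F S
        P00 = F00 * S00 + F01 * S01 + F02 * S02
        P01 = F00 * S01 + F01 * S11 + F02 * S12
        P02 = F00 * S02 + F01 * S12 + F02 * S22
        P10 = F10 * S00 + F11 * S01 + F12 * S02
        P11 = F10 * S01 + F11 * S11 + F12 * S12
        P12 = F10 * S02 + F11 * S12 + F12 * S22
        P20 = F20 * S00 + F21 * S01 + F22 * S02
        P21 = F20 * S01 + F21 * S11 + F22 * S12
        P22 = F20 * S02 + F21 * S12 + F22 * S22
        v0 = V0[e]
        # H = -V0 * P @ B^T ; columns are forces on nodes 1..3
        H00 = -v0 * (P00 * B[0, 0] + P01 * B[0, 1] + P02 * B[0, 2])
        H01 = -v0 * (P00 * B[1, 0] + P01 * B[1, 1] + P02 * B[1, 2])
        H02 = -v0 * (P00 * B[2, 0] + P01 * B[2, 1] + P02 * B[2, 2])
        H10 = -v0 * (P10 * B[0, 0] + P11 * B[0, 1] + P12 * B[0, 2])
        H11 = -v0 * (P10 * B[1, 0] + P11 * B[1, 1] + P12 * B[1, 2])
        H12 = -v0 * (P10 * B[2, 0] + P11 * B[2, 1] + P12 * B[2, 2])
        H20 = -v0 * (P20 * B[0, 0] + P21 * B[0, 1] + P22 * B[0, 2])
        H21 = -v0 * (P20 * B[1, 0] + P21 * B[1, 1] + P22 * B[1, 2])
        H22 = -v0 * (P20 * B[2, 0] + P21 * B[2, 1] + P22 * B[2, 2])
        f[n1, 0] += H00; f[n1, 1] += H10; f[n1, 2] += H20
        f[n2, 0] += H01; f[n2, 1] += H11; f[n2, 2] += H21
        f[n3, 0] += H02; f[n3, 1] += H12; f[n3, 2] += H22
        f[n0, 0] -= H00 + H01 + H02
        f[n0, 1] -= H10 + H11 + H12
        f[n0, 2] -= H20 + H21 + H22
    return -1


@njit(cache=True)
def relax_block(x, v, f, tets, Bm, V0, mu, K, minv, free, f_grav,
                dt, damping, n_steps, step0, ramp_steps):
    """Run ``n_steps`` of damped central-difference stepping in place.

    Returns (steps_done, inverted_element). ``f`` holds the last total
    force evaluation on exit.
    """
    half = 0.5 * damping * dt
    n = x.shape[0]
    for s in range(n_steps):
        lam = (step0 + s + 1.0) / ramp_steps
        if lam > 1.0:
            lam = 1.0
        bad = element_forces(x, tets, Bm, V0, mu, K, f)
        if bad >= 0:
            return s, bad
        for i in range(n):
            if free[i]:
                for d in range(3):
                    ftot = f[i, d] + lam * f_grav[i, d]
                    f[i, d] = ftot
                    v[i, d] = ((1.0 - half) * v[i, d] + dt * ftot * minv[i]) / (1.0 + half)
                    x[i, d] += dt * v[i, d]
            else:
                for d in range(3):
                    f[i, d] += lam * f_grav[i, d]
                    v[i, d] = 0.0
    return n_steps, -1
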