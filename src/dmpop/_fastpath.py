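"""Numba-compiled fixed-step RK4 kernel for the joint disease system.

Used by the calibration likelihood, where tens of thousands of forward
integrations dominate the cost.  Within a schedule segment every rate is
constant, so the kernel receives plain arrays and performs no lookups.
State layout (C order): counts (101, 2, 3) flattened, then accumulators
onsets (4, 2), diagnoses (4, 2), deaths (4, 2, 3), births, net migrants.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_AGES = 101
_N_COUNTS = N_AGES * 2 * 3


@njit(cache=False)
def _deriv(y, dy, mu, fert, sig, lam, du, cfr_d, mig, srb, g_of_age, aging):
    for i in range(y.shape[0]):
        dy[i] = 0.0
    births = 0.0
    for a in range(N_AGES):
        fa = fert[a]
        if fa != 0.0:
            base = a * 6  # female block: sex index 0
            births += fa * (y[base] + y[base + 1] + y[base + 2])
    total = 0.0
    for a in range(N_AGES):
        g = g_of_age[a]
        for s in range(2):
            base = (a * 2 + s) * 3
            h = y[base]
            u = y[base + 1]
            d = y[base + 2]
            m = mu[a, s]
            onset = lam[a, s] * h
            diag = sig[a, s] * u
            ex_u = du[a, s] * u
            ex_d = cfr_d * d
            dh = (mig - m) * h - onset
            duu = (mig - m) * u + onset - diag - ex_u
            dd = (mig - m) * d + diag - ex_d
            if aging:
                dh -= h
                duu -= u
                dd -= d
                if a > 0:
                    pb = ((a - 1) * 2 + s) * 3
                    dh += y[pb]
                    duu += y[pb + 1]
                    dd += y[pb + 2]
            dy[base] = dh
            dy[base + 1] = duu
            dy[base + 2] = dd
            total += h + u + d
            gs = g * 2 + s
            dy[_N_COUNTS + gs] += onset
            dy[_N_COUNTS + 8 + gs] += diag
            dbase = _N_COUNTS + 16 + gs * 3
            death_h = m * h
            death_u = m * u + ex_u
            death_d = m * d + ex_d
            if aging and a == N_AGES - 1:
                death_h += h
                death_u += u
                death_d += d
            dy[dbase] += death_h
            dy[dbase + 1] += death_u
            dy[dbase + 2] += death_d
    dy[0] += (1.0 - srb) * births      # a=0, female, H
    dy[3] += srb * births              # a=0, male, H
    dy[_N_COUNTS + 40] += births
    dy[_N_COUNTS + 41] += mig * total


@njit(cache=False)
def rk4_segment(y, dt, n_steps, mu, fert, sig, lam, du, cfr_d, mig, srb,
                g_of_age, aging):
    n = y.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    for _ in range(n_steps):
        _deriv(y, k1, mu, fert, sig, lam, du, cfr_d, mig, srb, g_of_age, aging)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        _deriv(tmp, k2, mu, fert, sig, lam, du, cfr_d, mig, srb, g_of_age, aging)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        _deriv(tmp, k3, mu, fert, sig, lam, du, cfr_d, mig, srb, g_of_age, aging)
        for i in range(n):
            tmp[i] = y[i] + dt * k3[i]
        _deriv(tmp, k4, mu, fert, sig, lam, du, cfr_d, mig, srb, g_of_age, aging)
        for i in range(n):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
    return y
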