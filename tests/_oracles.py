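"""Independent oracles used only by the tests.

Each oracle recomputes a quantity by a different route than the package:
flow-by-flow enumeration for derivatives, an annual Leslie-matrix
(cohort-component) projection for the demographic trajectory, and the
matrix exponential for the within-cell three-status chain.
"""

import numpy as np
from scipy.linalg import expm

from dmpop.grids import N_AGES


def enumerate_demographic_flows(counts, mortality, fertility, migration_per_1000,
                                srb, aging=True):
    """Brute-force derivative: loop over every compartment and flow."""
    d = np.zeros_like(counts)
    n_ages = counts.shape[0]
    for a in range(n_ages):
        for s in range(2):
            d[a, s] -= mortality[a, s] * counts[a, s]
            d[a, s] += migration_per_1000 / 1000.0 * counts[a, s]
            if aging:
                d[a, s] -= counts[a, s]            # outflow (age 100 dies)
                if a > 0:
                    d[a, s] += counts[a - 1, s]    # inflow from below
    births = sum(fertility[a] * counts[a, 0] for a in range(n_ages))
    d[0, 0] += (1 - srb) * births
    d[0, 1] += srb * births
    return d


def leslie_projection(counts, schedule, t0, years):
    """Annual cohort-component projection on the same piecewise-constant
    schedule: survival exp(-mu), newborns from mid-period mothers with
    half-year exposure, migration as a multiplicative factor."""
    n = counts.copy()
    totals = [n.sum()]
    for k in range(years):
        t = t0 + k + 0.5
        mu = schedule.mortality_at(t)
        fert = schedule.fertility_at(t)
        surv = np.exp(-mu)
        new = np.zeros_like(n)
        new[1:] = n[:-1] * surv[:-1]               # age 100 falls off (dies)
        births = float(fert @ (n[:, 0] * np.exp(-mu[:, 0] / 2)))
        srb = schedule.sex_ratio_at_birth
        infant_surv = np.exp(-mu[0] / 2)
        new[0, 0] = (1 - srb) * births * infant_surv[0]
        new[0, 1] = srb * births * infant_surv[1]
        new *= np.exp(schedule.migration_at(t) / 1000.0)
        n = new
        totals.append(n.sum())
    return n, np.array(totals)


def three_state_chain_solution(h0, u0, d0, lam, sigma, delta_u, delta_d, t):
    """Matrix-exponential solution of the closed H->U->D cell."""
    q = np.array([
        [-lam, 0.0, 0.0],
        [lam, -(sigma + delta_u), 0.0],
        [0.0, sigma, -delta_d],
    ])
    return expm(q * t) @ np.array([h0, u0, d0], dtype=float)
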