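"""Numba fast path for the sequential scan-path log-likelihood.

Same replay as :func:`lookdyn.likelihood.loglik_terms` for a single
parameter vector, compiled for the inner MCMC loop. The gamma survival
term of right-censored (truncated) fixations needs the regularised upper
incomplete gamma function, which is added outside the jitted kernel via
scipy: the kernel returns the gamma rate at each truncated fixation so
the wrapper can finish the computation. Agreement with the numpy
reference path is asserted in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.special import gammaincc


@njit(cache=False)
def _replay(aoi, dur, trunc, first, nxt, theta, a0):
    nu = theta[0]
    rho = theta[1]
    omega = theta[2]
    lam1, lam2, lam3 = theta[3], theta[4], theta[5]
    g = theta[6]
    mu = theta[7]
    s = theta[8]
    gln_s = math.lgamma(s)
    log_s_term = 0.0

    a1, a2, a3 = a0[0], a0[1], a0[2]
    ll = 0.0
    n_trunc = 0
    trunc_rate = np.empty(aoi.shape[0])
    for j in range(aoi.shape[0]):
        if first[j]:
            a1, a2, a3 = a0[0], a0[1], a0[2]
        i = aoi[j]
        T = dur[j]
        if i == 0:
            a1 *= lam1
            af = a1
        elif i == 1:
            a2 *= lam2
            af = a2
        else:
            a3 *= lam3
            af = a3
        mu_eff = mu * (1.0 + g * af)
        rate = s / mu_eff
        if trunc[j]:
            trunc_rate[n_trunc] = rate
            n_trunc += 1
        else:
            ll += s * math.log(rate) - gln_s + (s - 1.0) * math.log(T) - rate * T
        f = math.exp(-omega * T)
        a1 = a0[0] + (a1 - a0[0]) * f
        a2 = a0[1] + (a2 - a0[1]) * f
        a3 = a0[2] + (a3 - a0[2]) * f
        k = nxt[j]
        if k >= 0:
            l1 = nu * math.log(a1)
            l2 = nu * math.log(a2)
            l3 = nu * math.log(a3)
            m = max(l1, max(l2, l3))
            w1 = math.exp(l1 - m)
            w2 = math.exp(l2 - m)
            w3 = math.exp(l3 - m)
            rb = rho * math.exp(-m)
            if i == 0:
                w1 += rb
            elif i == 1:
                w2 += rb
            else:
                w3 += rb
            if k == 0:
                wk = w1
            elif k == 1:
                wk = w2
            else:
                wk = w3
            ll += math.log(wk) - math.log(w1 + w2 + w3)
    return ll, n_trunc, trunc_rate


def fast_total_loglik(packed, theta: np.ndarray, a0: np.ndarray) -> float:
    """Total log-likelihood for one parameter vector (natural scale)."""
    theta = np.asarray(theta, dtype=float)
    ll, n_trunc, trunc_rate = _replay(
        packed.aoi,
        packed.duration,
        packed.truncated.astype(np.bool_),
        packed.is_first.astype(np.bool_),
        packed.next_aoi,
        theta,
        np.asarray(a0, dtype=float),
    )
    if n_trunc:
        s = theta[8]
        T = packed.duration[packed.truncated]
        ll += float(np.sum(np.log(gammaincc(s, trunc_rate[:n_trunc] * T))))
    return float(ll)
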