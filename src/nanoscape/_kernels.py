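"""Numba-compiled hot paths for simulation and kernel-density scoring.

The nested-sampling likelihood evaluates the Euler-Maruyama integrator and the
Gaussian KDE hundreds of thousands of times, so both run as compiled loops
with no allocations inside the innermost loops.  The kernels take
pre-generated standard-normal increments: all randomness stays with numpy
Generators in the calling code.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def mixture_logpdf_sum(x, logw, means, variances):
    """Sum over x of log of the Gaussian mixture density (log-sum-exp)."""
    k = logw.shape[0]
    const = np.empty(k)
    for i in range(k):
        const[i] = logw[i] - 0.5 * (np.log(variances[i]) + _LOG_2PI)
    terms = np.empty(k)
    total = 0.0
    for j in range(x.shape[0]):
        mx = -np.inf
        for i in range(k):
            t = const[i] - 0.5 * (x[j] - means[i]) ** 2 / variances[i]
            terms[i] = t
            if t > mx:
                mx = t
        s = 0.0
        for i in range(k):
            s += np.exp(terms[i] - mx)
        total += mx + np.log(s)
    return total


@njit(cache=True)
def em_segment(x, normals, dt, sigma_dt, logw, means, variances, noise):
    """Advance states in place by Euler-Maruyama over one recording segment.

    x : (n,) current states, modified in place.
    normals : (n_steps, n) standard-normal increments.
    sigma_dt : sqrt(2 * B * dt).
    Drift is the analytic mixture score times B, computed with a per-point
    log-sum-exp so the tails never overflow.
    """
    n_steps = normals.shape[0]
    n = x.shape[0]
    k = logw.shape[0]
    const = np.empty(k)
    inv_var = np.empty(k)
    for i in range(k):
        const[i] = logw[i] - 0.5 * np.log(variances[i])
        inv_var[i] = 1.0 / variances[i]
    terms = np.empty(k)
    for s in range(n_steps):
        for j in range(n):
            xj = x[j]
            mx = -np.inf
            for i in range(k):
                d = xj - means[i]
                t = const[i] - 0.5 * d * d * inv_var[i]
                terms[i] = t
                if t > mx:
                    mx = t
            denom = 0.0
            num = 0.0
            for i in range(k):
                r = np.exp(terms[i] - mx)
                denom += r
                num += r * (means[i] - xj) * inv_var[i]
            x[j] = xj + noise * (num / denom) * dt + sigma_dt * normals[s, j]


@njit(cache=True)
def kde_logpdf(query, sample, bandwidth, floor):
    """Gaussian-kernel KDE log-density of each query point, floored.

    Kernel exponents are <= 0, so the sum is accumulated directly (no
    log-sum-exp shift needed); full underflow hits the floor, which is the
    clamping contract.
    """
    n = sample.shape[0]
    m = query.shape[0]
    out = np.empty(m)
    lognorm = np.log(n * bandwidth) + 0.5 * _LOG_2PI
    inv2h2 = 0.5 / (bandwidth * bandwidth)
    for j in range(m):
        q = query[j]
        s = 0.0
        for i in range(n):
            d = q - sample[i]
            s += np.exp(-d * d * inv2h2)
        v = np.log(s) - lognorm if s > 0.0 else floor
        out[j] = v if v > floor else floor
    return out
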