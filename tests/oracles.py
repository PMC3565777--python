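"""Independent oracles the tests check the package against.

Everything here is deliberately implemented without using the package's own
code paths: plain term-by-term summation for mixture densities,
Ornstein-Uhlenbeck closed forms for single-Gaussian dynamics, and a
Crank-Nicolson finite-difference solver for the density evolution equation.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.stats import norm


def mixture_pdf_termwise(weights, means, variances, x):
    """Mixture density by direct term-by-term summation."""
    total = np.zeros_like(np.asarray(x, dtype=float))
    for w, m, v in zip(weights, means, variances):
        total = total + w * norm.pdf(x, loc=m, scale=np.sqrt(v))
    return total


def mixture_tail_mass(weights, means, variances, threshold):
    """P(X > threshold) under the mixture, via the analytic normal CDF."""
    return float(sum(w * norm.sf(threshold, loc=m, scale=np.sqrt(v))
                     for w, m, v in zip(weights, means, variances)))


# -- Ornstein-Uhlenbeck closed forms (k=1 model) --------------------------

def ou_moments(x0, mu, var, B, t):
    """Mean and variance at time t of dX = -(B/var)(X-mu) dt + sqrt(2B) dW."""
    lam = B / var
    a = np.exp(-lam * t)
    mean = mu + (np.asarray(x0) - mu) * a
    variance = var * (1.0 - a**2)
    return mean, variance


def ou_day_logpdf(x, day0_sample, bandwidth, mu, var, B, t):
    """Exact day-t log density when starts are drawn from the day-0 KDE.

    The day-0 KDE is a Gaussian mixture with one kernel per data point, and
    the OU transition maps each Gaussian kernel to a Gaussian, so the day-t
    marginal is itself an n-component mixture -- no Monte Carlo needed.
    """
    lam = B / var
    a = np.exp(-lam * t)
    centers = mu + (np.asarray(day0_sample) - mu) * a
    width = np.sqrt(a**2 * bandwidth**2 + var * (1.0 - a**2))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    dens = np.mean(norm.pdf(x[:, None], loc=centers[None, :], scale=width), axis=1)
    return np.log(dens)


# -- Crank-Nicolson solver for dp/dt = -(A p)' + B p'' --------------------

def evolve_density_cn(drift_fn, B, p0_fn, x_grid, t_final, dt):
    """March the density evolution equation on a grid with Crank-Nicolson.

    Central differences for both the advection and diffusion terms, absorbing
    (zero) boundaries far outside the support.  Returns the density on
    x_grid at t_final, renormalized against the tiny boundary leakage.
    """
    x = np.asarray(x_grid, dtype=float)
    n = x.size
    dx = x[1] - x[0]
    A = drift_fn(x)

    main = np.full(n, -2.0 * B / dx**2)
    # row i couples to p_{i+1} with B/dx^2 - A_{i+1}/2dx and to p_{i-1} with
    # B/dx^2 + A_{i-1}/2dx; diags offset +1 element j lands at (j, j+1)
    upper = B / dx**2 - A[1:] / (2.0 * dx)
    lower = B / dx**2 + A[:-1] / (2.0 * dx)
    L = sparse.diags([lower, main, upper], offsets=[-1, 0, 1], format="csc")
    eye = sparse.identity(n, format="csc")
    lhs = splu((eye - 0.5 * dt * L).tocsc())
    rhs = (eye + 0.5 * dt * L).tocsr()

    p = np.clip(p0_fn(x), 0.0, None)
    p /= np.trapezoid(p, x)
    n_steps = int(round(t_final / dt))
    for _ in range(n_steps):
        p = lhs.solve(rhs @ p)
        p[0] = p[-1] = 0.0
    p = np.clip(p, 0.0, None)
    p /= np.trapezoid(p, x)
    return p


def finite_difference_drift(potential_fn, x, h=1e-5):
    """-(U(x+h) - U(x-h)) / 2h: the drift from the potential, numerically."""
    return -(potential_fn(x + h) - potential_fn(x - h)) / (2.0 * h)
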