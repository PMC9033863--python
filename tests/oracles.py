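"""Independent reference implementations used only to check fedcox.

The brute-force Cox evaluator materialises every risk set as an explicit
Python list and evaluates the likelihood term by term; it shares no code
with the package's vectorised suffix-sum implementation.  Finite
differences provide derivative oracles.
"""

from __future__ import annotations

import math

import numpy as np


def brute_log_partial_likelihood(times, events, X, beta):
    """Term-by-term evaluation with explicit risk sets (Breslow ties)."""
    times = np.asarray(times, float)
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    n = len(times)
    total = 0.0
    for i in range(n):
        if events[i] != 1:
            continue
        risk = [s for s in range(n) if times[s] >= times[i]]
        denom = sum(math.exp(float(X[s] @ beta)) for s in risk)
        total += float(X[i] @ beta) - math.log(denom)
    return total / n


def brute_score(times, events, X, beta):
    times = np.asarray(times, float)
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    n, p = X.shape
    g = np.zeros(p)
    for i in range(n):
        if events[i] != 1:
            continue
        risk = [s for s in range(n) if times[s] >= times[i]]
        w = np.array([math.exp(float(X[s] @ beta)) for s in risk])
        xbar = (w[:, None] * X[risk]).sum(axis=0) / w.sum()
        g += X[i] - xbar
    return g / n


def brute_hessian(times, events, X, beta):
    times = np.asarray(times, float)
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    n, p = X.shape
    H = np.zeros((p, p))
    for i in range(n):
        if events[i] != 1:
            continue
        risk = [s for s in range(n) if times[s] >= times[i]]
        w = np.array([math.exp(float(X[s] @ beta)) for s in risk])
        s0 = w.sum()
        xbar = (w[:, None] * X[risk]).sum(axis=0) / s0
        s2 = sum(wi * np.outer(xi, xi) for wi, xi in zip(w, X[risk])) / s0
        H -= s2 - np.outer(xbar, xbar)
    return H / n


def fd_gradient(f, beta, h=1e-6):
    """Central finite-difference gradient of a scalar function."""
    beta = np.asarray(beta, float)
    g = np.zeros_like(beta)
    for k in range(len(beta)):
        e = np.zeros_like(beta)
        e[k] = h
        g[k] = (f(beta + e) - f(beta - e)) / (2 * h)
    return g


def fd_jacobian(g, beta, h=1e-5):
    """Central finite-difference Jacobian of a vector function."""
    beta = np.asarray(beta, float)
    cols = []
    for k in range(len(beta)):
        e = np.zeros_like(beta)
        e[k] = h
        cols.append((g(beta + e) - g(beta - e)) / (2 * h))
    return np.column_stack(cols)


def grid_maximize_1d(f, lo=-5.0, hi=5.0, n_coarse=2001, refine=6):
    """Grid-search maximiser for one-parameter likelihoods."""
    for _ in range(refine):
        grid = np.linspace(lo, hi, n_coarse)
        vals = np.array([f(np.array([b])) for b in grid])
        k = int(np.argmax(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, n_coarse - 1)]
    return (lo + hi) / 2
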