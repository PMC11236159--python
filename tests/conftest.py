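"""Shared fixtures and independent numeric oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Independent finite-difference oracle for rectangular-duct Poiseuille flow
# ---------------------------------------------------------------------------

def fd_duct_solution(width: float, height: float, nx: int = 301, nz: int = 101):
    """Finite-difference Poisson solve of pressure-driven duct flow.

    Solves -lap u = 1 (unit G/mu) with u = 0 on the walls on an nx x nz
    grid, entirely independent of the series solution. Returns
    (Q_unit, wall_shear_unit) with the shear evaluated at the midpoint of
    the long wall by a second-order one-sided difference.
    """
    from scipy.sparse import csr_matrix, lil_matrix
    from scipy.sparse.linalg import spsolve

    w, h = max(width, height), min(width, height)
    x = np.linspace(0.0, w, nx)
    z = np.linspace(0.0, h, nz)
    dx, dz = x[1] - x[0], z[1] - z[0]
    Nx, Nz = nx - 2, nz - 2
    N = Nx * Nz
    A = lil_matrix((N, N))
    main = 2.0 / dx**2 + 2.0 / dz**2
    for j in range(Nz):
        for i in range(Nx):
            k = j * Nx + i
            A[k, k] = main
            if i > 0:
                A[k, k - 1] = -1.0 / dx**2
            if i < Nx - 1:
                A[k, k + 1] = -1.0 / dx**2
            if j > 0:
                A[k, k - Nx] = -1.0 / dz**2
            if j < Nz - 1:
                A[k, k + Nx] = -1.0 / dz**2
    u = spsolve(csr_matrix(A), np.ones(N)).reshape(Nz, Nx)
    U = np.zeros((nz, nx))
    U[1:-1, 1:-1] = u
    Q = np.trapezoid(np.trapezoid(U, x, axis=1), z)
    imid = nx // 2
    shear = (4.0 * U[1, imid] - U[2, imid]) / (2.0 * dz)
    return Q, shear


# ---------------------------------------------------------------------------
# Brute-force statistics oracles
# ---------------------------------------------------------------------------

def pearson_bruteforce(x, y) -> float:
    """Pearson r from the covariance definition, via an explicit loop."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    return sxy / (sxx * syy) ** 0.5


def welch_bruteforce(a, b):
    """Welch t and Welch-Satterthwaite df from the closed forms."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df


def permutation_pvalue(a, b, n_resamples: int = 10_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the difference in means."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na = len(a)
    observed = abs(np.mean(a) - np.mean(b))
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= observed - 1e-12:
            hits += 1
    return hits / n_resamples


def slopes_bruteforce(values, time):
    """Per-point central-difference slopes with 3-point running average,
    written as explicit loops (independent of the vectorized path)."""
    n = len(values)
    c = [float("nan")] * n
    for i in range(1, n - 1):
        c[i] = (values[i + 1] - values[i - 1]) / (time[i + 1] - time[i - 1])
    r = [float("nan")] * n
    for i in range(1, n - 1):
        window = [c[j] for j in range(max(1, i - 1), min(n - 1, i + 2))]
        r[i] = sum(window) / len(window)
    return r
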