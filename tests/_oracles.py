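"""Independent oracles the implementation is checked against.

These deliberately avoid the code paths (and where possible the library
routines) used by the package itself: linear programs are solved by
exhaustive vertex enumeration of the flux polytope, least squares by the
normal equations, and t quantiles by numerical integration of the density
plus bisection.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np
from scipy.integrate import quad


def enumerate_vertices(
    s: np.ndarray, lb: np.ndarray, ub: np.ndarray, tol: float = 1e-8
) -> list[np.ndarray]:
    """All vertices of {v : S v = 0, lb <= v <= ub} by brute force.

    Every vertex of the (bounded, pointed) polytope fixes enough variables
    at a bound that the remaining ones are uniquely determined by the
    equality system; enumerate all such patterns and keep the feasible ones.
    """
    n = s.shape[1]
    verts: list[np.ndarray] = []
    for k in range(n + 1):
        for free in combinations(range(n), k):
            fixed = [i for i in range(n) if i not in free]
            a = s[:, list(free)]
            if k and np.linalg.matrix_rank(a, tol=1e-9) < k:
                continue  # free block underdetermined: no unique vertex here
            for pattern in product((0, 1), repeat=len(fixed)):
                v = np.zeros(n)
                for i, side in zip(fixed, pattern):
                    v[i] = lb[i] if side == 0 else ub[i]
                if k:
                    b = -s[:, fixed] @ v[fixed] if fixed else np.zeros(s.shape[0])
                    x, *_ = np.linalg.lstsq(a, b, rcond=None)
                    if not np.allclose(a @ x, b, atol=tol):
                        continue
                    v[list(free)] = x
                if ((v >= lb - tol) & (v <= ub + tol)).all() and np.allclose(
                    s @ v, 0.0, atol=tol
                ):
                    verts.append(v)
    return verts


def brute_force_lp(
    s: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    sense: str = "max",
) -> float | None:
    """Optimal objective over the flux polytope, or None when infeasible."""
    verts = enumerate_vertices(s, lb, ub)
    if not verts:
        return None
    vals = [float(c @ v) for v in verts]
    return max(vals) if sense == "max" else min(vals)


def normal_equations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients via (X'X)^{-1} X'y."""
    return np.linalg.solve(x.T @ x, x.T @ y)


def t_pdf(x: float, df: int) -> float:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def t_cdf(x: float, df: int) -> float:
    if x < 0:
        return 1.0 - t_cdf(-x, df)
    tail, _ = quad(t_pdf, x, math.inf, args=(df,))
    return 1.0 - tail


def t_quantile(p: float, df: int) -> float:
    """Upper-tail t quantile (P[T > q] = p) by bisection on the CDF."""
    lo, hi = 0.0, 1e3
    for _ in range(200):
        mid = (lo + hi) / 2
        if t_cdf(mid, df) < 1.0 - p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def random_small_model(rng: np.random.Generator):
    """A random <=6-reaction stoichiometric system with bounds in [-10, 10].

    Returns (S, lb, ub); every reaction touches at least one metabolite.
    """
    n_mets = int(rng.integers(1, 4))
    n_rxns = int(rng.integers(2, 7))
    while True:
        s = rng.integers(-2, 3, size=(n_mets, n_rxns)).astype(float)
        if (np.abs(s).sum(axis=0) > 0).all():
            break
    lo = np.round(rng.uniform(-10, 10, size=n_rxns), 2)
    hi = np.round(rng.uniform(-10, 10, size=n_rxns), 2)
    lb, ub = np.minimum(lo, hi), np.maximum(lo, hi)
    return s, lb, ub
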