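"""Minimal linear-programming contract used by flux balance analysis.

A single entry point, :func:`solve_lp`, takes the objective vector, equality
constraints and variable bounds and returns a status plus one optimal
solution. The default backend is HiGHS through :func:`scipy.optimize.linprog`;
the contract is deliberately small so alternative backends (or the brute
force vertex-enumeration oracle used in the test-suite) can stand behind the
same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

#: primal/dual feasibility tolerance handed to the backend
DEFAULT_TOLERANCE = 1e-9


@dataclass
class LPResult:
    status: str                      # "optimal" | "infeasible" | "unbounded"
    x: np.ndarray | None             # one optimal point (None unless optimal)
    objective: float | None          # value of the *original* objective


def solve_lp(
    c: np.ndarray,
    a_eq: np.ndarray | None,
    b_eq: np.ndarray | None,
    bounds: list[tuple[float, float]],
    sense: str = "max",
    tolerance: float = DEFAULT_TOLERANCE,
) -> LPResult:
    """Solve ``opt c'x  s.t.  a_eq x = b_eq, lb <= x <= ub``.

    ``sense`` is ``"max"`` or ``"min"``. Returns one optimum; alternate
    optima are permitted, only the objective value is contractually unique.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    c = np.asarray(c, dtype=float)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": tolerance,
            "dual_feasibility_tolerance": tolerance,
        },
    )
    if res.status == 0:
        return LPResult("optimal", np.asarray(res.x), float(c @ res.x))
    if res.status == 2:
        return LPResult("infeasible", None, None)
    if res.status == 3:
        return LPResult("unbounded", None, None)
    raise RuntimeError(f"LP backend failure: {res.message}")
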