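"""Shared fixtures and the brute-force LP oracle.

The oracle enumerates vertices of the flux polytope {v : S v = 0,
lb <= v <= ub} directly: every vertex has at least n - rank(S) fluxes
pinned at a bound with the remaining columns linearly independent, so
trying all (subset, lower/upper) assignments and solving the residual
equality system visits every vertex.  All generator bounds are finite,
hence the polytope is bounded and the optimum (when the polytope is
non-empty) is attained at one of them.  The oracle shares no code with
the LP engine.
"""

from __future__ import annotations

import itertools
from typing import Optional, Tuple

import numpy as np
import pytest
from hypothesis import settings

from photogem import MetabolicModel, build_matrix

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def brute_force_lp(
    model: MetabolicModel,
    objective_id: str,
    sense: str = "maximize",
    feas_tol: float = 1e-7,
) -> Tuple[str, Optional[float]]:
    """Optimize by vertex enumeration.  Returns (status, objective value)."""
    sm = build_matrix(model)
    S = sm.to_dense()
    cols = sm.cols
    n = len(cols)
    lb = np.array([model.reactions[r].lower_bound for r in cols])
    ub = np.array([model.reactions[r].upper_bound for r in cols])
    j_obj = cols.index(objective_id)
    rank = int(np.linalg.matrix_rank(S)) if S.size else 0
    n_fixed = n - rank

    best: Optional[float] = None
    sign = 1.0 if sense == "maximize" else -1.0
    for fixed_tuple in itertools.combinations(range(n), n_fixed):
        fixed = list(fixed_tuple)
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free]
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue
        for pattern in itertools.product((0, 1), repeat=n_fixed):
            x = np.empty(n)
            for j, p in zip(fixed, pattern):
                x[j] = lb[j] if p == 0 else ub[j]
            if free:
                rhs = -S[:, fixed] @ x[fixed] if fixed else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                x[free] = sol
            if np.max(np.abs(S @ x)) > feas_tol if S.size else False:
                continue
            if np.any(x < lb - feas_tol) or np.any(x > ub + feas_tol):
                continue
            val = sign * x[j_obj]
            if best is None or val > best:
                best = val
    if best is None:
        return "infeasible", None
    return "optimal", sign * best


@pytest.fixture
def simple_chain_text() -> str:
    return "\n".join([
        "-REACTIONS",
        "E1: A_ext -> A",
        "G: A -> biomass_ext",
        "-CONSTRAINTS",
        "E1 [0, 10]",
        "-OBJ",
        "G 1",
    ]) + "\n"
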