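"""Flux balance analysis by linear programming.

The steady-state assumption S·v = 0 together with per-reaction flux
bounds defines a polytope of admissible flux vectors; FBA picks the one
optimizing a linear objective (usually the biomass drain, whose flux is
the specific growth rate).  Reversible reactions carry free flux within
[-1000, 1000] by default, irreversible ones are confined to v >= 0, and
experimentally constrained fluxes (uptakes in particular) are bounded by
their stated values.

The photoautotrophic simulation is a two-step optimization: maximize
growth with photon uptake unconstrained, then pin growth at that optimum
and minimize the total photon uptake — yielding the smallest light flux
that supports the observed carbon-limited growth.

Internal thermodynamically infeasible loops (futile cycles / Type III
extreme pathways) are detected by closing every exchange reaction and
asking, reaction by reaction, whether any steady-state flux vector still
drives it: in a closed system only internal cycles can carry flux.

Solved with HiGHS through :func:`scipy.optimize.linprog`; FBA optima are
generally degenerate, so callers should rely on objective values and
aggregate quantities rather than individual fluxes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import DEFAULT_BOUND, MetabolicModel, ModelError
from .stoich_audit import build_matrix

logger = logging.getLogger("photogem")

#: Tolerance used when asserting feasibility of reported solutions.
FEASIBILITY_TOL = 1e-6

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
SOLVER_ERROR = "solver_error"

_STATUS_MAP = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


@dataclass
class OptimizationSpec:
    """What to optimize and under which extra bounds.

    ``bound_overrides`` maps reaction id to an (lb, ub) pair replacing
    the model's bounds for this solve only.  ``flux_sum_constraints``
    adds linear equalities sum_i c_i v_i = total over named reactions —
    used e.g. to fix the combined CO2 + HCO3- inorganic-carbon uptake.
    """

    objective_id: str
    sense: str = "maximize"
    bound_overrides: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    flux_sum_constraints: List[Tuple[Dict[str, float], float]] = field(default_factory=list)

    def validate(self, model: MetabolicModel) -> None:
        if self.objective_id not in model.reactions:
            raise ModelError(f"objective {self.objective_id!r} not in model")
        if self.sense not in ("maximize", "minimize"):
            raise ModelError(f"unknown sense {self.sense!r}")
        for rid, (lb, ub) in self.bound_overrides.items():
            if rid not in model.reactions:
                raise ModelError(f"bound override references unknown reaction {rid!r}")
            if lb > ub:
                raise ModelError(f"override on {rid!r}: lb {lb} > ub {ub}")
        for coeffs, _ in self.flux_sum_constraints:
            for rid in coeffs:
                if rid not in model.reactions:
                    raise ModelError(
                        f"sum constraint references unknown reaction {rid!r}")


@dataclass
class FluxSolution:
    """One flux vector with its objective value and solver status."""

    status: str
    objective_id: str
    sense: str
    objective_value: Optional[float] = None
    fluxes: Dict[str, float] = field(default_factory=dict)
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL

    def total(self, reaction_ids: Iterable[str]) -> float:
        return float(sum(self.fluxes[r] for r in reaction_ids))


def _solve(
    model: MetabolicModel,
    c: np.ndarray,
    bounds: List[Tuple[float, float]],
    extra_rows: Optional[List[Tuple[Dict[str, float], float]]] = None,
) -> Tuple[str, Optional[np.ndarray], str]:
    """Minimize c·v subject to S v = 0, bounds, and optional extra equalities."""
    sm = build_matrix(model)
    cols = sm.cols
    A_eq = sm.matrix
    b_eq = np.zeros(A_eq.shape[0])
    if extra_rows:
        col_index = {rid: j for j, rid in enumerate(cols)}
        rows = sparse.lil_matrix((len(extra_rows), len(cols)))
        rhs = np.zeros(len(extra_rows))
        for i, (coeffs, total) in enumerate(extra_rows):
            for rid, coef in coeffs.items():
                rows[i, col_index[rid]] = coef
            rhs[i] = total
        A_eq = sparse.vstack([A_eq, rows.tocsr()])
        b_eq = np.concatenate([b_eq, rhs])
    if A_eq.shape[0] == 0:  # no balanced metabolite and no extra row
        A_eq, b_eq = None, None
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs",
                  options={"presolve": True})
    status = _STATUS_MAP.get(res.status, SOLVER_ERROR)
    return status, (res.x if res.status == 0 else None), res.message or ""


def solve_fba(model: MetabolicModel, spec: OptimizationSpec) -> FluxSolution:
    """Optimize one reaction's flux at steady state.

    Returns an :class:`FluxSolution` whose status faithfully reports
    infeasibility/unboundedness — a failed solve is never a silent zero.
    On success the solution satisfies max |S·v| <= 1e-6 and all bounds.
    """
    spec.validate(model)
    cols = list(model.reactions)
    bounds = []
    for rid in cols:
        rxn = model.reactions[rid]
        bounds.append(spec.bound_overrides.get(rid, (rxn.lower_bound, rxn.upper_bound)))
    c = np.zeros(len(cols))
    j = cols.index(spec.objective_id)
    c[j] = -1.0 if spec.sense == "maximize" else 1.0

    status, x, message = _solve(model, c, bounds, spec.flux_sum_constraints or None)
    if status != OPTIMAL:
        logger.info("FBA %s on %s: %s", spec.sense, spec.objective_id, status)
        return FluxSolution(status=status, objective_id=spec.objective_id,
                            sense=spec.sense, message=message)
    fluxes = {rid: float(v) for rid, v in zip(cols, x)}
    for rid, v in fluxes.items():
        if abs(abs(v) - DEFAULT_BOUND) < 1e-9:
            logger.info("flux %s hit the default bound magnitude %g", rid, DEFAULT_BOUND)
    return FluxSolution(status=OPTIMAL, objective_id=spec.objective_id,
                        sense=spec.sense, objective_value=fluxes[spec.objective_id],
                        fluxes=fluxes, message=message)


# ---------------------------------------------------------------------------
# Two-step photoautotrophic optimization
# ---------------------------------------------------------------------------

#: Relative slack when pinning the step-1 optimum in step 2; exact
#: fixing invites numerical infeasibility.
GROWTH_EPSILON = 1e-6


def two_step_photoautotrophic(
    model: MetabolicModel,
    photon_reactions: Sequence[str],
    carbon_uptake: Optional[float] = None,
    carbon_reactions: Optional[Sequence[str]] = None,
    combined_carbon: bool = True,
    objective_id: Optional[str] = None,
    epsilon: float = GROWTH_EPSILON,
) -> Tuple[FluxSolution, FluxSolution]:
    """Maximize growth with light unconstrained, then minimize photon uptake.

    Step 1 maximizes the biomass objective with every photon uptake
    reaction bounded only by the default magnitude.  Step 2 pins the
    biomass flux to (1 - epsilon) x the step-1 optimum and minimizes the
    *summed* flux through ``photon_reactions``; per-photosystem values
    can be read off the returned solution.

    The inorganic-carbon uptake, when given, is fixed either as the
    combined sum over ``carbon_reactions`` (default) or as an individual
    upper bound on each of them.

    Raises :class:`ModelError` when step 1 is not optimal; step-2
    infeasibility at epsilon is retried once at 10x epsilon.
    """
    if not photon_reactions:
        raise ModelError("photon_reactions must be non-empty")
    for rid in photon_reactions:
        if rid not in model.reactions:
            raise ModelError(f"photon reaction {rid!r} not in model")
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ModelError("no objective reaction given")

    overrides: Dict[str, Tuple[float, float]] = {
        rid: (0.0, DEFAULT_BOUND) for rid in photon_reactions}
    sums: List[Tuple[Dict[str, float], float]] = []
    if carbon_uptake is not None:
        if not carbon_reactions:
            raise ModelError("carbon_uptake given without carbon_reactions")
        if combined_carbon:
            sums.append(({rid: 1.0 for rid in carbon_reactions}, carbon_uptake))
        else:
            for rid in carbon_reactions:
                overrides[rid] = (0.0, carbon_uptake)

    step1 = solve_fba(model, OptimizationSpec(
        objective_id=objective_id, sense="maximize",
        bound_overrides=dict(overrides), flux_sum_constraints=list(sums)))
    if not step1.optimal:
        raise ModelError(f"two-step aborted: growth maximization {step1.status} "
                         f"({step1.message})")
    growth = step1.objective_value

    def _step2(eps: float) -> FluxSolution:
        ov = dict(overrides)
        ov[objective_id] = ((1.0 - eps) * growth, growth + abs(growth) * eps)
        # minimize summed photon uptake: use an auxiliary objective over
        # the photon columns via a sum constraint-free LP with custom c
        spec = OptimizationSpec(objective_id=photon_reactions[0], sense="minimize",
                                bound_overrides=ov, flux_sum_constraints=list(sums))
        spec.validate(model)
        cols = list(model.reactions)
        bounds = [ov.get(rid, (model.reactions[rid].lower_bound,
                               model.reactions[rid].upper_bound)) for rid in cols]
        c = np.zeros(len(cols))
        for rid in photon_reactions:
            c[cols.index(rid)] = 1.0
        status, x, message = _solve(model, c, bounds, sums or None)
        if status != OPTIMAL:
            return FluxSolution(status=status, objective_id="photon_total",
                                sense="minimize", message=message)
        fluxes = {rid: float(v) for rid, v in zip(cols, x)}
        total = sum(fluxes[r] for r in photon_reactions)
        return FluxSolution(status=OPTIMAL, objective_id="photon_total",
                            sense="minimize", objective_value=float(total),
                            fluxes=fluxes)

    step2 = _step2(epsilon)
    if not step2.optimal:
        logger.warning("step 2 %s at epsilon %g; retrying at %g",
                       step2.status, epsilon, 10 * epsilon)
        step2 = _step2(10 * epsilon)
    if not step2.optimal:
        raise ModelError(f"two-step aborted: photon minimization {step2.status} "
                         f"({step2.message})")
    return step1, step2


# ---------------------------------------------------------------------------
# Internal-loop detection
# ---------------------------------------------------------------------------

def detect_internal_loops(model: MetabolicModel, tol: float = FEASIBILITY_TOL) -> Set[str]:
    """Reactions able to carry flux with every exchange closed.

    All exchange reactions (columns touching an external metabolite, or
    single-participant columns) are constrained to zero; each remaining
    reaction's flux is maximized and minimized.  Any reaction with
    attainable |flux| > tol belongs to a thermodynamically infeasible
    internal cycle.  The result is invariant under reaction order.
    """
    if not model.reactions:
        return set()
    exchanges = set(model.exchange_reactions())
    overrides = {rid: (0.0, 0.0) for rid in exchanges}
    flagged: Set[str] = set()
    for rid in model.reactions:
        if rid in exchanges:
            continue
        for sense in ("maximize", "minimize"):
            sol = solve_fba(model, OptimizationSpec(
                objective_id=rid, sense=sense, bound_overrides=dict(overrides)))
            if sol.optimal and abs(sol.objective_value) > tol:
                flagged.add(rid)
                break
    return flagged


# ---------------------------------------------------------------------------
# Solution serialisation
# ---------------------------------------------------------------------------

def solution_tsv(solution: FluxSolution) -> str:
    lines = ["reaction\tflux"]
    for rid, v in solution.fluxes.items():
        lines.append(f"{rid}\t{v:.10g}")
    return "\n".join(lines) + "\n"


def solution_summary(solution: FluxSolution) -> Dict[str, object]:
    return {"status": solution.status, "objective_id": solution.objective_id,
            "sense": solution.sense, "objective_value": solution.objective_value}
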