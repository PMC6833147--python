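"""Linear-programming core: flux balance analysis and its derivatives.

FBA solves  max (or min) v_obj  s.t.  S v = 0,  lb <= v <= ub,
where S is the stoichiometric matrix (metabolites x reactions).  The dual
solution gives shadow prices (per metabolite balance) and reduced costs
(per flux bound); both are reported on the scale of the *stated* objective,
i.e. for a maximisation the reduced cost of a bound is d(max objective)/
d(bound) at the binding bound and 0 for interior variables.

The solver is HiGHS via scipy.optimize.linprog, run single-threaded with
a fixed configuration so that repeated solves are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csc_matrix

from .gem_core import Model, Reaction

FLUX_ZERO_TOL = 1e-6  # mmol/gDW/h; below this a flux is "zero"
FEASIBILITY_TOL = 1e-9


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)
    reduced_costs: dict[str, float] = field(default_factory=dict)
    shadow_prices: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def stoichiometric_matrix(model: Model):
    """S as a sparse CSC matrix plus the row/column id orderings."""
    met_ids = model.metabolite_ids
    rxn_ids = model.reaction_ids
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for mid, coeff in rxn.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            data.append(coeff)
    S = csc_matrix(
        (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids)), dtype=float
    )
    return S, met_ids, rxn_ids


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def _solve(model: Model, c: np.ndarray, sense: float):
    """Minimise sense*c.v over the flux polytope.  Returns the raw scipy
    result plus orderings; callers translate duals back to the stated sense."""
    S, met_ids, rxn_ids = stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(
        sense * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"presolve": True},
    )
    return res, met_ids, rxn_ids


def solve_fba(
    model: Model, objective: str | None = None, direction: str = "max"
) -> FluxSolution:
    """Flux balance analysis.

    Parameters
    ----------
    objective:
        Reaction id to optimise; defaults to the model's objective reaction.
    direction:
        ``"max"`` or ``"min"``.

    Infeasibility and unboundedness are reported in ``status``, never
    raised.
    """
    if objective is None:
        objective = model.objective_reaction
    if objective is None:
        raise ValueError("no objective reaction given and model declares none")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    rxn_ids = model.reaction_ids
    try:
        j_obj = rxn_ids.index(objective)
    except ValueError:
        raise KeyError(f"unknown objective reaction {objective!r}") from None
    c = np.zeros(len(rxn_ids))
    c[j_obj] = 1.0
    sense = -1.0 if direction == "max" else 1.0
    res, met_ids, rxn_ids = _solve(model, c, sense)
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxSolution(status=status)
    fluxes = dict(zip(rxn_ids, res.x))
    # scipy reports duals for the minimisation problem; flip to the stated
    # objective's scale.  reduced cost = d(obj)/d(bound) at the binding bound.
    rc = sense * (np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals))
    sp = sense * np.asarray(res.eqlin.marginals)
    return FluxSolution(
        status="optimal",
        objective=float(-res.fun) if direction == "max" else float(res.fun),
        fluxes=fluxes,
        reduced_costs=dict(zip(rxn_ids, rc)),
        shadow_prices=dict(zip(met_ids, sp)),
    )


def _with_objective_floor(model: Model, fraction: float, mu_max: float) -> Model:
    """Copy of the model with v_objective >= fraction * mu_max."""
    fixed = model.copy()
    obj = fixed.reaction(fixed.objective_reaction)
    obj.lower_bound = max(obj.lower_bound, fraction * mu_max)
    return fixed


def flux_variability(
    model: Model,
    reactions: list[str] | None = None,
    growth_fraction: float = 0.0,
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux min/max subject to v_obj >= fraction * mu_max.

    Raises if the base FBA is not optimal (FVA is undefined then).
    """
    base = solve_fba(model)
    if not base.optimal:
        raise RuntimeError(f"FVA requires an optimal base solution, got {base.status}")
    fixed = _with_objective_floor(model, growth_fraction, base.objective)
    rxn_ids = fixed.reaction_ids
    targets = reactions if reactions is not None else rxn_ids
    index = {r: j for j, r in enumerate(rxn_ids)}
    out: dict[str, tuple[float, float]] = {}
    n = len(rxn_ids)
    for rid in targets:
        j = index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo_res, _, _ = _solve(fixed, c, 1.0)
        hi_res, _, _ = _solve(fixed, c, -1.0)
        if lo_res.status != 0 or hi_res.status != 0:
            raise RuntimeError(f"FVA subproblem for {rid} not optimal")
        out[rid] = (float(lo_res.x[j]), float(hi_res.x[j]))
    return out


def zero_flux_reactions(
    model: Model, growth_fraction: float = 0.0, tol: float = FLUX_ZERO_TOL
) -> set[str]:
    """Reactions whose flux is zero over the whole feasible space at the
    given growth fraction (FVA min = max = 0 within tolerance)."""
    fva = flux_variability(model, growth_fraction=growth_fraction)
    return {rid for rid, (lo, hi) in fva.items() if abs(lo) <= tol and abs(hi) <= tol}


def add_demand(model: Model, metabolite_id: str) -> tuple[Model, str]:
    """Return a copy of the model with an irreversible sink
    ``DM_<met>: met -> (bounds [0, 1000])``; idempotent."""
    if not model.has_metabolite(metabolite_id):
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    dm_id = f"DM_{metabolite_id}"
    if model.has_reaction(dm_id):
        return model, dm_id
    new = model.copy()
    new.reactions.append(
        Reaction(
            dm_id,
            name=f"Demand for {metabolite_id}",
            stoichiometry={metabolite_id: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        )
    )
    return new, dm_id


def producibility(model: Model, metabolite_id: str, tol: float = FLUX_ZERO_TOL):
    """Maximal production flux of a metabolite (max of its demand sink).

    Returns ``(flux, producible)``; unbounded production reports inf.
    """
    with_dm, dm_id = add_demand(model, metabolite_id)
    sol = solve_fba(with_dm, objective=dm_id, direction="max")
    if sol.status == "unbounded":
        return float("inf"), True
    if not sol.optimal:
        return 0.0, False
    return sol.objective, sol.objective > tol


def finite_difference_check(
    model: Model,
    objective: str,
    exchange_id: str,
    delta: float = 1e-3,
    bound: str = "lower",
) -> tuple[float, float]:
    """Compare a reported reduced cost with the empirical objective slope.

    Relaxes the named bound of ``exchange_id`` by ``delta`` (lower bound
    decreases, upper bound increases) and re-solves.  Returns
    ``(reduced_cost, empirical_slope)`` where slope = d(objective)/d(relaxation).
    For small delta within one LP basis the two agree; a delta large enough
    to change the optimal basis makes the slope an underestimate.
    """
    base = solve_fba(model, objective=objective, direction="max")
    if not base.optimal:
        raise RuntimeError("base solution not optimal")
    rc = base.reduced_costs[exchange_id]
    bumped = model.copy()
    rxn = bumped.reaction(exchange_id)
    if bound == "lower":
        rxn.lower_bound -= delta
    else:
        rxn.upper_bound += delta
    new = solve_fba(bumped, objective=objective, direction="max")
    if not new.optimal:
        raise RuntimeError("perturbed solution not optimal")
    slope = (new.objective - base.objective) / delta
    return rc, slope
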