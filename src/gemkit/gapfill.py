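"""Minimal-addition gap filling against a universal reaction pool.

Given a model that cannot produce a target metabolite in a medium, find
the smallest set of pool reactions whose addition makes the target
producible (demand flux >= epsilon).  Formulated as a MILP with one binary
indicator per pool reaction; among equal-cardinality optima the
lexicographically smallest id set is returned, which makes results
deterministic and testable against exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import milp, LinearConstraint, Bounds
from scipy.sparse import lil_matrix

from .fba import add_demand, producibility
from .gem_core import Metabolite, Model, Reaction
from .model_io import MediumDefinition, apply_medium

PRODUCIBILITY_EPS = 0.01  # mmol/gDW/h demand flux deemed "producible"


class UnfillableError(RuntimeError):
    """No subset of the pool restores producibility of the target."""

    def __init__(self, target: str, dead_ends: list[str]):
        msg = f"target {target!r} cannot be made producible from the pool"
        if dead_ends:
            msg += f"; non-producible upstream metabolites: {dead_ends}"
        super().__init__(msg)
        self.target = target
        self.dead_ends = dead_ends


@dataclass
class UniversalPool:
    """Candidate reactions for gap filling, with provenance tags
    (template model, reference database...) for downstream human review."""

    reactions: list[Reaction]
    provenance: dict[str, str] = field(default_factory=dict)

    def validate_against(self, model: Model) -> None:
        clash = {r.id for r in self.reactions} & set(model.reaction_ids)
        if clash:
            raise ValueError(f"pool reaction ids already in model: {sorted(clash)}")


def augment(model: Model, pool: UniversalPool, selected: set[str]) -> Model:
    """Model plus the selected pool reactions (missing metabolites are
    added to the cytosol-like compartment of their id suffix, default c)."""
    new = model.copy()
    for rxn in pool.reactions:
        if rxn.id not in selected:
            continue
        for mid in rxn.stoichiometry:
            if not new.has_metabolite(mid):
                comp = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
                if comp not in new.compartments:
                    new.compartments[comp] = comp
                new.metabolites.append(Metabolite(mid, compartment=comp))
        new.reactions.append(rxn.copy())
    new.validate()
    return new


def _producible_with(
    model: Model, pool: UniversalPool, selected: set[str], target: str, eps: float
) -> bool:
    aug = augment(model, pool, selected)
    if not aug.has_metabolite(target):
        return False
    flux, _ = producibility(aug, target)
    return flux > eps * 0.999  # guard against solver round-off at the threshold


def _milp_min_additions(
    model: Model,
    pool: UniversalPool,
    target: str,
    eps: float,
    forced_in: set[str],
    forced_out: set[str],
    cardinality: int | None = None,
):
    """Solve min sum(y) s.t. S v = 0, demand(target) >= eps, pool fluxes
    gated by binaries.  Returns the selected id set or None if infeasible."""
    full = augment(model, pool, {r.id for r in pool.reactions})
    full, dm_id = add_demand(full, target)
    rxn_ids = full.reaction_ids
    met_ids = full.metabolite_ids
    met_index = {m: i for i, m in enumerate(met_ids)}
    n_v = len(rxn_ids)
    pool_ids = sorted(r.id for r in pool.reactions)
    pool_pos = {rid: k for k, rid in enumerate(pool_ids)}
    n_y = len(pool_ids)
    n = n_v + n_y

    A = lil_matrix((len(met_ids) + 2 * n_y + (1 if cardinality is not None else 0), n))
    lb_con = np.zeros(A.shape[0])
    ub_con = np.zeros(A.shape[0])

    for j, rxn in enumerate(full.reactions):
        for mid, coeff in rxn.stoichiometry.items():
            A[met_index[mid], j] = coeff
    # S v = 0 rows already have lb = ub = 0

    lb_v = np.array([r.lower_bound for r in full.reactions])
    ub_v = np.array([r.upper_bound for r in full.reactions])

    row = len(met_ids)
    for rid in pool_ids:
        j = rxn_ids.index(rid)
        k = pool_pos[rid]
        # v_j - ub_j * y_k <= 0
        A[row, j] = 1.0
        A[row, n_v + k] = -ub_v[j]
        lb_con[row] = -np.inf
        ub_con[row] = 0.0
        row += 1
        # v_j - lb_j * y_k >= 0
        A[row, j] = 1.0
        A[row, n_v + k] = -lb_v[j]
        lb_con[row] = 0.0
        ub_con[row] = np.inf
        row += 1
    if cardinality is not None:
        A[row, n_v:] = 1.0
        lb_con[row] = cardinality
        ub_con[row] = cardinality

    # demand flux floor enforces producibility
    j_dm = rxn_ids.index(dm_id)
    lb_v = lb_v.copy()
    lb_v[j_dm] = eps

    lb_y = np.zeros(n_y)
    ub_y = np.ones(n_y)
    for rid in forced_in:
        lb_y[pool_pos[rid]] = 1.0
    for rid in forced_out:
        ub_y[pool_pos[rid]] = 0.0

    c = np.concatenate([np.zeros(n_v), np.ones(n_y)])
    integrality = np.concatenate([np.zeros(n_v), np.ones(n_y)])
    res = milp(
        c,
        constraints=LinearConstraint(A.tocsc(), lb_con, ub_con),
        bounds=Bounds(np.concatenate([lb_v, lb_y]), np.concatenate([ub_v, ub_y])),
        integrality=integrality,
    )
    if res.status != 0:
        return None
    y = res.x[n_v:]
    return {rid for rid, k in pool_pos.items() if y[k] > 0.5}


def fill_gaps(
    model: Model,
    pool: UniversalPool,
    target: str,
    medium: MediumDefinition | None = None,
    eps: float = PRODUCIBILITY_EPS,
) -> set[str]:
    """Smallest set of pool reaction ids making ``target`` producible.

    Returns the empty set if the target is already producible in the
    medium.  Among equal-cardinality optima the lexicographically smallest
    id set is chosen (greedy force-in over sorted ids, each step a MILP
    feasibility check).  Raises :class:`UnfillableError` when even the full
    pool does not help, with a diagnostic list of non-producible
    metabolites upstream of the target.
    """
    pool.validate_against(model)
    base = apply_medium(model, medium) if medium is not None else model
    if base.has_metabolite(target):
        flux, _ = producibility(base, target)
        if flux > eps * 0.999:
            return set()
    if not _producible_with(base, pool, {r.id for r in pool.reactions}, target, eps):
        full = augment(base, pool, {r.id for r in pool.reactions})
        dead = _upstream_dead_ends(full, target, eps)
        raise UnfillableError(target, dead)

    first = _milp_min_additions(base, pool, target, eps, set(), set())
    if first is None:  # full pool worked but MILP infeasible: should not happen
        raise UnfillableError(target, [])
    k = len(first)
    # lexicographically smallest size-k solution: greedily force each id IN
    # (sorted order) whenever a size-k completion containing it still exists
    chosen: set[str] = set()
    excluded: set[str] = set()
    for rid in sorted(r.id for r in pool.reactions):
        trial = _milp_min_additions(
            base, pool, target, eps, chosen | {rid}, excluded, cardinality=k
        )
        if trial is not None:
            chosen.add(rid)
        else:
            excluded.add(rid)
        if len(chosen) == k:
            break
    return chosen


def _upstream_dead_ends(full: Model, target: str, eps: float) -> list[str]:
    """Metabolites feeding the target's producers that are themselves not
    producible even with the full pool — the likely true gaps."""
    if not full.has_metabolite(target):
        return [target]
    upstream: set[str] = set()
    for rxn in full.reactions:
        coeff = rxn.stoichiometry.get(target)
        if coeff is None:
            continue
        if (coeff > 0 and rxn.upper_bound > 0) or (coeff < 0 and rxn.lower_bound < 0):
            sign = 1.0 if coeff > 0 else -1.0
            for mid, c in rxn.stoichiometry.items():
                if mid != target and sign * c < 0:
                    upstream.add(mid)
    dead = []
    for mid in sorted(upstream):
        flux, ok = producibility(full, mid)
        if not ok:
            dead.append(mid)
    return dead


def fill_gaps_per_component(
    model: Model,
    pool: UniversalPool,
    components: list[str],
    medium: MediumDefinition | None = None,
    eps: float = PRODUCIBILITY_EPS,
) -> dict[str, set[str]]:
    """Gap-fill each biomass component separately, in order, against the
    incrementally augmented model.  A reaction added for an earlier
    component is available (at no cost) to later ones, so shared gaps are
    attributed to the first component that needed them."""
    current = apply_medium(model, medium) if medium is not None else model.copy()
    remaining = UniversalPool(list(pool.reactions), dict(pool.provenance))
    added: dict[str, set[str]] = {}
    for comp in components:
        try:
            s = fill_gaps(current, remaining, comp, medium=None, eps=eps)
        except UnfillableError as exc:
            raise UnfillableError(comp, exc.dead_ends) from exc
        added[comp] = s
        if s:
            current = augment(current, remaining, s)
            remaining = UniversalPool(
                [r for r in remaining.reactions if r.id not in s],
                {k: v for k, v in remaining.provenance.items() if k not in s},
            )
    return added
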