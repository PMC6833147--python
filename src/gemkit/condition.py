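"""Condition-specific model extraction from replicate expression data.

A gene is called inactive in a condition when it has a recorded value in
every replicate of that condition and all of them are exactly zero — no
abundance threshold is applied, and a gene missing from the table counts
as active ("no evidence" is not evidence of absence).  Reactions whose
GPR evaluates false under the inactive set are shut (bounds 0,0); every
other constraint is left intact.

Auxotrophies are biomass components that the condition model can no
longer produce; they are rescued by assuming the medium supplies them
(exchange + transport into the component's compartment), mirroring how a
rich medium masks a broken biosynthetic pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fba import FLUX_ZERO_TOL, producibility, solve_fba, zero_flux_reactions
from .gem_core import Metabolite, Model, Reaction, evaluate_gpr
from .model_io import ExpressionSet, MediumDefinition, apply_medium


@dataclass
class ConditionModel:
    base_model_id: str
    condition: str
    model: Model
    inactive_genes: set[str] = field(default_factory=set)
    deactivated_reactions: set[str] = field(default_factory=set)
    rescued_metabolites: set[str] = field(default_factory=set)


def call_inactive_genes(expr: ExpressionSet, condition: str) -> set[str]:
    """Genes with zero expression in all replicates of the condition."""
    if condition not in expr.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    n_rep = expr.n_replicates[condition]
    inactive: set[str] = set()
    for g in expr.genes:
        vals = expr.replicate_values(g, condition)
        if vals is None or len(vals) < n_rep:
            continue  # missing evidence -> active
        if all(v == 0 for v in vals):
            inactive.add(g)
    return inactive


def inactive_in_any_condition(
    expr: ExpressionSet, conditions: list[str] | None = None
) -> set[str]:
    """Union of per-condition inactive calls — genes off in >= 1 condition."""
    conds = conditions if conditions is not None else expr.conditions
    out: set[str] = set()
    for cond in conds:
        out |= call_inactive_genes(expr, cond)
    return out


def derive_condition_model(
    model: Model, inactive: set[str], condition: str = ""
) -> ConditionModel:
    """Deactivate reactions whose GPR is false under the inactive gene set.

    Inactive ids not present in the model are ignored.  Spontaneous
    reactions (no GPR) are never deactivated.
    """
    relevant = inactive & model.genes
    new = model.copy()
    deactivated: set[str] = set()
    for rxn in new.reactions:
        if rxn.gpr is None:
            continue
        if not evaluate_gpr(rxn.gpr, relevant):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
            deactivated.add(rxn.id)
    return ConditionModel(
        base_model_id=model.id,
        condition=condition,
        model=new,
        inactive_genes=relevant,
        deactivated_reactions=deactivated,
    )


def condition_models_from_expression(
    model: Model, expr: ExpressionSet, conditions: list[str]
) -> dict[str, ConditionModel]:
    return {
        cond: derive_condition_model(model, call_inactive_genes(expr, cond), cond)
        for cond in conditions
    }


def detect_auxotrophies(
    cm: ConditionModel,
    components: list[str],
    medium: MediumDefinition | None = None,
    tol: float = FLUX_ZERO_TOL,
) -> set[str]:
    """Biomass components the condition model cannot produce in the medium."""
    m = apply_medium(cm.model, medium) if medium is not None else cm.model
    out: set[str] = set()
    for comp in components:
        flux, ok = producibility(m, comp, tol=tol)
        if not ok:
            out.add(comp)
    return out


def rescue_auxotrophies(
    cm: ConditionModel,
    aux: set[str],
    extracellular: str = "e",
    uptake_bound: float = 1000.0,
) -> ConditionModel:
    """Assume the medium supplies each auxotrophic metabolite.

    For each metabolite: ensure an extracellular counterpart, an exchange
    reaction with uptake open, and a transport reaction into the
    metabolite's own compartment.  Idempotent; rescuing the empty set is
    the identity.
    """
    new = cm.model.copy()
    if aux and extracellular not in new.compartments:
        new.compartments[extracellular] = "extracellular"
    for mid in sorted(aux):
        met = new.metabolite(mid)
        base = mid[: -len(met.compartment) - 1] if mid.endswith(f"_{met.compartment}") else mid
        ext_id = f"{base}_{extracellular}"
        if not new.has_metabolite(ext_id):
            new.metabolites.append(
                Metabolite(ext_id, name=met.name, compartment=extracellular,
                           formula=dict(met.formula), charge=met.charge)
            )
        ex_id = f"EX_{base}"
        if new.has_reaction(ex_id):
            rxn = new.reaction(ex_id)
            rxn.lower_bound = min(rxn.lower_bound, -uptake_bound)
        else:
            new.reactions.append(
                Reaction(ex_id, name=f"{base} exchange",
                         stoichiometry={ext_id: -1.0},
                         lower_bound=-uptake_bound, upper_bound=1000.0)
            )
        tr_id = f"T_rescue_{base}"
        if not new.has_reaction(tr_id):
            new.reactions.append(
                Reaction(tr_id, name=f"{base} rescue transport",
                         stoichiometry={ext_id: -1.0, mid: 1.0},
                         lower_bound=0.0, upper_bound=1000.0)
            )
    new.validate()
    return ConditionModel(
        base_model_id=cm.base_model_id,
        condition=cm.condition,
        model=new,
        inactive_genes=set(cm.inactive_genes),
        deactivated_reactions=set(cm.deactivated_reactions),
        rescued_metabolites=set(cm.rescued_metabolites) | set(aux),
    )


def condition_report(
    models: list[ConditionModel], growth_fraction: float = 0.9
) -> pd.DataFrame:
    """Per-condition summary: inactive genes, deactivated reactions,
    zero-flux reactions at the growth fraction, rescued auxotrophies and
    the growth-limiting uptake exchange (largest |reduced cost| among
    uptake exchanges at the growth optimum)."""
    rows = []
    base_ids = {cm.base_model_id for cm in models}
    if len(base_ids) > 1:
        raise ValueError(f"condition models from different bases: {sorted(base_ids)}")
    for cm in models:
        sol = solve_fba(cm.model)
        limiting = ""
        n_zero = None
        if sol.optimal and sol.objective > FLUX_ZERO_TOL:
            uptake_rcs = {
                r.id: sol.reduced_costs[r.id]
                for r in cm.model.exchanges()
                if r.lower_bound < 0
            }
            if uptake_rcs:
                limiting = max(uptake_rcs, key=lambda k: abs(uptake_rcs[k]))
                if abs(uptake_rcs[limiting]) <= FLUX_ZERO_TOL:
                    limiting = ""
            n_zero = len(zero_flux_reactions(cm.model, growth_fraction))
        rows.append(
            {
                "condition": cm.condition,
                "growth_rate": sol.objective if sol.optimal else 0.0,
                "n_inactive_genes": len(cm.inactive_genes),
                "n_deactivated_reactions": len(cm.deactivated_reactions),
                "n_zero_flux_reactions": n_zero,
                "auxotrophies": ";".join(sorted(cm.rescued_metabolites)),
                "limiting_exchange": limiting,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition", "growth_rate", "n_inactive_genes",
            "n_deactivated_reactions", "n_zero_flux_reactions",
            "auxotrophies", "limiting_exchange",
        ],
    )
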