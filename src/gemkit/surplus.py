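"""Surplus production capacity of biomass precursors at fixed growth.

For each precursor: solve for the maximal growth rate, clamp the biomass
reaction to a fraction of it (lower = upper bound, so precursor secretion
cannot be traded against extra growth), then maximise a demand sink for
the precursor.  The optimum is the flux the network could divert to that
precursor on top of what growth already consumes.

Across conditions, absolute surpluses are normalised per metabolite to
the largest value (100%), matching how multi-condition capacity profiles
are usually drawn (radar charts).
"""

from __future__ import annotations

import pandas as pd

from .condition import ConditionModel
from .fba import add_demand, producibility, solve_fba
from .gem_core import Model


class NoGrowthError(RuntimeError):
    pass


def surplus_capacity(model: Model, component: str, fraction: float = 0.9) -> float:
    """Max production flux of ``component`` with biomass fixed at
    ``fraction`` of its maximum.  fraction=0 reduces to plain
    producibility; fraction=1 measures slack at the growth optimum."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    base = solve_fba(model)
    if not base.optimal or base.objective <= 1e-9:
        raise NoGrowthError("no growth, surplus undefined")
    fixed = model.copy()
    obj = fixed.reaction(fixed.objective_reaction)
    # back off marginally from the exact optimum so the clamped LP stays
    # feasible under solver round-off
    mu = fraction * base.objective * (1 - 1e-9)
    obj.lower_bound = mu
    obj.upper_bound = mu
    with_dm, dm_id = add_demand(fixed, component)
    sol = solve_fba(with_dm, objective=dm_id, direction="max")
    if not sol.optimal:
        raise RuntimeError(
            f"surplus LP for {component} at fraction {fraction}: {sol.status}"
        )
    return sol.objective if sol.objective > 0.0 else 0.0


def surplus_table(
    models: list[ConditionModel],
    components: list[str],
    fraction: float = 0.9,
) -> pd.DataFrame:
    """Absolute and relative surplus per (condition, component).

    relative % = 100 * absolute / max-over-conditions for that component;
    an all-zero component reports 0% everywhere.  Per-cell failures (e.g.
    a condition that cannot grow) are recorded with a reason and excluded
    from the normalisation.
    """
    rows = []
    for cm in models:
        for comp in components:
            try:
                abs_surplus = surplus_capacity(cm.model, comp, fraction)
                reason = ""
            except (NoGrowthError, KeyError, RuntimeError) as exc:
                abs_surplus = None
                reason = str(exc)
            rows.append(
                {
                    "condition": cm.condition,
                    "metabolite": comp,
                    "absolute_surplus": abs_surplus,
                    "reason": reason,
                }
            )
    df = pd.DataFrame(rows)
    df = df.sort_values(["metabolite", "condition"], kind="stable")
    df["relative_pct"] = _relative_by_group(df)
    df = df.reset_index(drop=True)
    df.attrs["growth_fraction"] = fraction
    return df[["condition", "metabolite", "absolute_surplus", "relative_pct", "reason"]]


def _relative_by_group(df: pd.DataFrame) -> list[float | None]:
    out: list[float | None] = []
    peaks = df.groupby("metabolite")["absolute_surplus"].transform("max")
    for val, peak in zip(df["absolute_surplus"], peaks):
        if val is None or pd.isna(val):
            out.append(None)
        elif pd.isna(peak) or peak <= 0:
            out.append(0.0)
        else:
            out.append(100.0 * val / peak)
    return out
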