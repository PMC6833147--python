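"""Growth phenotype prediction: sole-source screens and rate accuracy.

A sole-source screen asks whether the model grows when a single carbon
(or nitrogen) source replaces the default one in a minimal medium; the
binary call is compared with literature observations.  Rate prediction
clamps a substrate exchange to a measured uptake rate and reports the
FBA growth optimum; agreement across substrates is summarised by the
Pearson correlation between observed and predicted rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fba import solve_fba
from .gem_core import Model
from .model_io import MediumDefinition, apply_medium

GROWTH_THRESHOLD = 1e-4  # h^-1: below this, the binary call is "no-growth"
DEFAULT_UPTAKE = 10.0  # mmol/gDW/h allowed for the varied substrate


@dataclass
class PhenotypeResult:
    substrate: str  # exchange reaction id
    role: str  # carbon | nitrogen
    predicted_growth: float
    call: str  # growth | no-growth
    observed: str = "unknown"  # growth | no-growth | unknown
    agreement: bool | None = None
    flag: str = ""


def sole_source_screen(
    model: Model,
    medium_base: MediumDefinition,
    substrates: list[tuple[str, str]],
    default_source: dict[str, str] | None = None,
    uptake: float = DEFAULT_UPTAKE,
    observations: dict[str, str] | None = None,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> list[PhenotypeResult]:
    """Test growth on each substrate as the sole source of its role.

    ``medium_base`` carries the non-varied components (salts; and the
    default carbon source, kept open when testing nitrogen sources).
    ``default_source`` maps role -> exchange id to close while that role
    is being varied.  A substrate whose exchange reaction is absent from
    the model is reported as no-growth with a "no transporter/exchange"
    flag rather than an error — missing uptake machinery is itself the
    in-silico explanation for a negative phenotype.
    """
    default_source = default_source or {}
    observations = observations or {}
    results = []
    for ex_id, role in substrates:
        medium = MediumDefinition(
            name=f"{medium_base.name}+{ex_id}",
            bounds=dict(medium_base.bounds),
        )
        closed = default_source.get(role)
        if closed and closed in medium.bounds and closed != ex_id:
            lo, hi = medium.bounds[closed]
            medium.bounds[closed] = (0.0, hi if hi >= 0 else 0.0)
        if model.has_reaction(ex_id):
            prior = medium.bounds.get(ex_id, (0.0, 1000.0))
            medium.bounds[ex_id] = (-abs(uptake), prior[1])
            sol = solve_fba(apply_medium(model, medium))
            mu = sol.objective if sol.optimal else 0.0
            flag = "" if sol.optimal else sol.status
        else:
            mu = 0.0
            flag = "no transporter/exchange"
        call = "growth" if mu > growth_threshold else "no-growth"
        obs = observations.get(ex_id, "unknown")
        results.append(
            PhenotypeResult(
                substrate=ex_id,
                role=role,
                predicted_growth=mu,
                call=call,
                observed=obs,
                agreement=(call == obs) if obs != "unknown" else None,
                flag=flag,
            )
        )
    return results


def predict_growth_at_uptake(model: Model, exchange_id: str, uptake: float) -> float:
    """Max growth with the substrate exchange clamped to the measured
    uptake rate (lower = upper bound = -uptake).  Infeasibility (e.g.
    maintenance unsatisfiable at that uptake) reports 0."""
    if uptake < 0:
        raise ValueError(f"uptake must be >= 0, got {uptake}")
    clamped = model.copy()
    rxn = clamped.reaction(exchange_id)
    rxn.lower_bound = -uptake
    rxn.upper_bound = -uptake
    sol = solve_fba(clamped)
    return sol.objective if sol.optimal else 0.0


def correlation_report(observed, predicted) -> dict:
    """Pearson r and r^2 between observed and predicted growth rates,
    with per-point residuals.  Zero variance in either vector makes the
    correlation undefined (reported as None)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    if obs.size < 3:
        raise ValueError(f"need >= 3 points, got {obs.size}")
    residuals = (pred - obs).tolist()
    if np.std(obs) == 0 or np.std(pred) == 0:
        return {"pearson_r": None, "r_squared": None, "residuals": residuals}
    r = float(np.corrcoef(obs, pred)[0, 1])
    return {"pearson_r": r, "r_squared": r * r, "residuals": residuals}
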