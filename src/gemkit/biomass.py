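"""Biomass pseudo-reaction construction from macromolecular composition.

The biomass equation of a GEM is assembled from the measured dry-weight
composition (g protein, carbohydrate, lipid, RNA, DNA per gDW) and the
monomer make-up of each macromolecular class (mole fractions of amino
acids, NTPs, dNTPs, sugars...).  Coefficients are scaled so the complete
equation consumes exactly 1 g of monomer mass per gDW of biomass formed.

Monomer masses are polymer-incorporated residue masses in g/mmol (free
monomer minus one water for the polymerising classes); this convention is
what makes the 1 g closure exact.  Polymerisation ATP costs are folded
into the growth-associated maintenance (GAM) term rather than charged per
monomer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .gem_core import Model, Reaction, Metabolite

MACRO_CLASSES = ("protein", "carbohydrate", "lipid", "RNA", "DNA", "other")

# One- and three-letter amino acid handling: sequences use one-letter codes,
# monomer ids use the lowercase three-letter code familiar from yeast GEMs.
_AA_CODES = {
    "A": "ala", "R": "arg", "N": "asn", "D": "asp", "C": "cys",
    "Q": "gln", "E": "glu", "G": "gly", "H": "his", "I": "ile",
    "L": "leu", "K": "lys", "M": "met", "F": "phe", "P": "pro",
    "S": "ser", "T": "thr", "W": "trp", "Y": "tyr", "V": "val",
}
_DNA_CODES = {"A": "dA", "C": "dC", "G": "dG", "T": "dT"}
_RNA_CODES = {"A": "A", "C": "C", "G": "G", "U": "U"}

_ALPHABETS = {"protein": _AA_CODES, "dna": _DNA_CODES, "rna": _RNA_CODES}


class CompositionError(ValueError):
    pass


@dataclass
class BiomassComposition:
    """Macromolecular composition of 1 gDW of cells.

    macro_fractions: g/gDW per class, must sum to 1 +- 0.01.
    monomer_fractions: per class, monomer-id -> mole fraction (sums to 1).
    monomer_masses: monomer-id -> residue mass, g/mmol.
    cell_wall_split: glucan/mannan/chitin g/gDW within the carbohydrate pool.
    trehalose_amylose_molar_ratio: molar ratio trehalose:amylose for the
    non-wall carbohydrate remainder.
    GAM: growth-associated maintenance, mmol ATP/gDW.
    """

    macro_fractions: dict[str, float]
    monomer_fractions: dict[str, dict[str, float]]
    monomer_masses: dict[str, float]
    cell_wall_split: dict[str, float] = field(default_factory=dict)
    trehalose_amylose_molar_ratio: float = 1.0
    GAM: float = 0.0

    def validate(self) -> None:
        total = sum(self.macro_fractions.values())
        if abs(total - 1.0) > 0.01:
            raise CompositionError(
                f"macromolecular fractions sum to {total:.4f}, expected 1 +- 0.01"
            )
        for cls, fracs in self.monomer_fractions.items():
            if not fracs:
                continue
            s = sum(fracs.values())
            if abs(s - 1.0) > 1e-9:
                raise CompositionError(
                    f"{cls} monomer fractions sum to {s!r}, expected 1"
                )
            for m in fracs:
                mass = self.monomer_masses.get(m)
                if mass is None or mass <= 0:
                    raise CompositionError(f"monomer {m}: missing or non-positive mass")


def monomer_fractions_from_sequences(
    sequences: Sequence[tuple[str, float]], alphabet: str
) -> dict[str, float]:
    """Weighted monomer mole fractions from sequences.

    fraction(m) = sum_s w_s * count_m(s) / sum_s w_s * len(s).  Weights are
    relative abundances (e.g. expression levels or copy numbers); they must
    be non-negative and not all zero.
    """
    try:
        codes = _ALPHABETS[alphabet]
    except KeyError:
        raise ValueError(f"unknown alphabet {alphabet!r}") from None
    if any(w < 0 for _, w in sequences):
        raise ValueError("sequence weights must be >= 0")
    counts: dict[str, float] = {}
    total = 0.0
    for si, (seq, w) in enumerate(sequences):
        if w == 0:
            continue
        for pos, ch in enumerate(seq.upper()):
            monomer = codes.get(ch)
            if monomer is None:
                raise ValueError(
                    f"invalid {alphabet} character {ch!r} in sequence {si} "
                    f"at position {pos}"
                )
            counts[monomer] = counts.get(monomer, 0.0) + w
            total += w
    if total == 0:
        raise ValueError("all sequence weights are zero (or sequences empty)")
    return {m: c / total for m, c in sorted(counts.items())}


def scale_to_biomass(comp: BiomassComposition) -> dict[str, dict[str, float]]:
    """Stoichiometric coefficients (mmol/gDW) per pseudo-reaction.

    For class c with dry-weight fraction f_c and monomer mole fractions
    x_m with residue masses M_m (g/mmol):

        coeff_m = f_c * x_m / sum_k x_k * M_k

    so that sum_m coeff_m * M_m = f_c, and over all classes the equation
    consumes exactly 1 g of monomers per gDW.
    """
    comp.validate()
    out: dict[str, dict[str, float]] = {}
    for cls, f_c in comp.macro_fractions.items():
        fracs = comp.monomer_fractions.get(cls, {})
        if f_c == 0 or not fracs:
            out[cls] = {}
            continue
        avg_mass = sum(x * comp.monomer_masses[m] for m, x in fracs.items())
        if avg_mass <= 0:
            raise CompositionError(f"{cls}: zero total monomer mass")
        out[cls] = {m: f_c * x / avg_mass for m, x in sorted(fracs.items())}
    return out


def biomass_mass(coefficients: Mapping[str, Mapping[str, float]],
                 monomer_masses: Mapping[str, float]) -> float:
    """Total monomer mass (g/gDW) consumed by the assembled equation."""
    return sum(
        coeff * monomer_masses[m]
        for per_class in coefficients.values()
        for m, coeff in per_class.items()
    )


def partition_carbohydrates(
    total_carb: float,
    wall: Mapping[str, float],
    ratio: float,
    masses: Mapping[str, float],
) -> dict[str, float]:
    """Split the carbohydrate dry-weight pool into wall polymers and storage.

    The wall components (glucan, mannan, chitin) are measured; whatever
    mass remains is divided between trehalose and amylose so that their
    molar ratio (trehalose:amylose) equals ``ratio``.  Masses are g/mmol.
    """
    wall_sum = sum(wall.values())
    if wall_sum > total_carb + 1e-12:
        raise CompositionError(
            f"cell wall mass {wall_sum} exceeds total carbohydrate {total_carb}"
        )
    remainder = max(total_carb - wall_sum, 0.0)
    out = {k: float(v) for k, v in wall.items()}
    m_tre = masses.get("trehalose")
    m_amy = masses.get("amylose")
    if remainder <= 0:
        out["trehalose"] = 0.0
        out["amylose"] = 0.0
        return out
    if not m_tre or not m_amy:
        raise CompositionError("need trehalose and amylose masses to split remainder")
    # moles: n_tre = ratio * n_amy; mass closure: n_tre*m_tre + n_amy*m_amy = r
    n_amy = remainder / (ratio * m_tre + m_amy)
    out["trehalose"] = ratio * n_amy * m_tre
    out["amylose"] = n_amy * m_amy
    return out


#: default metabolite ids for the energy term of the biomass reaction
ENERGY_METS = {"atp": "atp_c", "adp": "adp_c", "pi": "pi_c", "h2o": "h2o_c", "h": "h_c"}


def assemble_biomass(
    model: Model,
    coefficients: Mapping[str, Mapping[str, float]],
    GAM: float = 0.0,
    energy_mets: Mapping[str, str] = ENERGY_METS,
    biomass_id: str = "BIOMASS",
    compartment: str = "c",
) -> Model:
    """Add (or replace) per-class pseudo-reactions and the biomass reaction.

    Each non-empty class gets a pseudo-metabolite and a reaction
    ``<class>_pseudo: sum coeff_m * monomer_m -> class_pseudo``; the
    biomass reaction consumes one unit of each class pseudo-metabolite
    plus GAM ATP hydrolysis (ATP + H2O -> ADP + Pi + H).  Re-assembly is
    idempotent.  Raises if any referenced monomer is missing.
    """
    missing = sorted(
        {
            m
            for per_class in coefficients.values()
            for m in per_class
            if not model.has_metabolite(m)
        }
    )
    if missing:
        raise KeyError(f"biomass monomers not in model: {missing}")
    if GAM > 0:
        absent = [mid for mid in energy_mets.values() if not model.has_metabolite(mid)]
        if absent:
            raise KeyError(f"energy metabolites not in model: {absent}")

    new = model.copy()
    drop = {f"{cls}_pseudo_rxn" for cls in coefficients} | {biomass_id}
    new.reactions = [r for r in new.reactions if r.id not in drop]

    biomass_stoich: dict[str, float] = {}
    for cls, per_class in coefficients.items():
        if not per_class:
            continue
        pseudo_met = f"{cls}_pseudo_{compartment}"
        if not new.has_metabolite(pseudo_met):
            new.metabolites.append(
                Metabolite(pseudo_met, name=f"{cls} pool", compartment=compartment)
            )
        stoich = {m: -coeff for m, coeff in per_class.items()}
        stoich[pseudo_met] = 1.0
        new.reactions.append(
            Reaction(
                f"{cls}_pseudo_rxn",
                name=f"{cls} pseudo-reaction",
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=1000.0,
            )
        )
        biomass_stoich[pseudo_met] = -1.0

    if GAM > 0:
        biomass_stoich[energy_mets["atp"]] = (
            biomass_stoich.get(energy_mets["atp"], 0.0) - GAM
        )
        biomass_stoich[energy_mets["h2o"]] = (
            biomass_stoich.get(energy_mets["h2o"], 0.0) - GAM
        )
        biomass_stoich[energy_mets["adp"]] = (
            biomass_stoich.get(energy_mets["adp"], 0.0) + GAM
        )
        biomass_stoich[energy_mets["pi"]] = (
            biomass_stoich.get(energy_mets["pi"], 0.0) + GAM
        )
        biomass_stoich[energy_mets["h"]] = (
            biomass_stoich.get(energy_mets["h"], 0.0) + GAM
        )

    if not biomass_stoich:
        raise CompositionError("no biomass components: all classes empty")
    new.reactions.append(
        Reaction(
            biomass_id,
            name="Biomass",
            stoichiometry=biomass_stoich,
            lower_bound=0.0,
            upper_bound=1000.0,
        )
    )
    new.objective_reaction = biomass_id
    new.maintenance.GAM = GAM
    new.validate()
    return new


def add_ngam(
    model: Model,
    NGAM: float,
    energy_mets: Mapping[str, str] = ENERGY_METS,
    reaction_id: str = "NGAM",
) -> Model:
    """Non-growth-associated maintenance as an ATP hydrolysis reaction with
    a fixed lower bound of NGAM mmol ATP/gDW/h."""
    new = model.copy()
    new.reactions = [r for r in new.reactions if r.id != reaction_id]
    new.reactions.append(
        Reaction(
            reaction_id,
            name="Non-growth-associated maintenance",
            stoichiometry={
                energy_mets["atp"]: -1.0,
                energy_mets["h2o"]: -1.0,
                energy_mets["adp"]: 1.0,
                energy_mets["pi"]: 1.0,
                energy_mets["h"]: 1.0,
            },
            lower_bound=NGAM,
            upper_bound=1000.0,
        )
    )
    new.maintenance.NGAM = NGAM
    new.validate()
    return new
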