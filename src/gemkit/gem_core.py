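"""In-memory genome-scale model (GEM) representation.

A GEM is a compartmentalised stoichiometric network: metabolites, reactions
with flux bounds, boolean gene-protein-reaction (GPR) rules linking gene
activity to reaction availability, and a biomass pseudo-reaction used as
the growth objective.  Everything downstream of I/O operates on the types
defined here.

Conventions (standard in the COBRA community):

* flux units are mmol/gDW/h; growth flux is h^-1;
* exchange reactions move one metabolite across the system boundary;
  negative flux = uptake, positive flux = secretion;
* unconstrained reversible reactions get bounds (-1000, 1000), irreversible
  ones (0, 1000);
* a reaction without a GPR (spontaneous / non-gene-associated) is never
  deactivated by expression data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

DEFAULT_BOUND = 1000.0

# --------------------------------------------------------------------------
# GPR expressions
# --------------------------------------------------------------------------


class GprParseError(ValueError):
    """Raised for malformed GPR rule strings; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GprExpression:
    """Boolean AND/OR tree over gene identifiers.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``.  A leaf stores the
    gene id in ``gene``; internal nodes store >= 2 children.
    """

    op: str
    gene: str | None = None
    children: tuple["GprExpression", ...] = ()

    def __post_init__(self):
        if self.op == "gene":
            if not self.gene:
                raise ValueError("gene leaf requires a gene id")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.op} node requires >= 2 children")
        else:
            raise ValueError(f"unknown GPR node type {self.op!r}")

    def genes(self) -> set[str]:
        """All gene ids appearing in the tree."""
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, inactive: Iterable[str]) -> bool:
        """True iff the reaction remains catalysable when ``inactive`` genes
        are knocked out.  A leaf is true iff its gene is not inactive."""
        inactive = set(inactive)

        def ev(node: GprExpression) -> bool:
            if node.op == "gene":
                return node.gene not in inactive
            if node.op == "and":
                return all(ev(c) for c in node.children)
            return any(ev(c) for c in node.children)

        return ev(self)

    def render(self) -> str:
        """Canonical fully-parenthesised string with lowercase and/or."""

        def rn(node: GprExpression) -> str:
            if node.op == "gene":
                return node.gene
            inner = f" {node.op} ".join(rn(c) for c in node.children)
            return f"({inner})"

        s = rn(self)
        # strip the outermost parentheses for readability
        if s.startswith("(") and s.endswith(")"):
            s = s[1:-1]
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def gene(g: str) -> GprExpression:
    return GprExpression("gene", gene=g)


def gpr_and(*children: GprExpression) -> GprExpression:
    return GprExpression("and", children=tuple(children))


def gpr_or(*children: GprExpression) -> GprExpression:
    return GprExpression("or", children=tuple(children))


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GprExpression:
    """Parse a boolean rule string like ``"g1 and (g2 or g3)"``.

    ``and`` binds tighter than ``or``; keywords are case-insensitive;
    any other token is a gene identifier.  Raises :class:`GprParseError`
    with the offending position for unbalanced parentheses or empty rules.
    """
    if text is None or not text.strip():
        raise GprParseError("empty GPR rule", 0)
    tokens: list[tuple[str, int]] = [
        (m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)
    ]
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(text))

    def parse_or() -> GprExpression:
        nonlocal pos
        terms = [parse_and()]
        while True:
            tok, _ = peek()
            if tok is not None and tok.lower() == "or":
                pos += 1
                terms.append(parse_and())
            else:
                break
        return terms[0] if len(terms) == 1 else GprExpression("or", children=tuple(terms))

    def parse_and() -> GprExpression:
        nonlocal pos
        factors = [parse_atom()]
        while True:
            tok, _ = peek()
            if tok is not None and tok.lower() == "and":
                pos += 1
                factors.append(parse_atom())
            else:
                break
        return (
            factors[0]
            if len(factors) == 1
            else GprExpression("and", children=tuple(factors))
        )

    def parse_atom() -> GprExpression:
        nonlocal pos
        tok, at = peek()
        if tok is None:
            raise GprParseError("unexpected end of rule", at)
        if tok == "(":
            pos += 1
            inner = parse_or()
            tok2, at2 = peek()
            if tok2 != ")":
                raise GprParseError("unbalanced parenthesis", at2)
            pos += 1
            return inner
        if tok == ")":
            raise GprParseError("unexpected ')'", at)
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected keyword {tok!r}", at)
        pos += 1
        return GprExpression("gene", gene=tok)

    expr = parse_or()
    tok, at = peek()
    if tok is not None:
        raise GprParseError(f"unexpected token {tok!r}", at)
    return expr


def evaluate_gpr(gpr: GprExpression | None, inactive: Iterable[str]) -> bool:
    """Evaluate a GPR under a gene knockout set.

    An absent GPR evaluates to True: spontaneous reactions are not under
    gene control and stay active under any expression state.
    """
    if gpr is None:
        return True
    return gpr.evaluate(inactive)


# --------------------------------------------------------------------------
# Model entities
# --------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] = field(default_factory=dict)
    charge: int | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    def copy(self) -> "Metabolite":
        return Metabolite(
            self.id,
            self.name,
            self.compartment,
            dict(self.formula),
            self.charge,
            dict(self.annotations),
        )


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation chemical formula ('C6H12O6') to element counts."""
    if not text:
        return {}
    counts: dict[str, int] = {}
    span = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != span:
            raise ValueError(f"invalid formula {text!r}")
        span = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if span != len(text):
        raise ValueError(f"invalid formula {text!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(counts.items()) if n
    )


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GprExpression | None = None
    subsystem: str = ""
    notes: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_boundary(self) -> bool:
        """Boundary pseudo-reaction: touches exactly one metabolite.

        Exchanges, demands and sinks are all boundary reactions; whether a
        boundary reaction is an *exchange* additionally requires its
        metabolite to be extracellular, which only the model knows — see
        :meth:`Model.is_exchange`."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            self.id,
            self.name,
            dict(self.stoichiometry),
            self.lower_bound,
            self.upper_bound,
            self.gpr,
            self.subsystem,
            self.notes,
        )


@dataclass
class Maintenance:
    """ATP maintenance parameters: GAM (mmol ATP/gDW, growth-associated),
    NGAM (mmol ATP/gDW/h, flat) and the P/O ratio.  Values are study inputs;
    there are no universal defaults."""

    GAM: float = 0.0
    NGAM: float = 0.0
    PO_ratio: float = 0.0


class ModelValidationError(ValueError):
    pass


@dataclass
class Model:
    id: str
    compartments: dict[str, str] = field(default_factory=dict)  # id -> name
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)
    objective_reaction: str | None = None
    maintenance: Maintenance = field(default_factory=Maintenance)

    # ---- indexing -----------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"unknown metabolite {mid!r}")

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction {rid!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def has_metabolite(self, mid: str) -> bool:
        return any(m.id == mid for m in self.metabolites)

    def is_exchange(self, rxn: Reaction, extracellular: str = "e") -> bool:
        """Boundary reaction whose single metabolite is extracellular.

        If the model has no compartment named ``extracellular``, any
        boundary reaction counts (single-compartment toy models)."""
        if not rxn.is_boundary:
            return False
        if extracellular not in self.compartments:
            return True
        mid = next(iter(rxn.stoichiometry))
        return self.metabolite(mid).compartment == extracellular

    def exchanges(self, extracellular: str = "e") -> list[Reaction]:
        return [r for r in self.reactions if self.is_exchange(r, extracellular)]

    def copy(self) -> "Model":
        return Model(
            self.id,
            dict(self.compartments),
            [m.copy() for m in self.metabolites],
            [r.copy() for r in self.reactions],
            set(self.genes),
            self.objective_reaction,
            replace(self.maintenance),
        )

    # ---- validation ---------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on the
        first violation found."""
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            dupes = {m for m in met_ids if met_ids.count(m) > 1}
            raise ModelValidationError(f"duplicate metabolite ids: {sorted(dupes)}")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = {r for r in rxn_ids if rxn_ids.count(r) > 1}
            raise ModelValidationError(f"duplicate reaction ids: {sorted(dupes)}")
        met_set = set(met_ids)
        for m in self.metabolites:
            if m.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {m.id}: unknown compartment {m.compartment!r}"
                )
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id}: empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id}: lower bound exceeds upper bound"
                )
            missing = set(r.stoichiometry) - met_set
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id}: unknown metabolites {sorted(missing)}"
                )
            if r.gpr is not None:
                orphan = r.gpr.genes() - self.genes
                if orphan:
                    raise ModelValidationError(
                        f"reaction {r.id}: GPR genes not in model: {sorted(orphan)}"
                    )
        if self.objective_reaction is not None and self.objective_reaction not in set(
            rxn_ids
        ):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )


# --------------------------------------------------------------------------
# Structural queries
# --------------------------------------------------------------------------


@dataclass
class BalanceReport:
    reaction_id: str
    element_net: dict[str, float]
    charge_net: float | None
    verdict: str  # balanced | unbalanced | exchange | unknown


def check_mass_charge_balance(model: Model, rxn_id: str) -> BalanceReport:
    """Elemental and charge balance of one reaction.

    Exchange reactions are exempt (verdict ``"exchange"``): they move mass
    across the system boundary by design.  A participant with an empty
    formula makes the verdict ``"unknown"``.
    """
    rxn = model.reaction(rxn_id)
    if rxn.is_boundary:
        return BalanceReport(rxn_id, {}, None, "exchange")
    element_net: dict[str, float] = {}
    charge_net = 0.0
    unknown = False
    for mid, coeff in rxn.stoichiometry.items():
        met = model.metabolite(mid)
        if not met.formula:
            unknown = True
            continue
        for el, n in met.formula.items():
            element_net[el] = element_net.get(el, 0.0) + coeff * n
        if met.charge is None:
            unknown = True
        else:
            charge_net += coeff * met.charge
    element_net = {el: v for el, v in element_net.items() if abs(v) > 1e-9}
    if unknown:
        return BalanceReport(rxn_id, element_net, None, "unknown")
    balanced = not element_net and abs(charge_net) <= 1e-9
    return BalanceReport(
        rxn_id, element_net, charge_net, "balanced" if balanced else "unbalanced"
    )


def model_statistics(model: Model) -> dict:
    """Entity counts in the style of published GEM comparison tables.

    A reaction is counted in every compartment any of its participants
    resides in, so per-compartment reaction counts sum to >= the total.
    Metabolites count once, by their own compartment.
    """
    comp_of = {m.id: m.compartment for m in model.metabolites}
    rxn_by_comp: dict[str, int] = {c: 0 for c in model.compartments}
    met_by_comp: dict[str, int] = {c: 0 for c in model.compartments}
    for m in model.metabolites:
        met_by_comp[m.compartment] += 1
    n_exchange = 0
    for r in model.reactions:
        comps = {comp_of[mid] for mid in r.stoichiometry}
        for c in comps:
            rxn_by_comp[c] += 1
        if model.is_exchange(r):
            n_exchange += 1
    return {
        "genes": len(model.genes),
        "reactions": len(model.reactions),
        "exchange_reactions": n_exchange,
        "metabolites": len(model.metabolites),
        "reactions_per_compartment": rxn_by_comp,
        "metabolites_per_compartment": met_by_comp,
    }


def transport_reaction_counts(
    model: Model, extracellular: str = "e"
) -> dict[str, int]:
    """Count transport reactions: cell<->extracellular vs organelle<->organelle.

    A transport reaction spans >= 2 compartments and is not an exchange.
    """
    comp_of = {m.id: m.compartment for m in model.metabolites}
    plasma = 0
    intra = 0
    for r in model.reactions:
        if r.is_boundary:
            continue
        comps = {comp_of[mid] for mid in r.stoichiometry}
        if len(comps) < 2:
            continue
        if extracellular in comps:
            plasma += 1
        else:
            intra += 1
    return {"plasma_membrane": plasma, "intracellular": intra}


def transportable_cytosolic_metabolites(
    model: Model,
    cytosol: str = "c",
    extracellular: str = "e",
    definition: str = "cross_compartment",
) -> set[str]:
    """Cytosolic metabolites the cell can move to/from the extracellular space.

    ``definition="cross_compartment"`` (default): cytosolic metabolites
    participating in at least one reaction that also involves an
    extracellular metabolite.  ``definition="exchange"``: cytosolic
    metabolites whose extracellular counterpart (same base id) has an
    exchange reaction.  Both countings are exposed because the published
    counts never state which was used.
    """
    for comp in (cytosol, extracellular):
        if comp not in model.compartments:
            raise KeyError(f"compartment {comp!r} not in model")
    comp_of = {m.id: m.compartment for m in model.metabolites}
    if definition == "cross_compartment":
        out: set[str] = set()
        for r in model.reactions:
            comps = {comp_of[mid] for mid in r.stoichiometry}
            if cytosol in comps and extracellular in comps:
                out |= {mid for mid in r.stoichiometry if comp_of[mid] == cytosol}
        return out
    if definition == "exchange":
        exchanged_mets = {
            next(iter(r.stoichiometry))
            for r in model.reactions
            if model.is_exchange(r, extracellular)
        }
        base_of = lambda mid, comp: mid[: -len(comp) - 1] if mid.endswith(f"_{comp}") else mid
        exchanged_bases = {
            base_of(mid, extracellular)
            for mid in exchanged_mets
            if comp_of[mid] == extracellular
        }
        return {
            m.id
            for m in model.metabolites
            if m.compartment == cytosol and base_of(m.id, cytosol) in exchanged_bases
        }
    raise ValueError(f"unknown definition {definition!r}")
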