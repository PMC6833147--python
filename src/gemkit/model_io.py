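"""Read and write models and datasets in standard formats.

Models travel as SBML Level 3 + FBC v2 (bounds as parameters, GPRs as
gene-product associations) or as a directory of TSV tables mirroring the
usual RXNS/METS/GENES spreadsheet layout.  Expression data is a long-format
TSV (gene, condition, replicate, value).  Media are YAML files mapping
exchange-reaction ids to (lower, upper) bound overrides.

Everything downstream of this module consumes only :mod:`gemkit.gem_core`
types.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import libsbml
import pandas as pd
import yaml

from .gem_core import (
    GprExpression,
    Maintenance,
    Metabolite,
    Model,
    ModelValidationError,
    Reaction,
    format_formula,
    parse_formula,
    parse_gpr,
)


# --------------------------------------------------------------------------
# Media
# --------------------------------------------------------------------------


@dataclass
class MediumDefinition:
    """Exchange-bound overrides defining a growth medium.

    ``bounds`` maps exchange reaction id -> (lower, upper) in mmol/gDW/h;
    negative lower bound = allowed uptake.  Exchanges absent from the map
    are closed for uptake (lower bound 0) when the medium is applied.
    """

    name: str = "medium"
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self):
        for rid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"medium {self.name}: {rid} lower {lo} > upper {hi}")


def read_medium(path: str | Path) -> MediumDefinition:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    bounds = {
        rid: (float(pair[0]), float(pair[1]))
        for rid, pair in (doc.get("bounds") or {}).items()
    }
    return MediumDefinition(
        name=doc.get("name", Path(path).stem),
        bounds=bounds,
        description=doc.get("description", ""),
    )


def write_medium(medium: MediumDefinition, path: str | Path) -> None:
    doc = {
        "name": medium.name,
        "description": medium.description,
        "bounds": {rid: [lo, hi] for rid, (lo, hi) in sorted(medium.bounds.items())},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def apply_medium(model: Model, medium: MediumDefinition) -> Model:
    """New model with the medium's exchange bounds applied.

    Every exchange reaction *not* listed in the medium has its lower bound
    raised to 0 (no uptake); listed exchanges get exactly the stated
    bounds.  Non-exchange reactions are untouched.  Idempotent.
    """
    for rid in medium.bounds:
        if not model.has_reaction(rid):
            raise KeyError(f"medium {medium.name}: unknown reaction {rid!r}")
        if not model.is_exchange(model.reaction(rid)):
            raise ValueError(f"medium {medium.name}: {rid} is not an exchange reaction")
    new = model.copy()
    for rxn in new.reactions:
        if not new.is_exchange(rxn):
            continue
        if rxn.id in medium.bounds:
            rxn.lower_bound, rxn.upper_bound = medium.bounds[rxn.id]
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return new


# --------------------------------------------------------------------------
# Expression data
# --------------------------------------------------------------------------


@dataclass
class ExpressionSet:
    """Per-gene expression values by condition and replicate.

    ``values[(gene, condition)]`` is the list of replicate values, in
    replicate order.  Genes absent from a condition are simply missing —
    absence means "no evidence", never zero.
    """

    genes: list[str]
    conditions: list[str]
    values: dict[tuple[str, str], list[float]]
    n_replicates: dict[str, int]

    def replicate_values(self, g: str, cond: str) -> list[float] | None:
        return self.values.get((g, cond))


def read_expression(path: str | Path) -> ExpressionSet:
    """Read a long-format expression table with columns
    gene, condition, replicate, value."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene": str, "condition": str},
        float_precision="round_trip",
    )
    required = {"gene", "condition", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if (df["value"] < 0).any():
        bad = df[df["value"] < 0].iloc[0]
        raise ValueError(
            f"negative expression value for gene {bad['gene']} "
            f"condition {bad['condition']}"
        )
    dup = df.duplicated(subset=["gene", "condition", "replicate"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise ValueError(
            f"duplicate entry for (gene={bad['gene']}, condition="
            f"{bad['condition']}, replicate={bad['replicate']})"
        )
    return expression_from_frame(df)


def expression_from_frame(df: pd.DataFrame) -> ExpressionSet:
    genes = sorted(df["gene"].unique())
    conditions = sorted(df["condition"].unique())
    values: dict[tuple[str, str], list[float]] = {}
    for (g, cond), sub in df.groupby(["gene", "condition"], sort=True):
        sub = sub.sort_values("replicate")
        values[(g, cond)] = [float(v) for v in sub["value"]]
    n_replicates = {
        cond: int(df[df["condition"] == cond]["replicate"].nunique())
        for cond in conditions
    }
    return ExpressionSet(genes, conditions, values, n_replicates)


def write_expression(expr: ExpressionSet, path: str | Path) -> None:
    rows = []
    for (g, cond), vals in sorted(expr.values.items()):
        for i, v in enumerate(vals, start=1):
            rows.append((g, cond, i, v))
    pd.DataFrame(rows, columns=["gene", "condition", "replicate", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# --------------------------------------------------------------------------
# SBML
# --------------------------------------------------------------------------

_SID_ESCAPE = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str) -> str:
    """Sanitise an id to an SBML SId; the escape is reversible via __xx__
    hex codes."""
    out = _SID_ESCAPE.sub(lambda m: f"__{ord(m.group(0)):02x}__", raw)
    if out and out[0].isdigit():
        out = "_" + out
    return out


def _unsid(sid: str) -> str:
    if sid.startswith("_") and len(sid) > 1 and sid[1].isdigit():
        sid = sid[1:]
    return re.sub(r"__([0-9a-f]{2})__", lambda m: chr(int(m.group(1), 16)), sid)


class SbmlError(ValueError):
    pass


def _gpr_to_association(gpr: GprExpression, fbc_rxn) -> None:
    gpa = fbc_rxn.createGeneProductAssociation()

    def build(node: GprExpression, parent):
        if node.op == "gene":
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(_sid("G_" + node.gene))
        elif node.op == "and":
            op = parent.createAnd()
            for c in node.children:
                build(c, op)
        else:
            op = parent.createOr()
            for c in node.children:
                build(c, op)

    if gpr.op == "gene":
        ref = gpa.createGeneProductRef()
        ref.setGeneProduct(_sid("G_" + gpr.gene))
    else:
        build(gpr, gpa)


def _association_to_gpr(assoc) -> GprExpression:
    if assoc.isGeneProductRef():
        gid = _unsid(assoc.getGeneProduct())
        if gid.startswith("G_"):
            gid = gid[2:]
        return GprExpression("gene", gene=gid)
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    )
    if len(children) == 1:
        return children[0]
    op = "and" if assoc.isFbcAnd() else "or"
    return GprExpression(op, children=children)


def write_sbml(model: Model, path: str | Path) -> None:
    """Write SBML Level 3 Version 1 with the FBC v2 package."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for cid, cname in sorted(model.compartments.items()):
        comp = sbml_model.createCompartment()
        comp.setId(_sid(cid))
        comp.setName(cname or cid)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sid("M_" + met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sid(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    for g in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_" + g))
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = sbml_model.createReaction()
        sr.setId(_sid("R_" + rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        if rxn.notes or rxn.subsystem:
            body = ""
            if rxn.subsystem:
                body += f"<p>SUBSYSTEM: {rxn.subsystem}</p>"
            if rxn.notes:
                body += f"<p>NOTES: {rxn.notes}</p>"
            sr.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )
        for mid, coeff in sorted(rxn.stoichiometry.items()):
            if coeff < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(_sid("M_" + mid))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            _gpr_to_association(rxn.gpr, rplug)

    if model.objective_reaction is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid("R_" + model.objective_reaction))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SbmlError(f"could not write SBML to {path}")


def sbml_string(model: Model) -> str:
    import tempfile, os

    with tempfile.NamedTemporaryFile("r", suffix=".xml", delete=False) as fh:
        tmp = fh.name
    try:
        write_sbml(model, tmp)
        with open(tmp) as fh:
            return fh.read()
    finally:
        os.unlink(tmp)


def _strip_prefix(sid: str, prefix: str) -> str:
    raw = _unsid(sid)
    return raw[len(prefix):] if raw.startswith(prefix) else raw


def read_sbml(path: str | Path) -> Model:
    """Read an SBML L3 + FBC model (tolerating FBC v1 / COBRA-notes
    dialects for bounds and GPRs) into a validated :class:`Model`."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SbmlError(f"SBML parse error: {err.getMessage() if err else 'unknown'}")
    sm = doc.getModel()
    if sm is None:
        raise SbmlError(f"no model element in {path}")
    mplug = sm.getPlugin("fbc")

    model = Model(id=_unsid(sm.getId()) or Path(str(path)).stem)
    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        model.compartments[_unsid(comp.getId())] = comp.getName() or ""

    label_of_gene: dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or _strip_prefix(gp.getId(), "G_")
            label_of_gene[gp.getId()] = label
            model.genes.add(label)

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        splug = sp.getPlugin("fbc")
        formula = {}
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.metabolites.append(
            Metabolite(
                id=_strip_prefix(sp.getId(), "M_"),
                name=sp.getName() or "",
                compartment=_unsid(sp.getCompartment()),
                formula=formula,
                charge=charge,
            )
        )

    boundary_species = {
        sm.getSpecies(i).getId()
        for i in range(sm.getNumSpecies())
        if sm.getSpecies(i).getBoundaryCondition()
    }

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = _strip_prefix(sr.getId(), "R_")
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            if ref.getSpecies() in boundary_species:
                continue
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            if ref.getSpecies() in boundary_species:
                continue
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}

        rplug = sr.getPlugin("fbc")
        lb = ub = None
        if rplug is not None and rplug.isSetLowerFluxBound():
            p = sm.getParameter(rplug.getLowerFluxBound())
            lb = p.getValue() if p is not None else None
        if rplug is not None and rplug.isSetUpperFluxBound():
            p = sm.getParameter(rplug.getUpperFluxBound())
            ub = p.getValue() if p is not None else None
        if lb is None or ub is None:
            # legacy dialect: kinetic-law parameters LOWER_BOUND/UPPER_BOUND
            kl = sr.getKineticLaw()
            if kl is not None:
                for k in range(kl.getNumParameters()):
                    p = kl.getParameter(k)
                    if p.getId() == "LOWER_BOUND":
                        lb = p.getValue()
                    elif p.getId() == "UPPER_BOUND":
                        ub = p.getValue()
        if lb is None or ub is None:
            raise SbmlError(f"reaction {rid}: missing flux bounds")
        if lb > ub:
            raise SbmlError(f"reaction {rid}: lower bound {lb} > upper bound {ub}")

        gpr = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gpr = _relabel(_association_to_gpr_raw(assoc), label_of_gene)
        if gpr is None:
            notes = sr.getNotesString() or ""
            m = re.search(r"GENE[ _]ASSOCIATION:\s*([^<]+)", notes)
            if m and m.group(1).strip():
                gpr = parse_gpr(m.group(1).strip())
                model.genes |= gpr.genes()

        subsystem = ""
        notes_text = ""
        notes = sr.getNotesString() or ""
        ms = re.search(r"SUBSYSTEM:\s*([^<]+)", notes)
        if ms:
            subsystem = ms.group(1).strip()
        mn = re.search(r"NOTES:\s*([^<]+)", notes)
        if mn:
            notes_text = mn.group(1).strip()

        model.reactions.append(
            Reaction(
                id=rid,
                name=sr.getName() or "",
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=gpr,
                subsystem=subsystem,
                notes=notes_text,
            )
        )

    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_reaction = _strip_prefix(
                obj.getFluxObjective(0).getReaction(), "R_"
            )

    try:
        model.validate()
    except ModelValidationError as exc:
        raise SbmlError(f"invalid model in {path}: {exc}") from exc
    return model


def _association_to_gpr_raw(assoc) -> GprExpression:
    if assoc.isGeneProductRef():
        return GprExpression("gene", gene=assoc.getGeneProduct())
    children = tuple(
        _association_to_gpr_raw(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    )
    if len(children) == 1:
        return children[0]
    return GprExpression("and" if assoc.isFbcAnd() else "or", children=children)


def _relabel(gpr: GprExpression, label_of_gene: dict[str, str]) -> GprExpression:
    if gpr.op == "gene":
        label = label_of_gene.get(gpr.gene)
        if label is None:
            raise SbmlError(f"unknown gene-product reference {gpr.gene!r}")
        return GprExpression("gene", gene=label)
    return GprExpression(
        gpr.op, children=tuple(_relabel(c, label_of_gene) for c in gpr.children)
    )


# --------------------------------------------------------------------------
# Tabular model format (RXNS / METS / GENES TSVs)
# --------------------------------------------------------------------------

_ARROW_RE = re.compile(r"\s*(<=>|<->|-->|<--|->|=>)\s*")


def parse_reaction_string(text: str) -> tuple[dict[str, float], bool]:
    """Parse 'A_c + 2 B_c -> C_c' into coefficients and reversibility.

    Returns (stoichiometry, reversible); '<=>' / '<->' mean reversible.
    An empty side is allowed (exchange/demand notation).
    """
    m = _ARROW_RE.search(text)
    if m is None:
        raise ValueError(f"no reaction arrow in {text!r}")
    arrow = m.group(1)
    lhs, rhs = text[: m.start()], text[m.end():]
    if arrow in ("<--",):
        lhs, rhs = rhs, lhs
    reversible = arrow in ("<=>", "<->")

    def side(chunk: str, sign: float, out: dict[str, float]):
        chunk = chunk.strip()
        if not chunk:
            return
        for term in chunk.split("+"):
            term = term.strip()
            if not term:
                raise ValueError(f"empty term in {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, mid = 1.0, parts[0]
            elif len(parts) == 2:
                coeff, mid = float(parts[0]), parts[1]
            else:
                raise ValueError(f"cannot parse term {term!r} in {text!r}")
            out[mid] = out.get(mid, 0.0) + sign * coeff

    stoich: dict[str, float] = {}
    side(lhs, -1.0, stoich)
    side(rhs, +1.0, stoich)
    stoich = {m_: c for m_, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ValueError(f"reaction {text!r} has empty net stoichiometry")
    return stoich, reversible


def format_reaction_string(rxn: Reaction) -> str:
    def fmt(coeff: float) -> str:
        return "" if coeff == 1 else f"{coeff:g} "

    lhs = " + ".join(
        f"{fmt(-c)}{m}" for m, c in sorted(rxn.stoichiometry.items()) if c < 0
    )
    rhs = " + ".join(
        f"{fmt(c)}{m}" for m, c in sorted(rxn.stoichiometry.items()) if c > 0
    )
    arrow = "<=>" if rxn.lower_bound < 0 else "->"
    return f"{lhs} {arrow} {rhs}".strip()


_RXN_COLUMNS = [
    "id", "name", "equation", "lower_bound", "upper_bound", "gpr",
    "subsystem", "notes",
]
_MET_COLUMNS = ["id", "name", "compartment", "formula", "charge"]


def write_model_tables(model: Model, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rxn_rows = [
        {
            "id": r.id,
            "name": r.name,
            "equation": format_reaction_string(r),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "gpr": r.gpr.render() if r.gpr is not None else "",
            "subsystem": r.subsystem,
            "notes": r.notes,
        }
        for r in model.reactions
    ]
    pd.DataFrame(rxn_rows, columns=_RXN_COLUMNS).to_csv(
        directory / "RXNS.tsv", sep="\t", index=False
    )
    met_rows = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "formula": format_formula(m.formula),
            "charge": "" if m.charge is None else m.charge,
        }
        for m in model.metabolites
    ]
    pd.DataFrame(met_rows, columns=_MET_COLUMNS).to_csv(
        directory / "METS.tsv", sep="\t", index=False
    )
    pd.DataFrame({"id": sorted(model.genes)}).to_csv(
        directory / "GENES.tsv", sep="\t", index=False
    )
    meta = {
        "id": model.id,
        "compartments": dict(sorted(model.compartments.items())),
        "objective_reaction": model.objective_reaction,
        "maintenance": {
            "GAM": model.maintenance.GAM,
            "NGAM": model.maintenance.NGAM,
            "PO_ratio": model.maintenance.PO_ratio,
        },
    }
    with open(directory / "MODEL.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_model_tables(directory: str | Path) -> Model:
    directory = Path(directory)
    rxns = pd.read_csv(directory / "RXNS.tsv", sep="\t", keep_default_na=False)
    mets = pd.read_csv(directory / "METS.tsv", sep="\t", keep_default_na=False)
    for col in ("id", "equation", "lower_bound", "upper_bound"):
        if col not in rxns.columns:
            raise ValueError(f"RXNS.tsv missing mandatory column {col!r}")
    for col in ("id", "compartment"):
        if col not in mets.columns:
            raise ValueError(f"METS.tsv missing mandatory column {col!r}")
    genes_path = directory / "GENES.tsv"
    genes: set[str] = set()
    if genes_path.exists():
        gdf = pd.read_csv(genes_path, sep="\t", keep_default_na=False)
        genes = {str(g) for g in gdf["id"] if str(g)}
    meta_path = directory / "MODEL.yaml"
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}

    model = Model(id=meta.get("id", directory.name))
    model.compartments = dict(meta.get("compartments") or {})
    maint = meta.get("maintenance") or {}
    model.maintenance = Maintenance(
        GAM=float(maint.get("GAM", 0.0)),
        NGAM=float(maint.get("NGAM", 0.0)),
        PO_ratio=float(maint.get("PO_ratio", 0.0)),
    )
    model.objective_reaction = meta.get("objective_reaction")
    model.genes = genes

    for _, row in mets.iterrows():
        comp = str(row["compartment"])
        if comp not in model.compartments:
            model.compartments[comp] = comp
        charge = row.get("charge", "")
        model.metabolites.append(
            Metabolite(
                id=str(row["id"]),
                name=str(row.get("name", "")),
                compartment=comp,
                formula=parse_formula(str(row.get("formula", ""))),
                charge=None if charge in ("", None) or (
                    isinstance(charge, float) and math.isnan(charge)
                ) else int(charge),
            )
        )

    for _, row in rxns.iterrows():
        stoich, _ = parse_reaction_string(str(row["equation"]))
        gpr_text = str(row.get("gpr", "")).strip()
        gpr = parse_gpr(gpr_text) if gpr_text else None
        if gpr is not None:
            model.genes |= gpr.genes()
        model.reactions.append(
            Reaction(
                id=str(row["id"]),
                name=str(row.get("name", "")),
                stoichiometry=stoich,
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
                gpr=gpr,
                subsystem=str(row.get("subsystem", "")),
                notes=str(row.get("notes", "")),
            )
        )

    model.validate()
    return model
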