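"""Synthetic models and datasets for testing every pipeline stage.

Nothing here is downloaded: toy GEMs with GPRs and a biomass reaction,
replicate expression matrices with planted all-zero genes, and noisy
uptake-vs-growth tables are all generated deterministically from a seed.

The planted-model generator mirrors the structure the analysis targets:
a compartmentalised network with exchange reactions and gene-associated
transporters, several linear biosynthesis modules feeding biomass
precursors, and a cofactor chain shaped like riboflavin biosynthesis —
two converging linear branches (a GTP-like and a pentose-phosphate-like
arm) joining at a lumazine-like intermediate, then a linear tail
riboflavin -> FMN -> FAD with one gene per step.  Planting the right
gene inactive in a condition severs the chain and creates a genuine
cofactor auxotrophy, which is exactly the event the condition-model
stage must detect and rescue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba import producibility, solve_fba
from .gem_core import Metabolite, Model, Reaction, gene, gpr_and, gpr_or, parse_gpr
from .gapfill import UniversalPool
from .condition import derive_condition_model
from .model_io import ExpressionSet, MediumDefinition, expression_from_frame
from .phenotype import predict_growth_at_uptake

# --------------------------------------------------------------------------
# Hand-built fixture catalogue
# --------------------------------------------------------------------------


def toy1() -> Model:
    """Smallest useful model: one substrate, one transporter, one
    conversion, one growth sink.  mu_max = 10 at uptake bound 10."""
    m = Model(id="TOY1", compartments={"e": "extracellular", "c": "cytosol"})
    m.metabolites = [
        Metabolite("A_e", "substrate A", "e", {"C": 1, "H": 2, "O": 1}, 0),
        Metabolite("A_c", "substrate A", "c", {"C": 1, "H": 2, "O": 1}, 0),
        Metabolite("B_c", "precursor B", "c", {"C": 1, "H": 2, "O": 1}, 0),
    ]
    m.genes = {"g1", "g2", "g3"}
    m.reactions = [
        Reaction("EX_A", "A exchange", {"A_e": -1.0}, -10.0, 1000.0),
        Reaction("T_A", "A transport", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0,
                 gpr=gene("g1")),
        Reaction("R1", "A to B", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0,
                 gpr=gpr_and(gene("g2"), gene("g3"))),
        Reaction("GROWTH", "growth sink", {"B_c": -1.0}, 0.0, 1000.0),
    ]
    m.objective_reaction = "GROWTH"
    m.validate()
    return m


def toy_bio(n_precursors: int = 5) -> Model:
    """Biomass over >= 5 precursors drawn from one carbon source.

    Each unit of biomass consumes 1/n of each precursor, so carbon
    closes: mu_max equals the uptake bound (10).
    """
    m = Model(id="TOY-BIO", compartments={"e": "extracellular", "c": "cytosol"})
    m.metabolites = [
        Metabolite("S_e", "substrate", "e"),
        Metabolite("S_c", "substrate", "c"),
    ]
    m.genes = {"g_t"}
    m.reactions = [
        Reaction("EX_S", "substrate exchange", {"S_e": -1.0}, -10.0, 1000.0),
        Reaction("T_S", "substrate transport", {"S_e": -1.0, "S_c": 1.0},
                 0.0, 1000.0, gpr=gene("g_t")),
    ]
    biomass: dict[str, float] = {}
    for i in range(1, n_precursors + 1):
        pid = f"P{i}_c"
        g = f"g_p{i}"
        m.metabolites.append(Metabolite(pid, f"precursor {i}", "c"))
        m.genes.add(g)
        m.reactions.append(
            Reaction(f"R_P{i}", f"make precursor {i}", {"S_c": -1.0, pid: 1.0},
                     0.0, 1000.0, gpr=gene(g))
        )
        biomass[pid] = -1.0 / n_precursors
    m.reactions.append(Reaction("BIOMASS", "biomass", biomass, 0.0, 1000.0))
    m.objective_reaction = "BIOMASS"
    m.validate()
    return m


def gap1() -> tuple[Model, UniversalPool, str]:
    """One missing conversion; only R_fix in the pool closes the gap."""
    m = Model(id="GAP1", compartments={"e": "extracellular", "c": "cytosol"})
    m.metabolites = [
        Metabolite("A_e", compartment="e"),
        Metabolite("A_c", compartment="c"),
        Metabolite("C_c", compartment="c"),
    ]
    m.reactions = [
        Reaction("EX_A", "", {"A_e": -1.0}, -10.0, 1000.0),
        Reaction("T_A", "", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0),
        Reaction("DMT_C", "", {"C_c": -1.0}, 0.0, 1000.0),
    ]
    m.validate()
    pool = UniversalPool(
        reactions=[
            Reaction("R_decoy1", "", {"A_c": -1.0, "D_c": 1.0}, 0.0, 1000.0),
            Reaction("R_decoy2", "", {"D_c": -1.0, "E_c": 1.0}, 0.0, 1000.0),
            Reaction("R_fix", "", {"A_c": -1.0, "C_c": 1.0}, 0.0, 1000.0),
        ],
        provenance={"R_decoy1": "reference-db", "R_decoy2": "reference-db",
                    "R_fix": "template-model"},
    )
    return m, pool, "C_c"


def gap2() -> tuple[Model, UniversalPool, str]:
    """Two reactions missing in series; the unique fix is the exact pair."""
    m = Model(id="GAP2", compartments={"e": "extracellular", "c": "cytosol"})
    m.metabolites = [
        Metabolite("A_e", compartment="e"),
        Metabolite("A_c", compartment="c"),
        Metabolite("C_c", compartment="c"),
    ]
    m.reactions = [
        Reaction("EX_A", "", {"A_e": -1.0}, -10.0, 1000.0),
        Reaction("T_A", "", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0),
        Reaction("DMT_C", "", {"C_c": -1.0}, 0.0, 1000.0),
    ]
    m.validate()
    pool = UniversalPool(
        reactions=[
            Reaction("R_step1", "", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0),
            Reaction("R_step2", "", {"B_c": -1.0, "C_c": 1.0}, 0.0, 1000.0),
            Reaction("R_decoy1", "", {"A_c": -1.0, "D_c": 1.0}, 0.0, 1000.0),
            Reaction("R_decoy2", "", {"D_c": -1.0, "E_c": 1.0}, 0.0, 1000.0),
            Reaction("R_decoy3", "", {"E_c": -1.0, "F_c": 1.0}, 0.0, 1000.0),
        ],
        provenance={rid: "reference-db"
                    for rid in ("R_step1", "R_step2", "R_decoy1", "R_decoy2",
                                "R_decoy3")},
    )
    return m, pool, "C_c"


# --------------------------------------------------------------------------
# Planted study generator
# --------------------------------------------------------------------------


@dataclass
class ToySpec:
    """Blueprint for a planted study model.

    planted_inactive maps condition -> genes that will show all-zero
    expression there; planted_auxotrophies maps condition -> biomass
    components that must become non-producible once those genes are off.
    Consistency (the listed knockouts really sever the listed components,
    and nothing else kills growth outright) is verified at build time.
    """

    n_compartments: int = 2
    n_pathway_modules: int = 5
    planted_auxotrophies: dict[str, set[str]] = field(default_factory=dict)
    planted_inactive: dict[str, set[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_compartments < 2:
            raise ValueError("need at least extracellular + cytosol")
        if self.n_pathway_modules < 1:
            raise ValueError("need at least one pathway module")


RIBOFLAVIN = "ribo_c"


def default_study_spec(seed: int = 0) -> ToySpec:
    """The shipped four-condition design: a temperature/aeration contrast
    with a cofactor auxotrophy planted in the static and hot conditions
    and the most inactive genes in the hot one."""
    return ToySpec(
        n_compartments=2,
        n_pathway_modules=5,
        planted_inactive={
            "30D": {"g_mod1_spare", "g_mod2_spare"},
            "30DS": {"g_rib3"},
            "30X": {"g_xks"},
            "45D": {"g_rib4", "g_fmn1", "g_mod3_spare", "g_mod4_spare",
                    "g_mod5_spare"},
        },
        planted_auxotrophies={
            "30DS": {RIBOFLAVIN},
            "45D": {RIBOFLAVIN},
        },
        seed=seed,
    )


def make_toy_model(spec: ToySpec) -> Model:
    """Deterministic planted model for a :class:`ToySpec`.

    Structure: glucose uptake and a gene-bearing transporter; one
    xylose arm gated by a kinase-like gene; ``n_pathway_modules``
    two-step linear modules each yielding a biomass precursor (with a
    spare isoenzyme gene on the second step, so planting the spare
    inactive changes expression but not the network); the riboflavin-like
    chain; biomass over the precursors plus the cofactor.
    """
    m = Model(
        id=f"PLANT-{spec.seed}",
        compartments={"e": "extracellular", "c": "cytosol"},
    )
    if spec.n_compartments >= 3:
        m.compartments["m"] = "mitochondria"

    def met(mid, name="", comp="c"):
        if not m.has_metabolite(mid):
            m.metabolites.append(Metabolite(mid, name, comp))
        return mid

    def rxn(rid, stoich, lb, ub, gpr_text=None):
        g = parse_gpr(gpr_text) if gpr_text else None
        if g is not None:
            m.genes |= g.genes()
        m.reactions.append(Reaction(rid, rid, stoich, lb, ub, gpr=g))

    met("glc_e", "glucose", "e")
    met("glc_c", "glucose", "c")
    rxn("EX_glc", {"glc_e": -1.0}, -10.0, 1000.0)
    rxn("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, 1000.0, "g_t_glc")

    # xylose arm: closed by default, gated by a xylulokinase-like gene
    met("xyl_e", "xylose", "e")
    met("xyl_c", "xylose", "c")
    rxn("EX_xyl", {"xyl_e": -1.0}, 0.0, 1000.0)
    rxn("T_xyl", {"xyl_e": -1.0, "xyl_c": 1.0}, 0.0, 1000.0, "g_t_xyl")
    rxn("R_xyl_assim", {"xyl_c": -1.0, "glc_c": 1.0}, 0.0, 1000.0, "g_xks")

    biomass: dict[str, float] = {}
    n = spec.n_pathway_modules
    for i in range(1, n + 1):
        inter = met(f"I{i}_c", f"module {i} intermediate")
        prec = met(f"P{i}_c", f"precursor {i}")
        rxn(f"R_mod{i}_a", {"glc_c": -1.0, inter: 1.0}, 0.0, 1000.0,
            f"g_mod{i}_a")
        # spare isoenzyme: reaction survives if either gene is expressed
        rxn(f"R_mod{i}_b", {inter: -1.0, prec: 1.0}, 0.0, 1000.0,
            f"g_mod{i}_b or g_mod{i}_spare")
        biomass[prec] = -1.0 / n

    # riboflavin-like chain: two converging branches, then a linear tail
    met("gtp_c", "GTP-like branch head")
    met("ru5p_c", "pentose-phosphate branch head")
    met("draul_c", "ribitylaminouracil-like intermediate")
    met("dhbp_c", "dihydroxybutanone-phosphate-like intermediate")
    met("lum_c", "lumazine-like intermediate")
    met(RIBOFLAVIN, "riboflavin")
    met("fmn_c", "FMN")
    met("fad_c", "FAD")
    rxn("R_gtp", {"glc_c": -1.0, "gtp_c": 1.0}, 0.0, 1000.0, "g_gtp")
    rxn("R_ru5p", {"glc_c": -1.0, "ru5p_c": 1.0}, 0.0, 1000.0, "g_ru5p")
    rxn("R_rib_gtp_arm", {"gtp_c": -1.0, "draul_c": 1.0}, 0.0, 1000.0, "g_rib1")
    rxn("R_rib3", {"ru5p_c": -1.0, "dhbp_c": 1.0}, 0.0, 1000.0, "g_rib3")
    rxn("R_rib4", {"draul_c": -1.0, "dhbp_c": -1.0, "lum_c": 1.0}, 0.0, 1000.0,
        "g_rib4")
    rxn("R_rib5", {"lum_c": -1.0, RIBOFLAVIN: 1.0}, 0.0, 1000.0, "g_rib5")
    rxn("R_fmn1", {RIBOFLAVIN: -1.0, "fmn_c": 1.0}, 0.0, 1000.0, "g_fmn1")
    rxn("R_fad1", {"fmn_c": -1.0, "fad_c": 1.0}, 0.0, 1000.0, "g_fad1")
    biomass[RIBOFLAVIN] = -0.01

    if spec.n_compartments >= 3:
        # route the last module's precursor through the organelle
        last = f"P{n}_c"
        met(f"P{n}_m", f"precursor {n}", "m")
        rxn(f"T_P{n}_in", {last: -1.0, f"P{n}_m": 1.0}, -1000.0, 1000.0,
            f"g_t_p{n}")
        met("spare_m", "organelle spare", "m")
        rxn("R_org", {f"P{n}_m": -1.0, "spare_m": 1.0}, 0.0, 1000.0, "g_org")
        rxn("DMT_spare", {"spare_m": -1.0}, 0.0, 1000.0)

    rxn("BIOMASS", biomass, 0.0, 1000.0)
    m.objective_reaction = "BIOMASS"
    m.validate()
    _check_planted_consistency(m, spec)
    return m


def _check_planted_consistency(model: Model, spec: ToySpec) -> None:
    base = solve_fba(model)
    if not base.optimal or base.objective <= 1e-6:
        raise ValueError("generated model does not grow in its default medium")
    for cond, mets in spec.planted_auxotrophies.items():
        inactive = spec.planted_inactive.get(cond, set())
        cm = derive_condition_model(model, inactive, cond)
        for mid in mets:
            flux, ok = producibility(cm.model, mid)
            if ok:
                raise ValueError(
                    f"inconsistent spec: {mid} still producible in {cond} "
                    f"with {sorted(inactive)} inactive"
                )


def default_medium(model: Model) -> MediumDefinition:
    """Minimal glucose medium for generated models."""
    return MediumDefinition(
        name="minimal_glucose",
        bounds={"EX_glc": (-10.0, 1000.0)},
        description="glucose as sole carbon source",
    )


# --------------------------------------------------------------------------
# Expression and growth-rate tables
# --------------------------------------------------------------------------


def make_expression(
    model: Model,
    planted_inactive: dict[str, set[str]],
    n_replicates: int = 3,
    seed: int = 0,
) -> ExpressionSet:
    """Replicate expression table with planted all-zero genes.

    Planted genes get exactly 0 in every replicate of their condition;
    all other genes draw strictly positive log-normal values.  In each
    condition one non-planted gene additionally gets a zero in exactly
    one replicate, so the all-replicates rule is genuinely exercised.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for cond, gs in planted_inactive.items():
        extra = gs - model.genes
        if extra:
            raise ValueError(f"planted genes not in model ({cond}): {sorted(extra)}")
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes)
    rows = []
    for cond in sorted(planted_inactive):
        planted = planted_inactive[cond]
        non_planted = [g for g in genes if g not in planted]
        teaser = rng.choice(non_planted) if non_planted else None
        teaser_rep = int(rng.integers(1, n_replicates + 1))
        for g in genes:
            for rep in range(1, n_replicates + 1):
                if g in planted:
                    value = 0.0
                elif n_replicates > 1 and g == teaser and rep == teaser_rep:
                    value = 0.0
                else:
                    value = float(rng.lognormal(mean=2.0, sigma=1.0))
                    value = max(value, 1e-6)
                rows.append((g, cond, rep, value))
    df = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "value"])
    return expression_from_frame(df)


def make_growth_table(
    model: Model,
    substrates: list[tuple[str, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Uptake-rate vs growth-rate table with additive Gaussian noise.

    ``substrates`` lists (exchange id, uptake rate); the true growth rate
    comes from FBA at the clamped uptake, the observed one adds noise
    truncated at zero (growth rates cannot be negative).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for ex_id, uptake in substrates:
        mu = predict_growth_at_uptake(model, ex_id, uptake)
        observed = max(0.0, mu + float(rng.normal(0.0, noise_sd))) if noise_sd else mu
        rows.append((ex_id, uptake, mu, observed))
    return pd.DataFrame(rows, columns=["substrate", "uptake", "true_mu", "observed_mu"])


# --------------------------------------------------------------------------
# Random models for solver cross-validation
# --------------------------------------------------------------------------


def random_toy_model(rng: np.random.Generator) -> Model:
    """Random bounded network: a connected conversion chain from one
    substrate plus random extra (possibly reversible) reactions and an
    occasional dead end.  All bounds finite and 0-feasible, so FBA is
    always optimal — which is what makes these usable for comparing two
    LP implementations pointwise."""
    k = int(rng.integers(2, 7))
    m = Model(id="RND", compartments={"e": "extracellular", "c": "cytosol"})
    m.metabolites.append(Metabolite("S_e", compartment="e"))
    for i in range(k + 1):
        m.metabolites.append(Metabolite(f"M{i}_c", compartment="c"))
    uptake = float(rng.integers(1, 11))
    m.reactions.append(Reaction("EX_S", "", {"S_e": -1.0}, -uptake, 1000.0))
    m.reactions.append(
        Reaction("T_S", "", {"S_e": -1.0, "M0_c": 1.0}, 0.0, 1000.0)
    )
    for i in range(k):
        coeff = float(rng.integers(1, 3))
        rev = bool(rng.random() < 0.3)
        m.reactions.append(
            Reaction(
                f"R{i}", "",
                {f"M{i}_c": -1.0, f"M{i + 1}_c": coeff},
                -1000.0 if rev else 0.0,
                1000.0,
            )
        )
    n_extra = int(rng.integers(0, 4))
    for j in range(n_extra):
        a, b = rng.choice(k + 1, size=2, replace=False)
        m.reactions.append(
            Reaction(
                f"X{j}", "",
                {f"M{int(a)}_c": -float(rng.integers(1, 3)),
                 f"M{int(b)}_c": float(rng.integers(1, 3))},
                -1000.0 if rng.random() < 0.5 else 0.0,
                float(rng.integers(1, 1001)),
            )
        )
    if rng.random() < 0.3:
        m.metabolites.append(Metabolite("DEAD_c", compartment="c"))
        m.reactions.append(
            Reaction("R_dead", "", {"DEAD_c": -1.0, "M0_c": 1.0}, 0.0, 1000.0)
        )
    m.reactions.append(
        Reaction("GROWTH", "", {f"M{k}_c": -1.0}, 0.0, 1000.0)
    )
    m.objective_reaction = "GROWTH"
    m.validate()
    return m
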