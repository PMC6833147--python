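"""Study orchestration: validate -> screen -> condition models -> surplus.

A single YAML config drives the whole workflow; outputs (condition models
as SBML, TSV reports, a log and a config snapshot) land in a run
directory, every file stamped with the config hash so a rerun is
attributable and byte-identical for identical inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .condition import (
    condition_models_from_expression,
    condition_report,
    detect_auxotrophies,
    rescue_auxotrophies,
)
from .fba import solve_fba
from .model_io import (
    MediumDefinition,
    apply_medium,
    read_expression,
    read_medium,
    read_sbml,
    write_sbml,
)
from .surplus import surplus_table

logger = logging.getLogger("gemkit.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str, hint: str = ""):
        text = f"[{stage}] {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)
        self.stage = stage


@dataclass
class RunConfig:
    model_path: str
    expression_path: str
    conditions: list[str]
    medium_path: str | None = None
    rich_medium_path: str | None = None
    components: list[str] = field(default_factory=list)
    growth_fraction: float = 0.9
    flux_zero_tol: float = 1e-6
    seed: int = 0
    output_dir: str = "run_output"

    def __post_init__(self):
        if not 0.0 <= self.growth_fraction <= 1.0:
            raise ValueError("growth_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "model_path": self.model_path,
            "expression_path": self.expression_path,
            "conditions": list(self.conditions),
            "medium_path": self.medium_path,
            "rich_medium_path": self.rich_medium_path,
            "components": list(self.components),
            "growth_fraction": self.growth_fraction,
            "flux_zero_tol": self.flux_zero_tol,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    def digest(self) -> str:
        # output_dir is excluded: two runs of the same analysis into
        # different directories are the same study
        doc = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(path: Path, config_hash: str) -> None:
    with open(path, "a") as fh:
        fh.write(f"# config_hash: {config_hash}\n")


def run_study(config: RunConfig) -> Path:
    """Run the full study; returns the run directory.

    Stages: load inputs, base-model FBA sanity check, per-condition model
    derivation from expression, auxotrophy detection and rescue, the
    condition report, and the surplus table at the configured growth
    fraction.  Any stage failure raises :class:`StageError` naming the
    stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = config.digest()
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        logger.info("gemkit %s run, config hash %s", __version__, config_hash)
        with open(out / "config_snapshot.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
            fh.write(f"# config_hash: {config_hash}\n")

        try:
            model = read_sbml(config.model_path)
        except Exception as exc:
            raise StageError("load-model", str(exc),
                             "check the SBML file and its FBC bounds") from exc
        try:
            expr = read_expression(config.expression_path)
        except FileNotFoundError as exc:
            raise StageError("load-expression",
                             f"expression file not found: {config.expression_path}",
                             "point expression_path at a gene/condition/"
                             "replicate/value TSV") from exc
        except Exception as exc:
            raise StageError("load-expression", str(exc)) from exc

        medium = read_medium(config.medium_path) if config.medium_path else None
        rich = (
            read_medium(config.rich_medium_path)
            if config.rich_medium_path
            else medium
        )
        if medium is not None:
            model = apply_medium(model, medium)

        base = solve_fba(model)
        if not base.optimal or base.objective <= 0:
            raise StageError("validate", "base model does not grow in the medium",
                             "open enough exchange bounds in the medium YAML")
        logger.info("stage validate: mu_max %.6f (%.2fs)", base.objective,
                    time.time() - t0)

        missing = [c for c in config.conditions if c not in expr.conditions]
        if missing:
            raise StageError("condition-models",
                             f"conditions absent from expression data: {missing}")
        cms = condition_models_from_expression(model, expr, config.conditions)

        components = config.components or [
            mid for mid, coeff in model.reaction(model.objective_reaction)
            .stoichiometry.items() if coeff < 0
        ]

        rescued = {}
        for cond, cm in cms.items():
            working = apply_medium(cm.model, rich) if rich is not None else cm.model
            cm.model = working
            aux = detect_auxotrophies(cm, components, medium=None,
                                      tol=config.flux_zero_tol)
            cm = rescue_auxotrophies(cm, aux)
            rescued[cond] = cm
            write_sbml(cm.model, out / f"cm_{cond}.xml")
            logger.info(
                "stage condition-models: %s inactive=%d deactivated=%d aux=%s",
                cond, len(cm.inactive_genes), len(cm.deactivated_reactions),
                sorted(aux),
            )

        report = condition_report(list(rescued.values()), config.growth_fraction)
        report_path = out / "condition_report.tsv"
        report.to_csv(report_path, sep="\t", index=False)
        _stamp(report_path, config_hash)

        table = surplus_table(list(rescued.values()), components,
                              config.growth_fraction)
        surplus_path = out / "surplus_table.tsv"
        table.to_csv(surplus_path, sep="\t", index=False)
        _stamp(surplus_path, config_hash)
        logger.info("run complete in %.2fs", time.time() - t0)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
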