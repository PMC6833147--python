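import numpy as np
import pandas as pd
import pytest

from gemkit.condition import (
    call_inactive_genes,
    condition_models_from_expression,
    condition_report,
    derive_condition_model,
    detect_auxotrophies,
    inactive_in_any_condition,
    rescue_auxotrophies,
)
from gemkit.fba import producibility, solve_fba
from gemkit.model_io import expression_from_frame
from gemkit.synth import (
    RIBOFLAVIN,
    ToySpec,
    default_study_spec,
    make_expression,
    make_toy_model,
)


def _expr(rows):
    return expression_from_frame(
        pd.DataFrame(rows, columns=["gene", "condition", "replicate", "value"])
    )


class TestCallInactiveGenes:
    def test_all_zero_replicates_called_inactive(self):
        expr = _expr([("g", "A", r, 0.0) for r in (1, 2, 3)])
        assert call_inactive_genes(expr, "A") == {"g"}

    def test_any_nonzero_replicate_keeps_gene_active(self):
        expr = _expr([("g", "A", 1, 0.0), ("g", "A", 2, 5.0), ("g", "A", 3, 0.0)])
        assert call_inactive_genes(expr, "A") == set()

    def test_no_abundance_threshold_tiny_values_are_active(self):
        expr = _expr([("g", "A", r, 1e-12) for r in (1, 2, 3)])
        assert call_inactive_genes(expr, "A") == set()

    def test_gene_missing_from_condition_is_active(self):
        expr = _expr(
            [("g1", "A", r, 0.0) for r in (1, 2, 3)]
            + [("g2", "B", r, 1.0) for r in (1, 2, 3)]
        )
        assert call_inactive_genes(expr, "B") == set()

    def test_partial_replicates_do_not_count(self):
        # only 2 of 3 replicates recorded, both zero: no call
        expr = _expr(
            [("g1", "A", 1, 0.0), ("g1", "A", 2, 0.0)]
            + [("g2", "A", r, 1.0) for r in (1, 2, 3)]
        )
        assert call_inactive_genes(expr, "A") == set()

    def test_unknown_condition_raises(self):
        expr = _expr([("g", "A", 1, 1.0)])
        with pytest.raises(KeyError):
            call_inactive_genes(expr, "Z")

    def test_union_over_conditions(self, study_expression, study_spec):
        union = inactive_in_any_condition(study_expression)
        planted_union = set().union(*study_spec.planted_inactive.values())
        assert union == planted_union

    def test_planted_recovery_exact_over_many_random_fixtures(self, study_model):
        rng = np.random.default_rng(7)
        genes = sorted(study_model.genes)
        for trial in range(100):
            planted = {
                "condA": set(rng.choice(genes, size=rng.integers(0, 6), replace=False)),
                "condB": set(rng.choice(genes, size=rng.integers(0, 6), replace=False)),
            }
            expr = make_expression(study_model, planted, 3, seed=trial)
            for cond, truth in planted.items():
                assert call_inactive_genes(expr, cond) == truth


class TestDeriveConditionModel:
    def test_and_rule_deactivates_and_kills_growth(self, toy1_model):
        cm = derive_condition_model(toy1_model, {"g2"})
        assert cm.deactivated_reactions == {"R1"}
        assert solve_fba(cm.model).objective == pytest.approx(0.0, abs=1e-9)

    def test_empty_inactive_set_is_identity(self, toy1_model):
        cm = derive_condition_model(toy1_model, set())
        assert cm.deactivated_reactions == set()
        assert solve_fba(cm.model).objective == pytest.approx(10.0)

    def test_non_model_genes_ignored(self, toy1_model):
        cm = derive_condition_model(toy1_model, {"not_a_gene"})
        assert cm.inactive_genes == set()
        assert cm.deactivated_reactions == set()

    def test_other_constraints_left_intact(self, study_model):
        cm = derive_condition_model(study_model, {"g_rib4"})
        for r in study_model.reactions:
            got = cm.model.reaction(r.id)
            if r.id in cm.deactivated_reactions:
                assert (got.lower_bound, got.upper_bound) == (0.0, 0.0)
            else:
                assert (got.lower_bound, got.upper_bound) == (
                    r.lower_bound, r.upper_bound,
                )

    def test_growth_never_exceeds_base(self, study_model):
        rng = np.random.default_rng(3)
        base_mu = solve_fba(study_model).objective
        genes = sorted(study_model.genes)
        for trial in range(20):
            inactive = set(rng.choice(genes, size=rng.integers(0, 8), replace=False))
            cm = derive_condition_model(study_model, inactive)
            sol = solve_fba(cm.model)
            mu = sol.objective if sol.optimal else 0.0
            assert mu <= base_mu + 1e-9

    def test_deactivation_monotone_in_inactive_genes(self, study_model):
        rng = np.random.default_rng(4)
        genes = sorted(study_model.genes)
        for trial in range(20):
            small = set(rng.choice(genes, size=3, replace=False))
            big = small | set(rng.choice(genes, size=3, replace=False))
            d_small = derive_condition_model(study_model, small).deactivated_reactions
            d_big = derive_condition_model(study_model, big).deactivated_reactions
            assert d_small <= d_big


class TestAuxotrophies:
    def test_planted_break_detected(self, study_model, study_expression):
        cms = condition_models_from_expression(
            study_model, study_expression, ["30D", "30DS", "45D"]
        )
        components = [
            mid for mid, c in study_model.reaction("BIOMASS").stoichiometry.items()
            if c < 0
        ]
        assert detect_auxotrophies(cms["30D"], components) == set()
        assert detect_auxotrophies(cms["30DS"], components) == {RIBOFLAVIN}
        assert detect_auxotrophies(cms["45D"], components) == {RIBOFLAVIN}

    def test_all_genes_inactive_flags_every_gene_dependent_component(self, study_model):
        cm = derive_condition_model(study_model, set(study_model.genes))
        components = [
            mid for mid, c in study_model.reaction("BIOMASS").stoichiometry.items()
            if c < 0
        ]
        assert detect_auxotrophies(cm, components) == set(components)

    def test_rescue_restores_growth(self, study_model, study_expression):
        cms = condition_models_from_expression(study_model, study_expression, ["45D"])
        cm = cms["45D"]
        assert not solve_fba(cm.model).objective > 1e-6
        rescued = rescue_auxotrophies(cm, {RIBOFLAVIN})
        assert solve_fba(rescued.model).objective > 1e-6
        flux, ok = producibility(rescued.model, RIBOFLAVIN)
        assert ok

    def test_rescue_of_empty_set_is_identity(self, study_model):
        cm = derive_condition_model(study_model, set(), "x")
        rescued = rescue_auxotrophies(cm, set())
        assert len(rescued.model.reactions) == len(cm.model.reactions)

    def test_rescue_idempotent(self, study_model, study_expression):
        cms = condition_models_from_expression(study_model, study_expression, ["45D"])
        once = rescue_auxotrophies(cms["45D"], {RIBOFLAVIN})
        twice = rescue_auxotrophies(once, {RIBOFLAVIN})
        assert len(twice.model.reactions) == len(once.model.reactions)
        assert twice.rescued_metabolites == {RIBOFLAVIN}


class TestConditionReport:
    def test_planted_counts_reproduced(self, study_model):
        planted = {"c1": 5, "c2": 2, "c3": 1}
        rng = np.random.default_rng(9)
        genes = sorted(study_model.genes)
        planted_sets = {
            cond: set(rng.choice(genes, size=n, replace=False))
            for cond, n in planted.items()
        }
        expr = make_expression(study_model, planted_sets, 3, seed=2)
        cms = condition_models_from_expression(study_model, expr, list(planted))
        report = condition_report(
            [rescue_auxotrophies(cm, detect_auxotrophies(
                cm, [RIBOFLAVIN])) for cm in cms.values()],
            growth_fraction=0.9,
        )
        got = dict(zip(report["condition"], report["n_inactive_genes"]))
        assert got == planted

    def test_identical_conditions_identical_rows(self, study_model, study_expression):
        cms = condition_models_from_expression(
            study_model, study_expression, ["30D"]
        )
        cm = cms["30D"]
        report = condition_report([cm, cm], growth_fraction=0.9)
        assert report.iloc[0].drop("condition").equals(report.iloc[1].drop("condition"))

    def test_empty_model_list_gives_empty_table(self):
        report = condition_report([], growth_fraction=0.9)
        assert len(report) == 0

    def test_limiting_exchange_is_carbon_source(self, study_model):
        cm = derive_condition_model(study_model, set(), "base")
        report = condition_report([cm], growth_fraction=0.9)
        assert report.loc[0, "limiting_exchange"] == "EX_glc"
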