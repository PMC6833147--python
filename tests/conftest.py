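from itertools import combinations

import numpy as np
import pytest

from gemkit.gapfill import _producible_with
from gemkit.synth import (
    default_study_spec,
    make_expression,
    make_toy_model,
    toy1,
    toy_bio,
)


@pytest.fixture
def toy1_model():
    return toy1()


@pytest.fixture
def toy_bio_model():
    return toy_bio()


@pytest.fixture(scope="session")
def study_spec():
    return default_study_spec(seed=0)


@pytest.fixture(scope="session")
def study_model(study_spec):
    return make_toy_model(study_spec)


@pytest.fixture(scope="session")
def study_expression(study_spec, study_model):
    return make_expression(study_model, study_spec.planted_inactive, 3, seed=0)


def to_cobra(model):
    """Independent LP route: rebuild the model in cobrapy and let its own
    solver stack optimise it."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        mt.id: cobra.Metabolite(mt.id, compartment=mt.compartment)
        for mt in model.metabolites
    }
    rxns = [
        cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        for r in model.reactions
    ]
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites({mets[mid]: c for mid, c in r.stoichiometry.items()})
    cm.objective = model.objective_reaction
    return cm


def enumerate_min_fill(model, pool, target, eps=0.01):
    """Brute-force gap-fill oracle: smallest subset (then lexicographically
    smallest) of pool reactions restoring producibility, or None."""
    ids = sorted(r.id for r in pool.reactions)
    for k in range(len(ids) + 1):
        for sub in combinations(ids, k):
            if _producible_with(model, pool, set(sub), target, eps):
                return set(sub)
    return None


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
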