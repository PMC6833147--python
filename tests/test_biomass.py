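import pytest
from hypothesis import given, settings, strategies as st

from gemkit.biomass import (
    BiomassComposition,
    CompositionError,
    assemble_biomass,
    add_ngam,
    biomass_mass,
    monomer_fractions_from_sequences,
    partition_carbohydrates,
    scale_to_biomass,
)
from gemkit.fba import solve_fba
from gemkit.gem_core import Metabolite, Model, Reaction


class TestMonomerFractions:
    def test_single_residue_type(self):
        assert monomer_fractions_from_sequences([("AAAA", 1)], "protein") == {"ala": 1.0}

    def test_equal_weights_symmetric(self):
        got = monomer_fractions_from_sequences([("AT", 1), ("GC", 1)], "dna")
        assert got == {"dA": 0.25, "dC": 0.25, "dG": 0.25, "dT": 0.25}

    def test_weighted_counts(self):
        got = monomer_fractions_from_sequences([("AAT", 2), ("G", 1)], "dna")
        assert got == pytest.approx({"dA": 4 / 7, "dT": 2 / 7, "dG": 1 / 7})

    def test_invalid_character_located(self):
        with pytest.raises(ValueError, match="sequence 1 at position 2"):
            monomer_fractions_from_sequences([("AT", 1), ("GGX", 1)], "dna")

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            monomer_fractions_from_sequences([("AT", 0.0)], "dna")

    def test_invariant_under_duplication_with_halved_weights(self):
        seqs = [("ATGGC", 2.0), ("TTA", 3.0)]
        dup = [(s, w / 2) for s, w in seqs for _ in range(2)]
        assert monomer_fractions_from_sequences(seqs, "dna") == pytest.approx(
            monomer_fractions_from_sequences(dup, "dna")
        )


class TestScaleToBiomass:
    def test_single_monomer(self):
        comp = BiomassComposition(
            macro_fractions={"protein": 1.0},
            monomer_fractions={"protein": {"ala": 1.0}},
            monomer_masses={"ala": 0.1},
        )
        assert scale_to_biomass(comp) == {"protein": {"ala": pytest.approx(10.0)}}

    def test_two_monomers_hand_algebra(self):
        comp = BiomassComposition(
            macro_fractions={"protein": 1.0},
            monomer_fractions={"protein": {"a": 0.5, "b": 0.5}},
            monomer_masses={"a": 0.1, "b": 0.3},
        )
        coeffs = scale_to_biomass(comp)
        assert coeffs["protein"] == pytest.approx({"a": 2.5, "b": 2.5})
        assert biomass_mass(coeffs, comp.monomer_masses) == pytest.approx(1.0)

    def test_zero_macro_fraction_gives_empty_class(self):
        comp = BiomassComposition(
            macro_fractions={"protein": 1.0, "DNA": 0.0},
            monomer_fractions={"protein": {"ala": 1.0}, "DNA": {"dA": 1.0}},
            monomer_masses={"ala": 0.1, "dA": 0.3},
        )
        assert scale_to_biomass(comp)["DNA"] == {}

    def test_macro_fractions_must_close(self):
        comp = BiomassComposition(
            macro_fractions={"protein": 0.5},
            monomer_fractions={"protein": {"ala": 1.0}},
            monomer_masses={"ala": 0.1},
        )
        with pytest.raises(CompositionError, match="sum"):
            scale_to_biomass(comp)

    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.05, 1.0),  # raw macro weight (normalised below)
                st.integers(1, 5),  # number of monomers
            ),
            min_size=1,
            max_size=5,
        ),
        masses=st.lists(st.floats(0.05, 0.5), min_size=25, max_size=25),
        fracs=st.lists(st.floats(0.01, 1.0), min_size=25, max_size=25),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mass_closure_for_random_compositions(self, data, masses, fracs):
        total = sum(w for w, _ in data)
        comp_fracs, comp_masses, macro = {}, {}, {}
        idx = 0
        for ci, (w, n_mono) in enumerate(data):
            cls = f"class{ci}"
            macro[cls] = w / total
            raw = fracs[idx: idx + n_mono]
            comp_fracs[cls] = {
                f"m{ci}_{k}": f / sum(raw) for k, f in enumerate(raw)
            }
            for k in range(n_mono):
                comp_masses[f"m{ci}_{k}"] = masses[idx + k]
            idx += n_mono
        comp = BiomassComposition(macro, comp_fracs, comp_masses)
        coeffs = scale_to_biomass(comp)
        assert biomass_mass(coeffs, comp_masses) == pytest.approx(1.0, abs=1e-6)


class TestPartitionCarbohydrates:
    def test_wall_exhausts_pool(self):
        got = partition_carbohydrates(0.3, {"glucan": 0.2, "mannan": 0.1}, 1.0,
                                      {"trehalose": 0.34, "amylose": 0.16})
        assert got["trehalose"] == 0.0 and got["amylose"] == 0.0

    def test_equal_ratio_equal_masses(self):
        got = partition_carbohydrates(
            0.4, {"glucan": 0.2, "mannan": 0.08, "chitin": 0.02}, 1.0,
            {"trehalose": 0.2, "amylose": 0.2},
        )
        assert got["trehalose"] == pytest.approx(0.05)
        assert got["amylose"] == pytest.approx(0.05)

    def test_molar_ratio_respected(self):
        masses = {"trehalose": 0.342, "amylose": 0.162}
        got = partition_carbohydrates(0.4, {"glucan": 0.3}, 2.0, masses)
        n_tre = got["trehalose"] / masses["trehalose"]
        n_amy = got["amylose"] / masses["amylose"]
        assert n_tre / n_amy == pytest.approx(2.0)
        assert sum(got.values()) == pytest.approx(0.4)

    def test_wall_exceeding_total_rejected(self):
        with pytest.raises(CompositionError, match="exceeds"):
            partition_carbohydrates(0.4, {"glucan": 0.5}, 1.0, {})


def _bio_host():
    """Small host with monomers, energy metabolites and substrate supply."""
    m = Model("host", compartments={"e": "extracellular", "c": "cytosol"})
    mets = ["S_e", "ala_c", "gly_c", "atp_c", "adp_c", "pi_c", "h2o_c", "h_c"]
    comps = {"S_e": "e"}
    m.metabolites = [Metabolite(x, "", comps.get(x, "c")) for x in mets]
    m.reactions = [
        Reaction("EX_S", "", {"S_e": -1.0}, -10.0, 1000.0),
        Reaction("EX_h2o", "", {"h2o_c": 1.0}, -1000.0, 1000.0),
        Reaction("R_ala", "", {"S_e": -1.0, "ala_c": 1.0}, 0, 1000),
        Reaction("R_gly", "", {"S_e": -1.0, "gly_c": 1.0}, 0, 1000),
        Reaction("R_atp", "", {"S_e": -1.0, "adp_c": -1.0, "pi_c": -1.0,
                               "atp_c": 1.0, "h2o_c": 1.0}, 0, 1000),
        Reaction("R_adp_cycle", "", {"adp_c": 1.0, "pi_c": 1.0, "h_c": -1.0}, -1000, 1000),
        Reaction("EX_h", "", {"h_c": 1.0}, -1000.0, 1000.0),
    ]
    m.validate()
    return m


ENERGY = {"atp": "atp_c", "adp": "adp_c", "pi": "pi_c", "h2o": "h2o_c", "h": "h_c"}


def _coeffs():
    comp = BiomassComposition(
        macro_fractions={"protein": 1.0},
        monomer_fractions={"protein": {"ala_c": 0.6, "gly_c": 0.4}},
        monomer_masses={"ala_c": 0.0712, "gly_c": 0.0571},
    )
    return scale_to_biomass(comp)


class TestAssembleBiomass:
    def test_assembled_model_grows(self):
        m = assemble_biomass(_bio_host(), _coeffs(), GAM=2.0, energy_mets=ENERGY)
        sol = solve_fba(m)
        assert sol.optimal and sol.objective > 0

    def test_zero_gam_has_no_atp_term(self):
        m = assemble_biomass(_bio_host(), _coeffs(), GAM=0.0, energy_mets=ENERGY)
        assert "atp_c" not in m.reaction("BIOMASS").stoichiometry

    def test_reassembly_idempotent(self):
        m1 = assemble_biomass(_bio_host(), _coeffs(), GAM=2.0, energy_mets=ENERGY)
        m2 = assemble_biomass(m1, _coeffs(), GAM=2.0, energy_mets=ENERGY)
        assert len(m2.reactions) == len(m1.reactions)
        assert solve_fba(m2).objective == pytest.approx(solve_fba(m1).objective)

    def test_missing_monomer_listed(self):
        coeffs = {"protein": {"ala_c": 1.0, "trp_c": 1.0}}
        with pytest.raises(KeyError, match="trp_c"):
            assemble_biomass(_bio_host(), coeffs, GAM=0.0)

    def test_increasing_gam_never_increases_growth(self):
        mus = []
        for gam in (0.0, 1.0, 4.0, 16.0):
            m = assemble_biomass(_bio_host(), _coeffs(), GAM=gam, energy_mets=ENERGY)
            mus.append(solve_fba(m).objective)
        assert all(a >= b - 1e-9 for a, b in zip(mus, mus[1:]))

    def test_ngam_reserves_substrate(self):
        m = assemble_biomass(_bio_host(), _coeffs(), GAM=0.0, energy_mets=ENERGY)
        mu0 = solve_fba(m).objective
        withn = add_ngam(m, NGAM=2.0, energy_mets=ENERGY)
        mu1 = solve_fba(withn).objective
        assert withn.maintenance.NGAM == 2.0
        assert mu1 < mu0
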