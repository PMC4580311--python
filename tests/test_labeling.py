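"""EMU decomposition and labeling simulation against the isotopomer oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xumpflux.labeling import (FluxVector, SteadyStateError, SubstrateLabeling,
                               brute_force_isotopomers, emu_decompose,
                               natural_abundance_mdv, simulate_mdvs)
from xumpflux.network import load_network

from conftest import (ORACLE_FRAGMENTS, ORACLE_TOY, POSITIONAL_LABELING,
                      SPLIT_FRAGMENTS, SPLIT_TOY)

ORACLE_FLUX = FluxVector({"upt": 1, "iso": 1, "split": 1, "merge": 1, "out": 1},
                         {"iso": 0.7})
TRACER = SubstrateLabeling({"A_e": [(0.2, "U"), (0.8, "natural")]})


class TestDecomposition:
    def test_identity_chain_traces_to_substrate(self):
        doc = {"metabolites": [
            {"id": "A_e", "compartment": "extracellular", "carbon_count": 2,
             "role": "exchange"},
            {"id": "B_c", "compartment": "cytosol", "carbon_count": 2}],
            "reactions": [{"id": "r", "stoichiometry": {"A_e": -1, "B_c": 1},
                           "atom_map": {"B_c": "A_e@1, A_e@2"}}]}
        system = emu_decompose(load_network(doc), {"B": [("B_c", (1, 2))]})
        assert set(system.producers) == {("B_c", (1, 2))}
        assert system.boundary == {("A_e", (1, 2))}

    def test_das_gap_backbone_traces_to_xylulose_carbons_3_to_5(self, builtin_network):
        system = emu_decompose(builtin_network, {"GAPp": [("GAP_p", (1, 2, 3))]})
        das_terms = [t for t in system.producers[("GAP_p", (1, 2, 3))]
                     if t.rxn_id == "DAS"]
        assert das_terms and das_terms[0].sources == (("XYL5P_p", (3, 4, 5)),)

    def test_emu_reactions_conserve_size(self, builtin_network):
        system = emu_decompose(builtin_network, {"Glu": [("AKG_m", (1, 2, 3, 4, 5))],
                                                 "Ala": [("PYR_c", (1, 2, 3))]})
        for emu, terms in system.producers.items():
            size = len(emu[1])
            for term in terms:
                assert sum(len(pos) for _, pos in term.sources) == size

    def test_missing_atom_map_is_an_error(self):
        doc = {"metabolites": [
            {"id": "A_e", "compartment": "extracellular", "carbon_count": 1,
             "role": "exchange"},
            {"id": "B_c", "compartment": "cytosol", "carbon_count": 1}],
            "reactions": [{"id": "r", "stoichiometry": {"A_e": -1, "B_c": 1}}]}
        with pytest.raises(ValueError, match="atom-mapped producer"):
            emu_decompose(load_network(doc), {"B": [("B_c", (1,))]})


class TestNaturalAbundance:
    def test_zero_carbons(self):
        assert natural_abundance_mdv(0).tolist() == [1.0]

    def test_binomial_half(self):
        assert natural_abundance_mdv(2, 0.5) == pytest.approx([0.25, 0.5, 0.25])

    def test_m0_closed_form(self):
        assert natural_abundance_mdv(3)[0] == pytest.approx((1 - 0.0107) ** 3)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            natural_abundance_mdv(2, 1.5)


class TestSimulation:
    def test_natural_substrate_gives_binomial_mdvs(self, oracle_toy):
        mdvs = simulate_mdvs(oracle_toy, ORACLE_FLUX, SubstrateLabeling({}),
                             ORACLE_FRAGMENTS)
        assert mdvs["F"].values == pytest.approx(natural_abundance_mdv(3), abs=1e-12)
        assert mdvs["D"].values == pytest.approx(natural_abundance_mdv(2), abs=1e-12)

    def test_fully_labeled_substrate_gives_mn_one(self, oracle_toy):
        lab = SubstrateLabeling({"A_e": [(1.0, "U")]}, natural_13c=0.0)
        mdvs = simulate_mdvs(oracle_toy, ORACLE_FLUX, lab, ORACLE_FRAGMENTS)
        for m in mdvs.values():
            assert m.values[-1] == pytest.approx(1.0)

    def test_no_tracer_no_natural_gives_unlabeled(self, oracle_toy):
        lab = SubstrateLabeling({}, natural_13c=0.0)
        mdvs = simulate_mdvs(oracle_toy, ORACLE_FLUX, lab, ORACLE_FRAGMENTS)
        for m in mdvs.values():
            assert m.values[0] == pytest.approx(1.0)

    def test_emu_matches_brute_force_on_tracer_mixture(self, oracle_toy):
        emu = simulate_mdvs(oracle_toy, ORACLE_FLUX, TRACER, ORACLE_FRAGMENTS)
        oracle = brute_force_isotopomers(oracle_toy, ORACLE_FLUX, TRACER,
                                         ORACLE_FRAGMENTS)
        for frag in ORACLE_FRAGMENTS:
            assert np.max(np.abs(emu[frag].values - oracle[frag].values)) < 1e-9

    def test_flux_scaling_invariance(self, oracle_toy):
        a = simulate_mdvs(oracle_toy, ORACLE_FLUX, TRACER, ORACLE_FRAGMENTS)
        b = simulate_mdvs(oracle_toy, ORACLE_FLUX.scaled(13.7), TRACER,
                          ORACLE_FRAGMENTS)
        for frag in ORACLE_FRAGMENTS:
            assert a[frag].values == pytest.approx(b[frag].values, abs=1e-12)

    def test_non_steady_state_flux_rejected(self, oracle_toy):
        bad = FluxVector({"upt": 1, "iso": 0.5, "split": 1, "merge": 1, "out": 1})
        with pytest.raises(SteadyStateError):
            simulate_mdvs(oracle_toy, bad, TRACER, ORACLE_FRAGMENTS)

    def test_mdvs_normalized_and_nonnegative(self, builtin_network):
        from xumpflux.synth import reference_fluxes
        fx = reference_fluxes(builtin_network, "methanol_glycerol")
        lab = SubstrateLabeling.uniform_tracer(["GLYC_e", "MEOH_e"])
        for m in simulate_mdvs(builtin_network, fx, lab).values():
            assert np.all(m.values >= 0)
            assert m.values.sum() == pytest.approx(1.0, abs=1e-9)


class TestBruteForce:
    def test_passthrough_of_substrate_labeling(self):
        doc = {"metabolites": [
            {"id": "A_e", "compartment": "extracellular", "carbon_count": 2,
             "role": "exchange"},
            {"id": "B_c", "compartment": "cytosol", "carbon_count": 2},
            {"id": "OUT_e", "compartment": "extracellular", "carbon_count": 2,
             "role": "exchange"}],
            "reactions": [
                {"id": "in", "stoichiometry": {"A_e": -1, "B_c": 1},
                 "atom_map": {"B_c": "A_e@1, A_e@2"}},
                {"id": "out", "stoichiometry": {"B_c": -1, "OUT_e": 1},
                 "atom_map": {"OUT_e": "B_c@1, B_c@2"}}]}
        net = load_network(doc)
        lab = SubstrateLabeling({"A_e": [(0.3, "U"), (0.7, "unlabeled")]},
                                natural_13c=0.0)
        mdvs = brute_force_isotopomers(net, FluxVector({"in": 1, "out": 1}), lab,
                                       {"B": [("B_c", (1, 2))]})
        assert mdvs["B"].values == pytest.approx([0.7, 0.0, 0.3])

    def test_state_space_limit_enforced(self):
        mets = [{"id": "A_e", "compartment": "extracellular", "carbon_count": 6,
                 "role": "exchange"},
                {"id": "OUT_e", "compartment": "extracellular", "carbon_count": 6,
                 "role": "exchange"}]
        rxns = []
        prev = "A_e"
        for i in range(5):  # 5 x 6 = 30 traced carbons > 25
            mets.append({"id": f"M{i}_c", "compartment": "cytosol",
                         "carbon_count": 6})
            rxns.append({"id": f"r{i}", "stoichiometry": {prev: -1, f"M{i}_c": 1},
                         "atom_map": {f"M{i}_c": ", ".join(
                             f"{prev}@{j}" for j in range(1, 7))}})
            prev = f"M{i}_c"
        rxns.append({"id": "out", "stoichiometry": {prev: -1, "OUT_e": 1},
                     "atom_map": {"OUT_e": ", ".join(
                         f"{prev}@{j}" for j in range(1, 7))}})
        net = load_network({"metabolites": mets, "reactions": rxns})
        flux = FluxVector({f"r{i}": 1.0 for i in range(5)} | {"out": 1.0})
        with pytest.raises(ValueError, match="25"):
            brute_force_isotopomers(net, flux, TRACER,
                                    {"M": [("M4_c", (1, 2, 3, 4, 5, 6))]})


@settings(max_examples=25, deadline=None, derandomize=True)
@given(keep=st.floats(0.05, 0.95))
def test_split_toy_emu_equals_oracle_for_random_fluxes(keep):
    """EMU and isotopomer enumeration agree for arbitrary feasible splits."""
    net = load_network(SPLIT_TOY)
    flux = FluxVector({"upt": 1.0, "keep": keep, "flip": 1.0 - keep, "out": 1.0})
    emu = simulate_mdvs(net, flux, POSITIONAL_LABELING, SPLIT_FRAGMENTS)
    oracle = brute_force_isotopomers(net, flux, POSITIONAL_LABELING,
                                     SPLIT_FRAGMENTS)
    for frag in SPLIT_FRAGMENTS:
        assert np.all(emu[frag].values >= 0)
        assert emu[frag].values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.max(np.abs(emu[frag].values - oracle[frag].values)) < 1e-9
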