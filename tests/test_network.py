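"""Model loading, balance validation, net reactions and variants."""

import numpy as np
import pytest

from xumpflux.network import (ModelError, load_builtin_model, load_network,
                              build_variant, cofactor_trace, net_reaction,
                              parse_formula, stoichiometric_matrix,
                              validate_balance)

XUMP_MULTISET = {"DAS": 3, "DAK": 3, "TPI_p": 1, "FBA_p": 1, "FBP_p": 1,
                 "TKL1_p": 1, "SBA_p": 1, "SHB17": 1, "TKL2_p": 1,
                 "RKI_p": 1, "RPE_p": 1}
XUMP_INTERNAL = ["XYL5P_p", "DHA_p", "DHAP_p", "FBP_p", "F6P_p", "E4P_p",
                 "S17BP_p", "S7P_p", "R5P_p", "RU5P_p"]

CLASSICAL_MULTISET = {"DAS": 3, "DAK": 3, "dhap_px": 3, "gap_px": 3,
                      "TPI_c": 1, "FBA_c": 2, "FBPase_c": 2, "TKL2_c": -1,
                      "TAL_c": -1, "TKL1_c": -1, "RKI_c": -1, "RPE_c": 1,
                      "x5p_imp": 3}
CLASSICAL_INTERNAL = ["XYL5P_p", "DHA_p", "DHAP_p", "DHAP_c", "FBP_c", "F6P_c",
                      "E4P_c", "S7P_c", "R5P_c", "RU5P_c", "X5P_c", "GAP_p"]


class TestLoading:
    def test_builtin_model_contains_xump_cycle_enzymes(self, builtin_network):
        for rxn in ("DAS", "DAK", "FBA_p", "FBP_p", "SHB17", "TKL1_p", "TKL2_p",
                    "RKI_p", "RPE_p"):
            assert rxn in builtin_network.reactions
        assert builtin_network.reactions["SHB17"].enzyme == "SHB17"
        assert "S17BP_p" in builtin_network.metabolites

    def test_empty_reaction_list_is_valid(self):
        net = load_network({"metabolites": [], "reactions": []})
        assert len(net.reactions) == 0

    def test_dangling_metabolite_reference_rejected(self):
        doc = {"metabolites": [{"id": "A_c", "compartment": "cytosol",
                                "carbon_count": 1}],
               "reactions": [{"id": "r", "stoichiometry": {"A_c": -1, "B_c": 1}}]}
        with pytest.raises(ModelError, match="undeclared metabolite"):
            load_network(doc)

    def test_duplicate_ids_rejected(self):
        met = {"id": "A_c", "compartment": "cytosol", "carbon_count": 1}
        with pytest.raises(ModelError, match="duplicate"):
            load_network({"metabolites": [met, met], "reactions": []})

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ModelError, match="compartment"):
            load_network({"metabolites": [{"id": "A", "compartment": "vacuole"}],
                          "reactions": []})

    def test_formula_carbon_mismatch_rejected(self):
        with pytest.raises(ModelError, match="carbons"):
            load_network({"metabolites": [{"id": "A_c", "compartment": "cytosol",
                                           "carbon_count": 2, "formula": "CH4O"}],
                          "reactions": []})

    def test_parse_formula(self):
        assert parse_formula("C7H16O13P2") == {"C": 7, "H": 16, "O": 13, "P": 2}
        with pytest.raises(ModelError):
            parse_formula("c7h16")


class TestBalance:
    def test_every_shipped_reaction_is_carbon_balanced(self, builtin_network):
        reports = validate_balance(builtin_network)
        failures = [r for r, rep in reports.items() if not rep.ok]
        assert failures == []
        # non-exempt reactions are positively checked, not skipped
        checked = [r for r, rep in reports.items() if rep.carbon_ok is True]
        assert len(checked) >= 40

    def test_das_balances_six_carbons(self, builtin_network):
        rep = validate_balance(builtin_network)["DAS"]
        assert rep.carbon_ok and rep.carbon_delta == 0

    def test_atom_maps_are_bijections(self, builtin_network):
        reports = validate_balance(builtin_network)
        mapped = [r for r, rep in reports.items() if rep.atom_map_ok is not None]
        assert mapped and all(reports[r].atom_map_ok for r in mapped)

    def test_zero_stoichiometry_reaction_passes(self):
        net = load_network({"metabolites": [], "reactions":
                            [{"id": "noop", "stoichiometry": {}}]})
        assert validate_balance(net)["noop"].ok

    def test_missing_phosphate_product_flags_element_imbalance(self, builtin_network):
        import json
        from importlib import resources
        doc = json.loads((resources.files("xumpflux.models")
                          / "xump_peroxisomal.json").read_text())
        for r in doc["reactions"]:
            if r["id"] == "SHB17":
                del r["stoichiometry"]["Pi"]
        net = load_network(doc)
        rep = validate_balance(net)["SHB17"]
        assert rep.element_ok is False
        assert rep.element_delta.get("P") == pytest.approx(-1)
        assert rep.carbon_ok  # carbon alone still balances


class TestNetReaction:
    def test_xump_cycle_yields_one_gap_per_three_formaldehyde(self, builtin_network):
        nr = net_reaction(builtin_network, XUMP_MULTISET, XUMP_INTERNAL)
        assert nr.stoichiometry == pytest.approx(
            {"HCHO_p": -3, "GAP_p": 1, "ATP": -3, "ADP": 3, "H2O": -2, "Pi": 2})

    def test_dissimilation_yields_two_nadh_per_formaldehyde(self, builtin_network):
        nr = net_reaction(builtin_network, {"FLD": 1, "FGH": 1, "FDH": 1},
                          ["SFGSH_c", "FOR_c"])
        assert nr.coefficient("NADH") == pytest.approx(2)
        assert nr.coefficient("CO2_c") == pytest.approx(1)
        assert nr.coefficient("HCHO_c") == pytest.approx(-1)

    def test_empty_multiset_gives_empty_net(self, builtin_network):
        assert net_reaction(builtin_network, {}, []).stoichiometry == {}

    def test_non_cancelling_internal_metabolite_raises(self, builtin_network):
        bad = dict(XUMP_MULTISET, DAS=2)  # inconsistent cycle multiplicity
        with pytest.raises(ModelError, match="does not cancel"):
            net_reaction(builtin_network, bad, XUMP_INTERNAL)

    def test_negative_multiplicity_requires_reversible(self, builtin_network):
        with pytest.raises(ModelError, match="irreversible"):
            net_reaction(builtin_network, {"DAS": -1}, [])


class TestCofactorTrace:
    def test_aox_plus_catalase_consumes_half_o2_per_methanol(self, builtin_network):
        trace = cofactor_trace(builtin_network, {"AOX": 1.0, "CTA1": 1.0})
        assert trace["O2"] == pytest.approx(-0.5)

    def test_zero_flux_gives_zeros(self, builtin_network):
        trace = cofactor_trace(builtin_network, {r: 0.0 for r in
                                                 builtin_network.reactions})
        assert all(v == 0 for v in trace.values())

    def test_oxidative_ppp_produces_two_nadph(self, builtin_network):
        assert cofactor_trace(builtin_network, {"oxppp": 1.0})["NADPH"] == 2

    def test_unknown_reaction_id_raises(self, builtin_network):
        with pytest.raises(ModelError, match="unknown reaction"):
            cofactor_trace(builtin_network, {"nope": 1.0})


class TestStoichiometricMatrix:
    def test_two_reaction_chain_shape_and_balance(self):
        doc = {"metabolites": [
            {"id": "A_c", "compartment": "cytosol", "carbon_count": 1},
            {"id": "B_c", "compartment": "cytosol", "carbon_count": 1},
            {"id": "C_c", "compartment": "cytosol", "carbon_count": 1}],
            "reactions": [
                {"id": "r1", "stoichiometry": {"A_c": -1, "B_c": 1},
                 "atom_map": {"B_c": "A_c@1"}},
                {"id": "r2", "stoichiometry": {"B_c": -1, "C_c": 1},
                 "atom_map": {"C_c": "B_c@1"}}]}
        S, mi, ri, isolated = stoichiometric_matrix(load_network(doc))
        assert S.shape == (3, 2)
        assert S[mi["B_c"]].sum() == 0  # internal row balances over the chain
        assert isolated == []

    def test_xump_multiset_lies_in_null_space(self, builtin_network):
        S, mi, ri, _ = stoichiometric_matrix(builtin_network)
        v = np.zeros(S.shape[1])
        for r, mult in XUMP_MULTISET.items():
            v[ri[r]] = mult
        resid = S @ v
        for m in XUMP_INTERNAL:
            assert abs(resid[mi[m]]) < 1e-12

    def test_isolated_metabolite_reported(self):
        doc = {"metabolites": [
            {"id": "A_c", "compartment": "cytosol", "carbon_count": 1},
            {"id": "Z_c", "compartment": "cytosol", "carbon_count": 1}],
            "reactions": []}
        *_, isolated = stoichiometric_matrix(load_network(doc))
        assert isolated == ["A_c", "Z_c"]


class TestVariants:
    def test_peroxisomal_variant_contains_shb17_and_s17bp(self, builtin_network):
        assert "SHB17" in builtin_network.reactions
        assert "S17BP_p" in builtin_network.metabolites

    def test_classical_variant_removes_s17bp_but_keeps_net_assimilation(
            self, builtin_network):
        classical = build_variant(builtin_network, "classical_ppp")
        assert "S17BP_p" not in classical.metabolites
        assert "SHB17" not in classical.reactions
        reports = validate_balance(classical)
        assert all(rep.ok for rep in reports.values())
        nr = net_reaction(classical, CLASSICAL_MULTISET, CLASSICAL_INTERNAL)
        assert nr.coefficient("HCHO_p") == pytest.approx(-3)
        assert nr.coefficient("GAP_c") == pytest.approx(1)
        assert nr.coefficient("ATP") == pytest.approx(-3)

    def test_same_tag_is_idempotent(self, builtin_network):
        assert build_variant(builtin_network, "xump_peroxisomal") == builtin_network

    def test_unknown_tag_rejected(self, builtin_network):
        with pytest.raises(ModelError, match="unknown variant"):
            build_variant(builtin_network, "no_such_variant")
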