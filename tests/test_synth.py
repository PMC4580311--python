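"""Determinism and truth-recovery of the synthetic-data generators."""

import numpy as np
import pytest

from xumpflux.labeling import SubstrateLabeling, simulate_mdvs
from xumpflux.physiology import biomass_yield, reduction_balance
from xumpflux.proteomics import enrichment_ratios
from xumpflux.synth import (SynthSpec, gen_chemostat_obs, gen_mdv_dataset,
                            gen_omics_tables, gen_peptide_table,
                            reference_fluxes)


class TestReferenceFluxes:
    @pytest.mark.parametrize("condition", ["glucose", "methanol_glycerol"])
    def test_steady_state_and_irreversibility(self, builtin_network, condition):
        from xumpflux.network import stoichiometric_matrix
        fx = reference_fluxes(builtin_network, condition)
        S, _, ri, _ = stoichiometric_matrix(builtin_network)
        v = np.array([fx.net[r] for r in ri])
        assert np.max(np.abs(S @ v)) < 1e-9
        for r, val in fx.net.items():
            if not builtin_network.reactions[r].reversible:
                assert val >= -1e-9

    def test_half_of_methanol_dissimilated_by_default(self, builtin_network):
        fx = reference_fluxes(builtin_network, "methanol_glycerol")
        assert fx.net["FLD"] == pytest.approx(0.5 * fx.net["meoh_upt"])
        assert fx.net["DAS"] == pytest.approx(0.5 * fx.net["meoh_upt"])
        # net peroxisomal export: one triose per three assimilated C1
        assert fx.net["gap_px"] == pytest.approx(fx.net["DAS"] / 3)

    def test_overrides_change_the_split(self, builtin_network):
        fx = reference_fluxes(builtin_network, "methanol_glycerol",
                              overrides={"FLD": 0.6 * 0.81})
        assert fx.net["DAS"] == pytest.approx(0.4 * 0.81)


class TestMdvStage:
    def test_zero_noise_reproduces_simulation(self, builtin_network):
        fx = reference_fluxes(builtin_network, "methanol_glycerol")
        spec = SynthSpec(seed=2, mdv_noise_sd=0.0, rate_noise_rel=0.0)
        meas, truth = gen_mdv_dataset(builtin_network, fx, spec)
        lab = SubstrateLabeling.uniform_tracer(["GLYC_e", "MEOH_e"])
        clean = simulate_mdvs(builtin_network, fx, lab)
        for frag, m in meas.mdvs.items():
            assert m.values == pytest.approx(clean[frag].values, abs=1e-12)

    def test_same_seed_bit_identical(self, builtin_network):
        fx = reference_fluxes(builtin_network, "methanol_glycerol")
        m1, _ = gen_mdv_dataset(builtin_network, fx, SynthSpec(seed=5))
        m2, _ = gen_mdv_dataset(builtin_network, fx, SynthSpec(seed=5))
        for frag in m1.mdvs:
            assert np.array_equal(m1.mdvs[frag].values, m2.mdvs[frag].values)
        assert m1.rates == m2.rates

    def test_noise_magnitude_matches_spec(self, builtin_network):
        fx = reference_fluxes(builtin_network, "methanol_glycerol")
        sd = 0.004
        devs = []
        lab = SubstrateLabeling.uniform_tracer(["GLYC_e", "MEOH_e"])
        clean = simulate_mdvs(builtin_network, fx, lab)
        for seed in range(50):
            spec = SynthSpec(seed=seed, mdv_noise_sd=sd, rate_noise_rel=0.0)
            meas, _ = gen_mdv_dataset(builtin_network, fx, spec)
            for frag, m in meas.mdvs.items():
                devs.extend(m.values - clean[frag].values)
        sample_sd = np.std(devs)
        assert 0.8 * sd <= sample_sd <= 1.2 * sd


class TestOmicsStage:
    def test_zero_noise_recovers_planted_groups_exactly(self):
        from xumpflux.omics import classify_pairs, pairs_from_tables
        spec = SynthSpec(seed=1, base_sd=0.0, rep_noise_sd=0.0)
        t, p, truth = gen_omics_tables(spec)
        pairs = pairs_from_tables(t, p)
        by_gene = {pair.gene: pair for pair in pairs}
        for _, row in truth.iterrows():
            assert by_gene[row["gene"]].transcript_call == row["transcript_call"]
            assert by_gene[row["gene"]].protein_call == row["protein_call"]
        _, counts, frac = classify_pairs(pairs)
        assert counts.get("background") == 575 - 130

    def test_no_de_genes_all_background(self):
        from xumpflux.omics import classify_pairs, pairs_from_tables
        spec = SynthSpec(seed=1, n_de=0, base_sd=0.0, rep_noise_sd=0.0)
        t, p, _ = gen_omics_tables(spec)
        _, counts, frac = classify_pairs(pairs_from_tables(t, p))
        assert counts == {"background": 575}
        assert frac == 0.0

    def test_invalid_grid_proportions_rejected(self):
        spec = SynthSpec(seed=1, de_grid={("up", "up"): 0.7})
        with pytest.raises(ValueError, match="proportions"):
            gen_omics_tables(spec)

    def test_replicate_structure(self):
        t, p, _ = gen_omics_tables(SynthSpec(seed=4))
        assert [c for c in p.columns if c.startswith("rep")] == \
            [f"rep{i}" for i in range(1, 7)]

    def test_seed_determinism(self):
        t1, p1, _ = gen_omics_tables(SynthSpec(seed=9))
        t2, p2, _ = gen_omics_tables(SynthSpec(seed=9))
        assert t1.equals(t2) and p1.equals(p2)


class TestPeptideStage:
    def test_zero_noise_recovers_planted_factors(self):
        spec = SynthSpec(seed=6, peptide_lognormal_sd=0.0)
        records, factors = gen_peptide_table(spec)
        table = enrichment_ratios(records, "AOX1")
        for prot, planted in factors.items():
            if planted is None:
                assert table[prot].flag == "only_in_pex"
            elif planted == 0:
                assert table[prot].norm_ratio == 0.0
            else:
                assert table[prot].norm_ratio == pytest.approx(planted, rel=1e-9)

    def test_lognormal_noise_recovery(self):
        """With lognormal peak-area noise of sd 0.2 and 10 peptides per
        protein the typical recovered factor sits within ~15 % of the planted
        value (the per-protein ratio error has sd near 9 %)."""
        spec = SynthSpec(seed=8, peptide_lognormal_sd=0.2)
        records, factors = gen_peptide_table(spec)
        table = enrichment_ratios(records, "AOX1")
        devs = [abs(table[p].norm_ratio / planted - 1.0)
                for p, planted in factors.items() if planted]
        assert np.median(devs) <= 0.15
        assert max(devs) <= 0.40  # ~4 sigma guard for the worst of 12 proteins

    def test_misconfigured_reference_rejected(self):
        spec = SynthSpec(seed=1, enrichment={"AOX1": 2.0, "X": 1.0})
        with pytest.raises(ValueError, match="reference"):
            gen_peptide_table(spec)


class TestChemostatStage:
    def test_truth_is_exactly_balanced(self):
        for cond in ("glucose", "methanol_glycerol"):
            _, truth = gen_chemostat_obs(SynthSpec(seed=2, condition=cond))
            assert reduction_balance(truth) == pytest.approx(1.0, abs=1e-12)

    def test_yield_pattern_echoes_study_design(self):
        _, glc = gen_chemostat_obs(SynthSpec(seed=2, condition="glucose"))
        _, mix = gen_chemostat_obs(SynthSpec(seed=2,
                                             condition="methanol_glycerol"))
        assert biomass_yield(glc) == pytest.approx(0.54, abs=0.01)
        assert biomass_yield(mix) == pytest.approx(0.57, abs=0.01)

    def test_seed_reproducibility(self):
        a, _ = gen_chemostat_obs(SynthSpec(seed=3))
        b, _ = gen_chemostat_obs(SynthSpec(seed=3))
        assert a == b
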