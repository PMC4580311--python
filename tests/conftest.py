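import numpy as np
import pytest

from xumpflux.labeling import MDV, MDVSet, SubstrateLabeling, FluxVector, simulate_mdvs
from xumpflux.network import load_builtin_model, load_network


@pytest.fixture(scope="session")
def builtin_network():
    return load_builtin_model()


#: linear chain with an isotopically distinguishable bypass: the two routes
#: B -> C keep or invert the carbon order, so positional labeling of the
#: substrate identifies the split ratio
SPLIT_TOY = {
    "metabolites": [
        {"id": "A_e", "compartment": "extracellular", "carbon_count": 3, "role": "exchange"},
        {"id": "B_c", "compartment": "cytosol", "carbon_count": 3},
        {"id": "C_c", "compartment": "cytosol", "carbon_count": 3},
        {"id": "OUT_e", "compartment": "extracellular", "carbon_count": 3, "role": "exchange"},
    ],
    "reactions": [
        {"id": "upt", "stoichiometry": {"A_e": -1, "B_c": 1},
         "atom_map": {"B_c": "A_e@1, A_e@2, A_e@3"}},
        {"id": "keep", "stoichiometry": {"B_c": -1, "C_c": 1},
         "atom_map": {"C_c": "B_c@1, B_c@2, B_c@3"}},
        {"id": "flip", "stoichiometry": {"B_c": -1, "C_c": 1},
         "atom_map": {"C_c": "B_c@3, B_c@2, B_c@1"}},
        {"id": "out", "stoichiometry": {"C_c": -1, "OUT_e": 1},
         "atom_map": {"OUT_e": "C_c@1, C_c@2, C_c@3"}},
    ],
}

#: small network exercising every EMU construct: a reversible isomerase with
#: a rotated map, a cleavage, and a condensation with 50/50 scrambling
ORACLE_TOY = {
    "metabolites": [
        {"id": "A_e", "compartment": "extracellular", "carbon_count": 3, "role": "exchange"},
        {"id": "B_c", "compartment": "cytosol", "carbon_count": 3},
        {"id": "C_c", "compartment": "cytosol", "carbon_count": 3},
        {"id": "D_c", "compartment": "cytosol", "carbon_count": 2},
        {"id": "E_c", "compartment": "cytosol", "carbon_count": 1},
        {"id": "F_c", "compartment": "cytosol", "carbon_count": 3},
        {"id": "OUT_e", "compartment": "extracellular", "carbon_count": 3, "role": "exchange"},
    ],
    "reactions": [
        {"id": "upt", "stoichiometry": {"A_e": -1, "B_c": 1},
         "atom_map": {"B_c": "A_e@1, A_e@2, A_e@3"}},
        {"id": "iso", "reversible": True, "stoichiometry": {"B_c": -1, "C_c": 1},
         "atom_map": {"C_c": "B_c@3, B_c@1, B_c@2"}},
        {"id": "split", "stoichiometry": {"C_c": -1, "D_c": 1, "E_c": 1},
         "atom_map": {"D_c": "C_c@1, C_c@2", "E_c": "C_c@3"}},
        {"id": "merge", "stoichiometry": {"D_c": -1, "E_c": -1, "F_c": 1},
         "atom_maps": [
             {"weight": 0.5, "map": {"F_c": "D_c@1, D_c@2, E_c@1"}},
             {"weight": 0.5, "map": {"F_c": "D_c@2, D_c@1, E_c@1"}}]},
        {"id": "out", "stoichiometry": {"F_c": -1, "OUT_e": 1},
         "atom_map": {"OUT_e": "F_c@1, F_c@2, F_c@3"}},
    ],
}

ORACLE_FRAGMENTS = {"F": [("F_c", (1, 2, 3))], "F12": [("F_c", (1, 2))],
                    "D": [("D_c", (1, 2))]}

SPLIT_FRAGMENTS = {"C1": [("C_c", (1,))], "C12": [("C_c", (1, 2))],
                   "C": [("C_c", (1, 2, 3))]}

POSITIONAL_LABELING = SubstrateLabeling(
    {"A_e": [(0.5, [1.0, 0.0, 0.0]), (0.5, "natural")]})


@pytest.fixture
def split_toy():
    return load_network(SPLIT_TOY)


@pytest.fixture
def oracle_toy():
    return load_network(ORACLE_TOY)


def split_measurements(network, true_keep=0.7, sd=0.004, rng=None):
    """Measurement set for the split toy from a known split ratio."""
    from xumpflux.fluxfit import MeasurementSet
    truth = FluxVector({"upt": 1.0, "keep": true_keep, "flip": 1.0 - true_keep,
                        "out": 1.0})
    clean = simulate_mdvs(network, truth, POSITIONAL_LABELING, SPLIT_FRAGMENTS)
    mdvs = MDVSet()
    for frag, m in clean.items():
        vals = m.values
        if rng is not None and sd > 0:
            vals = np.clip(vals + rng.normal(0.0, sd, vals.size), 0.0, None)
            vals = vals / vals.sum()
        mdvs[frag] = MDV(frag, vals, sd=np.full(vals.size, max(sd, 1e-6)))
    meas = MeasurementSet(mdvs=mdvs, rates={"upt": (1.0, 0.01)},
                          labeling=POSITIONAL_LABELING, fragments=SPLIT_FRAGMENTS)
    return meas, truth
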