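"""Simulate steady-state 13C labeling of proteinogenic amino acids.

Builds the reference flux distributions for growth on glucose and on the
methanol/glycerol mix (20 % U-13C tracer in each feed), simulates the
amino-acid backbone MDVs with the EMU cascade, and asks whether the two
hypotheses for xylulose-5-phosphate regeneration -- peroxisomal
rearrangements through S1,7BP versus recycling through the cytosolic
non-oxidative PPP -- are distinguishable in this measurement space.

Writes results/mdvs_<condition>.csv and results/labeling_comparison.json.
"""

import json
from pathlib import Path

import numpy as np

from xumpflux.io import write_mdv_csv
from xumpflux.labeling import SubstrateLabeling, simulate_mdvs
from xumpflux.network import load_builtin_model
from xumpflux.synth import CONDITIONS, reference_fluxes


def main():
    outdir = Path(__file__).resolve().parents[1] / "results"
    outdir.mkdir(exist_ok=True)
    base = load_builtin_model()
    report = {}

    for condition, tmpl in CONDITIONS.items():
        fluxes = reference_fluxes(base, condition)
        labeling = SubstrateLabeling.uniform_tracer(tmpl["substrates"])
        mdvs = simulate_mdvs(base, fluxes, labeling)
        write_mdv_csv(mdvs, outdir / f"mdvs_{condition}.csv")
        m1 = {f: float(m.values[1]) for f, m in sorted(mdvs.items())}
        print(f"{condition}: wrote {len(mdvs)} fragment MDVs "
              f"(m1 fractions: { {k: round(v, 3) for k, v in m1.items()} })")
        report[condition] = {f: m.values.tolist() for f, m in sorted(mdvs.items())}

    # can the default amino-acid fragments discriminate the two variants?
    classical = load_builtin_model("classical_ppp")
    fx = reference_fluxes(base, "methanol_glycerol")
    # the classical variant shares all fluxes except the rearrangement set
    fx_cl = {r: v for r, v in fx.net.items() if r in classical.reactions}
    fx_cl.update({"dhap_px": fx.net["DAK"] - 0.0, "x5p_imp": fx.net["DAS"]})
    # re-solve cytosolic recycling fluxes on the classical network
    from xumpflux.synth import _ENERGY_FIXES
    from xumpflux.labeling import FluxVector
    import numpy.linalg as la
    from xumpflux.network import stoichiometric_matrix
    S, _, ri, _ = stoichiometric_matrix(classical)
    fixed = {r: fx.net[r] for r in ("glc_upt", "glyc_upt", "meoh_upt",
                                    "biomass", "FLD", "oxppp", "PFK")}
    fixed.update(_ENERGY_FIXES)
    rows, rhs = [S], [np.zeros(S.shape[0])]
    for r, val in fixed.items():
        e = np.zeros(S.shape[1]); e[ri[r]] = 1.0
        rows.append(e[None, :]); rhs.append([val])
    v, *_ = la.lstsq(np.vstack(rows), np.concatenate(rhs), rcond=None)
    flux_cl = FluxVector({r: float(v[j]) for r, j in ri.items()})

    lab = SubstrateLabeling.uniform_tracer(["GLYC_e", "MEOH_e"])
    mdv_perox = simulate_mdvs(base, fx, lab)
    mdv_class = simulate_mdvs(classical, flux_cl, lab)
    diffs = {f: float(np.max(np.abs(mdv_perox[f].values - mdv_class[f].values)))
             for f in mdv_perox}
    report["variant_discriminability"] = diffs
    print("max |MDV difference| between variants per fragment:",
          {k: round(v, 5) for k, v in diffs.items()})
    print("-> with cytosolic amino-acid reporters the two hypotheses are "
          "nearly isotopically equivalent" if max(diffs.values()) < 0.01 else
          "-> the variants leave measurable differences in these fragments")

    (outdir / "labeling_comparison.json").write_text(json.dumps(report, indent=1))
    print(f"wrote {outdir / 'labeling_comparison.json'}")


if __name__ == "__main__":
    main()
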