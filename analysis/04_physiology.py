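"""Chemostat balances and composition arithmetic for both growth conditions.

From the bundled printed rates (D = 0.1 1/h chemostats) this script
recomputes biomass yields, electron-balance closures, CER/OUR contrasts and
specific protein synthesis rates; summarizes the amino-acid and lipid
composition tables as totals and log2 fold changes; and evaluates the
accurate mass of sedoheptulose-1,7-bisphosphate used to identify the
metabolite.  Writes results/physiology.json.
"""

import json
from pathlib import Path

from xumpflux.io import load_dataset
from xumpflux.physiology import (ChemostatState, biomass_yield,
                                 composition_summary, monoisotopic_mz,
                                 percent_change, protein_synthesis_rate,
                                 reduction_balance)


def main():
    outdir = Path(__file__).resolve().parents[1] / "results"
    outdir.mkdir(exist_ok=True)
    rows = load_dataset("chemostat_rates").set_index("condition")
    report = {"conditions": {}}

    states = {}
    for cond, row in rows.iterrows():
        q = {s: row[f"q_{s}"] for s in ("glucose", "glycerol", "methanol")
             if row[f"q_{s}"] > 0}
        st = ChemostatState(D=row["D"], q=q, cer=row["cer"], our=row["our"],
                            biomass=row["biomass_gL"],
                            protein_content=row["protein_content"])
        states[cond] = st
        entry = {
            "yield_gCDW_per_gS": round(biomass_yield(st), 3),
            "electron_closure": round(reduction_balance(st), 3),
            "protein_synthesis_g_per_gCDW_h":
                round(protein_synthesis_rate(st.D, st.protein_content), 4),
        }
        report["conditions"][cond] = entry
        print(f"{cond}: Y_X/S = {entry['yield_gCDW_per_gS']:.2f}, "
              f"closure = {entry['electron_closure']:.2f}, "
              f"q_P = {entry['protein_synthesis_g_per_gCDW_h']:.3f} g/gCDW/h")

    glc, mix = states["glucose"], states["methanol_glycerol"]
    report["contrasts"] = {
        "cer_change_pct": round(percent_change(glc.cer, mix.cer), 1),
        "our_change_pct": round(percent_change(glc.our, mix.our), 1),
        "protein_content_change_pct":
            round(percent_change(glc.protein_content, mix.protein_content), 1),
    }
    print("CER change {:+.1f} %, OUR change {:+.1f} %, protein content "
          "{:+.1f} %".format(*report["contrasts"].values()))

    aa = load_dataset("composition_amino_acids")
    free = composition_summary(
        aa.dropna(subset=["free_glucose", "free_methanol_glycerol"]),
        "free_glucose", "free_methanol_glycerol")
    bound = composition_summary(
        aa.dropna(subset=["bound_glucose", "bound_methanol_glycerol"]),
        "bound_glucose", "bound_methanol_glycerol")
    lipids = load_dataset("composition_lipids")
    fa = composition_summary(lipids[lipids["class"] == "fatty_acid_total"],
                             "glucose", "methanol_glycerol")
    tot = lambda df: df[df["analyte"] == "Total"].iloc[0]
    report["composition"] = {
        "free_aa_total_log2fc": round(float(tot(free)["log2fc"]), 3),
        "bound_aa_total_log2fc": round(float(tot(bound)["log2fc"]), 3),
        "bound_ala_log2fc": round(float(
            bound.loc[bound["analyte"] == "Ala", "log2fc"].iloc[0]), 3),
        "fatty_acid_sum_glucose": round(float(tot(fa)["glucose"]), 2),
        "fatty_acid_sum_methanol_glycerol":
            round(float(tot(fa)["methanol_glycerol"]), 2),
    }
    print("composition:", report["composition"])

    mz = monoisotopic_mz("C7H16O13P2", "[M-H]-")
    report["s17bp_mz_neg"] = round(mz, 4)
    print(f"[S1,7BP - H]- exact mass: {mz:.4f}")

    (outdir / "physiology.json").write_text(json.dumps(report, indent=1))
    print(f"wrote {outdir / 'physiology.json'}")


if __name__ == "__main__":
    main()
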