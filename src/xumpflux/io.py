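"""Readers, writers, run configuration and the pipeline driver.

One format per role: JSON for model documents and run reports, TSV for rate
and omics tables, CSV only for MDVs (wide mass-isotopomer columns), YAML for
run configurations.  All numerics are serialized at full precision; rounding
happens only in rendered reports.  Every reader/writer pair round-trips.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .labeling import MDV, MDVSet

log = logging.getLogger("xumpflux")

__all__ = [
    "SchemaError",
    "read_table",
    "read_mdv_csv",
    "write_mdv_csv",
    "read_rates_tsv",
    "write_rates_tsv",
    "write_network",
    "RunConfig",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(path, schema: dict[str, type], sep: str = "\t") -> pd.DataFrame:
    """Read a delimited table and validate it against a column->type schema.

    Missing columns raise a :class:`SchemaError` naming the column;
    unparseable numerics raise with the 1-based data row number.  An empty
    file yields an empty frame with the schema's columns and a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        log.warning("%s: empty table", path)
        return pd.DataFrame({c: pd.Series(dtype="float64" if t is float else "object")
                             for c, t in schema.items()})
    for col, typ in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
        if typ is float:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise SchemaError(
                    f"{path}: column {col!r} is not numeric at row {bad[0] + 1} "
                    f"(value {df[col].iloc[bad[0]]!r})")
            df[col] = coerced
    return df


# -- MDV CSV -----------------------------------------------------------------

def write_mdv_csv(mdvs: MDVSet, path):
    kmax = max(m.n_carbons for m in mdvs.values())
    rows = []
    for frag, m in sorted(mdvs.items()):
        row = {"fragment_id": frag}
        for i in range(kmax + 1):
            row[f"m{i}"] = m.values[i] if i < m.values.size else np.nan
            if m.sd is not None:
                row[f"sd{i}"] = m.sd[i] if i < m.sd.size else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mdv_csv(path) -> MDVSet:
    df = read_table(path, {"fragment_id": str}, sep=",")
    mcols = sorted((c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    if not mcols:
        raise SchemaError(f"{path}: no mass-isotopomer columns m0..mk")
    sdcols = [f"sd{c[1:]}" for c in mcols]
    has_sd = all(c in df.columns for c in sdcols)
    out = MDVSet()
    for _, row in df.iterrows():
        vals = row[mcols].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        sd = None
        if has_sd:
            sd = row[sdcols].to_numpy(dtype=float)[: vals.size]
        out[row["fragment_id"]] = MDV(row["fragment_id"], vals, sd=sd)
    return out


# -- rates TSV ---------------------------------------------------------------

RATE_SCHEMA = {"quantity": str, "value": float, "sd": float, "units": str}


def write_rates_tsv(rates: dict[str, tuple[float, float]], path,
                    units: str = "mmol/gCDW/h"):
    df = pd.DataFrame([{"quantity": q, "value": v, "sd": s, "units": units}
                       for q, (v, s) in sorted(rates.items())])
    df.to_csv(path, sep="\t", index=False)


def read_rates_tsv(path) -> dict[str, tuple[float, float]]:
    df = read_table(path, RATE_SCHEMA)
    return {row["quantity"]: (float(row["value"]), float(row["sd"]))
            for _, row in df.iterrows()}


# -- model JSON --------------------------------------------------------------

def write_network(network, path):
    """Serialize a network back to the model JSON dialect."""
    doc = {
        "variant": network.variant,
        "lumping": network.lumping_notes,
        "metabolites": [
            {"id": m.id, "compartment": m.compartment,
             "carbon_count": m.carbon_count,
             **({"formula": m.formula} if m.formula else {}),
             **({"role": m.role} if m.role != "balanced" else {})}
            for m in network.metabolites.values()
        ],
        "reactions": [],
        "biomass": network.biomass,
    }
    for r in network.reactions.values():
        entry = {"id": r.id, "stoichiometry": r.stoichiometry}
        if r.reversible:
            entry["reversible"] = True
        if r.kind != "metabolic":
            entry["kind"] = r.kind
        if r.enzyme:
            entry["enzyme"] = r.enzyme
        if r.group:
            entry["group"] = r.group
        if len(r.atom_maps) == 1 and r.atom_maps[0][0] == 1.0:
            entry["atom_map"] = {
                p: ", ".join(f"{s}@{i}" for s, i in src)
                for p, src in r.atom_maps[0][1].items()}
        elif r.atom_maps:
            entry["atom_maps"] = [
                {"weight": w,
                 "map": {p: ", ".join(f"{s}@{i}" for s, i in src)
                         for p, src in amap.items()}}
                for w, amap in r.atom_maps]
        doc["reactions"].append(entry)
    Path(path).write_text(json.dumps(doc, indent=1))


# -- bundled printed-table inputs -------------------------------------------

def load_dataset(name: str) -> pd.DataFrame:
    """Load one of the bundled input tables (printed study tables shipped as
    TSV): ``composition_amino_acids``, ``composition_lipids``,
    ``chemostat_rates``, ``pts1_tails``."""
    from importlib import resources
    path = resources.files("xumpflux.data") / f"{name}.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


# -- run configuration and pipeline -----------------------------------------

@dataclass
class RunConfig:
    """Configuration of an end-to-end run (synthgen -> simulate -> fit ->
    physiology -> omics -> enrichment)."""

    seed: int
    outdir: str
    variant: str = "xump_peroxisomal"
    condition: str = "methanol_glycerol"
    n_starts: int = 3
    stages: tuple = ("synthgen", "fit", "physiology", "omics", "enrichment")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "seed" not in doc:
            raise ValueError("run config must declare a seed (stochastic stages)")
        known = {f.name for f in cls.__dataclass_fields__.values()}
        extra = set(doc) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)

    def to_yaml(self, path):
        doc = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(doc))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages on synthetic data and write a JSON run
    report with seeds, output hashes and headline results."""
    from . import __version__
    from .fluxfit import FitOptions, fit_fluxes, normalize_fluxes
    from .network import load_builtin_model
    from .omics import classify_pairs, correlate_pairs, pairs_from_tables
    from .physiology import biomass_yield, reduction_balance
    from .proteomics import enrichment_ratios
    from .synth import (SynthSpec, gen_chemostat_obs, gen_mdv_dataset,
                        gen_omics_tables, gen_peptide_table, reference_fluxes)

    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = SynthSpec(seed=config.seed, condition=config.condition)
    network = load_builtin_model(config.variant)
    report = {"version": __version__, "seed": config.seed,
              "variant": config.variant, "condition": config.condition,
              "stages": {}, "outputs": {}}

    truth_fluxes = meas = None
    for stage in config.stages:
        try:
            if stage == "synthgen":
                truth_fluxes = reference_fluxes(network, config.condition)
                meas, truth = gen_mdv_dataset(network, truth_fluxes, spec)
                write_mdv_csv(meas.mdvs, outdir / "mdvs.csv")
                write_rates_tsv(meas.rates, outdir / "rates.tsv")
                report["stages"]["synthgen"] = {
                    "fragments": sorted(meas.mdvs), "n_rates": len(meas.rates)}
            elif stage == "fit":
                if meas is None:
                    raise RuntimeError("fit requires the synthgen stage")
                # measured rates stay soft residuals; only structural zeros
                # are fixed hard
                fixed = {"resp_nadh": 0.0, "resp_fadh": 0.0,
                         "atp_maint": 0.0, "nadph_drain": 0.0}
                if config.condition == "methanol_glycerol":
                    fixed.update({"PFK": 0.0, "glc_upt": 0.0})
                else:
                    fixed.update({"FBPase_c": 0.0, "glyc_upt": 0.0,
                                  "meoh_upt": 0.0})
                est = fit_fluxes(network, meas,
                                 FitOptions(seed=config.seed, n_starts=config.n_starts,
                                            fixed=fixed))
                basis_rxns = [r for r in ("glc_upt", "glyc_upt", "meoh_upt")
                              if est.net.get(r, 0) > 1e-9]
                pct = normalize_fluxes(network, est.net, basis_rxns)
                table = pd.DataFrame(
                    {"reaction": list(est.net), "net": list(est.net.values()),
                     "pct_cmol": [pct[r] for r in est.net]})
                table.to_csv(outdir / "fluxes.tsv", sep="\t", index=False)
                rec = {r: (est.net[r], truth_fluxes.net[r]) for r in
                       ("DAS", "FLD", "oxppp", "gap_px")}
                report["stages"]["fit"] = {
                    "ssr": est.ssr, "dof": est.dof,
                    "recovered_vs_truth": rec}
            elif stage == "physiology":
                obs, truth = gen_chemostat_obs(spec)
                report["stages"]["physiology"] = {
                    "yield_obs": biomass_yield(obs),
                    "closure_obs": reduction_balance(obs),
                    "closure_truth": reduction_balance(truth)}
            elif stage == "omics":
                t_df, p_df, truth_df = gen_omics_tables(spec)
                t_df.to_csv(outdir / "transcripts.tsv", sep="\t", index=False)
                p_df.to_csv(outdir / "proteins.tsv", sep="\t", index=False)
                pairs = pairs_from_tables(t_df, p_df)
                _, counts, frac = classify_pairs(pairs)
                r, r2 = correlate_pairs(pairs)
                report["stages"]["omics"] = {
                    "group_counts": counts, "differential_fraction": frac,
                    "r": r, "r2": r2}
            elif stage == "enrichment":
                records, factors = gen_peptide_table(spec)
                table = enrichment_ratios(records, spec.reference_protein)
                df = pd.DataFrame(
                    [{"protein": p, "ratio": rec.display_ratio(), "flag": rec.flag}
                     for p, rec in sorted(table.items())])
                df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
                report["stages"]["enrichment"] = {
                    "reference_ratio": table[spec.reference_protein].norm_ratio,
                    "n_proteins": len(table)}
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "report.json":
            report["outputs"][f.name] = _sha256(f)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
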