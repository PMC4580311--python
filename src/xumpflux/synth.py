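"""Seeded generators for every synthetic input the analysis stages consume.

Each generator is a pure function of a :class:`SynthSpec`: identical specs
produce bit-identical output.  Every stage draws from its own RNG stream
derived from ``(seed, stage name)`` so that adding a stage never shifts the
draws of another.  Alongside each dataset the generating truth is returned,
which is what the downstream recovery tests assert against.

The default parameters emulate the study design the package models: carbon-
limited chemostats at D = 0.1 1/h on glucose or a methanol/glycerol mix, a
20 % fully-13C-labelled / 80 % natural substrate mixture for the labeling
experiments, three biological x two technical replicates for the omics
tables (575 gene-protein pairs, 130 of them differentially regulated,
co-regulation rho = 0.78), and peak-area peptide tables with planted
peroxisomal enrichment factors normalized to alcohol oxidase.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fluxfit import MeasurementSet
from .labeling import (DEFAULT_FRAGMENTS, FluxVector, MDV, MDVSet,
                       SubstrateLabeling, simulate_mdvs)
from .network import MetabolicNetwork, stoichiometric_matrix
from .physiology import (BIOMASS_CMOL_MASS, BIOMASS_GAMMA, ChemostatState,
                         DEGREE_OF_REDUCTION, SUBSTRATE_CARBONS)
from .proteomics import PeptideRecord

__all__ = [
    "SynthSpec",
    "stage_rng",
    "reference_fluxes",
    "gen_mdv_dataset",
    "gen_omics_tables",
    "gen_peptide_table",
    "gen_chemostat_obs",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream for one generator stage."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


#: planted enrichment factors (relative to the reference protein) for the
#: peptide-table generator; None marks proteins detected only in peroxisomal
#: preparations, 0.0 proteins absent from them
DEFAULT_ENRICHMENT = {
    "AOX1": 1.0, "DAS1": 14.8, "DAS2": 7.1, "DAK2": 0.26, "FBA1-2": 0.96,
    "FBP1": 2.4, "SHB17": 3.0, "RKI1-2": 3.0, "TAL1-2": None, "CTA1": 1.26,
    "PMP47": 8.0, "FDH1": 0.12, "TKL1": 0.0, "FBA1-1": 0.0, "PGK1": 0.0,
}

#: planted (transcript call, protein call) proportions among the
#: differentially regulated pairs; concordant induction dominates
DEFAULT_DE_GRID = {
    ("up", "up"): 0.50, ("down", "down"): 0.12,
    ("up", "unchanged"): 0.14, ("unchanged", "up"): 0.12,
    ("down", "unchanged"): 0.07, ("unchanged", "down"): 0.05,
}


@dataclass
class SynthSpec:
    """Parameters of all synthetic-data stages; ``seed`` is mandatory."""

    seed: int
    # -- labeling stage
    tracer_fraction: float = 0.20
    mdv_noise_sd: float = 0.004
    rate_noise_rel: float = 0.03
    # -- omics stage
    n_genes: int = 575
    n_de: int = 130
    rho: float = 0.78
    base_sd: float = 0.12        # sd of the correlated background fold changes
    effect_log2fc: float = 1.5   # planted |log2FC| of regulated pairs
    rep_noise_sd: float = 0.30   # per-replicate measurement noise
    n_bio: int = 3
    n_tech: int = 2
    de_grid: dict = field(default_factory=lambda: dict(DEFAULT_DE_GRID))
    # -- peptide stage
    enrichment: dict = field(default_factory=lambda: dict(DEFAULT_ENRICHMENT))
    reference_protein: str = "AOX1"
    peptides_per_protein: int = 10
    peptide_lognormal_sd: float = 0.2
    # -- chemostat stage
    condition: str = "methanol_glycerol"
    chem_noise_rel: float = 0.03

    @property
    def n_replicates(self) -> int:
        return self.n_bio * self.n_tech


# -- reference flux vectors --------------------------------------------------

#: per-condition template: uptake rates (mmol gCDW^-1 h^-1) echoing typical
#: chemostat measurements at D = 0.1 1/h, dissimilated methanol fraction,
#: oxidative-PPP flux, and the direction-fixing futile-cycle constraint
CONDITIONS = {
    "methanol_glycerol": {
        "uptakes": {"glc_upt": 0.0, "glyc_upt": 1.64, "meoh_upt": 0.81},
        "growth": 0.1, "dissim_fraction": 0.5, "oxppp": 0.45, "futile": {"PFK": 0.0},
        "substrates": ["GLYC_e", "MEOH_e"],
    },
    "glucose": {
        "uptakes": {"glc_upt": 1.02, "glyc_upt": 0.0, "meoh_upt": 0.0},
        "growth": 0.1, "dissim_fraction": 0.0, "oxppp": 0.70,
        "futile": {"FBPase_c": 0.0}, "substrates": ["GLC_e"],
    },
}

_ENERGY_FIXES = {"resp_nadh": 0.0, "resp_fadh": 0.0, "atp_maint": 0.0,
                 "nadph_drain": 0.0}


def reference_fluxes(network: MetabolicNetwork, condition: str = "methanol_glycerol",
                     overrides: dict = None) -> FluxVector:
    """Unique steady-state flux vector for a growth condition.

    Fixes the uptake rates, growth rate, the dissimilated methanol fraction,
    the oxidative-PPP flux, the futile-cycle direction and the cofactor-only
    pseudo-reactions, then solves ``S v = 0``; the resulting system is fully
    determined for the shipped model.  ``overrides`` replaces any fixed value
    (e.g. a different dissimilation split).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    tmpl = CONDITIONS[condition]
    fixed = dict(tmpl["uptakes"])
    fixed["biomass"] = tmpl["growth"]
    fixed["FLD"] = tmpl["dissim_fraction"] * fixed.get("meoh_upt", 0.0)
    fixed["oxppp"] = tmpl["oxppp"]
    fixed.update(tmpl["futile"])
    fixed.update(_ENERGY_FIXES)
    fixed.update(overrides or {})

    S, _, rxn_index, _ = stoichiometric_matrix(network)
    nr = S.shape[1]
    rows, rhs = [S], [np.zeros(S.shape[0])]
    for r, val in fixed.items():
        e = np.zeros(nr)
        e[rxn_index[r]] = 1.0
        rows.append(e[None, :])
        rhs.append([val])
    M, b = np.vstack(rows), np.concatenate(rhs)
    v, *_ = np.linalg.lstsq(M, b, rcond=None)
    resid = np.max(np.abs(M @ v - b))
    if resid > 1e-8 * max(1.0, np.max(np.abs(b))):
        raise ValueError(f"condition constraints inconsistent (residual {resid:.3g})")
    for r, j in rxn_index.items():
        if v[j] < -1e-9 and not network.reactions[r].reversible:
            raise ValueError(f"reference fluxes violate irreversibility of {r!r} "
                             f"({v[j]:.4g})")
    return FluxVector({r: float(v[j]) for r, j in rxn_index.items()})


# -- stage generators --------------------------------------------------------

def gen_mdv_dataset(network: MetabolicNetwork, true_fluxes: FluxVector,
                    spec: SynthSpec, fragments=None):
    """Noisy MDV measurement set from a known flux vector.

    Simulated MDVs receive additive Gaussian noise of sd ``mdv_noise_sd``,
    are clipped at zero and renormalized to sum 1.  Measured rates (the
    uptakes and the growth rate) receive relative Gaussian noise.  Returns
    ``(measurements, truth)`` with the generating fluxes in ``truth``.
    """
    rng = stage_rng(spec.seed, "mdv")
    fragments = dict(fragments or DEFAULT_FRAGMENTS)
    tmpl = CONDITIONS.get(spec.condition, CONDITIONS["methanol_glycerol"])
    labeling = SubstrateLabeling.uniform_tracer(tmpl["substrates"],
                                                tracer_fraction=spec.tracer_fraction)
    clean = simulate_mdvs(network, true_fluxes, labeling, fragments)
    mdvs = MDVSet()
    for frag, mdv in clean.items():
        vals = mdv.values.copy()
        if spec.mdv_noise_sd > 0:
            vals = np.clip(vals + rng.normal(0.0, spec.mdv_noise_sd, vals.size), 0.0, None)
            vals = vals / vals.sum()
        sd = np.full(vals.size, max(spec.mdv_noise_sd, 1e-6))
        mdvs[frag] = MDV(frag, vals, sd=sd)
    rates = {}
    for r in list(tmpl["uptakes"]) + ["biomass", "co2_out"]:
        true = true_fluxes.net[r]
        if true <= 0:
            continue
        sd = max(spec.rate_noise_rel * true, 1e-6)
        noisy = true + (rng.normal(0.0, sd) if spec.rate_noise_rel > 0 else 0.0)
        rates[r] = (noisy, sd)
    meas = MeasurementSet(mdvs=mdvs, rates=rates, labeling=labeling,
                          fragments=fragments)
    truth = {"fluxes": dict(true_fluxes.net), "exch": dict(true_fluxes.exch),
             "clean_mdvs": {f: m.values.copy() for f, m in clean.items()}}
    return meas, truth


def _tier_fc(call: str, effect: float) -> float:
    return {"up": effect, "down": -effect}.get(call, 0.0)


def gen_omics_tables(spec: SynthSpec):
    """Transcript and protein fold-change tables with planted regulation.

    A correlated bivariate-normal background (correlation ``rho``) underlies
    all pairs; ``n_de`` pairs additionally receive planted offsets according
    to the ``de_grid`` proportions.  Replicate-level values carry Gaussian
    noise of sd ``rep_noise_sd``; transcript p-values come from two-sample
    t statistics across biological replicates and protein p-values from
    one-sample t statistics of the replicate ratios.  With all noise at zero
    the planted calls are recovered exactly.

    Returns ``(transcripts, proteins, truth)`` data frames.
    """
    if spec.n_de > spec.n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    total = sum(spec.de_grid.values())
    if abs(total - 1.0) > 1e-9 or any(v < 0 for v in spec.de_grid.values()):
        raise ValueError("de_grid proportions must be non-negative and sum to 1")
    rng = stage_rng(spec.seed, "omics")
    n = spec.n_genes
    genes = [f"gene{i:04d}" for i in range(n)]

    cov = spec.base_sd ** 2 * np.array([[1.0, spec.rho], [spec.rho, 1.0]])
    base = (rng.multivariate_normal([0.0, 0.0], cov, size=n)
            if spec.base_sd > 0 else np.zeros((n, 2)))

    labels = [("unchanged", "unchanged")] * n
    cells, props = zip(*spec.de_grid.items())
    counts = np.floor(np.asarray(props) * spec.n_de).astype(int)
    for i in range(spec.n_de - counts.sum()):  # distribute the remainder
        counts[i % len(counts)] += 1
    de_idx = rng.choice(n, size=spec.n_de, replace=False)
    k = 0
    for cell, cnt in zip(cells, counts):
        for _ in range(cnt):
            labels[de_idx[k]] = cell
            k += 1

    t_true = base[:, 0] + np.array([_tier_fc(lab[0], spec.effect_log2fc)
                                    for lab in labels])
    p_true = base[:, 1] + np.array([_tier_fc(lab[1], spec.effect_log2fc)
                                    for lab in labels])

    n_rep = spec.n_replicates
    noise = spec.rep_noise_sd

    def t_pvalue(fc):
        if noise == 0:
            return 0.0 if fc != 0 else 1.0
        a = rng.normal(0.0, noise, n_rep)
        b = fc + rng.normal(0.0, noise, n_rep)
        from scipy.stats import ttest_ind
        return float(ttest_ind(b, a).pvalue)

    t_p = np.array([t_pvalue(fc) for fc in t_true])
    transcripts = pd.DataFrame({"gene": genes, "log2fc": t_true, "pval": t_p})

    def rep_noise():
        # technical scatter around the biological ratio: centered so the
        # reported mean fold change is unbiased per protein
        e = rng.normal(0.0, noise, n_rep)
        return e - e.mean()

    reps = np.array([fc + (rep_noise() if noise > 0 else np.zeros(n_rep))
                     for fc in p_true])
    if noise == 0:
        prot_p = np.where(p_true != 0, 0.0, 1.0)
    else:
        from scipy.stats import ttest_1samp
        prot_p = ttest_1samp(reps, 0.0, axis=1).pvalue
    proteins = pd.DataFrame({"protein": genes,
                             **{f"rep{i+1}": reps[:, i] for i in range(n_rep)},
                             "pval": prot_p})
    truth = pd.DataFrame({"gene": genes,
                          "transcript_call": [lab[0] for lab in labels],
                          "protein_call": [lab[1] for lab in labels],
                          "transcript_log2fc": t_true,
                          "protein_log2fc": p_true})
    return transcripts, proteins, truth


def gen_peptide_table(spec: SynthSpec):
    """Peak-area peptide records with planted peroxisomal enrichment.

    Each protein gets ``peptides_per_protein`` peptides whose homogenate
    peak areas are lognormal around a common scale; peroxisomal areas are
    the planted enrichment factor times a reference-level baseline with the
    same lognormal noise.  Factor ``None`` plants a protein detected only in
    peroxisomal preparations; factor 0 one absent from them.  Returns
    ``(records, truth_factors)``.
    """
    factors = dict(spec.enrichment)
    ref = spec.reference_protein
    if factors.get(ref) != 1.0:
        raise ValueError(f"reference protein {ref!r} must be planted with factor 1")
    rng = stage_rng(spec.seed, "peptides")
    base_area = 1.0e5
    ref_scale = 2.5  # raw pex/hom ratio of the reference; cancels on normalization
    sd = spec.peptide_lognormal_sd
    records = []

    def lognoise():
        return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0

    for prot, factor in factors.items():
        for i in range(spec.peptides_per_protein):
            pep = f"{prot}_pep{i}"
            rep = f"r{i % 3 + 1}"  # peptides spread over three replicate preps
            intensity = float(rng.uniform(300.0, 1.0e4))
            if factor is not None:  # quantified in homogenates
                records.append(PeptideRecord(pep, prot, rep, intensity,
                                             base_area * lognoise(), "homogenate"))
            if factor is None or factor > 0:
                f = ref_scale if factor is None else factor * ref_scale
                records.append(PeptideRecord(pep, prot, rep, intensity,
                                             base_area * f * lognoise(), "peroxisome"))
    return records, factors


def gen_chemostat_obs(spec: SynthSpec):
    """Noisy chemostat observation plus its exactly balanced truth.

    The truth state closes both the electron balance (OUR from the degree of
    reduction of substrates and biomass) and the carbon balance (CER as
    substrate carbon minus biomass carbon), so ``reduction_balance(truth)``
    is exactly 1.  The observation perturbs every rate by relative Gaussian
    noise ``chem_noise_rel``.
    """
    tmpl = CONDITIONS.get(spec.condition)
    if tmpl is None:
        raise ValueError(f"unknown condition {spec.condition!r}")
    q = {"glc_upt": "glucose", "glyc_upt": "glycerol", "meoh_upt": "methanol"}
    uptakes = {q[r]: v for r, v in tmpl["uptakes"].items() if v > 0}
    D = tmpl["growth"]
    e_in = sum(v * DEGREE_OF_REDUCTION[s] * SUBSTRATE_CARBONS[s]
               for s, v in uptakes.items())
    x_cmol = D * 1000.0 / BIOMASS_CMOL_MASS
    our = (e_in - x_cmol * BIOMASS_GAMMA) / 4.0
    cer = sum(v * SUBSTRATE_CARBONS[s] for s, v in uptakes.items()) - x_cmol
    protein = 0.54 if spec.condition == "methanol_glycerol" else 0.40
    feed = ({"glycerol": 49.0, "methanol": 8.5} if spec.condition == "methanol_glycerol"
            else {"glucose": 50.0})
    mw = {"glucose": 180.16, "glycerol": 92.09, "methanol": 32.04}
    yield_xs = D / sum(v * mw[s] / 1000.0 for s, v in uptakes.items())
    biomass = yield_xs * sum(feed.values())
    truth = ChemostatState(D=D, q=uptakes, cer=cer, our=our, biomass=biomass,
                           feed=feed, protein_content=protein)

    rng = stage_rng(spec.seed, "chemostat")
    rel = spec.chem_noise_rel

    def jitter(x):
        return float(max(x * (1.0 + rng.normal(0.0, rel)), 0.0)) if rel > 0 else x

    obs = ChemostatState(
        D=D, q={s: jitter(v) for s, v in uptakes.items()},
        cer=jitter(cer), our=jitter(our), biomass=jitter(biomass),
        feed=dict(feed), protein_content=jitter(protein))
    return obs, truth
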