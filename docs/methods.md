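# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `xumpflux`, in the order of the pipeline.

## The metabolic model

The shipped default network (`src/xumpflux/models/xump_peroxisomal.json`)
describes central carbon metabolism of a methylotrophic yeast growing on
glucose or a methanol/glycerol mix: 47 reactions over 54 metabolites in
four compartments (extracellular, cytosol, peroxisome, mitochondrion).
Compartments are encoded as id suffixes `_e/_c/_p/_m`; the same chemical
species in two compartments is two metabolites, and transport steps are
explicit, because peroxisomal compartmentalization of the assimilation
pathway is the scientific point of the model.

Groups of reactions:

* **methanol**: AOX (methanol + O₂ → formaldehyde + H₂O₂), catalase, the
  formaldehyde transporter, and the cytosolic dissimilation chain
  FLD → FGH → FDH (2 NADH per methanol dissimilated).
* **XuMP core**: DAS (HCHO + XYL5P → DHA + GAP, a transketolase-type
  transfer of XYL5P carbons 1–2 onto formaldehyde), DAK, and GAP export.
* **XuMP rearrangements** (all peroxisomal): TPI, FBP aldolase and
  phosphatase, a transketolase step F6P + GAP → XYL5P + E4P, the aldol
  condensation DHAP + E4P → S1,7BP, Shb17
  (S1,7BP → S7P + Pᵢ), a second transketolase step
  S7P + GAP → XYL5P + R5P, and RKI/RPE. Their multiset sums to
  3 HCHO + 3 ATP + 2 H₂O → GAP + 3 ADP + 2 Pᵢ, which `net_reaction`
  verifies symbolically. The S1,7BP-forming aldolase is a single reaction
  with a free enzyme label (the responsible isoform is not settled).
* **glycolysis / gluconeogenesis**, with GAPDH+PGK and PGM+enolase lumped,
  and PFK / FBPase as separate irreversible reactions (the futile pair is
  resolved per condition by fixing the inactive direction to zero).
* **PPP**: the oxidative branch lumped into one reaction producing
  2 NADPH + CO₂, plus the full non-oxidative branch.
* **TCA**, lumped into CS+ACO+IDH, KGDH+SCS, SDH+FUM and MDH. The
  succinate/fumarate symmetry is modeled as two atom maps of weight ½
  (identity and carbon-order reversal) on the SDH+FUM lump.
* **energy pseudo-reactions** (respiration at P/O 2 and 1, ATP
  maintenance, an NADPH drain). These touch no balanced carbon pool and
  are fixed to zero in all labeling work; they exist for cofactor
  bookkeeping via `cofactor_trace`.
* **biomass**: precursor drains with literature-typical yeast demands
  (mmol/gCDW), explicitly *not* measured in this project; the coefficients
  are a documented default in the model file.

Carbon indices are 1-based with C1 at the carbonyl/carboxyl end.
Validation checks carbon balance per reaction (cofactors excluded),
bijectivity of every atom map over traced carbons, and — advisory only,
where all participants carry formulas — full element balance. Exchange and
biomass reactions are exempt from the carbon check, following
constraint-based-modeling convention. Cofactors (NAD(P)H, ATP, FAD, O₂,
GSH, CoA) are not steady-state balanced; peroxisomal H₂O₂ is, which ties
the catalase flux to AOX.

The `classical_ppp` variant removes the nine peroxisomal rearrangement
reactions (and with them S1,7BP) and adds DHAP export and XYL5P import, so
regeneration runs through the existing cytosolic non-oxidative PPP. Both
variants pass validation and produce the same net assimilation
stoichiometry — the two hypotheses are deliberately indistinguishable at
the level of net carbon conversion.

## Labeling simulation

`simulate_mdvs` implements the elementary-metabolite-unit (EMU)
decomposition: target fragments are traced backward through the atom maps,
the resulting EMUs are grouped by size, and one linear system per size is
solved, with condensation products entering as convolutions of
smaller-size MDVs. Reversible reactions carry a net and a non-negative
exchange flux (`v⁺ = max(net,0) + exch`, `v⁻ = max(−net,0) + exch`);
reverse-direction atom maps are the inverse bijections of the forward
maps. The decomposition is restricted to directions actually carrying flux
(> 1e-12), which is what makes condition-dependent dead branches (e.g. the
whole peroxisome on glucose) drop out instead of producing singular
systems; a required pool without consumption flux raises a dedicated
error.

`brute_force_isotopomers` is the verification oracle: a damped fixed-point
iteration of the full positional-isotopomer balance (state space 2ⁿ per
pool, tolerance 1e-14, capped at 50 000 sweeps), marginalized to fragment
MDVs, limited to 25 traced carbons. It shares no code path with the EMU
cascade; the two agree to < 1e-9 on every test fixture, including
reversible exchange and scrambling maps.

Substrate labeling is a mixture of components per feed metabolite — fully
¹³C-labelled, natural abundance (default 1.07 % ¹³C), unlabeled, or
explicit per-position probabilities. The default experiment design is 20 %
fully labelled / 80 % natural substrate on every consumed feed.
Derivatization-atom corrections are out of scope: measured MDVs are
assumed pre-corrected.

The default fragment map reports amino-acid carbon backbones through their
biosynthetic precursors: Ala ← pyruvate, Ser ← 3-phosphoglycerate,
Gly ← Ser C1–C2, Asp/Thr ← oxaloacetate, Glu/Pro ← 2-oxoglutarate. This is
a configurable convention; amino acids formed by multi-precursor
condensations with carbon loss (Phe, Tyr, Val, Leu, Ile) are omitted from
the default table because their maps are easy to get silently wrong and
add little identifiability for the fluxes this model exposes. Fragments
composed of several EMUs are convolved, which is exact at isotopic steady
state for independent pools.

## Flux estimation

Net fluxes are parameterized as `v = v₀ + N·θ` on the null space of the
stoichiometric matrix after hard equality constraints, so steady state
holds exactly for every candidate. The objective is the variance-weighted
SSR over measured fragment MDVs plus measured extracellular rates (rates
are soft residuals — they carry measurement error; hard-fixing a dependent
rate such as CO₂ evolution would contradict the carbon balance).
Irreversibility is enforced by penalty residuals (weight 1e4 per unit
violation); outside the feasible polytope the labeling residuals are
evaluated at the clipped flux vector so that only the penalties act there.
The solver is scipy's trust-region reflective least squares with central
finite differences — one-sided differences can report false convergence
when an iterate lands exactly on a bound and the probe step samples the
frozen side. Tolerances: gtol 1e-10, xtol 1e-12, ftol 1e-12.

Multi-start (default 10 starts, seed mandatory) draws random vertices of
the flux polytope via linear programs with random costs, jittered by 5 %
of the measured-rate scale. Identifiability is checked by the singular
values of the Jacobian at the optimum: directions moving the normalized
residuals by less than 1e-3 per unit parameter are reported as
unidentifiable with a warning, never silently fixed.

Confidence intervals are parametric bootstrap: measurements perturbed
within their stated standard deviations, refit from the point estimate,
percentile interval of the refitted fluxes; deterministic per seed. On the
two-route toy network the 95 % interval covers the true flux in ≈95 % of
simulated datasets (200 simulations, 50 bootstrap draws each, asserted
within [0.88, 1.0] to absorb the binomial and percentile-interval error).

Flux maps are reported in %Cmol of substrate uptake: each flux times the
carbon atoms it transfers, divided by the summed carbon uptake of the
basis reactions, ×100 — invariant under uniform flux scaling.

## Physiology

Yield: `Y_X/S = D / Σ qᵢ·MWᵢ` with anhydrous molecular weights (glucose
180.16, glycerol 92.09, methanol 32.04 g/mol). Electron closure:
4 electrons per O₂, biomass at 26.4 g/Cmol with degree of reduction 4.2
per Cmol (configurable literature defaults, not measured here), substrate
degrees of reduction per carbon 4.0 / 4.67 / 6.0 for glucose / glycerol /
methanol. Protein synthesis rate is `D × protein content`. Composition
tables are summarized with per-analyte and total log₂(cmp/ref); a zero
reference flags the row instead of raising. Monoisotopic m/z uses IUPAC
2021 lightest-isotope masses and handles `[M−H]⁻`/`[M+H]⁺` with electron
mass included; the bundled S1,7BP formula C₇H₁₆O₁₃P₂ evaluates to
368.9993 in negative mode. Report rounding is two decimals; full precision
is kept internally.

## Omics regulation calling

Transcripts: Benjamini–Yekutieli step-up adjustment
(`c(m) = Σ 1/i`, valid under arbitrary dependence), then called up/down at
fold change ≥ 1.5 (boundary inclusive — the verbal rule is ambiguous and
the inclusive reading is documented here) with adjusted p < 0.05.
Proteins: two-tier rule (|FC| > 1.5 with p < 0.1, or 1.3 < |FC| ≤ 1.5 with
p < 0.05), more than half of the replicates concordant in direction;
|FC| ≤ 1.3 with p > 0.05 is "unchanged"; everything else is "excluded"
from further consideration. Pairs are classified on the 3×3 grid of calls;
the unchanged/unchanged cell is the background, NA and excluded-containing
cells are reported but do not enter the differential fraction (they
correspond to pairs that would have been dropped before pairing).
All non-empty cells are reported rather than a fixed seven-group layout,
since which discordant cells are populated depends on the data.

## Proteome quantification

Peptide filters: ion intensity ≥ 300, proteins with at least two
quantifying spectra, proteins present in at least three replicates; every
exclusion is logged with its reason. Protein ratios: log₂ peptide ratios
outside median ± 1.5·IQR are discarded (the upstream software's exact
outlier rule is unpublished; this default is configurable), then a
weighted mean (equal weights unless intensity-based weights are supplied)
with a t-distribution p-value against ratio 0 using the effective sample
size. Enrichment: peak areas summed per protein and fraction, the
peroxisome/homogenate ratio divided by the reference protein's ratio
(alcohol oxidase by default), so the reference is exactly 1; proteins
absent from homogenates are flagged ">>1", proteins absent from the
peroxisomal fraction score 0. The PTS1 screen is a plain C-terminal
tripeptide rule ([SAC][KRH][LM] canonical, relaxed sets for the twilight
zone) with a small exception table for tails whose published verdicts a
context-free tripeptide rule cannot reproduce; it is deliberately *not* a
trained targeting predictor, and the bundled tail table serves as a
regression fixture.

## Synthetic data

Every generator is a pure function of a `SynthSpec`; each stage draws from
`default_rng([seed, crc32(stage)])` so stages are decoupled and adding one
never shifts another's stream. Defaults encode the emulated study design:

* **chemostats** at D = 0.1 h⁻¹, glucose 1.02 mmol g⁻¹ h⁻¹ or
  glycerol 1.64 + methanol 0.81; the truth state closes carbon and
  electron balances exactly, observations get 3 % relative Gaussian noise.
* **labeling**: 20 % U-¹³C tracer, additive Gaussian MDV noise sd 0.004
  (clipped at 0, renormalized — common MFA practice), 3 % relative rate
  noise. The reference flux vector dissimilates half of the methanol and
  carries 0.45 mmol g⁻¹ h⁻¹ oxidative PPP flux; both are overridable.
* **omics**: 575 pairs, 130 planted as differentially regulated with
  |log₂FC| = 1.5 distributed over concordant-dominated grid proportions;
  a latent bivariate-normal background (sd 0.12, correlation 0.78)
  underlies all pairs; 3 biological × 2 technical replicates with
  per-replicate noise sd 0.30, centered per protein so the reported mean
  fold change is unbiased; p-values from t statistics of the generated
  replicates. With all noise at zero the planted calls are recovered
  exactly; at the defaults the recovered differential fraction is ≈0.23.
* **peptides**: 10 peptides per protein spread over three replicate
  preparations, lognormal peak-area noise sd 0.2, planted enrichment
  factors echoing the expected biology (assimilation enzymes enriched,
  cytosolic controls depleted/absent, one protein only in peroxisomal
  preparations).

What the generators deliberately do **not** emulate: microarray
normalization and moderated-variance testing (p-values come from plain t
statistics), isobaric-tag reporter interference, GC-MS fragment-specific
error structure, or day-to-day chemostat drift. Passing recovery tests
therefore demonstrates correctness of the downstream arithmetic and
estimation machinery under the stated noise model, not robustness to every
artifact of the real instruments.

## Problem sizes and numerical conventions

The statistical test batteries run on a two-route three-carbon toy network
(oracle-verified) rather than the full model: χ² calibration over 20
seeds, coverage over 200 simulations × 50 bootstrap draws, recovery to
1e-3 relative. The full 47-reaction model is exercised by a noise-free
recovery test and the analysis drivers; its EMU simulation takes ~20 ms,
a full fit under a second. Simulated MDVs are normalized to sum 1 within
1e-9; flux directions below 1e-12 are treated as zero; the brute-force
oracle refuses networks above 25 traced carbons. Model variants are
derived, never hand-duplicated, so the two stay in sync by construction.

## Known limitations

* The model is a teaching/analysis-scale network (47 reactions), not a
  genome-scale reconstruction; biomass coefficients and energy parameters
  are literature defaults.
* Exchange-flux fitting is off by default; when enabled it is bounded by
  ten times the measured-rate scale to keep the EMU systems
  well-conditioned.
* The default amino-acid fragment set limits identifiability to the
  fluxes those precursors see; peroxisome-internal rearrangement fluxes
  are constrained mainly through the stoichiometric coupling to DAS.
* Printed-table inputs (chemostat rates, composition tables, C-terminal
  tails) are transcribed study tables bundled as TSV; their arithmetic,
  not their measurement, is reproduced here.
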