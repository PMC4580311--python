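"""Chemostat steady-state balances, composition arithmetic and exact masses.

At steady state in a carbon-limited chemostat the dilution rate equals the
specific growth rate, so macroscopic quantities follow from a handful of
measured rates: biomass yield ``Y_X/S = D / sum_i(q_i * MW_i)``, electron
(degree-of-reduction) closure, and specific protein synthesis rate
``D x protein content``.  Composition tables (amino acids, lipids) are
summarized as totals and log2 fold changes between growth conditions, and a
small monoisotopic-mass utility supports accurate-mass identification of
metabolites such as sedoheptulose-1,7-bisphosphate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import parse_formula

__all__ = [
    "ChemostatState",
    "MOLECULAR_WEIGHTS",
    "DEGREE_OF_REDUCTION",
    "biomass_yield",
    "reduction_balance",
    "protein_synthesis_rate",
    "composition_summary",
    "percent_change",
    "monoisotopic_mz",
]

#: g/mol of the anhydrous substrates (a glucose feed is commonly weighed as
#: the monohydrate, 198.17 g/mol; uptake rates are molar so only the
#: anhydrous mass enters the yield)
MOLECULAR_WEIGHTS = {"glucose": 180.16, "glycerol": 92.09, "methanol": 32.04}

#: carbon atoms per molecule
SUBSTRATE_CARBONS = {"glucose": 6, "glycerol": 3, "methanol": 1}

#: degree of reduction per carbon (available electrons / C)
DEGREE_OF_REDUCTION = {"glucose": 4.0, "glycerol": 4.67, "methanol": 6.0}

#: literature-typical biomass composition: g per Cmol of biomass and degree
#: of reduction per Cmol; configurable defaults, not measured in this project
BIOMASS_CMOL_MASS = 26.4
BIOMASS_GAMMA = 4.2


@dataclass
class ChemostatState:
    """One steady-state chemostat condition.

    Units: ``D`` h^-1; ``feed`` g/L per substrate; ``biomass`` g CDW/L;
    ``q`` mmol gCDW^-1 h^-1 per substrate (uptake positive); ``cer``/``our``
    mmol gCDW^-1 h^-1; ``protein_content`` g protein / g CDW.
    """

    D: float
    q: dict[str, float]
    cer: float = 0.0
    our: float = 0.0
    biomass: float = 0.0
    feed: dict[str, float] = field(default_factory=dict)
    protein_content: float = 0.0

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("dilution rate must be > 0")
        vals = [self.cer, self.our, self.biomass, self.protein_content,
                *self.q.values(), *self.feed.values()]
        if any(v < 0 for v in vals):
            raise ValueError("chemostat quantities must be non-negative")


def biomass_yield(state: ChemostatState,
                  molecular_weights=MOLECULAR_WEIGHTS) -> float:
    """Biomass yield Y_X/S in g CDW per g substrate consumed.

    ``Y = D / sum_i(q_i * MW_i / 1000)`` with q in mmol gCDW^-1 h^-1.
    """
    denom = 0.0
    for sub, q in state.q.items():
        if q > 0:
            if sub not in molecular_weights:
                raise ValueError(f"no molecular weight configured for {sub!r}")
            denom += q * molecular_weights[sub] / 1000.0
    if denom == 0:
        raise ValueError("all substrate uptake rates are zero")
    return state.D / denom


def reduction_balance(state: ChemostatState, gamma_biomass: float = BIOMASS_GAMMA,
                      biomass_cmol_mass: float = BIOMASS_CMOL_MASS,
                      gamma=DEGREE_OF_REDUCTION) -> float:
    """Electron-balance closure of a chemostat state.

    Returns (electrons to O2 + electrons to biomass) / electrons from
    substrates; 1.0 is a closed balance.  Oxygen accepts 4 electrons per
    mole; biomass forms at ``D`` g gCDW^-1 h^-1, i.e.
    ``D * 1000 / biomass_cmol_mass`` mCmol gCDW^-1 h^-1 carrying
    ``gamma_biomass`` electrons per Cmol.
    """
    e_in = 0.0
    for sub, q in state.q.items():
        if q > 0:
            if sub not in gamma:
                raise ValueError(f"no degree of reduction configured for {sub!r}")
            e_in += q * gamma[sub] * SUBSTRATE_CARBONS[sub]
    if e_in == 0:
        raise ValueError("no substrate consumed")
    e_o2 = 4.0 * state.our
    e_x = state.D * 1000.0 / biomass_cmol_mass * gamma_biomass
    return (e_o2 + e_x) / e_in


def protein_synthesis_rate(D: float, protein_content: float) -> float:
    """Specific protein synthesis rate, g protein gCDW^-1 h^-1 = D x content."""
    if D < 0 or protein_content < 0:
        raise ValueError("inputs must be non-negative")
    return D * protein_content


def percent_change(a: float, b: float) -> float:
    """Relative change from a to b in percent: (b - a) / a x 100."""
    if a <= 0:
        raise ValueError("reference value must be > 0")
    return (b - a) / a * 100.0


def composition_summary(table: pd.DataFrame, ref_col: str, cmp_col: str,
                        analyte_col: str = "analyte") -> pd.DataFrame:
    """Totals, log2 fold changes and percent changes of a composition table.

    ``table`` holds one analyte per row with paired values for the reference
    condition (``ref_col``) and the comparison condition (``cmp_col``).  The
    returned frame adds ``log2fc = log2(cmp/ref)`` and ``pct_change`` per
    analyte plus a ``Total`` row with column sums.  Zero reference values
    yield NaN fold changes and set the ``undefined_fc`` flag instead of
    raising.
    """
    df = table[[analyte_col, ref_col, cmp_col]].copy()
    if (df[[ref_col, cmp_col]] < 0).any().any():
        raise ValueError("composition values must be >= 0")
    total = pd.DataFrame({analyte_col: ["Total"],
                          ref_col: [df[ref_col].sum()],
                          cmp_col: [df[cmp_col].sum()]})
    out = pd.concat([df, total], ignore_index=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out[cmp_col] / out[ref_col]
        out["log2fc"] = np.where(out[ref_col] > 0, np.log2(ratio), np.nan)
        out["pct_change"] = np.where(
            out[ref_col] > 0, (out[cmp_col] - out[ref_col]) / out[ref_col] * 100.0,
            np.nan)
    out["undefined_fc"] = out[ref_col] <= 0
    return out


# monoisotopic masses of the lightest isotope (IUPAC 2021), u
MONOISOTOPIC_MASS = {
    "H": 1.0078250319, "C": 12.0, "N": 14.0030740052, "O": 15.9949146221,
    "P": 30.97376151, "S": 31.97207069, "Na": 22.98976928, "K": 38.96370649,
    "Cl": 34.96885271, "F": 18.99840316, "Fe": 55.93493633, "Mg": 23.98504170,
}
ELECTRON_MASS = 0.00054857990907

MZ_MODES = ("neutral", "[M-H]-", "[M+H]+")


def monoisotopic_mz(formula, mode: str = "neutral") -> float:
    """Monoisotopic m/z of a formula in the given ionization mode.

    ``formula`` is an elemental formula string (e.g. ``C7H16O13P2``) or an
    element->count map.  ``[M-H]-`` subtracts a proton (electron retained),
    ``[M+H]+`` adds one.
    """
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    if not counts:
        raise ValueError("empty formula")
    mass = 0.0
    for el, n in counts.items():
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"element {el!r} not in the monoisotopic mass table")
        if n <= 0 or n != int(n):
            raise ValueError(f"element count for {el!r} must be a positive integer")
        mass += MONOISOTOPIC_MASS[el] * int(n)
    if mode == "neutral":
        return mass
    if mode == "[M-H]-":
        return mass - MONOISOTOPIC_MASS["H"] + ELECTRON_MASS
    if mode == "[M+H]+":
        return mass + MONOISOTOPIC_MASS["H"] - ELECTRON_MASS
    raise ValueError(f"unknown mode {mode!r}; expected one of {MZ_MODES}")
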