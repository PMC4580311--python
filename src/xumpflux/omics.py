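"""Differential-regulation calling and transcript-protein co-regulation.

Transcripts are called differentially expressed at a 1.5-fold cutoff with
Benjamini-Yekutieli adjusted p < 0.05 (the BY procedure controls the FDR
under arbitrary dependence, appropriate for correlated microarray probes).
Proteins use a two-tier rule -- strong fold change with lenient p, or
moderate fold change with strict p -- plus a replicate-consistency
requirement; records meeting neither the significance nor the "not changed"
definition are excluded from further analysis.  Gene-protein pairs are then
placed on a 3x3 grid of (transcript call x protein call) whose
unchanged/unchanged cell is the background, and co-regulation is quantified
by the Pearson correlation of the paired log2 fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TranscriptRecord",
    "ProteinRecord",
    "OmicsPair",
    "by_adjust",
    "call_transcript",
    "call_protein",
    "classify_pairs",
    "correlate_pairs",
]

TRANSCRIPT_FC_CUTOFF = 1.5
TRANSCRIPT_ALPHA = 0.05
# protein two-tier rule: (|FC|, p) thresholds
PROTEIN_TIER1 = (1.5, 0.1)
PROTEIN_TIER2 = (1.3, 0.05)
PROTEIN_UNCHANGED_FC = 1.3
PROTEIN_UNCHANGED_P = 0.05
PROTEIN_CONSISTENCY = 0.5


def by_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment.

    ``adj_(i) = min_{j >= i} ( m * c(m) / j * p_(j) )`` on the ascending
    order statistics, with ``c(m) = sum_{k=1..m} 1/k``, capped at 1.
    Monotone in rank order and always >= the raw p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


@dataclass
class TranscriptRecord:
    gene: str
    log2fc: float
    p: float
    adj_p: float | None = None

    def __post_init__(self):
        for v in (self.p, self.adj_p):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.gene}: p-value {v} outside [0, 1]")


@dataclass
class ProteinRecord:
    protein: str
    rep_log2fc: tuple[float, ...]
    p: float

    def __post_init__(self):
        self.rep_log2fc = tuple(float(x) for x in self.rep_log2fc)
        if not self.rep_log2fc:
            raise ValueError(f"{self.protein}: no replicate fold changes")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"{self.protein}: p-value {self.p} outside [0, 1]")

    @property
    def mean_log2fc(self) -> float:
        return float(np.mean(self.rep_log2fc))

    @property
    def n_replicates(self) -> int:
        return len(self.rep_log2fc)

    @property
    def consistency(self) -> float:
        """Fraction of replicates whose fold change has the sign of the mean."""
        mean = self.mean_log2fc
        if mean == 0:
            return 0.0
        same = sum(1 for x in self.rep_log2fc if math.copysign(1, x) == math.copysign(1, mean) and x != 0)
        return same / len(self.rep_log2fc)


def call_transcript(record: TranscriptRecord, fc_cutoff: float = TRANSCRIPT_FC_CUTOFF,
                    alpha: float = TRANSCRIPT_ALPHA) -> str:
    """``up`` / ``down`` / ``unchanged`` at the fold-change and adjusted-p
    cutoffs (fold-change boundary inclusive)."""
    if record.adj_p is None:
        raise ValueError(f"{record.gene}: adjusted p-value missing")
    fold = 2.0 ** record.log2fc
    if record.adj_p < alpha:
        if fold >= fc_cutoff:
            return "up"
        if fold <= 1.0 / fc_cutoff:
            return "down"
    return "unchanged"


def call_protein(record: ProteinRecord) -> str:
    """Two-tier significance call with replicate-consistency requirement.

    Significant if (|FC| > 1.5 and p < 0.1) or (1.3 < |FC| <= 1.5 and
    p < 0.05), and more than half of the replicates agree in direction;
    ``unchanged`` if |FC| <= 1.3 and p > 0.05; otherwise ``excluded``.
    """
    fold = 2.0 ** record.mean_log2fc
    mag = max(fold, 1.0 / fold)
    tier1 = mag > PROTEIN_TIER1[0] and record.p < PROTEIN_TIER1[1]
    tier2 = PROTEIN_TIER2[0] < mag <= PROTEIN_TIER1[0] and record.p < PROTEIN_TIER2[1]
    if (tier1 or tier2) and record.consistency > PROTEIN_CONSISTENCY:
        return "up" if record.mean_log2fc > 0 else "down"
    if mag <= PROTEIN_UNCHANGED_FC and record.p > PROTEIN_UNCHANGED_P:
        return "unchanged"
    return "excluded"


@dataclass
class OmicsPair:
    gene: str
    transcript_call: str  # up / down / unchanged / NA
    protein_call: str     # up / down / unchanged / NA
    transcript_log2fc: float | None = None
    protein_log2fc: float | None = None

    @property
    def group(self) -> str:
        if "NA" in (self.transcript_call, self.protein_call):
            return "NA"
        if self.transcript_call == "unchanged" and self.protein_call == "unchanged":
            return "background"
        return f"transcript_{self.transcript_call}/protein_{self.protein_call}"


def classify_pairs(pairs: Sequence[OmicsPair]):
    """Group gene-protein pairs on the 3x3 regulation grid.

    Returns ``(groups, counts, differential_fraction)`` where ``groups`` maps
    group label -> list of gene ids, ``counts`` the corresponding sizes, and
    ``differential_fraction`` is 1 minus the background fraction among fully
    evaluable pairs (groups with an NA or excluded member do not enter the
    fraction, mirroring how unevaluable proteins are dropped before
    pairing).  The counts always partition the input.
    """
    groups: dict[str, list[str]] = {}
    for pair in pairs:
        groups.setdefault(pair.group, []).append(pair.gene)
    counts = {g: len(v) for g, v in groups.items()}
    n_called = sum(c for g, c in counts.items()
                   if g != "NA" and "excluded" not in g)
    frac = 0.0
    if n_called:
        frac = 1.0 - counts.get("background", 0) / n_called
    return groups, counts, frac


def correlate_pairs(pairs: Sequence[OmicsPair]):
    """Pearson correlation of transcript vs protein log2 fold changes.

    Pairs with an NA call or missing fold change are excluded; at least three
    complete pairs with non-zero variance are required.  Returns ``(r, r2)``.
    """
    xs, ys = [], []
    for p in pairs:
        if p.group == "NA" or p.transcript_log2fc is None or p.protein_log2fc is None:
            continue
        xs.append(p.transcript_log2fc)
        ys.append(p.protein_log2fc)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(xs)}")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance in fold changes")
    r = float(stats.pearsonr(xs, ys).statistic)
    return r, r * r


def pairs_from_tables(transcripts, proteins) -> list[OmicsPair]:
    """Build called gene-protein pairs from the standard input tables.

    ``transcripts`` needs columns gene/log2fc/pval (BY adjustment is applied
    here across all genes); ``proteins`` needs protein/rep1..repN/pval.
    Genes missing from either table get an NA call on that side.
    """
    t = transcripts.set_index("gene")
    adj = by_adjust(t["pval"].to_numpy())
    t = t.assign(adj_pval=adj)
    rep_cols = [c for c in proteins.columns if c.startswith("rep")]
    p = proteins.set_index("protein")
    pairs = []
    for gene in sorted(set(t.index) | set(p.index)):
        if gene in t.index:
            row = t.loc[gene]
            t_call = call_transcript(TranscriptRecord(gene, row["log2fc"],
                                                      row["pval"], row["adj_pval"]))
            t_fc = float(row["log2fc"])
        else:
            t_call, t_fc = "NA", None
        if gene in p.index:
            row = p.loc[gene]
            reps = tuple(float(row[c]) for c in rep_cols if np.isfinite(row[c]))
            rec = ProteinRecord(gene, reps, float(row["pval"]))
            p_call = call_protein(rec)
            p_fc = rec.mean_log2fc
        else:
            p_call, p_fc = "NA", None
        pairs.append(OmicsPair(gene, t_call, p_call, t_fc, p_fc))
    return pairs
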