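"""Compartmentalized stoichiometric models with carbon atom transition maps.

The central object is :class:`MetabolicNetwork`: a set of metabolites
distributed over four compartments (extracellular, cytosol, peroxisome,
mitochondrion) and reactions with signed stoichiometry and, for every
carbon-carrying reaction, an atom map recording which substrate carbon each
product carbon derives from.  Atom maps are what make steady-state isotope
labeling simulation possible (see :mod:`xumpflux.labeling`).

The shipped default model describes central carbon metabolism of a
methylotrophic yeast: methanol oxidation and dissimilation, the peroxisomal
xylulose-monophosphate (XuMP) assimilation cycle running through
sedoheptulose-1,7-bisphosphate, glycolysis/gluconeogenesis, the pentose
phosphate pathway, and a lumped TCA cycle.  A second variant replaces the
peroxisomal sugar-phosphate rearrangements with recycling through the
canonical cytosolic non-oxidative PPP; both variants assimilate three
formaldehyde into one triose phosphate.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "NetReaction",
    "BalanceReport",
    "load_network",
    "load_builtin_model",
    "validate_balance",
    "net_reaction",
    "cofactor_trace",
    "stoichiometric_matrix",
    "build_variant",
]

COMPARTMENTS = ("extracellular", "cytosol", "peroxisome", "mitochondrion")

#: metabolite roles: ``balanced`` pools obey steady state and carry traced
#: carbons; ``cofactor`` species (NAD(P)H, ATP, O2, GSH, ...) are bookkept but
#: their carbons are not traced; ``exchange`` species cross the system
#: boundary and are not steady-state constrained.
ROLES = ("balanced", "cofactor", "exchange")

#: reaction kinds; ``exchange`` and ``biomass`` reactions are exempt from the
#: carbon-balance check (they move material across the system boundary or into
#: a macromolecular pseudo-species), following common practice in constraint-
#: based modeling toolkits.
REACTION_KINDS = ("metabolic", "transport", "exchange", "biomass")

_SUFFIX = {"_e": "extracellular", "_c": "cytosol", "_p": "peroxisome", "_m": "mitochondrion"}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelError(ValueError):
    """Raised for malformed model documents or inconsistent networks."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C7H16O13P2`` into a count map."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ModelError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise ModelError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    carbon_count: int = 0
    formula: str | None = None
    role: str = "balanced"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelError(f"{self.id}: unknown compartment {self.compartment!r}")
        if self.role not in ROLES:
            raise ModelError(f"{self.id}: unknown role {self.role!r}")
        if self.carbon_count < 0:
            raise ModelError(f"{self.id}: negative carbon count")
        if self.formula is not None:
            n_c = parse_formula(self.formula).get("C", 0)
            if n_c != self.carbon_count:
                raise ModelError(
                    f"{self.id}: formula {self.formula} has {n_c} carbons, "
                    f"declared carbon_count is {self.carbon_count}"
                )

    @property
    def species(self) -> str:
        """Base species name with any compartment suffix stripped."""
        if len(self.id) > 2 and self.id[-2:] in _SUFFIX:
            return self.id[:-2]
        return self.id


# An atom map is a dict: product metabolite id -> tuple of (substrate id,
# 1-based substrate carbon index), one entry per product carbon in order.
AtomMap = dict[str, tuple[tuple[str, int], ...]]


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    #: weighted atom maps; more than one entry encodes carbon scrambling
    #: through symmetric intermediates (e.g. succinate/fumarate), each map
    #: carrying the given fraction of the reaction flux.
    atom_maps: tuple[tuple[float, AtomMap], ...] = ()
    enzyme: str | None = None
    kind: str = "metabolic"
    group: str | None = None

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"{self.id}: unknown reaction kind {self.kind!r}")
        if self.atom_maps:
            w = sum(wt for wt, _ in self.atom_maps)
            if abs(w - 1.0) > 1e-9:
                raise ModelError(f"{self.id}: atom map weights sum to {w}, expected 1")

    @property
    def substrates(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class NetReaction:
    """Net stoichiometry of a weighted reaction multiset after cancelling
    declared internal intermediates."""

    stoichiometry: dict[str, float]

    def coefficient(self, met_id: str) -> float:
        return self.stoichiometry.get(met_id, 0.0)


@dataclass
class BalanceReport:
    reaction_id: str
    kind: str
    carbon_ok: bool | None  # None = exempt (exchange/biomass)
    carbon_delta: float
    element_ok: bool | None  # None = not all formulas present
    element_delta: dict[str, float]
    atom_map_ok: bool | None  # None = no atom map
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (self.carbon_ok is not False and self.element_ok is not False
                and self.atom_map_ok is not False)


class MetabolicNetwork:
    """A validated compartmentalized metabolic network."""

    def __init__(self, metabolites, reactions, variant="xump_peroxisomal",
                 biomass=None, lumping_notes=None):
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelError(f"duplicate reaction id {rxn.id!r}")
            self.reactions[rxn.id] = rxn
        self.variant = variant
        self.biomass: dict[str, float] = dict(biomass or {})
        self.lumping_notes: dict[str, str] = dict(lumping_notes or {})
        self._check_references()

    # -- validation ---------------------------------------------------------

    def _check_references(self):
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}")
            for _, amap in rxn.atom_maps:
                self._check_atom_map(rxn, amap)
        for met_id in self.biomass:
            if met_id not in self.metabolites:
                raise ModelError(f"biomass drain references undeclared metabolite {met_id!r}")

    def _check_atom_map(self, rxn: Reaction, amap: AtomMap):
        """Atom maps must be a bijection between traced substrate carbons and
        traced product carbons (carbons of non-cofactor metabolites)."""
        used: set[tuple[str, int]] = set()
        for prod_id, sources in amap.items():
            if prod_id not in rxn.products:
                raise ModelError(f"{rxn.id}: atom map names non-product {prod_id!r}")
            met = self.metabolites[prod_id]
            if len(sources) != met.carbon_count:
                raise ModelError(
                    f"{rxn.id}: atom map for {prod_id} covers {len(sources)} of "
                    f"{met.carbon_count} carbons")
            for sub_id, idx in sources:
                if sub_id not in rxn.substrates:
                    raise ModelError(
                        f"{rxn.id}: atom map source {sub_id!r} is not a substrate")
                sub = self.metabolites[sub_id]
                if not 1 <= idx <= sub.carbon_count:
                    raise ModelError(
                        f"{rxn.id}: carbon index {sub_id}@{idx} out of range "
                        f"(1..{sub.carbon_count})")
                if (sub_id, idx) in used:
                    raise ModelError(
                        f"{rxn.id}: substrate carbon {sub_id}@{idx} mapped twice")
                used.add((sub_id, idx))
        # bijectivity: every traced substrate carbon must be consumed,
        # every traced product carbon produced
        traced_sub = {
            (m, i)
            for m, coeff in rxn.substrates.items()
            if self.metabolites[m].role != "cofactor"
            for i in range(1, self.metabolites[m].carbon_count + 1)
        }
        traced_prod_total = sum(
            self.metabolites[m].carbon_count
            for m in rxn.products
            if self.metabolites[m].role != "cofactor"
        )
        mapped_prod_total = sum(len(s) for p, s in amap.items()
                                if self.metabolites[p].role != "cofactor")
        if used != traced_sub or mapped_prod_total != traced_prod_total:
            raise ModelError(
                f"{rxn.id}: atom map is not a bijection over traced carbons "
                f"(substrate carbons mapped {len(used)}/{len(traced_sub)}, "
                f"product carbons {mapped_prod_total}/{traced_prod_total})")

    # -- convenience --------------------------------------------------------

    def balanced_metabolites(self) -> list[str]:
        return [m for m, met in self.metabolites.items() if met.role == "balanced"]

    def carbon_metabolites(self) -> list[str]:
        return [m for m, met in self.metabolites.items()
                if met.role == "balanced" and met.carbon_count > 0]

    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            list(self.metabolites.values()), list(self.reactions.values()),
            variant=self.variant, biomass=self.biomass,
            lumping_notes=self.lumping_notes)

    def __eq__(self, other):
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (self.metabolites == other.metabolites
                and self.reactions == other.reactions
                and self.variant == other.variant
                and self.biomass == other.biomass)


# -- model document parsing -------------------------------------------------

_ATOM_RE = re.compile(r"^\s*([\w-]+)@(\d+)\s*$")


def _parse_atom_map(doc: dict) -> AtomMap:
    amap: AtomMap = {}
    for prod, spec in doc.items():
        parts = spec.split(",") if isinstance(spec, str) else list(spec)
        sources = []
        for part in parts:
            m = _ATOM_RE.match(part)
            if not m:
                raise ModelError(f"cannot parse atom source {part!r} for {prod!r}")
            sources.append((m.group(1), int(m.group(2))))
        amap[prod] = tuple(sources)
    return amap


def _reaction_from_doc(doc: dict) -> Reaction:
    maps: list[tuple[float, AtomMap]] = []
    if "atom_map" in doc and doc["atom_map"] is not None:
        maps.append((1.0, _parse_atom_map(doc["atom_map"])))
    for entry in doc.get("atom_maps", []):
        maps.append((float(entry["weight"]), _parse_atom_map(entry["map"])))
    return Reaction(
        id=doc["id"],
        stoichiometry={m: float(c) for m, c in doc["stoichiometry"].items()},
        reversible=bool(doc.get("reversible", False)),
        atom_maps=tuple(maps),
        enzyme=doc.get("enzyme"),
        kind=doc.get("kind", "metabolic"),
        group=doc.get("group"),
    )


def load_network(source) -> MetabolicNetwork:
    """Load and validate a network from a model document.

    ``source`` may be a path to a JSON file, a JSON string, or an already
    parsed dict with ``metabolites``, ``reactions`` and optional ``variant``,
    ``biomass`` and ``lumping`` keys.
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.exists():
            text = p.read_text()
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            text = source
        else:
            raise FileNotFoundError(source)
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelError(f"model document is not valid JSON: {exc}") from exc
    else:
        doc = source
    try:
        mets = [Metabolite(id=m["id"], compartment=m["compartment"],
                           carbon_count=int(m.get("carbon_count", 0)),
                           formula=m.get("formula"), role=m.get("role", "balanced"))
                for m in doc["metabolites"]]
        rxns = [_reaction_from_doc(r) for r in doc["reactions"]]
    except KeyError as exc:
        raise ModelError(f"model document missing required key: {exc}") from exc
    return MetabolicNetwork(
        mets, rxns, variant=doc.get("variant", "xump_peroxisomal"),
        biomass=doc.get("biomass"), lumping_notes=doc.get("lumping"))


def load_builtin_model(variant: str = "xump_peroxisomal") -> MetabolicNetwork:
    """Load the shipped default central-carbon model (or a variant of it)."""
    path = resources.files("xumpflux.models") / "xump_peroxisomal.json"
    net = load_network(json.loads(path.read_text()))
    if variant == net.variant:
        return net
    return build_variant(net, variant)


# -- operations -------------------------------------------------------------

def validate_balance(network: MetabolicNetwork) -> dict[str, BalanceReport]:
    """Per-reaction carbon balance, advisory element balance and atom-map
    status report.  Report-only: never raises for imbalances."""
    reports = {}
    for rxn in network.reactions.values():
        exempt = rxn.kind in ("exchange", "biomass")
        c_delta = sum(
            coeff * network.metabolites[m].carbon_count
            for m, coeff in rxn.stoichiometry.items()
            if network.metabolites[m].role != "cofactor"
        )
        carbon_ok = None if exempt else abs(c_delta) < 1e-9
        messages = []
        # element balance is advisory and only checked when every participant
        # carries a formula
        element_delta: dict[str, float] = {}
        element_ok: bool | None = None
        if not exempt and all(network.metabolites[m].formula for m in rxn.stoichiometry):
            for m, coeff in rxn.stoichiometry.items():
                for el, n in parse_formula(network.metabolites[m].formula).items():
                    element_delta[el] = element_delta.get(el, 0.0) + coeff * n
            element_delta = {el: d for el, d in element_delta.items() if abs(d) > 1e-9}
            element_ok = not element_delta
            if not element_ok:
                messages.append(f"element imbalance: {element_delta}")
        atom_ok = None
        if rxn.atom_maps:
            try:
                for _, amap in rxn.atom_maps:
                    network._check_atom_map(rxn, amap)
                atom_ok = True
            except ModelError as exc:
                atom_ok = False
                messages.append(str(exc))
        if carbon_ok is False:
            messages.append(f"carbon imbalance: {c_delta:+g}")
        reports[rxn.id] = BalanceReport(
            reaction_id=rxn.id, kind=rxn.kind, carbon_ok=carbon_ok,
            carbon_delta=c_delta, element_ok=element_ok,
            element_delta=element_delta, atom_map_ok=atom_ok, messages=messages)
    return reports


def net_reaction(network: MetabolicNetwork, multiset, internal=()) -> NetReaction:
    """Sum a weighted reaction multiset and require the declared internal
    intermediates to cancel exactly.

    ``multiset`` maps reaction id to multiplicity; negative multiplicities run
    a reversible reaction backwards.  Raises :class:`ModelError` if an
    internal metabolite does not cancel (inconsistent cycle multiplicities) or
    a negative multiplicity is applied to an irreversible reaction.
    """
    net: dict[str, float] = {}
    for rxn_id, mult in dict(multiset).items():
        if rxn_id not in network.reactions:
            raise ModelError(f"unknown reaction {rxn_id!r} in multiset")
        rxn = network.reactions[rxn_id]
        if mult < 0 and not rxn.reversible:
            raise ModelError(f"negative multiplicity on irreversible reaction {rxn_id!r}")
        for m, coeff in rxn.stoichiometry.items():
            net[m] = net.get(m, 0.0) + mult * coeff
    for m in internal:
        if abs(net.get(m, 0.0)) > 1e-9:
            raise ModelError(
                f"internal metabolite {m!r} does not cancel (net {net.get(m, 0.0):+g}); "
                "cycle multiplicities are inconsistent")
    return NetReaction({m: c for m, c in net.items() if abs(c) > 1e-9})


def cofactor_trace(network: MetabolicNetwork, flux_vector: dict[str, float],
                   species=("NADH", "NADPH", "ATP", "O2", "CO2", "FADH2")) -> dict[str, float]:
    """Net production rate of each cofactor species under a flux vector.

    Species are matched by base name, summing over compartment instances, so
    "CO2" covers both the cytosolic pool and the exported species.  Unknown
    reaction ids raise.
    """
    for rxn_id in flux_vector:
        if rxn_id not in network.reactions:
            raise ModelError(f"unknown reaction id {rxn_id!r} in flux vector")
    out = {}
    for sp in species:
        total = 0.0
        for rxn_id, v in flux_vector.items():
            rxn = network.reactions[rxn_id]
            for m, coeff in rxn.stoichiometry.items():
                if network.metabolites[m].species == sp:
                    total += v * coeff
        out[sp] = total
    return out


def stoichiometric_matrix(network: MetabolicNetwork):
    """Stoichiometric matrix over balanced metabolites.

    Returns ``(S, met_index, rxn_index, isolated)`` where rows follow
    ``met_index`` (balanced metabolites), columns follow ``rxn_index``, and
    ``isolated`` lists balanced metabolites with an all-zero row.
    """
    mets = network.balanced_metabolites()
    rxns = network.reaction_ids()
    met_index = {m: i for i, m in enumerate(mets)}
    rxn_index = {r: j for j, r in enumerate(rxns)}
    S = np.zeros((len(mets), len(rxns)))
    for r, j in rxn_index.items():
        for m, coeff in network.reactions[r].stoichiometry.items():
            if m in met_index:
                S[met_index[m], j] = coeff
    isolated = [m for m, i in met_index.items() if not S[i].any()]
    return S, met_index, rxn_index, isolated


#: reactions specific to the peroxisomal XuMP rearrangement hypothesis
XUMP_GROUP = "xump_rearrangement"
#: transports added when rearrangements move to the cytosolic PPP
_CLASSICAL_EXTRA = [
    {
        "id": "dhap_px", "stoichiometry": {"DHAP_p": -1, "DHAP_c": 1},
        "kind": "transport", "atom_map": {"DHAP_c": "DHAP_p@1, DHAP_p@2, DHAP_p@3"},
    },
    {
        "id": "x5p_imp", "stoichiometry": {"X5P_c": -1, "XYL5P_p": 1},
        "kind": "transport",
        "atom_map": {"XYL5P_p": "X5P_c@1, X5P_c@2, X5P_c@3, X5P_c@4, X5P_c@5"},
    },
]


def build_variant(base: MetabolicNetwork, variant_tag: str) -> MetabolicNetwork:
    """Derive a model variant from the shipped peroxisomal base model.

    ``classical_ppp`` removes the peroxisomal sugar-phosphate rearrangement
    reactions (and with them SHB17 and sedoheptulose-1,7-bisphosphate) and
    instead routes xylulose-5-phosphate regeneration through the existing
    cytosolic non-oxidative PPP, adding the triose export / pentose import
    transports that hypothesis requires.
    """
    if variant_tag not in ("xump_peroxisomal", "classical_ppp"):
        raise ModelError(f"unknown variant tag {variant_tag!r}")
    if variant_tag == base.variant:
        return base.copy()
    if base.variant != "xump_peroxisomal":
        raise ModelError("variants are derived from the xump_peroxisomal base model")
    keep = [r for r in base.reactions.values() if r.group != XUMP_GROUP]
    removed_ids = {r.id for r in base.reactions.values() if r.group == XUMP_GROUP}
    used = {m for r in keep for m in r.stoichiometry}
    extra = [_reaction_from_doc(d) for d in _CLASSICAL_EXTRA]
    used |= {m for r in extra for m in r.stoichiometry}
    mets = [m for m in base.metabolites.values() if m.id in used]
    net = MetabolicNetwork(mets, keep + extra, variant="classical_ppp",
                           biomass=base.biomass, lumping_notes=base.lumping_notes)
    net.lumping_notes = dict(base.lumping_notes)
    net.lumping_notes["variant"] = (
        f"classical_ppp: removed {sorted(removed_ids)}; added dhap_px, x5p_imp")
    return net
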