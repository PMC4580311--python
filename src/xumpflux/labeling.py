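"""Steady-state 13C labeling simulation via elementary metabolite units (EMU).

Given a metabolic network with carbon atom maps, a steady-state flux vector
and the isotopic composition of the feed, this module predicts the mass
distribution vectors (MDVs) of measured fragments -- here the carbon
backbones of proteinogenic amino acids, each standing in for its
central-carbon precursor pool.

Two independent routes are provided:

* :func:`simulate_mdvs` -- EMU decomposition followed by size-ordered linear
  solves; efficient, used everywhere downstream.
* :func:`brute_force_isotopomers` -- direct fixed-point solution of the full
  positional-isotopomer balance (state space ``2^n``), restricted to small
  networks; serves as the verification oracle for the EMU implementation.

Reversible reactions carry a net and an exchange flux; directional fluxes are
``v+ = max(net, 0) + exch`` and ``v- = max(-net, 0) + exch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .network import MetabolicNetwork, AtomMap

__all__ = [
    "SubstrateLabeling",
    "FluxVector",
    "MDV",
    "MDVSet",
    "FragmentMap",
    "DEFAULT_FRAGMENTS",
    "SteadyStateError",
    "SingularEMUError",
    "natural_abundance_mdv",
    "emu_decompose",
    "simulate_mdvs",
    "brute_force_isotopomers",
]

NATURAL_13C = 0.0107  # natural abundance of 13C

FLUX_TOL = 1e-12


class SteadyStateError(ValueError):
    """Flux vector violates the stoichiometric steady-state constraint."""


class SingularEMUError(ValueError):
    """An EMU balance system is singular (unreachable or zero-throughput pool)."""


# -- substrate labeling ------------------------------------------------------

@dataclass
class SubstrateLabeling:
    """Isotopic composition of the feed substrates.

    ``mixtures`` maps a boundary (exchange-role) metabolite id to a list of
    ``(fraction, spec)`` components, where ``spec`` is ``"U"`` (uniformly
    13C-labelled), ``"natural"`` (natural abundance), ``"unlabeled"``
    (12C only), or an explicit per-carbon 13C-probability sequence.
    Unlisted substrates default to natural abundance.
    """

    mixtures: dict[str, list[tuple[float, object]]] = field(default_factory=dict)
    natural_13c: float = NATURAL_13C

    def __post_init__(self):
        if not 0.0 <= self.natural_13c <= 1.0:
            raise ValueError(f"natural 13C fraction {self.natural_13c} outside [0, 1]")
        for met, comps in self.mixtures.items():
            total = sum(f for f, _ in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{met}: mixture fractions sum to {total}, expected 1")
            for f, _ in comps:
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"{met}: component fraction {f} outside [0, 1]")

    @classmethod
    def uniform_tracer(cls, substrates, tracer_fraction=0.20, natural_13c=NATURAL_13C):
        """The classic chemostat design: a `tracer_fraction` of fully
        13C-labelled substrate mixed with naturally labelled substrate,
        applied to each listed feed."""
        mix = [(tracer_fraction, "U"), (1.0 - tracer_fraction, "natural")]
        return cls({s: list(mix) for s in substrates}, natural_13c=natural_13c)

    def _positional_probs(self, spec, n: int) -> np.ndarray:
        if isinstance(spec, str):
            if spec == "U":
                return np.ones(n)
            if spec == "natural":
                return np.full(n, self.natural_13c)
            if spec == "unlabeled":
                return np.zeros(n)
            raise ValueError(f"unknown labeling spec {spec!r}")
        probs = np.asarray(spec, dtype=float)
        if probs.shape != (n,):
            raise ValueError(f"positional spec length {probs.size} != {n} carbons")
        return probs

    def components(self, met_id: str, n: int):
        comps = self.mixtures.get(met_id, [(1.0, "natural")])
        return [(f, self._positional_probs(spec, n)) for f, spec in comps]

    def emu_mdv(self, met_id: str, positions: tuple[int, ...], n_carbons: int) -> np.ndarray:
        """MDV of a substrate EMU: mixture of per-position Bernoulli convolutions."""
        out = np.zeros(len(positions) + 1)
        for frac, probs in self.components(met_id, n_carbons):
            mdv = np.array([1.0])
            for pos in positions:
                p = probs[pos - 1]
                mdv = np.convolve(mdv, [1.0 - p, p])
            out += frac * mdv
        return out

    def isotopomer_dist(self, met_id: str, n_carbons: int) -> np.ndarray:
        """Full positional-isotopomer distribution (length ``2^n``) of a
        substrate pool; bit ``i-1`` set means carbon ``i`` is 13C."""
        dist = np.zeros(2 ** n_carbons)
        for frac, probs in self.components(met_id, n_carbons):
            comp = np.array([1.0])
            for i in range(n_carbons):
                comp = np.concatenate([comp * (1 - probs[i]), comp * probs[i]])
            dist += frac * comp
        return dist


# -- flux vectors ------------------------------------------------------------

@dataclass
class FluxVector:
    """Net fluxes per reaction plus exchange fluxes for reversible reactions."""

    net: dict[str, float]
    exch: dict[str, float] = field(default_factory=dict)

    def scaled(self, factor: float) -> "FluxVector":
        return FluxVector({r: v * factor for r, v in self.net.items()},
                          {r: v * factor for r, v in self.exch.items()})

    def directional(self, network: MetabolicNetwork, strict: bool = True):
        """Yield ``(rxn_id, sense, flux)`` for every direction with positive
        flux; ``sense`` is +1 (as written) or -1 (reverse).

        With ``strict=False`` a negative net flux on an irreversible reaction
        is simulated through the inverted atom map instead of raising; the
        flux fitter relies on this to keep the objective finite just outside
        the feasible region while its penalty terms pull back inside.
        """
        for rxn_id, v in self.net.items():
            rxn = network.reactions[rxn_id]
            exch = self.exch.get(rxn_id, 0.0)
            if exch < 0:
                raise ValueError(f"{rxn_id}: negative exchange flux")
            if exch > 0 and not rxn.reversible:
                raise ValueError(f"{rxn_id}: exchange flux on irreversible reaction")
            if strict and v < -FLUX_TOL and not rxn.reversible:
                raise ValueError(f"{rxn_id}: negative net flux on irreversible reaction")
            fwd = max(v, 0.0) + exch
            bwd = max(-v, 0.0) + exch
            if fwd > FLUX_TOL:
                yield rxn_id, +1, fwd
            if bwd > FLUX_TOL:
                yield rxn_id, -1, bwd


def check_steady_state(network: MetabolicNetwork, fluxes: FluxVector, rtol=1e-6):
    from .network import stoichiometric_matrix
    S, _, rxn_index, _ = stoichiometric_matrix(network)
    v = np.zeros(S.shape[1])
    for r, val in fluxes.net.items():
        v[rxn_index[r]] = val
    resid = S @ v
    scale = max(np.max(np.abs(v)), 1.0)
    if np.max(np.abs(resid)) > rtol * scale:
        raise SteadyStateError(
            f"flux vector violates steady state (max |S v| = {np.max(np.abs(resid)):.3g})")


# -- MDVs and fragments ------------------------------------------------------

@dataclass
class MDV:
    fragment_id: str
    values: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.values < -1e-9):
            raise ValueError(f"{self.fragment_id}: negative mass-isotopomer fraction")

    @property
    def n_carbons(self) -> int:
        return self.values.size - 1

    def check_normalized(self, tol=1e-9):
        s = float(self.values.sum())
        if abs(s - 1.0) > tol:
            raise ValueError(f"{self.fragment_id}: MDV sums to {s}, expected 1")


class MDVSet(dict):
    """Mapping fragment id -> :class:`MDV`."""

    def to_arrays(self):
        return {k: v.values for k, v in self.items()}


#: fragment id -> list of (metabolite id, carbon positions); a fragment with
#: several entries is the concatenation of those EMUs and its MDV the
#: convolution of their MDVs.
FragmentMap = dict[str, list[tuple[str, tuple[int, ...]]]]

#: Default amino-acid backbone -> precursor mapping for the shipped model.
#: This is the standard single-precursor convention (alanine reports pyruvate,
#: serine/glycine report 3-phosphoglycerate, aspartate/threonine report
#: oxaloacetate, glutamate/proline report 2-oxoglutarate); it is a
#: configuration table, not a fixed property of the method.
DEFAULT_FRAGMENTS: FragmentMap = {
    "Ala": [("PYR_c", (1, 2, 3))],
    "Ser": [("PG3_c", (1, 2, 3))],
    "Gly": [("PG3_c", (1, 2))],
    "Asp": [("OAA_m", (1, 2, 3, 4))],
    "Thr": [("OAA_m", (1, 2, 3, 4))],
    "Glu": [("AKG_m", (1, 2, 3, 4, 5))],
    "Pro": [("AKG_m", (1, 2, 3, 4, 5))],
}


def natural_abundance_mdv(n_carbons: int, p13c: float = NATURAL_13C) -> np.ndarray:
    """Binomial mass distribution of an ``n``-carbon fragment at 13C
    probability ``p13c`` per position."""
    if n_carbons < 0:
        raise ValueError("n_carbons must be >= 0")
    if not 0.0 <= p13c <= 1.0:
        raise ValueError(f"p13c {p13c} outside [0, 1]")
    return binom.pmf(np.arange(n_carbons + 1), n_carbons, p13c)


# -- EMU decomposition -------------------------------------------------------

EmuKey = tuple[str, tuple[int, ...]]  # (metabolite id, sorted 1-based positions)


@dataclass
class EmuTerm:
    """One production route of a target EMU: a reaction direction, the map
    weight, and the source EMUs (more than one = condensation)."""

    rxn_id: str
    sense: int
    weight: float
    sources: tuple[EmuKey, ...]


@dataclass
class EmuSystem:
    """Size-ordered EMU reaction systems reachable backward from the targets."""

    network: MetabolicNetwork
    targets: dict[str, list[EmuKey]]  # fragment -> component EMUs
    producers: dict[EmuKey, list[EmuTerm]]  # balanced-pool EMUs only
    boundary: set[EmuKey]

    def by_size(self) -> dict[int, list[EmuKey]]:
        out: dict[int, list[EmuKey]] = {}
        for emu in self.producers:
            out.setdefault(len(emu[1]), []).append(emu)
        return {s: sorted(v) for s, v in sorted(out.items())}

    @property
    def emus(self) -> set[EmuKey]:
        return set(self.producers) | self.boundary


def _directions(network: MetabolicNetwork, active=None):
    """All reaction directions with their product-side atom maps.

    Reverse-direction maps are the inverse bijection of the forward maps.
    ``active`` optionally restricts to a set of ``(rxn_id, sense)`` keys.
    """
    dirs = []
    for rxn in network.reactions.values():
        if not rxn.atom_maps:
            continue
        if active is None:
            senses = [+1, -1] if rxn.reversible else [+1]
        else:
            senses = [s for s in (+1, -1) if (rxn.id, s) in active]
        for sense in senses:
            maps = []
            for w, amap in rxn.atom_maps:
                maps.append((w, amap if sense > 0 else _invert_map(amap)))
            dirs.append((rxn.id, sense, maps))
    return dirs


def _invert_map(amap: AtomMap) -> AtomMap:
    inv: dict[str, dict[int, tuple[str, int]]] = {}
    for prod, sources in amap.items():
        for prod_idx, (sub, sub_idx) in enumerate(sources, start=1):
            inv.setdefault(sub, {})[sub_idx] = (prod, prod_idx)
    return {sub: tuple(m[i] for i in range(1, max(m) + 1)) for sub, m in inv.items()}


def emu_decompose(network: MetabolicNetwork, fragments: FragmentMap,
                  active=None) -> EmuSystem:
    """Minimal EMU set reachable backward from the target fragments.

    ``active`` may restrict the trace to reaction directions carrying flux;
    the structural decomposition (default) includes both directions of every
    reversible reaction.
    """
    dirs = _directions(network, active)
    producers_of: dict[str, list] = {}
    for rxn_id, sense, maps in dirs:
        for w, amap in maps:
            for prod in amap:
                producers_of.setdefault(prod, []).append((rxn_id, sense, w, amap))

    targets: dict[str, list[EmuKey]] = {}
    stack: list[EmuKey] = []
    for frag, parts in fragments.items():
        keys = []
        for met, pos in parts:
            if met not in network.metabolites:
                raise ValueError(f"fragment {frag!r}: unknown metabolite {met!r}")
            n = network.metabolites[met].carbon_count
            if any(not 1 <= p <= n for p in pos):
                raise ValueError(f"fragment {frag!r}: carbon positions {pos} out of range")
            keys.append((met, tuple(sorted(pos))))
        targets[frag] = keys
        stack.extend(keys)

    producers: dict[EmuKey, list[EmuTerm]] = {}
    boundary: set[EmuKey] = set()
    while stack:
        emu = stack.pop()
        met, pos = emu
        if emu in producers or emu in boundary:
            continue
        if network.metabolites[met].role == "exchange":
            boundary.add(emu)
            continue
        routes = producers_of.get(met, [])
        if not routes:
            raise ValueError(
                f"metabolite {met!r} required by fragment tracing has no atom-mapped producer")
        terms = []
        for rxn_id, sense, w, amap in routes:
            groups: dict[str, list[int]] = {}
            for p in pos:
                sub, idx = amap[met][p - 1]
                groups.setdefault(sub, []).append(idx)
            sources = tuple(sorted((sub, tuple(sorted(idxs)))
                                   for sub, idxs in groups.items()))
            terms.append(EmuTerm(rxn_id, sense, w, sources))
            stack.extend(sources)
        producers[emu] = terms
    return EmuSystem(network, targets, producers, boundary)


# -- EMU simulation ----------------------------------------------------------

def _consumption_flux(network, fluxes: FluxVector, met: str, strict=True) -> float:
    """Total flux consuming a metabolite pool (all reactions, mapped or not)."""
    total = 0.0
    for rxn_id, sense, f in fluxes.directional(network, strict=strict):
        coeff = network.reactions[rxn_id].stoichiometry.get(met, 0.0)
        if sense * coeff < 0:
            total += f * abs(coeff)
    return total


def simulate_mdvs(network: MetabolicNetwork, fluxes: FluxVector,
                  labeling: SubstrateLabeling, fragments: FragmentMap = None,
                  check_steady: bool = True, strict: bool = True) -> MDVSet:
    """Simulate fragment MDVs at isotopic steady state by cascaded EMU solves."""
    if fragments is None:
        fragments = DEFAULT_FRAGMENTS
    if check_steady:
        check_steady_state(network, fluxes)

    active = {(r, s) for r, s, _ in fluxes.directional(network, strict=strict)}
    flux_of = {(r, s): f for r, s, f in fluxes.directional(network, strict=strict)}
    system = emu_decompose(network, fragments, active=active)

    solved: dict[EmuKey, np.ndarray] = {}
    for emu in system.boundary:
        met, pos = emu
        n = network.metabolites[met].carbon_count
        solved[emu] = labeling.emu_mdv(met, pos, n)

    for size, emus in system.by_size().items():
        index = {e: i for i, e in enumerate(emus)}
        n = len(emus)
        A = np.zeros((n, n))
        b = np.zeros((n, size + 1))
        for emu, i in index.items():
            met, _ = emu
            out = _consumption_flux(network, fluxes, met, strict=strict)
            if out <= FLUX_TOL:
                raise SingularEMUError(
                    f"pool {met!r} has no consumption flux but is required for "
                    "fragment labeling (unreachable at this flux vector)")
            A[i, i] -= out
            for term in system.producers[emu]:
                f = flux_of.get((term.rxn_id, term.sense), 0.0) * term.weight
                if f <= FLUX_TOL:
                    continue
                if (len(term.sources) == 1 and term.sources[0] in index):
                    A[i, index[term.sources[0]]] += f
                else:
                    mdv = np.array([1.0])
                    for src in term.sources:
                        mdv = np.convolve(mdv, solved[src])
                    b[i] += f * mdv
        try:
            X = np.linalg.solve(A, -b)
        except np.linalg.LinAlgError as exc:
            raise SingularEMUError(f"singular EMU system at size {size}: {exc}") from exc
        for emu, i in index.items():
            solved[emu] = X[i]

    out = MDVSet()
    for frag, parts in system.targets.items():
        mdv = np.array([1.0])
        for key in parts:
            mdv = np.convolve(mdv, solved[key])
        mdv = np.clip(mdv, 0.0, None)
        out[frag] = MDV(frag, mdv / mdv.sum())
    return out


# -- brute-force isotopomer oracle ------------------------------------------

MAX_BRUTE_CARBONS = 25


def _marginal(dist: np.ndarray, n: int, positions: tuple[int, ...]) -> np.ndarray:
    """Marginalize a 2^n isotopomer distribution onto a carbon subset."""
    k = len(positions)
    out = np.zeros(2 ** k)
    for state in range(dist.size):
        sub = 0
        for j, p in enumerate(positions):
            if state >> (p - 1) & 1:
                sub |= 1 << j
        out[sub] += dist[state]
    return out


def _mdv_from_dist(dist: np.ndarray, n: int) -> np.ndarray:
    mdv = np.zeros(n + 1)
    for state in range(dist.size):
        mdv[bin(state).count("1")] += dist[state]
    return mdv


def brute_force_isotopomers(network: MetabolicNetwork, fluxes: FluxVector,
                            labeling: SubstrateLabeling,
                            fragments: FragmentMap = None,
                            tol: float = 1e-14, max_iter: int = 50000) -> MDVSet:
    """Steady-state isotopomer distributions by direct fixed-point solution.

    Independent of the EMU machinery: iterates the full positional-isotopomer
    balance over every balanced carbon-carrying pool until convergence, then
    marginalizes to fragment MDVs.  Restricted to networks with at most
    25 traced carbons.
    """
    if fragments is None:
        fragments = DEFAULT_FRAGMENTS
    check_steady_state(network, fluxes)
    carbon_mets = network.carbon_metabolites()
    total_c = sum(network.metabolites[m].carbon_count for m in carbon_mets)
    if total_c > MAX_BRUTE_CARBONS:
        raise ValueError(
            f"network has {total_c} traced carbons; brute-force enumeration is "
            f"limited to {MAX_BRUTE_CARBONS}")

    n_of = {m: network.metabolites[m].carbon_count for m in carbon_mets}
    dist = {m: np.zeros(2 ** n_of[m]) for m in carbon_mets}
    for m in carbon_mets:
        dist[m][0] = 1.0

    def boundary_dist(met):
        return labeling.isotopomer_dist(met, network.metabolites[met].carbon_count)

    # precompute production routes: (product met, flux, map restricted to product)
    routes: dict[str, list] = {m: [] for m in carbon_mets}
    for rxn_id, sense, f in fluxes.directional(network):
        rxn = network.reactions[rxn_id]
        if not rxn.atom_maps:
            continue
        for w, amap in ((w, a if sense > 0 else _invert_map(a)) for w, a in rxn.atom_maps):
            for prod, sources in amap.items():
                if prod in routes:
                    routes[prod].append((f * w, sources))

    outflux = {m: _consumption_flux(network, fluxes, m) for m in carbon_mets}

    def product_dist(prod, sources):
        """Distribution of the product pattern from independent substrate pools."""
        n = len(sources)
        groups: dict[str, list[tuple[int, int]]] = {}
        for prod_idx, (sub, sub_idx) in enumerate(sources, start=1):
            groups.setdefault(sub, []).append((prod_idx, sub_idx))
        result = np.ones(2 ** n)
        for sub, pairs in groups.items():
            sub_dist = (dist[sub] if sub in dist else boundary_dist(sub))
            sub_pos = tuple(si for _, si in pairs)
            marg = _marginal(sub_dist, 0, sub_pos)
            factor = np.zeros(2 ** n)
            for state in range(2 ** n):
                sub_state = 0
                for j, (pi, _) in enumerate(pairs):
                    if state >> (pi - 1) & 1:
                        sub_state |= 1 << j
                # only consistent if bits outside this group ignored -> use
                # multiplication of marginals across groups
                factor[state] = marg[sub_state]
            result *= factor
        return result

    for _ in range(max_iter):
        delta = 0.0
        new = {}
        for m in carbon_mets:
            if outflux[m] <= FLUX_TOL:
                new[m] = dist[m]
                continue
            acc = np.zeros_like(dist[m])
            for f, sources in routes[m]:
                acc += f * product_dist(m, sources)
            nd = acc / outflux[m]
            delta = max(delta, float(np.max(np.abs(nd - dist[m]))))
            new[m] = nd
        dist = new
        if delta < tol:
            break
    else:
        raise RuntimeError("isotopomer fixed-point iteration did not converge")

    out = MDVSet()
    for frag, parts in fragments.items():
        mdv = np.array([1.0])
        for met, pos in parts:
            d = dist[met] if met in dist else boundary_dist(met)
            part = _mdv_from_dist(_marginal(d, 0, tuple(sorted(pos))), len(pos))
            mdv = np.convolve(mdv, part)
        out[frag] = MDV(frag, mdv)
    return out
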