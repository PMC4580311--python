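"""Flux estimation from 13C labeling data by constrained least squares.

Net fluxes are parameterized on the null space of the stoichiometric matrix
(after applying hard equality constraints), so every candidate flux vector
satisfies steady state by construction.  The variance-weighted sum of squared
residuals

    SSR = sum(((sim - meas) / sd)^2)

over measured fragment MDVs and extracellular rates is minimized with a
bounded trust-region least-squares solver from multiple random feasible
starting points.  Measured rates enter as soft residuals (they carry
measurement error), irreversibility as smooth penalty terms on the null-space
coordinates.  Confidence intervals come from a parametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import least_squares, linprog

from .labeling import (FluxVector, FragmentMap, MDVSet, SubstrateLabeling,
                       DEFAULT_FRAGMENTS, simulate_mdvs)
from .network import MetabolicNetwork, stoichiometric_matrix

__all__ = [
    "InfeasibleError",
    "FreeFluxBasis",
    "MeasurementSet",
    "FitOptions",
    "FluxEstimate",
    "parameterize_free_fluxes",
    "fit_fluxes",
    "normalize_fluxes",
    "monte_carlo_ci",
]

DEFAULT_FLUX_BOUND = 1000.0


class InfeasibleError(ValueError):
    """The constraint set admits no flux vector (empty polytope)."""


class UnidentifiableWarning(UserWarning):
    """Some free fluxes are not constrained by the measurements."""


@dataclass
class FreeFluxBasis:
    """Affine parameterization ``v = v0 + N @ theta`` of the steady-state
    flux polytope after equality constraints."""

    network: MetabolicNetwork
    rxn_index: dict[str, int]
    v0: np.ndarray
    N: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    fixed: dict[str, float]

    @property
    def dim(self) -> int:
        return self.N.shape[1]

    def flux_dict(self, theta: np.ndarray) -> dict[str, float]:
        v = self.v0 + self.N @ np.atleast_1d(theta)
        return {r: float(v[j]) for r, j in self.rxn_index.items()}

    def flux_array(self, theta: np.ndarray) -> np.ndarray:
        if self.dim == 0:
            return self.v0.copy()
        return self.v0 + self.N @ np.atleast_1d(theta)


def default_bounds(network: MetabolicNetwork, overrides=None,
                   flux_bound=DEFAULT_FLUX_BOUND):
    lb, ub = {}, {}
    for rxn in network.reactions.values():
        lo = -flux_bound if rxn.reversible else 0.0
        lb[rxn.id], ub[rxn.id] = lo, flux_bound
    for r, (lo, hi) in (overrides or {}).items():
        lb[r], ub[r] = lo, hi
    return lb, ub


def parameterize_free_fluxes(network: MetabolicNetwork, fixed=None, bounds=None,
                             flux_bound=DEFAULT_FLUX_BOUND) -> FreeFluxBasis:
    """Null-space basis of the steady-state constraint restricted by hard
    equality constraints (``fixed``: reaction id -> flux value).

    Raises :class:`InfeasibleError` when the equalities contradict steady
    state or the irreversibility bounds leave an empty polytope.
    """
    fixed = dict(fixed or {})
    S, _, rxn_index, _ = stoichiometric_matrix(network)
    nr = S.shape[1]
    rows = [S]
    rhs = [np.zeros(S.shape[0])]
    for r, val in fixed.items():
        e = np.zeros(nr)
        e[rxn_index[r]] = 1.0
        rows.append(e[None, :])
        rhs.append([val])
    M = np.vstack(rows)
    b = np.concatenate(rhs)
    v0, *_ = np.linalg.lstsq(M, b, rcond=None)
    if np.max(np.abs(M @ v0 - b)) > 1e-8 * max(1.0, np.max(np.abs(b))):
        raise InfeasibleError("equality constraints are inconsistent with steady state")
    N = null_space(M)
    lbd, ubd = default_bounds(network, bounds, flux_bound)
    lb = np.array([lbd[r] for r in rxn_index])
    ub = np.array([ubd[r] for r in rxn_index])
    if np.any(lb > ub + 1e-12):
        raise InfeasibleError("contradictory bounds (lb > ub)")
    basis = FreeFluxBasis(network, rxn_index, v0, N, lb, ub, fixed)
    _feasible_theta(basis)  # raises if the polytope is empty
    return basis


def _feasible_theta(basis: FreeFluxBasis, cost=None):
    """A feasible point of the polytope lb <= v0 + N theta <= ub (LP)."""
    if basis.dim == 0:
        v = basis.v0
        if np.any(v < basis.lb - 1e-8) or np.any(v > basis.ub + 1e-8):
            raise InfeasibleError("fixed flux vector violates bounds")
        return np.zeros(0)
    c = np.zeros(basis.dim) if cost is None else cost
    A_ub = np.vstack([basis.N, -basis.N])
    b_ub = np.concatenate([basis.ub - basis.v0, basis.v0 - basis.lb])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * basis.dim,
                  method="highs")
    if not res.success:
        raise InfeasibleError(f"infeasible constraints (empty flux polytope): {res.message}")
    return res.x


@dataclass
class MeasurementSet:
    """Everything the fit is conditioned on: fragment MDVs with standard
    deviations, extracellular rates (reaction id -> (value, sd)), the
    substrate labeling design, and the fragment map."""

    mdvs: MDVSet
    rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    labeling: SubstrateLabeling = field(default_factory=SubstrateLabeling)
    fragments: FragmentMap = field(default_factory=lambda: dict(DEFAULT_FRAGMENTS))

    def __post_init__(self):
        for frag, mdv in self.mdvs.items():
            if mdv.sd is None or np.any(mdv.sd <= 0):
                raise ValueError(f"{frag}: measured MDVs need positive sds")
        for r, (_, sd) in self.rates.items():
            if sd <= 0:
                raise ValueError(f"rate {r}: sd must be > 0")

    @property
    def n_residuals(self) -> int:
        return sum(m.values.size for m in self.mdvs.values()) + len(self.rates)


@dataclass
class FitOptions:
    seed: int
    n_starts: int = 10
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    exch_reactions: tuple = ()
    exch_bound: float = None  # default: 10 x the measured-rate scale
    gtol: float = 1e-10
    xtol: float = 1e-12
    ftol: float = 1e-12
    penalty_weight: float = 1e4


@dataclass
class FluxEstimate:
    net: dict[str, float]
    exch: dict[str, float]
    ssr: float
    dof: int
    theta: np.ndarray
    basis: FreeFluxBasis
    start_log: list
    ci: dict = None
    normalization: dict = None
    unidentifiable: list = field(default_factory=list)

    def flux_vector(self) -> FluxVector:
        return FluxVector(dict(self.net), dict(self.exch))


def _residuals(params, basis, meas, exch_rxns, network, weight):
    k = basis.dim
    theta, exch_vals = params[:k], params[k:]
    v = basis.flux_array(theta)
    # simulate at the nearest bound-feasible point: outside the polytope the
    # labeling residuals stay frozen at their boundary value and the penalty
    # terms alone pull the iterate back inside
    v_sim = np.clip(v, basis.lb, basis.ub)
    fluxes = FluxVector({r: float(v_sim[j]) for r, j in basis.rxn_index.items()},
                        {r: float(e) for r, e in zip(exch_rxns, exch_vals)})
    res = []
    try:
        sim = simulate_mdvs(network, fluxes, meas.labeling, meas.fragments,
                            check_steady=False, strict=False)
        for frag, m in meas.mdvs.items():
            res.append((sim[frag].values - m.values) / m.sd)
    except (ValueError, np.linalg.LinAlgError):
        # infeasible direction pattern (e.g. zero-throughput pool): push back
        res.append(np.full(sum(m.values.size for m in meas.mdvs.values()), 1e3))
    for r, (val, sd) in meas.rates.items():
        res.append([(v[basis.rxn_index[r]] - val) / sd])
    viol = np.maximum(0.0, np.maximum(basis.lb - v, v - basis.ub))
    res.append(weight * viol)
    return np.concatenate([np.atleast_1d(np.asarray(r, dtype=float)) for r in res])


def fit_fluxes(network: MetabolicNetwork, measurements: MeasurementSet,
               options: FitOptions) -> FluxEstimate:
    """Estimate net (and optionally exchange) fluxes by variance-weighted
    least squares from ``n_starts`` random feasible initializations.

    Every candidate satisfies steady state exactly; irreversibility enters as
    penalty residuals.  The best converged start is returned together with a
    per-start log.  A rank check of the Jacobian at the optimum flags
    unidentifiable free-flux directions with a warning.
    """
    basis = parameterize_free_fluxes(network, fixed=options.fixed,
                                     bounds=options.bounds)
    rng = np.random.default_rng(options.seed)
    exch_rxns = tuple(options.exch_reactions)
    for r in exch_rxns:
        if not network.reactions[r].reversible:
            raise ValueError(f"exchange flux requested on irreversible reaction {r!r}")
    scale = max((abs(val) for val, _ in measurements.rates.values()), default=1.0)
    exch_hi = options.exch_bound if options.exch_bound is not None else 10.0 * scale

    def run(x0):
        lo = np.concatenate([np.full(basis.dim, -np.inf), np.zeros(len(exch_rxns))])
        hi = np.concatenate([np.full(basis.dim, np.inf),
                             np.full(len(exch_rxns), exch_hi)])
        return least_squares(
            _residuals, x0, bounds=(lo, hi), jac="3-point",
            args=(basis, measurements, exch_rxns, network, options.penalty_weight),
            method="trf", gtol=options.gtol, xtol=options.xtol, ftol=options.ftol)

    starts = []
    for _ in range(max(1, options.n_starts)):
        cost = rng.standard_normal(basis.dim)
        th = _feasible_theta(basis, cost)
        jitter = 0.05 * scale * rng.standard_normal(basis.dim)
        starts.append(np.concatenate([th + jitter,
                                      rng.uniform(0, 0.1 * exch_hi, len(exch_rxns))]))

    best, log = None, []
    for i, x0 in enumerate(starts):
        try:
            sol = run(x0)
        except Exception as exc:  # pragma: no cover - solver failure path
            log.append({"start": i, "status": "error", "message": str(exc)})
            continue
        ssr = float(np.sum(sol.fun ** 2))
        log.append({"start": i,
                    "status": "converged" if sol.success else "not-converged",
                    "ssr": ssr})
        if sol.success and (best is None or ssr < best[0]):
            best = (ssr, sol)
    if best is None:
        raise RuntimeError("no start converged")
    ssr, sol = best

    n_params = basis.dim + len(exch_rxns)
    dof = measurements.n_residuals - n_params
    unident = []
    if n_params:
        sv = np.linalg.svd(sol.jac, compute_uv=False)
        # absolute floor on the weighted-residual sensitivity: directions
        # that move the normalized residuals by less than ~1e-3 per unit
        # parameter are indistinguishable from finite-difference noise
        rank = int(np.sum(sv > 1e-3))
        if rank < n_params:
            _, _, Vt = np.linalg.svd(sol.jac)
            for row in Vt[rank:]:
                load = np.abs(basis.N @ row[:basis.dim]) if basis.dim else np.zeros(0)
                rxns = [r for r, j in basis.rxn_index.items() if load[j] > 1e-6]
                unident.extend(rxns)
            unident = sorted(set(unident))
            warnings.warn(
                f"measurement set is rank-deficient: {n_params - rank} free "
                f"direction(s) unidentifiable (fluxes: {unident})",
                UnidentifiableWarning, stacklevel=2)

    theta = sol.x[:basis.dim]
    net = basis.flux_dict(theta)
    exch = {r: float(e) for r, e in zip(exch_rxns, sol.x[basis.dim:])}
    return FluxEstimate(net=net, exch=exch, ssr=ssr, dof=dof, theta=sol.x,
                        basis=basis, start_log=log, unidentifiable=unident)


def carbon_transfer(network: MetabolicNetwork, rxn_id: str) -> float:
    """Carbon atoms moved per unit flux: summed carbons of non-cofactor
    products (equals the substrate side for a carbon-balanced reaction)."""
    rxn = network.reactions[rxn_id]
    return sum(coeff * network.metabolites[m].carbon_count
               for m, coeff in rxn.products.items()
               if network.metabolites[m].role != "cofactor")


def normalize_fluxes(network: MetabolicNetwork, net_flux: dict[str, float],
                     basis_reactions) -> dict[str, float]:
    """Express fluxes in %Cmol of substrate uptake.

    Each flux is converted to a carbon flux (flux x carbons transferred) and
    divided by the total carbon uptake of the basis reaction(s), x100.
    Invariant under uniform flux scaling.
    """
    if isinstance(basis_reactions, str):
        basis_reactions = [basis_reactions]
    basis_c = sum(net_flux[r] * carbon_transfer(network, r) for r in basis_reactions)
    if basis_c <= 0:
        raise ValueError("basis uptake carbon flux is zero")
    return {r: 100.0 * v * carbon_transfer(network, r) / basis_c
            for r, v in net_flux.items()}


def perturb_measurements(meas: MeasurementSet, rng) -> MeasurementSet:
    from .labeling import MDV
    mdvs = MDVSet()
    for frag, m in meas.mdvs.items():
        vals = np.clip(m.values + rng.normal(0.0, m.sd), 0.0, None)
        mdvs[frag] = MDV(frag, vals / vals.sum(), sd=m.sd.copy())
    rates = {r: (val + rng.normal(0.0, sd), sd) for r, (val, sd) in meas.rates.items()}
    return MeasurementSet(mdvs=mdvs, rates=rates, labeling=meas.labeling,
                          fragments=meas.fragments)


def monte_carlo_ci(network: MetabolicNetwork, measurements: MeasurementSet,
                   estimate: FluxEstimate, n_samples: int = 100, seed: int = 0,
                   level: float = 0.95, options: FitOptions = None) -> dict:
    """Parametric-bootstrap confidence intervals per net flux.

    Measurements are perturbed within their stated sds and refit from the
    point estimate (warm start, single start per replicate); percentile
    intervals of the refitted fluxes are returned.  Deterministic per seed.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    opts = options or FitOptions(seed=seed, n_starts=1)
    rng = np.random.default_rng(seed)
    exch_rxns = tuple(opts.exch_reactions)
    basis = estimate.basis
    samples = []
    lo = np.concatenate([np.full(basis.dim, -np.inf), np.zeros(len(exch_rxns))])
    hi = np.concatenate([np.full(basis.dim, np.inf),
                         np.full(len(exch_rxns), np.inf)])
    for _ in range(n_samples):
        pm = perturb_measurements(measurements, rng)
        sol = least_squares(
            _residuals, estimate.theta, bounds=(lo, hi), jac="3-point",
            args=(basis, pm, exch_rxns, network, opts.penalty_weight),
            method="trf", gtol=opts.gtol, xtol=opts.xtol, ftol=opts.ftol)
        samples.append(basis.flux_array(sol.x[:basis.dim]))
    arr = np.array(samples)
    a = (1.0 - level) / 2.0
    lo_q, hi_q = np.quantile(arr, [a, 1.0 - a], axis=0)
    return {r: (float(lo_q[j]), float(hi_q[j])) for r, j in basis.rxn_index.items()}
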